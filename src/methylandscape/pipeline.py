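"""End-to-end two-genotype methylome comparison.

``run_comparison`` drives the whole analysis — simulate (or load) two
per-cytosine methylomes, conversion QC, binned CG levels and differential
bins, chromatin-state model and methylation association, CH context tables
— and writes a machine-readable summary plus TSV tables under one output
directory.  Identical config + seed gives byte-identical outputs; all
randomness fans out from the single top-level seed through labeled
sub-seeds.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, chromatin, differential, noncg
from .conversion import estimate_conversion
from .errors import StageError
from .io import merge_cg_strands, write_bed, write_cytosine_report, write_fasta
from .simulate import (DEFAULT_CONTROL, DEFAULT_MUTANT, FixtureConfig, GenotypeParams,
                       classify_contexts, generate_genome, simulate_mark_tracks,
                       simulate_methylome)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one comparison run needs; exactly two genotypes."""

    outdir: Path = Path("methylandscape_run")
    seed: int = 0
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    control: GenotypeParams = DEFAULT_CONTROL
    test: GenotypeParams = DEFAULT_MUTANT
    # user-supplied inputs override simulation when set
    control_report: Path | None = None
    test_report: Path | None = None
    bin_size: int = 10_000
    min_sites_per_bin: int = 5
    cg_threshold_pct: float = 20.0
    ca_threshold_pct: float = 10.0
    site_min_depth: int = 16  # "depth > 15"
    delta_breaks: tuple[float, ...] = (20.0, 40.0, 60.0)
    window: int = 200
    n_states: int = 8
    binarize_p: float = 1e-4
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-2
    write_intermediate: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for thr in (self.cg_threshold_pct, self.ca_threshold_pct):
            if thr <= 0:
                raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("control", "test"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = GenotypeParams(**raw[key])
        if "fixture" in raw and isinstance(raw["fixture"], dict):
            if "contigs" in raw["fixture"]:
                raw["fixture"]["contigs"] = tuple(
                    (str(n), int(l)) for n, l in raw["fixture"]["contigs"])
            raw["fixture"] = FixtureConfig(**raw["fixture"])
        return cls(**raw)

    def subseed(self, k: int) -> int:
        return (int(self.seed) * 1009 + k) % (2**31)


@contextmanager
def _stage(name: str):
    log.info("stage: %s", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_comparison(config: RunConfig) -> dict:
    """Run the full comparison; returns the summary dict (also written as
    ``summary.json`` alongside TSV tables in ``config.outdir``)."""
    for label in ("control_report", "test_report"):
        path = getattr(config, label)
        if path is not None and not Path(path).exists():
            raise StageError(f"stage 'inputs' failed: missing {label} path {path}")
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": int(config.seed),
                     "genotypes": [config.control.name, config.test.name]}

    with _stage("genome"):
        genome = generate_genome(config.fixture, seed=config.subseed(1))
        main_sizes = {c: s for c, s in genome.sizes.items()
                      if c != genome.spike_in_name}
        templates = classify_contexts(genome)

    with _stage("mark_tracks"):
        marks_track = simulate_mark_tracks(genome, seed=config.subseed(2))

    with _stage("methylomes"):
        if config.control_report is not None:
            from .io import read_cytosine_report
            m_control = read_cytosine_report(config.control_report)
            m_test = read_cytosine_report(config.test_report)
        else:
            m_control = simulate_methylome(
                genome, replace(config.control, seed=config.subseed(3)), templates)
            m_test = simulate_methylome(
                genome, replace(config.test, seed=config.subseed(4)), templates)

    with _stage("conversion_qc"):
        qc = {}
        for name, rec in ((config.control.name, m_control),
                          (config.test.name, m_test)):
            est = estimate_conversion(rec, genome.spike_in_name)
            qc[name] = {"conversion_rate": est.rate, "error_rate": est.error_rate,
                        "n_cytosines": est.n_cytosines_observed,
                        "total_depth": est.total_depth}
        summary["conversion_qc"] = qc

    with _stage("cg_levels"):
        main_control = m_control[m_control["chrom"] != genome.spike_in_name]
        main_test = m_test[m_test["chrom"] != genome.spike_in_name]
        cg_control = merge_cg_strands(main_control[main_control["context"] == "CG"])
        cg_test = merge_cg_strands(main_test[main_test["context"] == "CG"])
        summary["global_cg_level"] = {
            config.control.name: binning.global_level(cg_control, "CG"),
            config.test.name: binning.global_level(cg_test, "CG")}
        bins_control = binning.bin_levels(
            cg_control, config.bin_size, "CG", min_sites=config.min_sites_per_bin,
            contig_sizes=main_sizes)
        bins_test = binning.bin_levels(
            cg_test, config.bin_size, "CG", min_sites=config.min_sites_per_bin,
            contig_sizes=main_sizes)
        hist = binning.level_histogram(bins_control)
        hist["count_test"] = binning.level_histogram(bins_test)["count"]
        hist.to_csv(outdir / "cg_bin_histogram.tsv", sep="\t", index=False)

    with _stage("differential_cg"):
        cmp_cg = differential.compare(bins_control, bins_test,
                                      config.cg_threshold_pct)
        strata = differential.stratify_by_delta(cmp_cg, config.delta_breaks)
        summary["cg_differential"] = {
            "threshold_pct": config.cg_threshold_pct,
            "n_paired_bins": cmp_cg.n_paired,
            "n_hyper": len(cmp_cg.hyper), "n_hypo": len(cmp_cg.hypo),
            "strata_sizes": {k: len(v) for k, v in strata.items()}}

    with _stage("annotation_levels"):
        ann = {}
        for name, rec in ((config.control.name, cg_control),
                          (config.test.name, cg_test)):
            ann[name] = binning.annotation_levels(rec, genome.domains, "CG")["level"]
        ann_tbl = pd.DataFrame(ann)
        ann_tbl["gain"] = ann_tbl[config.test.name] - ann_tbl[config.control.name]
        ann_tbl.to_csv(outdir / "annotation_levels.tsv", sep="\t")
        summary["annotation_gain"] = ann_tbl["gain"].to_dict()

    with _stage("chromatin_states"):
        matrix = chromatin.binarize_tracks(
            marks_track, p_threshold=config.binarize_p,
            exclude_contigs=[genome.spike_in_name])
        model = chromatin.fit_hmm(matrix, config.n_states,
                                  seed=config.subseed(5),
                                  max_iter=config.hmm_max_iter,
                                  tol=config.hmm_tol)
        track = chromatin.decode(model, matrix)
        order = model.state_order_by_emission("H3K36me3")
        frames = model.to_frames()
        frames["emission"].to_csv(outdir / "state_emissions.tsv", sep="\t")
        summary["chromatin"] = {
            "n_states": config.n_states,
            "final_log_likelihood": model.log_likelihood_trace[-1],
            "occupancy": track.occupancy,
            "display_order_by_k36me3": (order + 1)}

    with _stage("state_methylation"):
        per_state = {}
        for name, rec in ((config.control.name, cg_control),
                          (config.test.name, cg_test)):
            lv = binning.site_levels(rec, config.site_min_depth)
            per_state[name] = chromatin.state_methylation(track, lv)
        tbl = pd.concat(per_state, axis=1)
        tbl.to_csv(outdir / "state_methylation.tsv", sep="\t")
        summary["state_methylation_median"] = {
            name: per_state[name]["median"].to_dict() for name in per_state}
        comp = chromatin.state_composition(track, strata, config.bin_size)
        comp.to_csv(outdir / "state_composition_by_stratum.tsv", sep="\t")
        summary["state_composition"] = {
            label: comp.loc[label].to_dict() for label in comp.index}

    with _stage("ch_methylation"):
        ch = {}
        for name, rec in ((config.control.name, main_control),
                          (config.test.name, main_test)):
            tbl = noncg.ch_levels(rec, "dinucleotide")
            ch[name] = tbl["level"]
            pref = noncg.next_nucleotide_preference(rec, genome)
            pref.to_csv(outdir / f"next_base_preference_{name}.tsv", sep="\t")
            summary.setdefault("next_base_preference", {})[name] = \
                pref["preference"].to_dict()
        ca_control = binning.bin_levels(main_control, config.bin_size, "CA",
                                        min_sites=config.min_sites_per_bin,
                                        contig_sizes=main_sizes)
        ca_test = binning.bin_levels(main_test, config.bin_size, "CA",
                                     min_sites=config.min_sites_per_bin,
                                     contig_sizes=main_sizes)
        cmp_ca = differential.compare(ca_control, ca_test, config.ca_threshold_pct)
        pd.DataFrame(ch).to_csv(outdir / "ch_dinucleotide_levels.tsv", sep="\t")
        summary["ch_levels"] = {name: s.to_dict() for name, s in ch.items()}
        summary["ca_differential"] = {
            "threshold_pct": config.ca_threshold_pct,
            "n_hyper": len(cmp_ca.hyper), "n_hypo": len(cmp_ca.hypo)}

    with _stage("write_outputs"):
        if config.write_intermediate:
            write_fasta(genome.contigs, outdir / "genome.fa")
            write_bed(genome.domains, outdir / "domains.bed")
            marks_track.to_csv(outdir / "mark_counts.tsv", sep="\t", index=False)
            write_cytosine_report(m_control,
                                  outdir / f"{config.control.name}.cov.tsv.gz")
            write_cytosine_report(m_test, outdir / f"{config.test.name}.cov.tsv.gz")
        bins_control.to_tsv(outdir / f"cg_bins_{config.control.name}.tsv")
        bins_test.to_tsv(outdir / f"cg_bins_{config.test.name}.tsv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary


__all__ = ["RunConfig", "run_comparison"]
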