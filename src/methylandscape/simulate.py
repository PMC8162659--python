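"""Synthetic genomes, histone-mark tracks and genotype-specific methylomes.

The generator emulates the statistical structure of an oocyte methylome
contrast between a wild-type-like control and a DNMT3A-PWWP-mutant-like
genotype:

* a chromatin landscape of labeled domains — transcribed/H3K36-marked,
  Polycomb/H3K27me3, bivalent (K4me3+K27me3), H3K9me2 blocks, a pericentric
  satellite tandem array, and unmarked remainder — laid out as contiguous
  blocks along each contig;
* bimodal CG methylation coupled to the K36 domains (high in transcribed
  chromatin, low elsewhere) in the control;
* a mutant-specific additive CG gain confined to chromatin lacking
  H3K36me2/3, largest on the satellite array;
* CA-dominant CH methylation with a next-base (3' of the CH dinucleotide)
  preference, the hallmark of DNMT3A flanking preference;
* an unmethylated spike-in contig whose apparent methylation is pure
  bisulfite conversion error.

All randomness is driven by explicit integer seeds through
``numpy.random.default_rng``; every function is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AnnotationSet, classify_contexts

UNMARKED = "unmarked"
SATELLITE = "satellite_array"

DEFAULT_DOMAIN_FRACTIONS: dict[str, float] = {
    "transcribed_k36": 0.30,
    "polycomb_k27": 0.20,
    "bivalent": 0.05,
    "k9me2_block": 0.10,
}

#: mark -> {domain label: Poisson fold-enrichment over background}
DEFAULT_MARK_ENRICHMENT: dict[str, dict[str, float]] = {
    "H3K36me3": {"transcribed_k36": 8.0},
    "H3K36me2": {"transcribed_k36": 6.0},
    "H3K27me3": {"polycomb_k27": 8.0, "bivalent": 6.0, SATELLITE: 4.0},
    "H3K4me3": {"bivalent": 8.0},
    "H3K9me2": {"k9me2_block": 6.0, SATELLITE: 2.0},
}


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic genome."""

    contigs: tuple[tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 500_000))
    spike_in_name: str = "lambda_spike"
    spike_in_length: int = 48_502
    gc_content: float = 0.42
    domain_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_FRACTIONS))
    satellite_monomer_length: int = 234
    satellite_copies: int = 100  # one tandem array per contig
    block_length: int = 25_000  # granularity of domain placement

    def validate(self) -> None:
        if self.spike_in_length <= 0 or self.satellite_monomer_length <= 0:
            raise ConfigError("lengths must be positive")
        for name, length in self.contigs:
            sat = self.satellite_monomer_length * self.satellite_copies
            total = sum(self.domain_fractions.values()) + sat / length
            if total > 1.0:
                raise ConfigError(
                    f"domain fractions + satellite occupy {total:.3f} > 1 of {name}")
        if not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0,1)")


@dataclass
class GenomeFixture:
    """A small synthetic genome with labeled chromatin domains."""

    contigs: list[tuple[str, str]]
    spike_in_name: str
    domains: AnnotationSet

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs}

    def main_contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs if name != self.spike_in_name]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def generate_genome(config: FixtureConfig = FixtureConfig(), seed: int = 0) -> GenomeFixture:
    """Build contig sequences plus a non-overlapping domain annotation layer.

    Domains are placed as shuffled contiguous blocks of roughly
    ``config.block_length`` bp so that each label's total length matches its
    requested fraction up to block granularity.  The satellite array is a
    literal tandem repeat of one random monomer, written into the contig
    sequence.  The spike-in contig carries no domain labels.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    monomer = _random_sequence(rng, config.satellite_monomer_length, 0.30)
    sat_len = config.satellite_monomer_length * config.satellite_copies
    contigs: list[tuple[str, str]] = []
    rows: list[tuple[str, int, int, str]] = []
    for name, length in config.contigs:
        seq = list(_random_sequence(rng, length, config.gc_content))
        blocks: list[tuple[str, int]] = [(SATELLITE, sat_len)]
        for label, frac in config.domain_fractions.items():
            target = int(round(frac * length))
            n_blocks = max(1, int(round(target / config.block_length)))
            per, extra = divmod(target, n_blocks)
            blocks += [(label, per + (1 if i < extra else 0)) for i in range(n_blocks)]
        labeled = sum(b for _, b in blocks)
        free = length - labeled
        n_un = max(1, int(round(free / config.block_length)))
        per, extra = divmod(free, n_un)
        blocks += [(UNMARKED, per + (1 if i < extra else 0)) for i in range(n_un)]
        order = rng.permutation(len(blocks))
        cursor = 0
        for i in order:
            label, blen = blocks[i]
            if blen == 0:
                continue
            rows.append((name, cursor, cursor + blen, label))
            if label == SATELLITE:
                tandem = (monomer * (blen // len(monomer) + 1))[:blen]
                seq[cursor:cursor + blen] = list(tandem)
            cursor += blen
        contigs.append((name, "".join(seq)))
    contigs.append((config.spike_in_name,
                    _random_sequence(rng, config.spike_in_length, 0.50)))
    domains = AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
    return GenomeFixture(contigs=contigs, spike_in_name=config.spike_in_name,
                         domains=domains)


# ---------------------------------------------------------------------------
# histone-mark count tracks
# ---------------------------------------------------------------------------

def _window_domain_labels(genome: GenomeFixture, chrom: str,
                          starts: np.ndarray, window: int) -> np.ndarray:
    """Domain label at each window midpoint; '' on the spike-in / gaps."""
    labels = np.full(len(starts), "", dtype=object)
    mids = starts + window // 2
    iv = genome.domains.intervals
    for s, e, lab in iv.loc[iv["chrom"] == chrom, ["start", "end", "label"]
                            ].itertuples(index=False):
        labels[(mids >= s) & (mids < e)] = lab
    return labels


def simulate_mark_tracks(
    genome: GenomeFixture,
    marks: Sequence[str] | None = None,
    window: int = 200,
    enrichment: Mapping[str, Mapping[str, float]] | None = None,
    background_rate: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson read-count tracks in fixed windows, one column per mark.

    A window's mean is ``background_rate`` times its domain's fold-enrichment
    for the mark (1.0 outside mapped domains); the spike-in contig gets
    background only.
    """
    if enrichment is None:
        enrichment = DEFAULT_MARK_ENRICHMENT
    if marks is None:
        marks = list(enrichment)
    known = set(genome.domains.labels) | {UNMARKED, SATELLITE}
    for mark in marks:
        if mark not in enrichment:
            raise ConfigError(f"no domain mapping for mark {mark!r}")
        unknown = set(enrichment[mark]) - known
        if unknown:
            raise ConfigError(f"mark {mark!r} maps unknown domains {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    frames = []
    for chrom, seq in genome.contigs:
        starts = np.arange(0, len(seq), window)
        labels = _window_domain_labels(genome, chrom, starts, window)
        cols = {"chrom": np.repeat(chrom, len(starts)), "start": starts,
                "end": np.minimum(starts + window, len(seq))}
        for mark in marks:
            fold = np.ones(len(starts))
            if chrom != genome.spike_in_name:
                for dom, f in enrichment[mark].items():
                    fold[labels == dom] = f
            cols[mark] = rng.poisson(background_rate * fold)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype methylation parameters.

    CG methylation probability is set per chromatin domain
    (``cg_level_by_domain`` plus the additive ``cg_gain_by_domain``, clipped
    to [0,1]).  CH methylation is a dinucleotide base rate modulated by the
    base 3' of the CH site (``next_base_weights``, rescaled to mean 1).
    ``conversion_error`` is the probability that a truly unmethylated C is
    read as methylated (bisulfite conversion failure); it acts only in that
    direction.
    """

    name: str
    cg_level_by_domain: Mapping[str, float]
    ch_level_by_dinucleotide: Mapping[str, float]
    cg_gain_by_domain: Mapping[str, float] = field(default_factory=dict)
    next_base_weights: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0})
    conversion_error: float = 0.005
    depth_mean: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        for p in list(self.cg_level_by_domain.values()) + \
                list(self.ch_level_by_dinucleotide.values()):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0,1]")
        if not 0.0 <= self.conversion_error <= 1.0:
            raise ConfigError("conversion_error outside [0,1]")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be > 0")
        if any(w < 0 for w in self.next_base_weights.values()):
            raise ConfigError("next_base_weights must be non-negative")


# Defaults calibrated to the oocyte contrast: bimodal control CG landscape
# (~37% global), mutant gain confined to chromatin lacking K36me2/3 with the
# satellite array gaining most, CA-dominant CH rising from 5.9% to 7.2%.
DEFAULT_CONTROL = GenotypeParams(
    name="control",
    cg_level_by_domain={"transcribed_k36": 0.90, "polycomb_k27": 0.10,
                        "bivalent": 0.08, "k9me2_block": 0.15,
                        SATELLITE: 0.25, UNMARKED: 0.15},
    ch_level_by_dinucleotide={"CA": 0.059, "CT": 0.012, "CC": 0.008},
    next_base_weights={"A": 1.0, "C": 1.8, "G": 0.6, "T": 1.0},
    conversion_error=0.005,
    depth_mean=30.0,
    seed=11,
)

DEFAULT_MUTANT = replace(
    DEFAULT_CONTROL,
    name="mutant",
    cg_gain_by_domain={"polycomb_k27": 0.35, "k9me2_block": 0.30,
                       UNMARKED: 0.30, SATELLITE: 0.50, "bivalent": 0.10,
                       "transcribed_k36": 0.0},
    ch_level_by_dinucleotide={"CA": 0.072, "CT": 0.014, "CC": 0.009},
    seed=13,
)


def _site_domain_labels(genome: GenomeFixture, templates: pd.DataFrame) -> np.ndarray:
    """Domain label for every template row ('' on the spike-in)."""
    labels = np.full(len(templates), "", dtype=object)
    iv = genome.domains.intervals
    pos0 = templates["pos"].to_numpy() - 1
    chroms = templates["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        sub = iv[iv["chrom"] == chrom].sort_values("start")
        if not len(sub):
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        labs = sub["label"].to_numpy()
        idx = np.searchsorted(starts, pos0[mask], side="right") - 1
        ok = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
        vals = np.full(mask.sum(), "", dtype=object)
        vals[ok] = labs[idx[ok]]
        labels[mask] = vals
    return labels


def site_methylation_probabilities(genome: GenomeFixture, params: GenotypeParams,
                                   templates: pd.DataFrame | None = None
                                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (templates, per-row true methylation probability p).

    CG rows take the domain level (+ gain, clipped); CH rows take the
    dinucleotide level scaled by the next-base weight (mean-1 normalized,
    clipped); spike-in rows get p = 0.  Exposed separately from the sampler
    so tests can check the probability model without sampling noise.
    """
    params.validate()
    if templates is None:
        templates = classify_contexts(genome)
    labels = _site_domain_labels(genome, templates)
    tri = templates["tri"].to_numpy()
    context = templates["context"].to_numpy()
    p = np.zeros(len(templates))
    is_cg = context == "CG"
    cg_levels = {d: min(1.0, max(0.0, v + params.cg_gain_by_domain.get(d, 0.0)))
                 for d, v in params.cg_level_by_domain.items()}
    for dom, lvl in cg_levels.items():
        p[is_cg & (labels == dom)] = lvl
    w = params.next_base_weights
    dinuc = np.array([t[:2] for t in tri])
    nxt = np.array([t[2] for t in tri])
    wvals = np.array([w.get(b, 0.0) if b in "ACGT" else 0.0 for b in nxt])
    for d, lvl in params.ch_level_by_dinucleotide.items():
        group = ~is_cg & (dinuc == d) & np.isin(nxt, list("ACGT"))
        if not group.any():
            continue
        # normalize by the group's mean weight so the pooled true level of
        # the dinucleotide equals the configured level
        p[group] = np.clip(lvl * wvals[group] / wvals[group].mean(), 0.0, 1.0)
    p[templates["chrom"].to_numpy() == genome.spike_in_name] = 0.0
    return templates, p


def simulate_methylome(genome: GenomeFixture, params: GenotypeParams,
                       templates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw a per-cytosine methylome as a record frame.

    Per strand-resolved cytosine: depth ~ Poisson(depth_mean) and
    methylated count ~ Binomial(depth, p + (1-p)·conversion_error).  Both
    strands of a CpG share the same site-level p (CpG symmetry) but are
    sampled independently; CH sites are independent per strand.  Zero-depth
    rows are kept (they are "uncovered", not level-0).
    """
    templates, p = site_methylation_probabilities(genome, params, templates)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 303]))
    p_eff = p + (1.0 - p) * params.conversion_error
    depth = rng.poisson(params.depth_mean, size=len(templates))
    meth = rng.binomial(depth, p_eff)
    out = templates.copy()
    out["count_meth"] = meth
    out["count_unmeth"] = depth - meth
    return out
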