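"""Shared fixtures: a small fast genome for unit tests and the full default
synthetic comparison (built once per session) for end-to-end checks."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pytest

from methylandscape import (DEFAULT_CONTROL, DEFAULT_MUTANT, FixtureConfig,
                            binarize_tracks, bin_levels, classify_contexts,
                            compare, decode, fit_hmm, generate_genome,
                            merge_cg_strands, simulate_mark_tracks,
                            simulate_methylome, stratify_by_delta)

SMALL_CONFIG = FixtureConfig(
    contigs=(("chr1", 60_000), ("chr2", 60_000)),
    spike_in_length=8_000,
    satellite_copies=10,
    block_length=5_000,
)


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(SMALL_CONFIG, seed=5)


@pytest.fixture(scope="session")
def small_templates(small_genome):
    return classify_contexts(small_genome)


@pytest.fixture(scope="session")
def small_methylome(small_genome, small_templates):
    return simulate_methylome(small_genome, replace(DEFAULT_CONTROL, seed=21),
                              small_templates)


@dataclass
class SyntheticComparison:
    """The default wild-type-vs-mutant contrast, fully analysed."""

    genome: object
    control: object  # record frames, spike-in included
    mutant: object
    cg_control: object  # strand-merged CG records, main contigs only
    cg_mutant: object
    bins_control: object
    bins_mutant: object
    comparison: object
    strata: dict
    matrix: object
    model: object
    track: object


@pytest.fixture(scope="session")
def fgo_comparison():
    """Default-scale synthetic oocyte contrast (the study conditions)."""
    genome = generate_genome(FixtureConfig(), seed=1)
    templates = classify_contexts(genome)
    control = simulate_methylome(genome, replace(DEFAULT_CONTROL, seed=101),
                                 templates)
    mutant = simulate_methylome(genome, replace(DEFAULT_MUTANT, seed=102),
                                templates)
    sizes = {c: s for c, s in genome.sizes.items() if c != genome.spike_in_name}
    cg = {}
    bins = {}
    for name, rec in (("control", control), ("mutant", mutant)):
        main = rec[rec["chrom"] != genome.spike_in_name]
        cg[name] = merge_cg_strands(main[main["context"] == "CG"])
        bins[name] = bin_levels(cg[name], 10_000, "CG", min_sites=5,
                                contig_sizes=sizes)
    cmp = compare(bins["control"], bins["mutant"], 20.0)
    strata = stratify_by_delta(cmp, (20.0, 40.0, 60.0))
    marks = simulate_mark_tracks(genome, seed=103)
    matrix = binarize_tracks(marks, exclude_contigs=[genome.spike_in_name])
    model = fit_hmm(matrix, n_states=8, seed=104)
    track = decode(model, matrix)
    return SyntheticComparison(
        genome=genome, control=control, mutant=mutant,
        cg_control=cg["control"], cg_mutant=cg["mutant"],
        bins_control=bins["control"], bins_mutant=bins["mutant"],
        comparison=cmp, strata=strata, matrix=matrix, model=model, track=track)
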