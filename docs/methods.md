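# Methods

## Scope and data model

The package analyses per-cytosine bisulfite methylation calls (the
Bismark cytosine-report dialect) and windowed histone-mark read counts.
Alignment, trimming and methylation calling are upstream of this artifact;
its atomic observation is one strand-resolved cytosine with methylated and
unmethylated read counts, a context class (CG/CHG/CHH) and its
trinucleotide. Internally intervals are 0-based half-open; cytosine
reports are 1-based; BED/bedGraph exports are 0-based half-open. All
coordinate conversions live in `methylandscape.io`.

## Weighted methylation

Every level in the package is a *weighted* level: pooled methylated counts
divided by pooled total counts over the sites of a region, never the mean
of per-site fractions. Weighted levels are invariant to reordering records
and to splitting a site's counts across records, and the global level
equals the depth-weighted mean of bin levels — properties the test suite
asserts. Bins tile each contig from coordinate 0; the last, truncated bin
is kept and flagged `partial`. A bin with fewer than `min_sites` covered
sites (default 5 per 10-kb bin, exposed as a parameter) or below a pooled
depth floor is *missing* (NaN), which differential calling treats as
absent — missing is never 0. CpG strand merging sums the counts of the
plus-strand C at p and the minus-strand C at p+1 into one record keyed to
p; site-level analyses use strand-merged CG sites by default, while CH
analyses stay strand-resolved.

## Differential bins

Two bin tracks on the same grid are paired on bins non-missing in both;
the per-bin delta is test − control in percentage points. Hyper/hypo sets
use inclusive thresholds (Δ ≥ 20 for CG, Δ ≥ 10 for CA by convention).
No significance test is applied — the contrast is a fixed-threshold call,
matching the practice this package reimplements. Venn overlap percentages
are 100·|A∩B|/|A| (and /|B|); the percentage of an empty set is reported
as undefined rather than 0. Hyper bins are stratified by delta into
intervals `[b_i, b_{i+1})` with the last stratum closed at 100; when the
first break equals the calling threshold the strata partition the hyper
set exactly.

## Chromatin-state model

Chromatin states are learned from binarized mark calls in fixed windows
(default 200 bp). Binarization uses a genome-wide Poisson background per
mark: a window with count c is called present iff P(X ≥ c; λ = mean
count) < 1e-4. No input-control track or local background is modeled;
both the window size and the p-threshold are parameters.

The state model is a first-order HMM whose emission for state s is a
product of independent Bernoullis over marks, with per-contig sequence
resets. Fitting is Baum-Welch EM using the scaled (normalized)
forward-backward recursions; emission log-likelihood matrices are
computed in log space and row-rescaled before scaling, so long sequences
and near-degenerate emissions stay finite. Numerical guards: emissions
are clamped to [1e-6, 1−1e-6], transitions receive a 1e-6 pseudocount,
and the log-likelihood is asserted non-decreasing at every iteration
(within 1e-6 relative round-off; a violation raises rather than
continuing). Initialization draws emissions from seeded uniform(0.2, 0.8)
and uniform transitions; a single restart is the default with an optional
best-of-n restart mode. EM stops when the improvement drops below `tol`
(default 0.01 nats) or at `max_iter` (default 100). State labels are
identifiable only up to permutation; for display, states can be ordered
by descending H3K36me3 emission. The state count is always an explicit
parameter (8 for the five-mark panel, 5 for a three-mark panel, by
convention) — it is never inferred.

Decoding is posterior argmax per window (ties toward the lowest state
index). Per-state methylation summaries take single-site CG levels
(depth > 15 by default), map each site to its window's state, and report
median and quartiles. Stratum composition is the fraction of windows of
each state among all windows inside a stratum's bins; it requires the bin
size to be a multiple of the window size.

## Conversion QC

The bisulfite conversion rate pools all contexts over the unmethylated
spike-in contig: rate = Σ unmethylated / Σ total. Per-context estimation
and per-site depth filters are omitted deliberately — pooling dominates
the noise — and zero spike-in coverage is an explicit QC failure, not a
rate of 0. The rate is reported as QC only; levels are not corrected.

## CH methylation

CH levels are pooled per dinucleotide (CA/CT/CC) or per trinucleotide,
strand-resolved, with CG records excluded; dinucleotide levels are by
construction the count-weighted mean of their trinucleotide levels. The
next-base preference weights each CH site's following base (the third
base of the trinucleotide, on the cytosine's own strand) by its
methylated read count, normalized to a distribution over {A,C,G,T}; the
background uses total counts instead. Methylated-count weighting is used
because no site-level "methylated CH" calling rule is established; no
depth threshold is applied by default.

## Synthetic-data generator

The generator emulates an oocyte-like contrast between a control and a
PWWP-mutant-like genotype. What it models:

- **Genome** — by default two 500-kb contigs plus a 48,502-bp spike-in
  (lambda-phage length), random sequence at 42% GC. Chromatin domains are
  contiguous blocks (≈25 kb granularity) tiling each contig:
  transcribed/K36 30%, Polycomb/K27 20%, bivalent 5%, K9me2 block 10%, one
  satellite tandem array (234-bp monomer × 100 copies — a literal tandem
  repeat written into the sequence), remainder unmarked. The small scale
  keeps the full pipeline in seconds while leaving ~100 bins of 10 kb and
  ~43k merged CpGs — enough for every downstream statistic.
- **Mark tracks** — Poisson counts per 200-bp window, mean = background
  (5 reads/window) × a per-domain fold-enrichment (K36 marks over
  transcribed domains, K27 over Polycomb/bivalent/satellite, K4me3 over
  bivalent, K9me2 over its blocks); spike-in windows get background only.
- **Methylomes** — per cytosine, depth ~ Poisson(30) and methylated count
  ~ Binomial(depth, p + (1−p)·ε) where ε is the conversion error (0.005
  by default, acting only in the unmethylated→methylated direction; over-
  conversion of 5mC is ignored) and p is the true methylation
  probability: per-domain CG levels (control: 0.90 transcribed, 0.10-0.15
  elsewhere, 0.25 satellite — a bimodal landscape pooling to ≈37%
  globally), plus an additive mutant gain confined to domains lacking
  K36 (0.35 Polycomb, 0.30 K9me2/unmarked, 0.50 satellite, 0.10 bivalent,
  0 transcribed), clipped to [0,1]. Both strands of a CpG share the site
  p (CpG symmetry) but are sampled independently; CH sites are
  independent per strand. CH probabilities are dinucleotide base rates
  (control CA/CT/CC = 5.9/1.2/0.8%, mutant CA = 7.2% — the printed global
  CA levels of the contrast this emulates) scaled by a next-base weight
  (A:1.0, C:1.8, G:0.6, T:1.0 — DNMT3A-like C preference), normalized by
  the genome's empirical mean weight per dinucleotide so the pooled true
  level equals the configured rate. Apparent levels sit ≈ (1−p)·ε above
  the true ones because conversion failure is part of the observation
  model, exactly as in real WGBS.

What it does **not** model: read-level sequence simulation, alignment or
mapping bias, PBAT-specific coverage structure (depth is plain Poisson),
CpG-island fine structure, copy-number variation of the satellite, or any
error mode beyond the single conversion-error scalar. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under a faithful statistical cartoon, not performance on real
mouse data.

The mutant's per-domain gain magnitudes are genuinely unconstrained by
any published quantity; they were chosen once so that the qualitative
pattern of the real contrast emerges — hyper bins concentrated outside
K36 chromatin, satellite with the largest annotation gain, no hypo bins —
and are ordinary parameters of `GenotypeParams`, not assertions about
effect sizes in vivo.

## Determinism and problem sizes

Every stochastic routine takes an explicit integer seed through
`numpy.random.default_rng`; the pipeline fans one top-level seed out into
labeled sub-seeds per stage, and re-running an identical config produces
byte-identical summaries. The test suite and the acceptance script run
the default-scale fixture (1 Mb + spike-in, depth 30), a 2-state
emission-recovery simulation of 10⁵ windows, and exhaustive-enumeration
likelihood checks on sequences of length ≤ 8 — sizes chosen so the entire
suite completes in well under a minute of compute per component while the
recovery tolerances (±0.05 emission, ±3 SE on pooled levels) remain
binding.

## Known limitations

- The HMM uses a single Poisson background per mark; strong coverage
  nonuniformity would require a local background the package does not
  implement.
- Bin pairing requires identical grids; comparing methylomes on
  different assemblies or contig sets is out of scope.
- CH next-base preference conditions only on the single following base;
  wider flanking models are not implemented.
- Statistical DMR testing and multiple-testing correction are
  deliberately absent: differential calls are fixed-threshold, matching
  the reimplemented analysis.
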