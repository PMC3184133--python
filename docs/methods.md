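# Methods

This note documents the models, estimators and design choices behind each
pipeline stage, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing the
outputs.

## Intensity model and background correction

Probe intensities are modelled as the convolution of a Gaussian optical
background and an exponentially distributed specific signal,

    I = B + S,   B ~ N(μ, σ²),   S ~ Exp(mean α),

the standard "normexp" convolution for single-channel expression arrays.
Fitting is by maximum likelihood: moment-based initialisation (the
exponential component carries the skewness, `α₀ = (m₃/2)^{1/3}`), EM
refinement to a parameter tolerance of 1e-8 or 500 iterations, and a final
Nelder–Mead polish of the exact convolution likelihood. The polish matters
in one regime: when the data carry essentially no background (σ → 0) the
EM update for μ has a vanishing gradient along the ridge and stalls away
from the optimum; the direct likelihood step recovers μ ≈ 0 there. Each
probe is replaced by the posterior mean `E[S | I]`, which is strictly
positive, so downstream log transforms are safe. A constant input vector
cannot identify the model; the corrector then subtracts the minimum and
adds one intensity unit, with a warning.

After correction, a variance-stabilising offset (default 16 intensity
units, configurable, 0 disables) is added before the log2 transform. This
is the customary companion of normexp correction: probes whose signal is
of the order of the background otherwise produce wildly noisy log-ratios.
With the offset in place, fewer than 1 % of null-pair probes exceed
|M| = 0.8 (≈ 1.75-fold) under the default simulation conditions — the
fold-change cutoff sits above the noise floor, which is its purpose.

## Pairwise MA-trend normalization

Arrays are normalized pairwise against a baseline array (the first
replicate of the first condition unless overridden). In MA space
(`A = (log2 T + log2 B)/2`, `M = log2 T − log2 B`) the probes are divided
into up to 30 rank-quantile bins of A (never fewer than 10 probes per
bin); the per-bin median A and median M define a piecewise-linear trend
which is subtracted from every probe's M, constant beyond the outer bin
centres. Running medians over quantile bins are robust to a minority of
genuinely regulated probes — a planted 2-fold change in 5 % of probes
survives trend removal within 0.1 log2 units — while a smooth monotone
distortion of the intensity scale (the kind introduced by scanner or
labelling nonlinearity) is removed to a residual per-decile |median M|
below 0.05. Fewer than 50 probes cannot support the fit and raise an
error. The exact estimator behind the original method's name is not
recoverable from public sources; this running-median construction is this
package's documented stand-in and is specified entirely by its contract
(trend removal, robustness, monotone interpolation in A).

## Rank-based differential expression

For a contrast, each probe contributes `Δ = mean(log2 treatment) −
mean(log2 control)`. The per-probe Δ values are ranked across all probes,
and a gene's statistic is the centred absolute rank sum of its probes,

    T_g = | Σ_{p ∈ g} rank(Δ_p) − k_g (N+1)/2 |,

with `k_g` the gene's probe count and `N` the total probe count. This uses
the multiple-measurements-per-transcript design directly and is invariant
to monotone distortions of the ratio scale. Whether ranks should be taken
within arrays or on the pooled contrast vector is a genuinely open
reading; the pooled-Δ form was chosen because it is the direct rank
analogue of the per-gene mean contrast and is fully testable.

The null distribution comes from permuting array condition labels: all
distinct relabelings when there are at most 2000 (for 3 vs 3 arrays, 19
non-identity relabelings), otherwise Monte-Carlo with a recorded seed.
Permuted statistics are pooled across genes of equal probe count, giving
p-value resolution of order `1/(R · G)` rather than `1/R` — essential at
small sample sizes, where R alone is tiny. Genes whose observed fold
change already exceeds the selection cutoff are left out of the null pool
(falling back to all genes if fewer than 20 or 20 % remain): truly
regulated genes would otherwise donate extreme permuted statistics and
inflate the null tail, costing sensitivity. Under a global null nothing is
excluded in practice (a median fold change beyond 1.75 at σ = 0.2 is a
5-sigma event), and the empirical p-value distribution stays
(super-)uniform within binomial error.

Genes with a single probe are excluded with a warning; a 1 vs 1 contrast
admits no informative relabeling and returns p = 1 with a warning.
Selection is `|FC| ≥ 1.75` and `P < 0.01`, reported with the
negative-reciprocal convention for down-regulation; no multiple-testing
correction is applied by default (a Benjamini–Hochberg switch exists).
Sensitivity under the default conditions (log2FC 1.5, σ = 0.2, 3 vs 3,
≥ 8 probes) exceeds 0.9 with type-I error ≤ 0.02 at α = 0.01.

The endpoint-overlap statistic requires direction agreement between the
stage and endpoint contrasts by default (`require_direction=False`
relaxes it). Hierarchical clustering uses average linkage on
`1 − Pearson r` of per-stage mean log2 ratios; a constant profile has
undefined correlation and is assigned the maximal distance 2 with a
warning. qRT-PCR fold changes follow the cycle-threshold identity
`2^{−(xn − yn)}`.

## Promoter windows

The promoter of a gene is `[−1500, +500)` around the annotated TSS in
transcription orientation — exactly 2000 bases, with the TSS base at
in-window offset 1500. Coordinates are 0-based half-open internally; BED
is taken as-is (single-base intervals denote the TSS itself; longer
intervals are gene spans, TSS = start on `+`, end−1 on `−`) and GFF3 is
converted from 1-based inclusive on read. Minus-strand windows are taken
mirrored on the reference and reverse-complemented. Windows overhanging a
contig end are truncated and flagged `clipped`, never padded with N —
fabricated sequence would be scanned downstream as if it were real.
Duplicate TSS annotations keep the first record with a warning.

## Motif scanning

A PWM is a 4×L count matrix; scoring is log2-odds of the pseudocounted
column probabilities (pseudocount 0.25 per cell) against the background
(uniform by default, optionally composition-derived). A window is a hit
when its score reaches `threshold_fraction × max achievable score`; the
default fraction 0.85 is configurable, since external scanning services
set thresholds internally and no single value is canonical. Both strands
are scanned; windows containing N score −∞; overlapping hits are all
reported because the downstream statistic counts occurrences, and
multi-occurrence "clusters" within one promoter are meaningful. The
scanner is verified against exhaustive per-window scoring, and raising
the threshold fraction can only shrink the hit set.

Libraries parse from TRANSFAC-style flat files (via Biopython) or a
simple text dialect (`>NAME` followed by A C G T count rows); a directory
may mix both. The six bundled matrices (SRY, FTS-1, Evi-1, GC-Box, Elk-1,
CREB) are synthetic convenience fixtures whose consensus sequences match
the elements' canonical cores — they are not reproductions of any
database entry, and element identity in a real analysis is configuration.

## CRE frequency statistic

For an element within a gene group at one stage,

    freq% = 100 × (total occurrences across the group's promoters)
                / (number of genes in the group).

Counting is deliberately uncapped per promoter, so values above 100 %
occur whenever elements cluster; that is the statistic's intended
behaviour, not saturation. Elements are ranked by descending frequency
within each (stage, group); ties break lexicographically by element name
(deterministic, and logged when a tie crosses the top-k boundary). The
top-k report defaults to k = 6; "common" mode keeps only elements in the
top k of every stage. Down-regulated groups and transcription-factor
subsets use the identical statistic on a different input gene list — the
package does not classify genes as transcription factors. No enrichment
test against background promoters is computed; the statistic is a
descriptive frequency, and a statistical enrichment layer would be an
extension, not a reimplementation.

## Dumbbell decoys

Construction is sequence-level: `ODN1 = core × n + arm1`,
`ODN2 = revcomp(core × n) + arm2` (n = 2 by default), so the repeat
regions are reverse complements by construction and the arms — each a
5 bp stem around a 5 nt loop in the published pairs — close the duplex
into the nuclease-resistant dumbbell. Verification offers (a) 5'-anchored
maximal tandem-repeat detection, preferring the longest unit (so a
homopolymer run `AAAAAA` reports unit `AAA` × 2), and (b) the longest
reverse-complementary block between a pair, by longest-common-substring
dynamic programming against the reverse complement, with a configurable
pass threshold (15 bp default). Two of the five published pairs (Evi-1,
GC-Box) carry spaced rather than exact-tandem repeats; for them duplex
verification plus substring search of the declared core is the
appropriate check, and the fixture marks which pairs are exact tandems.
All comparisons are case-insensitive, 5'→3'. Loop geometry after ligation
is not modelled; verification is purely sequence-level.

## Synthetic data: what it emulates and what it does not

The expression generator emulates a multi-probe oligonucleotide array
time course: per-probe affinities `~ Exp(signal_scale)` shared across
arrays, additive Gaussian background per measurement, log-normal
measurement noise (σ = 0.2 log2 units), per-array monotone power-law
distortion of the log-intensity scale (exponent drawn up to 1.2; the
baseline array is undistorted), and stage-specific planted fold changes
(exactly `round(frac × n)` genes per direction per stage). A Markov
persistence parameter (0.6) carries a gene's regulation into the next
stage, which is what produces non-trivial Venn overlap and growing
endpoint sharing. Defaults — 100 ± 15 background units, mean signal 3000
units, 3 replicates, 11 probes per gene (8 in the quick demo) — are
scanner-scale values typical of this array class.

The promoter generator plants `Poisson(freq)` consensus copies per gene,
uniformly placed without overlap, on a random strand, in i.i.d. background
sequence of chosen GC content, and can embed the windows into a synthetic
genome (with both gene orientations) so that extraction is exercised
end-to-end and must reproduce every window exactly.

Deliberately not emulated: probe-sequence affinity structure (GC/position
effects), cross-hybridisation, correlated (co-regulated) gene programs
beyond the planted labels, dinucleotide or repeat structure in promoter
background, and degenerate (non-consensus) planted sites. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model and calibrated behaviour under its noise — not
performance on real arrays or real promoters, where probe effects and
motif degeneracy would lower scanning recall and widen DE noise.

## Problem sizes and determinism

The bundled demo runs 240 genes × 8 probes × 15 arrays with 2 kb
promoters (a 0.53 Mb synthetic genome) in a few seconds; the acceptance
checks use up to 1100 genes × 11 probes and 200 promoters per group —
sizes chosen so the full verification suite completes in minutes on a
single CPU while keeping binomial error bars on the recovered rates
small. Every random draw flows from explicit seeds through
`numpy.random.default_rng`; file outputs use fixed float formatting and
no timestamps, so a rerun with the same configuration is byte-identical
(verified by SHA-256 checksums in the run manifest). TSV outputs carry
the configuration hash in a `#` header line; FASTA/BED/Newick formats
have no comment syntax and are covered by the manifest instead.
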