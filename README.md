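# emtcre

Transcriptional-network analysis of epithelial–mesenchymal transition
(EMT) time courses: from probe-level microarray intensities to the
cis-regulatory elements (CREs) that dominate the promoters of regulated
genes, and to the dumbbell decoy oligonucleotides that block them.

When kidney proximal-tubule epithelial cells are pushed toward a
fibroblast fate (TGF-β/EGF induction), transcription is remodelled in
waves over hours to days. A practical way to read those waves is to (1)
call differentially expressed genes per stage against the non-induced
baseline, (2) pull the promoter of every regulated gene, (3) count
occurrences of known transcription-factor binding elements, and (4) ask
which elements dominate each stage — those are the candidate network hubs,
and synthetic decoys carrying two copies of such an element can titrate
the factors away. This package implements that entire computational arc as
a reusable, tested pipeline, plus a synthetic-data generator with planted
ground truth so every stage is verifiable offline.

## What is computed

- **Background correction** — observed intensity is modelled as
  `I = B + S` with `B ~ N(μ, σ²)` (optical background) and
  `S ~ Exp(α)` (specific signal); parameters are fitted by maximum
  likelihood (EM with a direct likelihood polish) and each probe is
  replaced by the posterior mean `E[S | I]`.
- **Pairwise normalization** — for each array against the baseline array,
  the log-ratio `M = log2 T − log2 B` is regressed on mean log-intensity
  `A` by a running median over rank-quantile bins and the fitted trend is
  subtracted, removing smooth nonlinear inter-array bias.
- **Rank-based differential expression** — a gene's statistic is the
  (centred) sum of the ranks of its probes' mean log2 ratios, exploiting
  the multiple-probes-per-transcript array design; p-values come from
  permuting array condition labels with statistics pooled across genes of
  equal probe count. Selection uses |fold change| ≥ 1.75 and P < 0.01.
- **Gene-set logic** — 7-region Venn partitions of the three stage sets,
  the percent up-regulated per stage, overlap with the fibroblast-endpoint
  contrast, and average-linkage hierarchical clustering
  (distance = 1 − Pearson r of stage profiles, Newick output).
- **Promoters** — strand-aware TSS-anchored windows, −1500 to +500
  (2000 bp), extracted from genome FASTA + BED6/GFF3 annotations.
- **CRE scanning** — TRANSFAC-style and simple-dialect PWM libraries,
  log2-odds scoring on both strands, hits at ≥ 85 % of the maximum
  achievable score by default.
- **Percentile of frequency** — per element, stage and gene group:
  `freq% = 100 · (total occurrences) / (number of genes)`; values exceed
  100 % when elements cluster in promoters. Elements are ranked per stage
  and the top six reported.
- **Dumbbell decoys** — `ODN1 = core×2 + arm1`,
  `ODN2 = revcomp(core×2) + arm2`; tandem-repeat detection and
  reverse-complementary duplex verification, validated against five
  published decoy pairs shipped as a fixture.

## Worked example

The numbered drivers under `analysis/` run the bundled demo configuration
(a 240-gene, 8-probe, 15-array synthetic time course: T0, T6, T18, T96
plus a fibroblast endpoint) and write their tables under `results/run/`:

```bash
cd analysis
python 01_simulate_timecourse.py
python 02_normalize_arrays.py
python 03_differential_expression.py
python 04_extract_and_scan_promoters.py
python 05_profile_cre_frequencies.py
python 06_design_decoys.py
```

Step 03 prints the stage-wise balance and set structure of the calls:

```
percent up-regulated among selected genes:
  T6         24 up /   12 down -> 66.7%
  T18        24 up /   12 down -> 66.7%
  T96        24 up /   12 down -> 66.7%
up: 8 genes shared by all three stages
T96 vs NIH3T3: 23 shared (64% of stage, 64% of endpoint)
```

— all 36 planted genes per stage are recovered (the demo plants 10 % up,
5 % down at log2FC 1.5), and overlap with the endpoint grows along the
time course because regulation persists stage to stage. Step 05 charts
the CRE frequencies of the called groups:

```
top 6 elements per stage/group:
  T6    up    SRY, FTS-1, GC-Box, Elk-1, CREB, Evi-1
  T96   up    SRY, FTS-1, Evi-1, GC-Box, Elk-1, CREB
frequency trend (last - first stage, up-regulated genes):
  SRY      -100.0%
  FTS-1    -4.2%
  Evi-1    +58.3%
```

— the demo plants an SRY-rich early wave that decays, a persistent FTS-1
signal and a rising Evi-1 signal, and the profile recovers exactly that
ordering. Step 06 then builds dumbbell decoys for the four most frequent
up-regulated elements and verifies each duplex (e.g. FTS-1:
`tgattgatccttgattgatcctcttggtttttccaag`, 22 bp complementary block).

The same stages are available as a CLI (`emtcre simulate|normalize|de|
venn|promoters|scan|profile|decoy|run-all`); `emtcre run-all --out run/`
executes everything end to end and writes a manifest with SHA-256
checksums — reruns are byte-identical.

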