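# Demo configuration: a small synthetic EMT time course that exercises every
# pipeline stage in a few minutes on one CPU.
seed: 1
stages:
  baseline: T0
  emt: [T6, T18, T96]
  endpoint: NIH3T3
sim:
  n_genes: 240
  probes_per_gene: 8
  n_replicates: 3
  frac_up: 0.10
  frac_down: 0.05
  planted_log2fc: 1.5
  persistence: 0.6
n_perm: 600
thresholds:
  fc_cutoff: 1.75
  alpha: 0.01
  threshold_fraction: 0.85
  top_k: 6
  up: 1500
  down: 500
promoters:
  gc_content: 0.45
  # planted mean occurrences per promoter, by ground-truth group
  group_freqs:
    T6_up:  {SRY: 2.0, FTS-1: 1.2, GC-Box: 1.0, Elk-1: 0.6}
    T18_up: {FTS-1: 1.2, Evi-1: 1.0, GC-Box: 0.8, SRY: 0.5}
    T96_up: {FTS-1: 1.0, GC-Box: 0.5, Evi-1: 0.4}
    down:   {CREB: 1.0, GC-Box: 0.8, SRY: 0.3}
    "null": {Elk-1: 0.2}
decoys:
  top_n: 4
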