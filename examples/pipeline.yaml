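# Full-pipeline configuration for `chromarch run-all --config`.
# Values shown are the defaults; delete anything you don't override.

outdir: chromarch_run
seed: 0

# Synthetic dataset (see docs/methods.md for what each knob emulates).
simulation:
  chrom_sizes: {chr1: 10000000, chr2: 10000000}
  bin_size: 25000            # standard compartment-analysis resolution
  a_fraction: 0.45           # genome share of the A compartment
  mean_block_len: 500000     # mean compartment block (bp)
  compartment_strength: 0.6  # checkerboard contrast kappa
  decay_exponent: 1.0        # contact decay ~ (d+1)^-alpha
  depth: 200000              # expected contacts per chromosome
  tad_mean_size: 750000
  tad_boost: 3.0             # within-TAD contact multiplier tau
  peak_count: 10000
  peak_a_enrichment: 4.0     # odds for placing a peak in an A bin
  n_fragments: 3000          # restriction fragments per chromosome
  n_baits: 80
  calls_per_bait: 6
  feature_fold: 2.0          # planted other-end enrichment phi
  n_proteins: 1000
  partner_fraction: 0.05
  dropout_rate: 0.1

metaplot_window: 200000      # half-window around B->A boundaries (bp)
scc_h: 1                     # smoothing half-window (bins)
scc_max_dist: 5000000        # SCC stratum ceiling (bp)
tad_window: 500000           # insulation window (bp)
tad_min_drop: 0.1            # boundary prominence (log2 units)
score_threshold: 5           # confident-interaction cutoff (inclusive)
pir_max_dist: 1000000        # cis other-end ceiling (bp)
pir_n_rand: 100              # random fragment subsets for the null
ratio_thresholds: [10, 50, 500]   # partner sweep; 500 is strict (>)
alpha: 0.05                  # ORA / consensus FDR level
switch_threshold: 0.2        # min |score change| for a compartment switch
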