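# chromarch

Where does a chromatin architectural protein sit in the 3D nucleus, and
does losing it change higher-order chromatin structure? `chromarch` is a
Python toolkit for answering that class of question the way it is asked
for the HMGN nucleosome-binding proteins (HMGN1/HMGN2) in wild-type
versus double-knockout (DKO) mouse cells: score A/B compartments from
Hi–C contact matrices, co-localize ChIP-seq peaks and signal with
compartments and their B→A boundaries, quantify contact-map similarity
and TAD-boundary stability between genotypes, test feature enrichment at
promoter-interacting regions (PIRs) from promoter capture Hi–C, and
select ChIP–MS binding partners with GO over-representation and
cross-experiment consensus.

Every analysis is exercisable end-to-end on synthetic data with planted
ground truth — compartment labels, TADs, enriched features, binding
partners — so the statistical behaviour of each stage (recovery,
calibration, ordering) is tested without any external download.

## The statistics at the core

**Compartment score.** Per chromosome, mask bins with zero marginal
count, divide each entry by the mean count at its diagonal distance
(observed/expected), correlate the normalised columns, and take the
eigenvector of the largest-magnitude eigenvalue of that correlation
matrix, rescaled to [−1, 1]. Sign is oriented so positive scores (the A
compartment) correlate with a supplied activity track; A/B labels follow
the sign.

**Stratum-adjusted correlation (SCC).** After mean-filter smoothing with
half-window *h*, compute a Pearson correlation r_k per diagonal distance
k and combine as Σ w_k r_k / Σ w_k with w_k = n_k·s_k(a)·s_k(b) — the
pair count times the per-stratum standard deviations.

**Insulation TADs.** Insulation of bin i is log2 of the mean count in
the w×w square of upstream versus downstream bins, centred on the
chromosome mean; boundaries are insulation minima with prominence ≥
`min_drop`, and domain stability is a boundary Jaccard with ±1-bin
tolerance.

**PIR feature enrichment.** Tested fragments are the distinct non-bait
other-ends of confident interaction calls (score ≥ 5) in cis within 1 Mb
of their bait. The null redraws same-size fragment sets matched on
distance-to-nearest-bait composition (log-spaced bins); the report gives
observed, expected with a 95% null interval, fold, and an empirical
two-sided p (plus a normal approximation).

**Partner rule.** A protein is a binding partner in an experiment group
when WT1 ≠ 0, WT2 ≠ 0 and (WT1+WT2)/2 ÷ (DKO1+DKO2)/2 ≥ threshold
(default 10; DKO average 0 counts as infinite ratio). The threshold
sweep reports counts at ≥10, ≥50 and, strictly, >500. Partner sets feed
a one-sided Fisher/hypergeometric over-representation test with
Benjamini–Hochberg FDR, and a consensus over the four experiment groups
(two immunoprecipitations × two cell types).

## Worked example

Simulate a complete dataset (two 10 Mb chromosomes, 25 kb bins) and run
every stage:

```bash
chromarch run-all --seed 3 --outdir demo_run
```

`demo_run/report.json` then contains, among others:

```json
"occupancy":    {"n_peaks": 10000, "fraction_A": 0.7404, "n_b_to_a_boundaries": 14},
"scc":          {"wt_rep1_vs_rep2": 0.9128, "wt_vs_dko": 0.9103},
"tads":         {"n_tads_wt": 35, "n_tads_dko": 36, "boundary_jaccard": 0.925},
"pir":          {"observed": 276, "expected_mean": 152.13, "fold": 1.814, "p_value": 0.0198},
"partners":     {"sweep": {"10": 200, "50": 200, "500": 200}}
```

Reading these numbers: 74% of the simulated peaks fall in A-compartment
bins (the generator plants 4:1 odds for A on a genome that is ~44% A, so
4·0.44/(4·0.44+0.56) ≈ 0.76 is the target); contact-map similarity
between the two wild-type replicates and between genotypes is equally
high, while TAD counts and boundaries are nearly identical — the planted
"knockout" changes sequencing noise, not structure, and the analysis
correctly reports structure as unchanged. The PIR feature is recovered
as ~1.8-fold enriched over the distance-matched expectation (2-fold
planted, attenuated by the exchangeable null's pool; the
`fold_background` column in `pir_enrichment.tsv` gives the unbiased
estimate), and all 200 planted partners pass every ratio cutoff because
their DKO abundance is simulated as zero.

Individual stages are also available as subcommands (`simulate`,
`compartments`, `occupancy`, `scc`, `tads`, `tads-compare`,
`pir-enrich`, `partners`, `ora`, `consensus`), e.g.:

```bash
chromarch simulate --seed 3 --outdir demo
chromarch scc --matrix-a demo/wt_rep1.matrix.tsv --bins-a demo/wt_rep1.bins.bed \
              --matrix-b demo/wt_rep2.matrix.tsv --bins-b demo/wt_rep2.bins.bed \
              --out demo/scc.tsv
# SCC 0.912768
```

## Data formats

Triplet contact matrices with a 4-column bin BED, BED peaks, bedGraph
signal, a tiling fragment map with bait flags, bait/other-end/score
interaction TSV, long-format abundance TSV (protein, group, WT1, WT2,
DKO1, DKO2), and GMT annotation. All intervals are 0-based half-open.
See `docs/methods.md` for the model, parameter defaults, and known
limitations.
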