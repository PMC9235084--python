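# Methods

## Scope and model overview

`chromarch` analyses binned, intrachromosomal Hi–C contact matrices and
their derived structures (A/B compartments, TADs), promoter capture
interaction calls, ChIP-seq peaks/signal, and label-free ChIP–MS
abundance tables. It consumes interaction calls and abundances as
tables: read alignment, interaction-call statistics (CHiCAGO-style
models), differential-interaction models, and peptide search are out of
scope. A synthetic-data layer generates every input with planted ground
truth so that each stage's recovery, calibration and ordering behaviour
is testable offline.

## Compartment scoring

Scores are computed per chromosome from the dense symmetric block:

1. mask bins with zero marginal count (no imputation);
2. divide each entry by the mean count at its diagonal distance
   (observed/expected); distances with zero mean contribute 0;
3. correlate the O/E columns over non-masked bins; zero-variance
   columns are masked, not errors;
4. take the eigenvector of the largest-magnitude eigenvalue and rescale
   by its maximum absolute entry, so scores lie in [−1, 1];
5. orient the sign so the score correlates positively with a per-bin
   activity reference (peak density or any active-chromatin track);
   positive = A, negative = B.

This is the standard eigenvector-of-O/E-correlation procedure. It is a
deliberate substitution for likelihood-based compartment callers whose
internal optimisation is not public in detail; the contract — a per-bin
score in [−1, 1] whose sign is the compartment call — is identical, and
on ≤50-bin matrices the implementation is verified to 1e−8 against an
independent dense eigendecomposition oracle. Chromosomes are processed
independently (per-chromosome eigenvectors), and a chromosome must have
at least 20 bins. A constant matrix leaves every O/E column without
variance and raises an error rather than returning arbitrary signs.

Compartment segments are maximal same-label runs (NA bins belong to
neither side); the A:B ratio is total A bp over total B bp, infinite
with a warning when no B exists. A B→A boundary is the start of the
first A bin of an A run whose nearest labeled left neighbour is B; NA
runs between B and A do not create boundaries. `compare_profiles`
reports Pearson r over jointly labeled bins and calls a bin "switched"
only when the score flips sign *and* moves by at least
`switch_threshold` (default 0.2) — small-magnitude sign flips are noise,
and depletion experiments that leave structure intact should report few
or no switches.

## Contact-map similarity (SCC)

Both matrices are smoothed with a (2h+1)×(2h+1) mean filter whose
neighbourhood is clipped at the block edge and renormalised by the
clipped size (h = 0 is the identity). For each diagonal distance
k ≤ max_dist with ≥ 3 pairs and nonzero variance in both matrices, a
Pearson correlation r_k is computed and combined as Σ w_k r_k / Σ w_k
with w_k = n_k·s_k(a)·s_k(b) (pair count × per-stratum population SDs).
Defaults h = 1 and max_dist = 5 Mb at 25 kb bins; multi-chromosome SCC
is the pair-count-weighted mean of per-chromosome SCCs. Identical
matrices give exactly 1; scaling one matrix leaves the value unchanged.
No variance-stabilising rank transformation is applied; on the package's
own fixtures the statistic is verified to 1e−10 against a brute-force
per-diagonal oracle. Two caveats: clipped smoothing neighbourhoods at
stratum edges induce a small shared component between *independent*
matrices, which decays with chromosome length (at 400-bin chromosomes
the structureless |SCC| stays below 0.1 at h = 1); and SCC carries no
significance model here.

## TAD boundaries

Insulation of bin i with window w bins is the mean count in the square
of the w bins upstream of i against bins [i, i+w), log2-normalised by
the chromosome mean of that statistic; undefined within w bins of the
chromosome ends. Placing the square's corner on bin i (rather than
straddling it) makes the minimum fall on the first bin of the
downstream domain, consistent with the B→A boundary convention.
Boundaries are local minima with prominence ≥ `min_drop` (default 0.1
log2 units — the smallest drop we accept as a domain edge rather than
noise; implemented with `scipy.signal.find_peaks`, whose prominence is
exactly the depth below the nearest flanking maxima). Domains are the
spans between successive boundaries filtered to [min_size, max_size]
(defaults 75 kb–5 Mb; window default 500 kb). Nested/hierarchical
domains are not modelled: the questions this package answers rest on
domain counts, size distributions, and boundary stability, all of which
the flat caller provides. Boundary agreement between two TAD sets is a
greedy one-to-one Jaccard with ±1-bin tolerance.

## PIR feature enrichment

Confident calls (score ≥ 5, inclusive; duplicate bait/other-end pairs
deduplicated keeping the maximum score) define the tested set: distinct
non-bait other-end fragments in cis within 1 Mb of their bait. Observed
is the number of tested fragments overlapping the feature by ≥ 1 bp
(fragment-level, not bp-level). The null redraws, `n_rand` = 100 times,
a random set of non-bait fragments with the same size and the same
composition across 20 log-spaced bins of distance to the nearest bait.
Expected value and the 95% interval come from the null's empirical
distribution; the p-value is the +1-smoothed two-sided empirical tail,
with a normal-approximation p reported alongside.

Two design points deserve emphasis:

* **One matching covariate.** Both the tested set and the pool are
  binned by distance to the *nearest* bait. Distance to a fragment's
  own bait reaches the 1 Mb call ceiling while nearest-bait distances
  are bounded by half the bait spacing, so matching one against the
  other is infeasible at realistic bait density — and "comparable
  distance from promoters" is a property of a fragment's position
  relative to all baits, which the nearest-bait distance measures for
  random fragments and tested fragments alike. Bait fragments are
  excluded from the tested set (a bait other-end sits at distance 0,
  which no non-bait fragment can match).
* **Tested fragments stay in the sampling pool.** Under the null
  hypothesis the tested fragments are exchangeable with the rest of
  their distance stratum, and only a pool that includes them makes the
  observed count one more draw from the same finite population — the
  empirical p is then exactly valid (measured type-I error 0.05 at
  α = 0.05; Kolmogorov–Smirnov-uniform over seeds). Excluding them
  shrinks the null's spread by the finite-population factor and
  inflates the type-I error (measured 0.10–0.17 depending on the
  tested fraction). The price is that a pool containing enriched
  fragments dilutes strong enrichment, attenuating `fold` =
  observed/expected by 1/(1 + f·(φ−1)) for tested fraction f. The
  result therefore also reports `fold_background` — observed over the
  distance-weighted overlap rate of *non-tested* pool fragments — which
  is the unbiased estimate of enrichment against pure background and is
  the quantity the recovery tests target.

An empty feature returns a flagged zero-fold result rather than an
error. Enlarging a feature never decreases the observed count.

## ChIP–MS partner selection, ORA, consensus

The partner rule is applied per (protein, experiment-group) record:
present in both WT replicates (WT1 ≠ 0 and WT2 ≠ 0) and replicate-
averaged WT/DKO ratio ≥ threshold. A DKO average of zero with positive
WT yields an infinite ratio, which passes any finite cutoff — a partner
absent from the knockout is the strongest possible call, and this
convention needs no pseudocount (a pseudocount mode exists but is off
by default). The threshold sweep reports counts at 10 and 50 (inclusive
≥) and 500 (strict >), following the printed convention of the counts
it mirrors, in both tallies: distinct (protein, group) pairs and
distinct proteins. Counts are asserted non-increasing in the threshold.
Selection is invariant to global abundance rescaling.

ORA uses the one-sided Fisher exact (hypergeometric upper-tail) test per
term after intersecting term membership with the explicit universe,
Benjamini–Hochberg FDR across tested terms, and ranking by descending
−log10(q). The universe is always an explicit input (all detected
proteins is the natural choice). Consensus categories are terms with
q < α in all four experiment groups (ES_N1, ES_N2, MEF_N1, MEF_N2 by
default); terms significant in ≥ 2 groups are "common", in exactly one
"unique", and a top-k listing ranks consensus terms by the pooled
partner set's ORA.

## Synthetic data generator

Each generator derives an independent RNG stream from (seed, operation
name), so outputs are bit-identical under a fixed config and adding one
generator never shifts another's stream.

* **Compartment truth**: strictly alternating A/B blocks with geometric
  lengths (memoryless, variable like real compartment tracks); the A
  and B means are 2·a_fraction and 2·(1−a_fraction) times
  `mean_block_len`, so the A fraction converges to `a_fraction`
  (default 0.45, in the 4:5–9:10 range reported for real A:B genome
  shares) while the mean block stays at `mean_block_len` (default
  500 kb). TADs tile each chromosome with geometric sizes around
  `tad_mean_size` (default 750 kb, mid-range for mammalian domains).
* **Contact matrices**: Poisson counts with mean ∝ depth ·
  (d+1)^−α · (1 + κ·s_i·s_j) · τ^[same TAD], with decay α = 1,
  checkerboard strength κ = 0.6, TAD boost τ = 3, and `depth` expected
  contacts per chromosome (default 200 000 over 400 bins ≈ 1000 per
  bin). An optional gamma-mixing overdispersion parameter (default 0)
  gives negative-binomial counts. Replicates share the truth and differ
  only in the count draw — the simulated "knockout" deliberately has
  unchanged structure, which is the regime the WT/DKO comparisons are
  designed to report faithfully.
* **Peaks and signal**: peak bins drawn with odds e:1 for A over B bins
  (e = 4 default, infinite = A-only); the signal track is per-bin peak
  coverage plus exponential noise (mean 0.1).
* **Capture interactions**: fragments tile each chromosome evenly
  (3000 per 10 Mb chromosome ≈ 3.3 kb, the HindIII scale); 80 baits
  per chromosome with 6 calls per bait reproduce, at desk scale, the
  real proportions of ~820k fragments, ~22k baits and ~100–145k PIRs
  (~15% of fragments tested, ~5–6 PIRs per bait) — proportions that
  matter because the resampling null's accuracy depends on the tested
  fraction of each distance stratum. Other-ends are sampled in cis
  within 1 Mb with probability ∝ 1/(d + 150 kb), scores are
  5 + Exp(5). The feature covers other-end fragments with probability
  φ·base_rate versus base_rate elsewhere (base rate 0.15), so the
  planted φ is the ratio of overlap rates that `fold_background`
  estimates.
* **Abundance tables**: 1000 proteins, 5% planted partners shared
  across the four groups; abundances are log-normal (location 14,
  scale 1.5 on the natural-log scale) with replicate noise of 0.3 log
  units; partners carry `partner_leak` (default 0 — absent in DKO) in
  both DKO replicates; dropout (default rate 0.1) zeroes WT entries of
  non-partners only, so planted truth remains recoverable at any
  dropout rate. Under this noise fewer than 1% of non-partners exceed
  a 10-fold ratio.
* **GO annotation**: 100 null terms (uniform draws from the universe)
  plus 3 planted terms of size 25 whose members come from the partner
  set with probability 0.8.

What the generator does **not** emulate: mappability and GC biases,
restriction-site placement, distance-dependent feature density,
copy-number effects, inter-chromosomal contacts, correlated protein
abundances, and the DAG structure of real GO. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data artefacts.

## Numerical choices and problem sizes

* Eigenvectors via `numpy.linalg.eigh` on the symmetric correlation
  matrix; the largest-|λ| eigenvector is selected explicitly.
* Per-stratum SDs are population (ddof = 0) throughout SCC.
* The empirical p uses +1 smoothing in both tails and doubles the
  smaller tail, capped at 1.
* Statistical test fixtures are sized so that asymptotic claims hold:
  the ORA null-uniformity check runs at a proteome-scale universe
  (21 000 ids, term size 1000, sample 6000) because hypergeometric
  p-values are discrete and super-uniform — at small sizes the p-value
  atoms alone exceed a Kolmogorov–Smirnov critical value; structureless
  SCC bounds use 400-bin chromosomes for the edge-effect reason above;
  generator-convergence Monte Carlo uses 3000 seeds at 3·SE tolerance.
  Simulation-based tests use 5–20 Mb genomes at 25 kb bins, chosen as
  the smallest sizes at which the tested asymptotics are in force.
* The pipeline runner writes a provenance sidecar (stage, parameters,
  seed, SHA-256 of inputs and outputs) next to every stage output;
  reruns with an identical config are bit-identical.

## Known limitations

* Compartment calling is per-chromosome and intrachromosomal only; no
  cross-chromosome sign harmonisation beyond the shared reference
  track.
* The eigenvector method substitutes for likelihood-based callers; on
  real data the two agree in sign far more than in magnitude, and only
  the sign (plus a magnitude threshold for switches) is interpreted
  here.
* SCC lacks the rank/variance-stabilising transformation of some
  published implementations; values on real deep matrices will differ
  in the third decimal, orderings should not.
* The PIR null conditions on the realized feature; its exactness
  argument assumes feature placement is exchangeable within distance
  strata, which real clustered features violate to an unquantified
  degree.
* Partner selection trusts the label-free abundances as given; no
  normalisation across samples is applied before the ratio rule.
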