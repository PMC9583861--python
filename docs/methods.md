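# Methods

This note documents the statistical model behind `isomirnet`, the
defaults it ships with, the numerical conventions, and what the
synthetic cohorts can and cannot demonstrate.

## 5′-isomiR representation

A 5′-isomiR is a pair (mature arm, signed shift).  Shifts are measured
in the mature 5′→3′ direction: `+k` removes the first *k* templated
nucleotides, `−k` extends the 5′ end by *k* templated nucleotides into
the hairpin.  Coordinates are 1-based inclusive everywhere (the miRBase
GFF3 convention); on the minus strand the 5′ end of a molecule is the
higher genomic coordinate, and all local coordinates run in the
hairpin's own 5′→3′ sense so shift arithmetic is strand-independent.
Only templated 5′ variation is modeled: non-templated additions and
3′-end variants are out of scope, and isoform records differing only at
the 3′ end are summed into one 5′-isomiR during aggregation.

The name dialect is `<mature>—<shift>` with an em-dash separator and an
explicit `+` on positive shifts (`hsa-miR-203a-3p—0`,
`hsa-miR-514a-3p—-3`).  Readers also accept `--` as an ASCII fallback;
output always uses the em-dash.

Derived sequences keep the 3′ end fixed at the canonical mature 3′ end
by default, so a `+1` isomiR is one nucleotide shorter and a `−1`
isomiR one longer.  The seed is positions 2–7 of the derived sequence;
two adjacent isomiRs (shifts k and k+1) therefore have 6-mer seeds
overlapping in 5 nt, which merge into a 7-mer "merged seed region".
When several arm paralogs produce the same 7-mer, duplicates are
removed keeping the highest-scoring pair (ties resolved by name).

## Normalization

The expression chain mirrors the standard edgeR recipe:

* **Low-expression filter** — keep features with count ≥ `min_count`
  (10) in ≥ `min_samples` (min(n, 10)) samples and total ≥ `min_total`
  (15).  These mirror the widely used default rule; all three are
  exposed because no single convention exists.
* **TMM factors** — trimmed mean of M-values per Robinson & Oshlack:
  reference sample = upper quartile of count fractions closest to the
  mean; M/A values on features positive in both sample and reference;
  30% two-sided trim on M and 5% on A (rank-based); precision-weighted
  mean of surviving M values; factors rescaled to geometric mean 1.
  The implementation reproduces Bioconductor edgeR's `calcNormFactors`
  to ~1e−8 (cross-checked in the test suite via Rscript).
* **RPM / FPKM** — `count / (library · factor) · 1e6`, FPKM additionally
  divided by transcript length / 1e3.  Library size is the raw column
  sum.  Normalization is computed independently per cohort.
* **log2** — `log2(x + 1)`; the pseudocount is configurable.

The **highly expressed** set of a cohort ranks isomiRs by raw read
totals pooled over the cohort's samples (pre-normalization, matching
the "share of sequencing reads" definition) and takes the shortest
prefix covering ≥ 95%.  Because the ranking is total-descending, the
returned set is minimal: dropping its smallest member always falls
below the threshold.  Ties are broken by name for determinism.

## Targetome harmonization

Two prediction dialects are consumed as score tables; the package never
computes the scores themselves.  miRDB-style scores (0–100) are kept at
≥ 80, the conventional high-confidence default.  TargetScan-style CWCS
has no conventional cut-off, so per isomiR the predictions are sorted
ascending (most negative = strongest predicted repression first) and
the top *n* are taken with *n* = the number of surviving miRDB targets;
the targetome is the union with per-gene provenance.  Consequences
worth noting: an isomiR with no miRDB target above threshold has an
empty targetome regardless of its TargetScan table, and the harmonized
targetome size is always between *n* and 2·*n*.  CWCS ties are broken
lexicographically by gene id; when TargetScan lists fewer than *n*
genes all are taken.  Prediction eligibility requires a sequence length
of 17–29 nt inclusive.  Targetomes are sequence-derived and therefore
cancer-agnostic; predicted targets missing from a cohort's expression
matrix are dropped at the correlation stage (with a logged count), not
from the targetome.

## Interaction networks

For each putative pair the package computes Spearman's correlation
(mid-ranks for ties; p-value from the large-sample t approximation, an
exact permutation option exists for n ≤ 10) and BH-adjusts the p-values
two ways: over all putative pairs of the cohort (`FDR_global`, used for
network views) and within each isomiR's own list (`FDR_local`, used for
single-isomiR or single-gene queries).  An edge is significant at
*r* < −0.3 **and** FDR < 0.05; all inequalities are strict, including
the |r| > 0.5 co-expression threshold.  The BH denominator includes
every putative pair with measurable expression; pairs skipped for
constant profiles are logged.  Correlation is restricted to the
cohort's highly expressed isomiRs by default (configurable).

ITA (isomiR targeting activity) is the significant out-degree; isomiRs
tested but without significant targets report 0.  Co-expression modules
are the maximal cliques (NetworkX `find_cliques`, i.e. Bron–Kerbosch
with pivoting) of the |r| > 0.5 graph, singletons included; each module
is represented by its highest-median-expression member, ties broken by
name.

The universal network keeps isomiRs highly expressed in
≥ `abundant_min_cancers` (10) cohorts, and an incident edge survives if
it is significant in at least ⌈0.5 · h⌉ of the h cohorts where the
isomiR is highly expressed.  The ceiling reading of "at least half" is
the default; a floor variant is available.  Edge weight is the
supporting-cohort count.

Over-representation analysis is a one-sided hypergeometric tail of the
query against each GMT set intersected with the background universe
(the cohort's measured genes), BH-corrected across sets at FDR < 0.05.

The uracil-start test for top-ranked merged seed regions is a one-df
chi-square goodness of fit of (#starting with U, #other) against a
configurable null frequency.  The default null is the uniform 0.25; a
uniform null is a modeling choice, not an estimate of the true
nucleotide composition at seed position 1, so the null frequency is an
explicit parameter rather than a constant.

## Synthetic cohorts

`generate_truth` draws uniform-random RNA hairpins of 60–120 nt, one
20–24 nt mature window each, the canonical isomiR plus extra shifts
from {−1, +1, +2}, Pareto-distributed abundance weights (shape 1.5, so
a few isomiRs dominate the read pool and the 95% rule is non-trivial),
and planted monotone-negative isomiR→gene interactions with one
regulator per gene.  Counts are negative-binomial (dispersion 0.1)
around abundance × lognormal library size, with a per-sample lognormal
modulation (σ = 0.6) of each isomiR's abundance so cross-sample
correlation is estimable.  Planted genes follow
`baseline − β · z(isomiR) + noise` on the log2 scale with baseline
~ Normal(8, 2) and noise σ = 1; unplanted genes are independent of all
isomiRs.  Gene counts for the file-level pipeline are Poisson
inversions of log2-FPKM, a monotone transform that preserves the
planted rank correlations.

Under this model the (isomiR, gene) pair is approximately bivariate
Gaussian with Pearson r = −β/√(β² + σ²), hence population Spearman
ρ = −(6/π)·asin(r/2); `beta_for_spearman` inverts this so recovery
studies can plant a chosen population ρ (the recovery harness uses
ρ = −0.6).  The convergence of the empirical Spearman to this value is
verified in the tests at n = 10⁴ within ±0.02.

What the generator does **not** emulate: hairpin secondary structure
and realistic seed–site sequence matching (prediction tables are
planted, not computed from sequence), sequencing error, batch effects,
tumor heterogeneity, and correlated confounding between isomiRs and
genes (each planted gene has exactly one regulator).  Passing the
recovery criteria therefore demonstrates that the statistical chain —
normalization, correlation, BH gating — recovers monotone negative
dependence at the stated effect size and sample size; it does not
validate target prediction itself, which enters the real pipeline as
externally supplied score tables.

## Problem sizes and determinism

The packaged study conditions are 3 cohorts × 60 samples, 40 isomiRs
from 20 hairpins, 300 genes, 50 planted interactions; the recovery
harness uses 100-sample cohorts with 50 planted pairs and 450 decoy
putative pairs, pooled over 20 simulation seeds.  These sizes make the
whole suite and the acceptance script run in well under a minute each
while keeping every statistic estimable.  A single master seed fixes
the truth, counts, expression, prediction tables and therefore every
output byte; the golden-run test asserts bit-for-bit reproducibility of
the full output tree, and every output file carries a hash of the
scientific configuration (thresholds, seed, cohort ids — not file
paths).

## Known limitations

* Only 5′ shifts are modeled; 3′ heterogeneity is collapsed.
* The published chi-square for uracil-started merged seeds is not
  reproducible without the original expected frequencies; the test
  statistic is exposed with a configurable null instead.
* FDR_global depends on the putative-pair universe, so adding or
  removing prediction sources changes significance calls even for
  unchanged pairs; the run report logs the tested-pair count for this
  reason.
* The Spearman p-value uses the t approximation; for very small cohorts
  (n ≤ 10) the exact permutation option should be preferred.
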