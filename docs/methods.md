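# Methods

## Pipeline overview

The package screens chemicals for disease association in three stages:
gene-level scoring from each evidence stream, chemical gene-set enrichment
against the ranked genes, and cross-stream/cross-disease intersection of
the significant chemicals.

### Summary-based TWAS

For each gene with expression-weight vector *w* over *m* cis-SNPs, GWAS
z-score vector *Z* and reference LD matrix *L*, the statistic is
`z_TWAS = w'Z / sqrt(w'Lw)`; under `Z ~ MVN(0, L)` it is exactly standard
normal, and a two-sided normal p-value is attached (clipped to
[1e-300, 1]). Assumptions: weights and z-scores are aligned to the same
effect allele (no strand/allele harmonizer is included), and *L* reflects
the population underlying the GWAS.

Numerical guards: the pipeline entry point (`run_twas`) ridges the LD
matrix, `L ← (1−τ)L + τI` with τ = 0.01, before the quadratic form, so
near-singular blocks cannot blow up the denominator; a gene whose `w'Lw`
remains below 1e-10 is skipped with a logged count. The low-level `twas_z`
defaults to the exact formula (τ = 0) so that analytic closed forms hold
to machine precision; the ridge perturbs a well-conditioned block's
statistic by well under 1%, which is negligible against its unit sampling
noise. SNPs missing from the GWAS are dropped jointly from *w*, *L* and
*Z*; genes left with no SNP are skipped, never imputed.

### Gene scoring

Each stream yields non-negative magnitudes sorted descending (ties broken
by gene id, so ranking is total and deterministic):

* TWAS stream (default GWAS-side evidence): r = |z_TWAS|, one stream per
  tissue.
* Best-SNP stream (optional alternative): r = max |z| over SNPs within
  ±`window_bp` (default 50,000 bp — a conventional cis window; the choice
  is configurable because no canonical value exists) of the gene span, on
  the gene's chromosome. Genes with no in-window SNP are excluded from
  that stream's universe rather than scored zero — absence of evidence is
  not evidence of a null gene.
* Expression stream: r = |t| from a Welch (unequal-variance) two-sample
  comparison of case vs control samples. A moderated/shrunken variance
  estimator (limma-style) is deliberately not used; with the default
  sample sizes (77 + 117) the difference is small, and Welch keeps the
  stream free of tuning constants. Genes with zero variance in both
  groups score 0 with a logged warning.

Scores are magnitudes because the enrichment statistic below is one-sided
toward the top of the list; directional variants are out of scope.

### Enrichment statistic

For a ranked universe of N genes and a set S with N_H members in the
universe, `ES(S)` is the maximum over prefix positions j of the running
sum that adds `|r|^p / N_R` at members and subtracts `1/(N−N_H)` at
non-members, with `N_R = Σ_{S} |r|^p`. The sum ends at exactly 0, so
0 ≤ ES ≤ 1 by construction: this is the max-of-running-sum form, not the
classic signed maximum-absolute-deviation GSEA, and bottom-concentrated
("protective") sets are invisible to it. A classic two-sided variant is
available behind the non-default `two_sided=True` flag.

The weight exponent defaults to p = 1 (score-weighted hits, the common
GSEA default); p = 0 gives the unweighted Kolmogorov–Smirnov form.

A property worth knowing: for p > 0 the ES is **not** monotone under
promoting a member up the ranking — the promotion inflates N_R and can
dilute a maximum attained at an earlier hit (verified by exact rational
arithmetic on a random instance). Monotonicity does hold at p = 0, where
N_R = N_H is unchanged and the running sum increases pointwise.

### Permutation null, NES, p-values

Only summary-level data exist, so the permutation unit is gene labels:
each permutation draws a uniformly random same-size subset of the
universe and records its ES (equivalent to score permutation under
exchangeability). Sets of equal overlap size share one null, seeded per
size from the run seed, which makes a 500-chemical screen cost roughly
190 nulls rather than 500. Per set,

* `NES = (ES − mean(ES_null)) / SD(ES_null)` (SD with denominator n−1;
  a numerically constant null reports NES = 0),
* `p = (1 + #{ES_null ≥ ES_obs}) / (Λ + 1)` — the add-one estimator,
  never exactly 0, minimum attainable 1/(Λ+1).

The default Λ = 5,000 permutations resolves p down to ~2e-4.  p-values
are counted on the ES scale; with a shared null per set size the ES-count
and NES-count orderings coincide, so either convention gives the same
empirical p. Significance is declared at raw p < α = 0.05 (the screen is
intentionally liberal; it feeds an intersection step), with
Benjamini–Hochberg q-values reported in an extra column for users who
want FDR control. Sets with overlap outside [5, 500] after intersection
with the universe are skipped and counted in the run log: singleton sets
make the running sum degenerate and huge sets are uninformative.

### Integration

Per disease, a chemical is "common" when significant in the expression
screen and in ≥ 1 GWAS-side tissue screen; per-tissue common counts and
the multi-tissue overlap are retained so the totals satisfy
inclusion–exclusion exactly. A chemical absent from a stream (not tested)
is never declared common. Across diseases the pan-disease set is the
exact name intersection of the per-disease common sets; chemical names
are opaque keys matched by string equality after whitespace trimming (no
synonym resolution).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the biology of any real cohort:

* **LD**: one AR(1) block per gene, `L[i,j] = rho^|i−j|`, default
  ρ = 0.5, 10 SNPs/gene — positive definite with realistic decay.
* **Weights**: i.i.d. standard normal, rescaled so `w'Lw = 1`.
* **GWAS z-scores**: per gene `Z = λ·Lw/sqrt(w'Lw) + ε`, `ε ~ MVN(0, L)`
  for causal genes, `ε` alone otherwise, so E[z_TWAS] = λ for causal
  genes and z_TWAS ~ N(0,1) for null genes. Effects enter through the
  mean of exactly the statistic the pipeline computes; no individual-level
  genotypes, allele frequencies or effect heterogeneity are simulated.
* **Chemical sets**: 500 sets (default), sizes uniform on [10, 200],
  members sampled without replacement per set from 2,000 genes; the first
  5 sets are causal, each contributing `causal_fraction` (default 0.5) of
  its members to the causal gene pool.
* **Expression**: unit-normal log-intensities, 77 cases / 117 controls
  (the tumor/mucosa sample split of the motivating comparison); causal
  genes are shifted by +δ (default 1.0) in cases.

Default effect sizes λ = 4 and δ = 1 are power-testing choices — large
enough that a fully causal set is detected essentially always, small
enough that partially causal sets are not trivially saturated; they are
conventions of the simulator, not estimates of any real chemical's
effect.

A single global seed fans out through fixed `SeedSequence` spawn keys
(sets, weights per tissue, GWAS per disease×tissue, expression per
disease), so multiple diseases share one chemical-set collection and
causal-gene pool while drawing independent noise, and each component is
independently reproducible.

What passing tests on these inputs do **not** show: robustness to allele
misalignment, LD mismatch between reference and GWAS population,
weight-model estimation error, expression batch effects, or CTD
annotation bias. The generator is a calibration instrument, not a
realism claim.

## Numerical and design choices

* All tables are UTF-8 TSV with header; "." is missing; coordinates are
  1-based inclusive. Round-trips are exact at full float precision.
* The running sum is clamped at 0 from below only through the maximum
  (the final prefix value is 0 analytically; floating error of ~1e-16 is
  absorbed by the clamp).
* Null ES values are computed by a vectorized kernel that evaluates the
  running sum only at hit positions (its maximum is always attained
  immediately after a hit); the test suite proves it equal to the
  single-pass scorer, and the single-pass scorer equal to a brute-force
  double loop, to 1e-12.
* Determinism: identical configs and seeds yield byte-identical output
  trees; this is asserted end-to-end at the default study scale.
* Tie-breaks: equal scores rank by gene id ascending; results sort by
  (empirical p, chemical name).

## Problem sizes used by the test and acceptance runs

Calibration checks use 5,000 null genes (TWAS) and 500 random sets at 500
permutations (enrichment); effect recovery uses 1,000 causal genes and 20
end-to-end replicates at the default 2,000-gene / 500-chemical scale with
500 permutations; the full-study determinism check and the acceptance
script run 1,000 permutations. These sizes give stable statistics at
minutes-scale runtimes on a single CPU; Λ = 5,000 remains the library
default for real screens.

## Known limitations

* One-sided enrichment: protective (bottom-of-list) chemical sets are not
  detected unless the two-sided variant is enabled.
* Gene-label permutation assumes score exchangeability across genes; it
  does not preserve LD-induced correlation between nearby genes' scores,
  so empirical p-values can be mildly anti-conservative when many set
  members are cis-neighbors.
* Raw p < 0.05 across streams controls the per-stream error rate only;
  the intersection step reduces, but does not formally control, the
  family-wise error of the final chemical list.
* No allele harmonization, no weight training, no covariate adjustment in
  the expression comparison.
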