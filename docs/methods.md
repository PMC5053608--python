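# Methods

This note documents the statistical model behind `fisherset`, the
conventions and numerical choices the implementation makes where more than
one reasonable option exists, what the synthetic-data engine does and does
not emulate, and the problem sizes used by the test suite and the
acceptance script.

## Model and statistics

**Per-gene tests.** Differential expression of each gene between the two
phenotype groups is scored by a two-sample test: the pooled-variance
(Student) t-test with `n1 + n2 − 2` degrees of freedom (Welch available as
an option) or the Wilcoxon rank-sum test (exact enumeration up to a total
of 20 samples when the gene has no ties, otherwise the normal
approximation with tie and continuity correction). P-values are two-sided
by default: the Fisher combination requires null-uniform inputs, and
two-sided p-values of a continuous statistic are uniform under the null
regardless of effect direction. Genes constant across all samples get
p = 1 with a logged warning, and all p-values are floored at 1e-300 before
any logarithm.

**Truncated Fisher combination.** The set statistic is
`F = −2 Σ ln(max(p_k, p_min))` over the K genes of the set. `p_min = 0`
gives the classical Fisher statistic, chi-squared with 2K df under
independence. The truncation floor (default `p_min = .01` in the analysis
pipeline) bounds any single gene's contribution at `−2 ln p_min`, so that
set-level significance requires the joint involvement of several genes
rather than one extreme p-value.

**Null of the truncated statistic.** Each term of F is a mixture: with
probability `p_min` the gene is floored and contributes the constant
`−2 ln p_min`; otherwise it contributes `−2 ln U` with `U ~ Uniform(p_min, 1)`,
i.e. twice a truncated Exp(1) on `(0, c)`, `c = −ln p_min`. Two
representations are implemented:

* *Monte-Carlo* (default, mirroring how the distribution is naturally
  constructed): sort `n_draws` simulated statistics; tail probabilities
  use the add-one rule `(1 + #{draws ≥ F})/(1 + n_draws)` and quantiles
  use linear interpolation of the order statistics.
* *Analytic* (the oracle in the tests): a Binomial(K, p_min) mixture over
  the number of floored genes, with the conditional sum of `m` truncated
  exponentials in closed form by inclusion–exclusion,
  `P(S_m ≤ x) = (1−e^{−c})^{−m} Σ_i (−1)^i C(m,i) e^{−ic} γ̃(m, x−ic)`,
  where γ̃ is the regularized lower incomplete gamma function. Terms are
  accumulated in log-magnitude form with compensated summation; the
  alternating series is well conditioned for the floors used in practice
  (`p_min ≤ .3` or so at K ≤ 80). The boundary atom at `−2K ln p_min`
  (all genes floored) has exact mass `p_min^K`, which the survival
  function reproduces.

The two representations agree to within Monte-Carlo sampling error
(sup-distance ≈ 1e-3 at 2·10⁵ draws), and both collapse to chi-squared(2K)
at `p_min = 0`.

**Threshold solvers.** Two design questions about the statistic are
answered in closed form or from the null:

* *Dominant genes (classical Fisher):* the common p-value that
  `n_dominant` genes must reach, with the remaining genes held at
  `p_rest = .5`, for the set to clear level α — solved from
  `−2[n_d ln p + (K−n_d) ln p_rest] = χ²_{2K,1−α}`. If the background
  genes alone clear the bar the result is flagged unattainable.
* *Minimum floored genes (truncated Fisher):* the smallest j with
  `−2[j ln p_min + (K−j) ln .5] > F_α`, where `F_α` is the (1−α)-quantile
  of the truncated null. The inequality is strict, with ties broken
  upward. For `p_min = 0` one gene always suffices. The published integer
  grid (K ∈ {10, 20, 40, 80} × p_min ∈ {.05, .01, .001, 0} at α = .01) is
  reproduced exactly by both the 10⁶-draw Monte-Carlo null and the
  analytic null.

The exact chi-squared solver matches the published dominant-gene grid to
its two-significant-figure printed precision within one unit of the second
digit (the printed table itself appears to carry Monte-Carlo noise in the
last digit; four of twenty cells round to the adjacent value).

**Permutation inference.** Group labels are permuted preserving group
sizes; per-gene p-values and the set statistic are recomputed for every
permutation with the same vectorized kernels used for the observed
labelling (so observed and permuted values are exactly comparable, also
for the rank-sum test where the observed value uses the same normal
approximation inside the engine). Conventions:

* `p_perm = (count_ge + 1)/(B + 1)`, ties counting toward `count_ge`.
  This is the add-one rule: it keeps p-values positive and respects the
  1/B resolution bound of a permutation test.
* Permutations are sampled uniformly *with replacement* from the
  arrangement space; exhaustive enumeration is available when
  `C(n, n1) ≤ 10⁵`.
* All six statistics are oriented so that larger values are more extreme,
  so a single upper-tail rank applies to each.

**Stouffer orientation.** Stouffer's statistic is
`Z_s = Σ z_k / √K` with `z_k = Φ⁻¹(1 − p_k)` when the supplied p-values
are one-sided. The permutation and simulation drivers feed *two-sided*
per-gene p-values, which they map through `z_k = Φ⁻¹(1 − p_k/2)` — the
magnitude of the underlying z. This is a deliberate choice: with the
signed transform of two-sided p-values, sets whose strong genes move in
opposite directions score near zero and the method decorrelates from
Fisher (measured r ≈ .90 on null replicates); the magnitude convention
reproduces the high Fisher–Stouffer agreement (r ≈ .98) that a
combined-evidence method should show, and is the convention under which
the published method-correlation and power figures are recovered.

**SAM-GS.** The t-like component is `d_i = (x̄_i^{(1)} − x̄_i^{(2)})/(se_i + s0)`
with `se_i` the pooled standard error of the mean difference and fudge
constant `s0 = 0` by default (configurable); the statistic is `Σ d_i²`.
With `s0 = 0` and K = 1 it reduces to the squared pooled t.

**Hotelling's T².** `T² = n1 n2/(n1+n2) · d' S⁻¹ d` with S the pooled
covariance. When S is singular (K ≥ n1 + n2 − 2, or exact collinearity)
the Moore–Penrose pseudo-inverse is used and the effective rank logged.

**K-S statistic.** The standard two-sided one-sample Kolmogorov–Smirnov
distance between the set's p-values and Uniform(0,1),
`d = max_k max(k/K − p_(k), p_(k) − (k−1)/K)`.

## P-value extrapolation

A permutation run yields, for every permuted statistic F_b, an
independence-null tail probability `p_uncorr(F_b)` (chi-squared, or the
truncated null when `p_min > 0`) and a rank-based `p_corr(F_b)` among all
B permuted values. On correlated data the permutation distribution of F is
wider than chi-squared, so `p_corr > p_uncorr` in the tail and the ln-ln
relationship is well approximated by a line over a few decades:
`ln p_corr = m ln p_uncorr + ln b`, i.e. `p_corr = b · p_uncorr^m`.

* *Within-run fit* (`fit_extrapolation`): OLS over the permuted pairs with
  `p_corr` in `[10/B, .5]` — below 10/B the rank granularity distorts
  `ln p_corr`, above .5 the tail model is irrelevant. Both bounds are
  configurable; at least 50 usable pairs are required.
* *Pooled fit* (`run_regression_study` / `fit_pooled_regression`): each
  replicate dataset contributes one pair (its observed statistic's two
  p-values) and all pairs with `p_corr < 1` enter the fit. Pooled points
  are independent datasets, so the granularity cutoff needed within a run
  does not apply.
* *Extrapolated p-value:* `min(1, b · p_uncorr^m)`, reported by the
  pipeline when fewer than 10 of B permuted statistics reach the observed
  one (i.e. the observed value is past the budget's resolution).

The regression study at inter-gene correlation r = .05 (100 genes,
100 + 100 patients) uses **one-sided** per-gene t p-values. This is the
condition under which the study recovers the published coefficients
(m ≈ .27–.30, with b ≈ .5–.7 depending on fit depth); with two-sided
per-gene p-values the permutation null of F is much closer to chi-squared
and the slope sits near .8. A directional gene-level test is the natural
reading of a simulation in which the two groups are drawn from two normal
distributions, and the package treats it as part of that study's
conditions (`SimulationConfig.one_sided`, default off elsewhere). At
r = 0 the fit recovers the identity line (m, b) ≈ (1, 1) within
simulation error, as it must.

## Gene-pair dependency factors

During a permutation run each gene is flagged "significant" when its
p-value is ≤ λ (default .05). With `P(A)` the fraction of permutations in
which gene A is flagged and `P(A∧B)` the fraction where both are, the
dependency factor is `P(A∧B)/(P(A)P(B))` — algebraically equal to
`P(A|B)/P(A)` and to `P(B|A)/P(B)`, hence exactly symmetric as computed.
A factor above 1 means the two genes tend to be significant in the same
arbitrary relabellings, i.e. they are statistically linked in the data
regardless of phenotype. Degenerate cases are data, not errors: pairs
involving a never-flagged gene are NaN with a `defined` mask. An exact
duplicate gene attains the maximum factor `1/P(A)` (≈ 1/λ when the
per-gene test is calibrated); independent genes sit near 1. Note that
these probabilities describe the permutation ensemble, not the original
labelling.

## Multiple testing

Across a collection of M tested sets the Benjamini–Hochberg step-up
retains the largest prefix of the ascending p-values with
`p_(k) < k·α/M`. The strict inequality is used as specified for this
procedure; it differs from the conventional `≤` only when a p-value ties
the threshold exactly. Ties in p are ordered by set name (stable), making
the output order reproducible.

## Synthetic-data engine

`SimulationConfig` describes one two-group experiment: K genes,
`n1 + n2` samples, per-gene normal expression with standard deviation σ
(default 1), group-2 mean `mu2` (the signal; default 0), and inter-gene
correlation r imposed by applying the Cholesky factor of the target
correlation matrix to iid normals. The target is compound-symmetric for
scalar r; the oscillating "mixed" rule `r_ij = .15 + .15 sin(2π i j)` is
also implemented — note that for integer gene indices the sine term is
identically zero up to floating-point residue, so the rule effectively
yields a constant .15 off-diagonal; the matrix is eigen-repaired
(eigenvalues floored at 1e-6, diagonal renormalized) before factoring,
with a warning if repair moves any entry by more than .05.

Replicate seeds are spawned deterministically from the master seed
(`numpy.random.SeedSequence`), so every driver is reproducible end to end.

What the generator emulates: the two-phenotype comparison of per-gene
(log-scale) expression with equal variances, exchangeable samples, and
homogeneous pairwise correlation. What it does not: probe-level artifacts,
normalization effects, heavy tails, variance heterogeneity between genes
or groups, realistic block-structured correlation, or confounded designs.
Passing simulation-based tests therefore demonstrates the statistical
machinery under the stated model, not robustness to those features of
real microarray data.

### Study conditions and scales

The study drivers fix the conditions of the corresponding published
experiments; the replicate and permutation budgets are the package's
scaled-down defaults, chosen so that the Monte-Carlo standard error is
several times smaller than each comparison tolerance:

| study | conditions | scale used (original) |
|---|---|---|
| method correlation | K = 20 null genes, 50 + 50 patients, shared permutations per replicate | 2,000 replicates, B = 200 (100,000 p-values, B = 10,000) |
| power | K = 20, shift .15σ in group 2, 50/100/200 patients per group | 2,000 replicates, B = 500 (10,000 replicates, B = 10,000) |
| type-I | K = 20 null genes, 50 + 50 patients | 2,000 replicates, B = 500 (10,000 replicates, B = 10,000) |
| regression | K = 100 genes at r = .05, 100 + 100 patients, one-sided gene p | 200–400 replicates, B = 5,000 (B = 100,000) |
| truncated-null thresholds | K ≤ 80, α = .01 | 10⁶ Monte-Carlo draws, or the analytic mixture |

At these scales the binomial SE of a power estimate is ≤ .011, the
Fisher-z SE of a correlation near .99 is ≈ .0004, and the published
integer thresholds are stable to the quantile convention.

## Numerical choices and degenerate inputs

* p-values are clamped to `[1e-300, 1]` before logarithms and to
  `[1e-300, 1 − 1e-16]` before normal-quantile transforms (with a warning
  at the boundaries).
* Constant genes: p = 1 (t and rank-sum), logged.
* Zero pooled standard error with a nonzero mean difference and `s0 = 0`
  is an error in SAM-GS; with a zero difference the component is 0.
* Fisher statistic values are validated non-negative; `p_min ∈ [0, 1)`.
* The pipeline builds one truncated null per distinct matched set size
  (2·10⁵ draws by default) and caches it across sets.
* Gene matching is exact and case-sensitive; duplicate expression rows
  keep the first occurrence with a warning; GMT lines with duplicate gene
  ids are deduplicated with a warning, and duplicate set names are an
  error.
* Sets with fewer than two matched genes are skipped (and listed), since
  a one-gene "set" statistic is just the gene itself.

## Known limitations

* The truncated-null analytic CDF loses accuracy for large `p_min`
  (≳ .5) at large K, where the inclusion–exclusion series alternates with
  large terms; the Monte-Carlo representation has no such restriction.
* The power-law extrapolation is a model, not a guarantee: it assumes the
  ln-ln relationship stays linear beyond the fitted range. The pipeline
  reports both `p_perm` and `p_extrapolated` so the reader can see when
  the extrapolation was used.
* Dependency factors are estimated at a single λ per run and inherit
  Monte-Carlo noise of order `1/√(B λ)` in each marginal.
* Wilcoxon permutation columns always use the tie-corrected normal
  approximation (including the observed column, for comparability), so
  very small samples analysed with the rank-sum test trade a little
  per-gene accuracy for an internally consistent ranking.
* The engine analyses one set at a time; permutations are not shared
  across sets in the pipeline (they are shared across *methods* in the
  comparison studies, where that removes budget noise from the
  correlations).
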