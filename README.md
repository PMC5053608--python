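# fisherset

Self-contained statistical analysis of gene sets: a truncated Fisher
combination statistic with its exact and Monte-Carlo null distributions,
phenotype-permutation p-values with power-law tail extrapolation, gene-pair
dependency factors, and Benjamini–Hochberg FDR across set collections —
plus a simulation engine for power, type-I and method-comparison studies.

## The problem

Given a gene × sample expression matrix with two phenotype groups (e.g.
leukemia vs. healthy) and a collection of a-priori gene sets (pathways,
signatures — MSigDB GMT files), decide which sets are differentially
expressed *using only the genes inside each set* (a self-contained test,
as opposed to competitive tests like GSEA that score a set against its
complement).

The core statistic combines the per-gene two-sample p-values
`p_1, …, p_K` of a set's K genes:

```
F = −2 Σ_k ln( max(p_k, p_min) )
```

With `p_min = 0` this is Fisher's classical combined-probability statistic,
chi-squared with 2K degrees of freedom when the genes are independent. The
truncation floor `p_min > 0` is the twist: without it, a single gene with
p ≈ 10⁻⁶ can carry an entire 10-gene set to significance on its own. With
the floor in place, several genes must individually reach `p_min` before
the set can clear a given significance level — the package's threshold
solvers compute exactly how many (e.g. 5 of 10 genes at `p_min = .05` for
set-level α = .01).

Because genes in a set are co-regulated, the chi-squared independence null
is anti-conservative in practice. Set-level inference therefore uses
phenotype-label permutations, which preserve the inter-gene correlation in
every resample:

```
p_perm = (1 + #{permuted F ≥ observed F}) / (1 + B)
```

A permutation p-value can never be smaller than ≈ 1/B. For strongly
separated phenotypes, where the true p-value is far below any affordable
budget, the package fits the power law `p_corr = b · p_uncorr^m`
(equivalently `ln p_corr = m ln p_uncorr + ln b`) to the permutation run
and extrapolates. It also estimates, for every gene pair in a set, the
dependency factor `P(A|B)/P(A)` — how much one gene's "significance" in a
permutation raises the other's — from the same permutations.

Five comparison statistics are included (Stouffer's Z, Tail Strength, the
one-sample Kolmogorov–Smirnov distance, SAM-GS, Hotelling's T²), and the
Benjamini–Hochberg step-up controls the FDR across a tested collection.

## Worked example

A synthetic two-set experiment — ten "NOTCH_SIGNALING" genes shifted by
0.9σ between 15 cases and 15 controls, ten "CONTROL_SET" genes null:

```sh
fisherset analyze expr.tsv labels.tsv sets.gmt \
    --out-dir out -B 2000 --p-min 0.01 --seed 0
# 2 sets analysed; 1 retained at FDR 0.05; results in out/results.tsv
```

`out/results.tsv`:

```
set              K   genes_found  F        p_min  p_perm      count_ge  p_uncorr     p_extrapolated  p_reported   bh_retained
NOTCH_SIGNALING  10  10           65.3613  0.01   0.00049975  0         4.99998e-06  3.9122e-05      3.9122e-05   True
CONTROL_SET      10  10           14.5257  0.01   0.809095    1618      0.803111                     0.809095     False
```

Reading the shifted set's row: its truncated Fisher statistic is
F = 65.4; none of the 2,000 permutations reached it, so the rank-based
p-value saturates at its floor 1/2001 ≈ 5·10⁻⁴. Because the observed
statistic is beyond the budget's resolution, the power-law fit to the
permutation run extrapolates the reported p-value to 3.9·10⁻⁵ — above the
independence-null p (5·10⁻⁶, anti-conservative under correlation) but far
below the permutation floor. The null set sits at p ≈ 0.81 and only the
shifted set survives BH at FDR .05.

The simulation drivers print study tables; for example a scaled-down power
run (200 replicate datasets, B = 200 permutations, 20 genes shifted by
.15σ, 100 patients per group):

```python
>>> from fisherset import SimulationConfig, run_power_study
>>> cfg = SimulationConfig(K=20, n1=100, n2=100, mu2=0.15,
...                        n_datasets=200, B=200, seed=5)
>>> run_power_study(cfg)
        fraction_significant  n_datasets    B  alpha
fisher                  0.86         200  200   0.05
```

i.e. a 0.15σ shift over 20 genes is detected 86% of the time at this
sample size — at full scale the package's estimate is ≈ .85 (see below).

Other entry points: `fisherset thresholds --table dominant|minimum`
(significance-threshold tables), `fisherset simulate-power|simulate-type1|
simulate-correlation|simulate-regression` (study drivers with presets),
and the library API (`fisher_F`, `permute_set`, `fit_extrapolation`,
`dependency_factors`, `benjamini_hochberg`, …).

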