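"""Phenotype-label permutation inference for set statistics.

The permutation p-value compares the observed set statistic with the same
statistic recomputed under shuffled group labels.  Because whole samples
are relabelled, the inter-gene correlation structure is preserved in every
permutation - this is the mechanism by which the permutation p-value
("p_corr") accounts for gene-gene dependence that the chi-squared
independence null ("p_uncorr") ignores.

Two by-products of a permutation run are exposed:

* a power-law fit ``p_corr = b * p_uncorr**m`` (equivalently
  ``ln p_corr = m ln p_uncorr + ln b``) relating the two p-value scales,
  which extrapolates permutation p-values far below the 1/B resolution of
  the permutation budget; and
* a gene-pair dependency matrix ``P(A and B) / (P(A) P(B))`` - the factor
  by which one gene's "significance" in a permutation raises the other's -
  estimated from per-permutation per-gene significance flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from . import _engine
from .gene_tests import ExpressionMatrix
from .null_models import ModifiedFisherNull
from .set_statistics import GeneSet, SetStatistic

logger = logging.getLogger(__name__)


@dataclass
class PermutationOutcome:
    """Result of one permutation run for one gene set."""

    observed: SetStatistic
    B: int
    count_ge: int
    p_perm: float
    seed: int | None
    permuted: np.ndarray
    gene_ids: list[str]
    lam: float
    sig_counts: np.ndarray       # per gene: #permutations significant at lam
    joint_counts: np.ndarray     # per gene pair: #permutations both significant
    test: str = "t"

    def __post_init__(self) -> None:
        if not 0 <= self.count_ge <= self.B:
            raise ValueError("count_ge must lie in [0, B]")
        expected = (self.count_ge + 1) / (self.B + 1)
        if abs(self.p_perm - expected) > 1e-12:
            raise ValueError("p_perm must equal (count_ge + 1)/(B + 1)")


@dataclass
class RegressionFit:
    """Power-law map between independence-null and permutation p-values."""

    m: float
    b: float
    n_points: int
    fit_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")


@dataclass
class DependencyMatrix:
    """Pairwise gene dependency factors from a permutation run.

    ``factor[i, j] = P(i and j) / (P(i) P(j))``, algebraically equal to
    ``P(i|j)/P(i)`` and to ``P(j|i)/P(j)``, hence symmetric by
    construction.  Entries involving a gene never significant in any
    permutation are undefined (NaN, ``defined`` False).
    """

    gene_ids: list[str]
    lam: float
    P_single: np.ndarray
    joint: np.ndarray
    factor: np.ndarray
    defined: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.factor, index=self.gene_ids,
                            columns=self.gene_ids)


def permute_set(mat: ExpressionMatrix, gene_set: GeneSet, method: str = "fisher",
                B: int = 1000, seed: int | None = 0, p_min: float = 0.0,
                lam: float = 0.05, test: str = "t", s0: float = 0.0,
                exhaustive: bool = False,
                stouffer_two_sided: bool = True) -> PermutationOutcome:
    """Permutation p-value of one set statistic.

    Group labels are shuffled B times preserving group sizes (uniformly
    with replacement; ``exhaustive=True`` enumerates all arrangements when
    there are at most 100,000).  Per-gene p-values and the set statistic
    are recomputed for every permutation with the same vectorized kernels
    used for the observed labelling, and

        p_perm = (count_ge + 1) / (B + 1)

    where ties (permuted == observed) count toward ``count_ge``.  Per-gene
    significance flags at level ``lam`` are recorded for dependency
    estimation.
    """
    if B < 1 and not exhaustive:
        raise ValueError("B must be >= 1")
    present = [g for g in gene_set.gene_ids if g in set(mat.gene_ids)]
    if not present:
        raise ValueError(f"empty gene set after matching: {gene_set.name!r}")
    sub = mat.subset(present)
    X = sub.values
    n, n1 = sub.n_samples, sub.n1

    rng = np.random.default_rng(seed)
    if exhaustive:
        perm = _engine.exhaustive_masks(n, n1)
        B = perm.shape[0]
    else:
        perm = _engine.permutation_masks(n, n1, B, rng)
    masks = np.vstack([_engine.observed_mask(sub.group1_mask), perm])

    needs_p = method in ("fisher", "stouffer", "tail_strength", "ks")
    P = _engine.gene_pvalues(X, masks, test=test) if needs_p or lam is not None else None
    values = _engine.statistic_columns(method, X, masks, P, p_min=p_min, s0=s0,
                                       stouffer_two_sided=stouffer_two_sided)
    observed = SetStatistic(method, float(values[0]), K=len(gene_set),
                            p_min=p_min if method == "fisher" else 0.0,
                            genes_found=len(present))
    permuted = values[1:]
    count_ge = int((permuted >= observed.value).sum())
    p_perm = (count_ge + 1) / (B + 1)

    sig = P[:, 1:] <= lam                      # K x B boolean
    sig_counts = sig.sum(axis=1).astype(np.int64)
    sig_f = sig.astype(np.float64)
    joint_counts = np.rint(sig_f @ sig_f.T).astype(np.int64)

    return PermutationOutcome(
        observed=observed, B=B, count_ge=count_ge, p_perm=p_perm, seed=seed,
        permuted=np.asarray(permuted, dtype=float), gene_ids=list(present),
        lam=lam, sig_counts=sig_counts, joint_counts=joint_counts, test=test,
    )


def total_arrangements(n: int, n1: int) -> int:
    """Size of the label-arrangement space C(n, n1)."""
    return comb(n, n1)


# ---------------------------------------------------------------------------
# regression extrapolation
# ---------------------------------------------------------------------------

def fit_extrapolation(outcome: PermutationOutcome,
                      null: ModifiedFisherNull | None = None,
                      fit_range: tuple[float, float] | None = None,
                      min_points: int = 50) -> RegressionFit:
    """Fit ``ln p_corr = m ln p_uncorr + ln b`` from a permutation run.

    Every permuted statistic F_b contributes one pair: its independence-
    null upper tail (chi-squared for ``p_min = 0``, else the truncated-
    Fisher null, which must be supplied) and its rank-based p among all B
    permuted statistics.  Ordinary least squares is run over pairs with
    p_corr inside ``fit_range`` (default ``[10/B, 0.5]``: below 10/B rank
    granularity distorts ln p_corr, above 0.5 the tail model is
    irrelevant).
    """
    stat = outcome.observed
    if stat.method != "fisher":
        raise ValueError("extrapolation is defined for the Fisher statistic")
    F = outcome.permuted
    B = outcome.B
    if stat.p_min == 0.0:
        p_uncorr = stats.chi2.sf(F, 2 * stat.K)
    else:
        if null is None:
            raise ValueError("nonzero p_min requires the truncated null")
        if null.K != stat.K or null.p_min != stat.p_min:
            raise ValueError("null does not match the statistic's (K, p_min)")
        p_uncorr = np.asarray(null.sf(F), dtype=float)
    srt = np.sort(F)
    count_ge = B - np.searchsorted(srt, F, side="left")
    p_corr = count_ge / B
    if fit_range is None:
        fit_range = (10.0 / B, 0.5)
    lo, hi = fit_range
    keep = (p_corr >= lo) & (p_corr <= hi) & (p_uncorr > 0)
    if keep.sum() < min_points:
        raise ValueError(
            f"only {int(keep.sum())} pairs in fit range {fit_range}; increase B"
        )
    m, ln_b = np.polyfit(np.log(p_uncorr[keep]), np.log(p_corr[keep]), 1)
    return RegressionFit(m=float(m), b=float(np.exp(ln_b)),
                         n_points=int(keep.sum()), fit_range=(float(lo), float(hi)))


def extrapolate_pvalue(fit: RegressionFit, p_uncorr: float) -> float:
    """Predicted permutation p-value ``min(1, b * p_uncorr**m)``."""
    if not 0.0 < p_uncorr < 1.0:
        raise ValueError("p_uncorr must lie in (0, 1)")
    return float(min(1.0, fit.b * p_uncorr ** fit.m))


def fit_pooled_regression(p_uncorr: np.ndarray, p_corr: np.ndarray,
                          fit_range: tuple[float, float] | None = None,
                          min_points: int = 50) -> RegressionFit:
    """OLS of ln(p_corr) on ln(p_uncorr) over pooled pairs.

    Used by the simulation driver, where each replicate dataset contributes
    one (p_uncorr, p_corr) pair; with ``fit_range=None`` all pairs with
    p_corr < 1 enter the fit (pooled pairs are independent datasets, so the
    rank-granularity cutoff needed for within-run pairs does not apply).
    """
    p_uncorr = np.asarray(p_uncorr, dtype=float)
    p_corr = np.asarray(p_corr, dtype=float)
    keep = (p_uncorr > 0) & (p_corr > 0) & (p_corr < 1)
    if fit_range is not None:
        keep &= (p_corr >= fit_range[0]) & (p_corr <= fit_range[1])
    if keep.sum() < min_points:
        raise ValueError(f"only {int(keep.sum())} usable pairs; increase the "
                         "number of replicates")
    m, ln_b = np.polyfit(np.log(p_uncorr[keep]), np.log(p_corr[keep]), 1)
    rng = fit_range if fit_range is not None else (0.0, 1.0)
    return RegressionFit(m=float(m), b=float(np.exp(ln_b)),
                         n_points=int(keep.sum()),
                         fit_range=(float(rng[0]), float(rng[1])))


# ---------------------------------------------------------------------------
# gene-pair dependencies
# ---------------------------------------------------------------------------

def dependency_factors(outcome: PermutationOutcome) -> DependencyMatrix:
    """Pairwise dependency factors from the recorded significance flags.

    ``P(A)`` is the fraction of permutations in which gene A is significant
    at level ``lam``; the factor ``P(A and B)/(P(A) P(B))`` is symmetric
    and exceeds 1 when the genes tend to be significant together.  Pairs
    involving a never-significant gene are undefined (NaN), which is data,
    not an error.
    """
    B = outcome.B
    P_single = outcome.sig_counts / B
    joint = outcome.joint_counts / B
    denom = np.outer(P_single, P_single)
    defined = denom > 0
    factor = np.full_like(denom, np.nan)
    factor[defined] = joint[defined] / denom[defined]
    return DependencyMatrix(gene_ids=list(outcome.gene_ids), lam=outcome.lam,
                            P_single=P_single, joint=joint, factor=factor,
                            defined=defined)
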