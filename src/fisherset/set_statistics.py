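"""Self-contained set-level statistics.

Six statistics are supported.  Four combine a vector of per-gene p-values
(Fisher with an optional truncation floor, Stouffer, Tail Strength and the
one-sample Kolmogorov-Smirnov distance to U(0,1)); two operate on the
expression submatrix directly (the SAM-GS L2 statistic and Hotelling's T2).

The central statistic is the truncated ("modified") Fisher combination

    F = -2 * sum_k ln(max(p_k, p_min))

where the floor ``p_min`` stops a handful of extremely small gene p-values
from single-handedly making the whole set significant.  With ``p_min = 0``
this is the classical Fisher statistic, chi-squared with 2K degrees of
freedom under independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special

from .gene_tests import P_FLOOR, ExpressionMatrix, PValueVector

logger = logging.getLogger(__name__)

METHODS = ("fisher", "stouffer", "tail_strength", "ks", "samgs", "hotelling")


@dataclass
class GeneSet:
    """A named collection of gene identifiers.

    ``n_total`` optionally records the set size before matching against an
    expression matrix (so that "genes found" can be reported).
    """

    name: str
    description: str = ""
    gene_ids: list[str] = field(default_factory=list)
    n_total: int | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"gene set {self.name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class SetStatistic:
    """One set-level statistic value with its method tag and set size."""

    method: str
    value: float
    K: int
    p_min: float = 0.0
    genes_found: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.method == "fisher" and self.value < -1e-9:
            raise ValueError("Fisher statistic cannot be negative")


def _as_p(p) -> np.ndarray:
    arr = p.p if isinstance(p, PValueVector) else np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty gene set after matching")
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return arr


def fisher_F(p, p_min: float = 0.0) -> SetStatistic:
    """Truncated Fisher combination ``-2 sum ln(max(p_k, p_min))``.

    ``p_min = 0`` gives the classical statistic (p-values are still floored
    at a machine-safe 1e-300 before the logarithm).
    """
    arr = _as_p(p)
    if not 0.0 <= p_min < 1.0:
        raise ValueError("p_min must lie in [0, 1)")
    floor = max(p_min, P_FLOOR)
    value = float(-2.0 * np.log(np.clip(arr, floor, None)).sum())
    return SetStatistic("fisher", value, K=arr.size, p_min=p_min,
                        genes_found=arr.size)


def stouffer_Z(p, two_sided: bool = False) -> SetStatistic:
    """Stouffer's combined z-statistic ``Z_s = sum_k z_k / sqrt(K)``.

    By default ``z_k = Phi^-1(1 - p_k)``, appropriate when the p-values are
    one-sided.  With ``two_sided=True`` each two-sided p-value is mapped
    through ``z_k = Phi^-1(1 - p_k / 2)`` (the magnitude of the underlying
    z), which is the convention used by the permutation and simulation
    drivers in this package.  The consolidated p-value is the upper tail
    ``1 - Phi(Z_s)`` (see :func:`stouffer_set_pvalue`).
    """
    arr = _as_p(p)
    eps = np.finfo(float).tiny
    if np.any(arr >= 1.0) or np.any(arr <= eps):
        logger.warning("p-values at 0 or 1 clamped for the z transform")
    arr = np.clip(arr, 1e-300, 1 - 1e-16)
    z = special.ndtri(1.0 - (arr / 2.0 if two_sided else arr))
    value = float(z.sum() / np.sqrt(arr.size))
    return SetStatistic("stouffer", value, K=arr.size, genes_found=arr.size)


def stouffer_set_pvalue(stat: SetStatistic) -> float:
    """Upper-tail consolidated p-value ``1 - Phi(Z_s)``."""
    if stat.method != "stouffer":
        raise ValueError("statistic is not a Stouffer Z")
    return float(special.ndtr(-stat.value))


def tail_strength(p) -> SetStatistic:
    """Taylor-Tibshirani Tail Strength: mean of ``1 - p_(k) (K+1)/k``."""
    arr = np.sort(_as_p(p))
    K = arr.size
    k = np.arange(1, K + 1)
    value = float(np.mean(1.0 - arr * (K + 1) / k))
    return SetStatistic("tail_strength", value, K=K, genes_found=K)


def ks_statistic(p) -> SetStatistic:
    """Two-sided one-sample K-S distance between the p-values and U(0,1)."""
    arr = np.sort(_as_p(p))
    K = arr.size
    k = np.arange(1, K + 1)
    d = max(np.max(k / K - arr), np.max(arr - (k - 1) / K))
    return SetStatistic("ks", float(d), K=K, genes_found=K)


def _group_moments(mat: ExpressionMatrix, gene_set: GeneSet):
    sub = mat.subset(gene_set.gene_ids)
    m = sub.group1_mask
    return sub.values[:, m], sub.values[:, ~m], sub


def samgs_statistic(mat: ExpressionMatrix, gene_set: GeneSet,
                    s0: float = 0.0) -> SetStatistic:
    """SAM-GS statistic: squared L2 norm of the t-like vector.

    ``d_i = (mean1_i - mean2_i) / (se_i + s0)`` with ``se_i`` the pooled
    standard error of the mean difference, and the statistic is
    ``sum_i d_i**2``.  With ``s0 = 0`` and a single gene this reduces to the
    squared pooled t statistic.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    x1, x2, sub = _group_moments(mat, gene_set)
    n1, n2 = x1.shape[1], x2.shape[1]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    se = np.sqrt(ss / (n1 + n2 - 2) * (1.0 / n1 + 1.0 / n2))
    denom = se + s0
    d = np.zeros_like(diff)
    nonzero = denom > 0
    if np.any(~nonzero & (diff != 0)):
        raise ValueError("zero standard error with nonzero mean difference "
                         "and s0 = 0")
    d[nonzero] = diff[nonzero] / denom[nonzero]
    return SetStatistic("samgs", float(np.sum(d * d)), K=len(gene_set),
                        genes_found=sub.n_genes)


def hotelling_T2(mat: ExpressionMatrix, gene_set: GeneSet) -> SetStatistic:
    """Hotelling's T2 for the two-group mean-vector difference.

    ``T2 = n1 n2/(n1+n2) * d' S^-1 d`` with ``S`` the pooled covariance
    matrix.  When S is singular (K >= n1 + n2 - 2 or exact collinearity)
    the Moore-Penrose pseudo-inverse is used and the effective rank logged.
    """
    x1, x2, sub = _group_moments(mat, gene_set)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for a covariance")
    K = sub.n_genes
    d = x1.mean(axis=1) - x2.mean(axis=1)
    S1 = np.atleast_2d(np.cov(x1))
    S2 = np.atleast_2d(np.cov(x2))
    S = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    value = float(n1 * n2 / (n1 + n2) * d @ _solve_spd(S, d, K, n1 + n2))
    return SetStatistic("hotelling", value, K=len(gene_set), genes_found=K)


def _solve_spd(S: np.ndarray, d: np.ndarray, K: int, n: int) -> np.ndarray:
    if K >= n - 2:
        return _pinv_solve(S, d)
    try:
        return linalg.solve(S, d, assume_a="pos")
    except linalg.LinAlgError:
        return _pinv_solve(S, d)


def _pinv_solve(S: np.ndarray, d: np.ndarray) -> np.ndarray:
    rank = np.linalg.matrix_rank(S)
    logger.info("singular pooled covariance: pseudo-inverse, effective rank %d",
                rank)
    return linalg.pinvh(S) @ d
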