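"""Vectorized phenotype-permutation kernels.

Everything here operates on a gene x sample matrix ``X`` and a stack of
boolean group-1 masks (one row per label arrangement, the first row usually
being the observed labelling).  Group sums against the mask stack turn the
per-permutation two-sample t statistics into two matrix products, which is
what makes permutation studies with thousands of replicates tractable.

These kernels intentionally mirror the scalar routines in
:mod:`fisherset.gene_tests` and :mod:`fisherset.set_statistics`; the test
suite asserts column-by-column agreement between the two paths.
"""

from __future__ import annotations

from math import comb
from itertools import combinations

import numpy as np
from scipy import linalg, special, stats

from .gene_tests import P_FLOOR

#: arrangement-space size below which exhaustive enumeration is offered
EXHAUSTIVE_LIMIT = 100_000


def observed_mask(group1_mask: np.ndarray) -> np.ndarray:
    return np.asarray(group1_mask, dtype=bool)[None, :]


def permutation_masks(n: int, n1: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """B random group-1 masks, sampled uniformly with replacement."""
    idx = np.argsort(rng.random((B, n)), axis=1)[:, :n1]
    masks = np.zeros((B, n), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def exhaustive_masks(n: int, n1: int) -> np.ndarray:
    """All C(n, n1) group-1 masks (only when the space is small)."""
    total = comb(n, n1)
    if total > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{total} arrangements exceed the exhaustive limit {EXHAUSTIVE_LIMIT}"
        )
    masks = np.zeros((total, n), dtype=bool)
    for row, cols in enumerate(combinations(range(n), n1)):
        masks[row, list(cols)] = True
    return masks


def _group_sums(X: np.ndarray, masks: np.ndarray):
    n = X.shape[1]
    n1 = int(masks[0].sum())
    n2 = n - n1
    Mf = masks.T.astype(float)                     # n x B
    S1 = X @ Mf                                    # K x B
    Q1 = (X * X) @ Mf
    T = X.sum(axis=1, keepdims=True)
    Q = (X * X).sum(axis=1, keepdims=True)
    return n1, n2, S1, Q1, T - S1, Q - Q1


def t_pvalues(X: np.ndarray, masks: np.ndarray, one_sided: bool = False) -> np.ndarray:
    """Pooled-variance t-test p-values, shape (K, B).

    Two-sided by default; ``one_sided=True`` gives the upper-tail p of the
    signed statistic (group 1 mean larger => small p).
    """
    n = X.shape[1]
    n1, n2, S1, Q1, S2, Q2 = _group_sums(X, masks)
    ss = (Q1 - S1 * S1 / n1) + (Q2 - S2 * S2 / n2)
    sp2 = ss / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = S1 / n1 - S2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    if one_sided:
        p = stats.t.sf(t, n - 2)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # degenerate columns (zero pooled variance): p = 1 when diff is also 0
    bad = ~np.isfinite(p)
    if bad.any():
        p = np.where(bad & (diff == 0), 1.0, p)
        p = np.where(~np.isfinite(p), P_FLOOR, p)
    return np.clip(p, P_FLOOR, 1.0)


def wilcoxon_pvalues(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Rank-sum p-values via the tie- and continuity-corrected normal
    approximation, shape (K, B).

    Ranks per gene do not change under label permutation, so the rank sum
    of group 1 is again a matrix product.
    """
    K, n = X.shape
    n1 = int(masks[0].sum())
    n2 = n - n1
    ranks = stats.rankdata(X, axis=1)
    W1 = ranks @ masks.T.astype(float)             # K x B
    mu = n1 * (n + 1) / 2.0
    # tie correction per gene: sum over tie groups of (t^3 - t)
    srt = np.sort(X, axis=1)
    tie_sum = np.empty(K)
    for i in range(K):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_sum[i] = np.sum(counts.astype(float) ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    sd = np.sqrt(var)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.clip(np.abs(W1 - mu) - 0.5, 0.0, None) / sd
    p = 2.0 * special.ndtr(-z)
    p = np.where(np.isfinite(p), p, 1.0)           # all-tied genes
    return np.clip(p, P_FLOOR, 1.0)


def gene_pvalues(X: np.ndarray, masks: np.ndarray, test: str = "t",
                 one_sided: bool = False) -> np.ndarray:
    if test == "t":
        return t_pvalues(X, masks, one_sided=one_sided)
    if test == "wilcoxon":
        if one_sided:
            raise ValueError("one-sided rank-sum p-values are not supported")
        return wilcoxon_pvalues(X, masks)
    raise ValueError(f"unknown per-gene test {test!r}")


# ---------------------------------------------------------------------------
# column-wise set statistics
# ---------------------------------------------------------------------------

def fisher_columns(P: np.ndarray, p_min: float = 0.0) -> np.ndarray:
    floor = max(p_min, P_FLOOR)
    return -2.0 * np.log(np.clip(P, floor, None)).sum(axis=0)


def stouffer_columns(P: np.ndarray, two_sided: bool = True) -> np.ndarray:
    Pc = np.clip(P, 1e-300, 1 - 1e-16)
    z = special.ndtri(1.0 - (Pc / 2.0 if two_sided else Pc))
    return z.sum(axis=0) / np.sqrt(P.shape[0])


def tail_strength_columns(P: np.ndarray) -> np.ndarray:
    K = P.shape[0]
    srt = np.sort(P, axis=0)
    k = np.arange(1, K + 1)[:, None]
    return np.mean(1.0 - srt * (K + 1) / k, axis=0)


def ks_columns(P: np.ndarray) -> np.ndarray:
    K = P.shape[0]
    srt = np.sort(P, axis=0)
    k = np.arange(1, K + 1)[:, None]
    d_plus = (k / K - srt).max(axis=0)
    d_minus = (srt - (k - 1) / K).max(axis=0)
    return np.maximum(d_plus, d_minus)


def samgs_columns(X: np.ndarray, masks: np.ndarray, s0: float = 0.0) -> np.ndarray:
    n = X.shape[1]
    n1, n2, S1, Q1, S2, Q2 = _group_sums(X, masks)
    ss = (Q1 - S1 * S1 / n1) + (Q2 - S2 * S2 / n2)
    se = np.sqrt(ss / (n - 2) * (1.0 / n1 + 1.0 / n2))
    diff = S1 / n1 - S2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (se + s0)
    d = np.where(np.isfinite(d), d, 0.0)
    return (d * d).sum(axis=0)


def hotelling_columns(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    K, n = X.shape
    n1 = int(masks[0].sum())
    n2 = n - n1
    out = np.empty(masks.shape[0])
    use_pinv = K >= n - 2
    for b in range(masks.shape[0]):
        m = masks[b]
        x1 = X[:, m]
        x2 = X[:, ~m]
        d = x1.mean(axis=1) - x2.mean(axis=1)
        S = ((n1 - 1) * np.atleast_2d(np.cov(x1))
             + (n2 - 1) * np.atleast_2d(np.cov(x2))) / (n - 2)
        if use_pinv:
            sol = linalg.pinvh(S) @ d
        else:
            try:
                sol = linalg.solve(S, d, assume_a="pos")
            except linalg.LinAlgError:
                sol = linalg.pinvh(S) @ d
        out[b] = n1 * n2 / n * d @ sol
    return out


def statistic_columns(method: str, X: np.ndarray, masks: np.ndarray,
                      P: np.ndarray | None, p_min: float = 0.0,
                      s0: float = 0.0, stouffer_two_sided: bool = True) -> np.ndarray:
    """Set statistic per mask column; all six methods rank "larger = more
    significant" so a shared upper-tail permutation p applies."""
    if method in ("fisher", "stouffer", "tail_strength", "ks") and P is None:
        raise ValueError(f"method {method!r} needs per-gene p-values")
    if method == "fisher":
        return fisher_columns(P, p_min)
    if method == "stouffer":
        return stouffer_columns(P, two_sided=stouffer_two_sided)
    if method == "tail_strength":
        return tail_strength_columns(P)
    if method == "ks":
        return ks_columns(P)
    if method == "samgs":
        return samgs_columns(X, masks, s0=s0)
    if method == "hotelling":
        return hotelling_columns(X, masks)
    raise ValueError(f"unknown method {method!r}")
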