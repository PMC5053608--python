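"""Null distributions and threshold solvers for the (truncated) Fisher
combination statistic.

With ``p_min = 0`` the Fisher statistic of K independent uniform p-values is
chi-squared with 2K degrees of freedom.  With a truncation floor
``p_min > 0`` each gene contributes ``-2 ln(max(U, p_min))``, i.e. a point
mass ``-2 ln p_min`` with probability ``p_min`` plus a truncated
exponential otherwise.  Two representations of that null are provided:

* Monte-Carlo (the default): sort a large number of simulated draws and
  read tail probabilities and quantiles off the empirical distribution.
* Analytic: a binomial mixture over the number of floored genes, with the
  conditional sum of truncated exponentials evaluated in closed form by
  inclusion-exclusion over regularized incomplete gamma functions.

The threshold solvers answer two design questions about the statistic: how
small a handful of dominant gene p-values must be to carry an entire set to
significance (classical Fisher), and - once the floor is in place - how
many genes at the floor are required (the point of the truncation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, exp, fsum, lgamma, log

import numpy as np
from scipy import optimize, special, stats

from .set_statistics import SetStatistic

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# analytic pieces: sum of m iid truncated Exp(1) variables on (0, c)
# ---------------------------------------------------------------------------

def _truncated_exp_sum_cdf(x: float, m: int, c: float) -> float:
    """P(V_1 + ... + V_m <= x) for iid V with density e^-v / (1 - e^-c)
    on (0, c).  Inclusion-exclusion over how many terms exceed c."""
    if m == 0:
        return 1.0 if x >= 0 else 0.0
    if x <= 0:
        return 0.0
    if x >= m * c:
        return 1.0
    log_z = log(1.0 - exp(-c))
    terms = []
    for i in range(min(m, int(x // c)) + 1):
        g = special.gammainc(m, x - i * c)  # regularized lower gamma
        if g <= 0.0:
            continue
        log_mag = (lgamma(m + 1) - lgamma(i + 1) - lgamma(m - i + 1)
                   - i * c - m * log_z + log(g))
        terms.append((-1.0) ** i * exp(log_mag))
    return min(1.0, max(0.0, fsum(terms)))


def _truncated_exp_sum_sf(x: float, m: int, c: float) -> float:
    if m == 0:
        return 1.0 if x <= 0 else 0.0
    if x <= 0:
        return 1.0
    if x >= m * c:
        return 0.0
    return 1.0 - _truncated_exp_sum_cdf(x, m, c)


@dataclass
class ModifiedFisherNull:
    """Null distribution of the truncated Fisher statistic.

    ``kind`` is "mc" (sorted Monte-Carlo draws in ``draws``) or "analytic"
    (closed-form mixture; ``draws`` is None).  ``p_min = 0`` collapses to
    the chi-squared(2K) distribution in either representation.
    """

    K: int
    p_min: float
    kind: str = "mc"
    draws: np.ndarray | None = None
    n_draws: int = 0
    seed: int | None = None

    @property
    def max_support(self) -> float:
        if self.p_min == 0.0:
            return np.inf
        return -2.0 * self.K * np.log(self.p_min)

    # -- distribution functions ------------------------------------------
    def sf(self, x) -> np.ndarray | float:
        """Upper-tail probability P(F >= x) (ties included, matching the
        Monte-Carlo counting convention)."""
        x = np.asarray(x, dtype=float)
        if self.p_min == 0.0:
            out = stats.chi2.sf(x, 2 * self.K)
        elif self.kind == "mc":
            idx = np.searchsorted(self.draws, x, side="left")
            out = (1.0 + (self.n_draws - idx)) / (1.0 + self.n_draws)
        else:
            out = np.vectorize(self._analytic_sf)(x)
        return float(out) if out.ndim == 0 else out

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if self.p_min == 0.0:
            out = stats.chi2.cdf(x, 2 * self.K)
        elif self.kind == "mc":
            out = np.searchsorted(self.draws, x, side="right") / self.n_draws
        else:
            out = np.vectorize(self._analytic_cdf)(x)
        return float(out) if out.ndim == 0 else out

    def quantile(self, q: float) -> float:
        """q-quantile; linear interpolation of the sorted draws for the MC
        representation, bisection of the CDF for the analytic one."""
        if not 0.0 < q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.p_min == 0.0:
            return float(stats.chi2.ppf(q, 2 * self.K))
        if self.kind == "mc":
            return float(np.quantile(self.draws, q))
        hi = self.max_support
        return float(optimize.brentq(lambda x: self._analytic_cdf(x) - q,
                                     0.0, hi, xtol=1e-10 * max(hi, 1.0)))

    def mean(self) -> float:
        if self.p_min == 0.0:
            return 2.0 * self.K
        if self.kind == "mc":
            return float(self.draws.mean())
        c = -log(self.p_min)
        # E[-2 ln max(U, p_min)] = 2 * (E[V] * (1 - p_min) + c * p_min)
        ev = (1.0 - (1.0 + c) * exp(-c)) / (1.0 - exp(-c))
        return 2.0 * self.K * (ev * (1.0 - self.p_min) + c * self.p_min)

    # -- analytic mixture -------------------------------------------------
    def _mixture(self, x: float, surv: bool) -> float:
        c = -log(self.p_min)
        pmf = stats.binom.pmf(np.arange(self.K + 1), self.K, self.p_min)
        total = 0.0
        for j in range(self.K + 1):
            if pmf[j] < 1e-18:
                continue
            u = (x - 2.0 * j * c) / 2.0
            m = self.K - j
            part = (_truncated_exp_sum_sf(u, m, c) if surv
                    else _truncated_exp_sum_cdf(u, m, c))
            total += pmf[j] * part
        return min(1.0, max(0.0, total))

    def _analytic_cdf(self, x: float) -> float:
        return self._mixture(x, surv=False)

    def _analytic_sf(self, x: float) -> float:
        return self._mixture(x, surv=True)


def build_modified_null(K: int, p_min: float, n_draws: int = 10**6,
                        seed: int | None = 0, method: str = "mc",
                        chunk: int = 200_000) -> ModifiedFisherNull:
    """Construct the null of the truncated Fisher statistic for (K, p_min).

    The Monte-Carlo representation draws K iid U(0,1) per replicate and
    applies the truncated statistic; draws are stored sorted.  The analytic
    representation needs no sampling and serves as an independent oracle.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 <= p_min < 1.0:
        raise ValueError("p_min must lie in [0, 1)")
    if method == "analytic" or p_min == 0.0:
        return ModifiedFisherNull(K=K, p_min=p_min, kind="analytic",
                                  draws=None, n_draws=0, seed=None)
    if method != "mc":
        raise ValueError(f"unknown representation {method!r}")
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        u = rng.random((m, K))
        np.clip(u, p_min, None, out=u)
        out[done:done + m] = -2.0 * np.log(u).sum(axis=1)
        done += m
    out.sort()
    return ModifiedFisherNull(K=K, p_min=p_min, kind="mc", draws=out,
                              n_draws=n_draws, seed=seed)


# ---------------------------------------------------------------------------
# set-level p-values
# ---------------------------------------------------------------------------

def chisq_set_pvalue(stat: SetStatistic) -> float:
    """Upper-tail chi-squared(2K) p-value of a classical Fisher statistic."""
    if stat.method != "fisher":
        raise ValueError("statistic is not a Fisher combination")
    if stat.p_min != 0.0:
        raise ValueError("nonzero p_min: use the modified null")
    return float(stats.chi2.sf(stat.value, 2 * stat.K))


def modified_set_pvalue(stat: SetStatistic, null: ModifiedFisherNull) -> float:
    """Upper-tail p-value of a truncated Fisher statistic under ``null``.

    The Monte-Carlo representation returns ``(1 + #{draws >= F}) /
    (1 + n_draws)``; the analytic one returns the exact tail mass (with the
    atom at F included, so the boundary value ``F = -2K ln p_min`` yields
    ``p_min**K`` exactly).
    """
    if stat.method != "fisher":
        raise ValueError("statistic is not a Fisher combination")
    if stat.K != null.K or stat.p_min != null.p_min:
        raise ValueError(
            f"statistic (K={stat.K}, p_min={stat.p_min}) does not match "
            f"null (K={null.K}, p_min={null.p_min})"
        )
    return float(null.sf(stat.value))


# ---------------------------------------------------------------------------
# threshold solvers
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    """Outcome of a significance-threshold calculation."""

    K: int
    alpha: float
    F_alpha: float
    p_min: float | None = None
    n_dominant: int | None = None
    p_single: float | None = None
    K_min: int | None = None
    attainable: bool = True


def dominant_gene_threshold(K: int, n_dominant: int, alpha: float = 0.01,
                            p_rest: float = 0.5) -> ThresholdResult:
    """Common p-value that ``n_dominant`` genes must reach for the whole
    set to be significant at ``alpha`` under classical Fisher.

    The remaining ``K - n_dominant`` genes are assumed to sit at
    ``p_rest`` (0.5 by default, i.e. perfectly unremarkable).  Solves
    ``-2 [n_d ln p + (K - n_d) ln p_rest] = chi2_{2K, 1-alpha}``.
    """
    if not 1 <= n_dominant <= K:
        raise ValueError("n_dominant must lie in [1, K]")
    if not 0.0 < p_rest < 1.0:
        raise ValueError("p_rest must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    F_alpha = float(stats.chi2.isf(alpha, 2 * K))
    ln_p = (-F_alpha / 2.0 - (K - n_dominant) * np.log(p_rest)) / n_dominant
    if ln_p >= 0.0:
        # the unremarkable genes alone already exceed the critical value
        return ThresholdResult(K=K, alpha=alpha, F_alpha=F_alpha,
                               n_dominant=n_dominant, p_single=1.0,
                               attainable=False)
    return ThresholdResult(K=K, alpha=alpha, F_alpha=F_alpha,
                           n_dominant=n_dominant, p_single=float(np.exp(ln_p)))


def minimum_genes_required(K: int, p_min: float, alpha: float = 0.01,
                           null: ModifiedFisherNull | None = None,
                           n_draws: int = 10**6,
                           seed: int | None = 0,
                           method: str = "mc") -> ThresholdResult:
    """Smallest number of genes at the floor ``p_min`` needed to push a set
    of K genes past the ``alpha`` critical value of the truncated null.

    The remaining genes are assumed to sit at p = 0.5.  The critical value
    ``F_alpha`` is the (1 - alpha)-quantile of the truncated-Fisher null;
    the count ``K_min`` is the smallest j with
    ``-2 [j ln p_min + (K - j) ln 0.5] > F_alpha`` (strict).  For
    ``p_min = 0`` a single gene always suffices.
    """
    if p_min == 0.0:
        F_alpha = float(stats.chi2.isf(alpha, 2 * K))
        return ThresholdResult(K=K, alpha=alpha, F_alpha=F_alpha,
                               p_min=p_min, K_min=1)
    if null is None:
        null = build_modified_null(K, p_min, n_draws=n_draws, seed=seed,
                                   method=method)
    if null.K != K or null.p_min != p_min:
        raise ValueError("null was built for different (K, p_min)")
    F_alpha = null.quantile(1.0 - alpha)
    js = np.arange(1, K + 1)
    floored = -2.0 * (js * np.log(p_min) + (K - js) * np.log(0.5))
    passing = js[floored > F_alpha]
    if passing.size == 0:
        return ThresholdResult(K=K, alpha=alpha, F_alpha=F_alpha, p_min=p_min,
                               K_min=None, attainable=False)
    return ThresholdResult(K=K, alpha=alpha, F_alpha=F_alpha, p_min=p_min,
                           K_min=int(passing[0]))


def required_proportion_curve(K_list, p_min_list, alpha: float = 0.01,
                              n_draws: int = 10**6, seed: int | None = 0,
                              method: str = "mc"):
    """Proportion K_min / K of genes required at the floor, over a grid.

    Returns a pandas DataFrame indexed by K with one column per p_min
    (NaN where no count of floored genes attains significance).
    """
    import pandas as pd

    rows = {}
    for K in K_list:
        row = {}
        for p_min in p_min_list:
            res = minimum_genes_required(K, p_min, alpha=alpha,
                                         n_draws=n_draws, seed=seed,
                                         method=method)
            row[p_min] = (res.K_min / K) if res.K_min is not None else np.nan
        rows[K] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "K"
    return df


def dominant_gene_table(K_list=(10, 20, 40, 80), n_dominant_list=(1, 2, 3, 4, 5),
                        alpha: float = 0.01, p_rest: float = 0.5):
    """Dominant-gene thresholds over a grid (DataFrame, K by n_dominant)."""
    import pandas as pd

    data = {
        K: {n: dominant_gene_threshold(K, n, alpha=alpha, p_rest=p_rest).p_single
            for n in n_dominant_list}
        for K in K_list
    }
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "K"
    df.columns = [f"p ({n} gene{'s' if n > 1 else ''})" for n in n_dominant_list]
    return df


def minimum_genes_table(K_list=(10, 20, 40, 80), p_min_list=(0.05, 0.01, 0.001, 0.0),
                        alpha: float = 0.01, n_draws: int = 10**6,
                        seed: int | None = 0, method: str = "mc"):
    """Minimum floored-gene counts over a grid (DataFrame, K by p_min)."""
    import pandas as pd

    data = {}
    for K in K_list:
        row = {}
        for p_min in p_min_list:
            res = minimum_genes_required(K, p_min, alpha=alpha,
                                         n_draws=n_draws, seed=seed,
                                         method=method)
            row[f"p_min={p_min}"] = res.K_min
        data[K] = row
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "K"
    return df
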