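"""Benjamini-Hochberg false-discovery-rate control across gene sets.

When a whole collection of sets is tested, the BH step-up procedure orders
the set p-values ``p_(1) <= ... <= p_(M)`` and retains the largest prefix
``k*`` with ``p_(k) < k * alpha / M``.  The strict inequality is used here
(the conventional procedure uses <=; the two differ only at exact ties,
see the package docs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FdrResult:
    """Outcome of the BH step-up procedure."""

    set_names: list[str]       # ordered by ascending p (ties by name)
    p_sorted: np.ndarray
    alpha: float
    k_star: int
    retained: list[str]

    def __post_init__(self) -> None:
        if not 0 <= self.k_star <= len(self.set_names):
            raise ValueError("k_star out of range")


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> FdrResult:
    """BH step-up over a named collection of p-values.

    ``pvalues`` is a mapping (or pandas Series) of set name -> p-value in
    [0, 1].  Ties in p are broken by a stable sort on the set name so the
    output order is reproducible.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    items = list(pvalues.items())
    if not items:
        raise ValueError("no p-values supplied")
    names = [str(k) for k, _ in items]
    p = np.asarray([float(v) for _, v in items])
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    order = sorted(range(len(p)), key=lambda i: (p[i], names[i]))
    p_sorted = p[order]
    sorted_names = [names[i] for i in order]
    M = len(p)
    k = np.arange(1, M + 1)
    passing = np.nonzero(p_sorted < k * alpha / M)[0]
    k_star = int(passing[-1] + 1) if passing.size else 0
    return FdrResult(set_names=sorted_names, p_sorted=p_sorted, alpha=alpha,
                     k_star=k_star, retained=sorted_names[:k_star])
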