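"""Per-gene two-sample differential-expression tests.

Every set-level statistic in this package consumes the vector of individual
gene p-values produced here (or the expression submatrix directly).  Two
tests are provided: the two-sample pooled-variance t-test (Welch optional)
and the Wilcoxon rank-sum test.  P-values are two-sided by default so that
they are uniform under the null, which the Fisher combination requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

#: floor applied to p-values before any logarithm, to keep ln(p) finite
P_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a two-group phenotype.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``, arbitrary units.
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    group_labels
        One of exactly two phenotype labels per sample; each group must
        contain at least two samples.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group_labels = np.asarray([str(g) for g in self.group_labels])
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match row count")
        if len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.group_labels.shape[0] != self.values.shape[1]:
            raise ValueError("group_labels length does not match sample count")
        groups = list(dict.fromkeys(self.group_labels))  # first-appearance order
        if len(groups) != 2:
            raise ValueError(
                f"exactly two phenotype groups required, got {len(groups)}"
            )
        counts = {g: int((self.group_labels == g).sum()) for g in groups}
        if min(counts.values()) < 2:
            raise ValueError(f"each group needs >= 2 samples, got {counts}")
        self._groups = tuple(groups)

    # -- convenience accessors -------------------------------------------
    @property
    def groups(self) -> tuple[str, str]:
        """The two group labels, in order of first appearance."""
        return self._groups

    @property
    def group1_mask(self) -> np.ndarray:
        return self.group_labels == self._groups[0]

    @property
    def n1(self) -> int:
        return int(self.group1_mask.sum())

    @property
    def n2(self) -> int:
        return self.values.shape[1] - self.n1

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset to ``gene_ids`` (all must be present), preserving order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[rows],
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            group_labels=self.group_labels.copy(),
        )


@dataclass
class PValueVector:
    """Per-gene p-values in (0, 1] with matching identifiers."""

    p: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    test_name: str = ""

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("p must be a 1-D vector")
        if self.gene_ids and len(self.gene_ids) != self.p.shape[0]:
            raise ValueError("gene_ids length does not match p length")
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.p.shape[0]


def _split(mat: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    m = mat.group1_mask
    return mat.values[:, m], mat.values[:, ~m]


def t_test_per_gene(mat: ExpressionMatrix, equal_var: bool = True) -> PValueVector:
    """Two-sided two-sample t-test for every gene.

    Uses the pooled-variance (Student) statistic with ``n1 + n2 - 2``
    degrees of freedom by default; set ``equal_var=False`` for Welch.
    Genes that are constant across all samples get p = 1 with a warning.
    """
    x1, x2 = _split(mat)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x1, x2, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "%d gene(s) constant in both groups; p set to 1", int(degenerate.sum())
        )
        p[degenerate] = 1.0
    return PValueVector(
        p=np.clip(p, P_FLOOR, 1.0), gene_ids=list(mat.gene_ids), test_name="t"
    )


def wilcoxon_test_per_gene(mat: ExpressionMatrix) -> PValueVector:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for every gene.

    Exact enumeration is used when the total sample size is at most 20 and
    the gene has no ties; otherwise the normal approximation with tie and
    continuity correction.  All-tied genes get p = 1 with a warning.
    """
    x1, x2 = _split(mat)
    n_total = mat.n_samples
    p = np.empty(mat.n_genes)
    n_degenerate = 0
    for i in range(mat.n_genes):
        a, b = x1[i], x2[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[i] = 1.0
            n_degenerate += 1
            continue
        has_ties = len(np.unique(np.concatenate([a, b]))) < n_total
        method = "exact" if (n_total <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
        p[i] = min(float(res.pvalue), 1.0)
    if n_degenerate:
        logger.warning("%d gene(s) fully tied; p set to 1", n_degenerate)
    return PValueVector(
        p=np.clip(p, P_FLOOR, 1.0), gene_ids=list(mat.gene_ids), test_name="wilcoxon"
    )


def exact_rank_sum_pvalue(x1: np.ndarray, x2: np.ndarray) -> float:
    """Two-sided rank-sum p-value by full enumeration (small-sample oracle).

    Enumerates all C(n1+n2, n1) assignments of the pooled observations to
    group 1 and counts rank sums at least as extreme as the observed one in
    either direction.  Intended for tests; cost grows combinatorially.
    """
    from itertools import combinations

    pooled = np.concatenate([x1, x2])
    ranks = stats.rankdata(pooled)
    n1 = len(x1)
    observed = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total
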