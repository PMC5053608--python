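"""Readers and writers for the pipeline's file formats.

Expression matrices are TSV/CSV with gene identifiers in the first column
and sample identifiers in the header; phenotype labels come in a separate
two-column file.  Gene-set collections use the GMT format distributed by
MSigDB (tab-separated: name, description, then gene ids).  Gene-id
matching is exact and case-sensitive throughout - silent case-folding
causes false matches across nomenclatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_tests import ExpressionMatrix
from .permutation import DependencyMatrix
from .set_statistics import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """A list of gene sets with unique names, usually read from a GMT file."""

    sets: list[GeneSet] = field(default_factory=list)
    source: str | None = None
    skipped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set name(s): {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def _sep_for(path) -> str | None:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_matrix(expr_path, labels_path) -> ExpressionMatrix:
    """Read an expression TSV/CSV plus a two-column (sample, group) label
    file into an :class:`ExpressionMatrix`.

    Duplicate gene ids keep the first occurrence with a warning (probe
    collapsing is upstream of this package).  Label-file samples are
    matched to expression columns by id; every expression column must be
    labelled.
    """
    df = pd.read_csv(expr_path, sep=_sep_for(expr_path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.warning("%d duplicate gene id(s): keeping first occurrence", n)
        df = df[~df.index.duplicated(keep="first")]

    lab = pd.read_csv(labels_path, sep=None, engine="python", header=None,
                      comment="#", dtype=str)
    if lab.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, group")
    lab = lab.iloc[:, :2]
    lab.columns = ["sample_id", "group"]
    first = lab.iloc[0]
    if (first["sample_id"].lower() in ("sample", "sample_id", "id")
            and first["group"].lower() in ("group", "label", "phenotype", "class")):
        lab = lab.iloc[1:]
    mapping = dict(zip(lab["sample_id"], lab["group"]))
    missing = [s for s in df.columns if s not in mapping]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(df.index),
        sample_ids=[str(c) for c in df.columns],
        group_labels=np.array([mapping[str(c)] for c in df.columns]),
    )


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, name TAB description TAB gene ids...

    Duplicate gene ids within a line are deduplicated with a warning;
    a line with fewer than three fields or a repeated set name is an
    error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning("%s:%d: %d duplicate gene id(s) in set %r "
                               "deduplicated", path, lineno,
                               len(genes) - len(unique), name)
            sets.append(GeneSet(name=name, description=description,
                                gene_ids=unique, n_total=len(unique)))
    return GeneSetCollection(sets=sets, source=str(path))


def match_sets(collection: GeneSetCollection,
               mat: ExpressionMatrix) -> GeneSetCollection:
    """Drop set genes absent from the matrix; record the original sizes.

    Sets reduced to fewer than two genes are skipped (listed in
    ``skipped``) with a warning.  Each surviving set's ``n_total`` is its
    size before matching, so "genes found" can be reported as
    ``len(set)`` of ``n_total``.
    """
    present = set(mat.gene_ids)
    matched: list[GeneSet] = []
    skipped: list[str] = []
    for s in collection:
        found = [g for g in s.gene_ids if g in present]
        if len(found) < 2:
            logger.warning("set %r has %d gene(s) in the matrix; skipped",
                           s.name, len(found))
            skipped.append(s.name)
            continue
        matched.append(GeneSet(name=s.name, description=s.description,
                               gene_ids=found,
                               n_total=s.n_total or len(s.gene_ids)))
    return GeneSetCollection(sets=matched, source=collection.source,
                             skipped=skipped)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_dependency_tsv(dep: DependencyMatrix, path) -> None:
    """Square TSV of dependency factors (gene ids as header), heat-map
    ready."""
    write_table(dep.to_frame(), path)


def plot_dependency_heatmap(dep: DependencyMatrix, path) -> None:
    """Optional heat-map export of the dependency factors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    data = np.ma.masked_invalid(dep.factor)
    im = ax.imshow(data, cmap="hot_r", interpolation="nearest")
    ax.set_xticks(range(len(dep.gene_ids)))
    ax.set_yticks(range(len(dep.gene_ids)))
    ax.set_xticklabels(dep.gene_ids, rotation=90, fontsize=6)
    ax.set_yticklabels(dep.gene_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="P(A|B)/P(A)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
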