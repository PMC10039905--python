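"""Clone bookkeeping on single-cell whole-chromosome copy-number matrices.

A clone is a group of at least two cells with identical whole-chromosome
profiles; cells with a profile seen only once are "unique genomes".
Distances between cells are Manhattan (L1) over chromosomes.  The
heterogeneity score here is a documented surrogate — mean per-cell
Manhattan distance to the population's modal profile, per chromosome — and
is not numerically comparable to scores produced by external single-cell
copy-number callers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CHROMOSOMES

__all__ = [
    "CellMatrix",
    "CloneCall",
    "call_clones",
    "manhattan_matrix",
    "heterogeneity_score",
]


@dataclass
class CellMatrix:
    """Cells x chromosomes integer copy numbers (whole-chromosome)."""

    values: np.ndarray
    cell_ids: list[str] | None = None
    columns: tuple[str, ...] = CHROMOSOMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("cell matrix must be 2-D (cells x chromosomes)")
        if (self.values < 0).any():
            raise ValueError("copy numbers must be non-negative")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.values.shape[0])]
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match the number of rows")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column labels must match the number of columns")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.cell_ids, columns=list(self.columns))
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CellMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), cell_ids=list(df.index.astype(str)),
                   columns=tuple(df.columns.astype(str)))


@dataclass
class CloneCall:
    """Clone assignment of a cell matrix.

    ``labels[i]`` is the clone index of cell i, or -1 for a unique genome.
    Clone indices are ordered by decreasing size.  ``fractions`` are clone
    sizes over the total cell count, so they sum to <= 1 (unique genomes
    account for the remainder).
    """

    labels: np.ndarray
    profiles: np.ndarray  # (n_clones, n_chrom)
    fractions: np.ndarray
    n_unique_genomes: int

    @property
    def n_clones(self) -> int:
        return self.profiles.shape[0]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "clone": [chr(ord("A") + i) if i < 26 else f"C{i}" for i in range(self.n_clones)],
            "n_cells": [(self.labels == i).sum() for i in range(self.n_clones)],
            "fraction": self.fractions,
        })


def call_clones(matrix: CellMatrix | np.ndarray) -> CloneCall:
    """Group cells with identical profiles; size >= 2 makes a clone."""
    values = matrix.values if isinstance(matrix, CellMatrix) else np.asarray(matrix)
    if values.shape[0] < 1:
        raise ValueError("need at least one cell")
    uniq, inverse, counts = np.unique(
        values, axis=0, return_inverse=True, return_counts=True
    )
    clone_mask = counts >= 2
    order = np.argsort(-counts[clone_mask], kind="stable")
    clone_profiles = uniq[clone_mask][order]
    old_to_new = -np.ones(uniq.shape[0], dtype=np.int64)
    old_to_new[np.flatnonzero(clone_mask)[order]] = np.arange(order.size)
    labels = old_to_new[inverse]
    n = values.shape[0]
    fractions = np.array([(labels == i).sum() / n for i in range(order.size)])
    return CloneCall(
        labels=labels,
        profiles=clone_profiles,
        fractions=fractions,
        n_unique_genomes=int((labels == -1).sum()),
    )


def manhattan_matrix(matrix: CellMatrix | np.ndarray) -> np.ndarray:
    """Pairwise Manhattan distances between cells (symmetric, zero diagonal)."""
    values = matrix.values if isinstance(matrix, CellMatrix) else np.asarray(matrix)
    if values.shape[0] < 2:
        raise ValueError("need at least two cells")
    return squareform(pdist(values.astype(float), metric="cityblock"))


def heterogeneity_score(matrix: CellMatrix | np.ndarray) -> float:
    """Mean per-cell Manhattan distance to the modal profile, per chromosome.

    Zero iff every cell equals the per-chromosome modal profile.  A
    surrogate summary of karyotype heterogeneity; see the module docstring.
    """
    values = matrix.values if isinstance(matrix, CellMatrix) else np.asarray(matrix)
    if values.shape[0] < 2:
        raise ValueError("need at least two cells")
    n_chrom = values.shape[1]
    modal = np.empty(n_chrom, dtype=np.int64)
    for j in range(n_chrom):
        vals, counts = np.unique(values[:, j], return_counts=True)
        modal[j] = vals[np.argmax(counts)]
    dist = np.abs(values - modal).sum(axis=1)
    return float(dist.mean() / n_chrom)
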