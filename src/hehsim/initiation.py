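"""Founder karyotypes for the five aneuploidy-initiation mechanisms.

Five routes to a hyperdiploid founder population are modelled:

1. ``diploid_sequential`` — a normal diploid cell; gains accrue later by
   individual nondisjunction events during clonal evolution.
2. ``tetraploid_sequential`` — a tetraploid cell; chromosomes are lost
   during subsequent divisions.
3. ``diploid_tripolar`` — a single tripolar mitosis of a diploid cell.
4. ``tetraploid_tripolar`` — a tripolar mitosis of a tetraploid cell.
5. ``mitotic_catastrophe`` — complete loss of sister-chromatid cohesion,
   so all chromatids of a replicated diploid segregate independently.

Tripolar mechanics: after replication every homologue contributes one
sister-chromatid pair; each pair disjoins to the two poles of a pole pair
chosen uniformly among the three ({0,1}, {0,2}, {1,2}), independently per
pair.  The diploid/tripolar founder inherits the union of two fixed poles
(bipolar cytokinesis of the tripolar spindle); the tetraploid/tripolar
founder inherits a single pole.  Founders containing a nullisomic
chromosome are redrawn so the initial population size is exact.

Per-chromosome founder distributions (exact, by enumeration):

=====================  ==========================================
diploid_tripolar       totals {2: 4/9, 3: 4/9, 4: 1/9}; no UPIDs
tetraploid_tripolar    per-homologue {0: 1/9, 1: 4/9, 2: 4/9}
mitotic_catastrophe    per-homologue Binomial(2, 1/2)
=====================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import N_CHROM, CellKaryotype

__all__ = [
    "MODEL_NAMES",
    "InitiationModel",
    "found_diploid",
    "found_tetraploid",
    "found_diploid_tripolar",
    "found_tetraploid_tripolar",
    "found_mitotic_catastrophe",
    "draw_founders",
]

MODEL_NAMES = (
    "diploid_sequential",
    "tetraploid_sequential",
    "diploid_tripolar",
    "tetraploid_tripolar",
    "mitotic_catastrophe",
)


@dataclass(frozen=True)
class InitiationModel:
    """An initiation mechanism plus the seed of its founder stream."""

    name: str
    rng_seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.name!r}; expected one of {MODEL_NAMES}"
            )


def _redraw_nullisomic(draw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n founders, redrawing any cell with a nullisomic chromosome."""
    out = draw(n, rng)
    bad = np.flatnonzero((out.sum(axis=2) == 0).any(axis=1))
    while bad.size:
        out[bad] = draw(bad.size, rng)
        bad = bad[(out[bad].sum(axis=2) == 0).any(axis=1)]
    return out


def _diploid_batch(n: int, rng=None) -> np.ndarray:
    return np.ones((n, N_CHROM, 2), dtype=np.int16)


def _tetraploid_batch(n: int, rng=None) -> np.ndarray:
    return np.full((n, N_CHROM, 2), 2, dtype=np.int16)


def _diploid_tripolar_batch(n: int, rng: np.random.Generator) -> np.ndarray:
    # Each homologue's sister pair lands on pole pair {0,1}, {0,2} or {1,2};
    # the founder keeps poles 0 and 1, so it receives 2 copies iff the pair
    # is {0,1} (probability 1/3), else 1.  No nullisomy is possible.
    pair_choice = rng.integers(0, 3, size=(n, N_CHROM, 2))
    return np.where(pair_choice == 0, 2, 1).astype(np.int16)


def _tetraploid_tripolar_batch(n: int, rng: np.random.Generator) -> np.ndarray:
    # Two sister pairs per homologue; each pair puts one chromatid on the
    # single founder pole iff that pole is in the chosen pair (prob 2/3).
    hits = rng.random(size=(n, N_CHROM, 2, 2)) < 2.0 / 3.0
    return hits.sum(axis=3).astype(np.int16)


def _mitotic_catastrophe_batch(n: int, rng: np.random.Generator) -> np.ndarray:
    # 92 chromatids of a replicated diploid segregate independently; the
    # founder is one daughter, so each homologue keeps Binomial(2, 1/2).
    hits = rng.random(size=(n, N_CHROM, 2, 2)) < 0.5
    return hits.sum(axis=3).astype(np.int16)


_BATCHES = {
    "diploid_sequential": _diploid_batch,
    "tetraploid_sequential": _tetraploid_batch,
    "diploid_tripolar": _diploid_tripolar_batch,
    "tetraploid_tripolar": _tetraploid_tripolar_batch,
    "mitotic_catastrophe": _mitotic_catastrophe_batch,
}


def draw_founders(model: str | InitiationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` founder cells for a model as an ``(n, 23, 2)`` array.

    Founders with any nullisomic chromosome are redrawn.
    """
    name = model.name if isinstance(model, InitiationModel) else model
    if name not in _BATCHES:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return _redraw_nullisomic(_BATCHES[name], n, rng)


def found_diploid() -> CellKaryotype:
    """A 46,XX founder: (1, 1) on every chromosome."""
    return CellKaryotype.diploid()


def found_tetraploid() -> CellKaryotype:
    """A 92,XXXX founder: (2, 2) on every chromosome."""
    return CellKaryotype.tetraploid()


def found_diploid_tripolar(rng: np.random.Generator) -> CellKaryotype:
    return CellKaryotype(draw_founders("diploid_tripolar", 1, rng)[0])


def found_tetraploid_tripolar(rng: np.random.Generator) -> CellKaryotype:
    return CellKaryotype(draw_founders("tetraploid_tripolar", 1, rng)[0])


def found_mitotic_catastrophe(rng: np.random.Generator) -> CellKaryotype:
    return CellKaryotype(draw_founders("mitotic_catastrophe", 1, rng)[0])
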