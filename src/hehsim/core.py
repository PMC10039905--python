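"""Homologue-resolved karyotype model and selection scoring.

The unit of state is a karyotype over the 23 chromosome pairs 1-22 and X
(the model is female, 46,XX; Y is not represented).  Each chromosome carries
a pair of non-negative integers: the copy number of each parental homologue.
Homologue labels are abstract ("hom1"/"hom2") and imply no parental phasing.

Populations of cells are stored as integer arrays of shape ``(n, 23, 2)``
so that the generation loop in :mod:`hehsim.evolution` is fully vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import beta as _beta

__all__ = [
    "CHROMOSOMES",
    "CHROM_INDEX",
    "N_CHROM",
    "ChromosomeState",
    "CellKaryotype",
    "SelectionConfig",
    "mcn",
    "classify_chromosome",
    "classify_pair_arrays",
    "upid_frequency",
    "s_aneuploidy",
    "s_score",
    "population_scores",
    "loss_outcomes",
]

#: Chromosome labels in canonical order (1-based names, no "chr" prefix).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)
CHROM_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}
N_CHROM = 23

# Default selection-group memberships.  Strong positive selection acts on
# trisomies of X, 4, 6, 10, 14, 17, 18 (group 1) and, more strongly, on
# gain of chromosome 21 (group 2).  The remaining chromosomes (group 3) are
# under negative selection; the extended four-group score splits group 3
# into a negatively selected part (group 3b) and a weakly positively
# selected part (group 4: 5, 8, 11, 12, 22).
DEFAULT_GROUP1 = frozenset({"X", "4", "6", "10", "14", "17", "18"})
DEFAULT_GROUP2 = frozenset({"21"})
DEFAULT_GROUP3 = frozenset(CHROMOSOMES) - DEFAULT_GROUP1 - DEFAULT_GROUP2
DEFAULT_GROUP4 = frozenset({"5", "8", "11", "12", "22"})
DEFAULT_GROUP3B = DEFAULT_GROUP3 - DEFAULT_GROUP4
#: Chromosomes whose UPID/disomy ratio defines the stopping rule
#: (1-3, 5, 7-8, 11-13, 15, 16, 19, 20, 22).
DEFAULT_TRACKED = frozenset(
    {"1", "2", "3", "5", "7", "8", "11", "12", "13", "15", "16", "19", "20", "22"}
)


class ChromosomeState(str, Enum):
    """Copy-number state of one chromosome pair, homologue-resolved."""

    NULLISOMY = "nullisomy"
    MONOSOMY = "monosomy"
    HETERODISOMY = "heterodisomy"
    UPID = "UPID"
    TRISOMY = "trisomy"
    TETRASOMY_2_2 = "tetrasomy_2_2"
    TETRASOMY_3_1 = "tetrasomy_3_1"
    TETRASOMY_4_0 = "tetrasomy_4_0"
    PENTASOMY_PLUS = "pentasomy_plus"


def classify_chromosome(n_hom1: int, n_hom2: int) -> ChromosomeState:
    """Classify an unordered homologue copy-number pair.

    Symmetric in homologue order.  A uniparental isodisomy (UPID) is a
    disomy made of two copies of the same homologue ({2, 0}); a 2:2
    tetrasomy duplicates both homologues while a 3:1 tetrasomy triplicates
    one and retains the other.
    """
    a, b = int(n_hom1), int(n_hom2)
    if a < 0 or b < 0:
        raise ValueError(f"negative homologue count: ({n_hom1}, {n_hom2})")
    total = a + b
    if total == 0:
        return ChromosomeState.NULLISOMY
    if total == 1:
        return ChromosomeState.MONOSOMY
    if total == 2:
        return ChromosomeState.UPID if (a == 2 or b == 2) else ChromosomeState.HETERODISOMY
    if total == 3:
        return ChromosomeState.TRISOMY
    if total == 4:
        hi = max(a, b)
        if hi == 2:
            return ChromosomeState.TETRASOMY_2_2
        if hi == 3:
            return ChromosomeState.TETRASOMY_3_1
        return ChromosomeState.TETRASOMY_4_0
    return ChromosomeState.PENTASOMY_PLUS


@dataclass(frozen=True)
class CellKaryotype:
    """A single cell's homologue-resolved karyotype.

    Parameters
    ----------
    copies
        Integer array of shape ``(23, 2)`` of homologue copy numbers in
        :data:`CHROMOSOMES` order, or a mapping from chromosome label to a
        ``(n_hom1, n_hom2)`` pair.
    """

    copies: np.ndarray

    def __init__(self, copies: np.ndarray | Mapping[str, tuple[int, int]]):
        if isinstance(copies, Mapping):
            missing = set(CHROMOSOMES) - set(copies)
            extra = set(copies) - set(CHROMOSOMES)
            if missing or extra:
                raise ValueError(
                    f"karyotype must cover exactly chromosomes 1-22,X; "
                    f"missing={sorted(missing)} extra={sorted(extra)}"
                )
            arr = np.array([copies[c] for c in CHROMOSOMES], dtype=np.int64)
        else:
            arr = np.asarray(copies, dtype=np.int64)
        if arr.shape != (N_CHROM, 2):
            raise ValueError(f"expected shape (23, 2), got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("homologue copy numbers must be non-negative")
        arr.setflags(write=False)
        object.__setattr__(self, "copies", arr)

    @classmethod
    def diploid(cls) -> "CellKaryotype":
        return cls(np.ones((N_CHROM, 2), dtype=np.int64))

    @classmethod
    def tetraploid(cls) -> "CellKaryotype":
        return cls(np.full((N_CHROM, 2), 2, dtype=np.int64))

    def pair(self, chromosome: str) -> tuple[int, int]:
        a, b = self.copies[CHROM_INDEX[str(chromosome)]]
        return int(a), int(b)

    def totals(self) -> np.ndarray:
        return self.copies.sum(axis=1)

    @property
    def mcn(self) -> int:
        """Modal chromosome number: total copies over all 23 pairs."""
        return int(self.copies.sum())

    def state(self, chromosome: str) -> ChromosomeState:
        return classify_chromosome(*self.pair(chromosome))

    def states(self) -> dict[str, ChromosomeState]:
        return {c: self.state(c) for c in CHROMOSOMES}

    def has_nullisomy(self) -> bool:
        return bool((self.totals() == 0).any())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellKaryotype):
            return NotImplemented
        return bool(np.array_equal(self.copies, other.copies))

    def __hash__(self) -> int:
        return hash(self.copies.tobytes())


def mcn(karyotype: CellKaryotype) -> int:
    """Modal chromosome number of a cell: sum of all homologue copies."""
    return karyotype.mcn


def _as_chrom_set(chroms: Iterable[str | int]) -> frozenset[str]:
    out = frozenset(str(c) for c in chroms)
    bad = out - set(CHROMOSOMES)
    if bad:
        raise ValueError(f"unknown chromosomes: {sorted(bad)}")
    return out


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of missegregation, selection, and the stopping rule.

    The survival/proliferation score of a cell is

        S = 0.5 + (NT_g1 + 2 NT_g2 - NT_g3 - S_aneuploidy) / 23

    in the three-group form, where NT_gk counts group-k chromosomes in a
    selected abnormal state and S_aneuploidy is a beta-law penalty in the
    excess-ploidy coordinate x = (MCN - 46) / 46.  The four-group form
    replaces NT_g3 with NT_g3b and adds +0.02 NT_g4 for the weakly
    positively selected chromosomes.  Survival probability is the score
    clamped to [0, 1].

    Notes
    -----
    ``penalty_form`` selects between the cumulative beta probability
    (default; monotone increasing in MCN, which is what an aneuploidy
    burden penalty requires) and the scaled beta density, which with shape
    a = 0.18 diverges at MCN just above 46 and *decreases* over the
    hyperdiploid range.  ``penalty_inside_fraction`` controls whether the
    penalty shares the /23 normalisation of the group terms (default) or
    is subtracted from the score directly; only the default combination
    produces a fitness landscape on which hyperdiploid karyotypes can
    outcompete diploid ones (see docs/methods.md).
    """

    group1: frozenset[str] = DEFAULT_GROUP1
    group2: frozenset[str] = DEFAULT_GROUP2
    group3: frozenset[str] = DEFAULT_GROUP3
    group3b: frozenset[str] = DEFAULT_GROUP3B
    group4: frozenset[str] = DEFAULT_GROUP4
    base_survival: float = 0.5
    group2_weight: float = 2.0
    group4_weight: float = 0.02
    m_misseg: float = 15e-4
    tetraploid_loss_prob: float = 0.35
    penalty_a: float = 0.18
    penalty_b: float = 0.65
    penalty_loc: float = 0.0
    penalty_scale: float = 1.8
    penalty_form: str = "cumulative"  # or "density"
    penalty_inside_fraction: bool = True
    four_groups: bool = False
    nt_counting: str = "gain_loss"  # or "trisomy_only"
    pop_size: int = 50_000
    upid_stop: float = 0.025
    upid_denominator: str = "disomies"  # or "all_tracked"
    max_generations: int = 2000
    tracked_chromosomes: frozenset[str] = DEFAULT_TRACKED

    def __post_init__(self):
        object.__setattr__(self, "group1", _as_chrom_set(self.group1))
        object.__setattr__(self, "group2", _as_chrom_set(self.group2))
        object.__setattr__(self, "group3", _as_chrom_set(self.group3))
        object.__setattr__(self, "group3b", _as_chrom_set(self.group3b))
        object.__setattr__(self, "group4", _as_chrom_set(self.group4))
        object.__setattr__(
            self, "tracked_chromosomes", _as_chrom_set(self.tracked_chromosomes)
        )
        if self.group2 & (self.group1 | self.group3):
            raise ValueError("group2 must be disjoint from groups 1 and 3")
        if self.group1 | self.group2 | self.group3 != set(CHROMOSOMES):
            raise ValueError("groups 1-3 must partition the 23 chromosomes")
        if self.group3b | self.group4 != self.group3 or (self.group3b & self.group4):
            raise ValueError("group3b and group4 must partition group3")
        for name in ("base_survival", "tetraploid_loss_prob", "upid_stop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.m_misseg <= 0:
            raise ValueError("m_misseg must be positive")
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.penalty_form not in ("cumulative", "density"):
            raise ValueError("penalty_form must be 'cumulative' or 'density'")
        if self.nt_counting not in ("gain_loss", "trisomy_only"):
            raise ValueError("nt_counting must be 'gain_loss' or 'trisomy_only'")
        if self.upid_denominator not in ("disomies", "all_tracked"):
            raise ValueError("upid_denominator must be 'disomies' or 'all_tracked'")

    # index arrays used by the vectorised scorer
    def _indices(self, chroms: frozenset[str]) -> np.ndarray:
        return np.array(sorted(CHROM_INDEX[c] for c in chroms), dtype=np.intp)

    @property
    def group1_idx(self) -> np.ndarray:
        return self._indices(self.group1)

    @property
    def group2_idx(self) -> np.ndarray:
        return self._indices(self.group2)

    @property
    def group3_idx(self) -> np.ndarray:
        return self._indices(self.group3b if self.four_groups else self.group3)

    @property
    def group4_idx(self) -> np.ndarray:
        return self._indices(self.group4)

    @property
    def tracked_idx(self) -> np.ndarray:
        return self._indices(self.tracked_chromosomes)

    def with_(self, **kwargs) -> "SelectionConfig":
        return replace(self, **kwargs)


def s_aneuploidy(mcn_value, config: SelectionConfig = SelectionConfig()):
    """Aneuploidy penalty as a function of the modal chromosome number.

    Zero for MCN <= 46; above that, the beta law with the configured shape,
    location, and scale evaluated at x = (MCN - 46) / 46, either as the
    cumulative probability (default) or as the scaled density.  x is
    clamped to the law's support.

    Accepts scalars or arrays and broadcasts.
    """
    m = np.asarray(mcn_value, dtype=float)
    if (m < 0).any():
        raise ValueError("MCN must be non-negative")
    x = (m - 46.0) / 46.0
    lo = config.penalty_loc
    hi = config.penalty_loc + config.penalty_scale
    x = np.clip(x, lo, hi)
    if config.penalty_form == "cumulative":
        pen = _beta.cdf(x, config.penalty_a, config.penalty_b,
                        loc=config.penalty_loc, scale=config.penalty_scale)
    else:
        # the density diverges at the support edges for a, b < 1; evaluate
        # just inside and only for MCN > 46 (diploid and below carry no
        # penalty by construction)
        eps = 1e-9 * config.penalty_scale
        xi = np.clip(x, lo + eps, hi - eps)
        pen = _beta.pdf(xi, config.penalty_a, config.penalty_b,
                        loc=config.penalty_loc, scale=config.penalty_scale)
    pen = np.where(m <= 46.0, 0.0, pen)
    return pen if pen.ndim else float(pen)


def _nt_counts(totals: np.ndarray, config: SelectionConfig):
    """Abnormal-state counts per group from per-chromosome totals (n, 23)."""
    if config.nt_counting == "trisomy_only":
        g1 = (totals[..., config.group1_idx] == 3).sum(axis=-1)
        g2 = (totals[..., config.group2_idx] == 3).sum(axis=-1)
        g3 = (totals[..., config.group3_idx] == 3).sum(axis=-1)
        g4 = (totals[..., config.group4_idx] == 3).sum(axis=-1)
    else:
        g1 = (totals[..., config.group1_idx] >= 3).sum(axis=-1)
        g2 = (totals[..., config.group2_idx] > 2).sum(axis=-1)
        g3 = (totals[..., config.group3_idx] != 2).sum(axis=-1)
        g4 = (totals[..., config.group4_idx] >= 3).sum(axis=-1)
    return g1, g2, g3, g4


def population_scores(
    homologues: np.ndarray,
    config: SelectionConfig = SelectionConfig(),
    *,
    apply_penalty: bool = True,
) -> np.ndarray:
    """Survival/proliferation score for every cell of an (n, 23, 2) array.

    Returns the raw scores (not clamped); survival probability is the
    score clamped to [0, 1].
    """
    totals = np.asarray(homologues).sum(axis=2)
    mcns = totals.sum(axis=1)
    g1, g2, g3, g4 = _nt_counts(totals, config)
    bonus = g1 + config.group2_weight * g2 - g3
    if config.four_groups:
        bonus = bonus + config.group4_weight * g4
    pen = s_aneuploidy(mcns, config) if apply_penalty else 0.0
    if config.penalty_inside_fraction:
        return config.base_survival + (bonus - pen) / N_CHROM
    return config.base_survival + bonus / N_CHROM - pen


def s_score(
    karyotype: CellKaryotype,
    config: SelectionConfig = SelectionConfig(),
    *,
    apply_penalty: bool = True,
) -> float:
    """Survival/proliferation score of a single cell (unclamped)."""
    return float(
        population_scores(karyotype.copies[None], config, apply_penalty=apply_penalty)[0]
    )


def classify_pair_arrays(hom1: np.ndarray, hom2: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_chromosome` over parallel count arrays.

    Returns an object array of :class:`ChromosomeState`.
    """
    a = np.asarray(hom1, dtype=np.int64)
    b = np.asarray(hom2, dtype=np.int64)
    total = a + b
    hi = np.maximum(a, b)
    out = np.empty(total.shape, dtype=object)
    out.fill(ChromosomeState.PENTASOMY_PLUS)
    out[total == 0] = ChromosomeState.NULLISOMY
    out[total == 1] = ChromosomeState.MONOSOMY
    out[(total == 2) & (hi == 1)] = ChromosomeState.HETERODISOMY
    out[(total == 2) & (hi == 2)] = ChromosomeState.UPID
    out[total == 3] = ChromosomeState.TRISOMY
    out[(total == 4) & (hi == 2)] = ChromosomeState.TETRASOMY_2_2
    out[(total == 4) & (hi == 3)] = ChromosomeState.TETRASOMY_3_1
    out[(total == 4) & (hi == 4)] = ChromosomeState.TETRASOMY_4_0
    return out


def upid_frequency(
    cells: np.ndarray | Sequence[CellKaryotype],
    tracked: Iterable[str] | None = None,
    *,
    denominator: str = "disomies",
) -> float:
    """UPID frequency of a population over a tracked chromosome set.

    With ``denominator="disomies"`` (default) this is the number of tracked
    chromosome slots in the UPID state divided by the number of tracked
    slots in any disomic state (heterodisomy or UPID), pooled over all
    cells — the UPIDs/all-disomies ratio.  With ``"all_tracked"`` the
    denominator is every tracked slot.  Returns 0.0 when the denominator
    is empty.
    """
    if isinstance(cells, np.ndarray):
        arr = cells
    else:
        cells = list(cells)
        if len(cells) == 0:
            raise ValueError("empty population")
        arr = np.stack([k.copies for k in cells])
    if arr.size == 0:
        raise ValueError("empty population")
    tracked_set = DEFAULT_TRACKED if tracked is None else _as_chrom_set(tracked)
    idx = np.array(sorted(CHROM_INDEX[c] for c in tracked_set), dtype=np.intp)
    sub = arr[:, idx, :]
    totals = sub.sum(axis=2)
    is_dis = totals == 2
    is_upid = is_dis & (sub.max(axis=2) == 2)
    if denominator == "disomies":
        denom = int(is_dis.sum())
    elif denominator == "all_tracked":
        denom = int(totals.size)
    else:
        raise ValueError("denominator must be 'disomies' or 'all_tracked'")
    if denom == 0:
        return 0.0
    return float(is_upid.sum()) / denom


def loss_outcomes(n_hom1: int, n_hom2: int) -> dict[ChromosomeState, Fraction]:
    """Outcome distribution when a trisomy loses one copy chosen uniformly.

    From a (2, 1) trisomy the lost copy is one of the duplicated homologue's
    two (leaving a heterodisomy, probability 2/3) or the single copy of the
    other homologue (leaving a UPID, probability 1/3).
    """
    a, b = int(n_hom1), int(n_hom2)
    if a < 0 or b < 0 or a + b != 3:
        raise ValueError(f"loss_outcomes requires a trisomic pair, got ({n_hom1}, {n_hom2})")
    dist: dict[ChromosomeState, Fraction] = {}
    for hom, count in ((0, a), (1, b)):
        if count == 0:
            continue
        pair = (a - 1, b) if hom == 0 else (a, b - 1)
        state = classify_chromosome(*pair)
        dist[state] = dist.get(state, Fraction(0)) + Fraction(count, 3)
    return dist
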