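"""Synthetic cohorts, variant tables and single-cell matrices.

These generators emulate the statistical structure of a 577-case-style
high-hyperdiploid cohort — the observed marginal frequencies of gains,
tetrasomies (and their 2:2 / 3:1 split), pentasomy 21, the flat ~2.5%
UPID/disomy ratio with the chromosome-9 excess, bulk subclone
detectability — plus trisomy-timed VAF structure for mutation timing and
clone-structured single-cell copy-number matrices.  They exist so every
analysis stage is testable end-to-end without access to restricted
patient data; chromosome gains are sampled independently per chromosome
(marginals only — real joint dependence between gains is not modelled).

All generators are bit-reproducible under a fixed seed and retain truth
labels where recovery is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CHROMOSOMES, CellKaryotype
from .cohort import CohortTable
from .single_cell import CellMatrix
from .timing import VariantRecord, expected_vaf

__all__ = [
    "CohortGeneratorConfig",
    "generate_cohort",
    "generate_variants",
    "generate_cell_matrix",
]

#: Per-chromosome gain frequencies of the emulated cohort (fraction of
#: cases with >= 3 copies).  Chromosomes absent here use ``baseline_gain``.
DEFAULT_GAIN_PROBS: dict[str, float] = {
    "21": 1.00, "X": 0.97, "14": 0.95, "6": 0.89, "18": 0.83, "4": 0.82,
    "17": 0.78, "10": 0.74, "8": 0.38, "5": 0.23, "9": 0.19, "11": 0.14,
    "12": 0.14, "22": 0.11,
}

#: Fraction of cases with tetrasomy of the given chromosome.
DEFAULT_TETRASOMY_PROBS: dict[str, float] = {
    "21": 0.81, "X": 0.20, "14": 0.17, "18": 0.12, "10": 0.083,
    "8": 0.026, "4": 0.017,
}


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Marginal frequencies and nuisance rates of the cohort generator."""

    n_cases: int = 577
    gain_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAIN_PROBS))
    tetrasomy_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TETRASOMY_PROBS)
    )
    baseline_gain: float = 0.05
    pentasomy_21: float = 0.045
    tetrasomy_31_share: float = 0.05
    upid_rate: float = 0.025
    upid_rate_chr9: float = 0.17
    monosomy_rate: float = 0.00045
    subclone_rate: float = 0.28
    subclone_fraction_range: tuple[float, float] = (0.10, 0.50)
    detectability_floor: float = 0.20
    male_fraction: float = 0.0
    y_gain_male: float = 0.21
    y_nullisomy_male: float = 0.04
    mcn_range: tuple[int, int] | None = None
    seed: int = 0

    def gain_prob(self, chrom: str) -> float:
        return self.gain_probs.get(chrom, self.baseline_gain)

    def tetrasomy_prob(self, chrom: str) -> float:
        return self.tetrasomy_probs.get(chrom, 0.0)

    def upid_prob(self, chrom: str) -> float:
        return self.upid_rate_chr9 if chrom == "9" else self.upid_rate

    def with_(self, **kwargs) -> "CohortGeneratorConfig":
        return replace(self, **kwargs)


def _sample_case(cfg: CohortGeneratorConfig, rng: np.random.Generator):
    """One case's dominant homologue pairs, in CHROMOSOMES order."""
    pairs = np.empty((len(CHROMOSOMES), 2), dtype=np.int64)
    for j, chrom in enumerate(CHROMOSOMES):
        p_gain = cfg.gain_prob(chrom)
        p_tet = cfg.tetrasomy_prob(chrom)
        p_pent = cfg.pentasomy_21 if chrom == "21" else 0.0
        u = rng.random()
        if u < p_pent:
            pairs[j] = (3, 2)
        elif u < p_pent + p_tet:
            pairs[j] = (3, 1) if rng.random() < cfg.tetrasomy_31_share else (2, 2)
        elif u < p_gain:
            pairs[j] = (2, 1)
        elif u < p_gain + cfg.monosomy_rate:
            pairs[j] = (1, 0)
        else:
            pairs[j] = (2, 0) if rng.random() < cfg.upid_prob(chrom) else (1, 1)
    return pairs


def generate_cohort(config: CohortGeneratorConfig | None = None) -> CohortTable:
    """Sample a homologue-resolved cohort table at the configured marginals.

    Each case's chromosomes are drawn independently at the stated
    frequencies.  When ``subclone_rate`` fires, one gained chromosome
    receives a loss-from-trisomy subclone (heterodisomy with probability
    2/3, UPID 1/3) whose clonal fraction is uniform over
    ``subclone_fraction_range``; subclones below ``detectability_floor``
    are merged into the major clone (not emitted), mimicking bulk
    copy-number resolution.  With ``mcn_range`` set, cases are
    rejection-sampled into that modal-number window.  Male cases (when
    ``male_fraction > 0``) receive X/Y sex-chromosome handling (XXYY or
    XXXYY gains, occasional Y nullisomy) instead of the female X margins.
    """
    cfg = config or CohortGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    rows: list[dict] = []
    x_idx = CHROMOSOMES.index("X")
    for i in range(cfg.n_cases):
        case_id = f"case{i:04d}"
        male = rng.random() < cfg.male_fraction
        while True:
            pairs = _sample_case(cfg, rng)
            y_pair = None
            if male:
                if rng.random() < cfg.y_gain_male:
                    # XXYY, occasionally XXXYY
                    xxx = rng.random() < 0.2
                    pairs[x_idx] = (2, 1) if xxx else (2, 0)
                    y_pair = (2, 0)
                else:
                    pairs[x_idx] = (1, 0)
                    y_pair = (0, 0) if rng.random() < cfg.y_nullisomy_male else (1, 0)
            mcn = int(pairs.sum()) + (sum(y_pair) if y_pair is not None else 0)
            if cfg.mcn_range is None or cfg.mcn_range[0] <= mcn <= cfg.mcn_range[1]:
                break
        sex = "M" if male else "F"
        sub_chrom = None
        if rng.random() < cfg.subclone_rate:
            gained = [j for j in range(len(CHROMOSOMES)) if pairs[j].sum() == 3]
            if gained:
                sub_chrom = int(rng.choice(gained))
        for j, chrom in enumerate(CHROMOSOMES):
            frac = 1.0
            sub_pair = None
            if j == sub_chrom:
                f = rng.uniform(*cfg.subclone_fraction_range)
                if f >= cfg.detectability_floor:
                    frac = 1.0 - f
                    sub_pair = (1, 1) if rng.random() < 2.0 / 3.0 else (2, 0)
                    sub_frac = f
            rows.append({
                "case_id": case_id, "sex": sex, "chromosome": chrom,
                "n_hom1": int(pairs[j, 0]), "n_hom2": int(pairs[j, 1]),
                "clonal_fraction": frac,
            })
            if sub_pair is not None:
                rows.append({
                    "case_id": case_id, "sex": sex, "chromosome": chrom,
                    "n_hom1": sub_pair[0], "n_hom2": sub_pair[1],
                    "clonal_fraction": sub_frac,
                })
        if male and y_pair is not None:
            rows.append({
                "case_id": case_id, "sex": sex, "chromosome": "Y",
                "n_hom1": y_pair[0], "n_hom2": y_pair[1],
                "clonal_fraction": 1.0,
            })
    columns = ["case_id", "sex", "chromosome", "n_hom1", "n_hom2", "clonal_fraction"]
    return CohortTable(pd.DataFrame(rows, columns=columns))


def generate_variants(
    karyotype: CellKaryotype,
    n_btri: int,
    n_batri: int,
    depth: int = 60,
    purity: float = 1.0,
    seed: int = 0,
) -> tuple[list[VariantRecord], list[str]]:
    """Draw timed SNVs on the trisomic chromosomes of a karyotype.

    BTRI variants sit on the duplicated homologue (2 of 3 copies,
    expected VAF 2/3 purity-adjusted); B/ATRI variants on a single copy
    (expected VAF 1/3).  Read counts are binomial at ``depth``.  Returns
    the variants and their ground-truth labels, in matching order.
    """
    rng = np.random.default_rng(seed)
    totals = karyotype.totals()
    trisomic = [CHROMOSOMES[j] for j in np.flatnonzero(totals == 3)]
    if (n_btri > 0 or n_batri > 0) and not trisomic:
        raise ValueError("karyotype has no trisomic chromosome to time variants on")
    variants: list[VariantRecord] = []
    labels: list[str] = []
    bases = np.array(list("ACGT"))
    for label, k_copies, n in (("BTRI", 2, n_btri), ("B_ATRI", 1, n_batri)):
        v_exp = expected_vaf(k_copies, 3, purity) if n else 0.0
        for _ in range(n):
            chrom = trisomic[rng.integers(len(trisomic))]
            ref, alt = rng.choice(4, size=2, replace=False)
            variants.append(VariantRecord(
                chromosome=chrom,
                position=int(rng.integers(1, 200_000_000)),
                ref=str(bases[ref]),
                alt=str(bases[alt]),
                alt_reads=int(rng.binomial(depth, v_exp)),
                depth=depth,
                sample_phase="diagnosis",
                total_copies=3,
                tumour_purity=purity,
            ))
            labels.append(label)
    return variants, labels


def generate_cell_matrix(
    clone_profiles: np.ndarray,
    clone_fractions,
    n_cells: int,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CellMatrix, np.ndarray]:
    """Draw single cells from clone profiles with sporadic +/-1 noise.

    ``clone_fractions`` must sum to 1.  Each cell copies its clone's
    profile; every chromosome is independently perturbed by +-1 with
    probability ``noise_rate`` (clipped at zero copies).  Returns the
    matrix and the ground-truth clone index per cell.
    """
    profiles = np.asarray(clone_profiles, dtype=np.int64)
    if profiles.ndim != 2:
        raise ValueError("clone_profiles must be (n_clones, n_chromosomes)")
    fractions = np.asarray(clone_fractions, dtype=float)
    if fractions.shape[0] != profiles.shape[0]:
        raise ValueError("one fraction per clone profile required")
    if not np.isclose(fractions.sum(), 1.0):
        raise ValueError(f"clone fractions must sum to 1, got {fractions.sum():.4f}")
    rng = np.random.default_rng(seed)
    truth = rng.choice(profiles.shape[0], size=n_cells, p=fractions)
    values = profiles[truth].copy()
    if noise_rate > 0:
        hit = rng.random(values.shape) < noise_rate
        delta = np.where(rng.random(values.shape) < 0.5, 1, -1)
        values = np.clip(values + hit * delta, 0, None)
    cols = CHROMOSOMES if profiles.shape[1] == len(CHROMOSOMES) else tuple(
        f"c{j}" for j in range(profiles.shape[1])
    )
    return CellMatrix(values, columns=cols), truth
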