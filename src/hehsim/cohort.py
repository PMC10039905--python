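"""Cohort-level karyotype statistics.

A cohort table is a long-format record set: one row per case, chromosome
and clone, with homologue-resolved copy numbers and the clone's fraction
of cells.  The dominant clone of a case-chromosome is the record with
``clonal_fraction >= 0.5``; subclonal records carry smaller fractions.
Statistics operate on dominant records unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .core import (
    CHROMOSOMES,
    ChromosomeState,
    classify_pair_arrays,
)

__all__ = [
    "CohortTable",
    "CohortProfile",
    "copy_state_spectrum",
    "tetrasomy_type_fractions",
    "upid_disomy_ratio",
    "mcn_profiles",
    "subclonality_ratio_test",
    "cohort_profile",
    "population_to_cohort",
]

REQUIRED_COLUMNS = ("case_id", "sex", "chromosome", "n_hom1", "n_hom2", "clonal_fraction")
VALID_CHROMS = set(CHROMOSOMES) | {"Y"}

#: Aberration classes used for per-chromosome profiles.
PROFILE_STATES = (
    ChromosomeState.MONOSOMY,
    ChromosomeState.HETERODISOMY,
    ChromosomeState.UPID,
    ChromosomeState.TRISOMY,
    ChromosomeState.TETRASOMY_2_2,
    ChromosomeState.TETRASOMY_3_1,
    ChromosomeState.TETRASOMY_4_0,
    ChromosomeState.PENTASOMY_PLUS,
)


@dataclass
class CohortTable:
    """Long-format per-case, per-chromosome copy states.

    Columns: ``case_id``, ``sex`` (F/M), ``chromosome`` (1..22, X, Y),
    ``n_hom1``, ``n_hom2``, ``clonal_fraction`` in (0, 1], and optionally
    ``state_annotation``.
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = set(REQUIRED_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        df = self.df.copy()
        df["chromosome"] = df["chromosome"].astype(str)
        bad = set(df["chromosome"]) - VALID_CHROMS
        if bad:
            raise ValueError(f"invalid chromosome labels: {sorted(bad)}")
        if (df[["n_hom1", "n_hom2"]].to_numpy() < 0).any():
            raise ValueError("homologue counts must be non-negative")
        cf = df["clonal_fraction"].to_numpy(dtype=float)
        if ((cf <= 0) | (cf > 1)).any():
            raise ValueError("clonal_fraction must lie in (0, 1]")
        self.df = df

    @property
    def n_cases(self) -> int:
        return self.df["case_id"].nunique()

    def dominant(self) -> pd.DataFrame:
        """Dominant (clonal_fraction >= 0.5) record per case-chromosome."""
        dom = self.df[self.df["clonal_fraction"] >= 0.5]
        return dom.sort_values("clonal_fraction").drop_duplicates(
            ["case_id", "chromosome"], keep="last"
        )

    def subclonal(self) -> pd.DataFrame:
        return self.df[self.df["clonal_fraction"] < 0.5]

    def autosomal_x(self) -> "CohortTable":
        """Drop chromosome Y records (simulator-facing comparisons)."""
        return CohortTable(self.df[self.df["chromosome"] != "Y"].copy())

    def states(self, df: pd.DataFrame | None = None) -> pd.Series:
        d = self.dominant() if df is None else df
        return pd.Series(
            classify_pair_arrays(d["n_hom1"].to_numpy(), d["n_hom2"].to_numpy()),
            index=d.index,
        )

    def case_mcn(self) -> pd.Series:
        """Modal chromosome number per case from dominant records."""
        d = self.dominant()
        tot = d["n_hom1"] + d["n_hom2"]
        return tot.groupby(d["case_id"]).sum()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chromosome": str}))


def _coarse_state(total: np.ndarray) -> np.ndarray:
    out = np.full(total.shape, "pentasomy+", dtype=object)
    out[total == 0] = "nullisomy"
    out[total == 1] = "monosomy"
    out[total == 2] = "disomy"
    out[total == 3] = "trisomy"
    out[total == 4] = "tetrasomy"
    return out


def copy_state_spectrum(cohort: CohortTable) -> pd.DataFrame:
    """Counts and fractions of chromosome pairs per coarse copy state.

    Pools dominant records over the whole cohort into the classes
    monosomy / disomy / trisomy / tetrasomy / pentasomy+ (and nullisomy
    if present).  Fractions sum to 1.
    """
    d = cohort.dominant()
    total = (d["n_hom1"] + d["n_hom2"]).to_numpy()
    states = _coarse_state(total)
    counts = pd.Series(states).value_counts()
    order = [s for s in ("nullisomy", "monosomy", "disomy", "trisomy",
                         "tetrasomy", "pentasomy+") if s in counts.index]
    counts = counts.loc[order]
    return pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})


def tetrasomy_type_fractions(cohort: CohortTable) -> dict:
    """Share of 2:2 vs 3:1 (vs 4:0) configurations among tetrasomies.

    Records lacking homologue resolution (NaN counts) are excluded and
    reported under ``n_unresolved``.  Returns overall shares plus a
    per-chromosome breakdown.
    """
    d = cohort.dominant()
    tot = d["n_hom1"] + d["n_hom2"]
    tetra = d[tot == 4].copy()
    unresolved = tetra["n_hom1"].isna() | tetra["n_hom2"].isna()
    res = tetra[~unresolved]
    hi = res[["n_hom1", "n_hom2"]].max(axis=1)
    res = res.assign(tetra_type=np.select([hi == 2, hi == 3], ["2:2", "3:1"], "4:0"))
    overall = res["tetra_type"].value_counts(normalize=True).to_dict()
    per_chrom = (
        res.groupby("chromosome")["tetra_type"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    return {
        "n_tetrasomies": int(len(res)),
        "n_unresolved": int(unresolved.sum()),
        "overall": {t: float(overall.get(t, 0.0)) for t in ("2:2", "3:1", "4:0")},
        "per_chromosome": per_chrom,
    }


def upid_disomy_ratio(cohort: CohortTable) -> pd.Series:
    """Per chromosome, UPID count / all-disomy count (dominant records).

    Chromosomes with no disomic records get NaN.
    """
    d = cohort.dominant()
    tot = d["n_hom1"] + d["n_hom2"]
    dis = d[tot == 2].copy()
    is_upid = dis[["n_hom1", "n_hom2"]].max(axis=1) == 2
    grp = is_upid.groupby(dis["chromosome"])
    ratio = grp.sum() / grp.count()
    order = [c for c in list(CHROMOSOMES) + ["Y"] if c in ratio.index]
    return ratio.loc[order].astype(float)


def mcn_profiles(cohort: CohortTable, *, split_at: int = 62) -> dict:
    """Mean trisomy and tetrasomy counts per modal chromosome number.

    Computes, per case: MCN, number of trisomic and tetrasomic
    chromosomes, then averages within each observed MCN value (empty MCN
    bins are absent, not zero).  Also splits the cohort at ``split_at``
    (cases below vs at-or-above), where the trisomy:tetrasomy balance of
    the cohort changes.
    """
    d = cohort.dominant()
    tot = d["n_hom1"] + d["n_hom2"]
    per_case = pd.DataFrame({
        "mcn": tot.groupby(d["case_id"]).sum(),
        "n_trisomy": (tot == 3).groupby(d["case_id"]).sum(),
        "n_tetrasomy": (tot == 4).groupby(d["case_id"]).sum(),
    })
    by_mcn = per_case.groupby("mcn").agg(
        n_cases=("n_trisomy", "size"),
        mean_trisomies=("n_trisomy", "mean"),
        mean_tetrasomies=("n_tetrasomy", "mean"),
    )
    lower = per_case[per_case["mcn"] < split_at]
    upper = per_case[per_case["mcn"] >= split_at]
    return {
        "per_case": per_case,
        "by_mcn": by_mcn,
        "split": {
            f"mcn<{split_at}": int(len(lower)),
            f"mcn>={split_at}": int(len(upper)),
        },
    }


def subclonality_ratio_test(n_disomy_trisomy: int, n_upid_trisomy: int) -> float:
    """Two-sided exact binomial test of the loss-from-trisomy null.

    Loss of one copy from a (2, 1) trisomy yields a heterodisomy with
    probability 2/3 and a UPID with probability 1/3, so among cases with
    disomy/trisomy or UPID/trisomy subclonality the UPID/trisomy count is
    Binomial(n, 1/3) under the null.  Two-sided p by the minimum-likelihood
    method: the sum of all outcome probabilities no larger than the
    observed outcome's.
    """
    a, b = int(n_disomy_trisomy), int(n_upid_trisomy)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    n = a + b
    if n == 0:
        raise ValueError("at least one subclonal record is required")
    return float(binomtest(b, n, 1.0 / 3.0, alternative="two-sided").pvalue)


@dataclass
class CohortProfile:
    """Profile axes used for model comparison.

    ``state_freq``: per-chromosome frequency of each homologue-resolved
    aberration class (rows sum to 1).  ``by_mcn``: mean trisomy and
    tetrasomy counts per MCN.  ``mcn_hist``: cases per MCN.
    """

    state_freq: pd.DataFrame
    by_mcn: pd.DataFrame
    mcn_hist: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "state_freq": {
                c: {str(s): float(v) for s, v in row.items()}
                for c, row in self.state_freq.iterrows()
            },
            "by_mcn": {
                int(m): {
                    "n_cases": int(r["n_cases"]),
                    "mean_trisomies": float(r["mean_trisomies"]),
                    "mean_tetrasomies": float(r["mean_tetrasomies"]),
                }
                for m, r in self.by_mcn.iterrows()
            },
            "mcn_hist": {int(k): int(v) for k, v in self.mcn_hist.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CohortProfile":
        sf = pd.DataFrame(d["state_freq"]).T
        sf.index.name = "chromosome"
        bm = pd.DataFrame(d["by_mcn"]).T
        bm.index = bm.index.astype(int)
        bm.index.name = "mcn"
        hist = pd.Series({int(k): int(v) for k, v in d["mcn_hist"].items()})
        return cls(state_freq=sf, by_mcn=bm.sort_index(), mcn_hist=hist.sort_index())


def cohort_profile(cohort: CohortTable) -> CohortProfile:
    """Build the comparison profile of a cohort (chromosome Y excluded)."""
    c = cohort.autosomal_x()
    d = c.dominant()
    states = c.states(d).astype(str)
    tab = (
        pd.crosstab(d["chromosome"], states, normalize="index")
        .reindex(index=list(CHROMOSOMES), fill_value=0.0)
        .reindex(columns=[s.value for s in PROFILE_STATES], fill_value=0.0)
    )
    prof = mcn_profiles(c)
    hist = prof["per_case"]["mcn"].value_counts().sort_index()
    return CohortProfile(state_freq=tab, by_mcn=prof["by_mcn"], mcn_hist=hist)


def population_to_cohort(cells: np.ndarray, *, prefix: str = "cell") -> CohortTable:
    """View simulated cells as a cohort table (each cell one 46,XX case)."""
    cells = np.asarray(cells)
    n = cells.shape[0]
    case_ids = np.repeat([f"{prefix}{i}" for i in range(n)], len(CHROMOSOMES))
    chroms = np.tile(np.array(CHROMOSOMES, dtype=object), n)
    return CohortTable(pd.DataFrame({
        "case_id": case_ids,
        "sex": "F",
        "chromosome": chroms,
        "n_hom1": cells[:, :, 0].ravel(),
        "n_hom2": cells[:, :, 1].ravel(),
        "clonal_fraction": 1.0,
    }))
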