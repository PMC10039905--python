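"""Mutation timing on gained chromosomes from variant allele fractions.

On a trisomic chromosome, an SNV acquired *before* the gain and lying on
the duplicated homologue is present on 2 of 3 copies and shows a VAF near
2/3 (a BTRI mutation); an SNV on a single homologue — acquired after the
gain, or before it on the homologue that was not duplicated — shows a VAF
near 1/3 (B/ATRI).  The BTRI fraction of a trisomy therefore measures its
age: the younger the gain, the longer the chromosome existed unduplicated
and the larger the share of its mutations that predate (and ride along
with) the duplication.

In a tumour/normal mixture of purity ``p`` a variant on ``k`` of ``C``
tumour copies of a chromosome has expected VAF

    k p / (C p + 2 (1 - p))

since normal cells contribute two reference copies.  Classification is by
binomial read-count likelihood under the two expected VAFs, with an
ambiguity band where the log-likelihood ratio is small; a fixed-window
mode splitting at the midpoint of the two expectations is available for
threshold-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom, mannwhitneyu

__all__ = [
    "TimingLabel",
    "VariantRecord",
    "expected_vaf",
    "classify_timing",
    "btri_fraction_by_group",
    "assign_homologue",
    "homologue_concordance",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_variants_vcf",
]


class TimingLabel(str, Enum):
    BTRI = "BTRI"
    B_ATRI = "B_ATRI"
    AMBIGUOUS = "ambiguous"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class VariantRecord:
    """A somatic SNV with read support and chromosome copy context."""

    chromosome: str
    position: int
    ref: str
    alt: str
    alt_reads: int
    depth: int
    sample_phase: str = "diagnosis"  # diagnosis | remission | relapse
    total_copies: int = 2
    homologue_split: tuple[int, int] | None = None
    tumour_purity: float = 1.0

    def __post_init__(self):
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads must satisfy 0 <= {self.alt_reads} <= depth {self.depth}"
            )
        if self.sample_phase not in ("diagnosis", "remission", "relapse"):
            raise ValueError(f"invalid sample_phase {self.sample_phase!r}")
        if not 0.0 < self.tumour_purity <= 1.0:
            raise ValueError("tumour_purity must be in (0, 1]")

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValueError("VAF undefined at depth 0")
        return self.alt_reads / self.depth


def expected_vaf(k_copies: int, total_copies: int, purity: float = 1.0) -> float:
    """Expected VAF of a variant on k of C tumour copies at given purity."""
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    return (k_copies * purity) / (total_copies * purity + 2.0 * (1.0 - purity))


def classify_timing(
    variant: VariantRecord,
    *,
    min_depth: int = 10,
    llr_threshold: float = 2.0,
    method: str = "likelihood",
) -> TimingLabel:
    """Time an SNV relative to its chromosome's gain.

    Applicable only on chromosomes with >= 3 copies; otherwise
    ``NOT_APPLICABLE``.  With ``method="likelihood"`` (default) the label
    is the read-count binomial hypothesis (expected VAF 2/3-like for a
    duplicated homologue vs 1/3-like for a single homologue,
    purity-adjusted) with the higher likelihood, ``AMBIGUOUS`` when the
    absolute log-likelihood ratio falls below ``llr_threshold`` or depth
    below ``min_depth``.  With ``method="window"`` the split is at the
    midpoint of the two expected VAFs (0.5 at purity 1), with no
    ambiguity band other than the depth floor.
    """
    if variant.depth == 0:
        raise ValueError("cannot classify a variant with zero depth")
    if variant.total_copies < 3:
        return TimingLabel.NOT_APPLICABLE
    if variant.depth < min_depth:
        return TimingLabel.AMBIGUOUS
    c = variant.total_copies
    p = variant.tumour_purity
    v_btri = expected_vaf(c - 1, c, p)  # duplicated homologue: C-1 of C for a trisomy
    v_batri = expected_vaf(1, c, p)
    if method == "window":
        mid = 0.5 * (v_btri + v_batri)
        return TimingLabel.BTRI if variant.vaf >= mid else TimingLabel.B_ATRI
    if method != "likelihood":
        raise ValueError("method must be 'likelihood' or 'window'")
    ll_btri = binom.logpmf(variant.alt_reads, variant.depth, v_btri)
    ll_batri = binom.logpmf(variant.alt_reads, variant.depth, v_batri)
    llr = ll_btri - ll_batri
    if abs(llr) < llr_threshold:
        return TimingLabel.AMBIGUOUS
    return TimingLabel.BTRI if llr > 0 else TimingLabel.B_ATRI


def btri_fraction_by_group(classified: pd.DataFrame) -> dict:
    """Per-group BTRI fractions and a Mann-Whitney comparison.

    ``classified`` needs columns ``case_id``, ``group`` (e.g. "pos" for
    strong-pos + weak-pos chromosomes vs "neg") and ``timing`` (BTRI /
    B_ATRI; other labels are dropped).  Fractions are pooled
    BTRI / (BTRI + B_ATRI) per group; the p-value is a two-sided
    Mann-Whitney test on per-case BTRI fractions between the two groups
    (NaN when either group lacks informative cases or there are not
    exactly two groups).
    """
    df = classified.copy()
    df["timing"] = df["timing"].map(
        lambda t: t.value if isinstance(t, TimingLabel) else str(t)
    )
    df = df[df["timing"].isin([TimingLabel.BTRI.value, TimingLabel.B_ATRI.value])]
    out: dict = {"fractions": {}, "counts": {}, "p_value": float("nan")}
    for grp, sub in df.groupby("group"):
        n_btri = int((sub["timing"] == TimingLabel.BTRI.value).sum())
        n = int(len(sub))
        out["counts"][grp] = (n_btri, n)
        out["fractions"][grp] = n_btri / n if n else float("nan")
    groups = sorted(out["counts"])
    if len(groups) == 2:
        per_case = (
            df.assign(is_btri=df["timing"] == TimingLabel.BTRI.value)
            .groupby(["group", "case_id"])["is_btri"]
            .mean()
        )
        a = per_case.loc[groups[0]].to_numpy()
        b = per_case.loc[groups[1]].to_numpy()
        if a.size and b.size and (np.ptp(np.concatenate([a, b])) > 0):
            out["p_value"] = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        elif a.size and b.size:
            out["p_value"] = 1.0
    return out


def assign_homologue(allele_fraction: float, *, upper: float = 0.6, lower: float = 0.4) -> str:
    """Assign a heterozygous variant to a homologue by its allele fraction.

    Fractions above ``upper`` go to one homologue ("hom1"), below
    ``lower`` to the other ("hom2"); the dead zone in between is
    "unassigned".
    """
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele fraction must be in [0, 1]")
    if allele_fraction > upper:
        return "hom1"
    if allele_fraction < lower:
        return "hom2"
    return "unassigned"


def homologue_concordance(
    diagnosis: pd.DataFrame,
    relapse: pd.DataFrame,
    *,
    mode: str = "trisomy",
    upid_screen: float = 0.8,
) -> str:
    """Is the gained/retained homologue the same at diagnosis and relapse?

    Both frames need columns ``chromosome``, ``position`` and ``baf``.
    In ``trisomy`` mode, variants informative at diagnosis (BAF > 0.6 or
    < 0.4) are looked up at the same position in the relapse sample and
    vote "same" when their homologue assignment agrees.  In ``upid`` mode
    only diagnosis variants with BAF > ``upid_screen`` are screened; a
    relapse BAF >= 0.5 votes "same".  Returns the majority vote among
    {"same", "different"}, or "uninformative" when no variant is usable
    (ties included).
    """
    if mode not in ("trisomy", "upid"):
        raise ValueError("mode must be 'trisomy' or 'upid'")
    merged = diagnosis.merge(
        relapse, on=["chromosome", "position"], suffixes=("_dx", "_rel")
    )
    votes_same = votes_diff = 0
    for _, row in merged.iterrows():
        if mode == "upid":
            if row["baf_dx"] <= upid_screen:
                continue
            if row["baf_rel"] >= 0.5:
                votes_same += 1
            else:
                votes_diff += 1
        else:
            a_dx = assign_homologue(row["baf_dx"])
            a_rel = assign_homologue(row["baf_rel"])
            if "unassigned" in (a_dx, a_rel):
                continue
            if a_dx == a_rel:
                votes_same += 1
            else:
                votes_diff += 1
    if votes_same == votes_diff:
        return "uninformative"
    return "same" if votes_same > votes_diff else "different"


# ---------------------------------------------------------------------------
# I/O

TSV_COLUMNS = [
    "chromosome", "position", "ref", "alt", "alt_reads", "depth",
    "sample_phase", "total_copies", "tumour_purity",
]


def write_variants_tsv(variants, path: str | Path, *, truth: list[str] | None = None) -> None:
    rows = []
    for i, v in enumerate(variants):
        row = {c: getattr(v, c) for c in TSV_COLUMNS}
        if truth is not None:
            row["truth_label"] = truth[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        VariantRecord(
            chromosome=str(r["chromosome"]),
            position=int(r["position"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            alt_reads=int(r["alt_reads"]),
            depth=int(r["depth"]),
            sample_phase=str(r.get("sample_phase", "diagnosis")),
            total_copies=int(r.get("total_copies", 2)),
            tumour_purity=float(r.get("tumour_purity", 1.0)),
        )
        for _, r in df.iterrows()
    ]


def read_variants_vcf(
    path: str | Path,
    *,
    sample_phase: str = "diagnosis",
    copy_context: dict[str, int] | None = None,
    tumour_purity: float = 1.0,
) -> list[VariantRecord]:
    """Read somatic SNVs from a VCF with per-sample AD/DP FORMAT fields.

    ``copy_context`` maps chromosome label to its total copy number in the
    tumour (default 2 for chromosomes not listed).
    """
    from cyvcf2 import VCF

    copy_context = copy_context or {}
    out = []
    vcf = VCF(str(path))
    for rec in vcf:
        chrom = rec.CHROM.removeprefix("chr")
        ad = rec.format("AD")
        if ad is not None:
            alt_reads = int(ad[0][1])
            depth = int(ad[0].sum())
        else:
            depth = int(rec.format("DP")[0][0])
            alt_reads = int(round(rec.INFO.get("AF", 0.0) * depth))
        out.append(
            VariantRecord(
                chromosome=chrom,
                position=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else ".",
                alt_reads=alt_reads,
                depth=depth,
                sample_phase=sample_phase,
                total_copies=int(copy_context.get(chrom, 2)),
                tumour_purity=tumour_purity,
            )
        )
    return out
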