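"""Phenotype assignment, patient/cohort aggregation and cohort comparisons.

Each CTC carries one of four co-expression phenotypes from its ALDH1 level
(high vs low/negative collapsed) and TWIST localization (nuclear vs
cytoplasmic/negative collapsed).  Patient profiles hold the 4-vector of
phenotype counts; cohort summaries report, per marker category, the
percentage of patients with any / exclusively such CTCs, the pooled CTC-level
percentage, and the unweighted mean of per-patient percentages — the standard
reporting layout for this assay.  Cohorts are compared with the chi-square
test with continuity correction on patient frequencies, the Mann-Whitney test
on per-patient percentage distributions, and Spearman rank correlation on
pooled per-CTC marker indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

PHENOTYPES = ("high_nuc", "high_cytneg", "lowneg_nuc", "lowneg_cytneg")

#: marker categories -> indices of PHENOTYPES contributing to the category
CATEGORIES: dict[str, tuple[int, ...]] = {
    "aldh1_high": (0, 1),
    "aldh1_lowneg": (2, 3),
    "twist_nuc": (0, 2),
    "twist_cytneg": (1, 3),
    "high_nuc": (0,),
    "high_cytneg": (1,),
    "lowneg_nuc": (2,),
    "lowneg_cytneg": (3,),
}


def assign_phenotype(aldh1_level: str, twist_loc: str) -> str:
    """Four-way co-expression phenotype: high vs low/neg ALDH1 x nuclear vs
    cytoplasmic/absent TWIST."""
    if aldh1_level not in ("high", "low", "neg"):
        raise ValueError(f"bad ALDH1 level {aldh1_level!r}")
    if twist_loc not in ("nuc", "cyt", "neg"):
        raise ValueError(f"bad TWIST localization {twist_loc!r}")
    a = "high" if aldh1_level == "high" else "lowneg"
    t = "nuc" if twist_loc == "nuc" else "cytneg"
    return f"{a}_{t}"


@dataclass
class PatientProfile:
    """Per-patient CTC phenotype counts."""

    patient_id: str
    setting: str  # "early" | "metastatic"
    counts: np.ndarray  # length-4 int vector, PHENOTYPES order
    pbmcs_analyzed: int = 500_000

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4,) or np.any(self.counts < 0):
            raise ValueError("counts must be 4 non-negative integers")

    @property
    def total_ctc(self) -> int:
        return int(self.counts.sum())

    @property
    def detected(self) -> bool:
        return self.total_ctc >= 1

    def category_count(self, category: str) -> int:
        return int(self.counts[list(CATEGORIES[category])].sum())


def profiles_from_counts_table(table: pd.DataFrame) -> list[PatientProfile]:
    """Build profiles from the cohort counts CSV schema
    (``patient_id,setting,total_ctc,n_high_nuc,...``)."""
    cols = [f"n_{p}" for p in PHENOTYPES]
    return [
        PatientProfile(
            patient_id=str(row["patient_id"]),
            setting=str(row["setting"]),
            counts=np.array([row[c] for c in cols], dtype=int),
        )
        for _, row in table.iterrows()
    ]


def phenotype_percentages(counts: Sequence[int]) -> tuple[float, ...]:
    """Per-phenotype percentages of one patient's CTCs, one-decimal rounding
    applied only at this reporting step."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("patient has no CTCs; CTC-negative patients are excluded")
    return tuple(float(round(100.0 * c / total, 1)) for c in counts)


def summarize_patient(calls: Iterable[tuple[str, str]]) -> dict:
    """Counts and percentages from a patient's per-CTC (ALDH1, TWIST) calls."""
    counts = np.zeros(4, dtype=int)
    for aldh1, twist in calls:
        counts[PHENOTYPES.index(assign_phenotype(aldh1, twist))] += 1
    return {
        "counts": counts,
        "total_ctc": int(counts.sum()),
        "percentages": phenotype_percentages(counts),
    }


@dataclass
class CohortSummary:
    """Cohort-level aggregation over detected patients."""

    setting: str
    n_patients: int
    n_detected: int
    total_ctcs: int
    detection_rate_pct: float
    median_ctc_per_detected: float
    ctc_range: tuple[int, int]
    per_category: pd.DataFrame = field(repr=False)

    def row(self, category: str) -> pd.Series:
        return self.per_category.loc[category]


def summarize_cohort(profiles: Sequence[PatientProfile], setting: str | None = None) -> CohortSummary:
    """Aggregate patient profiles into the cohort reporting layout.

    The detection rate is over all patients; every other statistic is over
    detected patients only.  Pooled CTC-level percentages use all CTCs of the
    cohort; per-patient means are unweighted means of per-patient percentages.
    A patient is *exclusive* for a category when every one of their CTCs
    carries it.
    """
    if not profiles:
        raise ValueError("no patient profiles given")
    if setting is None:
        setting = profiles[0].setting
    detected = [p for p in profiles if p.detected]
    n, k = len(profiles), len(detected)
    pooled = np.sum([p.counts for p in detected], axis=0) if detected else np.zeros(4, int)
    total = int(pooled.sum())

    rows = {}
    for cat in CATEGORIES:
        if detected:
            with_any = [p for p in detected if p.category_count(cat) > 0]
            exclusive = [p for p in detected if p.category_count(cat) == p.total_ctc]
            pcts = [100.0 * p.category_count(cat) / p.total_ctc for p in detected]
            rows[cat] = {
                "patients_with_any_pct": 100.0 * len(with_any) / k,
                "patients_exclusive_pct": 100.0 * len(exclusive) / k,
                "ctc_level_pct": 100.0 * pooled[list(CATEGORIES[cat])].sum() / total,
                "per_patient_mean_pct": float(np.mean(pcts)),
                "per_patient_min_pct": float(np.min(pcts)),
                "per_patient_max_pct": float(np.max(pcts)),
            }
        else:
            rows[cat] = dict.fromkeys(
                [
                    "patients_with_any_pct",
                    "patients_exclusive_pct",
                    "ctc_level_pct",
                    "per_patient_mean_pct",
                    "per_patient_min_pct",
                    "per_patient_max_pct",
                ],
                float("nan"),
            )
    totals = [p.total_ctc for p in detected]
    return CohortSummary(
        setting=setting,
        n_patients=n,
        n_detected=k,
        total_ctcs=total,
        detection_rate_pct=100.0 * k / n,
        median_ctc_per_detected=float(np.median(totals)) if totals else float("nan"),
        ctc_range=(min(totals), max(totals)) if totals else (0, 0),
        per_category=pd.DataFrame.from_dict(rows, orient="index"),
    )


# ---------------------------------------------------------------------------
# statistics


def chi_square_yates(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Chi-square test with continuity correction on a 2x2 table.

    The Yates-corrected statistic sums ``(max(|O - E| - 0.5, 0))^2 / E`` with
    expected counts from the margins; the p-value is the upper tail of the
    chi-square distribution with one degree of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column margins must be positive")
    res = sps.chi2_contingency(t, correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    pvalue: float
    method: str  # "exact" | "asymptotic"


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small untied samples and the normal
    approximation with tie correction otherwise; the method used is recorded
    in the result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), pvalue=float(res.pvalue), method=method)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float
    defined: bool


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with midrank ties, two-sided p-value.

    A constant input vector leaves the correlation undefined; this is flagged
    rather than raised, since degenerate cohorts legitimately occur.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return SpearmanResult(float("nan"), float("nan"), defined=False)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), defined=True)


def per_ctc_indicators(profiles: Sequence[PatientProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-CTC binary indicators (ALDH1-high, TWIST-nuclear).

    The phenotype counts fully determine the joint distribution of the two
    indicators, so the per-CTC vectors can be reconstructed exactly.
    """
    high, nuc = [], []
    for p in profiles:
        for idx, (h, t) in enumerate([(1, 1), (1, 0), (0, 1), (0, 0)]):
            high.extend([h] * int(p.counts[idx]))
            nuc.extend([t] * int(p.counts[idx]))
    return np.asarray(high), np.asarray(nuc)


def compare_cohorts(
    early: Sequence[PatientProfile],
    metastatic: Sequence[PatientProfile],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Category-by-category comparison of two cohorts.

    For each marker category: chi-square with continuity correction on the
    2x2 table of detected patients with/without such CTCs (and on the
    exclusive version), and Mann-Whitney on the per-patient percentage
    distributions.  Rows follow the cohort-summary category order.  With
    ``bh_correction`` the chi-square p-values additionally get a
    Benjamini-Hochberg adjusted column (no correction by default).
    """
    se, sm = summarize_cohort(early), summarize_cohort(metastatic)
    de = [p for p in early if p.detected]
    dm = [p for p in metastatic if p.detected]
    if not de or not dm:
        raise ValueError("both cohorts need at least one detected patient")

    rows = []
    for cat in CATEGORIES:
        ae = sum(1 for p in de if p.category_count(cat) > 0)
        am = sum(1 for p in dm if p.category_count(cat) > 0)
        ee = sum(1 for p in de if p.category_count(cat) == p.total_ctc)
        em = sum(1 for p in dm if p.category_count(cat) == p.total_ctc)

        def _p(a, b):
            table = [[a, len(de) - a], [b, len(dm) - b]]
            try:
                return chi_square_yates(table)[1]
            except ValueError:  # empty margin (e.g. category absent in both)
                return float("nan")

        pct_e = [100.0 * p.category_count(cat) / p.total_ctc for p in de]
        pct_m = [100.0 * p.category_count(cat) / p.total_ctc for p in dm]
        mw = mann_whitney(pct_e, pct_m)
        rows.append(
            {
                "category": cat,
                "early_patients_pct": se.row(cat)["patients_with_any_pct"],
                "metastatic_patients_pct": sm.row(cat)["patients_with_any_pct"],
                "p_chi2_any": _p(ae, am),
                "early_exclusive_pct": se.row(cat)["patients_exclusive_pct"],
                "metastatic_exclusive_pct": sm.row(cat)["patients_exclusive_pct"],
                "p_chi2_exclusive": _p(ee, em),
                "early_per_patient_mean_pct": se.row(cat)["per_patient_mean_pct"],
                "metastatic_per_patient_mean_pct": sm.row(cat)["per_patient_mean_pct"],
                "p_mannwhitney": mw.pvalue,
                "early_ctc_pct": se.row(cat)["ctc_level_pct"],
                "metastatic_ctc_pct": sm.row(cat)["ctc_level_pct"],
            }
        )
    report = pd.DataFrame(rows).set_index("category")
    if bh_correction:
        for col in ("p_chi2_any", "p_chi2_exclusive", "p_mannwhitney"):
            report[col + "_bh"] = _benjamini_hochberg(report[col].to_numpy())
    return report


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs are passed through."""
    adjusted = np.full_like(pvals, np.nan, dtype=float)
    mask = np.isfinite(pvals)
    p = pvals[mask]
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.clip(ranked, 0, 1)
    adjusted[mask] = out
    return adjusted
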