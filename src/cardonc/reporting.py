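"""Descriptive statistics and registry report surfaces.

Proportions are displayed as percentages rounded half-up; two-group
comparisons of dichotomous variables use the Pearson chi-squared test
without continuity correction (1 df); continuous variables are summarized
as median (IQR) with linearly interpolated quartiles.

Report builders take the phenotyped members table (one row per registry
member, as produced by :func:`cardonc.phenotyping.phenotype_members`) and
emit plain dict/DataFrame structures: LVEF assessment rates by exposure
class, post-treatment LVD/HFrEF prevalence, and the care-gap worklists
(missing baseline LVEF; outcome patients off each GDMT class, with rates
stratified by cardiology referral).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwo",
    "CareGapReport",
    "proportion_pct",
    "chisq_2x2",
    "median_iqr",
    "assessment_summary",
    "prevalence_table",
    "care_gap_report",
]

GDMT_CLASSES = ("beta_blocker", "acei_or_arb", "mra")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def proportion_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def chisq_2x2(table: TwoByTwo, continuity_correction: bool = False
              ) -> tuple[float, float]:
    """Pearson chi-squared test with 1 df; correction off by default."""
    arr = table.as_array()
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("both margins must be positive")
    statistic, p, _, _ = stats.chi2_contingency(
        arr, correction=continuity_correction)
    return float(statistic), float(p)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linearly interpolated (inclusive) quartiles."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty list")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _class_masks(members: pd.DataFrame) -> dict[str, pd.Series]:
    ac = members["anthracycline"].astype(bool)
    her2 = members["her2"].astype(bool)
    return {
        "all": pd.Series(True, index=members.index),
        "anthracycline": ac,
        "her2": her2,
        "not_ac_her2": ~ac & ~her2,
    }


def assessment_summary(members: pd.DataFrame) -> pd.DataFrame:
    """Pre-/post-exposure LVEF assessment counts and rates per exposure
    class (all / anthracycline / HER2 / neither)."""
    rows = []
    for name, mask in _class_masks(members).items():
        sub = members[mask]
        n = len(sub)
        n_pre = int(sub["pre_assessed"].sum())
        n_post = int(sub["post_assessed"].sum())
        rows.append({
            "class": name, "n": n,
            "n_pre": n_pre,
            "pre_pct": proportion_pct(n_pre, n, 2) if n else float("nan"),
            "n_post": n_post,
            "post_pct": proportion_pct(n_post, n, 2) if n else float("nan"),
        })
    return pd.DataFrame(rows)


def prevalence_table(members: pd.DataFrame) -> pd.DataFrame:
    """Post-treatment LVD and HFrEF prevalence by exposure class.

    LVD denominators are the post-assessed members (only screened patients
    are at risk of a measured low LVEF); HFrEF denominators are all
    members (the Problem-List phenotype needs no imaging).
    """
    rows = []
    for name, mask in _class_masks(members).items():
        sub = members[mask]
        assessed = sub[sub["post_assessed"].astype(bool)]
        n_lvd = int(assessed["lvd"].sum())
        n_hf = int(sub["hfref"].sum())
        rows.append({
            "class": name,
            "lvef_assessed_n": len(assessed),
            "lvd_n": n_lvd,
            "lvd_pct": (proportion_pct(n_lvd, len(assessed), 1)
                        if len(assessed) else float("nan")),
            "problem_list_n": len(sub),
            "hfref_n": n_hf,
            "hfref_pct": (proportion_pct(n_hf, len(sub), 1)
                          if len(sub) else float("nan")),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CareGapReport:
    """Actionable worklists and referral-stratified GDMT rates."""

    missing_baseline_lvef: tuple[str, ...]
    outcome_patients: tuple[str, ...]
    n_referred: int
    off_gdmt: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gdmt_rates: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "missing_baseline_lvef": list(self.missing_baseline_lvef),
            "n_outcome_patients": len(self.outcome_patients),
            "n_referred": self.n_referred,
            "off_gdmt": {k: list(v) for k, v in self.off_gdmt.items()},
            "gdmt_rates": self.gdmt_rates,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def care_gap_report(members: pd.DataFrame) -> CareGapReport:
    """Build the care-gap report from a phenotyped members table.

    GDMT rates among outcome (LVD or HFrEF) patients are stratified by
    cardiology referral and compared per drug class with the chi-squared
    test (no continuity correction); the test is skipped when a stratum
    is empty.
    """
    missing = tuple(members.loc[~members["pre_assessed"].astype(bool),
                                "patient_id"])
    outcome_mask = members["lvd"].astype(bool) | members["hfref"].astype(bool)
    outcome = members[outcome_mask]
    referred = outcome["referred"].astype(bool)

    off_gdmt: dict[str, tuple[str, ...]] = {}
    rates: dict[str, dict] = {}
    for cls in GDMT_CLASSES:
        on = outcome[cls].astype(bool)
        off_gdmt[cls] = tuple(outcome.loc[~on, "patient_id"])
        entry: dict = {}
        for label, mask in (("referred", referred), ("not_referred", ~referred)):
            n, k = int(mask.sum()), int((on & mask).sum())
            entry[label] = {
                "n": n, "on_gdmt": k,
                "pct": proportion_pct(k, n, 1) if n else None,
            }
        if entry["referred"]["n"] and entry["not_referred"]["n"]:
            tab = TwoByTwo(
                a=entry["referred"]["on_gdmt"],
                b=entry["referred"]["n"] - entry["referred"]["on_gdmt"],
                c=entry["not_referred"]["on_gdmt"],
                d=entry["not_referred"]["n"] - entry["not_referred"]["on_gdmt"],
            )
            _, entry["p_value"] = chisq_2x2(tab)
        else:
            entry["p_value"] = None
        rates[cls] = entry

    return CareGapReport(
        missing_baseline_lvef=missing,
        outcome_patients=tuple(outcome["patient_id"]),
        n_referred=int(referred.sum()),
        off_gdmt=off_gdmt,
        gdmt_rates=rates,
    )
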