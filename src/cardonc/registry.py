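"""Nested cohort construction with attrition accounting.

Three filters produce the analysis population:

1. broad cancer population — any Problem-List code in the cancer value set;
2. treated registry — at least one treatment episode starting inside the
   closed treatment window;
3. baseline exclusion — patients with LV dysfunction (any LVEF below the
   threshold) or a heart-failure Problem-List entry strictly predating
   their initial exposure date are removed.

"Predated" is strict: same-day events count as post-treatment, consistent
with the phenotyping module's same-day-is-post convention.  Problem-List
entries without an onset date predate nothing (the patient is kept).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, asdict

import pandas as pd

from .dataset import EHRDataset
from .ontology import ConceptHierarchy, ValueSetRule, expand_value_set

__all__ = [
    "RegistryCriteria",
    "AttritionReport",
    "MissingEpisodeError",
    "build_cancer_population",
    "build_registry",
    "exclude_baseline_dysfunction",
]


class MissingEpisodeError(ValueError):
    """A registry patient has no treatment episode to anchor 'predated'."""


@dataclass(frozen=True)
class RegistryCriteria:
    cancer_rule: ValueSetRule
    treatment_window: tuple[dt.date, dt.date]
    require_treatment_episode: bool = True

    def __post_init__(self) -> None:
        start, end = self.treatment_window
        if start >= end:
            raise ValueError("treatment_window start must precede end")


@dataclass(frozen=True)
class AttritionReport:
    """Counts at each cohort filter; conservation is enforced."""

    n_cancer_population: int
    n_treated_registry: int
    n_excluded_baseline: int
    n_final: int

    def __post_init__(self) -> None:
        counts = asdict(self)
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"attrition counts must be non-negative: {counts}")
        if self.n_treated_registry > self.n_cancer_population:
            raise ValueError("treated registry cannot exceed cancer population")
        if self.n_final != self.n_treated_registry - self.n_excluded_baseline:
            raise ValueError(
                "attrition not conserved: "
                f"{self.n_treated_registry} - {self.n_excluded_baseline} "
                f"!= {self.n_final}"
            )

    def to_dict(self) -> dict[str, int]:
        return asdict(self)


def build_cancer_population(
    dataset: EHRDataset, hierarchy: ConceptHierarchy, rule: ValueSetRule
) -> set[str]:
    """Patients with any Problem-List code in the expanded cancer value set."""
    vs = expand_value_set(hierarchy, rule)
    hits = dataset.problems.loc[dataset.problems["code"].isin(vs.codes), "patient_id"]
    return set(hits)


def initial_exposure_dates(dataset: EHRDataset) -> pd.Series:
    """Earliest episode start per patient (index: patient_id)."""
    if not len(dataset.episodes):
        return pd.Series(dtype="datetime64[ns]", name="start_date")
    return dataset.episodes.groupby("patient_id")["start_date"].min()


def build_registry(
    population: set[str], dataset: EHRDataset, criteria: RegistryCriteria
) -> set[str]:
    """Members of ``population`` with an episode starting inside the closed
    treatment window (both endpoints included)."""
    if not criteria.require_treatment_episode:
        return set(population)
    start = pd.Timestamp(criteria.treatment_window[0])
    end = pd.Timestamp(criteria.treatment_window[1])
    ep = dataset.episodes
    in_window = ep.loc[
        ep["start_date"].between(start, end) & ep["patient_id"].isin(population),
        "patient_id",
    ]
    return set(in_window)


def exclude_baseline_dysfunction(
    registry: set[str],
    dataset: EHRDataset,
    hierarchy: ConceptHierarchy,
    hf_rule: ValueSetRule,
    lvef_threshold: float = 50.0,
    *,
    n_cancer_population: int | None = None,
) -> tuple[set[str], AttritionReport]:
    """Drop registry patients whose LVD or heart failure predates exposure.

    A patient is excluded if any LVEF strictly below ``lvef_threshold`` was
    measured strictly before their initial exposure date, or any Problem-
    List entry in the heart-failure value set has an onset date strictly
    before it.  Same-day events are post-treatment and do not exclude.
    """
    if not 0 < lvef_threshold < 100:
        raise ValueError("lvef_threshold must lie in (0, 100)")
    exposure = initial_exposure_dates(dataset)
    missing = registry - set(exposure.index)
    if missing:
        raise MissingEpisodeError(
            f"registry patients without a treatment episode: {sorted(missing)[:5]}"
        )

    img = dataset.imaging
    img = img[img["patient_id"].isin(registry)]
    img_exp = img["patient_id"].map(exposure)
    low_before = img.loc[
        (img["lvef"] < lvef_threshold) & (img["study_date"] < img_exp), "patient_id"
    ]

    hf_codes = expand_value_set(hierarchy, hf_rule).codes
    prob = dataset.problems
    prob = prob[prob["patient_id"].isin(registry) & prob["code"].isin(hf_codes)]
    prob_exp = prob["patient_id"].map(exposure)
    # entries lacking an onset date predate nothing (comparison is False)
    hf_before = prob.loc[prob["onset_date"] < prob_exp, "patient_id"]

    excluded = set(low_before) | set(hf_before)
    final = registry - excluded
    report = AttritionReport(
        n_cancer_population=(len(registry) if n_cancer_population is None
                             else n_cancer_population),
        n_treated_registry=len(registry),
        n_excluded_baseline=len(excluded),
        n_final=len(final),
    )
    return final, report
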