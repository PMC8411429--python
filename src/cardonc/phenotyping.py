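"""Per-patient care measures: exposure profile, LVEF assessment timing,
LVD/HFrEF outcome flags, GDMT medication status, cardiology referral.

Conventions (applied uniformly and exposed as flags where noted):

* the initial exposure date is the earliest treatment-episode start;
* imaging strictly before that date is a pre-exposure assessment; imaging
  on or after it is post-exposure (``same_day_is_post``, default true);
* post-treatment LVD is a minimum post-exposure LVEF strictly below 50%,
  by any modality;
* HFrEF is a Problem-List entry in the heart-failure value set (systolic
  heart failure and/or dilated cardiomyopathy, with descendants) with
  onset on/after the exposure date — entries without an onset date count
  as present;
* GDMT classification is phrase containment over pharmaceutical class /
  subclass titles, case-insensitively, on the active medication list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab as vocab_mod
from .dataset import EHRDataset
from .ontology import ConceptHierarchy, ValueSetRule, ValueSet, expand_value_set
from .registry import initial_exposure_dates
from .vocab import DrugVocabulary

__all__ = [
    "ExposureProfile",
    "LVEFAssessmentSummary",
    "OutcomeFlags",
    "GDMTStatus",
    "classify_exposure",
    "summarize_lvef",
    "detect_lvd",
    "detect_hfref",
    "classify_gdmt",
    "referred_to_cardiology",
    "phenotype_members",
    "LVD_THRESHOLD",
]

LVD_THRESHOLD = 50.0
MODALITIES = ("echo", "MUGA", "cardiac MRI")

DEFAULT_CLASS_MAP = {
    "anthracycline": "anthracycline",
    "her2": "her2",
    "tki": "tki",
    "ici": "ici",
    "other": "other",
}


@dataclass(frozen=True)
class ExposureProfile:
    initial_exposure_date: pd.Timestamp
    anthracycline: bool = False
    her2_antibody: bool = False
    tki: bool = False
    ici: bool = False


@dataclass(frozen=True)
class LVEFAssessmentSummary:
    pre_assessed: bool
    post_assessed: bool
    pre_modalities: frozenset[str] = frozenset()
    post_modalities: frozenset[str] = frozenset()
    min_post_lvef: float | None = None

    def __post_init__(self) -> None:
        if self.post_assessed != (self.min_post_lvef is not None):
            raise ValueError("min_post_lvef must be present iff post_assessed")
        if self.pre_assessed != bool(self.pre_modalities):
            raise ValueError("pre_modalities nonempty iff pre_assessed")
        if self.post_assessed != bool(self.post_modalities):
            raise ValueError("post_modalities nonempty iff post_assessed")


@dataclass(frozen=True)
class OutcomeFlags:
    lvd: bool
    hfref: bool


@dataclass(frozen=True)
class GDMTStatus:
    beta_blocker: bool
    acei: bool
    arb: bool
    mra: bool

    @property
    def acei_or_arb(self) -> bool:
        return self.acei or self.arb


def classify_exposure(
    episodes: pd.DataFrame, class_map: dict[str, str] | None = None
) -> ExposureProfile:
    """Exposure flags across ALL of a patient's episodes; the initial
    exposure date is the earliest start."""
    if not len(episodes):
        raise ValueError("cannot classify exposure without treatment episodes")
    class_map = DEFAULT_CLASS_MAP if class_map is None else class_map
    cats = {class_map.get(c, "other") for c in episodes["drug_class"]}
    return ExposureProfile(
        initial_exposure_date=episodes["start_date"].min(),
        anthracycline="anthracycline" in cats,
        her2_antibody="her2" in cats,
        tki="tki" in cats,
        ici="ici" in cats,
    )


def summarize_lvef(
    imaging: pd.DataFrame,
    exposure_date: pd.Timestamp,
    *,
    same_day_is_post: bool = True,
) -> LVEFAssessmentSummary:
    """Split a patient's imaging into pre-/post-exposure assessments."""
    if exposure_date is None or pd.isna(exposure_date):
        raise ValueError("exposure_date is required")
    if len(imaging):
        bad = ~imaging["lvef"].between(1, 99)
        if bad.any():
            raise ValueError(
                f"LVEF outside [1, 99]: {imaging.loc[bad, 'lvef'].tolist()[:5]}"
            )
    if same_day_is_post:
        pre = imaging["study_date"] < exposure_date
    else:
        pre = imaging["study_date"] <= exposure_date
    post = ~pre
    post_lvef = imaging.loc[post, "lvef"]
    return LVEFAssessmentSummary(
        pre_assessed=bool(pre.any()),
        post_assessed=bool(post.any()),
        pre_modalities=frozenset(imaging.loc[pre, "modality"]),
        post_modalities=frozenset(imaging.loc[post, "modality"]),
        min_post_lvef=float(post_lvef.min()) if post.any() else None,
    )


def detect_lvd(summary: LVEFAssessmentSummary,
               threshold: float = LVD_THRESHOLD) -> bool:
    """Post-treatment LV dysfunction: minimum post-exposure LVEF strictly
    below the threshold, by any modality."""
    return summary.post_assessed and summary.min_post_lvef < threshold


def detect_hfref(
    problems: pd.DataFrame,
    hf_value_set: ValueSet,
    exposure_date: pd.Timestamp | None = None,
) -> bool:
    """Heart-failure / dilated-cardiomyopathy Problem-List phenotype.

    With an ``exposure_date``, only entries with onset on/after it (or no
    onset date at all) count; baseline entries are the registry builder's
    concern and were excluded upstream.
    """
    hits = problems[problems["code"].isin(hf_value_set.codes)]
    if exposure_date is not None and len(hits):
        onset = hits["onset_date"]
        hits = hits[onset.isna() | (onset >= exposure_date)]
    return bool(len(hits))


_WORD = r"[A-Za-z0-9]"


def _contains_phrase(title: str, phrase: str) -> bool:
    return phrase in " ".join(title.lower().split())


def _contains_word(title: str, word: str) -> bool:
    # whole-word match so e.g. "ARB" never matches "BARBITURATE"
    return re.search(rf"(?<!{_WORD}){re.escape(word)}(?!{_WORD})",
                     title, flags=re.IGNORECASE) is not None


def classify_gdmt(
    active_meds: pd.DataFrame, vocab: DrugVocabulary | None = None
) -> GDMTStatus:
    """Classify an active medication list into GDMT drug classes.

    Matching is monotone in list growth: adding rows can only turn flags
    on.  Rows with ``active`` false are ignored if the column is present.
    """
    vocab = vocab_mod.default_vocabulary() if vocab is None else vocab
    meds = active_meds
    if "active" in meds.columns and len(meds):
        meds = meds[meds["active"].astype(bool)]

    names = [str(x).lower() for x in meds.get("drug_name", pd.Series(dtype=object))]
    classes = [str(x) for x in meds.get("pharm_class", pd.Series(dtype=object))]
    subclasses = [str(x) for x in meds.get("pharm_subclass", pd.Series(dtype=object))]

    bb = any(
        ing.lower() in name for name in names
        for ing in vocab.beta_blocker_ingredients
    )
    acei = (
        any(_contains_phrase(t, vocab_mod.ACEI_PHRASE) for t in classes + subclasses)
        or any(combo.lower() in name for name in names
               for combo in vocab.acei_combinations)
    )
    arb = (
        any(_contains_phrase(t, p) for t in classes
            for p in vocab_mod.ARB_PHRASES)
        or any(_contains_word(t, vocab_mod.ARB_ABBREVIATION) for t in classes)
        or any(ing.lower() in name for name in names
               for ing in vocab.arb_extra_ingredients)
    )
    mra = any(_contains_phrase(t, vocab_mod.MRA_PHRASE) for t in subclasses)
    return GDMTStatus(beta_blocker=bb, acei=acei, arb=arb, mra=mra)


def referred_to_cardiology(referrals: pd.DataFrame) -> bool:
    """True iff any referral row has specialty cardiology."""
    if not len(referrals):
        return False
    return bool(
        referrals["specialty"].astype(str).str.lower().eq("cardiology").any()
    )


def cohort_hfref_flags(
    dataset: EHRDataset,
    members: set[str],
    hierarchy: ConceptHierarchy,
    hf_rule: ValueSetRule,
) -> pd.Series:
    """Vectorized HFrEF Problem-List flag for every member (same rule as
    :func:`detect_hfref`); returns a boolean Series indexed by patient id."""
    hf_vs = expand_value_set(hierarchy, hf_rule)
    exposure = initial_exposure_dates(dataset)
    prob = dataset.problems
    prob = prob[prob["patient_id"].isin(members) & prob["code"].isin(hf_vs.codes)]
    exp = prob["patient_id"].map(exposure)
    hits = prob.loc[prob["onset_date"].isna() | (prob["onset_date"] >= exp),
                    "patient_id"]
    idx = sorted(members)
    return pd.Series(pd.Index(idx).isin(set(hits)), index=idx, name="hfref")


def phenotype_members(
    dataset: EHRDataset,
    members: set[str],
    hierarchy: ConceptHierarchy,
    hf_rule: ValueSetRule,
    vocab: DrugVocabulary | None = None,
    *,
    same_day_is_post: bool = True,
    lvd_threshold: float = LVD_THRESHOLD,
) -> pd.DataFrame:
    """One phenotype record per registry member.

    Returns a DataFrame indexed 0..n-1 with columns: patient_id,
    initial_exposure_date, exposure flags, pre/post assessment flags and
    modalities, min_post_lvef, lvd, hfref, GDMT flags, referred.
    """
    hf_vs = expand_value_set(hierarchy, hf_rule)
    by_ep = {k: v for k, v in dataset.episodes.groupby("patient_id")}
    by_img = {k: v for k, v in dataset.imaging.groupby("patient_id")}
    by_prob = {k: v for k, v in dataset.problems.groupby("patient_id")}
    by_med = {k: v for k, v in dataset.medications.groupby("patient_id")}
    by_ref = {k: v for k, v in dataset.referrals.groupby("patient_id")}
    empty = {
        "img": dataset.imaging.iloc[0:0],
        "prob": dataset.problems.iloc[0:0],
        "med": dataset.medications.iloc[0:0],
        "ref": dataset.referrals.iloc[0:0],
    }

    rows = []
    for patient_id in sorted(members):
        exp = classify_exposure(by_ep[patient_id])
        summary = summarize_lvef(
            by_img.get(patient_id, empty["img"]),
            exp.initial_exposure_date,
            same_day_is_post=same_day_is_post,
        )
        lvd = detect_lvd(summary, threshold=lvd_threshold)
        hfref = detect_hfref(
            by_prob.get(patient_id, empty["prob"]), hf_vs,
            exposure_date=exp.initial_exposure_date,
        )
        gdmt = classify_gdmt(by_med.get(patient_id, empty["med"]), vocab)
        rows.append({
            "patient_id": patient_id,
            "initial_exposure_date": exp.initial_exposure_date,
            "anthracycline": exp.anthracycline,
            "her2": exp.her2_antibody,
            "tki": exp.tki,
            "ici": exp.ici,
            "pre_assessed": summary.pre_assessed,
            "post_assessed": summary.post_assessed,
            "pre_modalities": "|".join(sorted(summary.pre_modalities)),
            "post_modalities": "|".join(sorted(summary.post_modalities)),
            "min_post_lvef": summary.min_post_lvef,
            "lvd": lvd,
            "hfref": hfref,
            "beta_blocker": gdmt.beta_blocker,
            "acei": gdmt.acei,
            "arb": gdmt.arb,
            "acei_or_arb": gdmt.acei_or_arb,
            "mra": gdmt.mra,
            "referred": referred_to_cardiology(by_ref.get(patient_id, empty["ref"])),
        })
    return pd.DataFrame(rows)
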