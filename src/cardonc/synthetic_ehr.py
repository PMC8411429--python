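"""Synthetic EHR cohort generator with known per-patient ground truth.

Emulates the record structure a cardio-oncology registry is built from —
Problem Lists coded against the bundled concept hierarchy, chemotherapy
treatment episodes, cardiac imaging with LVEF values, active medication
lists with pharmaceutical class titles, and cardiology referrals — plus a
truth table so every downstream stage can be validated against what was
actually generated.

The generative model, per patient:

1. demographics (age, sex, vital status, comorbidities);
2. cancer status -> cancer Problem-List code; treated patients get one or
   more chemotherapy episodes whose classes (anthracycline, HER2 antibody,
   TKI, ICI, other) are independent Bernoulli draws with configured
   marginals; the earliest start date is the initial exposure date;
3. a small fraction carry baseline LV dysfunction (a pre-treatment LVEF
   below 50 or a heart-failure Problem-List entry predating exposure) and
   are expected to fall out of the final analysis population;
4. pre-/post-exposure LVEF screening is Bernoulli with class-specific
   probabilities; true post-treatment LVD drives the measured LVEF side
   of the 50% threshold (below 50 if LVD, at/above otherwise, with an
   optional misclassification overlap);
5. true HFrEF is documented on the Problem List through a noisy channel
   with configured sensitivity and specificity;
6. cardiology referral is Bernoulli given the true outcome, and GDMT
   medications are drawn with referral-dependent probabilities.

Everything is determined by ``(config, config.seed)``; identical configs
give byte-identical datasets.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import terminology as term
from .dataset import EHRDataset

__all__ = ["CohortConfig", "GDMTRates", "Demographics", "generate", "SyntheticTruth"]

#: the truth table is a DataFrame, one row per generated patient, with
#: columns patient_id, true_cancer, treated, exposure_class, anthracycline,
#: her2, tki, ici, baseline_dysfunction, pre_assessed, post_assessed,
#: true_lvd, true_hfref, hf_documented, referred
SyntheticTruth = pd.DataFrame

ClassProb = Union[float, dict[str, float]]

EXPOSURE_CLASSES = ("anthracycline", "her2", "tki", "ici", "other")

_DRUGS: dict[str, list[str]] = {
    "anthracycline": ["Doxorubicin", "Epirubicin", "Daunorubicin"],
    "her2": ["Trastuzumab", "Pertuzumab"],
    "tki": ["Sunitinib", "Imatinib", "Lapatinib"],
    "ici": ["Pembrolizumab", "Nivolumab"],
    "other": ["Cyclophosphamide", "Paclitaxel", "Carboplatin", "5-Fluorouracil"],
}

# (drug name, pharm class title, pharm subclass title)
_BETA_BLOCKERS = [
    ("Carvedilol 12.5 mg tablet", "Beta-Adrenergic Blockers", "Alpha-Beta Blockers"),
    ("Metoprolol Succinate ER 50 mg tablet", "Beta-Adrenergic Blockers",
     "Cardioselective Beta Blockers"),
    ("Bisoprolol Fumarate 5 mg tablet", "Beta-Adrenergic Blockers",
     "Cardioselective Beta Blockers"),
]
_ACEIS = [
    ("Lisinopril 10 mg tablet", "ACE Inhibitors", "ACE Inhibitors"),
    ("Enalapril 5 mg tablet", "ACE Inhibitors", "ACE Inhibitors, Dicarboxylate"),
    ("Benazepril/Amlodipine 10-5 mg capsule",
     "ACE Inhibitors & Calcium Channel Blockers",
     "ACE Inhibitors & Calcium Channel Blockers"),
]
_ARBS = [
    ("Losartan Potassium 50 mg tablet",
     "Angiotensin II Receptor Blockers (ARBs)", "Angiotensin II Receptor Blockers"),
    ("Valsartan 80 mg tablet",
     "Angiotensin II Receptor Blockers (ARBs)", "Angiotensin II Receptor Blockers"),
]
_MRAS = [
    ("Spironolactone 25 mg tablet", "Diuretics, Potassium-Sparing",
     "Aldosterone Receptor Antagonists"),
    ("Eplerenone 25 mg tablet", "Diuretics, Potassium-Sparing",
     "Aldosterone Receptor Antagonists"),
]
# none of these may trip any GDMT rule ("Barbiturates" probes ARB word-boundary)
_DECOY_MEDS = [
    ("Metoprolol Tartrate 25 mg tablet", "Beta-Adrenergic Blockers",
     "Cardioselective Beta Blockers"),
    ("Atorvastatin 20 mg tablet", "HMG-CoA Reductase Inhibitors", "Statins"),
    ("Phenobarbital 30 mg tablet", "Barbiturates", "Barbiturates"),
    ("Amlodipine 5 mg tablet", "Calcium Channel Blockers",
     "Dihydropyridine Calcium Channel Blockers"),
]


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_median: float = 63.0
    age_sd: float = Field(default=14.0, gt=0)
    female_frac: float = Field(default=0.5457, ge=0, le=1)
    alive_frac: float = Field(default=0.6738, ge=0, le=1)
    hypertension_prob: float = Field(default=0.258, ge=0, le=1)
    diabetes_prob: float = Field(default=0.1524, ge=0, le=1)


class GDMTRates(BaseModel):
    """Per-drug-class prescription probability by referral status."""

    model_config = ConfigDict(frozen=True)

    referred: float = Field(ge=0.0, le=1.0)
    not_referred: float = Field(ge=0.0, le=1.0)


def _default_gdmt() -> dict[str, GDMTRates]:
    return {
        "beta_blocker": GDMTRates(referred=0.441, not_referred=0.188),
        "acei_arb": GDMTRates(referred=0.474, not_referred=0.306),
        "mra": GDMTRates(referred=0.118, not_referred=0.024),
    }


class CohortConfig(BaseModel):
    """Generator parameters; defaults mirror the registry study conditions.

    Per-class probability fields accept either a scalar or a mapping keyed
    by exposure class; missing classes fall back to the ``"other"`` entry.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=10_000, ge=1)
    seed: int = 0
    treatment_window: tuple[dt.date, dt.date] = (dt.date(2011, 1, 1),
                                                 dt.date(2017, 6, 30))
    extraction_date: dt.date = dt.date(2017, 9, 30)

    cancer_prevalence: float = Field(default=0.92, ge=0, le=1)
    treated_prob: float = Field(default=0.90, ge=0, le=1)
    exposure_probs: dict[str, float] = Field(
        default_factory=lambda: {"anthracycline": 0.1778, "her2": 0.0495,
                                 "tki": 0.0882, "ici": 0.0031, "other": 0.68})

    # class-specific screening; the "other" entries are back-solved so the
    # marginal pre/post rates land at 19.77% / 40.91% under the exposure mix
    pre_screen_prob: ClassProb = Field(
        default_factory=lambda: {"her2": 0.278, "anthracycline": 0.2588,
                                 "other": 0.1794})
    post_screen_prob: ClassProb = Field(
        default_factory=lambda: {"her2": 0.851, "anthracycline": 0.691,
                                 "other": 0.3202})
    lvd_risk: ClassProb = Field(
        default_factory=lambda: {"her2": 0.049, "anthracycline": 0.042,
                                 "other": 0.126})
    hfref_risk: ClassProb = Field(
        default_factory=lambda: {"her2": 0.090, "anthracycline": 0.035,
                                 "other": 0.0198})

    baseline_dysfunction_prob: float = Field(default=0.045, ge=0, le=1)
    hfref_doc_sensitivity: float = Field(default=0.953, ge=0, le=1)
    hfref_doc_specificity: float = Field(default=0.835, ge=0, le=1)
    referral_prob_given_outcome: float = Field(default=0.639, ge=0, le=1)
    referral_prob_background: float = Field(default=0.02, ge=0, le=1)
    gdmt_probs: dict[str, GDMTRates] = Field(default_factory=_default_gdmt)

    demographics: Demographics = Field(default_factory=Demographics)

    # measured-LVEF distributions around the 50% threshold
    lvef_lvd_mean: float = 40.0
    lvef_lvd_sd: float = 6.0
    lvef_normal_mean: float = 60.0
    lvef_normal_sd: float = 5.0
    #: probability that a measured LVEF lands on the wrong side of 50%
    lvef_noise_overlap: float = Field(default=0.0, ge=0, le=1)

    decoy_med_prob: float = Field(default=0.30, ge=0, le=1)
    decoy_referral_prob: float = Field(default=0.15, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        start, end = self.treatment_window
        if start >= end:
            raise ValueError("treatment_window start must precede end")
        for name in ("exposure_probs", "pre_screen_prob", "post_screen_prob",
                     "lvd_risk", "hfref_risk"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(not 0 <= p <= 1 for p in vals):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
        if isinstance(self.exposure_probs, dict):
            unknown = set(self.exposure_probs) - set(EXPOSURE_CLASSES)
            if unknown:
                raise ValueError(f"exposure_probs: unknown classes {sorted(unknown)}")
        return self

    def resolve_class_prob(self, field: str, class_labels: np.ndarray) -> np.ndarray:
        """Per-patient probability vector for a scalar-or-dict field."""
        v = getattr(self, field)
        if not isinstance(v, dict):
            return np.full(len(class_labels), float(v))
        if "other" not in v:
            raise ValueError(f"{field}: class map needs an 'other' fallback")
        return np.array([v.get(c, v["other"]) for c in class_labels])


def _pick(rng: np.random.Generator, options: list, size: int) -> np.ndarray:
    idx = rng.integers(0, len(options), size=size)
    return np.array(options, dtype=object)[idx]


def _days(rng: np.random.Generator, lo: int, hi: int, size: int) -> pd.TimedeltaIndex:
    return pd.to_timedelta(rng.integers(lo, hi + 1, size=size), unit="D")


def generate(config: CohortConfig) -> tuple[EHRDataset, SyntheticTruth]:
    """Generate a synthetic EHR dataset and its ground-truth table."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    dem = config.demographics
    w_start = pd.Timestamp(config.treatment_window[0])
    w_end = pd.Timestamp(config.treatment_window[1])
    extraction = pd.Timestamp(config.extraction_date)
    span_days = (w_end - w_start).days

    pid = np.array([f"P{i:06d}" for i in range(n)], dtype=object)

    # --- demographics ---------------------------------------------------------
    age = np.clip(rng.normal(dem.age_median, dem.age_sd, n), 18, 95)
    birth = extraction - pd.to_timedelta((age * 365.25).round(), unit="D")
    sex = np.where(rng.random(n) < dem.female_frac, "F", "M")
    alive = rng.random(n) < dem.alive_frac
    htn = rng.random(n) < dem.hypertension_prob
    dm = rng.random(n) < dem.diabetes_prob

    patients = pd.DataFrame({
        "patient_id": pid, "birth_date": birth, "sex": sex, "alive": alive,
    })

    # --- cancer and treatment -------------------------------------------------
    true_cancer = rng.random(n) < config.cancer_prevalence
    treated = true_cancer & (rng.random(n) < config.treated_prob)

    flags = {}
    for cls in ("anthracycline", "her2", "tki", "ici"):
        flags[cls] = treated & (rng.random(n) < config.exposure_probs.get(cls, 0.0))
    other = treated & (rng.random(n) < config.exposure_probs.get("other", 0.0))
    none_yet = treated & ~(flags["anthracycline"] | flags["her2"] | flags["tki"]
                           | flags["ici"] | other)
    other |= none_yet  # every treated patient has at least one episode
    flags["other"] = other

    # risk/screening class: HER2 dominates, then anthracycline, then the rest
    class_label = np.select(
        [flags["her2"], flags["anthracycline"], flags["tki"], flags["ici"]],
        ["her2", "anthracycline", "tki", "ici"],
        default="other").astype(object)
    class_label[~treated] = ""

    exposure_offset = rng.integers(0, span_days + 1, size=n)
    exposure_date = w_start + pd.to_timedelta(exposure_offset, unit="D")

    episode_frames = []
    priority = {c: i for i, c in enumerate(EXPOSURE_CLASSES)}
    prio_class = np.select(
        [flags["anthracycline"], flags["her2"], flags["tki"], flags["ici"]],
        ["anthracycline", "her2", "tki", "ici"], default="other").astype(object)
    for cls in EXPOSURE_CLASSES:
        m = np.flatnonzero(flags[cls])
        if not len(m):
            continue
        # the patient's highest-priority class starts on the exposure date;
        # additional classes start up to 200 days later (min stays correct)
        is_first = prio_class[m] == cls
        offset = np.where(is_first, 0, rng.integers(1, 201, size=len(m)))
        episode_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "drug_name": _pick(rng, _DRUGS[cls], len(m)),
            "drug_class": cls,
            "start_date": exposure_date[m] + pd.to_timedelta(offset, unit="D"),
        }))
    episodes = (pd.concat(episode_frames, ignore_index=True) if episode_frames
                else pd.DataFrame(columns=["patient_id", "drug_name", "drug_class",
                                           "start_date"]))

    # --- baseline (pre-treatment) dysfunction ---------------------------------
    baseline = treated & (rng.random(n) < config.baseline_dysfunction_prob)
    base_low_lvef = baseline & (rng.random(n) < 0.5)   # imaging branch
    base_hf_doc = baseline & ~base_low_lvef            # Problem-List branch

    # --- screening ------------------------------------------------------------
    p_pre = config.resolve_class_prob("pre_screen_prob", class_label)
    p_post = config.resolve_class_prob("post_screen_prob", class_label)
    pre_draw = treated & (rng.random(n) < p_pre)
    pre_assessed = pre_draw | base_low_lvef
    post_assessed = treated & (rng.random(n) < p_post)

    # --- outcomes -------------------------------------------------------------
    p_lvd = config.resolve_class_prob("lvd_risk", class_label)
    true_lvd = post_assessed & (rng.random(n) < p_lvd)
    p_hf = config.resolve_class_prob("hfref_risk", class_label)
    true_hfref = treated & (rng.random(n) < p_hf)

    doc_pos = rng.random(n) < config.hfref_doc_sensitivity
    doc_neg = rng.random(n) < (1.0 - config.hfref_doc_specificity)
    hf_documented = treated & np.where(true_hfref, doc_pos, doc_neg)

    # measured LVEF side of the 50% threshold (optional misclassification)
    side_flip = rng.random(n) < config.lvef_noise_overlap
    measured_low = true_lvd ^ (side_flip & post_assessed)

    # --- problem list ---------------------------------------------------------
    prob_frames = []

    m = np.flatnonzero(true_cancer)
    onset = np.where(
        treated[m],
        (exposure_date[m] - _days(rng, 14, 365, len(m))).asi8,
        (w_start + _days(rng, 0, span_days, len(m))).asi8,
    )
    prob_frames.append(pd.DataFrame({
        "patient_id": pid[m],
        "code": _pick(rng, term.cancer_leaf_codes(), len(m)),
        "onset_date": pd.to_datetime(onset),
    }))

    m = np.flatnonzero(~true_cancer)
    if len(m):
        prob_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "code": _pick(rng, term.noncancer_codes(), len(m)),
            "onset_date": w_start + _days(rng, 0, span_days, len(m)),
        }))

    for mask, code in ((htn, term.HYPERTENSION), (dm, term.DIABETES)):
        m = np.flatnonzero(mask)
        if len(m):
            prob_frames.append(pd.DataFrame({
                "patient_id": pid[m], "code": code,
                "onset_date": w_start + _days(rng, -1500, span_days, len(m)),
            }))

    hf_codes = [term.SYSTOLIC_CHF, term.DILATED_CARDIOMYOPATHY, "chronic-systolic-chf"]
    m = np.flatnonzero(base_hf_doc)
    if len(m):
        prob_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "code": _pick(rng, hf_codes, len(m)),
            "onset_date": exposure_date[m] - _days(rng, 30, 1000, len(m)),
        }))
    m = np.flatnonzero(hf_documented)
    if len(m):
        prob_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "code": _pick(rng, hf_codes, len(m)),
            "onset_date": exposure_date[m] + _days(rng, 30, 400, len(m)),
        }))
    problems = pd.concat(prob_frames, ignore_index=True)

    # --- imaging --------------------------------------------------------------
    def lvef_values(size: int, low: bool) -> np.ndarray:
        if low:
            return np.clip(rng.normal(config.lvef_lvd_mean, config.lvef_lvd_sd,
                                      size), 5.0, 49.5).round(1)
        return np.clip(rng.normal(config.lvef_normal_mean, config.lvef_normal_sd,
                                  size), 50.0, 80.0).round(1)

    modalities = ["echo", "MUGA", "cardiac MRI"]
    mod_p = np.array([0.975, 0.015, 0.010])

    img_frames = []
    # pre-exposure studies: baseline-dysfunction imaging branch is low,
    # everyone else screened pre-exposure is normal
    for mask, low in ((base_low_lvef, True), (pre_draw & ~base_low_lvef, False)):
        m = np.flatnonzero(mask)
        if not len(m):
            continue
        img_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "modality": rng.choice(modalities, size=len(m), p=mod_p),
            "study_date": exposure_date[m] - _days(rng, 1, 365, len(m)),
            "lvef": lvef_values(len(m), low),
        }))
    # post-exposure studies (a same-day fraction exercises the boundary rule)
    m = np.flatnonzero(post_assessed)
    if len(m):
        offset = rng.integers(1, 601, size=len(m))
        offset[rng.random(len(m)) < 0.10] = 0  # ~10% land on the exposure date
        low = measured_low[m]
        vals = np.empty(len(m))
        vals[low] = lvef_values(int(low.sum()), True)
        vals[~low] = lvef_values(int((~low).sum()), False)
        img_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "modality": rng.choice(modalities, size=len(m), p=mod_p),
            "study_date": exposure_date[m] + pd.to_timedelta(offset, unit="D"),
            "lvef": vals,
        }))
        # a second, later study for ~15%, never below the first one's side
        extra = m[rng.random(len(m)) < 0.15]
        if len(extra):
            img_frames.append(pd.DataFrame({
                "patient_id": pid[extra],
                "modality": rng.choice(modalities, size=len(extra), p=mod_p),
                "study_date": exposure_date[extra] + _days(rng, 601, 900, len(extra)),
                "lvef": np.where(measured_low[extra],
                                 lvef_values(len(extra), True),
                                 lvef_values(len(extra), False)),
            }))
    imaging = (pd.concat(img_frames, ignore_index=True) if img_frames
               else pd.DataFrame(columns=["patient_id", "modality", "study_date",
                                          "lvef"]))

    # --- referrals ------------------------------------------------------------
    outcome = true_lvd | true_hfref
    referred = ((outcome & (rng.random(n) < config.referral_prob_given_outcome))
                | (treated & ~outcome
                   & (rng.random(n) < config.referral_prob_background)))
    ref_frames = []
    m = np.flatnonzero(referred)
    if len(m):
        ref_frames.append(pd.DataFrame({
            "patient_id": pid[m], "specialty": "cardiology",
            "referral_date": exposure_date[m] + _days(rng, 30, 500, len(m)),
        }))
    m = np.flatnonzero(rng.random(n) < config.decoy_referral_prob)
    if len(m):
        ref_frames.append(pd.DataFrame({
            "patient_id": pid[m], "specialty": "endocrinology",
            "referral_date": w_start + _days(rng, 0, span_days, len(m)),
        }))
    referrals = (pd.concat(ref_frames, ignore_index=True) if ref_frames
                 else pd.DataFrame(columns=["patient_id", "specialty",
                                            "referral_date"]))

    # --- medications ----------------------------------------------------------
    med_frames = []

    def med_rows(mask: np.ndarray, options: list[tuple[str, str, str]]):
        m = np.flatnonzero(mask)
        if not len(m):
            return
        rows = _pick(rng, options, len(m))
        med_frames.append(pd.DataFrame({
            "patient_id": pid[m],
            "drug_name": [r[0] for r in rows],
            "pharm_class": [r[1] for r in rows],
            "pharm_subclass": [r[2] for r in rows],
            "active": True,
            "as_of_date": extraction,
        }))

    on_gdmt = {}
    for drug_cls, options in (("beta_blocker", _BETA_BLOCKERS),
                              ("mra", _MRAS)):
        rates = config.gdmt_probs[drug_cls]
        p = np.where(referred, rates.referred, rates.not_referred)
        on = outcome & (rng.random(n) < p)
        on_gdmt[drug_cls] = on
        med_rows(on, options)
    rates = config.gdmt_probs["acei_arb"]
    p = np.where(referred, rates.referred, rates.not_referred)
    on_raas = outcome & (rng.random(n) < p)
    on_gdmt["acei_arb"] = on_raas
    takes_acei = rng.random(n) < 0.5
    med_rows(on_raas & takes_acei, _ACEIS)
    med_rows(on_raas & ~takes_acei, _ARBS)

    med_rows(rng.random(n) < config.decoy_med_prob, _DECOY_MEDS)

    medications = (pd.concat(med_frames, ignore_index=True) if med_frames
                   else pd.DataFrame(columns=["patient_id", "drug_name",
                                              "pharm_class", "pharm_subclass",
                                              "active", "as_of_date"]))
    if len(medications):
        medications = medications.sort_values(
            ["patient_id", "drug_name"], ignore_index=True)

    dataset = EHRDataset(
        patients=patients,
        problems=problems.sort_values(["patient_id", "code"], ignore_index=True),
        episodes=episodes.sort_values(["patient_id", "start_date"],
                                      ignore_index=True)
        if len(episodes) else episodes,
        imaging=imaging.sort_values(["patient_id", "study_date"],
                                    ignore_index=True) if len(imaging) else imaging,
        medications=medications,
        referrals=referrals.sort_values(["patient_id", "specialty"],
                                        ignore_index=True)
        if len(referrals) else referrals,
    ).validate()

    truth = pd.DataFrame({
        "patient_id": pid,
        "true_cancer": true_cancer,
        "treated": treated,
        "exposure_class": class_label,
        "anthracycline": flags["anthracycline"],
        "her2": flags["her2"],
        "tki": flags["tki"],
        "ici": flags["ici"],
        "baseline_dysfunction": baseline,
        "pre_assessed": pre_assessed,
        "post_assessed": post_assessed,
        "true_lvd": true_lvd,
        "true_hfref": true_hfref,
        "hf_documented": hf_documented,
        "referred": referred,
        "on_beta_blocker": on_gdmt["beta_blocker"],
        "on_acei_arb": on_gdmt["acei_arb"],
        "on_mra": on_gdmt["mra"],
    })
    return dataset, truth
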