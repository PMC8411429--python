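"""Care-measure derivation: exposure, LVEF timing, outcomes, GDMT."""

import numpy as np
import pandas as pd
import pytest

import cardonc as co
from cardonc import terminology as term
from cardonc.ontology import expand_value_set

EXP = pd.Timestamp("2014-06-01")


def episodes(*rows):
    return pd.DataFrame(
        [{"patient_id": "X", "drug_name": d, "drug_class": c,
          "start_date": pd.Timestamp(s)} for d, c, s in rows])


def imaging(*rows):
    return pd.DataFrame(
        [{"patient_id": "X", "modality": m, "study_date": pd.Timestamp(s),
          "lvef": v} for s, v, m in rows],
        columns=["patient_id", "modality", "study_date", "lvef"])


def meds(*rows):
    return pd.DataFrame(
        [{"patient_id": "X", "drug_name": n, "pharm_class": c,
          "pharm_subclass": s, "active": a, "as_of_date": EXP}
         for n, c, s, a in rows],
        columns=["patient_id", "drug_name", "pharm_class", "pharm_subclass",
                 "active", "as_of_date"])


@pytest.fixture(scope="module")
def hf_vs(hierarchy):
    return expand_value_set(hierarchy, term.heart_failure_rule())


class TestClassifyExposure:
    def test_single_anthracycline_episode(self):
        p = co.classify_exposure(episodes(("Doxorubicin", "anthracycline",
                                           "2014-06-01")))
        assert p.anthracycline and not (p.her2_antibody or p.tki or p.ici)
        assert p.initial_exposure_date == EXP

    def test_multiple_classes_all_flagged_date_is_first(self):
        p = co.classify_exposure(episodes(
            ("Doxorubicin", "anthracycline", "2014-06-01"),
            ("Trastuzumab", "her2", "2014-09-01")))
        assert p.anthracycline and p.her2_antibody
        assert p.initial_exposure_date == EXP

    def test_zero_episodes_is_an_error(self):
        with pytest.raises(ValueError):
            co.classify_exposure(episodes())

    def test_unknown_class_maps_to_other(self):
        p = co.classify_exposure(episodes(("Weird", "experimental",
                                           "2014-06-01")))
        assert not (p.anthracycline or p.her2_antibody or p.tki or p.ici)


class TestSummarizeLVEF:
    def test_study_day_before_exposure_is_pre_only(self):
        s = co.summarize_lvef(imaging(("2014-05-31", 60.0, "echo")), EXP)
        assert s.pre_assessed and not s.post_assessed
        assert s.min_post_lvef is None

    def test_same_day_study_is_post_by_convention(self):
        s = co.summarize_lvef(imaging(("2014-06-01", 60.0, "echo")), EXP)
        assert s.post_assessed and not s.pre_assessed
        assert s.min_post_lvef == 60.0

    def test_same_day_flag_flips_the_convention(self):
        s = co.summarize_lvef(imaging(("2014-06-01", 60.0, "echo")), EXP,
                              same_day_is_post=False)
        assert s.pre_assessed and not s.post_assessed

    def test_min_post_over_multiple_studies_and_modalities(self):
        s = co.summarize_lvef(imaging(
            ("2014-07-01", 55.0, "echo"),
            ("2015-01-01", 42.0, "MUGA"),
            ("2014-05-01", 61.0, "cardiac MRI")), EXP)
        assert s.min_post_lvef == 42.0
        assert s.post_modalities == {"echo", "MUGA"}
        assert s.pre_modalities == {"cardiac MRI"}

    def test_lvef_outside_1_99_is_a_data_quality_error(self):
        with pytest.raises(ValueError, match="LVEF"):
            co.summarize_lvef(imaging(("2014-07-01", 0.5, "echo")), EXP)

    def test_missing_exposure_date_is_an_error(self):
        with pytest.raises(ValueError):
            co.summarize_lvef(imaging(), pd.NaT)


class TestDetectLVD:
    @pytest.mark.parametrize("lvef,expected", [
        (50.0, False),   # strict threshold: 50 is not dysfunction
        (49.9, True),
        (50.1, False),
        (35.0, True),
    ])
    def test_threshold_strictness(self, lvef, expected):
        s = co.summarize_lvef(imaging(("2014-07-01", lvef, "echo")), EXP)
        assert co.detect_lvd(s) is expected

    def test_no_post_imaging_is_not_lvd(self):
        s = co.summarize_lvef(imaging(("2014-05-01", 30.0, "echo")), EXP)
        assert co.detect_lvd(s) is False


class TestDetectHFrEF:
    def probs(self, *rows):
        return pd.DataFrame(
            [{"patient_id": "X", "code": c,
              "onset_date": pd.Timestamp(d) if d else pd.NaT}
             for c, d in rows],
            columns=["patient_id", "code", "onset_date"])

    def test_empty_problem_list(self, hf_vs):
        assert co.detect_hfref(self.probs(), hf_vs) is False

    def test_dilated_cardiomyopathy_alone_suffices(self, hf_vs):
        probs = self.probs((term.DILATED_CARDIOMYOPATHY, "2015-01-01"))
        assert co.detect_hfref(probs, hf_vs, EXP) is True

    def test_descendant_code_matches(self, hf_vs):
        probs = self.probs(("chronic-systolic-chf", "2015-01-01"))
        assert co.detect_hfref(probs, hf_vs, EXP) is True

    def test_onset_before_exposure_does_not_count(self, hf_vs):
        probs = self.probs((term.SYSTOLIC_CHF, "2013-01-01"))
        assert co.detect_hfref(probs, hf_vs, EXP) is False

    def test_missing_onset_counts_as_present(self, hf_vs):
        probs = self.probs((term.SYSTOLIC_CHF, None))
        assert co.detect_hfref(probs, hf_vs, EXP) is True

    def test_non_hf_codes_ignored(self, hf_vs):
        probs = self.probs((term.HYPERTENSION, "2015-01-01"))
        assert co.detect_hfref(probs, hf_vs, EXP) is False


class TestClassifyGDMT:
    @pytest.mark.parametrize("name,cls,sub,flag", [
        ("Carvedilol 12.5 mg tablet", "Beta-Adrenergic Blockers", "", "beta_blocker"),
        ("CARVEDILOL 25 MG TABLET", "", "", "beta_blocker"),
        ("Metoprolol Succinate ER 50 mg", "Beta Blockers", "", "beta_blocker"),
        ("Bisoprolol Fumarate 5 mg", "", "", "beta_blocker"),
        ("Lisinopril 10 mg", "ACE Inhibitors", "", "acei"),
        ("Something", "ACE Inhibitors & Calcium Blockers", "", "acei"),
        ("Something", "", "ace   inhibitor combinations", "acei"),
        ("Lisinopril/Hydrochlorothiazide 20-25", "Antihypertensive Combinations",
         "", "acei"),
        ("Losartan 50 mg", "Angiotensin II Receptor Blockers (ARBs)", "", "arb"),
        ("Candesartan", "Angiotensin Receptor Antagonists", "", "arb"),
        ("Entresto", "ARB-Neprilysin Inhibitors", "", "arb"),
        ("Aliskiren/Valsartan 150-160", "Renin Inhibitor Combinations", "", "arb"),
        ("Spironolactone 25 mg", "Diuretics",
         "Aldosterone Receptor Antagonists", "mra"),
    ])
    def test_rule_matches(self, name, cls, sub, flag):
        st = co.classify_gdmt(meds((name, cls, sub, True)))
        assert getattr(st, flag) is True

    @pytest.mark.parametrize("name,cls,sub", [
        ("Metoprolol Tartrate 25 mg", "Beta-Adrenergic Blockers", ""),
        ("Phenobarbital 30 mg", "Barbiturates", "Barbiturates"),  # ARB boundary
        ("Atorvastatin 20 mg", "HMG-CoA Reductase Inhibitors", "Statins"),
        ("Amlodipine 5 mg", "Calcium Channel Blockers", ""),
    ])
    def test_non_gdmt_rows_match_nothing(self, name, cls, sub):
        st = co.classify_gdmt(meds((name, cls, sub, True)))
        assert not (st.beta_blocker or st.acei or st.arb or st.mra)

    def test_acei_or_arb_is_the_disjunction(self):
        st = co.classify_gdmt(meds(("Losartan 50 mg",
                                    "Angiotensin Receptor Antagonists", "", True)))
        assert st.acei_or_arb and not st.acei and st.arb

    def test_inactive_rows_are_ignored(self):
        st = co.classify_gdmt(meds(("Carvedilol 12.5 mg", "", "", False)))
        assert st.beta_blocker is False

    def test_empty_list_matches_nothing(self):
        st = co.classify_gdmt(meds())
        assert not (st.beta_blocker or st.acei or st.arb or st.mra)

    def test_monotone_in_list_growth(self):
        base = meds(("Carvedilol 12.5 mg", "", "", True),
                    ("Lisinopril 10 mg", "ACE Inhibitors", "", True))
        before = co.classify_gdmt(base)
        grown = co.classify_gdmt(pd.concat(
            [base, meds(("Atorvastatin", "HMG-CoA Reductase Inhibitors", "",
                         True))], ignore_index=True))
        for f in ("beta_blocker", "acei", "arb", "mra"):
            assert getattr(grown, f) >= getattr(before, f)


class TestReferral:
    def test_no_referrals(self):
        assert co.referred_to_cardiology(pd.DataFrame(
            columns=["patient_id", "specialty", "referral_date"])) is False

    def test_cardiology_referral_case_insensitive(self):
        df = pd.DataFrame([{"patient_id": "X", "specialty": "Cardiology",
                            "referral_date": EXP}])
        assert co.referred_to_cardiology(df) is True

    def test_other_specialty_does_not_count(self):
        df = pd.DataFrame([{"patient_id": "X", "specialty": "endocrinology",
                            "referral_date": EXP}])
        assert co.referred_to_cardiology(df) is False


class TestCohortPhenotyping:
    def test_one_record_per_member_and_category_coverage(self, clean_members):
        members, truth = clean_members
        assert members["patient_id"].is_unique
        cats = set(zip(members["pre_assessed"], members["post_assessed"]))
        assert cats == {(False, False), (True, False), (False, True),
                        (True, True)}

    def test_flags_recover_generator_truth(self, clean_members):
        members, truth = clean_members
        assert (members["lvd"].values == truth["true_lvd"].values).all()
        assert (members["hfref"].values == truth["true_hfref"].values).all()
        assert (members["referred"].values == truth["referred"].values).all()
        assert (members["pre_assessed"].values == truth["pre_assessed"].values).all()
        assert (members["post_assessed"].values == truth["post_assessed"].values).all()

    def test_lvd_implies_post_assessed(self, clean_members):
        members, _ = clean_members
        assert members.loc[members["lvd"], "post_assessed"].all()

    def test_vectorized_hfref_agrees_with_per_patient_rule(self, clean_members,
                                                           clean_cohort,
                                                           hierarchy):
        members, _ = clean_members
        _, ds, _ = clean_cohort
        flags = co.cohort_hfref_flags(ds, set(members["patient_id"]), hierarchy,
                                      term.heart_failure_rule())
        assert (flags.loc[members["patient_id"]].values
                == members["hfref"].values).all()
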