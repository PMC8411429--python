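"""Cohort construction filters and attrition accounting."""

import datetime as dt

import pandas as pd
import pytest

import cardonc as co
from cardonc import terminology as term
from conftest import run_registry, within_3se

WINDOW = (dt.date(2011, 1, 1), dt.date(2017, 6, 30))


def tiny_dataset(episode_dates, imaging=(), problems=(), patient_ids=None):
    """Hand-built single-table dataset; one patient per episode date."""
    ids = patient_ids or [f"X{i}" for i in range(len(episode_dates))]
    return co.EHRDataset(
        patients=pd.DataFrame({
            "patient_id": ids,
            "birth_date": pd.Timestamp("1950-01-01"),
            "sex": "F", "alive": True,
        }),
        problems=pd.DataFrame(
            [{"patient_id": p, "code": c, "onset_date": pd.Timestamp(d) if d else pd.NaT}
             for p, c, d in problems],
            columns=["patient_id", "code", "onset_date"]),
        episodes=pd.DataFrame({
            "patient_id": ids,
            "drug_name": "Doxorubicin", "drug_class": "anthracycline",
            "start_date": [pd.Timestamp(d) for d in episode_dates],
        }),
        imaging=pd.DataFrame(
            [{"patient_id": p, "modality": "echo",
              "study_date": pd.Timestamp(d), "lvef": v}
             for p, d, v in imaging],
            columns=["patient_id", "modality", "study_date", "lvef"]),
        medications=pd.DataFrame(columns=[
            "patient_id", "drug_name", "pharm_class", "pharm_subclass",
            "active", "as_of_date"]),
        referrals=pd.DataFrame(columns=["patient_id", "specialty",
                                        "referral_date"]),
    )


@pytest.fixture(scope="module")
def criteria():
    return co.RegistryCriteria(cancer_rule=term.cancer_rule(),
                               treatment_window=WINDOW)


class TestCancerPopulation:
    def test_no_cancer_codes_gives_empty_population(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"],
                          problems=[("X0", term.HYPERTENSION, "2010-01-01")])
        assert co.build_cancer_population(ds, hierarchy, term.cancer_rule()) == set()

    def test_excluded_benign_brain_code_not_admitted(self, hierarchy):
        ds = tiny_dataset(["2012-05-01", "2012-06-01"], problems=[
            ("X0", "meningioma", "2010-01-01"),       # benign brain branch
            ("X1", "glioblastoma", "2010-01-01"),     # malignant brain
        ])
        pop = co.build_cancer_population(ds, hierarchy, term.cancer_rule())
        assert pop == {"X1"}

    def test_family_history_code_not_admitted(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"],
                          problems=[("X0", "fh-breast-ca", "2010-01-01")])
        assert co.build_cancer_population(ds, hierarchy, term.cancer_rule()) == set()

    def test_recovers_generator_truth(self, default_cohort, hierarchy):
        _, ds, truth = default_cohort
        pop = co.build_cancer_population(ds, hierarchy, term.cancer_rule())
        assert pop == set(truth.loc[truth["true_cancer"], "patient_id"])


class TestTreatmentWindow:
    def test_episode_on_window_start_included(self, criteria):
        ds = tiny_dataset(["2011-01-01"])
        assert co.build_registry({"X0"}, ds, criteria) == {"X0"}

    def test_episode_on_window_end_included(self, criteria):
        ds = tiny_dataset(["2017-06-30"])
        assert co.build_registry({"X0"}, ds, criteria) == {"X0"}

    def test_episode_one_day_after_window_excluded(self, criteria):
        ds = tiny_dataset(["2017-07-01"])
        assert co.build_registry({"X0"}, ds, criteria) == set()

    def test_registry_recovers_treated_truth(self, default_cohort, criteria,
                                             hierarchy):
        _, ds, truth = default_cohort
        pop = co.build_cancer_population(ds, hierarchy, term.cancer_rule())
        reg = co.build_registry(pop, ds, criteria)
        assert reg == set(truth.loc[truth["treated"], "patient_id"])


class TestBaselineExclusion:
    def test_no_baseline_dysfunction_keeps_everyone(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"],
                          imaging=[("X0", "2013-01-01", 35.0)])  # post, not baseline
        final, rep = co.exclude_baseline_dysfunction(
            {"X0"}, ds, hierarchy, term.heart_failure_rule())
        assert final == {"X0"} and rep.n_excluded_baseline == 0

    def test_low_lvef_before_exposure_excludes(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"],
                          imaging=[("X0", "2012-04-01", 35.0)])
        final, rep = co.exclude_baseline_dysfunction(
            {"X0"}, ds, hierarchy, term.heart_failure_rule())
        assert final == set() and rep.n_excluded_baseline == 1

    def test_low_lvef_on_exposure_date_is_post_not_baseline(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"],
                          imaging=[("X0", "2012-05-01", 35.0)])
        final, _ = co.exclude_baseline_dysfunction(
            {"X0"}, ds, hierarchy, term.heart_failure_rule())
        assert final == {"X0"}

    def test_hf_problem_before_exposure_excludes(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"], problems=[
            ("X0", term.SYSTOLIC_CHF, "2011-01-01")])
        final, _ = co.exclude_baseline_dysfunction(
            {"X0"}, ds, hierarchy, term.heart_failure_rule())
        assert final == set()

    def test_hf_problem_without_onset_date_is_kept(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"], problems=[
            ("X0", term.SYSTOLIC_CHF, None)])
        final, _ = co.exclude_baseline_dysfunction(
            {"X0"}, ds, hierarchy, term.heart_failure_rule())
        assert final == {"X0"}

    def test_patient_without_episode_raises(self, hierarchy):
        ds = tiny_dataset(["2012-05-01"])
        with pytest.raises(co.registry.MissingEpisodeError):
            co.exclude_baseline_dysfunction(
                {"X0", "ghost"}, ds, hierarchy, term.heart_failure_rule())

    def test_excluded_set_matches_generator_truth(self, default_cohort):
        cfg, ds, truth = default_cohort
        _, reg, final, rep = run_registry(cfg, ds)
        t = truth.set_index("patient_id")
        expected_excluded = {p for p in reg if t.loc[p, "baseline_dysfunction"]}
        assert reg - final == expected_excluded
        assert rep.n_excluded_baseline == len(expected_excluded)

    def test_excluded_count_near_372_at_registry_scale(self):
        cfg = co.CohortConfig(n_patients=8275, seed=17, cancer_prevalence=1.0,
                              treated_prob=1.0)
        ds, _ = co.generate(cfg)
        _, reg, final, rep = run_registry(cfg, ds)
        assert len(reg) == 8275
        se = (8275 * 0.045 * 0.955) ** 0.5
        assert abs(rep.n_excluded_baseline - 372) <= 3 * se


class TestAttritionReport:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conserved"):
            co.AttritionReport(n_cancer_population=10, n_treated_registry=8,
                               n_excluded_baseline=1, n_final=8)

    def test_registry_cannot_exceed_population(self):
        with pytest.raises(ValueError):
            co.AttritionReport(n_cancer_population=5, n_treated_registry=8,
                               n_excluded_baseline=0, n_final=8)

    def test_pipeline_report_is_conserved(self, default_cohort):
        cfg, ds, _ = default_cohort
        pop, reg, final, rep = run_registry(cfg, ds)
        assert rep.n_cancer_population == len(pop)
        assert rep.n_treated_registry == len(reg)
        assert rep.n_final == len(final)
        assert rep.n_final == rep.n_treated_registry - rep.n_excluded_baseline

    def test_filters_commute_with_window_restriction(self, hierarchy):
        # excluding baseline dysfunction then filtering to the window equals
        # filtering first and then excluding, on the treated population
        ds = tiny_dataset(
            ["2012-05-01", "2018-01-01", "2013-02-01"],
            imaging=[("X0", "2012-04-01", 30.0), ("X2", "2013-01-01", 30.0)])
        criteria = co.RegistryCriteria(cancer_rule=term.cancer_rule(),
                                       treatment_window=WINDOW)
        everyone = {"X0", "X1", "X2"}
        reg_first = co.build_registry(everyone, ds, criteria)
        final_a, _ = co.exclude_baseline_dysfunction(
            reg_first, ds, hierarchy, term.heart_failure_rule())
        final_b_all, _ = co.exclude_baseline_dysfunction(
            everyone, ds, hierarchy, term.heart_failure_rule())
        final_b = co.build_registry(final_b_all, ds, criteria)
        assert final_a == final_b
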