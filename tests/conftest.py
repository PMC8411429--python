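from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cardonc as co
from cardonc import terminology as term


@pytest.fixture(scope="session")
def hierarchy():
    return term.default_hierarchy()


@pytest.fixture(scope="session")
def toy_hierarchy():
    """root 'neoplasm' -> {malignant, benign}; malignant -> breast-ca."""
    return co.ConceptHierarchy([
        co.Concept("neoplasm", "Neoplasm"),
        co.Concept("malignant", "Malignant neoplasm", {"neoplasm"}),
        co.Concept("benign", "Benign neoplasm", {"neoplasm"}),
        co.Concept("breast-ca", "Breast cancer", {"malignant"}),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """A 5000-patient cohort under the default study conditions."""
    cfg = co.CohortConfig(n_patients=5000, seed=11)
    ds, truth = co.generate(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Same conditions but with a noiseless documentation channel and no
    background referrals, so detected outcomes coincide with true ones and
    configured referral/GDMT rates are recoverable."""
    cfg = co.CohortConfig(
        n_patients=5000, seed=13,
        hfref_doc_sensitivity=1.0, hfref_doc_specificity=1.0,
        referral_prob_background=0.0,
    )
    ds, truth = co.generate(cfg)
    return cfg, ds, truth


def run_registry(cfg, ds):
    h = term.default_hierarchy()
    pop = co.build_cancer_population(ds, h, term.cancer_rule())
    reg = co.build_registry(
        pop, ds,
        co.RegistryCriteria(cancer_rule=term.cancer_rule(),
                            treatment_window=cfg.treatment_window),
    )
    final, report = co.exclude_baseline_dysfunction(
        reg, ds, h, term.heart_failure_rule(), n_cancer_population=len(pop))
    return pop, reg, final, report


@pytest.fixture(scope="session")
def clean_members(clean_cohort):
    """Phenotyped members table for the clean-channel cohort."""
    cfg, ds, truth = clean_cohort
    _, _, final, _ = run_registry(cfg, ds)
    h = term.default_hierarchy()
    members = co.phenotype_members(ds, final, h, term.heart_failure_rule())
    return members, truth.set_index("patient_id").loc[members["patient_id"]]


def within_3se(observed_k: int, n: int, p: float) -> bool:
    """|k/n - p| <= 3 * sqrt(p (1-p) / n) — the binomial sampling bound."""
    se = np.sqrt(p * (1 - p) / n)
    return abs(observed_k / n - p) <= 3 * se + 1e-12
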