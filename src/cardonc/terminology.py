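"""Synthetic clinical terminology used throughout the package.

A small SNOMED-like polyhierarchy with the structural features the cohort
rules exercise: a malignant-neoplasm subtree, carcinoma in situ, a brain
neoplasm subtree whose benign branch must be excluded, family-history
"situation" codes that must never admit a patient, heart-failure and
cardiomyopathy concepts for outcome detection, and common comorbidities.

This is a synthetic stand-in vocabulary (real SNOMED CT content is
licensed); the codes for the anchor concepts reuse well-known SNOMED CT
identifiers so the rules read naturally, and everything below them is
invented.
"""

from __future__ import annotations

from .ontology import Concept, ConceptHierarchy, ValueSetRule, ValueSetTerm

__all__ = [
    "MALIGNANT_NEOPLASM",
    "CARCINOMA_IN_SITU",
    "NEOPLASM_OF_BRAIN",
    "BENIGN_BRAIN_NEOPLASM",
    "FAMILY_HISTORY",
    "SYSTOLIC_CHF",
    "DILATED_CARDIOMYOPATHY",
    "HYPERTENSION",
    "DIABETES",
    "default_hierarchy",
    "cancer_rule",
    "heart_failure_rule",
    "cancer_leaf_codes",
    "noncancer_codes",
]

# anchor codes (SNOMED CT identifiers for readability; subtree is synthetic)
MALIGNANT_NEOPLASM = "363346000"      # Malignant neoplastic disease (disorder)
CARCINOMA_IN_SITU = "109355002"       # Carcinoma in situ (disorder)
ADENO_IN_SITU_VILLOUS = "99741000119100"
NEOPLASM_OF_BRAIN = "126952004"       # Neoplasm of brain (disorder)
BENIGN_BRAIN_NEOPLASM = "92030004"    # Benign neoplasm of brain (disorder)
FAMILY_HISTORY = "416471007"          # Family history of clinical finding (situation)
SYSTOLIC_CHF = "417996009"            # Systolic heart failure (disorder)
DILATED_CARDIOMYOPATHY = "399020009"  # Congestive cardiomyopathy (disorder)
HEART_FAILURE = "84114007"
HYPERTENSION = "38341003"
DIABETES = "73211009"

_CONCEPTS: list[tuple[str, str, list[str]]] = [
    # (code, display, parents)
    ("root", "Clinical finding (finding)", []),
    ("neoplasm", "Neoplastic disease (disorder)", ["root"]),
    (MALIGNANT_NEOPLASM, "Malignant neoplastic disease (disorder)", ["neoplasm"]),
    ("breast-ca", "Malignant neoplasm of breast (disorder)", [MALIGNANT_NEOPLASM]),
    ("lung-ca", "Malignant neoplasm of lung (disorder)", [MALIGNANT_NEOPLASM]),
    ("renal-cell-ca", "Renal cell carcinoma (disorder)", [MALIGNANT_NEOPLASM]),
    ("lymphoma", "Malignant lymphoma (disorder)", [MALIGNANT_NEOPLASM]),
    ("leukemia", "Leukemia (disorder)", [MALIGNANT_NEOPLASM]),
    ("melanoma", "Malignant melanoma (disorder)", [MALIGNANT_NEOPLASM]),
    (CARCINOMA_IN_SITU, "Carcinoma in situ (disorder)", ["neoplasm"]),
    ("dcis", "Ductal carcinoma in situ of breast (disorder)",
     [CARCINOMA_IN_SITU, "breast-ca"]),  # polyhierarchy: two parents
    (ADENO_IN_SITU_VILLOUS,
     "Adenocarcinoma in situ in villous adenoma (disorder)", [CARCINOMA_IN_SITU]),
    (NEOPLASM_OF_BRAIN, "Neoplasm of brain (disorder)", ["neoplasm"]),
    ("malignant-brain-ca", "Malignant neoplasm of brain (disorder)",
     [NEOPLASM_OF_BRAIN, MALIGNANT_NEOPLASM]),
    ("glioblastoma", "Glioblastoma multiforme (disorder)", ["malignant-brain-ca"]),
    (BENIGN_BRAIN_NEOPLASM, "Benign neoplasm of brain (disorder)",
     [NEOPLASM_OF_BRAIN]),
    ("meningioma", "Benign meningioma of brain (disorder)", [BENIGN_BRAIN_NEOPLASM]),
    (FAMILY_HISTORY, "Family history of clinical finding (situation)", ["root"]),
    ("fh-breast-ca", "Family history of malignant neoplasm of breast (situation)",
     [FAMILY_HISTORY]),
    ("cardiac", "Heart disease (disorder)", ["root"]),
    (HEART_FAILURE, "Heart failure (disorder)", ["cardiac"]),
    (SYSTOLIC_CHF, "Systolic heart failure (disorder)", [HEART_FAILURE]),
    ("chronic-systolic-chf", "Chronic systolic congestive heart failure (disorder)",
     [SYSTOLIC_CHF]),
    ("cardiomyopathy", "Cardiomyopathy (disorder)", ["cardiac"]),
    (DILATED_CARDIOMYOPATHY, "Dilated cardiomyopathy (disorder)", ["cardiomyopathy"]),
    (HYPERTENSION, "Hypertensive disorder (disorder)", ["cardiac"]),
    (DIABETES, "Diabetes mellitus (disorder)", ["root"]),
    ("copd", "Chronic obstructive lung disease (disorder)", ["root"]),
]


def default_hierarchy() -> ConceptHierarchy:
    """The bundled synthetic concept hierarchy."""
    return ConceptHierarchy(
        Concept(code=c, display=d, parent_codes=frozenset(p))
        for c, d, p in _CONCEPTS
    )


def cancer_rule() -> ValueSetRule:
    """The broad cancer-population rule: malignant disease, carcinoma in
    situ, or brain neoplasm (with descendants), excluding benign brain
    neoplasms and family-history situation codes."""
    return ValueSetRule(
        name="cancer-population",
        includes=(
            ValueSetTerm(MALIGNANT_NEOPLASM),
            ValueSetTerm(CARCINOMA_IN_SITU),
            ValueSetTerm(ADENO_IN_SITU_VILLOUS),
            ValueSetTerm(NEOPLASM_OF_BRAIN),
        ),
        excludes=(
            ValueSetTerm(BENIGN_BRAIN_NEOPLASM),
            ValueSetTerm(FAMILY_HISTORY),
        ),
    )


def heart_failure_rule() -> ValueSetRule:
    """Systolic heart failure and/or dilated cardiomyopathy, with
    descendants — the Problem-List HFrEF phenotype."""
    return ValueSetRule(
        name="hfref-problem-list",
        includes=(
            ValueSetTerm(SYSTOLIC_CHF),
            ValueSetTerm(DILATED_CARDIOMYOPATHY),
        ),
    )


def cancer_leaf_codes() -> list[str]:
    """Codes the generator assigns to true-cancer patients (all match the
    cancer rule)."""
    return ["breast-ca", "lung-ca", "renal-cell-ca", "lymphoma", "leukemia",
            "melanoma", "dcis", "glioblastoma"]


def noncancer_codes() -> list[str]:
    """Codes that must NOT admit a patient to the cancer population,
    including the excluded benign-brain and family-history branches."""
    return [HYPERTENSION, DIABETES, "copd", "meningioma", "fh-breast-ca"]
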