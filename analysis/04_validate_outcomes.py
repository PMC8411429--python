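#!/usr/bin/env python
"""Chart-review validation of EHR-derived outcome flags.

Simulates the validation design on the synthetic cohort: for LVD, 50
flagged-positive and 50 flagged-negative charts among post-assessed
members; for HFrEF, 100 + 100 among all members.  Two simulated reviewers
read each chart (ground truth corrupted at small, outcome-specific error
rates), disagreements go to a third reviewer who reads the truth, and the
adjudicated labels are cross-tabulated against the registry flags to give
sensitivity/specificity/PPV/NPV with exact 95% CIs.

Writes results/validation.json, plus results/table2_reference.json: the
published-design reference arms back-derived from stratum sizes and
predictive values (PPV .80/NPV 1.00 on 50+50; PPV .81/NPV .96 on 100+100).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import cardonc as co

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def metric_dict(m: co.MetricEstimate) -> dict | None:
    if not m.defined:
        return None
    return {"pct": round(100 * m.estimate, 1),
            "ci": [round(100 * m.ci_low, 1), round(100 * m.ci_high, 1)]}


def perf_dict(cm: co.ConfusionMatrix) -> dict:
    perf = co.diagnostic_performance(cm)
    return {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "sensitivity": metric_dict(perf.sensitivity),
        "specificity": metric_dict(perf.specificity),
        "ppv": metric_dict(perf.ppv),
        "npv": metric_dict(perf.npv),
    }


def review_arm(flags: dict, truth: dict, n_pos: int, n_neg: int,
               reviewer_errors: tuple[float, float], seed: int,
               outcome: str) -> dict:
    sample = co.sample_for_review(flags, n_pos, n_neg, seed=seed,
                                  outcome=outcome)
    rng = np.random.default_rng(seed + 1)
    e_a, e_b = reviewer_errors
    a = {i: bool(truth[i]) ^ bool(rng.random() < e_a) for i in sample.ids}
    b = {i: bool(truth[i]) ^ bool(rng.random() < e_b) for i in sample.ids}
    agreement = co.percent_agreement(a, b)
    c = {i: bool(truth[i]) for i in sample.ids if a[i] != b[i]}
    labels = co.adjudicate(a, b, c)
    cm = co.confusion_from_review({i: flags[i] for i in sample.ids}, labels)
    return {
        "charts_reviewed": len(sample.ids),
        "interrater_agreement_pct": round(100 * agreement, 1),
        "n_adjudicated": len(c),
        **perf_dict(cm),
    }


def main() -> None:
    members = pd.read_csv(ROOT / "scratch" / "members.csv")
    truth = pd.read_csv(ROOT / "scratch" / "data" / "cohort" / "truth.csv")
    t = truth.set_index("patient_id")

    at_risk_lvd = members[members["post_assessed"]]
    lvd_flags = dict(zip(at_risk_lvd["patient_id"], at_risk_lvd["lvd"]))
    lvd_truth = t.loc[at_risk_lvd["patient_id"], "true_lvd"].to_dict()

    hf_flags = dict(zip(members["patient_id"], members["hfref"]))
    hf_truth = t.loc[members["patient_id"], "true_hfref"].to_dict()

    out = {
        "lvd": {
            "population_at_risk": len(lvd_flags),
            **review_arm(lvd_flags, lvd_truth, 50, 50, (0.01, 0.05),
                         SEED, "lvd"),
        },
        "hfref": {
            "population_at_risk": len(hf_flags),
            **review_arm(hf_flags, hf_truth, 100, 100, (0.03, 0.11),
                         SEED + 100, "hfref"),
        },
    }
    (ROOT / "results" / "validation.json").write_text(
        json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))

    reference = {
        "lvd": perf_dict(co.confusion_from_predictive_values(50, 50, 0.80, 1.00)),
        "hfref": perf_dict(co.confusion_from_predictive_values(100, 100, 0.81, 0.96)),
    }
    (ROOT / "results" / "table2_reference.json").write_text(
        json.dumps(reference, indent=2) + "\n")


if __name__ == "__main__":
    main()
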