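#!/usr/bin/env python
"""Registry report: screening rates, outcome prevalence, care gaps.

Produces the cohort-level surfaces from the phenotyped members table —
LVEF assessment rates by exposure class, LVD/HFrEF prevalence, the
missing-baseline worklist, and referral-stratified GDMT rates with
chi-squared comparisons — as results/report.json and results/report.md.
"""

import json
from pathlib import Path

import pandas as pd

import cardonc as co

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    members = pd.read_csv(ROOT / "scratch" / "members.csv")
    patients = pd.read_csv(ROOT / "scratch" / "data" / "cohort" / "patients.csv",
                           parse_dates=["birth_date"])
    cfg = co.CohortConfig.model_validate_json(
        (ROOT / "scratch" / "data" / "cohort" / "config.json").read_text())

    ages = (pd.Timestamp(cfg.extraction_date)
            - patients.set_index("patient_id").loc[members["patient_id"],
                                                   "birth_date"]).dt.days / 365.25
    med, q1, q3 = co.median_iqr(ages)

    assessment = co.assessment_summary(members)
    prevalence = co.prevalence_table(members)
    gaps = co.care_gap_report(members)

    report = {
        "n_members": len(members),
        "age_median_iqr": [round(med, 1), round(q1, 1), round(q3, 1)],
        "assessment": assessment.to_dict(orient="records"),
        "prevalence": prevalence.to_dict(orient="records"),
        "care_gaps": {
            "n_missing_baseline_lvef": len(gaps.missing_baseline_lvef),
            "n_outcome_patients": len(gaps.outcome_patients),
            "n_referred": gaps.n_referred,
            "gdmt_rates": gaps.gdmt_rates,
        },
    }
    (ROOT / "results" / "report.json").write_text(
        json.dumps(report, indent=2) + "\n")

    lines = [
        "# Cardio-oncology registry report (synthetic cohort)",
        "",
        f"Final analysis population: **{len(members)}** members; "
        f"median age {med:.0f} (IQR {q1:.0f}-{q3:.0f}).",
        "",
        "## LVEF assessment by exposure class",
        "",
        assessment.to_markdown(index=False),
        "",
        "## Post-treatment LVD and HFrEF prevalence",
        "",
        prevalence.to_markdown(index=False),
        "",
        "## Care gaps",
        "",
        f"- {len(gaps.missing_baseline_lvef)} members lack a baseline "
        f"(pre-exposure) LVEF assessment.",
        f"- {len(gaps.outcome_patients)} members have post-treatment LVD or "
        f"HFrEF; {gaps.n_referred} were referred to cardiology.",
        "",
        "GDMT prescription rates among outcome patients, by referral:",
        "",
    ]
    for cls, entry in gaps.gdmt_rates.items():
        r, nr = entry["referred"], entry["not_referred"]
        p = entry["p_value"]
        lines.append(
            f"- {cls}: referred {r['on_gdmt']}/{r['n']} ({r['pct']}%) vs "
            f"not referred {nr['on_gdmt']}/{nr['n']} ({nr['pct']}%), "
            f"p={p:.3g}" if p is not None else f"- {cls}: insufficient strata")
    (ROOT / "results" / "report.md").write_text("\n".join(lines) + "\n")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
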