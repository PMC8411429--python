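#!/usr/bin/env python
"""Build the nested cohorts and the attrition report.

Reads the generated cohort, expands the cancer value set over the bundled
concept hierarchy, applies the treatment-window filter and the baseline
LVD/heart-failure exclusion, and writes the registry membership
(scratch/registry.csv) plus results/attrition.json.
"""

import json
from pathlib import Path

import pandas as pd

import cardonc as co
from cardonc import terminology as term

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "data" / "cohort"
    ds = co.read_dataset(data)
    cfg = co.CohortConfig.model_validate_json((data / "config.json").read_text())

    h = term.default_hierarchy()
    pop = co.build_cancer_population(ds, h, term.cancer_rule())
    registry = co.build_registry(
        pop, ds,
        co.RegistryCriteria(cancer_rule=term.cancer_rule(),
                            treatment_window=cfg.treatment_window))
    final, report = co.exclude_baseline_dysfunction(
        registry, ds, h, term.heart_failure_rule(),
        n_cancer_population=len(pop))

    pd.Series(sorted(final), name="patient_id").to_csv(
        ROOT / "scratch" / "registry.csv", index=False)
    (ROOT / "results" / "attrition.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n")
    print("attrition:", report.to_dict())


if __name__ == "__main__":
    main()
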