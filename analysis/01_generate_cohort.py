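#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws a 10,000-patient population under the default study conditions
(cancer prevalence 0.92, treated fraction 0.90, Table-1-style exposure
mix and demographics), writes the six EHR tables and the ground-truth
table under scratch/data/, and a summary of the generated marginals to
results/cohort_summary.json.
"""

import json
from pathlib import Path

import cardonc as co

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    cfg = co.CohortConfig(seed=SEED)
    ds, truth = co.generate(cfg)

    out = ROOT / "scratch" / "data" / "cohort"
    co.write_dataset(ds, out)
    truth.to_csv(out / "truth.csv", index=False)
    (out / "config.json").write_text(cfg.model_dump_json(indent=2))

    treated = truth[truth["treated"]]
    summary = {
        "n_patients": int(len(truth)),
        "n_cancer": int(truth["true_cancer"].sum()),
        "n_treated": int(len(treated)),
        "exposure_fractions": {
            cls: round(float(treated[cls].mean()), 4)
            for cls in ("anthracycline", "her2", "tki", "ici")
        },
        "pre_assessed_frac": round(float(treated["pre_assessed"].mean()), 4),
        "post_assessed_frac": round(float(treated["post_assessed"].mean()), 4),
        "true_lvd_frac_of_treated": round(float(treated["true_lvd"].mean()), 4),
        "true_hfref_frac_of_treated": round(float(treated["true_hfref"].mean()), 4),
        "table_rows": {k: int(len(v)) for k, v in ds.tables().items()},
    }
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    (res / "cohort_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote {out} ({summary['n_patients']} patients, "
          f"{summary['n_treated']} treated)")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
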