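#!/usr/bin/env python
"""Derive per-member care measures.

Phenotypes every final-registry member (exposure profile, pre/post LVEF
assessment, LVD and HFrEF outcome flags, GDMT status, cardiology
referral), writes the members table to scratch/members.csv and headline
counts to results/phenotype_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

import cardonc as co
from cardonc import terminology as term

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ds = co.read_dataset(ROOT / "scratch" / "data" / "cohort")
    members_ids = set(pd.read_csv(ROOT / "scratch" / "registry.csv")["patient_id"])
    h = term.default_hierarchy()
    members = co.phenotype_members(ds, members_ids, h, term.heart_failure_rule())
    members.to_csv(ROOT / "scratch" / "members.csv", index=False)

    n = len(members)
    summary = {
        "n_members": n,
        "pre_assessed": {"n": int(members["pre_assessed"].sum()),
                         "pct": co.proportion_pct(int(members["pre_assessed"].sum()), n, 2)},
        "post_assessed": {"n": int(members["post_assessed"].sum()),
                          "pct": co.proportion_pct(int(members["post_assessed"].sum()), n, 2)},
        "lvd": int(members["lvd"].sum()),
        "hfref": int(members["hfref"].sum()),
        "outcome_referred": int(
            (members["referred"] & (members["lvd"] | members["hfref"])).sum()),
    }
    (ROOT / "results" / "phenotype_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
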