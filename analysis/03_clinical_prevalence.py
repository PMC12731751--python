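#!/usr/bin/env python
"""Recompute the cohort's biosignature prevalence table from the packaged fixtures.

Counts carriers of each biosignature within the metastatic (n=11) and
high-risk (n=7) subgroups of the 55-patient cohort fixture and reports the
prevalence percentages (half-up, one decimal).  Writes
results/clinical_prevalence.csv.
"""

from pathlib import Path

import phylometab as pm

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    table1 = pm.load_table1_fixture()
    carriage, records = pm.load_table2_fixture()
    t = table1.table
    groups = {
        "metastatic": list(t.loc[t["metastasis"], "patient_id"]),
        "high_risk": list(t.loc[t["risk"] == "high", "patient_id"]),
    }
    rep = pm.biosignature_prevalence_report(carriage, table1, groups)
    rep = rep[rep["carriers"] > 0].reset_index(drop=True)
    OUT.mkdir(exist_ok=True)
    rep.to_csv(OUT / "clinical_prevalence.csv", index=False)
    print(rep.to_string(index=False))
    print(f"\nADT prevalence: {pm.prevalence(int(t['adt'].sum()), len(t))}% of {len(t)} patients")
    print(f"written to {OUT / 'clinical_prevalence.csv'}")


if __name__ == "__main__":
    main()
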