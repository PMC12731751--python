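#!/usr/bin/env python
"""Putative annotation of the simulated cohort's features.

Builds a small local compound table (monoisotopic masses of metabolites of
interest in this cohort) and matches the simulated feature m/z values at
5 ppm across H/Na/K adducts.  With random m/z values, hits are chance
matches — the point here is the matching machinery, and the hit count is a
useful feel for the false-candidate rate of 5 ppm windows.  Writes
results/annotation.csv.  Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import phylometab as pm
from phylometab.annotation import CompoundRecord

BASE = Path(__file__).resolve().parents[1] / "results"

COMPOUNDS = [
    CompoundRecord("D-tryptophan", 204.089878, "C11H12N2O2"),
    CompoundRecord("hypoxanthine", 136.038511, "C5H4N4O"),
    CompoundRecord("bilirubin", 584.263488, "C33H36N4O6"),
    CompoundRecord("phthalic acid", 166.026609, "C8H6O4"),
    CompoundRecord("carbamic acid", 61.016378, "CH3NO2"),
    CompoundRecord("phosphoric acid", 97.976896, "H3PO4"),
    CompoundRecord("2-methylglutaric acid", 146.057909, "C6H10O4"),
    CompoundRecord("tetrahydroisoquinoline", 133.089149, "C9H11N"),
]


def main():
    table = pm.read_feature_table(BASE / "cohort" / "feature_table.csv", ion_mode="positive")
    hits = pm.match_features(table, COMPOUNDS, tol_ppm=5.0)
    hits.to_csv(BASE / "annotation.csv", index=False)
    print(f"{len(hits)} candidate annotations among {table.n_features} features "
          f"x {len(COMPOUNDS)} compounds x 3 positive-mode adducts at 5 ppm")
    if len(hits):
        print(hits.to_string(index=False))


if __name__ == "__main__":
    main()
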