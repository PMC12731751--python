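"""Prevalence arithmetic, cohort fixtures, and clade-covariate association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylometab as pm
from phylometab.clinical import (
    AssociationResult,
    ClinicalTable,
    _fisher_midp,
    biosignature_prevalence_report,
    clade_covariate_association,
    clade_covariate_matrix,
    prevalence,
)


class TestPrevalence:
    @pytest.mark.parametrize(
        "carriers, size, expected",
        [(7, 11, 63.6), (5, 11, 45.5), (13, 55, 23.6), (0, 7, 0.0), (7, 7, 100.0),
         (6, 7, 85.7), (5, 7, 71.4), (1, 3, 33.3), (1, 8, 12.5)],
    )
    def test_half_up_rounding(self, carriers, size, expected):
        assert prevalence(carriers, size) == expected

    def test_errors(self):
        with pytest.raises(ValueError):
            prevalence(1, 0)
        with pytest.raises(ValueError):
            prevalence(5, 4)
        with pytest.raises(ValueError):
            prevalence(-1, 4)


class TestPrevalenceReport:
    def test_matches_brute_force_recount(self, rng, table1):
        patients = table1.patients
        carriage = pd.DataFrame(
            rng.random((55, 6)) < 0.4,
            index=pd.Index(patients, name="patient_id"),
            columns=[f"b{i}" for i in range(6)],
        )
        groups = {
            "g1": list(rng.choice(patients, 12, replace=False)),
            "g2": list(rng.choice(patients, 30, replace=False)),
        }
        rep = biosignature_prevalence_report(carriage, table1, groups)
        for _, row in rep.iterrows():
            manual = sum(bool(carriage.loc[p, row["biosignature"]]) for p in groups[row["group"]])
            assert row["carriers"] == manual
            assert row["prevalence_pct"] == prevalence(manual, len(groups[row["group"]]))

    def test_all_carriers_is_100(self, table1):
        ids = table1.patients[:5]
        carriage = pd.DataFrame({"b": True}, index=pd.Index(table1.patients, name="patient_id"))
        rep = biosignature_prevalence_report(carriage, table1, {"g": ids})
        assert rep.iloc[0]["prevalence_pct"] == 100.0

    def test_unresolvable_patient_listed(self, table1):
        carriage = pd.DataFrame({"b": True}, index=pd.Index(table1.patients, name="patient_id"))
        with pytest.raises(KeyError, match="GHOST"):
            biosignature_prevalence_report(carriage, table1, {"g": ["GHOST"]})

    def test_row_permutation_invariant(self, rng, table1):
        carriage = pd.DataFrame(
            rng.random((55, 3)) < 0.5,
            index=pd.Index(table1.patients, name="patient_id"),
            columns=list("xyz"),
        )
        groups = {"g": table1.patients[10:30]}
        r1 = biosignature_prevalence_report(carriage, table1, groups)
        perm = carriage.iloc[rng.permutation(55)]
        shuffled = ClinicalTable(table1.table.iloc[rng.permutation(55)].reset_index(drop=True))
        r2 = biosignature_prevalence_report(perm, shuffled, groups)
        assert r1.equals(r2)


class TestTable1Fixture:
    def test_marginal_counts(self, table1):
        t = table1.table
        assert len(t) == 55
        assert t["risk"].value_counts().to_dict() == {"intermediate": 34, "low": 14, "high": 7}
        assert t["race"].value_counts().to_dict() == {"White": 37, "Black": 15, "Other": 3}
        assert t["t_stage"].value_counts().to_dict() == {"T1c": 40, "T2a-b": 12, "T2c": 3}
        assert t["gleason"].value_counts().to_dict() == {
            "7(3+4;4+3)": 30, "6(3+3)": 20, "8(3+5;4+4)": 4, "9(4+5;5+4)": 1
        }
        assert int(t["adt"].sum()) == 13
        assert prevalence(int(t["adt"].sum()), 55) == 23.6

    def test_metastatic_subgroup(self, table1):
        t = table1.table
        met = t[t["metastasis"]]
        assert len(met) == 11
        assert met["risk"].value_counts().to_dict() == {"intermediate": 6, "low": 3, "high": 2}
        assert int(met["adt"].sum()) == 4

    def test_age_and_psa_ranges(self, table1):
        t = table1.table
        assert (t["age"].min(), int(t["age"].median()), t["age"].max()) == (52, 68, 90)
        assert t["psa_pre"].min() == 1.9 and t["psa_pre"].max() == 25.6
        assert t["psa_pre"].median() == 8.1

    def test_protocol_margins(self, table1):
        counts = table1.table["protocol"].value_counts()
        assert sorted(counts.to_list(), reverse=True) == [36, 9, 6, 4]


class TestTable2Fixture:
    def test_printed_prevalences_reproduced(self, table1, table2):
        carriage, records = table2
        t = table1.table
        groups = {
            "metastatic": list(t.loc[t["metastasis"], "patient_id"]),
            "high_risk": list(t.loc[t["risk"] == "high", "patient_id"]),
        }
        rep = biosignature_prevalence_report(carriage, table1, groups)
        got = rep.set_index(["group", "biosignature"])["prevalence_pct"]
        assert got[("metastatic", "d_tryptophan_pre")] == 63.6
        assert got[("metastatic", "hypoxanthine_pre")] == 100.0
        assert got[("metastatic", "phosphoric_acid_post")] == 45.5
        assert got[("metastatic", "mz_416.91035669_post")] == 63.6
        for marker in ("bilirubin_post", "pc_post", "phthalic_acid_post",
                       "benzoylphosphoadenosine_post"):
            assert got[("metastatic", marker)] == 100.0
        assert got[("high_risk", "carbamic_acid_post")] == 85.7
        assert got[("high_risk", "phosphoric_acid_post")] == 71.4
        for marker in ("hypoxanthine_pre", "mz_159.0093618_pre", "mz_120.0038_pre",
                       "mz_380.772_pre", "mz_197.08_pre"):
            assert got[("high_risk", marker)] == 100.0

    def test_records_carry_printed_counts(self, table2):
        _, records = table2
        rec = records.set_index(["group", "biosignature"])
        assert rec.loc[("metastatic", "d_tryptophan"), "prevalence_pct"] == 63.6
        assert rec.loc[("high_risk", "carbamic_acid"), "prevalence_pct"] == 85.7
        assert rec.loc[("all_patients", "adt"), "prevalence_pct"] == 23.6


class TestCovariateMatrix:
    def test_per_clade_medians(self, table1):
        t = table1.table
        ids = t["patient_id"].tolist()[:4]
        clin = ClinicalTable(
            t.iloc[:4].assign(psa_pre=[4.0, 6.0, 10.0, 12.0]).reset_index(drop=True)
        )
        assignment = {ids[0]: "c1", ids[1]: "c1", ids[2]: "c2", ids[3]: "c2"}
        _, summ = clade_covariate_matrix(assignment, clin, ["psa_pre"])
        med = summ.set_index("clade")["median"]
        assert med["c1"] == 5.0 and med["c2"] == 11.0

    def test_single_clade_equals_cohort_summary(self, table1):
        assignment = {p: "all" for p in table1.patients}
        _, summ = clade_covariate_matrix(assignment, table1, ["psa_pre"])
        assert summ.iloc[0]["median"] == table1.table["psa_pre"].median()

    def test_missing_cells_flagged_not_dropped(self, table1):
        t = table1.table.copy()
        t.loc[0, "psa_pre"] = np.nan
        clin = ClinicalTable(t.fillna({"psa_pre": np.nan}))
        assignment = {p: "all" for p in clin.patients}
        render, _ = clade_covariate_matrix(assignment, clin, ["psa_pre"])
        assert np.isnan(render.iloc[0]["psa_pre"])
        assert len(render) == 55

    def test_render_matrix_scaled_to_unit_interval(self, table1):
        assignment = {p: ("a" if i < 30 else "b") for i, p in enumerate(table1.patients)}
        render, _ = clade_covariate_matrix(assignment, table1, ["psa_pre", "age", "risk"])
        vals = render[["psa_pre", "age", "risk"]].to_numpy(float)
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1

    def test_independent_covariate_tracks_global_rate(self):
        # ADT assigned independently of clades: per-clade proportion within
        # 3 binomial standard errors of the global rate at n large
        cfg = pm.CohortConfig(n_outgroup=4, n_patients=400, n_noise_features=1,
                              clade_plan=(), seed=5)
        co = pm.generate_cohort(cfg)
        t = co.clinical.table
        p_global = t["adt"].mean()
        half = len(t) // 2
        for block in (t.iloc[:half], t.iloc[half:]):
            p_clade = block["adt"].mean()
            se = np.sqrt(p_global * (1 - p_global) / len(block))
            assert abs(p_clade - p_global) <= 3 * se


def exact_fisher_two_sided(table):
    """Independent oracle: enumerate the hypergeometric support directly."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = stats.hypergeom(n, r1, c1)
    support = range(max(0, c1 - (n - r1)), min(c1, r1) + 1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestAssociation:
    def test_perfect_separation_p_value(self, table1):
        ids = table1.patients[:10]
        t = table1.table.iloc[:10].copy()
        t["flag"] = [True] * 5 + [False] * 5
        clin = ClinicalTable(t.reset_index(drop=True))
        assignment = {p: ("A" if i < 5 else "B") for i, p in enumerate(ids)}
        r = clade_covariate_association(assignment, clin, "flag")
        assert r.test == "fisher_exact"
        assert r.p_value == pytest.approx(exact_fisher_two_sided(np.array([[5, 0], [0, 5]])))
        assert r.p_value == pytest.approx(0.00793650, rel=1e-4)

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        for _ in range(20):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            _, p = stats.fisher_exact(tab)
            assert p == pytest.approx(exact_fisher_two_sided(tab), rel=1e-9)

    def test_midp_no_larger_than_exact(self, rng):
        for _ in range(20):
            tab = rng.integers(1, 8, size=(2, 2))
            _, p = stats.fisher_exact(tab)
            assert _fisher_midp(tab) <= p + 1e-12

    def test_degenerate_table_flagged(self, table1):
        assignment = {p: "A" for p in table1.patients}  # single clade
        r = clade_covariate_association(assignment, table1, "adt")
        assert r.degenerate and r.p_value is None

    def test_chi2_for_multilevel_covariate(self, table1):
        assignment = {p: ("A" if i % 2 else "B") for i, p in enumerate(table1.patients)}
        r = clade_covariate_association(assignment, table1, "risk")
        assert r.test == "chi2" and 0 <= r.p_value <= 1
        assert r.contingency.shape == (2, 3)
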