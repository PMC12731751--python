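"""Clinical covariates, biosignature prevalence, and clade-covariate association.

This module joins cladogram membership and biosignature carriage with the
per-patient clinical table of the prostate-cancer SBRT/IMRT cohort (n = 55):
age, race, PSA before/after radiotherapy, androgen deprivation therapy (ADT),
D'Amico risk group, Gleason score, T-stage, metastasis and treatment
protocol.  It also packages two programmatically constructed fixtures that
reproduce the cohort's printed marginal counts and biosignature carriage
rates; per-patient values that were never printed (individual ages, PSA
values, cross-tabulations) are synthesized deterministically within the
printed ranges and are labelled synthetic — only the printed margins are
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

RISK_LEVELS = ("low", "intermediate", "high")
PROTOCOLS = ("SBRT_35Gy_5fx", "SBRT_36.25Gy_5fx", "SBRT_IMRT_19.5_45Gy", "SBRT_IMRT_19.5_50.4Gy")


@dataclass
class ClinicalTable:
    """One row per patient; see module docstring for the covariate set."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = ["patient_id", "age", "race", "psa_pre", "psa_post", "adt",
                    "risk", "gleason", "t_stage", "metastasis", "protocol"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if t["patient_id"].duplicated().any():
            raise ValueError("clinical table must have one row per patient")
        if (t["psa_pre"] < 0).any() or (t["psa_post"] < 0).any():
            raise ValueError("PSA values must be >= 0")
        bad = set(t["risk"]) - set(RISK_LEVELS)
        if bad:
            raise ValueError(f"unknown risk levels: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def patients(self) -> list[str]:
        return list(self.table["patient_id"])

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("patient_id")


def prevalence(carriers: int, group_size: int) -> float:
    """Percentage of carriers in a group, rounded half-up to one decimal.

    7 of 11 -> 63.6; 5 of 11 -> 45.5; 13 of 55 -> 23.6.
    """
    if group_size <= 0:
        raise ValueError("group_size must be > 0")
    if not 0 <= carriers <= group_size:
        raise ValueError(f"carriers ({carriers}) must lie in [0, group_size={group_size}]")
    pct = Decimal(100 * carriers) / Decimal(group_size)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _resolve_groups(grouping, clinical: ClinicalTable) -> dict[str, list[str]]:
    if isinstance(grouping, str):
        col = clinical.table[grouping]
        return {
            f"{grouping}={level}": list(clinical.table.loc[col == level, "patient_id"])
            for level in pd.unique(col)
        }
    return {name: list(ids) for name, ids in dict(grouping).items()}


def biosignature_prevalence_report(
    carriage,
    clinical: ClinicalTable,
    grouping,
    characters=None,
) -> pd.DataFrame:
    """Carrier counts and prevalence per (group, biosignature).

    ``carriage`` is a patient-indexed boolean/0-1 DataFrame (one column per
    biosignature); missing cells count as non-carrier.  ``grouping`` is either
    a clinical column name (one group per level) or a mapping
    ``{group name: [patient ids]}``.
    """
    if hasattr(carriage, "states"):
        carriage = carriage.states
    groups = _resolve_groups(grouping, clinical)
    known = set(clinical.patients)
    chars = list(characters) if characters is not None else list(carriage.columns)
    rows = []
    for name, ids in groups.items():
        if not ids:
            raise ValueError(f"group {name!r} is empty")
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise KeyError(f"group {name!r}: patient ids not in clinical table: {unknown}")
        missing_rows = [i for i in ids if i not in carriage.index]
        if missing_rows:
            raise KeyError(f"group {name!r}: patient ids not in carriage matrix: {missing_rows}")
        sub = carriage.loc[ids, chars]
        counts = sub.fillna(0).astype(bool).sum(axis=0)
        for char in chars:
            c = int(counts[char])
            rows.append(
                {
                    "group": name,
                    "group_size": len(ids),
                    "biosignature": char,
                    "carriers": c,
                    "prevalence_pct": prevalence(c, len(ids)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clade x covariate


def clade_covariate_matrix(assignment, clinical: ClinicalTable, covariates: list[str]):
    """Patient x covariate matrix scaled for gradient rendering, plus summaries.

    ``assignment`` maps patient_id -> clade label (dict or Series); clade
    order follows first appearance, patients keep the assignment order.
    Numeric covariates are min-max scaled per covariate in the render matrix
    (raw values are kept in the summaries); categorical covariates are mapped
    to evenly spaced codes.  Missing covariate cells stay NaN (flagged, not
    dropped).  Summaries give median/IQR for numeric and level proportions
    for categorical covariates, per clade.
    """
    assignment = pd.Series(dict(assignment)) if not isinstance(assignment, pd.Series) else assignment
    idx = clinical.indexed()
    unknown = [p for p in assignment.index if p not in idx.index]
    if unknown:
        raise KeyError(f"patients without clinical rows: {unknown}")
    sub = idx.loc[assignment.index, covariates]
    render = pd.DataFrame(index=sub.index, columns=covariates, dtype=float)
    for cov in covariates:
        col = sub[cov]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            lo, hi = col.min(), col.max()
            render[cov] = 0.5 if hi == lo else (col - lo) / (hi - lo)
        else:
            cats = pd.Categorical(col)
            k = len(cats.categories)
            codes = pd.Series(cats.codes, index=col.index).replace(-1, np.nan)
            render[cov] = codes if k <= 1 else codes / (k - 1)
    render.insert(0, "clade", assignment)

    rows = []
    for clade in pd.unique(assignment):
        members = assignment.index[assignment == clade]
        for cov in covariates:
            col = idx.loc[members, cov]
            if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
                rows.append(
                    {
                        "clade": clade,
                        "covariate": cov,
                        "level": None,
                        "n": int(col.notna().sum()),
                        "median": float(col.median()),
                        "iqr_lo": float(col.quantile(0.25)),
                        "iqr_hi": float(col.quantile(0.75)),
                        "proportion": None,
                    }
                )
            else:
                for level, cnt in col.value_counts(dropna=False).items():
                    rows.append(
                        {
                            "clade": clade,
                            "covariate": cov,
                            "level": level,
                            "n": int(cnt),
                            "median": None,
                            "iqr_lo": None,
                            "iqr_hi": None,
                            "proportion": float(cnt) / len(members),
                        }
                    )
    return render, pd.DataFrame(rows)


@dataclass
class AssociationResult:
    contingency: pd.DataFrame
    p_value: float | None
    test: str
    degenerate: bool
    n_tests_context: int = 1  # caller-visible count for multiplicity correction


def _fisher_midp(table: np.ndarray) -> float:
    """Two-sided mid-p Fisher test for a 2x2 table via hypergeometric enumeration."""
    a = table[0, 0]
    r1, r2 = table[0].sum(), table[1].sum()
    c1 = table[:, 0].sum()
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    eps = p_obs * 1e-9
    return float(pmf[pmf < p_obs - eps].sum() + 0.5 * pmf[np.abs(pmf - p_obs) <= eps].sum())


def clade_covariate_association(
    assignment, clinical: ClinicalTable, covariate: str, p_method: str = "auto"
) -> AssociationResult:
    """Contingency table of clade membership vs a categorical covariate.

    2x2 tables use Fisher's exact test (``p_method``: "fisher" two-sided,
    "fisher_midp" for calibration studies); larger tables use the chi-square
    test.  Degenerate tables (fewer than two non-empty rows or columns) are
    flagged and carry no p-value.  No multiplicity correction is applied.
    """
    assignment = pd.Series(dict(assignment)) if not isinstance(assignment, pd.Series) else assignment
    idx = clinical.indexed()
    col = idx.loc[assignment.index, covariate]
    tab = pd.crosstab(assignment, col)
    tab.index.name, tab.columns.name = "clade", covariate
    nonempty = (tab.sum(axis=1) > 0).sum(), (tab.sum(axis=0) > 0).sum()
    if tab.shape[0] < 2 or tab.shape[1] < 2 or min(nonempty) < 2:
        return AssociationResult(tab, None, "none", degenerate=True)
    arr = tab.to_numpy()
    if arr.shape == (2, 2):
        if p_method in ("auto", "fisher"):
            _, p = stats.fisher_exact(arr, alternative="two-sided")
            test = "fisher_exact"
        elif p_method == "fisher_midp":
            p, test = _fisher_midp(arr), "fisher_midp"
        elif p_method == "chi2":
            p, test = stats.chi2_contingency(arr)[1], "chi2"
        else:
            raise ValueError(f"unknown p_method {p_method!r}")
    else:
        p, test = stats.chi2_contingency(arr)[1], "chi2"
    return AssociationResult(tab, float(p), test, degenerate=False)


# ---------------------------------------------------------------------------
# packaged cohort fixtures (synthetic at patient level; printed margins exact)


def _patient_ids(n: int = 55) -> list[str]:
    return [f"P{i+1:02d}" for i in range(n)]


# index sets used by both fixtures (0-based patient indexes)
_LOW = list(range(0, 14))
_INTERMEDIATE = list(range(14, 48))
_HIGH = list(range(48, 55))
_METASTATIC = [0, 1, 2, 14, 15, 16, 17, 18, 19, 48, 49]   # 3 low, 6 intermediate, 2 high
_ADT = [14, 15, 16, 48, 20, 21, 22, 23, 24, 25, 26, 27, 50]  # 13; 4 metastatic


def load_table1_fixture() -> ClinicalTable:
    """Synthetic 55-patient cohort reproducing the printed marginal counts.

    Margins: race 15/37/3 (Black/White/Other); T-stage 40/12/3; Gleason
    20/30/4/1; D'Amico risk 14/34/7; ADT 13 yes / 42 no; protocol 6/36/9/4;
    metastasis in 11 patients (3 low, 6 intermediate, 2 high risk; 4 with
    ADT, one of whom is an intermediate-risk SBRT/IMRT patient).  Age spans
    52-90 with median 68; pre-treatment PSA spans 1.9-25.6 ng/mL with median
    8.1.  Per-patient values and cross-tabulations beyond these constraints
    are synthetic.
    """
    n = 55
    ids = _patient_ids(n)
    rng = np.random.default_rng(20081205)  # fixed: fixture is deterministic

    risk = np.empty(n, dtype=object)
    risk[_LOW], risk[_INTERMEDIATE], risk[_HIGH] = "low", "intermediate", "high"
    metastasis = np.zeros(n, dtype=bool)
    metastasis[_METASTATIC] = True
    adt = np.zeros(n, dtype=bool)
    adt[_ADT] = True

    protocol = np.empty(n, dtype=object)
    protocol[0:6] = PROTOCOLS[0]
    protocol[[14] + list(range(44, 52))] = PROTOCOLS[2]
    protocol[[43, 52, 53, 54]] = PROTOCOLS[3]
    protocol[[i for i in range(n) if protocol[i] is None]] = PROTOCOLS[1]

    def spread(counts_levels):
        out = []
        for level, cnt in counts_levels:
            out.extend([level] * cnt)
        return np.array(out, dtype=object)[rng.permutation(n)]

    race = spread([("Black", 15), ("White", 37), ("Other", 3)])
    t_stage = spread([("T1c", 40), ("T2a-b", 12), ("T2c", 3)])
    gleason = spread([("6(3+3)", 20), ("7(3+4;4+3)", 30), ("8(3+5;4+4)", 4), ("9(4+5;5+4)", 1)])

    ages_sorted = np.concatenate(
        [np.round(np.linspace(52, 68, 28)), np.round(np.linspace(68.8, 90, 27))]
    ).astype(int)
    age = ages_sorted[rng.permutation(n)]
    psa_sorted = np.concatenate(
        [np.round(np.linspace(1.9, 8.1, 28), 1), np.round(np.linspace(8.75, 25.6, 27), 1)]
    )
    psa_pre = psa_sorted[rng.permutation(n)]
    psa_post = np.round(psa_pre * 0.2, 2)
    testosterone = np.where(adt, 25.0 + 5.0 * (np.arange(n) % 30), 300.0 + 7.0 * (np.arange(n) % 43))

    return ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "age": age,
                "race": race,
                "psa_pre": psa_pre,
                "psa_post": psa_post,
                "testosterone": testosterone,
                "adt": adt,
                "risk": risk,
                "gleason": gleason,
                "t_stage": t_stage,
                "metastasis": metastasis,
                "protocol": protocol,
            }
        )
    )


def load_table2_fixture():
    """Synthetic patient-level biosignature carriage plus the printed records.

    Returns ``(carriage, records)``.  ``carriage`` is a boolean patient x
    biosignature DataFrame (column names suffixed ``_pre`` / ``_post`` for the
    sampling phase) built so that group-level recounts reproduce the printed
    biosignature figures: hypoxanthine in 11/11 metastatic and 7/7 high-risk
    patients pre-RT; D-tryptophan 7/11 metastatic pre-RT; bilirubin, PC,
    phthalic acid and 5'-benzoylphosphoadenosine in 11/11 metastatic post-RT;
    phosphoric acid 5/11 metastatic and 5/7 high-risk post-RT; carbamic acid
    6/7 high-risk post-RT; m/z 416.91035669 7/11 metastatic post-RT; the five
    pre-RT high-risk markers in 7/7 high-risk patients.  ``records`` stores
    the printed subgroup counts verbatim (including the internally
    inconsistent 6-of-7 / 5-of-7 entries), unreconciled.
    """
    ids = _patient_ids()
    idx = {i: ids[i] for i in range(55)}
    met = [idx[i] for i in _METASTATIC]
    high = [idx[i] for i in _HIGH]

    cols = [
        "hypoxanthine_pre", "d_tryptophan_pre", "tetrahydroisoquinoline_pre",
        "dihydrosanguinarine_pre", "methylglutaric_acid_pre",
        "mz_159.0093618_pre", "mz_120.0038_pre", "mz_380.772_pre", "mz_197.08_pre",
        "bilirubin_post", "pc_post", "phthalic_acid_post",
        "benzoylphosphoadenosine_post", "carbamic_acid_post", "phosphoric_acid_post",
        "mz_416.91035669_post", "mz_632.2994_post", "mz_312.0288_post",
        "mz_262.2532_post", "mz_184.0735_post", "mz_723.5443_post", "mz_701.561_post",
    ]
    carriage = pd.DataFrame(False, index=pd.Index(ids, name="patient_id"), columns=cols)

    def mark(col, members):
        carriage.loc[members, col] = True

    mark("hypoxanthine_pre", sorted(set(met) | set(high)))
    for c in ("mz_159.0093618_pre", "mz_120.0038_pre", "mz_380.772_pre", "mz_197.08_pre"):
        mark(c, high)
    mark("d_tryptophan_pre", [idx[i] for i in [0, 1, 2, 14, 15, 16, 17]])
    mark("tetrahydroisoquinoline_pre", [idx[49]])                 # high risk, no ADT
    mark("dihydrosanguinarine_pre", [idx[i] for i in [0, 1, 2, 17]])   # none with ADT
    mark("methylglutaric_acid_pre", [idx[i] for i in [14, 18, 19]])    # one with ADT

    for c in ("bilirubin_post", "pc_post", "benzoylphosphoadenosine_post"):
        mark(c, met)
    mark("phthalic_acid_post", sorted(set(met) | set(high)))      # all high-risk carry it
    mark("carbamic_acid_post", [idx[i] for i in range(48, 54)])   # 6 of 7 high risk
    mark("phosphoric_acid_post", [idx[i] for i in [14, 15, 16, 48, 49, 50, 51, 52]])
    mark("mz_416.91035669_post", [idx[i] for i in [0, 1, 2, 14, 15, 48, 49]])
    for c in ("mz_632.2994_post", "mz_312.0288_post", "mz_262.2532_post",
              "mz_184.0735_post", "mz_723.5443_post", "mz_701.561_post"):
        mark(c, [idx[48], idx[49]])  # high-risk AND metastatic patients

    records = pd.DataFrame(
        [
            ("metastatic", "pre_RT", "hypoxanthine", 11, 11),
            ("metastatic", "pre_RT", "d_tryptophan", 7, 11),
            ("metastatic", "post_RT", "bilirubin", 11, 11),
            ("metastatic", "post_RT", "pc", 11, 11),
            ("metastatic", "post_RT", "phthalic_acid", 11, 11),
            ("metastatic", "post_RT", "benzoylphosphoadenosine", 11, 11),
            ("metastatic", "post_RT", "phosphoric_acid", 5, 11),
            ("metastatic", "post_RT", "mz_416.91035669", 7, 11),
            ("high_risk", "pre_RT", "hypoxanthine", 7, 7),
            ("high_risk", "post_RT", "carbamic_acid", 6, 7),
            ("high_risk", "post_RT", "phosphoric_acid", 5, 7),
            ("all_patients", "", "adt", 13, 55),
        ],
        columns=["group", "phase", "biosignature", "carriers", "group_size"],
    )
    records["prevalence_pct"] = [
        prevalence(c, g) for c, g in zip(records["carriers"], records["group_size"])
    ]
    return carriage, records
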