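"""Synthetic serum-metabolomics cohorts with planted phylogenetic structure.

The generator emulates the statistical structure the pipeline assumes: an
outgroup of healthy specimens whose per-feature intensities set the normal
range, patient specimens arranged in planted clades, each clade defined by
planted synapomorphic features (up- or down-regulated, novel or vanished
peaks), plus nuisance features carrying no signal.  Baseline intensities are
log-normal — the conventional LC-MS abundance model; feature m/z is uniform
on the acquired mass range [50, 850] Da and retention time uniform on the
10-minute gradient.

At the defaults (effect size 3x outside the outgroup min-max, zero noise
amplitude, zero missingness) polarization recovers the planted binary matrix
exactly and the planted tree is a perfect phylogeny, so the whole pipeline
has a known ground truth.  Clinical covariates are drawn independently of
clade structure by default (mirroring a cohort in which treatment and risk do
not track the metabolic clades); an optional coupling knob plants a
clade-metastasis association for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from . import trees as T
from .clinical import ClinicalTable, PROTOCOLS
from .feature_io import FeatureTable, SampleManifest

DIRECTION_CYCLE = ("up", "down", "novel", "vanished")


@dataclass(frozen=True)
class CladeSpec:
    label: str
    members: tuple[str, ...]
    n_synapomorphies: int = 3
    directions: tuple[str, ...] = DIRECTION_CYCLE

    def __post_init__(self):
        if self.n_synapomorphies < 1:
            raise ValueError(f"clade {self.label}: need >= 1 synapomorphy")
        bad = set(self.directions) - set(DIRECTION_CYCLE)
        if bad:
            raise ValueError(f"clade {self.label}: unknown directions {sorted(bad)}")


@dataclass
class CohortConfig:
    """Study-condition knobs for a synthetic cohort.

    Clinical rates default to the real cohort's margins (risk 14/34/7 of 55,
    ADT 13/55, metastasis 11/55).  ``effect_size`` is the multiplicative shift
    of planted features relative to the outgroup min-max range (>1);
    ``noise_amplitude`` is the fraction of the outgroup range by which
    no-signal patient intensities may stray outside it (0 = always inside).
    """

    n_outgroup: int = 10
    n_patients: int = 12
    paired: bool = False
    clade_plan: tuple[CladeSpec, ...] | None = None
    n_noise_features: int = 30
    log_intensity_range: tuple[float, float] = (9.2, 13.8)  # ln scale, ~1e4..1e6
    sigma: float = 0.3
    effect_size: float = 3.0
    noise_amplitude: float = 0.0
    missing_rate: float = 0.0
    mz_range: tuple[float, float] = (50.0, 850.0)
    rt_range: tuple[float, float] = (0.0, 10.0)
    risk_probs: tuple[float, float, float] = (14 / 55, 34 / 55, 7 / 55)
    adt_rate: float = 13 / 55
    metastasis_rate: float = 11 / 55
    metastasis_clade: str | None = None
    metastasis_coupled_rate: float = 0.9
    seed: int = 0

    def patient_specimens(self) -> list[str]:
        pats = [f"PT{i+1:02d}" for i in range(self.n_patients)]
        if self.paired:
            return [f"{p}_{ph}" for p in pats for ph in ("pre", "post")]
        return pats

    def outgroup_specimens(self) -> list[str]:
        return [f"OG{i+1:02d}" for i in range(self.n_outgroup)]


def caterpillar_plan(
    specimens, n_synapomorphies: int = 3, directions: tuple[str, ...] = DIRECTION_CYCLE
) -> tuple[CladeSpec, ...]:
    """Nested ladder plan: clades {s2..sm}, {s3..sm}, ..., {s(m-1), sm}.

    Every internal edge of the caterpillar ingroup tree carries
    ``n_synapomorphies`` planted characters, so the planted tree is fully
    resolved and (noise-free) is the unique most-parsimonious tree.
    m specimens yield m - 2 clades.
    """
    specimens = list(specimens)
    if len(specimens) < 3:
        raise ValueError("caterpillar plan needs >= 3 specimens")
    return tuple(
        CladeSpec(
            label=f"clade{k}",
            members=tuple(specimens[k:]),
            n_synapomorphies=n_synapomorphies,
            directions=directions,
        )
        for k in range(1, len(specimens) - 1)
    )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    tree: object                       # rooted tuple over patient specimens
    matrix: pd.DataFrame               # specimens x features, 0/1
    clade_members: dict = field(default_factory=dict)
    clade_synapomorphies: dict = field(default_factory=dict)  # label -> {feature: direction}

    @property
    def newick(self) -> str:
        return T.to_newick(self.tree)

    def to_json(self) -> str:
        return json.dumps(
            {
                "tree": self.newick,
                "clade_members": {k: sorted(v) for k, v in self.clade_members.items()},
                "clade_synapomorphies": self.clade_synapomorphies,
            },
            indent=2,
        )


@dataclass
class Cohort:
    feature_table: FeatureTable
    manifest: SampleManifest
    clinical: ClinicalTable
    truth: GroundTruth

    def write(self, outdir) -> None:
        from pathlib import Path

        from .feature_io import write_feature_table, write_manifest

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.feature_table, out / "feature_table.csv")
        write_manifest(self.manifest, out / "manifest.csv")
        self.clinical.table.to_csv(out / "clinical.csv", index=False)
        (out / "ground_truth_tree.nwk").write_text(self.truth.newick + "\n")
        (out / "ground_truth.json").write_text(self.truth.to_json() + "\n")
        self.truth.matrix.to_csv(out / "ground_truth_matrix.csv")


def _validate_plan(plan, specimens):
    spec_set = set(specimens)
    for cs in plan:
        unknown = set(cs.members) - spec_set
        if unknown:
            raise ValueError(f"clade {cs.label}: unknown specimens {sorted(unknown)}")
        if len(cs.members) < 2:
            raise ValueError(f"clade {cs.label}: needs >= 2 members")
    sets = [frozenset(cs.members) for cs in plan]
    if len(set(cs.label for cs in plan)) != len(plan):
        raise ValueError("clade labels must be unique")
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            if not (a <= b or b <= a or not (a & b)):
                raise ValueError("clade plan must be a hierarchy (nested or disjoint sets)")


def _planted_tree(specimens, plan):
    """Rooted tuple over specimens consistent with the clade hierarchy;
    unconstrained parts become polytomies."""
    clusters = sorted({frozenset(cs.members) for cs in plan}, key=len, reverse=True)

    def build(cluster, splits):
        if len(cluster) == 1:
            return next(iter(cluster))
        kids, used = [], set()
        for s in splits:
            if s < cluster and not (s & used):
                kids.append(s)
                used |= s
        parts = [build(s, [t for t in splits if t < s]) for s in kids]
        parts.extend(sorted(cluster - used))
        if len(parts) == 1:
            return parts[0]
        return tuple(sorted(parts, key=T._min_leaf))

    return build(frozenset(specimens), clusters)


def _clinical_from(config: CohortConfig, rng, clade_members) -> ClinicalTable:
    n = config.n_patients
    ids = [f"PT{i+1:02d}" for i in range(n)]
    risk = rng.choice(["low", "intermediate", "high"], size=n, p=np.asarray(config.risk_probs) / sum(config.risk_probs))
    adt = rng.random(n) < config.adt_rate
    if config.metastasis_clade is not None:
        members = clade_members.get(config.metastasis_clade)
        if members is None:
            raise ValueError(f"metastasis_clade {config.metastasis_clade!r} not in plan")
        in_clade = np.array([any(s.startswith(p) for s in members) for p in ids])
        rate = np.where(in_clade, config.metastasis_coupled_rate, config.metastasis_rate / 2)
        metastasis = rng.random(n) < rate
    else:
        metastasis = rng.random(n) < config.metastasis_rate
    age = rng.integers(52, 91, size=n)
    psa_pre = np.round(np.exp(rng.normal(np.log(8.1), 0.5, size=n)).clip(1.9, 25.6), 1)
    psa_post = np.round(psa_pre * np.exp(rng.normal(-1.5, 0.3, size=n)), 2)
    testosterone = np.round(np.where(adt, rng.normal(40, 15, n), rng.normal(400, 120, n)).clip(1, None), 0)
    gleason = rng.choice(["6(3+3)", "7(3+4;4+3)", "8(3+5;4+4)", "9(4+5;5+4)"], size=n, p=[20 / 55, 30 / 55, 4 / 55, 1 / 55])
    t_stage = rng.choice(["T1c", "T2a-b", "T2c"], size=n, p=[40 / 55, 12 / 55, 3 / 55])
    protocol = rng.choice(list(PROTOCOLS), size=n, p=[6 / 55, 36 / 55, 9 / 55, 4 / 55])
    return ClinicalTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "age": age,
                "race": rng.choice(["Black", "White", "Other"], size=n, p=[15 / 55, 37 / 55, 3 / 55]),
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


def _manifest_from(config: CohortConfig) -> SampleManifest:
    rows = [
        {"specimen_id": s, "patient_id": "", "role": "outgroup", "note": "healthy donor"}
        for s in config.outgroup_specimens()
    ]
    for s in config.patient_specimens():
        if config.paired:
            pid, phase = s.rsplit("_", 1)
            role = "pre_RT" if phase == "pre" else "post_RT"
        else:
            pid, role = s, "pre_RT"
        rows.append({"specimen_id": s, "patient_id": pid, "role": role, "note": ""})
    return SampleManifest(pd.DataFrame(rows))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate (FeatureTable, SampleManifest, ClinicalTable, GroundTruth).

    Outgroup intensities are i.i.d. log-normal per feature; planted features
    are shifted outside the outgroup min-max for all clade members (per the
    clade's direction plan); no-signal patient values stay inside the
    outgroup range up to ``noise_amplitude``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    og = config.outgroup_specimens()
    pts = config.patient_specimens()
    if config.n_outgroup < 2:
        raise ValueError("need >= 2 outgroup specimens")
    plan = config.clade_plan
    if plan is None:
        plan = caterpillar_plan(pts) if len(pts) >= 3 else ()
    _validate_plan(plan, pts)

    n_syn = sum(cs.n_synapomorphies for cs in plan)
    n_feat = n_syn + config.n_noise_features
    if n_feat == 0:
        raise ValueError("plan yields zero features")

    feat_ids = [f"F{i+1:04d}" for i in range(n_feat)]
    lo_mz, hi_mz = config.mz_range
    mz = np.sort(rng.uniform(lo_mz, hi_mz, size=n_feat))
    rt = rng.uniform(*config.rt_range, size=n_feat)
    mu = rng.uniform(*config.log_intensity_range, size=n_feat)

    n_og, n_pt = len(og), len(pts)
    X_og = np.zeros((n_feat, n_og))
    X_pt = np.zeros((n_feat, n_pt))
    pt_index = {s: j for j, s in enumerate(pts)}

    planted = pd.DataFrame(0, index=pd.Index(pts, name="specimen"), columns=feat_ids, dtype=np.int8)
    clade_syn: dict[str, dict[str, str]] = {}
    clade_members = {cs.label: list(cs.members) for cs in plan}

    fidx = 0
    for cs in plan:
        clade_syn[cs.label] = {}
        members = [pt_index[m] for m in cs.members]
        others = [j for j in range(n_pt) if j not in set(members)]
        for k in range(cs.n_synapomorphies):
            direction = cs.directions[k % len(cs.directions)]
            f = fidx
            fidx += 1
            clade_syn[cs.label][feat_ids[f]] = direction
            planted.iloc[members, f] = 1
            if direction == "novel":
                X_og[f, :] = 0.0
                X_pt[f, members] = np.exp(rng.normal(mu[f], config.sigma, size=len(members)))
                X_pt[f, others] = 0.0
                continue
            vals = np.exp(rng.normal(mu[f], config.sigma, size=n_og))
            X_og[f, :] = vals
            m, M = vals.min(), vals.max()
            if others:
                X_pt[f, others] = rng.uniform(m, M, size=len(others))
            if direction == "up":
                X_pt[f, members] = M * config.effect_size * (1.0 + 0.25 * rng.random(len(members)))
            elif direction == "down":
                X_pt[f, members] = (m / config.effect_size) * (0.5 + 0.5 * rng.random(len(members)))
            elif direction == "vanished":
                X_pt[f, members] = 0.0

    amp = config.noise_amplitude
    for f in range(fidx, n_feat):
        vals = np.exp(rng.normal(mu[f], config.sigma, size=n_og))
        X_og[f, :] = vals
        m, M = vals.min(), vals.max()
        span = M - m
        X_pt[f, :] = rng.uniform(max(0.0, m - amp * span), M + amp * span, size=n_pt)

    intens = pd.DataFrame(
        np.hstack([X_og, X_pt]),
        index=pd.Index(feat_ids, name="feature_id"),
        columns=og + pts,
    )
    if config.missing_rate > 0:
        mask = rng.random((n_feat, n_pt)) < config.missing_rate
        block = intens[pts].to_numpy()
        block[mask] = np.nan
        intens[pts] = block

    meta = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feat_ids, name="feature_id"))
    table = FeatureTable(meta=meta, intensities=intens, ion_mode="positive")
    manifest = _manifest_from(config)
    clinical = _clinical_from(config, rng, clade_members)
    truth = GroundTruth(
        tree=_planted_tree(pts, plan) if len(pts) > 1 else pts[0],
        matrix=planted,
        clade_members=clade_members,
        clade_synapomorphies=clade_syn,
    )
    return Cohort(table, manifest, clinical, truth)


def generate_null_cohort(config: CohortConfig) -> Cohort:
    """Cohort with no planted structure: patients are drawn from the same
    log-normal as the outgroup.

    Under min-max polarization the chance that a fresh i.i.d. draw falls
    outside the range of ``n`` outgroup draws is 1/(n+1) per side — an
    expected derived rate of 2/(n_outgroup + 1) per cell.  The ground-truth
    tree is a star.
    """
    rng = np.random.default_rng(config.seed)
    og = config.outgroup_specimens()
    pts = config.patient_specimens()
    n_feat = config.n_noise_features
    if n_feat == 0:
        raise ValueError("need at least one feature")
    feat_ids = [f"F{i+1:04d}" for i in range(n_feat)]
    mz = np.sort(rng.uniform(*config.mz_range, size=n_feat))
    rt = rng.uniform(*config.rt_range, size=n_feat)
    mu = rng.uniform(*config.log_intensity_range, size=n_feat)
    all_cols = og + pts
    X = np.exp(rng.normal(mu[:, None], config.sigma, size=(n_feat, len(all_cols))))
    intens = pd.DataFrame(X, index=pd.Index(feat_ids, name="feature_id"), columns=all_cols)
    meta = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feat_ids, name="feature_id"))
    table = FeatureTable(meta=meta, intensities=intens, ion_mode="positive")
    manifest = _manifest_from(config)
    clinical = _clinical_from(config, rng, {})
    planted = pd.DataFrame(0, index=pd.Index(pts, name="specimen"), columns=feat_ids, dtype=np.int8)
    truth = GroundTruth(tree=tuple(pts), matrix=planted, clade_members={}, clade_synapomorphies={})
    return Cohort(table, manifest, clinical, truth)


def expected_null_derived_rate(n_outgroup: int) -> float:
    """Per-cell derived probability under min-max polarization of i.i.d. data."""
    return 2.0 / (n_outgroup + 1)
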