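"""End-to-end orchestration: read -> polarize -> search -> synapomorphies ->
clinical correlation -> annotation, with a run manifest.

Every stage writes its outputs to the run directory as plain text (CSV,
Newick, JSON), so downstream stages can be re-derived bit-identically from
disk.  The run manifest records the configuration hash, the master seed and
the headline counts of every stage.  All timestamps go to the log only, so a
rerun with the same configuration produces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import clinical as clin
from . import feature_io as fio
from . import parsimony as pars
from . import polarization as pol
from . import synapomorphy as syn


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    feature_table: str
    manifest: str
    out_dir: str
    clinical: str | None = None
    compounds: str | None = None
    mass_range: tuple[float, float] = (50.0, 850.0)
    polarization_method: str = "minmax"
    k: float = 2.0
    min_intensity: float = 0.0
    drop_uninformative: str | None = None
    ancestor_label: str = "HYP_ANCESTOR"
    n_replicates: int = 10
    seed: int = 0
    swap: str = "spr"
    keep_max: int = 100
    synapomorphy_mode: str = "strict"
    annotation_tol_ppm: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "mass_range" in data:
            data["mass_range"] = tuple(data["mass_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mass_range"] = list(d["mass_range"])
        return d

    def validate(self) -> None:
        for name in ("feature_table", "manifest", "clinical", "compounds"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"input path for {name!r} does not exist: {p}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory.

    Deterministic given the configuration (the master seed drives the tree
    search); any stage failure raises :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str):
        log_lines.append(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}")

    counts: dict = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
                raise PipelineError(name, str(exc)) from exc

        return wrap

    # --- read + filter -----------------------------------------------------
    def _read():
        table = fio.read_feature_table(config.feature_table)
        manifest = fio.read_manifest(config.manifest)
        counts["features_in"] = table.n_features
        table = fio.filter_mass_range(table, *config.mass_range)
        counts["features_after_mass_filter"] = table.n_features
        std = fio.check_internal_standards(table)
        std.to_csv(out / "internal_standards.csv", index=False)
        return table, manifest

    table, manifest = stage("read")(_read)
    log(f"read {counts['features_in']} features; {counts['features_after_mass_filter']} in mass range")

    # --- polarize ----------------------------------------------------------
    def _polarize():
        ranges = pol.compute_normal_ranges(
            table, manifest, method=config.polarization_method, k=config.k
        )
        matrix = pol.polarize(table, ranges, manifest, min_intensity=config.min_intensity)
        matrix = pol.append_hypothetical_ancestor(matrix, config.ancestor_label)
        removed = pd.DataFrame(columns=["character", "reason", "derived_count"])
        if config.drop_uninformative:
            matrix, removed = pol.drop_uninformative_characters(matrix, config.drop_uninformative)
        ranges.table.to_csv(out / "normal_ranges.csv")
        pol.write_matrix_csv(matrix, out / "polarized_matrix.csv")
        pol.write_directions_csv(matrix, out / "directions.csv")
        pol.write_phylip(matrix, out / "polarized_matrix.phy")
        removed.to_csv(out / "removed_characters.csv", index=False)
        return matrix

    matrix = stage("polarize")(_polarize)
    counts["specimens"] = len(matrix.specimens) - 1
    counts["characters"] = len(matrix.characters)
    log(f"polarized {counts['specimens']} specimens x {counts['characters']} characters")

    # --- tree search -------------------------------------------------------
    def _search():
        res = pars.heuristic_search(
            matrix,
            n_replicates=config.n_replicates,
            seed=config.seed,
            swap=config.swap,
            keep_max=config.keep_max,
        )
        with open(out / "best_trees.nwk", "w") as fh:
            for u in res.trees:
                fh.write(pars.write_newick(u) + "\n")
        shipped = res.trees[0] if res.n_trees == 1 else pars.strict_consensus(res.trees)
        clad = pars.root_on_outgroup(shipped, config.ancestor_label, matrix=matrix, n_trees=res.n_trees)
        pars.write_newick(clad, out / "cladogram.nwk")
        return res, clad

    res, clad = stage("search")(_search)
    counts["tree_length"] = res.length
    counts["n_best_trees"] = res.n_trees
    ci = pars.consistency_index(matrix, res.best)
    counts["consistency_index"] = ci
    log(f"tree length {res.length}, {res.n_trees} best tree(s), CI {ci}")

    # --- synapomorphies ----------------------------------------------------
    def _synapo():
        tab = syn.extract_synapomorphies(clad, matrix, mode=config.synapomorphy_mode)
        export = syn.synapomorphy_export(clad, tab, feature_meta=table.meta, directions=matrix.directions)
        export.to_csv(out / "synapomorphies.csv", index=False)
        tab.autapomorphies.to_csv(out / "autapomorphies.csv", index=False)
        with open(out / "cladogram_annotated.nwk", "w") as fh:
            fh.write(syn.annotated_newick(clad, tab) + "\n")
        return tab

    tab = stage("synapomorphy")(_synapo)
    counts["synapomorphies_total"] = len(tab.entries)
    counts["autapomorphies_total"] = len(tab.autapomorphies)
    counts["unplaced_characters"] = len(tab.unplaced)
    log(f"{len(tab.entries)} synapomorphies across {len(tab.counts())} nodes")

    # --- clinical ----------------------------------------------------------
    if config.clinical is not None:
        def _clinic():
            ct = clin.ClinicalTable(pd.read_csv(config.clinical))
            patient_of = manifest.patient_of()
            # clade = child of the ingroup root containing the specimen
            ingroup = clad.ingroup
            blocks = list(ingroup) if isinstance(ingroup, tuple) else [ingroup]
            assignment: dict[str, str] = {}
            for i, block in enumerate(blocks):
                from .trees import leaves

                for s in leaves(block):
                    pid = patient_of.get(s, s)
                    assignment.setdefault(pid, f"clade{i+1}")
            assignment = {p: c for p, c in assignment.items() if p in set(ct.patients)}
            pd.Series(assignment, name="clade").rename_axis("patient_id").to_csv(out / "clade_assignment.csv")
            covs = ["psa_pre", "psa_post", "testosterone", "adt", "risk", "metastasis"]
            covs = [c for c in covs if c in ct.table.columns]
            render, summaries = clin.clade_covariate_matrix(assignment, ct, covs)
            render.to_csv(out / "clade_covariate_matrix.csv")
            summaries.to_csv(out / "clade_covariate_summaries.csv", index=False)
            assoc = {}
            for cov in ("adt", "risk", "metastasis"):
                if cov in ct.table.columns:
                    r = clin.clade_covariate_association(assignment, ct, cov)
                    assoc[cov] = {
                        "p_value": r.p_value,
                        "test": r.test,
                        "degenerate": r.degenerate,
                        "table": r.contingency.to_dict(),
                    }
            (out / "clade_associations.json").write_text(json.dumps(assoc, indent=2, default=str))
            return len(assignment)

        counts["patients_assigned"] = stage("clinical")(_clinic)
        log(f"assigned {counts['patients_assigned']} patients to clades")

    # --- annotation --------------------------------------------------------
    if config.compounds is not None:
        def _annotate():
            comps = ann.read_compound_table(config.compounds)
            hits = ann.match_features(table, comps, tol_ppm=config.annotation_tol_ppm)
            hits.to_csv(out / "annotation.csv", index=False)
            return len(hits)

        counts["annotation_candidates"] = stage("annotation")(_annotate)
        log(f"{counts['annotation_candidates']} annotation candidates")

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "phylometab": __version__,
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
        },
        "counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
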