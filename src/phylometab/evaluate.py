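"""Evaluation utilities: planted-structure recovery and null calibration.

These run the pipeline on generated cohorts where the truth is known and
summarize how well it was recovered — used by the test suite and the
reproduction script, and handy for power studies on new configurations.
"""

from __future__ import annotations

import numpy as np

from . import parsimony as pars
from . import polarization as pol
from . import trees as T
from .clinical import clade_covariate_association
from .synapomorphy import SynapomorphyTable, extract_synapomorphies
from .synthetic import Cohort, CohortConfig, generate_cohort, generate_null_cohort

ANCESTOR = "HYP_ANCESTOR"


def polarize_cohort(cohort: Cohort, method: str = "minmax") -> pol.PolarizedMatrix:
    """Polarize a generated cohort and append the all-ancestral root taxon."""
    ranges = pol.compute_normal_ranges(cohort.feature_table, cohort.manifest, method=method)
    matrix = pol.polarize(cohort.feature_table, ranges, cohort.manifest)
    return pol.append_hypothetical_ancestor(matrix, ANCESTOR)


def synapomorphy_pairs(table: SynapomorphyTable) -> set[tuple[frozenset, str]]:
    """(clade leaf set, character) pairs asserted by a synapomorphy table."""
    return {
        (table.clades[nid], char)
        for nid, char in zip(table.entries["node_id"], table.entries["character"])
    }


def truth_pairs(cohort: Cohort) -> set[tuple[frozenset, str]]:
    return {
        (frozenset(cohort.truth.clade_members[label]), feat)
        for label, feats in cohort.truth.clade_synapomorphies.items()
        for feat in feats
    }


def recovery_metrics(cohort: Cohort, n_replicates: int = 5, seed: int = 0) -> dict:
    """Polarize, search, and score recovery of the planted structure.

    Returns the Robinson-Foulds distance between the inferred ingroup tree and
    the planted tree, the number of equally parsimonious trees found, and
    synapomorphy precision/recall against the planted per-clade lists.
    """
    matrix = polarize_cohort(cohort)
    n_taxa = len(matrix.specimens)
    if n_taxa <= 9:
        res = pars.exhaustive_search(matrix)
    else:
        res = pars.heuristic_search(matrix, n_replicates=n_replicates, seed=seed)
    shipped = res.trees[0] if res.n_trees == 1 else pars.strict_consensus(res.trees)
    clad = pars.root_on_outgroup(shipped, ANCESTOR, matrix=matrix, n_trees=res.n_trees)

    patients = [s for s in matrix.specimens if s != ANCESTOR]
    truth_rooted = (ANCESTOR, cohort.truth.tree)
    rf = pars.robinson_foulds(
        pars.unroot(clad), pars.unroot(pars.Cladogram(tree=truth_rooted, root_label=ANCESTOR))
    )
    found = synapomorphy_pairs(extract_synapomorphies(clad, matrix, mode="strict"))
    truth = truth_pairs(cohort)
    tp = len(found & truth)
    precision = tp / len(found) if found else 1.0
    recall = tp / len(truth) if truth else 1.0
    return {
        "rf_distance": rf,
        "n_best_trees": res.n_trees,
        "tree_length": res.length,
        "precision": precision,
        "recall": recall,
        "n_patients": len(patients),
    }


def null_association_pvalues(
    n_runs: int,
    seed: int,
    n_outgroup: int = 8,
    n_patients: int = 40,
    n_noise_features: int = 60,
    covariate: str = "risk",
    p_method: str = "auto",
) -> np.ndarray:
    """Clade-vs-covariate p-values on cohorts with no planted structure.

    Each run generates a fresh null cohort, infers a tree (one stepwise
    replicate + NNI), takes the tree's most balanced clade as the grouping,
    and tests it against a clinically independent covariate.  Under the null
    the returned p-values are approximately uniform.

    The default covariate is the three-level risk group: with a binary
    covariate the 2x2 table's modal outcome carries ~25% probability, so any
    deterministic p-value (exact, mid-p or chi-square) has an atom of that
    size and no finite-sample p distribution can look uniform — a property of
    discrete 2x2 tables, not of the implementation.  The 2x3 table spreads
    that mass over a far larger support.  Degenerate tables are skipped.
    """
    ss = np.random.SeedSequence(seed)
    pvals = []
    for child_ss in ss.spawn(n_runs):
        child = int(np.random.default_rng(child_ss).integers(0, 2**31 - 1))
        cfg = CohortConfig(
            n_outgroup=n_outgroup,
            n_patients=n_patients,
            n_noise_features=n_noise_features,
            seed=child,
        )
        cohort = generate_null_cohort(cfg)
        matrix = polarize_cohort(cohort)
        res = pars.heuristic_search(matrix, n_replicates=1, seed=child, swap="nni")
        u = T.rebase(res.trees[0], ANCESTOR)
        patients = [s for s in matrix.specimens if s != ANCESTOR]
        # clade under test: the tree's most balanced clade (splits of 1 vs n-1
        # give degenerate contingency tables with no power to detect anything)
        half = len(patients) / 2
        clade = min(T.bipartitions(u), key=lambda s: (abs(len(s) - half), sorted(s)))
        assignment = {p: ("A" if p in clade else "B") for p in patients}
        r = clade_covariate_association(assignment, cohort.clinical, covariate, p_method=p_method)
        if not r.degenerate:
            pvals.append(r.p_value)
    return np.asarray(pvals)
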