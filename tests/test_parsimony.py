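"""Tree primitives and maximum-parsimony scoring/search.

The independent oracles here are (a) brute-force enumeration over all
ancestral state assignments, (b) exhaustive topology enumeration, and
(c) dendropy's Fitch down-pass.
"""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.model import parsimony as dp_parsimony

import phylometab as pm
from phylometab import parsimony as P
from phylometab import trees as T
from phylometab.trees import Unrooted

from conftest import random_states


def brute_force_length(rooted, states: pd.DataFrame) -> int:
    """Minimum changes by enumerating every internal-node labeling."""
    from phylometab.synapomorphy import index_nodes

    internal = [node for _, node, _ in index_nodes(rooted)]
    total = 0
    for char in states.columns:
        leaf_state = states[char].to_dict()
        best = None
        for labels in itertools.product([0, 1], repeat=len(internal)):
            assign = {id(node): lab for node, lab in zip(internal, labels)}

            def state_of(node):
                return leaf_state[node] if isinstance(node, str) else assign[id(node)]

            changes = 0
            stack = [rooted]
            while stack:
                node = stack.pop()
                if isinstance(node, str):
                    continue
                for child in node:
                    changes += state_of(node) != state_of(child)
                    stack.append(child)
            best = changes if best is None else min(best, changes)
        total += best
    return total


def dendropy_length(u: Unrooted, states: pd.DataFrame) -> int:
    tns = dendropy.TaxonNamespace([str(i) for i in states.index])
    dt = P.to_dendropy(u, taxon_namespace=tns)
    mat = dendropy.StandardCharacterMatrix.from_dict(
        {str(i): "".join(map(str, row)) for i, row in zip(states.index, states.to_numpy())},
        taxon_namespace=tns,
    )
    tsm = mat.taxon_state_sets_map(gaps_as_missing=True)
    return dp_parsimony.fitch_down_pass(dt.postorder_node_iter(), taxon_state_sets_map=tsm)


class TestTreePrimitives:
    @pytest.mark.parametrize("n, expected", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_topology_enumeration_counts(self, n, expected):
        labels = [f"t{i}" for i in range(n)]
        tops = {T.canonical_unrooted(u) for u in T.enumerate_unrooted(labels)}
        assert len(tops) == expected == T.n_unrooted_topologies(n)

    def test_rebase_preserves_topology(self, rng):
        states = random_states(rng, 6, 4)
        for u in itertools.islice(T.enumerate_unrooted(list(states.index)), 20):
            for leaf in states.index:
                v = T.rebase(u, leaf)
                assert T.unrooted_leaves(v) == T.unrooted_leaves(u)
                assert T.canonical_unrooted(v) == T.canonical_unrooted(u)

    def test_bipartitions_match_dendropy(self, rng):
        states = random_states(rng, 7, 3)
        u = next(iter(T.enumerate_unrooted(list(states.index))))
        mine = {frozenset(min(s, T.unrooted_leaves(u) - s, key=lambda x: (len(x), sorted(x))))
                for s in T.bipartitions(u)}
        dt = P.to_dendropy(u)
        dt.encode_bipartitions()
        theirs = set()
        taxa = T.unrooted_leaves(u)
        for edge in dt.preorder_edge_iter():
            if edge.head_node.is_leaf() or edge.tail_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in edge.head_node.leaf_iter())
            if 1 < len(side) < len(taxa) - 1:
                theirs.add(frozenset(min(side, taxa - side, key=lambda x: (len(x), sorted(x)))))
        assert mine == theirs


class TestFitchLength:
    def test_single_clean_change(self):
        states = pd.DataFrame({"c": [0, 0, 1, 1]}, index=list("ABCD"))
        tree = (("A", "B"), ("C", "D"))
        assert P.fitch_length(tree, states) == 1

    def test_constant_matrix_zero(self):
        states = pd.DataFrame(np.ones((4, 3), dtype=np.int8), index=list("ABCD"))
        assert P.fitch_length((("A", "B"), ("C", "D")), states) == 0

    def test_alternating_character_needs_two_changes(self):
        states = pd.DataFrame({"c": [0, 1, 0, 1]}, index=list("ABCD"))
        tree = (("A", "B"), ("C", "D"))
        assert P.fitch_length(tree, states) == 2 == brute_force_length(tree, states)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            states = random_states(rng, n, int(rng.integers(2, 6)))
            u = next(itertools.islice(T.enumerate_unrooted(list(states.index)),
                                      int(rng.integers(0, T.n_unrooted_topologies(n))), None))
            rooted = (u.base, u.rest)
            assert P.fitch_length(u, states) == brute_force_length(rooted, states)

    def test_matches_dendropy(self, rng):
        for _ in range(10):
            states = random_states(rng, 7, 10)
            u = P.heuristic_search(states, n_replicates=2, seed=0).best
            assert P.fitch_length(u, states) == dendropy_length(u, states)

    def test_invariant_under_rebase_and_row_permutation(self, rng):
        states = random_states(rng, 6, 8)
        u = P.heuristic_search(states, n_replicates=1, seed=0).best
        L = P.fitch_length(u, states)
        for leaf in states.index:
            assert P.fitch_length(T.rebase(u, leaf), states) == L
        assert P.fitch_length(u, states.iloc[::-1]) == L

    def test_leaf_mismatch_reported(self, rng):
        states = random_states(rng, 5, 3)
        u = next(iter(T.enumerate_unrooted(list(states.index))))
        with pytest.raises(P.LeafMismatchError, match="t4"):
            P.fitch_length(u, states.iloc[:-1])

    def test_per_character_lengths(self, rng):
        states = random_states(rng, 6, 12)
        u = P.heuristic_search(states, n_replicates=1, seed=0).best
        per = P.fitch_length(u, states, per_character=True)
        assert per.sum() == P.fitch_length(u, states)
        arr = states.to_numpy()
        variable = (arr.min(axis=0) == 0) & (arr.max(axis=0) == 1)
        assert ((per.to_numpy() >= 1) == variable).all()
        assert P.fitch_length(u, states) >= int(variable.sum())


class TestSearch:
    def test_exhaustive_enumerates_all(self, rng):
        states = random_states(rng, 6, 5)
        res = P.exhaustive_search(states)
        assert res.n_evaluated == 105

    def test_exhaustive_guard(self, rng):
        states = random_states(rng, 10, 5)
        with pytest.raises(ValueError, match="guard"):
            P.exhaustive_search(states)

    def test_planted_perfect_phylogeny_unique_optimum(self):
        # caterpillar on 7 taxa, 2 characters per internal edge
        taxa = [f"t{i}" for i in range(7)]
        cols = {}
        for k in range(1, 6):
            for r in range(2):
                cols[f"e{k}_{r}"] = [1 if i >= k else 0 for i in range(7)]
        states = pd.DataFrame(cols, index=taxa, dtype=np.int8)
        res = P.exhaustive_search(states)
        assert res.n_trees == 1 and res.length == 10
        planted = Unrooted("t0", ("t1", ("t2", ("t3", ("t4", ("t5", "t6"))))))
        assert P.robinson_foulds(res.best, planted) == 0

    def test_heuristic_matches_exhaustive(self, rng):
        for trial in range(25):
            n = int(rng.integers(5, 8))
            states = random_states(rng, n, int(rng.integers(4, 15)))
            ex = P.exhaustive_search(states)
            h = P.heuristic_search(states, n_replicates=4, seed=trial)
            assert h.length == ex.length

    def test_heuristic_never_beats_exhaustive(self, rng):
        for trial in range(10):
            states = random_states(rng, 6, 8)
            ex = P.exhaustive_search(states)
            h = P.heuristic_search(states, n_replicates=0, seed=trial, swap="none")
            assert h.length >= ex.length

    def test_deterministic_given_seed(self, rng):
        states = random_states(rng, 8, 12)
        a = P.heuristic_search(states, n_replicates=5, seed=9)
        b = P.heuristic_search(states, n_replicates=5, seed=9)
        assert a.trees == b.trees and a.length == b.length

    def test_too_few_taxa(self, rng):
        states = random_states(rng, 2, 3)
        with pytest.raises(ValueError):
            P.heuristic_search(states)


class TestRootingConsensus:
    def test_root_on_outgroup_structure(self):
        u = Unrooted("O", ("A", ("B", "C")))
        clad = P.root_on_outgroup(u, "O")
        assert clad.tree == ("O", ("A", ("B", "C")))
        assert set(clad.leaves) == {"O", "A", "B", "C"}

    def test_root_unroot_round_trip(self, rng):
        states = random_states(rng, 7, 6)
        u = P.heuristic_search(states, n_replicates=1, seed=0).best
        clad = P.root_on_outgroup(u, "t3")
        assert P.robinson_foulds(P.unroot(clad), u) == 0
        assert set(clad.leaves) == set(T.unrooted_leaves(u))

    def test_missing_outgroup_label(self):
        u = Unrooted("O", ("A", ("B", "C")))
        with pytest.raises(KeyError):
            P.root_on_outgroup(u, "Z")

    def test_consensus_of_identical_trees(self, rng):
        states = random_states(rng, 6, 8)
        u = P.heuristic_search(states, n_replicates=1, seed=0).best
        assert P.robinson_foulds(P.strict_consensus([u, u]), u) == 0

    def test_consensus_of_disjoint_trees_is_star(self):
        a = Unrooted("a", (("b", "c"), ("d", "e")))
        b = Unrooted("a", (("b", "d"), ("c", "e")))
        cons = P.strict_consensus([a, b])
        assert len(T.bipartitions(cons)) == 0

    def test_consensus_clades_present_in_all_inputs(self, rng):
        states = random_states(rng, 7, 4)
        res = P.exhaustive_search(states)
        trees = res.trees[:5] if res.n_trees >= 2 else res.trees
        cons = P.strict_consensus(trees)
        taxa = T.unrooted_leaves(cons)

        def norm(splits):
            return {frozenset(min(s, taxa - s, key=lambda x: (len(x), sorted(x)))) for s in splits}

        cons_splits = norm(T.bipartitions(cons))
        for u in trees:
            assert cons_splits <= norm(T.bipartitions(T.rebase(u, cons.base)))

    def test_consensus_leafset_mismatch(self):
        a = Unrooted("a", ("b", ("c", "d")))
        b = Unrooted("a", ("b", ("c", "e")))
        with pytest.raises(P.LeafMismatchError):
            P.strict_consensus([a, b])


class TestConsistencyIndex:
    def test_perfect_phylogeny_ci_one(self):
        states = pd.DataFrame({"c1": [0, 0, 1, 1], "c2": [1, 1, 0, 0]}, index=list("ABCD"))
        assert P.consistency_index(states, (("A", "B"), ("C", "D"))) == 1.0

    def test_homoplasy_halves_ci(self):
        states = pd.DataFrame({"c": [0, 1, 0, 1]}, index=list("ABCD"))
        assert P.consistency_index(states, (("A", "B"), ("C", "D"))) == 0.5

    def test_zero_length_flagged(self):
        states = pd.DataFrame({"c": [0, 0, 0, 0]}, index=list("ABCD"))
        assert P.consistency_index(states, (("A", "B"), ("C", "D"))) is None

    def test_never_exceeds_one(self, rng):
        for _ in range(10):
            states = random_states(rng, 6, 10)
            u = P.heuristic_search(states, n_replicates=1, seed=0).best
            ci = P.consistency_index(states, u)
            if ci is not None:
                assert 0 < ci <= 1


class TestInterop:
    def test_newick_round_trip(self, tmp_path):
        rooted = ("ROOT_TAXON", ("A", ("B", "C")))
        path = tmp_path / "t.nwk"
        P.write_newick(rooted, path)
        assert T.canonical_rooted(P.read_newick(str(path))) == T.canonical_rooted(rooted)

    def test_phylip_round_trip(self, tmp_path, rng):
        states = random_states(rng, 5, 8)
        dirs = states.astype(object).replace({0: "none", 1: "up"})
        m = pm.PolarizedMatrix(states=states, directions=dirs)
        from phylometab.polarization import write_phylip

        path = tmp_path / "m.phy"
        write_phylip(m, path)
        back = P.read_phylip_matrix(path)
        assert (back.states.to_numpy() == states.to_numpy()).all()
        assert list(back.states.index) == list(states.index)
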