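"""Binary-character maximum parsimony (Wagner/Fitch) over polarized matrices.

Wagner parsimony on two unordered, freely reversible states is equivalent to
Fitch counting, so tree length is computed by Fitch set operations in the
search inner loop and by a vectorized two-state Sankoff dynamic program in the
public :func:`fitch_length` (the Sankoff form also scores polytomies exactly).

Search follows the classic scheme: stepwise addition (replicate 0 uses the
matrix row order — the "nonrandomized input"; further replicates use seeded
random addition orders) followed by NNI or SPR branch swapping to a local
optimum.  An exhaustive enumerator over all (2n-5)!! topologies serves as the
exact oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import trees as T
from .trees import Unrooted
from .polarization import PolarizedMatrix

_BIG = np.int64(10**9)


class LeafMismatchError(ValueError):
    pass


def _states_frame(matrix) -> pd.DataFrame:
    return matrix.states if isinstance(matrix, PolarizedMatrix) else matrix


def _check_leaves(tree_leaves, matrix_index):
    a, b = set(tree_leaves), set(matrix_index)
    if a != b:
        raise LeafMismatchError(
            f"tree/matrix leaf mismatch; only-in-tree={sorted(a - b)}, "
            f"only-in-matrix={sorted(b - a)}"
        )


# ---------------------------------------------------------------------------
# scoring


def _encode(states: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-taxon Fitch state sets: bit 0 = ancestral(0), bit 1 = derived(1)."""
    arr = states.to_numpy(np.uint8)
    return {str(name): np.where(row == 0, 1, 2).astype(np.uint8)
            for name, row in zip(states.index, arr)}


def _fitch(node, enc):
    """Set-based Fitch down-pass on a binary rooted tuple; returns (sets, count)."""
    if isinstance(node, str):
        return enc[node], 0
    a, b = node
    sa, ca = _fitch(a, enc)
    sb, cb = _fitch(b, enc)
    inter = sa & sb
    change = inter == 0
    return np.where(change, sa | sb, inter), ca + cb + int(change.sum())


def _score(u: Unrooted, enc) -> int:
    sets, count = _fitch(u.rest, enc)
    return count + int(((sets & enc[u.base]) == 0).sum())


def fitch_length(tree, matrix, per_character: bool = False):
    """Minimum number of 0<->1 changes on ``tree``, summed over characters.

    ``tree`` may be an :class:`~phylometab.trees.Unrooted` or any rooted tuple
    (polytomies allowed); ``matrix`` a :class:`PolarizedMatrix` or a 0/1
    DataFrame.  With ``per_character=True`` returns a Series of per-character
    lengths instead of the total.
    """
    states = _states_frame(matrix)
    rooted = (tree.base, tree.rest) if isinstance(tree, Unrooted) else tree
    _check_leaves(T.leaves(rooted), states.index)
    arr = {str(n): r for n, r in zip(states.index, states.to_numpy(np.int64))}
    nchar = states.shape[1]

    def cost(node) -> np.ndarray:  # shape (2, nchar)
        if isinstance(node, str):
            row = arr[node]
            return np.stack([np.where(row == 0, 0, _BIG), np.where(row == 1, 0, _BIG)])
        total = np.zeros((2, nchar), dtype=np.int64)
        for child in node:
            c = cost(child)
            total += np.minimum(c, c[::-1] + 1)
        return total

    per_char = cost(rooted).min(axis=0)
    if per_character:
        return pd.Series(per_char, index=states.columns, name="length")
    return int(per_char.sum())


def consistency_index(matrix, tree) -> float | None:
    """CI = (number of variable characters) / tree length; None if length 0."""
    states = _states_frame(matrix)
    length = fitch_length(tree, states)
    if length == 0:
        return None
    arr = states.to_numpy()
    n_var = int(((arr.min(axis=0) == 0) & (arr.max(axis=0) == 1)).sum())
    return n_var / length


# ---------------------------------------------------------------------------
# search


@dataclass
class SearchResult:
    """Outcome of a tree search: the distinct best topologies and their length."""

    trees: list[Unrooted]
    length: int
    method: str
    n_evaluated: int = 0
    replicates: int | None = None
    seed: int | None = None
    swap: str | None = None
    hit_cap: bool = False

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def best(self) -> Unrooted:
        return self.trees[0]


def exhaustive_search(matrix, max_taxa: int = 9) -> SearchResult:
    """Score every unrooted binary topology; exact optimum set for small n."""
    states = _states_frame(matrix)
    labels = [str(x) for x in states.index]
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds the exhaustive-search guard of {max_taxa} "
            f"({T.n_unrooted_topologies(n)} topologies); use heuristic_search"
        )
    enc = _encode(states)
    best_len = None
    best: list[Unrooted] = []
    count = 0
    for u in T.enumerate_unrooted(labels):
        count += 1
        L = _score(u, enc)
        if best_len is None or L < best_len:
            best_len, best = L, [T.canonical_unrooted(u)]
        elif L == best_len:
            best.append(T.canonical_unrooted(u))
    best = sorted(set(best), key=T.unrooted_to_newick)
    return SearchResult(trees=best, length=best_len, method="exhaustive", n_evaluated=count)


def _stepwise(order: list[str], enc) -> Unrooted:
    base, rest = order[0], order[1]
    for x in order[2:]:
        best_rest, best_len = None, None
        for cand in T.insertions(rest, x):  # deterministic edge order
            L = _score(Unrooted(base, cand), enc)
            if best_len is None or L < best_len:
                best_rest, best_len = cand, L
        rest = best_rest
    return Unrooted(base, rest)


def _nni_neighbors(node):
    if isinstance(node, str):
        return
    a, b = node
    if not isinstance(a, str):
        a1, a2 = a
        yield ((b, a2), a1)
        yield ((a1, b), a2)
    if not isinstance(b, str):
        b1, b2 = b
        yield (b1, (a, b2))
        yield (b2, (b1, a))
    for na in _nni_neighbors(a):
        yield (na, b)
    for nb in _nni_neighbors(b):
        yield (a, nb)


def _prunings(node):
    """Yield (pruned subtree, remainder) for every proper subtree of ``node``."""
    if isinstance(node, str):
        return
    a, b = node
    yield a, b
    yield b, a
    for s, ra in _prunings(a):
        yield s, (ra, b)
    for s, rb in _prunings(b):
        yield s, (a, rb)


def _spr_neighbors(node):
    for s, rem in _prunings(node):
        if isinstance(rem, str) and isinstance(s, str):
            continue
        yield from T.insertions(rem, s)


_NEIGHBORHOODS = {"nni": _nni_neighbors, "spr": _spr_neighbors}


def _hill_climb(u: Unrooted, enc, swap: str, ties: set | None = None, cap: int = 0):
    cur, cur_len = u.rest, _score(u, enc)
    if swap == "none":
        return Unrooted(u.base, cur), cur_len
    neighbors = _NEIGHBORHOODS[swap]
    while True:
        best, best_len = None, cur_len
        for cand in neighbors(cur):
            L = _score(Unrooted(u.base, cand), enc)
            if L < best_len:
                best, best_len = cand, L
            elif ties is not None and L == cur_len and len(ties) < cap:
                ties.add(T.canonical_unrooted(Unrooted(u.base, cand)))
        if best is None:
            return Unrooted(u.base, cur), cur_len
        cur, cur_len = best, best_len


def heuristic_search(
    matrix,
    n_replicates: int = 10,
    seed: int = 0,
    swap: str = "spr",
    keep_max: int = 100,
) -> SearchResult:
    """Randomized stepwise addition + branch swapping.

    Runs one replicate in matrix row order plus ``n_replicates`` seeded
    random-addition replicates, each refined by ``swap`` ("nni", "spr" or
    "none") hill-climbing.  Returns the distinct best topologies found (up to
    ``keep_max``); deterministic given (matrix, n_replicates, seed, swap).
    """
    if swap not in ("none", "nni", "spr"):
        raise ValueError(f"unknown swap mode {swap!r}")
    states = _states_frame(matrix)
    labels = [str(x) for x in states.index]
    if len(labels) < 3:
        raise ValueError("need >= 3 specimens for a tree search")
    enc = _encode(states)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(max(n_replicates, 0))
    best_len, found = None, set()
    n_eval = 0
    for rep in range(n_replicates + 1):
        if rep == 0:
            order = labels
        else:
            rng = np.random.default_rng(rep_seeds[rep - 1])
            order = [labels[i] for i in rng.permutation(len(labels))]
        u = _stepwise(order, enc)
        ties: set = set()
        u, L = _hill_climb(u, enc, swap, ties=ties, cap=keep_max)
        n_eval += 1
        cands = {T.canonical_unrooted(u)} | ties
        for c in cands:
            Lc = _score(c, enc)
            if best_len is None or Lc < best_len:
                best_len, found = Lc, {c}
            elif Lc == best_len:
                found.add(c)
    hit_cap = len(found) > keep_max
    trees = sorted(found, key=T.unrooted_to_newick)[:keep_max]
    return SearchResult(
        trees=trees,
        length=best_len,
        method="heuristic",
        n_evaluated=n_eval,
        replicates=n_replicates,
        seed=seed,
        swap=swap,
        hit_cap=hit_cap,
    )


# ---------------------------------------------------------------------------
# rooting and consensus


@dataclass
class Cladogram:
    """Rooted tree over specimens; root children are the outgroup (or the
    hypothetical all-ancestral taxon) and the ingroup subtree."""

    tree: tuple
    root_label: str
    length: int | None = None
    n_trees: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def leaves(self) -> tuple:
        return T.leaves(self.tree)

    @property
    def ingroup(self):
        """Subtree of patient specimens (everything except the root taxon)."""
        a, b = self.tree
        return b if a == self.root_label else a

    def newick(self) -> str:
        return T.to_newick(self.tree)


def root_on_outgroup(tree: Unrooted, outgroup_label: str, matrix=None, n_trees=None) -> Cladogram:
    """Root on the edge subtending the outgroup leaf; ingroup clades preserved."""
    if outgroup_label not in T.unrooted_leaves(tree):
        raise KeyError(f"outgroup label {outgroup_label!r} is not a leaf")
    based = T.rebase(tree, outgroup_label)
    rooted = (based.base, based.rest)
    length = None if matrix is None else fitch_length(based, matrix)
    return Cladogram(tree=rooted, root_label=outgroup_label, length=length, n_trees=n_trees)


def unroot(clad: Cladogram) -> Unrooted:
    a, b = clad.tree
    return Unrooted(a, b) if a == clad.root_label else Unrooted(b, a)


def strict_consensus(tree_list: list[Unrooted]) -> Unrooted:
    """Tree containing exactly the splits present in every input tree."""
    if not tree_list:
        raise ValueError("empty tree set")
    leaf_sets = {T.unrooted_leaves(u) for u in tree_list}
    if len(leaf_sets) > 1:
        raise LeafMismatchError("consensus requires a common leaf set")
    base = min(leaf_sets.pop())
    based = [T.rebase(u, base) for u in tree_list]
    common = set.intersection(*(T.bipartitions(u) for u in based))
    others = T.leaf_set(based[0].rest)

    def build(cluster: frozenset, splits: list[frozenset]):
        if len(cluster) == 1:
            return next(iter(cluster))
        kids, used = [], set()
        for s in splits:  # sorted descending by size: maximal first
            if s < cluster and not (s & used):
                kids.append(s)
                used |= s
        parts = [build(s, [t for t in splits if t < s]) for s in kids]
        parts.extend(sorted(cluster - used))
        if len(parts) == 1:
            return parts[0]
        return tuple(sorted(parts, key=T._min_leaf))

    ordered = sorted(common, key=len, reverse=True)
    return Unrooted(base, build(frozenset(others), ordered))


def robinson_foulds(a: Unrooted, b: Unrooted) -> int:
    """Unrooted RF distance: size of the symmetric difference of split sets."""
    la, lb = T.unrooted_leaves(a), T.unrooted_leaves(b)
    if la != lb:
        raise LeafMismatchError("RF distance requires identical leaf sets")

    def splits(u):
        out = set()
        for side in T.bipartitions(u):
            out.add(min(side, la - side, key=lambda s: (len(s), sorted(s))))
        return out

    return len(splits(a) ^ splits(b))


# ---------------------------------------------------------------------------
# Newick / PHYLIP interop


def write_newick(tree, path=None) -> str:
    if isinstance(tree, Cladogram):
        s = T.to_newick(tree.tree)
    elif isinstance(tree, Unrooted):
        s = T.unrooted_to_newick(tree)
    else:
        s = T.to_newick(tree)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def _from_dendropy(node):
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    kids = tuple(_from_dendropy(c) for c in node.child_nodes())
    return kids[0] if len(kids) == 1 else kids


def read_newick(source: str) -> tuple:
    """Parse a Newick string (or path) into a rooted tuple-tree."""
    import os

    if os.path.exists(source):
        with open(source) as fh:
            source = fh.read()
    dt = dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)
    return _from_dendropy(dt.seed_node)


def to_dendropy(tree, taxon_namespace=None) -> dendropy.Tree:
    """Convert a rooted tuple / Unrooted / Cladogram to a dendropy Tree."""
    if isinstance(tree, Cladogram):
        newick, rooted = T.to_newick(tree.tree), True
    elif isinstance(tree, Unrooted):
        newick, rooted = T.unrooted_to_newick(tree), False
    else:
        newick, rooted = T.to_newick(tree), True
    dt = dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=taxon_namespace,
        preserve_underscores=True,
        rooting="force-rooted" if rooted else "force-unrooted",
    )
    return dt


def read_phylip_matrix(path) -> PolarizedMatrix:
    """Read a relaxed sequential PHYLIP 0/1 matrix (legacy MIX input).

    Direction metadata is not representable in PHYLIP; derived cells are
    tagged with the generic direction label ``derived``.
    """
    with open(path) as fh:
        header = fh.readline().split()
        ntax, nchar = int(header[0]), int(header[1])
        names, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip().replace(" ", "")
            if len(seq) != nchar:
                raise ValueError(f"taxon {name!r}: expected {nchar} characters, got {len(seq)}")
            names.append(name)
            rows.append([int(c) for c in seq])
    if len(names) != ntax:
        raise ValueError(f"expected {ntax} taxa, found {len(names)}")
    states = pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=pd.Index(names, name="specimen"),
        columns=[f"char{i+1}" for i in range(nchar)],
    )
    directions = states.astype(object).replace({0: "none", 1: "derived"})
    return PolarizedMatrix(states=states, directions=directions)
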