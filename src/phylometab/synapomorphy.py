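"""Synapomorphy extraction: mapping derived character states onto the cladogram.

A synapomorphy is a derived state (1) shared by all members of a clade and
absent outside it — the "shared derived characters" that delineate each
patient subgroup.  Two accounting modes are provided:

* ``strict`` (default): character c annotates node v iff every leaf under v is
  derived and every patient leaf outside v is ancestral ("unique and
  unreversed").  Single-specimen derived states (autapomorphies) are reported
  in a separate per-specimen table, never as clade labels.
* ``reconstructed``: ancestral states are reconstructed by a minimum-change
  (two-state Sankoff) pass with ACCTRAN or DELTRAN tie resolution, the root
  being fixed all-ancestral; c annotates v iff a 0->1 change lies on v's stem
  edge.  Homoplasious characters may then annotate several nodes.

On homoplasy-free matrices the two modes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import trees as T
from .parsimony import Cladogram
from .trees import Unrooted


def index_nodes(rooted) -> list[tuple[str, object, frozenset]]:
    """Preorder list of internal nodes: (node_id, subtree, leaf set).

    IDs are ``n0`` (root), ``n1``, ... in preorder; leaves keep their labels.
    """
    out = []
    counter = [0]

    def walk(node):
        if isinstance(node, str):
            return
        nid = f"n{counter[0]}"
        counter[0] += 1
        out.append((nid, node, T.leaf_set(node)))
        for child in node:
            walk(child)

    walk(rooted)
    return out


@dataclass
class StateReconstruction:
    """Minimum-change ancestral states with the root fixed all-ancestral."""

    node_states: pd.DataFrame      # rows: node ids + leaf labels; columns: characters
    changes: pd.DataFrame          # columns: node (child end of edge), character, from, to
    resolution: str

    @property
    def n_changes(self) -> int:
        return len(self.changes)


def reconstruct_states(clad: Cladogram, matrix, resolution: str = "acctran") -> StateReconstruction:
    """Assign a 0/1 state to every node of a rooted cladogram, per character.

    Ties in the minimum-change assignment are resolved toward early changes
    (``acctran``: prefer the state opposite the parent) or late changes
    (``deltran``: prefer the parent's state).  The number of implied changes
    equals the parsimony tree length.
    """
    if isinstance(clad, Unrooted):
        raise ValueError("reconstruct_states requires a rooted cladogram")
    if resolution not in ("acctran", "deltran"):
        raise ValueError(f"unknown resolution {resolution!r}")
    rooted = clad.tree if isinstance(clad, Cladogram) else clad
    states = matrix.states if hasattr(matrix, "states") else matrix
    leaf_arr = {str(n): r for n, r in zip(states.index, states.to_numpy(np.int64))}
    nchar = states.shape[1]
    BIG = np.int64(10**9)

    cost: dict[str, np.ndarray] = {}
    children: dict[str, list[str]] = {}
    counter = [0]  # preorder ids, matching index_nodes

    def down_pre(node) -> str:
        if isinstance(node, str):
            row = leaf_arr[node]
            cost[node] = np.stack([np.where(row == 0, 0, BIG), np.where(row == 1, 0, BIG)])
            children[node] = []
            return node
        nid = f"n{counter[0]}"
        counter[0] += 1
        kids = [down_pre(c) for c in node]
        total = np.zeros((2, nchar), dtype=np.int64)
        for k in kids:
            c = cost[k]
            total += np.minimum(c, c[::-1] + 1)
        cost[nid] = total
        children[nid] = kids
        return nid

    root = down_pre(rooted)

    assign: dict[str, np.ndarray] = {root: np.zeros(nchar, dtype=np.int64)}
    stack = [root]
    while stack:
        u = stack.pop()
        pstate = assign[u]
        for v in children[u]:
            c0 = cost[v][0] + (pstate != 0)
            c1 = cost[v][1] + (pstate != 1)
            tie = (1 - pstate) if resolution == "acctran" else pstate
            v_state = np.where(c0 < c1, 0, np.where(c1 < c0, 1, tie))
            assign[v] = v_state.astype(np.int64)
            stack.append(v)

    # edge changes: walk parent -> child
    change_rows = []
    def collect(u):
        for v in children[u]:
            diff = assign[u] != assign[v]
            for j in np.flatnonzero(diff):
                change_rows.append(
                    {
                        "node": v,
                        "character": states.columns[j],
                        "from": int(assign[u][j]),
                        "to": int(assign[v][j]),
                    }
                )
            collect(v)
    collect(root)

    node_states = pd.DataFrame(
        {k: v for k, v in assign.items()}, index=states.columns
    ).T
    node_states.index.name = "node"
    changes = pd.DataFrame(change_rows, columns=["node", "character", "from", "to"])
    return StateReconstruction(node_states=node_states, changes=changes, resolution=resolution)


@dataclass
class SynapomorphyTable:
    """Per-node synapomorphy lists for a rooted cladogram.

    ``entries`` maps internal nodes (clades of >= 2 patient specimens) to the
    characters that define them; ``autapomorphies`` lists single-specimen
    derived states; ``unplaced`` (strict mode) are characters whose derived
    leaf set matches no clade of the tree (homoplasy under this topology).
    """

    mode: str
    entries: pd.DataFrame          # columns: node_id, character, clade_size
    autapomorphies: pd.DataFrame   # columns: specimen, character
    clades: dict = field(default_factory=dict)  # node_id -> frozenset of leaves
    unplaced: list = field(default_factory=list)

    def counts(self) -> pd.Series:
        if self.entries.empty:
            return pd.Series(dtype=int)
        return self.entries.groupby("node_id")["character"].count()

    def characters_of(self, node_id: str) -> list[str]:
        return list(self.entries.loc[self.entries["node_id"] == node_id, "character"])

    def node_of_clade(self, leaves) -> str | None:
        target = frozenset(leaves)
        for nid, cl in self.clades.items():
            if cl == target:
                return nid
        return None


def _patient_leaves(clad: Cladogram) -> list[str]:
    return [x for x in clad.leaves if x != clad.root_label]


def extract_synapomorphies(clad: Cladogram, matrix, mode: str = "strict") -> SynapomorphyTable:
    """Per-node synapomorphy lists and counts for a rooted cladogram.

    The root taxon (hypothetical all-ancestral specimen or outgroup) is
    excluded from all clades; a character derived in every patient annotates
    the ingroup root node.
    """
    if mode not in ("strict", "reconstructed"):
        raise ValueError(f"unknown mode {mode!r}")
    states = matrix.states if hasattr(matrix, "states") else matrix
    patients = _patient_leaves(clad)
    sub = states.loc[patients]
    arr = sub.to_numpy()

    nodes = index_nodes(clad.tree)
    root_taxon = {clad.root_label}
    clades = {
        nid: ls - root_taxon
        for nid, node, ls in nodes
        if len(ls - root_taxon) >= 2
    }
    # drop the root node when it duplicates the ingroup-root clade
    by_set: dict[frozenset, str] = {}
    for nid, cl in clades.items():
        if cl not in by_set or int(nid[1:]) > int(by_set[cl][1:]):
            by_set[cl] = nid
    clades = {nid: cl for cl, nid in by_set.items()}

    entry_rows, auta_rows, unplaced = [], [], []
    if mode == "strict":
        for j, char in enumerate(states.columns):
            derived = frozenset(np.asarray(patients)[arr[:, j] == 1])
            if len(derived) == 0:
                continue
            if len(derived) == 1:
                auta_rows.append({"specimen": next(iter(derived)), "character": char})
                continue
            nid = by_set.get(derived)
            if nid is None:
                unplaced.append(char)
            else:
                entry_rows.append({"node_id": nid, "character": char, "clade_size": len(derived)})
    else:
        rec = reconstruct_states(clad, states, resolution="acctran")
        gains = rec.changes[(rec.changes["from"] == 0) & (rec.changes["to"] == 1)]
        for node, char in zip(gains["node"], gains["character"]):
            if node in clades:
                entry_rows.append(
                    {"node_id": node, "character": char, "clade_size": len(clades[node])}
                )
            elif node in set(patients):
                auta_rows.append({"specimen": node, "character": char})
            # gains on internal nodes subtending a single patient + root taxon
            # cannot occur with the root fixed ancestral

    entries = pd.DataFrame(entry_rows, columns=["node_id", "character", "clade_size"])
    autap = pd.DataFrame(auta_rows, columns=["specimen", "character"])
    return SynapomorphyTable(
        mode=mode, entries=entries, autapomorphies=autap, clades=clades, unplaced=unplaced
    )


def shared_synapomorphies(clad: Cladogram, clade_a, clade_b, matrix, mode: str = "strict") -> set[str]:
    """Characters derived across two clades (their shared biosignature).

    ``clade_a`` / ``clade_b`` may be node ids from a :class:`SynapomorphyTable`
    or explicit leaf collections.  Strict mode returns the characters derived
    in *all* leaves of both clades; reconstructed mode returns the characters
    gained on the stem edge of their most recent common ancestor.
    """
    states = matrix.states if hasattr(matrix, "states") else matrix
    nodes = index_nodes(clad.tree)
    by_id = {nid: ls for nid, _, ls in nodes}

    def resolve(c) -> frozenset:
        if isinstance(c, str) and c in by_id:
            return by_id[c] - {clad.root_label}
        return frozenset(c)

    A, B = resolve(clade_a), resolve(clade_b)
    missing = (A | B) - set(clad.leaves)
    if missing:
        raise KeyError(f"leaves not in this cladogram: {sorted(missing)}")
    if mode == "strict":
        both = sorted(A | B)
        sub = states.loc[both].to_numpy()
        mask = (sub == 1).all(axis=0)
        return set(states.columns[mask])
    # reconstructed: gains on the MRCA stem
    mrca_id, mrca_size = None, None
    for nid, _, ls in nodes:  # preorder: on ties the deeper node wins
        cl = ls - {clad.root_label}
        if A <= cl and B <= cl and (mrca_size is None or len(cl) <= mrca_size):
            mrca_id, mrca_size = nid, len(cl)
    rec = reconstruct_states(clad, states, resolution="acctran")
    gains = rec.changes[
        (rec.changes["from"] == 0) & (rec.changes["to"] == 1) & (rec.changes["node"] == mrca_id)
    ]
    return set(gains["character"])


def annotated_newick(clad: Cladogram, table: SynapomorphyTable) -> str:
    """Newick with per-node synapomorphy counts as internal node labels."""
    counts = table.counts()
    nodes = index_nodes(clad.tree)
    lookup = {}
    for nid, node, _ in nodes:
        lookup[id(node)] = nid

    def render(node):
        if isinstance(node, str):
            return node
        nid = lookup[id(node)]
        c = int(counts.get(nid, 0))
        return "(" + ",".join(render(ch) for ch in node) + ")" + f"{nid}_{c}"

    return render(clad.tree) + ";"


def synapomorphy_export(
    clad: Cladogram, table: SynapomorphyTable, feature_meta=None, directions=None
) -> pd.DataFrame:
    """Long-format export: node_id, character, clade size, m/z, RT, direction."""
    out = table.entries.copy()
    if feature_meta is not None:
        out = out.join(feature_meta[["mz", "rt"]], on="character")
    if directions is not None:
        def majority(char):
            nid = out.loc[out["character"] == char, "node_id"].iloc[0]
            members = sorted(table.clades[nid])
            vals = directions.loc[members, char]
            vals = vals[vals != "none"]
            return vals.mode().iloc[0] if len(vals) else "none"

        out["direction"] = [majority(c) for c in out["character"]]
    return out
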