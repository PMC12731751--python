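"""Lightweight phylogenetic tree primitives.

Trees are nested tuples: a leaf is its label (``str``), an internal node is a
tuple of child subtrees (binary during search; strict-consensus trees may hold
polytomies).  An *unrooted* binary tree on ``n >= 3`` leaves is represented as
:class:`Unrooted` — a designated base leaf plus a rooted binary tuple over the
remaining leaves; the base leaf is attached to the root of that tuple.  This is
the classic "root at a leaf" encoding: it makes unrooted topologies hashable,
canonicalizable, and cheap to enumerate by sequential taxon insertion.

Interoperability with dendropy (Newick, Robinson-Foulds) lives in
:mod:`phylometab.parsimony`; this module is dependency-free on purpose so the
search inner loops stay fast.
"""

from __future__ import annotations

import itertools
from typing import Iterator, NamedTuple

Node = "str | tuple"  # informal alias: leaf label or tuple of Nodes


class Unrooted(NamedTuple):
    """Unrooted binary tree: a base leaf joined to the root of ``rest``."""

    base: str
    rest: tuple | str


def leaves(node) -> tuple:
    """Leaf labels of a rooted tuple-tree, left-to-right."""
    if isinstance(node, str):
        return (node,)
    out = []
    for child in node:
        out.extend(leaves(child))
    return tuple(out)


def leaf_set(node) -> frozenset:
    return frozenset(leaves(node))


def unrooted_leaves(u: Unrooted) -> frozenset:
    return leaf_set(u.rest) | {u.base}


def _min_leaf(node) -> str:
    if isinstance(node, str):
        return node
    return min(_min_leaf(c) for c in node)


def canonical_rooted(node):
    """Canonical form of a rooted tree: children sorted by their minimum leaf."""
    if isinstance(node, str):
        return node
    kids = sorted((canonical_rooted(c) for c in node), key=_min_leaf)
    return tuple(kids)


def canonical_unrooted(u: Unrooted) -> Unrooted:
    """Canonical form of an unrooted tree: rebased at the smallest leaf label.

    Two :class:`Unrooted` values describe the same unrooted topology iff their
    canonical forms are equal.
    """
    lo = min(unrooted_leaves(u))
    if u.base != lo:
        u = rebase(u, lo)
    return Unrooted(u.base, canonical_rooted(u.rest))


def insertions(node, x) -> Iterator:
    """All trees obtained by attaching subtree ``x`` on an edge of ``node``.

    Attachment "above" ``node`` itself is included, so a tree with m leaves
    yields 2m - 1 results — one per edge of the corresponding unrooted tree.
    """
    yield (node, x)
    if not isinstance(node, str):
        a, b = node
        for na in insertions(a, x):
            yield (na, b)
        for nb in insertions(b, x):
            yield (a, nb)


def enumerate_unrooted(labels) -> Iterator[Unrooted]:
    """Enumerate all distinct unrooted binary topologies over ``labels``.

    Sequential insertion; yields (2n-5)!! topologies for n labels, each once.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels for an unrooted topology")
    base = labels[0]

    def grow(rest, remaining):
        if not remaining:
            yield Unrooted(base, rest)
            return
        x, tail = remaining[0], remaining[1:]
        for bigger in insertions(rest, x):
            yield from grow(bigger, tail)

    yield from grow(labels[1], labels[2:])


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — number of unrooted binary topologies on n >= 3 leaves."""
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out


# ---------------------------------------------------------------------------
# adjacency conversion / rebasing


def _to_adjacency(u: Unrooted):
    counter = itertools.count()
    adj: dict[int, list[int]] = {}
    label: dict[int, str] = {}

    def link(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def build(node) -> int:
        nid = next(counter)
        adj.setdefault(nid, [])
        if isinstance(node, str):
            label[nid] = node
        else:
            for child in node:
                link(nid, build(child))
        return nid

    rid = build(u.rest)
    bid = next(counter)
    adj.setdefault(bid, [])
    label[bid] = u.base
    link(rid, bid)
    return adj, label, bid


def rebase(u: Unrooted, new_base: str) -> Unrooted:
    """Re-express the same unrooted topology with a different base leaf."""
    if new_base == u.base:
        return u
    adj, label, _ = _to_adjacency(u)
    try:
        start = next(i for i, lab in label.items() if lab == new_base)
    except StopIteration:
        raise KeyError(f"leaf {new_base!r} not in tree") from None

    def extract(nid, parent):
        if nid in label and nid != start:
            return label[nid]
        kids = [extract(c, nid) for c in adj[nid] if c != parent]
        if len(kids) == 1:  # old base leaf position collapses
            return kids[0]
        return tuple(kids)

    (root_neighbor,) = adj[start]
    return Unrooted(new_base, extract(root_neighbor, start))


def bipartitions(u: Unrooted) -> set[frozenset]:
    """Non-trivial splits, each as the leaf set on the side away from the base."""
    out: set[frozenset] = set()

    def walk(node, is_root):
        if isinstance(node, str):
            return
        if not is_root:
            out.add(leaf_set(node))
        for child in node:
            walk(child, False)

    walk(u.rest, True)
    return out


def rooted_clades(node, include_root: bool = False) -> set[frozenset]:
    """Leaf sets of the internal nodes of a rooted tree (root excluded by default)."""
    out: set[frozenset] = set()

    def walk(n, is_root):
        if isinstance(n, str):
            return
        if include_root or not is_root:
            out.add(leaf_set(n))
        for child in n:
            walk(child, False)

    walk(node, True)
    return out


def to_newick(node, suffix: str = ";") -> str:
    """Newick string of a rooted tuple-tree (labels written verbatim)."""

    def render(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(render(c) for c in n) + ")"

    return render(node) + suffix


def unrooted_to_newick(u: Unrooted) -> str:
    """Newick of an unrooted tree as a basal trifurcation (base leaf first)."""
    rest = u.rest
    if isinstance(rest, str):
        inner = [u.base, rest]
    else:
        inner = [u.base, *rest]

    def render(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(render(c) for c in n) + ")"

    return "(" + ",".join(render(c) for c in inner) + ");"
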