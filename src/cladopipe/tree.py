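"""Unrooted leaf-labelled trees and the moves the parsimony pipeline needs.

Trees are stored unrooted (parsimony length is rooting-invariant); a display
rooting on an outgroup is applied only when writing Newick.  Leaves are
integer ids equal to the index of their label in ``taxa``; internal node ids
are >= ``len(taxa)`` and carry no meaning.  A topology is identified by its
set of nontrivial bipartitions, encoded as integer bitmasks over leaf ids,
canonically oriented as the side *not* containing the lowest-numbered leaf.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "PhyloTree",
    "Bipartition",
    "Constraint",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "prune_taxa",
    "tbr_neighbors",
    "spr_neighbors",
    "satisfies_constraint",
    "displays_group",
    "tree_from_splits",
    "all_unrooted_topologies",
    "random_topology",
]


class PhyloTree:
    """Unrooted multifurcating tree over a fixed taxon name list.

    The leaf set may be a subset of ``taxa`` (partial trees occur during
    stepwise addition); absent taxa simply have no node.
    """

    __slots__ = ("taxa", "adj", "_splits", "_key")

    def __init__(self, taxa: Sequence[str], adj: dict):
        self.taxa = tuple(taxa)
        self.adj = {v: list(nbrs) for v, nbrs in adj.items()}
        self._splits = None
        self._key = None

    # -- basics ---------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def leaves(self) -> list:
        L = len(self.taxa)
        return sorted(v for v in self.adj if v < L)

    @property
    def n_leaves(self) -> int:
        L = len(self.taxa)
        return sum(1 for v in self.adj if v < L)

    def leaf_names(self) -> list:
        return [self.taxa[v] for v in self.leaves()]

    def is_leaf(self, v: int) -> bool:
        return v < len(self.taxa)

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def edges(self) -> Iterator[tuple]:
        for v, nbrs in self.adj.items():
            for u in nbrs:
                if v < u:
                    yield (v, u)

    def n_internal_edges(self) -> int:
        return sum(
            1 for v, u in self.edges()
            if not self.is_leaf(v) and not self.is_leaf(u)
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, self.adj)

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == (1 if self.is_leaf(v) else 3)
            for v, nbrs in self.adj.items()
        )

    def new_internal_id(self) -> int:
        return max(max(self.adj), len(self.taxa) - 1) + 1

    def _invalidate(self) -> None:
        self._splits = None
        self._key = None

    # -- mutation (used by builders; public surface is functional) ------------

    def add_edge(self, u: int, v: int) -> None:
        self.adj.setdefault(u, []).append(v)
        self.adj.setdefault(v, []).append(u)
        self._invalidate()

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self._invalidate()

    def normalize(self) -> "PhyloTree":
        """Suppress degree-2 internal nodes, drop bare internals, in place."""
        changed = True
        while changed:
            changed = False
            for v in list(self.adj):
                if self.is_leaf(v):
                    continue
                deg = len(self.adj[v])
                if deg == 2:
                    a, b = self.adj[v]
                    self.remove_edge(v, a)
                    self.remove_edge(v, b)
                    del self.adj[v]
                    self.add_edge(a, b)
                    changed = True
                elif deg <= 1:
                    for u in list(self.adj[v]):
                        self.remove_edge(v, u)
                    del self.adj[v]
                    changed = True
        self._invalidate()
        return self

    # -- splits ---------------------------------------------------------------

    def leafset_mask(self) -> int:
        m = 0
        for v in self.leaves():
            m |= 1 << v
        return m

    def splits(self) -> frozenset:
        """Nontrivial bipartitions as canonical masks (ref leaf excluded)."""
        if self._splits is not None:
            return self._splits
        leaves = self.leaves()
        if len(leaves) < 4:
            self._splits = frozenset()
            return self._splits
        ref = leaves[0]
        out = []
        # iterative postorder from ref's neighbour, never descending into ref
        root = self.adj[ref][0]
        mask = {}
        stack = [(root, ref, False)]
        while stack:
            v, parent, done = stack.pop()
            if self.is_leaf(v):
                mask[v] = 1 << v
                continue
            if not done:
                stack.append((v, parent, True))
                for u in self.adj[v]:
                    if u != parent:
                        stack.append((u, v, False))
            else:
                m = 0
                for u in self.adj[v]:
                    if u != parent:
                        m |= mask[u]
                mask[v] = m
        n = len(leaves)
        for v, parent in [(v, p) for (v, p, d) in _edge_iter(self, root, ref)]:
            m = mask[v]
            c = m.bit_count()
            if 2 <= c <= n - 2:
                out.append(m)
        self._splits = frozenset(out)
        return self._splits

    def topology_key(self):
        if self._key is None:
            self._key = (self.leafset_mask(), self.splits())
        return self._key

    def same_topology(self, other: "PhyloTree") -> bool:
        return self.taxa == other.taxa and self.topology_key() == other.topology_key()

    def __repr__(self) -> str:
        return f"<PhyloTree {self.n_leaves} leaves, {len(self.splits()) if self.n_leaves >= 4 else 0} internal splits>"


def _edge_iter(tree: PhyloTree, root: int, ref: int):
    """(node, parent) pairs for every edge below ``root``, excluding ref."""
    stack = [(root, ref)]
    while stack:
        v, parent = stack.pop()
        if v != root:
            yield (v, parent, None)
        if not tree.is_leaf(v):
            for u in tree.adj[v]:
                if u != parent:
                    stack.append((u, v))


@dataclass(frozen=True)
class Bipartition:
    """Canonical split: the leaf block not containing the reference taxon."""

    mask: int
    taxa: tuple

    def group(self) -> tuple:
        return tuple(
            self.taxa[i] for i in range(len(self.taxa)) if self.mask >> i & 1
        )

    def size(self) -> int:
        return self.mask.bit_count()

    def __str__(self) -> str:
        return "{" + ",".join(self.group()) + "}"


@dataclass(frozen=True)
class Constraint:
    """Monophyly constraint: groups of taxon names, enforced or forbidden.

    ``enforce`` requires every group to appear as a clade (some edge's
    bipartition isolates exactly that group); ``forbid`` is the negation.
    """

    groups: tuple
    mode: str = "enforce"

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(frozenset(g) for g in self.groups))
        if self.mode not in ("enforce", "forbid"):
            raise ValueError(f"unknown constraint mode {self.mode!r}")
        for g in self.groups:
            if len(g) < 2:
                raise ValueError("constraint group needs >= 2 members")


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy; serialization is a direct traversal)
# ---------------------------------------------------------------------------

def parse_newick(text: str, taxa: Optional[Sequence[str]] = None) -> PhyloTree:
    """Parse one Newick tree; returns an unrooted, normalized PhyloTree.

    ``taxa`` fixes the label-to-id mapping (e.g. the matrix taxon order);
    unknown labels raise ``ValueError``.  Without it, labels are taken in
    order of appearance.
    """
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    if taxa is None:
        taxa = labels
    index = {name: i for i, name in enumerate(taxa)}
    for lab in labels:
        if lab not in index:
            raise ValueError(f"leaf label {lab!r} not in taxon list")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in newick")

    next_id = len(taxa)
    ids = {}
    adj: dict = {}

    def node_id(nd):
        nonlocal next_id
        if nd not in ids:
            if nd.is_leaf():
                ids[nd] = index[nd.taxon.label]
            else:
                ids[nd] = next_id
                next_id += 1
            adj.setdefault(ids[nd], [])
        return ids[nd]

    for nd in dtree.preorder_node_iter():
        for ch in nd.child_nodes():
            u, v = node_id(nd), node_id(ch)
            adj[u].append(v)
            adj[v].append(u)
    tree = PhyloTree(taxa, adj)
    tree.normalize()
    return tree


def parse_newick_list(text: str, taxa: Optional[Sequence[str]] = None) -> list:
    """One tree per non-empty line."""
    return [
        parse_newick(line, taxa)
        for line in text.splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]


def write_newick(tree: PhyloTree, outgroup: Optional[str] = None) -> str:
    """Serialize; the basal trifurcation (or the outgroup's attachment) is
    written first so the string displays the conventional rooting."""
    leaves = tree.leaves()
    if not leaves:
        raise ValueError("empty tree")
    if len(leaves) == 1:
        return tree.taxa[leaves[0]] + ";"
    ref = tree.taxa.index(outgroup) if outgroup is not None else leaves[0]
    if ref not in tree.adj:
        raise ValueError(f"outgroup {outgroup!r} not a leaf of this tree")
    top = tree.adj[ref][0]
    if tree.is_leaf(top):  # two-leaf tree
        return f"({_nwk_label(tree, ref)},{_nwk_label(tree, top)});"

    def render(v: int, parent: int) -> str:
        if tree.is_leaf(v):
            return _nwk_label(tree, v)
        parts = [render(u, v) for u in tree.adj[v] if u != parent]
        return "(" + ",".join(parts) + ")"

    parts = [_nwk_label(tree, ref)] + [
        render(u, top) for u in tree.adj[top] if u != ref
    ]
    return "(" + ",".join(parts) + ");"


def _nwk_label(tree: PhyloTree, v: int) -> str:
    name = tree.taxa[v]
    if any(ch in name for ch in "(),:;[] '\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


# ---------------------------------------------------------------------------
# split algebra
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> set:
    """Nontrivial bipartitions, one per internal edge."""
    return {Bipartition(m, tree.taxa) for m in tree.splits()}


def splits_compatible(m1: int, m2: int) -> bool:
    """Canonical masks (sharing the excluded reference leaf) are compatible
    iff nested or disjoint."""
    inter = m1 & m2
    return inter == 0 or inter == m1 or inter == m2


def tree_from_splits(taxa: Sequence[str], leaf_ids: Iterable[int],
                     splits: Iterable[int]) -> PhyloTree:
    """Build the (unique) unrooted tree displaying exactly ``splits``.

    Canonical masks form a laminar family, so the clusters nest into a
    hierarchy directly.
    """
    leaf_ids = sorted(leaf_ids)
    clusters = sorted(set(splits), key=lambda m: m.bit_count())
    for a, b in itertools.combinations(clusters, 2):
        if not splits_compatible(a, b):
            raise ValueError("incompatible split set")
    next_id = len(taxa)
    root = next_id
    next_id += 1
    node_of = {}
    adj: dict = {root: []}
    # parent of a cluster: smallest strictly containing cluster, else root
    for i, m in enumerate(clusters):
        node_of[m] = next_id
        next_id += 1
        adj[node_of[m]] = []
    for i, m in enumerate(clusters):
        parent = root
        for big in clusters[i + 1:]:
            if m & big == m and m != big:
                parent = node_of[big]
                break
        adj[parent].append(node_of[m])
        adj[node_of[m]].append(parent)
    # attach each leaf to the smallest cluster containing it
    for v in leaf_ids:
        parent = root
        for m in clusters:
            if m >> v & 1:
                parent = node_of[m]
                break
        adj.setdefault(v, []).append(parent)
        adj[parent].append(v)
    tree = PhyloTree(taxa, adj)
    tree.normalize()
    return tree


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_taxa(tree: PhyloTree, drop: Iterable) -> PhyloTree:
    """Induced subtree after removing ``drop`` (names or leaf ids); degree-2
    nodes suppressed.  Refuses to prune below 3 leaves."""
    drop_ids = set()
    for d in drop:
        drop_ids.add(tree.taxa.index(d) if isinstance(d, str) else d)
    if not drop_ids:
        return tree.copy()
    leaves = set(tree.leaves())
    if not drop_ids <= leaves:
        raise ValueError("cannot prune taxa absent from the tree")
    if len(leaves - drop_ids) < 3:
        raise ValueError("pruning would leave fewer than 3 leaves")
    out = tree.copy()
    for v in drop_ids:
        u = out.adj[v][0]
        out.remove_edge(v, u)
        del out.adj[v]
    out.normalize()
    return out


# ---------------------------------------------------------------------------
# rearrangement moves
# ---------------------------------------------------------------------------

def _component(tree: PhyloTree, start: int, blocked: int) -> set:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in tree.adj[v]:
            if u != blocked and u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _side_subtree(tree: PhyloTree, nodes: set) -> PhyloTree:
    sub = PhyloTree(tree.taxa, {v: [u for u in tree.adj[v] if u in nodes]
                                for v in nodes})
    sub.normalize()
    return sub


def _attachment_points(sub: PhyloTree) -> list:
    """Where a reconnection can land: every edge, or the lone leaf itself."""
    if len(sub.adj) == 1:
        (v,) = sub.adj
        return [(v,)]
    return [e for e in sub.edges()]


def _join(tree_a: PhyloTree, tree_b: PhyloTree, pa, pb) -> PhyloTree:
    adj = {v: list(n) for v, n in tree_a.adj.items()}
    for v, n in tree_b.adj.items():
        adj[v] = list(n)
    out = PhyloTree(tree_a.taxa, adj)
    ends = []
    for point in (pa, pb):
        if len(point) == 1:
            ends.append(point[0])
        else:
            u, v = point
            w = out.new_internal_id()
            out.remove_edge(u, v)
            out.add_edge(u, w)
            out.add_edge(w, v)
            ends.append(w)
    out.add_edge(ends[0], ends[1])
    return out


def tbr_neighbors(tree: PhyloTree, dedup: bool = True) -> Iterator[PhyloTree]:
    """All distinct topologies one bisection-and-reconnection away.

    Every edge is cut; each side is reduced to its induced subtree and the
    two are rejoined across every pair of attachment points.  The input
    topology itself is never yielded.
    """
    seen = {tree.topology_key()} if dedup else None
    for (u, v) in list(tree.edges()):
        nodes_u = _component(tree, u, blocked=v)
        nodes_v = _component(tree, v, blocked=u)
        side_u = _side_subtree(tree, nodes_u)
        side_v = _side_subtree(tree, nodes_v)
        for pa in _attachment_points(side_u):
            for pb in _attachment_points(side_v):
                nb = _join(side_u, side_v, pa, pb)
                if dedup:
                    key = nb.topology_key()
                    if key in seen:
                        continue
                    seen.add(key)
                yield nb


def spr_neighbors(tree: PhyloTree, dedup: bool = True) -> Iterator[PhyloTree]:
    """Subtree-prune-regraft neighbourhood: the pruned side is rejoined at
    its stub (where it was cut), only the regraft point on the other side
    varies.  A subset of the TBR neighbourhood."""
    seen = {tree.topology_key()} if dedup else None
    for (u, v) in list(tree.edges()):
        for cut, keep in ((u, v), (v, u)):
            nodes_cut = _component(tree, cut, blocked=keep)
            nodes_keep = _component(tree, keep, blocked=cut)
            side_cut = _side_subtree(tree, nodes_cut)
            side_keep = _side_subtree(tree, nodes_keep)
            points = _stub_point(side_cut, tree, cut)
            for pa in points:
                for pb in _attachment_points(side_keep):
                    nb = _join(side_cut, side_keep, pa, pb)
                    if dedup:
                        key = nb.topology_key()
                        if key in seen:
                            continue
                        seen.add(key)
                    yield nb


def _stub_point(side: PhyloTree, orig: PhyloTree, cut: int) -> list:
    """The attachment point of the pruned side corresponding to its old cut
    node: the node itself if it survived normalization, else the edge its
    two remaining neighbours collapsed onto."""
    if cut in side.adj:
        return [(cut,)]
    nbrs = [x for x in orig.adj[cut] if x in side.adj]
    if len(nbrs) == 2 and nbrs[1] in side.adj.get(nbrs[0], []):
        u, v = nbrs
        return [(u, v) if u < v else (v, u)]
    return []


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def _group_mask(tree: PhyloTree, group) -> int:
    m = 0
    for name in group:
        m |= 1 << tree.taxa.index(name)
    return m


def displays_group(tree: PhyloTree, group) -> bool:
    """True iff some edge's bipartition isolates exactly ``group``."""
    gmask = _group_mask(tree, group)
    present = tree.leafset_mask()
    gmask &= present
    if gmask.bit_count() < 2:
        raise ValueError("group needs >= 2 members present in the tree")
    if gmask == present:
        raise ValueError("group equal to the whole leaf set is not a split")
    if tree.n_leaves < 4:
        return True  # any 2-block of a 3-leaf star is trivially a clade
    ref = tree.leaves()[0]
    target = gmask if not (gmask >> ref & 1) else present ^ gmask
    return target in tree.splits()


def satisfies_constraint(tree: PhyloTree, constraint: Constraint) -> bool:
    ok = all(displays_group(tree, g) for g in constraint.groups)
    return ok if constraint.mode == "enforce" else not ok


def constraint_applicable(tree: PhyloTree, constraint: Constraint) -> bool:
    """Whether the constraint can be evaluated on this (possibly partial)
    tree: every group restricted to present leaves keeps >= 2 members and
    is not the whole leaf set."""
    present = set(tree.leaf_names())
    for g in constraint.groups:
        gp = g & present
        if len(gp) < 2 or gp == present:
            return False
    return True


def restricted_constraint(constraint: Constraint, present) -> Optional[Constraint]:
    """Constraint induced on a subset of taxa, or None when inapplicable.

    Forbid-mode constraints only apply once every group member is present
    (a subgroup being a clade says nothing about the full group)."""
    present = set(present)
    groups = []
    for g in constraint.groups:
        gp = g & present
        if constraint.mode == "forbid" and gp != g:
            return None
        if len(gp) < 2 or gp == present:
            if constraint.mode == "enforce":
                continue
            return None
        groups.append(gp)
    if not groups:
        return None
    return Constraint(tuple(groups), constraint.mode)


# ---------------------------------------------------------------------------
# topology generation
# ---------------------------------------------------------------------------

def all_unrooted_topologies(taxa: Sequence[str],
                            leaf_ids: Optional[Sequence[int]] = None
                            ) -> Iterator[PhyloTree]:
    """Every unrooted binary topology on the given leaves, by stepwise
    addition ((2n-5)!! trees; use only for small n)."""
    if leaf_ids is None:
        leaf_ids = list(range(len(taxa)))
    leaf_ids = list(leaf_ids)
    if len(leaf_ids) < 3:
        raise ValueError("need >= 3 leaves")
    a, b, c = leaf_ids[:3]
    hub = len(taxa)
    base = PhyloTree(taxa, {a: [hub], b: [hub], c: [hub], hub: [a, b, c]})
    stack = [(base, 3)]
    while stack:
        t, k = stack.pop()
        if k == len(leaf_ids):
            yield t
            continue
        leaf = leaf_ids[k]
        for (u, v) in list(t.edges()):
            nt = t.copy()
            w = nt.new_internal_id()
            nt.remove_edge(u, v)
            nt.add_edge(u, w)
            nt.add_edge(w, v)
            nt.add_edge(w, leaf)
            stack.append((nt, k + 1))


def random_topology(taxa: Sequence[str], rng,
                    leaf_ids: Optional[Sequence[int]] = None) -> PhyloTree:
    """Uniform random unrooted binary topology (random stepwise addition at a
    uniformly chosen edge is uniform over topologies)."""
    if leaf_ids is None:
        leaf_ids = list(range(len(taxa)))
    leaf_ids = list(leaf_ids)
    if len(leaf_ids) < 4:
        raise ValueError("need >= 4 leaves")
    a, b, c = leaf_ids[:3]
    hub = len(taxa)
    t = PhyloTree(taxa, {a: [hub], b: [hub], c: [hub], hub: [a, b, c]})
    for leaf in leaf_ids[3:]:
        edges = sorted(t.edges())
        u, v = edges[int(rng.integers(len(edges)))]
        w = t.new_internal_id()
        t.remove_edge(u, v)
        t.add_edge(u, w)
        t.add_edge(w, v)
        t.add_edge(w, leaf)
    return t
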