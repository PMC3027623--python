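"""Parsimony scoring, ensemble indices, ancestral state sets, rule-1 collapsing.

Two engines share the work.  A fast postorder kernel (:mod:`._kernels`)
returns per-character step counts for any tree, binary or not — that is what
heuristic search hammers on.  A slower vectorised Sankoff down/up dynamic
program computes, for every node and state, the optimal cost of the subtree
below and of the rest of the tree; from those tables come most-parsimonious
reconstruction (MPR) state sets, per-edge minimum/maximum change counts over
all MPRs, and hence unambiguous synapomorphies and rule-1 branch collapsing
("contract an internal branch iff its minimum optimised length over MPRs is
zero").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import INF, steps_kernel
from .matrix import ORDERED, CharacterMatrix
from .tree import PhyloTree

__all__ = [
    "EncodedMatrix",
    "encode_matrix",
    "tree_steps",
    "character_length",
    "tree_length",
    "LengthReport",
    "ancestral_states",
    "MprSets",
    "MprChange",
    "collapse_zero_length",
    "SankoffTables",
    "sankoff_tables",
]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

class EncodedMatrix:
    """Array view of a character matrix ready for the scoring kernels.

    Characters are the matrix's *active* characters, in matrix order.
    ``weights`` may be replaced per-analysis (resampling passes integer
    multiplicities through here rather than materialising new matrices).
    """

    def __init__(self, matrix: CharacterMatrix, include_inactive: bool = False):
        self.matrix = matrix
        self.taxa = tuple(matrix.taxon_names)
        chars = [
            c for c in matrix.characters if include_inactive or c.active
        ]
        self.char_indices = np.array([c.index for c in chars], dtype=np.int64)
        self.n_chars = len(chars)
        self.ordered = np.array([c.kind == ORDERED for c in chars], dtype=bool)
        self.n_states = np.array([c.n_states for c in chars], dtype=np.int64)
        self.weights = np.array([c.weight for c in chars], dtype=np.float64)

        L = matrix.n_taxa
        masks = np.zeros((L, self.n_chars), dtype=np.int64)
        for i in range(L):
            row = matrix.cells[i]
            for k, c in enumerate(chars):
                masks[i, k] = row[c.index].mask()
        self.masks = masks

        self.u_pos = np.flatnonzero(~self.ordered)
        self.o_pos = np.flatnonzero(self.ordered)
        self.umask = np.ascontiguousarray(masks[:, self.u_pos])
        self.omask = np.ascontiguousarray(masks[:, self.o_pos])
        self.uK = self.n_states[self.u_pos].copy()
        self.oK = self.n_states[self.o_pos].copy()
        self._bound_cache: dict = {}

    def with_weights(self, weights: np.ndarray) -> "EncodedMatrix":
        out = EncodedMatrix.__new__(EncodedMatrix)
        out.__dict__ = dict(self.__dict__)
        out.weights = np.asarray(weights, dtype=np.float64)
        return out

    # -- conceivable-step bounds (leaf-set dependent) -----------------------

    def step_bounds(self, leaf_ids: Sequence[int]):
        """(min conceivable steps, max steps on a star tree) per character."""
        key = 0
        for v in leaf_ids:
            key |= 1 << v
        if key in self._bound_cache:
            return self._bound_cache[key]
        rows = np.fromiter(leaf_ids, dtype=np.int64)
        mins = np.zeros(self.n_chars, dtype=np.int64)
        stars = np.zeros(self.n_chars, dtype=np.int64)
        for k in range(self.n_chars):
            sub = self.masks[rows, k]
            K = int(self.n_states[k])
            if self.ordered[k]:
                lo = np.array([_mask_min(m) for m in sub])
                hi = np.array([_mask_max(m) for m in sub])
                mins[k] = max(0, int(lo.max() - hi.min()))
                stars[k] = min(
                    int(np.maximum(0, np.maximum(lo - s, s - hi)).sum())
                    for s in range(K)
                )
            else:
                mins[k] = _min_state_cover(sub, K) - 1
                counts = [int(((sub >> s) & 1).sum()) for s in range(K)]
                stars[k] = len(sub) - max(counts)
        self._bound_cache[key] = (mins, stars)
        return mins, stars


def _mask_min(m: int) -> int:
    return (int(m) & -int(m)).bit_length() - 1


def _mask_max(m: int) -> int:
    return int(m).bit_length() - 1


def _min_state_cover(masks: np.ndarray, K: int) -> int:
    """Smallest number of states hitting every leaf's state set."""
    from itertools import combinations

    for size in range(1, K + 1):
        for combo in combinations(range(K), size):
            sel = 0
            for s in combo:
                sel |= 1 << s
            if np.all(masks & sel):
                return size
    return K


def encode_matrix(matrix: CharacterMatrix,
                  include_inactive: bool = False) -> EncodedMatrix:
    return EncodedMatrix(matrix, include_inactive=include_inactive)


def _as_encoded(matrix) -> EncodedMatrix:
    if isinstance(matrix, EncodedMatrix):
        return matrix
    return EncodedMatrix(matrix)


# ---------------------------------------------------------------------------
# postorder arrays and kernel dispatch
# ---------------------------------------------------------------------------

def postorder_arrays(tree: PhyloTree):
    """CSR postorder arrays rooted at the lowest present leaf.

    Returns ``(child_ptr, child_idx, leaf_row, node_ids)`` with nodes in
    postorder positions and the reference leaf (which has one child) last.
    """
    leaves = tree.leaves()
    if len(leaves) < 3:
        raise ValueError("scoring requires >= 3 leaves")
    ref = leaves[0]
    order: list = []
    stack = [(ref, -1, False)]
    while stack:
        v, parent, done = stack.pop()
        children = [u for u in tree.adj[v] if u != parent]
        if done or not children:
            order.append(v)
            continue
        stack.append((v, parent, True))
        for u in children:
            stack.append((u, v, False))
    pos = {v: i for i, v in enumerate(order)}
    n = len(order)
    child_ptr = np.zeros(n + 1, dtype=np.int64)
    child_idx = np.zeros(max(n - 1, 1), dtype=np.int64)
    leaf_row = np.full(n, -1, dtype=np.int64)
    parents = {ref: -1}
    stack2 = [(ref, -1)]
    kids: dict = {v: [] for v in order}
    while stack2:
        v, parent = stack2.pop()
        for u in tree.adj[v]:
            if u != parent:
                kids[v].append(u)
                stack2.append((u, v))
    ptr = 0
    for i, v in enumerate(order):
        child_ptr[i] = ptr
        for u in kids[v]:
            child_idx[ptr] = pos[u]
            ptr += 1
        if tree.is_leaf(v):
            leaf_row[i] = v
    child_ptr[n] = ptr
    return child_ptr, child_idx, leaf_row, order


def tree_steps(tree: PhyloTree, matrix) -> np.ndarray:
    """Per-character parsimony steps (active characters, matrix order)."""
    enc = _as_encoded(matrix)
    child_ptr, child_idx, leaf_row, _ = postorder_arrays(tree)
    out_u, out_o = steps_kernel(
        child_ptr, child_idx, leaf_row, enc.umask, enc.uK, enc.omask, enc.oK
    )
    steps = np.zeros(enc.n_chars, dtype=np.int64)
    steps[enc.u_pos] = out_u
    steps[enc.o_pos] = out_o
    return steps


def character_length(tree: PhyloTree, matrix: CharacterMatrix,
                     char_index: int) -> int:
    """Minimal steps for one character (unordered: state changes; ordered:
    summed interval distance).  Missing cells are a free choice."""
    if not 0 <= char_index < matrix.n_characters:
        raise IndexError(f"character index {char_index} out of range")
    enc = encode_matrix(matrix, include_inactive=True)
    pos = int(np.flatnonzero(enc.char_indices == char_index)[0])
    return int(tree_steps(tree, enc)[pos])


@dataclass
class LengthReport:
    """Tree length with ensemble indices.

    ``ci``/``ri`` are computed over all active characters (the conventional
    headline values); the ``*_informative`` variants drop characters that
    cannot vary in length across topologies.
    """

    length: float
    per_character: np.ndarray
    char_indices: np.ndarray
    min_steps: int
    max_star_steps: int
    ci: float
    ri: float
    ci_informative: float
    ri_informative: float

    @property
    def is_integral(self) -> bool:
        return float(self.length).is_integer()


def tree_length(tree: PhyloTree, matrix) -> LengthReport:
    """Score a tree: L, per-character steps, and CI/RI ensemble indices."""
    enc = _as_encoded(matrix)
    steps = tree_steps(tree, enc)
    w = enc.weights
    L = float(np.dot(w, steps))
    mins, stars = enc.step_bounds(tree.leaves())
    M = float(np.dot(w, mins))
    G = float(np.dot(w, stars))
    ci, ri = _ensemble(L, M, G)
    informative = stars > mins
    Li = float(np.dot(w[informative], steps[informative]))
    Mi = float(np.dot(w[informative], mins[informative]))
    Gi = float(np.dot(w[informative], stars[informative]))
    ci_i, ri_i = _ensemble(Li, Mi, Gi)
    if L == 0:
        warnings.warn("tree length is 0; CI/RI undefined", stacklevel=2)
    return LengthReport(
        length=L if not L.is_integer() else int(L),
        per_character=steps,
        char_indices=enc.char_indices,
        min_steps=int(M) if M.is_integer() else M,
        max_star_steps=int(G) if G.is_integer() else G,
        ci=ci,
        ri=ri,
        ci_informative=ci_i,
        ri_informative=ri_i,
    )


def _ensemble(L: float, M: float, G: float):
    ci = M / L if L > 0 else float("nan")
    ri = (G - L) / (G - M) if G > M else float("nan")
    return ci, ri


# ---------------------------------------------------------------------------
# Sankoff down/up tables (MPR machinery)
# ---------------------------------------------------------------------------

class SankoffTables:
    """Down (subtree) and up (rest-of-tree) cost tables for every node,
    vectorised over characters; state axis padded to the largest alphabet."""

    def __init__(self, tree, order, pos, parent, D, O, Wstep, L, char_indices):
        self.tree = tree
        self.order = order          # node ids, postorder, root (ref leaf) last
        self.pos = pos              # node id -> position
        self.parent = parent        # node id -> parent id (root -> -1)
        self.D = D                  # (n, C, K) subtree cost given node state
        self.O = O                  # (n, C, K) outside cost given *parent* state
        self.Wstep = Wstep          # (C, K, K) step distances
        self.L = L                  # (C,) optimal lengths
        self.char_indices = char_indices

    # -- queries ------------------------------------------------------------

    def node_state_sets(self, node: int) -> np.ndarray:
        """(C, K) boolean: states appearing in some MPR at this node."""
        i = self.pos[node]
        if self.parent[node] == -1:
            total = self.D[i]
        else:
            inc = (self.O[i][:, :, None] + self.Wstep).min(axis=1)
            total = self.D[i] + inc
        return total == self.L[:, None]

    def edge_step_range(self, node: int):
        """(min, max) steps on the edge above ``node`` over all MPRs; arrays
        of shape (C,)."""
        i = self.pos[node]
        A = self.O[i][:, :, None] + self.Wstep + self.D[i][:, None, :]
        opt = A == self.L[:, None, None]
        big = np.int64(INF)
        wmin = np.where(opt, self.Wstep, big).min(axis=(1, 2))
        wmax = np.where(opt, self.Wstep, -big).max(axis=(1, 2))
        return wmin, wmax

    def edge_optimal_pairs(self, node: int, char_pos: int):
        """Optimal (parent_state, child_state) pairs on the edge above
        ``node`` for one character position."""
        i = self.pos[node]
        A = (self.O[i][char_pos][:, None] + self.Wstep[char_pos]
             + self.D[i][char_pos][None, :])
        t, s = np.nonzero(A == self.L[char_pos])
        return list(zip(t.tolist(), s.tolist()))


def sankoff_tables(tree: PhyloTree, matrix,
                   char_positions: Optional[Sequence[int]] = None,
                   leafcost: Optional[np.ndarray] = None,
                   Wstep: Optional[np.ndarray] = None) -> SankoffTables:
    """Run the down/up dynamic program.

    By default costs come from the encoded matrix (0/1 for unordered,
    |i-j| for ordered).  ``leafcost``/``Wstep`` may be supplied directly
    (the continuous linear-parsimony reconstruction reuses this engine with
    a breakpoint grid).
    """
    enc = _as_encoded(matrix) if matrix is not None else None
    if leafcost is None:
        if char_positions is None:
            char_positions = np.arange(enc.n_chars)
        char_positions = np.asarray(char_positions, dtype=np.int64)
        K = int(enc.n_states[char_positions].max())
        C = len(char_positions)
        Wstep = np.zeros((C, K, K), dtype=np.int64)
        Wcost = np.zeros((C, K, K), dtype=np.int64)
        for ci, cp in enumerate(char_positions):
            k = int(enc.n_states[cp])
            if enc.ordered[cp]:
                grid = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            else:
                grid = 1 - np.eye(k, dtype=np.int64)
            Wstep[ci, :k, :k] = grid
            Wcost[ci, :k, :k] = grid
            Wcost[ci, k:, :] = INF
            Wcost[ci, :, k:] = INF
        masks = enc.masks[:, char_positions]
        states = np.arange(K)
        allowed = (masks[:, :, None] >> states[None, None, :]) & 1
        leafcost = np.where(allowed == 1, 0, INF).astype(np.int64)
        char_indices = enc.char_indices[char_positions]
    else:
        leafcost = np.asarray(leafcost)
        Wstep = np.asarray(Wstep)
        Wcost = Wstep.copy()
        char_indices = np.arange(leafcost.shape[1])
        C, K = leafcost.shape[1], leafcost.shape[2]

    child_ptr, child_idx, leaf_row, order = postorder_arrays(tree)
    n = len(order)
    C, K = leafcost.shape[1], leafcost.shape[2]
    big = INF if leafcost.dtype.kind in "iu" else np.inf
    D = np.zeros((n, C, K), dtype=leafcost.dtype)
    E = np.zeros((n, C, K), dtype=leafcost.dtype)  # edge cost above each node

    for i in range(n):
        lo, hi = child_ptr[i], child_ptr[i + 1]
        acc = np.zeros((C, K), dtype=leafcost.dtype)
        if leaf_row[i] >= 0:
            acc = acc + leafcost[leaf_row[i]]
        for k in range(lo, hi):
            ch = child_idx[k]
            acc = acc + E[ch]
        D[i] = np.minimum(acc, big)
        # cost of the edge to the (future) parent, as seen from the parent
        E[i] = np.minimum((Wcost + D[i][:, None, :]).min(axis=2), big)

    L = D[n - 1].min(axis=1)

    parent = {order[-1]: -1}
    kids: dict = {v: [] for v in order}
    for i in range(n):
        lo, hi = child_ptr[i], child_ptr[i + 1]
        for k in range(lo, hi):
            kids[order[i]].append(order[child_idx[k]])
            parent[order[child_idx[k]]] = order[i]

    O = np.zeros((n, C, K), dtype=leafcost.dtype)
    for i in range(n - 1, -1, -1):
        p = order[i]
        base = np.zeros((C, K), dtype=leafcost.dtype)
        if leaf_row[i] >= 0:
            base = base + leafcost[leaf_row[i]]
        if parent[p] != -1:
            Ohat = np.minimum((O[i][:, :, None] + Wcost).min(axis=1), big)
            base = base + Ohat
        ch_pos = [child_idx[k] for k in range(child_ptr[i], child_ptr[i + 1])]
        if ch_pos:
            tot = base
            for cp in ch_pos:
                tot = tot + E[cp]
            for cp in ch_pos:
                O[cp] = np.minimum(tot - E[cp], big)

    pos = {v: i for i, v in enumerate(order)}
    return SankoffTables(tree, order, pos, parent, D, O, Wstep, L, char_indices)


# ---------------------------------------------------------------------------
# ancestral states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MprChange:
    """A state transition on an edge, present in at least one MPR."""

    parent: int
    child: int
    parent_states: frozenset
    child_states: frozenset
    min_steps: int
    max_steps: int

    @property
    def unambiguous(self) -> bool:
        return self.min_steps > 0


@dataclass
class MprSets:
    """Union-over-MPRs state sets per node, plus the typed change list."""

    char_index: int
    length: int
    node_states: dict
    changes: list = field(default_factory=list)

    def unambiguous_changes(self) -> list:
        return [c for c in self.changes if c.unambiguous]


def ancestral_states(tree: PhyloTree, matrix,
                     char_index: int) -> MprSets:
    """States each node can take in some most-parsimonious reconstruction,
    with per-edge change flags ('unambiguous' = a change on that edge occurs
    in every MPR)."""
    enc = _as_encoded(matrix) if not isinstance(matrix, EncodedMatrix) else matrix
    hits = np.flatnonzero(enc.char_indices == char_index)
    if len(hits) == 0:
        raise IndexError(f"character index {char_index} not in encoding")
    cp = int(hits[0])
    tab = sankoff_tables(tree, enc, char_positions=[cp])
    node_states = {}
    for v in tab.order:
        sets = tab.node_state_sets(v)[0]
        node_states[v] = frozenset(int(s) for s in np.flatnonzero(sets))
    changes = []
    for v in tab.order[:-1]:
        wmin, wmax = tab.edge_step_range(v)
        if wmax[0] > 0:
            pairs = tab.edge_optimal_pairs(v, 0)
            changes.append(
                MprChange(
                    parent=tab.parent[v],
                    child=v,
                    parent_states=frozenset(t for t, _ in pairs),
                    child_states=frozenset(s for _, s in pairs),
                    min_steps=int(wmin[0]),
                    max_steps=int(wmax[0]),
                )
            )
    return MprSets(
        char_index=char_index,
        length=int(tab.L[0]),
        node_states=node_states,
        changes=changes,
    )


# ---------------------------------------------------------------------------
# rule-1 collapsing
# ---------------------------------------------------------------------------

def collapse_zero_length(tree: PhyloTree, matrix,
                         rule: str = "rule1") -> PhyloTree:
    """Contract internal edges whose minimum length over all MPRs is zero.

    Contraction is iterative — one edge at a time, recomputing the MPR
    tables after each — because contracting one unsupported edge can make
    another formerly-unsupported edge necessary; the one-at-a-time order
    (first collapsible edge in postorder) keeps tree length invariant.
    """
    if rule != "rule1":
        raise ValueError(f"unknown collapse rule {rule!r}")
    enc = _as_encoded(matrix)
    out = tree.copy()
    active_w = enc.weights > 0
    while out.n_leaves >= 4:
        tab = sankoff_tables(out, enc)
        target = None
        for v in tab.order[:-1]:
            p = tab.parent[v]
            if out.is_leaf(v) or out.is_leaf(p):
                continue
            wmin, _ = tab.edge_step_range(v)
            if not np.any(wmin[active_w] > 0):
                target = (p, v)
                break
        if target is None:
            break
        p, v = target
        out.remove_edge(p, v)
        for u in list(out.adj[v]):
            out.remove_edge(v, u)
            out.add_edge(p, u)
        del out.adj[v]
        out.normalize()
    return out
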