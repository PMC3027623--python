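"""Mapping traits onto trees and diagnosing clade synapomorphies.

Discrete traits (e.g. sacral configurations such as S1+S2, DS+S1+S2,
DS+S1+S2+CS) are optimised exactly like matrix characters: MPR state sets
per node and a typed change list, with changes on terminal branches flagged
as autapomorphies.  Continuous traits (e.g. femoral lateromedial shaft
width, FML, in cm — a body-size proxy) are reconstructed under linear
parsimony (Manhattan cost): per-node closed intervals spanning every optimal
assignment, computed on the breakpoint grid of observed values, where linear
parsimony optima always lie.  A squared-change reconstruction is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .parsimony import _as_encoded, sankoff_tables
from .tree import PhyloTree

__all__ = [
    "DiscreteTrait",
    "ContinuousTrait",
    "TraitChange",
    "TraitReconstruction",
    "SynapomorphyRecord",
    "map_discrete_trait",
    "reconstruct_continuous",
    "diagnose_clade",
]

SYNAPOMORPHY = "synapomorphy_unambiguous"
AMBIGUOUS = "ambiguous"
AUTAPOMORPHY = "autapomorphy"

_TOL = 1e-9


@dataclass
class DiscreteTrait:
    """Named multistate trait with labelled states and per-taxon scores
    (``None``/absent = unknown)."""

    name: str
    states: tuple
    observations: Dict[str, Optional[int]]
    ordered: bool = False

    def __post_init__(self):
        self.states = tuple(self.states)
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        for taxon, s in self.observations.items():
            if s is not None and not 0 <= s < len(self.states):
                raise ValueError(f"state {s} of {taxon!r} outside alphabet")


@dataclass
class ContinuousTrait:
    """Positive per-taxon measurements; absent taxa are treated as unknown."""

    name: str
    values: Dict[str, float]

    def __post_init__(self):
        for taxon, v in self.values.items():
            if not v > 0:
                raise ValueError(f"value for {taxon!r} must be > 0")


@dataclass(frozen=True)
class TraitChange:
    parent: int
    child: int
    from_states: tuple
    to_states: tuple
    flag: str


@dataclass
class TraitReconstruction:
    """Per-node optimal state sets (discrete) or closed intervals
    (continuous) with the change list and total cost."""

    trait: str
    cost: float
    node_states: Dict[int, frozenset] = field(default_factory=dict)
    node_intervals: Dict[int, tuple] = field(default_factory=dict)
    changes: List[TraitChange] = field(default_factory=list)

    def changes_with_flag(self, flag: str) -> list:
        return [c for c in self.changes if c.flag == flag]


# ---------------------------------------------------------------------------
# discrete traits
# ---------------------------------------------------------------------------

def _discrete_tables(tree: PhyloTree, trait: DiscreteTrait):
    K = len(trait.states)
    n_taxa = len(tree.taxa)
    leafcost = np.zeros((n_taxa, 1, K), dtype=np.int64)
    any_observed = False
    present = set(tree.leaf_names())
    for i, name in enumerate(tree.taxa):
        s = trait.observations.get(name)
        if s is None:
            continue
        if name in present:
            any_observed = True
        leafcost[i] = 1 << 28
        leafcost[i, 0, s] = 0
    if not any_observed:
        raise ValueError("trait has no observed state on this tree's leaves")
    if trait.ordered:
        W = np.abs(np.subtract.outer(np.arange(K), np.arange(K)))
    else:
        W = 1 - np.eye(K, dtype=np.int64)
    return sankoff_tables(tree, None, leafcost=leafcost,
                          Wstep=W[None].astype(np.int64))


def map_discrete_trait(tree: PhyloTree, trait: DiscreteTrait) -> TraitReconstruction:
    """MPR reconstruction of a discrete trait; terminal-branch changes are
    flagged autapomorphies, internal unambiguous changes synapomorphies."""
    tab = _discrete_tables(tree, trait)
    rec = TraitReconstruction(trait=trait.name, cost=float(tab.L[0]))
    for v in tab.order:
        sets = tab.node_state_sets(v)[0]
        rec.node_states[v] = frozenset(int(s) for s in np.flatnonzero(sets))
    for v in tab.order[:-1]:
        wmin, wmax = tab.edge_step_range(v)
        if wmax[0] <= 0:
            continue
        pairs = tab.edge_optimal_pairs(v, 0)
        unamb = wmin[0] > 0
        if tree.is_leaf(v):
            flag = AUTAPOMORPHY if unamb else AMBIGUOUS
        else:
            flag = SYNAPOMORPHY if unamb else AMBIGUOUS
        rec.changes.append(
            TraitChange(
                parent=tab.parent[v], child=v,
                from_states=tuple(sorted({t for t, _ in pairs})),
                to_states=tuple(sorted({s for _, s in pairs})),
                flag=flag,
            )
        )
    return rec


# ---------------------------------------------------------------------------
# continuous traits (linear parsimony intervals; squared-change option)
# ---------------------------------------------------------------------------

def reconstruct_continuous(tree: PhyloTree, trait: ContinuousTrait,
                           method: str = "linear") -> TraitReconstruction:
    """Ancestral reconstruction of a continuous trait.

    ``linear``: Manhattan-cost parsimony; node intervals span the union of
    optimal assignments (endpoints are observed values).  ``squared``:
    squared-change parsimony; each node gets a point estimate (the harmonic
    solution where every internal value is the mean of its neighbours).
    """
    present = set(tree.leaf_names())
    observed = {t: v for t, v in trait.values.items() if t in present}
    if len(observed) < 2:
        raise ValueError("need >= 2 observed leaves")
    if method == "squared":
        return _squared_change(tree, trait, observed)
    if method != "linear":
        raise ValueError(f"unknown method {method!r}")

    grid = np.array(sorted(set(observed.values())), dtype=np.float64)
    G = len(grid)
    n_taxa = len(tree.taxa)
    leafcost = np.zeros((n_taxa, 1, G), dtype=np.float64)
    for i, name in enumerate(tree.taxa):
        if name in observed:
            leafcost[i] = np.inf
            leafcost[i, 0, int(np.searchsorted(grid, observed[name]))] = 0.0
    W = np.abs(np.subtract.outer(grid, grid))[None]
    tab = sankoff_tables(tree, None, leafcost=leafcost, Wstep=W)
    L = float(tab.L[0])
    rec = TraitReconstruction(trait=trait.name, cost=L)
    for v in tab.order:
        i = tab.pos[v]
        if tab.parent[v] == -1:
            total = tab.D[i][0]
        else:
            inc = (tab.O[i][0][:, None] + W[0]).min(axis=0)
            total = tab.D[i][0] + inc
        opt = np.flatnonzero(total <= L + _TOL)
        rec.node_intervals[v] = (float(grid[opt[0]]), float(grid[opt[-1]]))
    for v in tab.order[:-1]:
        i = tab.pos[v]
        A = tab.O[i][0][:, None] + W[0] + tab.D[i][0][None, :]
        optm = A <= L + _TOL
        if not optm.any():
            continue
        wmin = W[0][optm].min()
        wmax = W[0][optm].max()
        if wmax <= _TOL:
            continue
        flag = (AUTAPOMORPHY if tree.is_leaf(v) else SYNAPOMORPHY) \
            if wmin > _TOL else AMBIGUOUS
        par_idx = np.flatnonzero(optm.any(axis=1))
        chi_idx = np.flatnonzero(optm.any(axis=0))
        rec.changes.append(
            TraitChange(
                parent=tab.parent[v], child=v,
                from_states=(float(grid[par_idx[0]]), float(grid[par_idx[-1]])),
                to_states=(float(grid[chi_idx[0]]), float(grid[chi_idx[-1]])),
                flag=flag,
            )
        )
    return rec


def _squared_change(tree, trait, observed) -> TraitReconstruction:
    """Each unconstrained node takes the mean of its neighbours; solved as a
    sparse linear system over the tree."""
    nodes = sorted(tree.adj)
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for v in nodes:
        k = idx[v]
        name = tree.taxa[v] if tree.is_leaf(v) else None
        if name is not None and name in observed:
            A[k, k] = 1.0
            b[k] = observed[name]
        else:
            deg = len(tree.adj[v])
            A[k, k] = deg
            for u in tree.adj[v]:
                A[k, idx[u]] -= 1.0
    x = np.linalg.solve(A, b)
    cost = sum(
        (x[idx[u]] - x[idx[v]]) ** 2 for u, v in tree.edges()
    )
    rec = TraitReconstruction(trait=trait.name, cost=float(cost))
    for v in nodes:
        rec.node_intervals[v] = (float(x[idx[v]]), float(x[idx[v]]))
    return rec


# ---------------------------------------------------------------------------
# clade diagnosis (synapomorphy lists over the MPT set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapomorphyRecord:
    """A character change on a clade's stem branch.

    ``unambiguous`` means the change occurs in every MPR of every optimal
    tree; anything weaker (absent from some MPR or some tree) is reported as
    ambiguous.
    """

    char_index: int
    from_states: tuple
    to_states: tuple
    unambiguous: bool


def diagnose_clade(mpts: Sequence[PhyloTree], matrix,
                   clade: Iterable[str]) -> list:
    """Characters whose MPR places a change on the stem branch of ``clade``
    in at least one optimal tree, ordered by character index."""
    mpts = list(mpts)
    if not mpts:
        raise ValueError("need at least one tree")
    enc = _as_encoded(matrix)
    taxa = mpts[0].taxa
    clade = set(clade)
    cmask = 0
    for name in clade:
        cmask |= 1 << taxa.index(name)

    per_tree = []
    for k, t in enumerate(mpts):
        ref = t.leaves()[0]
        target = cmask if not (cmask >> ref & 1) else t.leafset_mask() ^ cmask
        if target not in t.splits():
            raise ValueError(f"clade not monophyletic in tree {k}")
        tab = sankoff_tables(t, enc)
        stem = _stem_node(t, tab, target)
        inverted = bool(cmask >> ref & 1)  # subtree side is the outside
        wmin, wmax = tab.edge_step_range(stem)
        per_tree.append((tab, stem, inverted, wmin, wmax))

    out = []
    C = len(per_tree[0][3])
    for cpos in range(C):
        if not any(wmax[cpos] > 0 for _, _, _, _, wmax in per_tree):
            continue
        unamb = all(wmin[cpos] > 0 for _, _, _, wmin, _ in per_tree)
        tab, stem, inverted, _, _ = per_tree[0]
        pairs = tab.edge_optimal_pairs(stem, cpos)
        outside = {t for t, _ in pairs}
        inside = {s for _, s in pairs}
        if inverted:
            outside, inside = inside, outside
        out.append(
            SynapomorphyRecord(
                char_index=int(tab.char_indices[cpos]),
                from_states=tuple(sorted(outside)),
                to_states=tuple(sorted(inside)),
                unambiguous=unamb,
            )
        )
    return out


def _stem_node(tree: PhyloTree, tab, target_mask: int) -> int:
    """Node whose subtree (as rooted for the tables) is exactly the target
    split block."""
    masks = {}
    for v in tab.order:
        if tree.is_leaf(v) and tab.parent[v] != -1:
            masks[v] = 1 << v
    for v in tab.order:
        if tree.is_leaf(v):
            continue
        m = 0
        for u in tree.adj[v]:
            if u != tab.parent[v]:
                m |= masks.get(u, 0)
        masks[v] = m
    for v, m in masks.items():
        if m == target_mask:
            return v
    raise ValueError("stem edge not found")
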