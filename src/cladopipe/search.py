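"""Heuristic maximum-parsimony tree search.

The strategy is the classic two-phase protocol: replicated random-addition
Wagner builds, each followed by TBR branch swapping holding a bounded buffer
of equally good trees, then a final unbounded round of TBR over the pooled
best trees to expand the full optimal set, which is rule-1 collapsed and
deduplicated.  Constrained variants (enforce or forbid monophyly) filter
candidate insertions and rearrangements; a suboptimal slack ``k`` retains
trees up to ``k`` steps above the best (used by Bremer support sweeps).

All randomness flows from one master seed: replicate ``i`` draws its own
generator from ``SeedSequence(seed, spawn_key=(i,))``, so runs are
reproducible and replicates independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .parsimony import EncodedMatrix, _as_encoded, collapse_zero_length, tree_steps
from .tree import (
    Constraint,
    PhyloTree,
    restricted_constraint,
    satisfies_constraint,
    tbr_neighbors,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "random_addition_wagner",
    "tbr_search",
    "replicated_search",
    "constrained_search",
]


@dataclass
class SearchConfig:
    """Knobs of the search protocol (defaults follow the standard
    1000-replicate, hold-10 recipe; tests and pseudoreplicates scale down)."""

    n_replicates: int = 1000
    hold_per_replicate: int = 10
    final_buffer_limit: Optional[int] = None  # None = unbounded
    seed: int = 0
    collapse: Optional[str] = "rule1"
    constraint: Optional[Constraint] = None
    suboptimal: float = 0.0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.hold_per_replicate < 1:
            raise ValueError("hold_per_replicate must be >= 1")
        if self.suboptimal < 0:
            raise ValueError("suboptimal slack must be >= 0")


@dataclass
class SearchResult:
    """Outcome of a (replicated) search."""

    best_length: float
    trees: List[PhyloTree]
    replicate_hits: int = 0
    log: List[float] = field(default_factory=list)
    n_replicates: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _score(tree: PhyloTree, enc: EncodedMatrix) -> float:
    s = float(np.dot(enc.weights, tree_steps(tree, enc)))
    return s


def _passes(tree: PhyloTree, constraint: Optional[Constraint]) -> bool:
    return constraint is None or satisfies_constraint(tree, constraint)


# ---------------------------------------------------------------------------
# Wagner stepwise addition
# ---------------------------------------------------------------------------

def _insert_leaf(tree: PhyloTree, edge, leaf: int) -> PhyloTree:
    out = tree.copy()
    u, v = edge
    w = out.new_internal_id()
    out.remove_edge(u, v)
    out.add_edge(u, w)
    out.add_edge(w, v)
    out.add_edge(w, leaf)
    return out


def random_addition_wagner(matrix, rng,
                           constraint: Optional[Constraint] = None,
                           order: Optional[Sequence[int]] = None) -> PhyloTree:
    """Build a starting tree by seeded random-addition-sequence Wagner
    stepwise insertion: each taxon joins at a currently best-length edge,
    ties broken by the replicate's random stream."""
    enc = _as_encoded(matrix)
    active = [i for i, t in enumerate(enc.matrix.taxa) if t.active]
    if len(active) < 4:
        raise ValueError("tree search requires >= 4 active taxa")
    if order is None:
        order = [active[i] for i in rng.permutation(len(active))]
    else:
        order = list(order)
    taxa = enc.taxa
    a, b, c = order[:3]
    hub = len(taxa)
    tree = PhyloTree(taxa, {a: [hub], b: [hub], c: [hub], hub: [a, b, c]})
    for leaf in order[3:]:
        present = [taxa[v] for v in tree.leaves()] + [taxa[leaf]]
        local = (restricted_constraint(constraint, present)
                 if constraint is not None else None)
        candidates = []
        for edge in sorted(tree.edges()):
            cand = _insert_leaf(tree, edge, leaf)
            if local is not None and not satisfies_constraint(cand, local):
                continue
            candidates.append((_score(cand, enc), cand))
        if not candidates:
            raise ValueError(
                f"constraint unsatisfiable while adding {taxa[leaf]!r}"
            )
        best = min(s for s, _ in candidates)
        pool = [t for s, t in candidates if s == best]
        tree = pool[int(rng.integers(len(pool)))]
    return tree


# ---------------------------------------------------------------------------
# TBR hill climbing with plateau buffer
# ---------------------------------------------------------------------------

def tbr_search(start: Iterable[PhyloTree], matrix,
               hold: Optional[int] = 10,
               constraint: Optional[Constraint] = None,
               suboptimal: float = 0.0) -> SearchResult:
    """Steepest-descent TBR from one or more start trees.

    Keeps a buffer of trees within ``suboptimal`` steps of the current best
    (capped at ``hold`` when given); every buffered tree is swapped until the
    buffer is closed under accepted rearrangements with no improvement left.
    """
    enc = _as_encoded(matrix)
    buffer: dict = {}
    for t in start:
        if not _passes(t, constraint):
            raise ValueError("start tree violates the constraint")
        buffer[t.topology_key()] = (t, _score(t, enc))
    if not buffer:
        raise ValueError("tbr_search needs at least one start tree")
    best = min(ln for _, ln in buffer.values())
    swapped: set = set()

    def prune():
        for k in [k for k, (_, ln) in buffer.items() if ln > best + suboptimal]:
            del buffer[k]
            swapped.discard(k)

    prune()
    while True:
        work = [k for k in buffer if k not in swapped]
        if not work:
            break
        key = work[0]
        tree, _ln = buffer[key]
        swapped.add(key)
        # score before deduplicating: most neighbours are worse, and their
        # split sets (the expensive part) never need computing
        for nb in tbr_neighbors(tree, dedup=False):
            ln = _score(nb, enc)
            if ln > best + suboptimal:
                continue
            if not _passes(nb, constraint):
                continue
            nkey = nb.topology_key()
            if nkey in buffer:
                continue
            if ln < best:
                best = ln
                buffer[nkey] = (nb, ln)
                prune()
            elif hold is None or len(buffer) < hold:
                buffer[nkey] = (nb, ln)

    trees = [t for t, ln in buffer.values() if ln <= best + suboptimal]
    return SearchResult(best_length=best, trees=trees)


# ---------------------------------------------------------------------------
# the full replicated protocol
# ---------------------------------------------------------------------------

def replicated_search(matrix, config: SearchConfig) -> SearchResult:
    """Random-addition + TBR replicates, pooled final TBR round, rule-1
    collapse and deduplication."""
    enc = _as_encoded(matrix)
    constraint = config.constraint
    pool: dict = {}
    pool_best = np.inf
    log: List[float] = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(rep,))
        )
        start = random_addition_wagner(enc, rng, constraint=constraint)
        res = tbr_search(
            [start], enc, hold=config.hold_per_replicate,
            constraint=constraint, suboptimal=config.suboptimal,
        )
        log.append(res.best_length)
        if res.best_length < pool_best - 1e-12:
            pool_best = res.best_length
            pool = {}
        if res.best_length <= pool_best + config.suboptimal + 1e-12:
            for t in res.trees:
                pool.setdefault(t.topology_key(), t)

    final = tbr_search(
        list(pool.values()), enc, hold=config.final_buffer_limit,
        constraint=constraint, suboptimal=config.suboptimal,
    )
    best = final.best_length

    trees = final.trees
    if config.collapse:
        seen: dict = {}
        for t in trees:
            ct = collapse_zero_length(t, enc, rule=config.collapse)
            seen.setdefault(ct.topology_key(), ct)
        trees = list(seen.values())
    hits = sum(1 for ln in log if abs(ln - best) < 1e-12)
    return SearchResult(
        best_length=best,
        trees=trees,
        replicate_hits=hits,
        log=log,
        n_replicates=config.n_replicates,
    )


def constrained_search(matrix, constraint: Constraint,
                       config: SearchConfig) -> SearchResult:
    """Search restricted to trees satisfying (or, in forbid mode, violating)
    the monophyly of the given groups."""
    cfg = replace(config, constraint=constraint)
    return replicated_search(matrix, cfg)
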