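"""Consensus trees, unstable-taxon pruning, Bremer and resampling support.

Strict consensus is the tree displaying exactly the bipartitions common to
every input tree; the reduced strict consensus first prunes unstable
("rogue") taxa, which otherwise collapse large regions into polytomies while
carrying no positional information themselves.  Bremer support of a clade is
the extra length of the best trees in which the clade is *not* monophyletic,
obtained exactly by a reverse-constraint (forbid) search or bounded from
below by a suboptimal sweep.  Bootstrap/jackknife support resamples
characters, re-searches each pseudoreplicate, and tallies clade frequencies
both as absolute percentages and as GC (group present minus most frequent
contradicting group), which is negative for groups beaten by a rival.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .parsimony import _as_encoded, tree_steps
from .search import SearchConfig, constrained_search, replicated_search
from .tree import (
    Bipartition,
    Constraint,
    PhyloTree,
    prune_taxa,
    splits_compatible,
    tree_from_splits,
)

__all__ = [
    "SupportTable",
    "InstabilityEntry",
    "InstabilityReport",
    "strict_consensus",
    "reduced_consensus",
    "identify_unstable_taxa",
    "bremer_supports",
    "resampling_support",
]


class SupportTable:
    """Per-bipartition support values; rows keyed by canonical split mask."""

    def __init__(self, taxa: Sequence[str]):
        self.taxa = tuple(taxa)
        self.rows: dict = {}

    def set(self, mask: int, column: str, value) -> None:
        self.rows.setdefault(mask, {})[column] = value

    def get(self, mask: int, column: str):
        return self.rows.get(mask, {}).get(column)

    def merge(self, other: "SupportTable") -> "SupportTable":
        for mask, cols in other.rows.items():
            for col, val in cols.items():
                self.set(mask, col, val)
        return self

    def bipartition(self, mask: int) -> Bipartition:
        return Bipartition(mask, self.taxa)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for mask in sorted(self.rows, key=lambda m: (m.bit_count(), m)):
            rec = {"group": ",".join(self.bipartition(mask).group())}
            rec.update(self.rows[mask])
            recs.append(rec)
        return pd.DataFrame(recs)

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _check_same_leaves(trees: List[PhyloTree]) -> None:
    if not trees:
        raise ValueError("need at least one tree")
    first = trees[0].leafset_mask()
    for t in trees[1:]:
        if t.leafset_mask() != first or t.taxa != trees[0].taxa:
            raise ValueError("consensus requires identical leaf sets")


def strict_consensus(trees: Iterable[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the bipartitions present in every input."""
    trees = list(trees)
    _check_same_leaves(trees)
    common = frozenset.intersection(*(t.splits() for t in trees))
    return tree_from_splits(trees[0].taxa, trees[0].leaves(), common)


def reduced_consensus(trees: Iterable[PhyloTree], prune) -> PhyloTree:
    """Strict consensus after a-posteriori pruning of the given taxa."""
    trees = list(trees)
    _check_same_leaves(trees)
    prune = list(prune)
    if not prune:
        return strict_consensus(trees)
    return strict_consensus([prune_taxa(t, prune) for t in trees])


# ---------------------------------------------------------------------------
# unstable taxa (greedy rogue pruning with cause classification)
# ---------------------------------------------------------------------------

@dataclass
class InstabilityEntry:
    taxon: str
    alternatives: list          # distinct attachment descriptors across trees
    cause: str                  # missing_data | character_conflict | unknown
    resolution_gain: int


@dataclass
class InstabilityReport:
    pruned: List[InstabilityEntry] = field(default_factory=list)

    @property
    def taxa(self) -> list:
        return [e.taxon for e in self.pruned]

    def __len__(self) -> int:
        return len(self.pruned)


def identify_unstable_taxa(trees: Iterable[PhyloTree],
                           matrix=None) -> InstabilityReport:
    """Greedy rogue-taxon analysis over a set of equally optimal trees.

    At each step the leaf whose solitary removal most increases the strict
    consensus's resolved node count is pruned; the loop stops when no removal
    helps.  For each pruned taxon the distinct attachment positions across
    the input trees are listed, and the cause is classified as missing data
    (its scored characters are equally optimised in every placement) or
    character conflict.  This is a self-contained stand-in for iterative
    positional-congruence reduction, not a re-implementation of any
    published code.
    """
    trees = list(trees)
    if len(trees) < 2:
        return InstabilityReport()
    _check_same_leaves(trees)
    taxa = trees[0].taxa
    pruned: list = []
    report = InstabilityReport()
    while True:
        remaining = [v for v in trees[0].leaves() if v not in pruned]
        if len(remaining) <= 4:
            break
        base = len(strict_consensus(
            [prune_taxa(t, pruned) for t in trees] if pruned else trees
        ).splits())
        best_gain, best_leaf = 0, None
        for v in sorted(remaining, key=lambda i: taxa[i]):
            cand = pruned + [v]
            gain = len(strict_consensus(
                [prune_taxa(t, cand) for t in trees]
            ).splits()) - base
            if gain > best_gain:
                best_gain, best_leaf = gain, v
        if best_leaf is None:
            break
        pruned.append(best_leaf)
        report.pruned.append(
            InstabilityEntry(
                taxon=taxa[best_leaf],
                alternatives=[],
                cause="unknown",
                resolution_gain=best_gain,
            )
        )

    for entry in report.pruned:
        x = taxa.index(entry.taxon)
        others = [v for v in pruned if v != x]
        entry.alternatives = _attachment_positions(trees, x, others)
        if matrix is not None:
            entry.cause = _classify_cause(trees, x, matrix)
    return report


def _attachment_positions(trees, x: int, other_pruned: list) -> list:
    """Distinct attachment descriptors of leaf ``x`` across trees, each the
    set of leaf-mask components surrounding its insertion point after the
    other rogues are removed."""
    seen: dict = {}
    for t in trees:
        tx = prune_taxa(t, other_pruned) if other_pruned else t
        u = tx.adj[x][0]
        comps = []
        for w in tx.adj[u]:
            if w == x:
                continue
            mask = 0
            stack = [(w, u)]
            while stack:
                v, par = stack.pop()
                if tx.is_leaf(v):
                    mask |= 1 << v
                for nxt in tx.adj[v]:
                    if nxt != par:
                        stack.append((nxt, v))
            comps.append(mask)
        seen.setdefault(frozenset(comps), None)
    return list(seen)


def _classify_cause(trees, x: int, matrix) -> str:
    """missing_data iff per-character optimised lengths are identical across
    all placements of ``x`` (compared on tree pairs that differ only in
    ``x``; falling back to the characters scored for ``x``)."""
    enc = _as_encoded(matrix)
    steps = [tree_steps(t, enc) for t in trees]
    by_rest: dict = {}
    for t, s in zip(trees, steps):
        rest_key = prune_taxa(t, [x]).topology_key()
        by_rest.setdefault(rest_key, []).append((t.topology_key(), s))
    compared = False
    for group in by_rest.values():
        if len(group) < 2:
            continue
        ref_key, ref = group[0]
        for key, s in group[1:]:
            if key == ref_key:
                continue
            compared = True
            if not np.array_equal(s, ref):
                return "character_conflict"
    if compared:
        return "missing_data"
    scored = np.array([
        not matrix.cells[x][int(j)].is_full_ambiguity
        for j in enc.char_indices
    ])
    ref = steps[0]
    for s in steps[1:]:
        if not np.array_equal(s[scored], ref[scored]):
            return "character_conflict"
    return "missing_data"


# ---------------------------------------------------------------------------
# Bremer support
# ---------------------------------------------------------------------------

def bremer_supports(matrix, mpts: List[PhyloTree],
                    config: Optional[SearchConfig] = None,
                    method: str = "reverse_constraint",
                    max_slack: float = 10.0) -> SupportTable:
    """Bremer (decay) support for every strict-consensus clade of the MPTs.

    ``reverse_constraint`` (exact): for each clade, search for the best tree
    in which the clade is non-monophyletic; support = extra steps needed.
    ``suboptimal_sweep`` (lower bound): one search retaining trees up to
    ``max_slack`` steps above the optimum; support = slack of the best
    retained tree lacking the clade.
    """
    enc = _as_encoded(matrix)
    mpts = list(mpts)
    _check_same_leaves(mpts)
    lengths = {float(np.dot(enc.weights, tree_steps(t, enc))) for t in mpts}
    if len(lengths) != 1:
        raise ValueError("input trees are not equally parsimonious")
    best = lengths.pop()
    consensus = strict_consensus(mpts)
    table = SupportTable(mpts[0].taxa)
    taxa = mpts[0].taxa
    cfg = config or SearchConfig(n_replicates=5, hold_per_replicate=5)

    if method == "reverse_constraint":
        for mask in sorted(consensus.splits()):
            group = {taxa[i] for i in range(len(taxa)) if mask >> i & 1}
            res = constrained_search(
                enc, Constraint([group], mode="forbid"), cfg
            )
            table.set(mask, "bremer", float(res.best_length - best))
    elif method == "suboptimal_sweep":
        cfg = replace(cfg, suboptimal=max_slack, collapse=None)
        res = replicated_search(enc, cfg)
        scored = [
            (float(np.dot(enc.weights, tree_steps(t, enc))), t)
            for t in res.trees
        ]
        for mask in sorted(consensus.splits()):
            lacking = [ln for ln, t in scored if mask not in t.splits()]
            table.set(
                mask, "bremer",
                float(min(lacking) - best) if lacking else float("inf"),
            )
    else:
        raise ValueError(f"unknown bremer method {method!r}")
    return table


# ---------------------------------------------------------------------------
# resampling (bootstrap / jackknife) with absolute and GC frequencies
# ---------------------------------------------------------------------------

def resampling_support(matrix, config: Optional[SearchConfig] = None,
                       scheme: str = "bootstrap",
                       n_reps: int = 100,
                       p_del: float = 0.36,
                       seed: int = 0,
                       reference_splits: Optional[Iterable[int]] = None
                       ) -> SupportTable:
    """Character resampling support.

    Bootstrap draws characters with replacement back to the original count;
    jackknife deletes each character independently with probability
    ``p_del`` (0.36 by convention).  Each pseudoreplicate is searched with
    the reduced-effort ``config`` and the bipartitions of its strict
    consensus tallied.  Absolute support is the percentage of
    pseudoreplicates displaying the group; GC subtracts the frequency of the
    most frequent contradicting group.
    """
    if scheme not in ("bootstrap", "jackknife"):
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc = _as_encoded(matrix)
    cfg = config or SearchConfig(n_replicates=3, hold_per_replicate=3)
    C = enc.n_chars
    counts: dict = {}
    scheme_tag = 0 if scheme == "bootstrap" else 1
    for rep in range(n_reps):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(scheme_tag, rep))
        rng = np.random.default_rng(ss)
        while True:
            if scheme == "bootstrap":
                w = np.bincount(rng.integers(0, C, C), minlength=C)
            else:
                w = (rng.random(C) >= p_del).astype(np.int64)
            if w.sum() > 0:
                break
        child_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        res = replicated_search(
            enc.with_weights(enc.weights * w),
            replace(cfg, seed=child_seed),
        )
        cons = strict_consensus(res.trees)
        for mask in cons.splits():
            counts[mask] = counts.get(mask, 0) + 1

    table = SupportTable(enc.taxa)
    report = set(counts)
    if reference_splits is not None:
        report |= set(reference_splits)
    for mask in report:
        freq = 100.0 * counts.get(mask, 0) / n_reps
        rivals = [
            100.0 * n / n_reps
            for m, n in counts.items()
            if not splits_compatible(mask, m)
        ]
        gc = freq - (max(rivals) if rivals else 0.0)
        table.set(mask, f"{scheme[:4]}_abs", freq)
        table.set(mask, f"{scheme[:4]}_gc", gc)
    return table
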