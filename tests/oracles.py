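"""Independent brute-force oracles used to verify the implementation.

Everything here deliberately avoids the package's dynamic-programming
scoring paths: costs are minimised by explicit enumeration over all
internal-node labelings (discrete) or over a value grid (continuous), and
the signed-rank null distribution is enumerated over all sign assignments.
Only viable at toy sizes, which is the point.
"""

import itertools

import numpy as np
from scipy import stats


def _dist(a, b, ordered):
    return abs(a - b) if ordered else (0 if a == b else 1)


def brute_force_char_length(tree, leaf_states, K, ordered):
    """Minimum cost over all internal labelings; leaf ambiguity resolved
    optimally per leaf (leaves have degree 1, so independently)."""
    internals = sorted(v for v in tree.adj if not tree.is_leaf(v))
    edges = list(tree.edges())
    best = None
    for combo in itertools.product(range(K), repeat=len(internals)):
        assign = dict(zip(internals, combo))
        total = 0
        for (u, v) in edges:
            if tree.is_leaf(u):
                u, v = v, u
            if tree.is_leaf(v):
                total += min(_dist(assign[u], s, ordered)
                             for s in leaf_states[v])
            else:
                total += _dist(assign[u], assign[v], ordered)
        if best is None or total < best:
            best = total
    return best


def brute_force_mpr(tree, leaf_states, K, ordered):
    """(length, node state unions, per-edge (min,max) change sizes) over all
    optimal full assignments."""
    internals = sorted(v for v in tree.adj if not tree.is_leaf(v))
    leaves = sorted(v for v in tree.adj if tree.is_leaf(v))
    edges = list(tree.edges())
    best = None
    optima = []
    for combo in itertools.product(range(K), repeat=len(internals)):
        for leafc in itertools.product(
            *[sorted(leaf_states[v]) for v in leaves]
        ):
            assign = dict(zip(internals, combo))
            assign.update(dict(zip(leaves, leafc)))
            total = sum(
                _dist(assign[u], assign[v], ordered) for (u, v) in edges
            )
            if best is None or total < best:
                best = total
                optima = []
            if total == best:
                optima.append(dict(assign))
    node_sets = {
        v: frozenset(a[v] for a in optima) for v in internals + leaves
    }
    edge_ranges = {}
    for (u, v) in edges:
        ws = [_dist(a[u], a[v], ordered) for a in optima]
        edge_ranges[(u, v)] = (min(ws), max(ws))
    return best, node_sets, edge_ranges


def grid_continuous_oracle(tree, values):
    """Linear-parsimony oracle: minimise Manhattan cost over the grid of
    observed values (optima lie on observed values); returns
    (cost, per-node optimal value sets)."""
    grid = sorted(set(values.values()))
    internals = sorted(v for v in tree.adj if not tree.is_leaf(v))
    free_leaves = sorted(
        v for v in tree.adj
        if tree.is_leaf(v) and tree.taxa[v] not in values
    )
    nodes = internals + free_leaves
    edges = list(tree.edges())
    best = None
    optima = []
    for combo in itertools.product(grid, repeat=len(nodes)):
        assign = dict(zip(nodes, combo))
        for v in tree.adj:
            if tree.is_leaf(v) and tree.taxa[v] in values:
                assign[v] = values[tree.taxa[v]]
        total = sum(abs(assign[u] - assign[v]) for (u, v) in edges)
        if best is None or total < best - 1e-12:
            best = total
            optima = []
        if abs(total - best) <= 1e-12:
            optima.append(dict(assign))
    node_sets = {v: sorted({a[v] for a in optima}) for v in nodes}
    return best, node_sets


def signed_rank_enumeration_p(diffs):
    """Two-tailed exact p by enumerating all sign assignments:
    min(1, 2 P(R+ <= observed))."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        rp = sum(r for r, s in zip(ranks, signs) if s)
        if rp <= obs + 1e-12:
            hits += 1
    return min(1.0, 2.0 * hits / 2 ** n)
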