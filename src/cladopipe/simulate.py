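"""Synthetic trees, matrices and traits with the structure the pipeline assumes.

Characters are simulated by placing a Poisson number of state changes on
uniformly chosen branches of a known tree (unordered characters jump to a
uniformly chosen different state, ordered characters step +/-1), which gives
direct control over homoplasy without branch lengths — parsimony never
consumes them.  Cells are then degraded to missing or polymorphic at the
requested rates; a "fragmentary taxon" mode concentrates missingness in
chosen rows to reproduce rogue-taxon behaviour.

``leoneras_like_fixture`` builds a 50-taxon x 277-character analogue of a
basal-sauropodomorph-grade analysis: a pectinate backbone with small
terminal clades, a sacral-configuration trait gaining elements toward the
crown with one autapomorphic deviation, a femoral-width (FML) body-size
proxy increasing toward one clade with one small-bodied exception, and two
heavily incomplete rogue taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .traits import ContinuousTrait, DiscreteTrait
from .tree import PhyloTree, parse_newick, random_topology

__all__ = [
    "SyntheticSpec",
    "simulate_tree",
    "simulate_matrix",
    "leoneras_like_fixture",
    "LeonerasLikeFixture",
]

SACRUM_STATES = (
    "S1+S2",            # plesiomorphic: the two primordial sacrals only
    "DS+S1+S2",         # dorsosacral added
    "S1+S2+CS",         # caudosacral added, dorsosacral lost (deviant)
    "DS+S1+S2+CS",      # four sacrals
    "2DS+S1+S2+CS",     # five sacrals
)


@dataclass
class SyntheticSpec:
    """Shape and noise parameters of a simulated matrix.

    Defaults emulate a basal-sauropodomorph-scale dataset: 50 taxa, 277
    mostly-binary characters, ~40% missing cells, a small ordered fraction,
    and a change rate giving moderate homoplasy.
    """

    n_taxa: int = 50
    n_chars: int = 277
    state_count_probs: Dict[int, float] = field(
        default_factory=lambda: {2: 0.75, 3: 0.20, 4: 0.05}
    )
    fraction_ordered: float = 0.10
    change_rate: float = 3.0         # expected changes per character per tree
    missing_fraction: float = 0.40
    polymorphic_fraction: float = 0.01
    fragmentary: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for frac in (self.fraction_ordered, self.missing_fraction,
                     self.polymorphic_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.state_count_probs.values()) - 1) > 1e-9:
            raise ValueError("state_count_probs must sum to 1")


def _default_names(n: int) -> list:
    return [f"T{i + 1:02d}" for i in range(n)]


def simulate_tree(n_taxa: int, seed: int = 0,
                  taxa: Optional[Sequence[str]] = None) -> PhyloTree:
    """Uniform random unrooted binary topology."""
    rng = np.random.default_rng(seed)
    names = list(taxa) if taxa is not None else _default_names(n_taxa)
    return random_topology(names, rng)


def simulate_matrix(tree: PhyloTree, spec: SyntheticSpec,
                    rng: Optional[np.random.Generator] = None) -> CharacterMatrix:
    """Evolve ``spec.n_chars`` characters on ``tree`` and degrade cells.

    Constant characters are retained (real matrices keep them; they just
    contribute nothing to length).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    leaves = tree.leaves()
    names = [tree.taxa[v] for v in leaves]
    edges = sorted(tree.edges())
    # root the tree at the first leaf for change propagation
    ref = leaves[0]
    order = []
    stack = [(ref, -1)]
    parent = {}
    while stack:
        v, p = stack.pop()
        order.append(v)
        parent[v] = p
        for u in tree.adj[v]:
            if u != p:
                stack.append((u, v))

    kcounts = sorted(spec.state_count_probs)
    kprobs = [spec.state_count_probs[k] for k in kcounts]
    rows = {v: [] for v in leaves}
    ordered_idx = []
    for j in range(spec.n_chars):
        K = int(rng.choice(kcounts, p=kprobs))
        is_ordered = rng.random() < spec.fraction_ordered and K > 2
        if is_ordered:
            ordered_idx.append(j)
        n_changes = rng.poisson(spec.change_rate)
        changes_on = {}
        for _ in range(n_changes):
            e = edges[int(rng.integers(len(edges)))]
            changes_on[e] = changes_on.get(e, 0) + 1
        state = {ref: int(rng.integers(K))}
        for v in order[1:]:
            p = parent[v]
            e = (p, v) if p < v else (v, p)
            s = state[p]
            for _ in range(changes_on.get(e, 0)):
                if is_ordered:
                    if s == 0:
                        s = 1
                    elif s == K - 1:
                        s = K - 2
                    else:
                        s += int(rng.choice([-1, 1]))
                else:
                    s = int((s + 1 + rng.integers(K - 1)) % K)
            state[v] = s
        for v in leaves:
            rows[v].append((state[v], K))

    symbols = "0123456789"
    text_rows = []
    for v, name in zip(leaves, names):
        miss = spec.fragmentary.get(name, spec.missing_fraction)
        out = []
        for s, K in rows[v]:
            u = rng.random()
            if u < miss:
                out.append("?")
            elif u < miss + spec.polymorphic_fraction and K >= 2:
                other = int((s + 1 + rng.integers(K - 1)) % K)
                pair = sorted({s, other})
                out.append("[" + "".join(symbols[x] for x in pair) + "]")
            else:
                out.append(symbols[s])
        text_rows.append(" ".join(out))
    return CharacterMatrix.from_rows(names, text_rows, ordered=ordered_idx)


# ---------------------------------------------------------------------------
# the study-shaped fixture
# ---------------------------------------------------------------------------

class LeonerasLikeFixture(NamedTuple):
    matrix: CharacterMatrix
    sacral_trait: DiscreteTrait
    fml_trait: ContinuousTrait
    tree: PhyloTree
    roles: dict


def leoneras_like_fixture(seed: int = 0) -> LeonerasLikeFixture:
    """50 taxa x 277 characters with the qualitative structure of a basal
    sauropodomorph analysis; see module docstring."""
    names = _default_names(50)
    # pectinate backbone of 12 grades; groups listed basal -> crown
    groups = [
        names[0:3], names[3:7], names[7:11], names[11:15], names[15:19],
        names[19:23], names[23:27], names[27:31], names[31:35], names[35:40],
        names[40:45], names[45:50],
    ]

    def clump(members):
        if len(members) == 1:
            return members[0]
        return "(" + members[0] + "," + clump(members[1:]) + ")"

    nwk = clump([clump(g) for g in groups]) + ";"
    tree = parse_newick(nwk, names)

    roles = {
        "outgroup": names[0],
        "rogues": [names[24], names[32]],
        "sacral_deviant": names[17],      # Plateosaurus-like S1+S2+CS
        "small_bodied_exception": names[41],  # Leonerasaurus-like
        "crown_clade": groups[-1] + groups[-2],
    }

    spec = SyntheticSpec(
        n_taxa=50, n_chars=277, seed=seed,
        fragmentary={r: 0.85 for r in roles["rogues"]},
    )
    matrix = simulate_matrix(tree, spec)

    # sacral configurations by grade: S1+S2 -> DS+S1+S2 -> DS+S1+S2+CS,
    # with one autapomorphic S1+S2+CS deviation and a five-sacral crown taxon
    obs: Dict[str, Optional[int]] = {}
    for gi, g in enumerate(groups):
        if gi < 3:
            s = 0
        elif gi < 8:
            s = 1
        else:
            s = 3
        for name in g:
            obs[name] = s
    obs[roles["sacral_deviant"]] = 2
    obs[names[49]] = 4
    sacral = DiscreteTrait("sacrum", SACRUM_STATES, obs)

    # FML (cm) increasing toward the crown; one small-bodied exception
    rng = np.random.default_rng(seed + 1)
    fml: Dict[str, float] = {}
    base = np.linspace(2.5, 14.0, len(groups))
    for gi, g in enumerate(groups):
        for name in g:
            if rng.random() < 0.3:     # incomplete femora are common
                continue
            fml[name] = round(float(base[gi] * rng.uniform(0.85, 1.15)), 2)
    fml[roles["small_bodied_exception"]] = 4.0
    fml[names[0]] = 2.5
    return LeonerasLikeFixture(matrix, sacral, ContinuousTrait("FML", fml),
                               tree, roles)
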