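import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cladopipe.matrix import CharacterMatrix
from cladopipe.tree import parse_newick


NAMES4 = ["A", "B", "C", "D"]


@pytest.fixture
def f1_matrix():
    """Three unordered binary characters on four taxa; all three topologies
    tie at length 5 (per-character lengths 1, 2, 2)."""
    return CharacterMatrix.from_rows(NAMES4, ["000", "011", "101", "110"])


@pytest.fixture
def tree_ab_cd(f1_matrix):
    return parse_newick("((A,B),(C,D));", NAMES4)


@pytest.fixture
def bremer_matrix():
    """Two characters supporting AB|CD, one supporting AC|BD: topology
    lengths 4/5/6, so Bremer(AB|CD) = 1."""
    return CharacterMatrix.from_rows(NAMES4, ["000", "001", "110", "111"])


def make_clean_eight_taxon(n_chars_per_clade=3):
    """Noiseless 8-taxon matrix: every clade of the symmetric true tree
    (((A,B),(C,D)),((E,F),(G,H))) is supported by congruent binary
    characters."""
    names = list("ABCDEFGH")
    clades = [
        {0, 1}, {2, 3}, {4, 5}, {6, 7}, {0, 1, 2, 3}, {4, 5, 6, 7},
    ]
    rows = {n: [] for n in names}
    for cl in clades:
        for _ in range(n_chars_per_clade):
            for i, n in enumerate(names):
                rows[n].append("1" if i in cl else "0")
    matrix = CharacterMatrix.from_rows(
        names, ["".join(rows[n]) for n in names]
    )
    true_tree = parse_newick("(((A,B),(C,D)),((E,F),(G,H)));", names)
    return matrix, true_tree, clades


@pytest.fixture
def clean_eight():
    return make_clean_eight_taxon()


def random_leaf_sets(rng, tree, K, ambiguous=True, missing=True):
    """Random per-leaf state sets for oracle comparisons."""
    out = {}
    for v in tree.leaves():
        r = rng.random()
        if missing and r < 0.1:
            out[v] = set(range(K))
        elif ambiguous and r < 0.2:
            size = int(rng.integers(2, K + 1))
            out[v] = set(rng.choice(K, size=size, replace=False).tolist())
        else:
            out[v] = {int(rng.integers(K))}
    return out


def matrix_from_leaf_sets(tree, leaf_sets, K, ordered):
    """Single-character matrix (alphabet size exactly K) matching a leaf-set
    assignment."""
    from cladopipe.matrix import (
        MISSING,
        OBSERVED,
        ORDERED,
        POLYMORPHIC,
        UNORDERED,
        CellState,
        CharacterDef,
        Taxon,
    )

    names = [tree.taxa[v] for v in tree.leaves()]
    cells = []
    for v in tree.leaves():
        ss = frozenset(leaf_sets[v])
        if len(ss) == K:
            cell = CellState(ss, MISSING)
        elif len(ss) == 1:
            cell = CellState(ss, OBSERVED)
        else:
            cell = CellState(ss, POLYMORPHIC)
        cells.append([cell])
    chars = [CharacterDef(0, ORDERED if ordered else UNORDERED, n_states=K)]
    return CharacterMatrix([Taxon(n) for n in names], chars, cells)
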