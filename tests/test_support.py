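import numpy as np
import pytest

from cladopipe.matrix import CharacterMatrix
from cladopipe.search import SearchConfig, replicated_search
from cladopipe.support import (
    bremer_supports,
    identify_unstable_taxa,
    reduced_consensus,
    resampling_support,
    strict_consensus,
)
from cladopipe.tree import (
    parse_newick,
    prune_taxa,
    random_topology,
)

from conftest import NAMES4, make_clean_eight_taxon


def test_strict_consensus_idempotent():
    t = parse_newick("((A,B),(C,D));", NAMES4)
    assert strict_consensus([t, t.copy()]).splits() == t.splits()


def test_strict_consensus_of_three_tied_is_star():
    trees = [
        parse_newick(n, NAMES4)
        for n in ["((A,B),(C,D));", "((A,C),(B,D));", "((A,D),(B,C));"]
    ]
    assert strict_consensus(trees).splits() == frozenset()


def test_strict_consensus_keeps_shared_split_only():
    taxa = ["A", "B", "C", "D", "E"]
    t1 = parse_newick("((A,B),(C,(D,E)));", taxa)
    t2 = parse_newick("(((A,B),C),(D,E));", taxa)
    cons = strict_consensus([t1, t2])
    assert cons.splits() == t1.splits() & t2.splits()
    assert len(cons.splits()) >= 1


def test_strict_consensus_is_split_intersection_random():
    taxa = [f"t{i}" for i in range(9)]
    rng = np.random.default_rng(8)
    for _ in range(15):
        trees = [random_topology(taxa, rng) for _ in range(3)]
        expected = frozenset.intersection(*(t.splits() for t in trees))
        assert strict_consensus(trees).splits() == expected


def test_consensus_rejects_mismatched_leaf_sets():
    t1 = parse_newick("((A,B),(C,D));", NAMES4)
    t2 = prune_taxa(parse_newick("((A,B),(C,D));", NAMES4), ["D"])
    with pytest.raises(ValueError):
        strict_consensus([t1, t2])


def test_reduced_consensus_commutes_with_pruning():
    taxa = [f"t{i}" for i in range(8)]
    rng = np.random.default_rng(9)
    for _ in range(10):
        trees = [random_topology(taxa, rng) for _ in range(3)]
        drop = ["t3", "t6"]
        direct = reduced_consensus(trees, drop)
        via = strict_consensus([prune_taxa(t, drop) for t in trees])
        assert direct.splits() == via.splits()


def test_reduced_consensus_empty_prune_is_strict():
    taxa = [f"t{i}" for i in range(6)]
    trees = [random_topology(taxa, np.random.default_rng(s)) for s in (0, 1)]
    assert reduced_consensus(trees, []).splits() == \
        strict_consensus(trees).splits()


def test_pruning_rogue_resolves_consensus():
    """A taxon attached at two different places in otherwise identical
    trees destroys resolution; removing it restores a resolved consensus."""
    taxa = ["A", "B", "C", "D", "E", "R"]
    t1 = parse_newick("(((A,R),B),(C,(D,E)));", taxa)
    t2 = parse_newick("((A,B),(C,((D,R),E)));", taxa)
    cons = strict_consensus([t1, t2])
    red = reduced_consensus([t1, t2], ["R"])
    assert len(red.splits()) > len(cons.splits())
    assert red.splits() == prune_taxa(t1, ["R"]).splits()


def test_identify_unstable_taxa_finds_the_rogue():
    taxa = ["A", "B", "C", "D", "E", "R"]
    t1 = parse_newick("(((A,R),B),(C,(D,E)));", taxa)
    t2 = parse_newick("((A,B),(C,((D,R),E)));", taxa)
    rep = identify_unstable_taxa([t1, t2])
    assert rep.taxa == ["R"]
    assert len(rep.pruned[0].alternatives) == 2
    assert rep.pruned[0].resolution_gain > 0


def test_identify_unstable_taxa_identical_trees_empty():
    taxa = [f"t{i}" for i in range(6)]
    t = random_topology(taxa, np.random.default_rng(10))
    assert len(identify_unstable_taxa([t, t.copy()])) == 0


def test_rogue_with_all_missing_data_classified_missing_data():
    """A taxon scored '?' everywhere floats among placements at no cost."""
    names = list("ABCDEFGH") + ["R"]
    matrix, _, _ = make_clean_eight_taxon()
    rows = ["".join(
        "1" if c.states == frozenset({1}) else "0" for c in matrix.cells[i]
    ) for i in range(8)]
    m = CharacterMatrix.from_rows(names, rows + ["?" * 18])
    res = replicated_search(m, SearchConfig(n_replicates=3, seed=11))
    assert res.n_trees > 1
    rep = identify_unstable_taxa(res.trees, m)
    assert "R" in rep.taxa
    entry = next(e for e in rep.pruned if e.taxon == "R")
    assert entry.cause == "missing_data"
    assert len(entry.alternatives) > 1


def test_conflicting_taxon_classified_character_conflict():
    """A taxon whose characters actively support two different positions."""
    names = list("ABCDEFGH") + ["R"]
    matrix, _, _ = make_clean_eight_taxon()
    rows = ["".join(
        "1" if c.states == frozenset({1}) else "0" for c in matrix.cells[i]
    ) for i in range(8)]
    # R shares derived states with {A,B} (characters 0-1) and equally with
    # {G,H} (characters 9-10): a genuine two-way character conflict
    r_row = "11" + "0" * 7 + "11" + "0" * 7
    m = CharacterMatrix.from_rows(names, rows + [r_row])
    res = replicated_search(m, SearchConfig(n_replicates=5, seed=12))
    rep = identify_unstable_taxa(res.trees, m)
    if "R" in rep.taxa:  # only meaningful when R is actually unstable
        entry = next(e for e in rep.pruned if e.taxon == "R")
        assert entry.cause == "character_conflict"


def test_bremer_worked_fixture(bremer_matrix):
    res = replicated_search(
        bremer_matrix, SearchConfig(n_replicates=3, seed=13)
    )
    table = bremer_supports(
        bremer_matrix, res.trees, SearchConfig(n_replicates=3, seed=13)
    )
    assert list(table.rows) == [0b1100]  # the {C,D} side of AB|CD
    assert table.get(0b1100, "bremer") == 1


def test_bremer_scales_with_duplicated_support():
    m = CharacterMatrix.from_rows(
        NAMES4, ["00000", "00001", "11110", "11111"]
    )
    res = replicated_search(m, SearchConfig(n_replicates=3, seed=14))
    table = bremer_supports(m, res.trees, SearchConfig(n_replicates=3, seed=14))
    assert table.get(0b1100, "bremer") == 3


def test_bremer_sweep_lower_bounds_exact(bremer_matrix):
    res = replicated_search(
        bremer_matrix, SearchConfig(n_replicates=3, seed=15)
    )
    sweep = bremer_supports(
        bremer_matrix, res.trees, SearchConfig(n_replicates=3, seed=15),
        method="suboptimal_sweep", max_slack=3,
    )
    assert sweep.get(0b1100, "bremer") == 1


def test_bootstrap_definitional_bounds():
    """Clean support for AC|BD: that split gets absolute = GC = 100, while
    the never-recovered AB|CD reference split gets GC = -100."""
    m = CharacterMatrix.from_rows(
        NAMES4, ["000000", "111111", "000000", "111111"]
    )
    table = resampling_support(
        m, SearchConfig(n_replicates=2), scheme="bootstrap", n_reps=30,
        seed=16, reference_splits={0b1100},
    )
    ac_mask = 0b1010  # {A,C}|{B,D} canonical side {B,D}? -> 1<<1 | 1<<3
    assert table.get(ac_mask, "boot_abs") == 100.0
    assert table.get(ac_mask, "boot_gc") == 100.0
    assert table.get(0b1100, "boot_abs") == 0.0
    assert table.get(0b1100, "boot_gc") == -100.0


def test_resampling_gc_bounded_by_absolute():
    matrix, _, _ = make_clean_eight_taxon()
    table = resampling_support(
        matrix, SearchConfig(n_replicates=2), scheme="jackknife",
        n_reps=30, seed=17,
    )
    for mask, cols in table.rows.items():
        assert -100 <= cols["jack_gc"] <= cols["jack_abs"] <= 100
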