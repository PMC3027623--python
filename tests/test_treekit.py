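import numpy as np
import pytest

from cladopipe.tree import (
    Constraint,
    all_unrooted_topologies,
    bipartitions,
    displays_group,
    parse_newick,
    prune_taxa,
    random_topology,
    satisfies_constraint,
    spr_neighbors,
    tbr_neighbors,
    tree_from_splits,
    write_newick,
)

ABCD = ["A", "B", "C", "D"]


def test_parse_four_leaf_has_single_split():
    t = parse_newick("((A,B),(C,D));", ABCD)
    assert len(t.splits()) == 1
    (m,) = t.splits()
    assert m == 0b1100  # {C,D}: the side not containing A


def test_star_tree_has_no_splits():
    t = parse_newick("(A,B,C,D);", ABCD)
    assert t.splits() == frozenset()
    assert bipartitions(t) == set()


def test_resolved_five_leaf_has_two_splits():
    t = parse_newick("((A,B),C,(D,E));", ["A", "B", "C", "D", "E"])
    assert len(t.splits()) == 2


def test_newick_roundtrip_random_trees():
    taxa = [f"t{i}" for i in range(20)]
    rng = np.random.default_rng(0)
    for _ in range(50):
        t = random_topology(taxa, rng)
        back = parse_newick(write_newick(t), taxa)
        assert back.splits() == t.splits()


def test_rooting_choice_does_not_change_splits():
    taxa = [f"t{i}" for i in range(8)]
    t = random_topology(taxa, np.random.default_rng(1))
    for og in taxa:
        assert parse_newick(write_newick(t, outgroup=og), taxa).splits() == t.splits()


def test_unknown_label_rejected():
    with pytest.raises(ValueError):
        parse_newick("((A,B),(C,X));", ABCD)


def test_prune_to_three_leaf_star():
    t = parse_newick("((A,B),(C,D));", ABCD)
    p = prune_taxa(t, ["C"])
    assert sorted(p.leaf_names()) == ["A", "B", "D"]
    assert p.splits() == frozenset()


def test_prune_induced_subtree():
    taxa = ["A", "B", "C", "D", "E"]
    t = parse_newick("((A,B),((C,D),E));", taxa)
    p = prune_taxa(t, ["E"])
    assert p.splits() == parse_newick("((A,B),(C,D));", taxa).splits()


def test_prune_nothing_is_identity():
    t = parse_newick("((A,B),(C,D));", ABCD)
    assert prune_taxa(t, []).splits() == t.splits()


def test_prune_below_three_leaves_errors():
    t = parse_newick("((A,B),(C,D));", ABCD)
    with pytest.raises(ValueError):
        prune_taxa(t, ["A", "B"])


def test_tbr_on_four_leaves_gives_other_two_topologies():
    t = parse_newick("((A,B),(C,D));", ABCD)
    nbrs = list(tbr_neighbors(t))
    assert len(nbrs) == 2
    keys = {n.topology_key() for n in nbrs}
    assert t.topology_key() not in keys
    assert keys == {
        parse_newick("((A,C),(B,D));", ABCD).topology_key(),
        parse_newick("((A,D),(B,C));", ABCD).topology_key(),
    }


def test_tbr_contains_spr_neighborhood():
    taxa = ["A", "B", "C", "D", "E"]
    t = parse_newick("((A,B),C,(D,E));", taxa)
    tbr = {n.topology_key() for n in tbr_neighbors(t)}
    spr = {n.topology_key() for n in spr_neighbors(t)}
    assert spr <= tbr


def test_tbr_never_yields_input():
    taxa = [f"t{i}" for i in range(7)]
    rng = np.random.default_rng(2)
    for _ in range(5):
        t = random_topology(taxa, rng)
        for nb in tbr_neighbors(t):
            assert nb.topology_key() != t.topology_key()


def test_six_leaf_topologies_unique_and_tbr_connected():
    """Bipartition sets identify topologies (105 distinct on 6 leaves) and
    the TBR graph on them is connected."""
    taxa = [f"t{i}" for i in range(6)]
    all_keys = {}
    for t in all_unrooted_topologies(taxa):
        all_keys[t.topology_key()] = t
    assert len(all_keys) == 105
    start = next(iter(all_keys))
    seen = {start}
    frontier = [all_keys[start]]
    while frontier:
        t = frontier.pop()
        for nb in tbr_neighbors(t):
            k = nb.topology_key()
            if k not in seen:
                seen.add(k)
                frontier.append(nb)
    assert seen == set(all_keys)


def test_tree_from_splits_reconstructs_topology():
    taxa = [f"t{i}" for i in range(9)]
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = random_topology(taxa, rng)
        back = tree_from_splits(taxa, t.leaves(), t.splits())
        assert back.splits() == t.splits()


def test_constraint_enforce_and_forbid():
    t = parse_newick("((A,B),(C,D));", ABCD)
    t_bad = parse_newick("((A,C),(B,D));", ABCD)
    c = Constraint([{"A", "B"}])
    assert satisfies_constraint(t, c)
    assert not satisfies_constraint(t_bad, c)
    f = Constraint([{"A", "B"}], mode="forbid")
    assert not satisfies_constraint(t, f)
    assert satisfies_constraint(t_bad, f)


def test_group_needs_two_members():
    t = parse_newick("((A,B),(C,D));", ABCD)
    with pytest.raises(ValueError):
        Constraint([{"A"}])
    with pytest.raises(ValueError):
        displays_group(t, {"A"})


def test_random_topology_is_uniform_on_four_taxa():
    rng = np.random.default_rng(4)
    counts = {}
    n = 3000
    for _ in range(n):
        t = random_topology(ABCD, rng)
        (m,) = t.splits()
        counts[m] = counts.get(m, 0) + 1
    assert set(counts) == {0b1100, 0b1010, 0b0110}
    for c in counts.values():
        assert abs(c / n - 1 / 3) < 0.03
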