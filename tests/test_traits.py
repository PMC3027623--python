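import numpy as np
import pytest

from cladopipe.matrix import CharacterMatrix
from cladopipe.parsimony import character_length
from cladopipe.traits import (
    AUTAPOMORPHY,
    SYNAPOMORPHY,
    ContinuousTrait,
    DiscreteTrait,
    diagnose_clade,
    map_discrete_trait,
    reconstruct_continuous,
)
from cladopipe.tree import parse_newick, random_topology

from conftest import NAMES4, make_clean_eight_taxon
from oracles import grid_continuous_oracle

SACRUM = ("S1+S2", "DS+S1+S2", "S1+S2+CS", "DS+S1+S2+CS")
NAMES6 = ["t1", "t2", "t3", "t4", "t5", "t6"]
PECTINATE6 = "(t1,(t2,(t3,(t4,(t5,t6)))));"


def test_single_caudosacral_gain():
    tree = parse_newick(PECTINATE6, NAMES6)
    trait = DiscreteTrait(
        "sacrum", SACRUM,
        {"t1": 0, "t2": 1, "t3": 1, "t4": 1, "t5": 3, "t6": 3},
    )
    rec = map_discrete_trait(tree, trait)
    assert rec.cost == 2  # S1+S2 -> DS+S1+S2 -> DS+S1+S2+CS
    gains = [c for c in rec.changes if c.flag == SYNAPOMORPHY]
    assert len(gains) == 2
    cs_gains = [
        c for c in gains
        if c.to_states == (3,) and c.from_states == (1,)
    ]
    assert len(cs_gains) == 1
    assert not tree.is_leaf(cs_gains[0].child)


def test_midtree_deviation_flagged_autapomorphy():
    tree = parse_newick(PECTINATE6, NAMES6)
    trait = DiscreteTrait(
        "sacrum", SACRUM,
        {"t1": 0, "t2": 1, "t3": 2, "t4": 1, "t5": 3, "t6": 3},
    )
    rec = map_discrete_trait(tree, trait)
    auts = rec.changes_with_flag(AUTAPOMORPHY)
    assert len(auts) == 1
    assert tree.taxa[auts[0].child] == "t3"
    assert auts[0].to_states == (2,)


def test_constant_trait_no_changes():
    tree = parse_newick(PECTINATE6, NAMES6)
    trait = DiscreteTrait("x", ("a", "b"), {n: 0 for n in NAMES6})
    rec = map_discrete_trait(tree, trait)
    assert rec.cost == 0
    assert rec.changes == []


def test_all_missing_trait_rejected():
    tree = parse_newick(PECTINATE6, NAMES6)
    trait = DiscreteTrait("x", ("a", "b"), {})
    with pytest.raises(ValueError):
        map_discrete_trait(tree, trait)


def test_discrete_cost_equals_character_length():
    rng = np.random.default_rng(30)
    taxa = [f"t{i}" for i in range(7)]
    for _ in range(10):
        tree = random_topology(taxa, rng)
        obs = {n: int(rng.integers(3)) for n in taxa}
        trait = DiscreteTrait("x", ("a", "b", "c"), obs)
        rec = map_discrete_trait(tree, trait)
        m = CharacterMatrix.from_rows(taxa, [str(obs[n]) for n in taxa])
        assert rec.cost == character_length(tree, m, 0)


def test_continuous_two_level_reconstruction(tree_ab_cd):
    trait = ContinuousTrait("x", {"A": 1, "B": 1, "C": 3, "D": 3})
    rec = reconstruct_continuous(tree_ab_cd, trait)
    assert rec.cost == 2
    internal = {k: v for k, v in rec.node_intervals.items() if k >= 4}
    assert sorted(internal.values()) == [(1.0, 1.0), (3.0, 3.0)]


def test_continuous_constant_is_free(tree_ab_cd):
    trait = ContinuousTrait("x", {n: 7.0 for n in NAMES4})
    rec = reconstruct_continuous(tree_ab_cd, trait)
    assert rec.cost == 0
    assert all(v == (7.0, 7.0) for v in rec.node_intervals.values())


def test_continuous_cherry_outlier():
    taxa = ["A", "B", "C"]
    tree = parse_newick("(A,B,C);", taxa)
    rec = reconstruct_continuous(
        tree, ContinuousTrait("x", {"A": 1, "B": 11, "C": 1})
    )
    assert rec.cost == 10
    hub = [v for v in tree.adj if not tree.is_leaf(v)][0]
    assert rec.node_intervals[hub] == (1.0, 1.0)


def test_continuous_matches_grid_oracle():
    """Linear-parsimony cost and node intervals equal brute-force grid
    minimisation on small trees, including missing leaves."""
    rng = np.random.default_rng(31)
    for trial in range(12):
        n = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n)]
        tree = random_topology(taxa, rng)
        values = {
            t: float(rng.integers(1, 8))
            for t in taxa if rng.random() > 0.15
        }
        if len(values) < 2:
            continue
        trait = ContinuousTrait("x", values)
        rec = reconstruct_continuous(tree, trait)
        cost, node_sets = grid_continuous_oracle(tree, values)
        assert rec.cost == pytest.approx(cost)
        for v, vals in node_sets.items():
            assert rec.node_intervals[v] == (min(vals), max(vals)), f"node {v}"


def test_squared_change_point_estimates(tree_ab_cd):
    trait = ContinuousTrait("x", {"A": 1, "B": 1, "C": 3, "D": 3})
    rec = reconstruct_continuous(tree_ab_cd, trait, method="squared")
    for lo, hi in rec.node_intervals.values():
        assert lo == hi
    assert rec.cost > 0


def test_diagnose_clean_clades():
    matrix, true_tree, clades = make_clean_eight_taxon()
    names = matrix.taxon_names
    for ci, clade_ids in enumerate(clades[:4]):
        clade = {names[i] for i in clade_ids}
        recs = diagnose_clade([true_tree], matrix, clade)
        expected = {ci * 3, ci * 3 + 1, ci * 3 + 2}
        assert {r.char_index for r in recs} == expected
        assert all(r.unambiguous for r in recs)
    # the deep clade's stem is the unrooted central edge, shared with its
    # complement clade: both character blocks change there
    recs = diagnose_clade([true_tree], matrix, {names[i] for i in clades[4]})
    assert {r.char_index for r in recs} == {12, 13, 14, 15, 16, 17}
    assert all(r.unambiguous for r in recs)


def test_diagnose_rejects_nonmonophyletic_clade():
    matrix, true_tree, _ = make_clean_eight_taxon()
    with pytest.raises(ValueError, match="tree 0"):
        diagnose_clade([true_tree], matrix, {"A", "E"})


def test_diagnose_flags_ambiguous_stem_change():
    # B polymorphic 0/1: the single change sits on the stem of {C,D} in one
    # MPR and on B's terminal branch in another
    taxa = ["A", "B", "C", "D"]
    tree = parse_newick("((A,B),(C,D));", taxa)
    m = CharacterMatrix.from_rows(taxa, ["0", "(01)", "1", "1"])
    recs = diagnose_clade([tree], m, {"C", "D"})
    assert len(recs) == 1
    assert not recs[0].unambiguous
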