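"""Dollo reconstruction: single-gain histories, ledgers, costs, clades."""

import itertools
import math

import numpy as np
import pytest

from domevol.domainome import Domainome, build_matrix
from domevol.dollo import (
    clade_summary,
    compare_topologies,
    infer_history,
    reconstruct,
    tree_cost,
)
from domevol.simulate import SimConfig, random_tree, simulate_domain_evolution
from domevol.tree import RootedTree

from ._oracles import all_tree_shapes, dollo_min_losses


def random_matrix(tree, n_domains, rng, p=0.5):
    leaves = tree.leaf_names()
    domes = {l: set() for l in leaves}
    for j in range(n_domains):
        col = rng.random(len(leaves)) < p
        if not col.any():
            col[rng.integers(len(leaves))] = True
        for leaf, state in zip(leaves, col):
            if state:
                domes[leaf].add(f"d{j:04d}")
    return build_matrix([Domainome(l, s) for l, s in domes.items()])


class TestInferHistory:
    def test_present_everywhere_gains_at_root(self, quartet):
        h = infer_history(quartet, {"A": 1, "B": 1, "C": 1, "D": 1}, "d")
        assert h.gain_node == quartet.root.name
        assert not h.loss_edges
        assert h.present_nodes == {n.name for n in quartet.preorder()}

    def test_single_leaf_presence_gains_at_leaf(self, quartet):
        h = infer_history(quartet, {"A": 0, "B": 0, "C": 1, "D": 0}, "d")
        assert h.gain_node == "C"
        assert not h.loss_edges
        assert h.present_nodes == {"C"}

    def test_disjoint_presence_two_losses(self, quartet):
        h = infer_history(quartet, {"A": 1, "B": 0, "C": 1, "D": 0}, "d")
        assert h.gain_node == quartet.root.name
        assert h.loss_edges == {"B", "D"}
        assert h.cost == 3

    def test_all_absent_rejected(self, quartet):
        with pytest.raises(ValueError, match="all-absent"):
            infer_history(quartet, {"A": 0, "B": 0, "C": 0, "D": 0}, "d")

    def test_missing_leaf_rejected(self, quartet):
        with pytest.raises(ValueError, match="lacks states"):
            infer_history(quartet, {"A": 1, "B": 0, "C": 1}, "d")

    def test_gain_node_is_ancestor_of_presence_leaves(self):
        rng = np.random.default_rng(4)
        tree = random_tree(10, 17)
        for _ in range(50):
            col = {l: int(rng.random() < 0.4) for l in tree.leaf_names()}
            if not any(col.values()):
                continue
            h = infer_history(tree, col, "d")
            for leaf, state in col.items():
                if state:
                    assert tree.is_ancestor_or_self(h.gain_node, leaf)

    def test_loss_count_matches_bruteforce_on_enumerated_shapes(self):
        """Exhaustive check on every rooted shape with <= 5 leaves."""
        rng = np.random.default_rng(99)
        for n in range(2, 6):
            for tree in all_tree_shapes(n):
                leaves = tree.leaf_names()
                for _ in range(20):
                    col = {l: int(rng.random() < 0.5) for l in leaves}
                    if not any(col.values()):
                        col[leaves[0]] = 1
                    h = infer_history(tree, col, "d")
                    assert len(h.loss_edges) == dollo_min_losses(tree, col)


class TestReconstruct:
    def test_single_domain_everywhere(self, quartet):
        m = build_matrix([Domainome(l, {"d"}) for l in "ABCD"])
        ledger = reconstruct(quartet, m)
        assert ledger.cost == 1
        for node in quartet.preorder():
            assert ledger.present[node.name] == {"d"}
        assert ledger.root_present == {"d"}

    def test_conservation_identity_random_matrix(self, quartet):
        rng = np.random.default_rng(1)
        tree = random_tree(12, 8)
        m = random_matrix(tree, 50, rng)
        ledger = reconstruct(tree, m)
        for node in tree.preorder():
            if node.parent is None:
                continue
            expected = (
                ledger.present[node.parent.name] | ledger.gained[node.name]
            ) - ledger.lost[node.name]
            assert ledger.present[node.name] == expected
            assert not (ledger.gained[node.name] & ledger.lost[node.name])

    def test_zero_loss_simulation_recovered_exactly(self):
        tree = random_tree(12, 23)
        truth = simulate_domain_evolution(
            SimConfig(tree=tree, n_domains=100, loss_prob=0.0, seed=5)
        )
        ledger = reconstruct(tree, truth.matrix())
        for acc in truth.observable_domains:
            h = ledger.histories[acc]
            assert h.gain_node == truth.origin[acc]
            assert h.loss_edges == truth.loss_edges[acc] == frozenset()

    def test_leaf_state_agreement(self):
        rng = np.random.default_rng(6)
        tree = random_tree(9, 31)
        m = random_matrix(tree, 30, rng)
        ledger = reconstruct(tree, m)
        for leaf in tree.leaf_names():
            assert ledger.present[leaf] == m.row_domainome(leaf).domains

    def test_label_mismatch_reports_symmetric_difference(self, quartet):
        m = build_matrix([Domainome(l, {"d"}) for l in ["A", "B", "C", "E"]])
        with pytest.raises(ValueError, match="E"):
            reconstruct(quartet, m)

    def test_determinism_across_runs(self):
        rng = np.random.default_rng(8)
        tree = random_tree(10, 3)
        m = random_matrix(tree, 40, rng)
        l1, l2 = reconstruct(tree, m), reconstruct(tree, m)
        assert l1.present == l2.present
        assert l1.gained == l2.gained and l1.lost == l2.lost


class TestCost:
    def test_disjoint_presence_cost_three(self, quartet):
        m = build_matrix(
            [Domainome("A", {"d"}), Domainome("B", set()),
             Domainome("C", {"d"}), Domainome("D", set())]
        )
        assert tree_cost(quartet, m) == 3

    def test_child_order_permutation_invariance(self):
        rng = np.random.default_rng(10)
        t1 = RootedTree.from_newick("((A,B),(C,D),E);")
        t2 = RootedTree.from_newick("(E,(D,C),(B,A));")
        m = random_matrix(t1, 40, rng)
        assert tree_cost(t1, m) == tree_cost(t2, m)

    def test_cost_equals_ledger_cost(self):
        rng = np.random.default_rng(12)
        tree = random_tree(8, 44)
        m = random_matrix(tree, 25, rng)
        assert tree_cost(tree, m) == reconstruct(tree, m).cost

    def test_monotonicity_dropping_absent_leaf(self):
        """Removing a state-0 leaf never increases a domain's loss count."""
        rng = np.random.default_rng(13)
        tree = RootedTree.from_newick("((A,B),((C,D),(E,F)));")
        for _ in range(30):
            col = {l: int(rng.random() < 0.5) for l in tree.leaf_names()}
            absent = [l for l, s in col.items() if s == 0]
            if not absent or sum(col.values()) == 0:
                continue
            losses_full = len(infer_history(tree, col, "d").loss_edges)
            drop = absent[int(rng.integers(len(absent)))]
            pruned = _prune_leaf(tree, drop)
            sub_col = {l: col[l] for l in pruned.leaf_names()}
            losses_pruned = len(infer_history(pruned, sub_col, "d").loss_edges)
            assert losses_pruned <= losses_full


def _prune_leaf(tree, leaf_name):
    t = tree.copy()
    node = t.node(leaf_name)
    parent = node.parent
    parent.children.remove(node)
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        gp = parent.parent
        gp.children[gp.children.index(parent)] = only
        only.parent = gp
    return RootedTree(t.root)


class TestTopologyComparison:
    def test_identical_trees_identical_costs(self, quartet):
        rng = np.random.default_rng(14)
        m = random_matrix(quartet, 20, rng)
        ranked = compare_topologies([quartet, quartet.copy()], m)
        assert ranked[0][1] == ranked[1][1]

    def test_single_presence_only_matrix_costs_equal_domain_count(self):
        t1 = RootedTree.from_newick("((A,B),(C,D));")
        t2 = RootedTree.from_newick("((A,C),(B,D));")
        domes = [Domainome("A", {"d1"}), Domainome("B", {"d2"}),
                 Domainome("C", set()), Domainome("D", set())]
        m = build_matrix(domes)
        for _, cost in compare_topologies([t1, t2], m):
            assert cost == 2

    def test_leaf_set_mismatch_rejected(self, quartet):
        other = RootedTree.from_newick("((A,B),(C,E));")
        m = random_matrix(quartet, 5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="leaf set"):
            compare_topologies([quartet, other], m)

    def test_generating_tree_usually_cheapest(self):
        """Data simulated on T1 should rarely favor an SPR-perturbed tree."""
        from domevol.simulate import spr_perturb

        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            tree = random_tree(12, 1000 + rep)
            truth = simulate_domain_evolution(
                SimConfig(tree=tree, n_domains=300, loss_prob=0.15, seed=2000 + rep)
            )
            m = truth.matrix()
            alt = spr_perturb(tree, 3000 + rep, n_moves=2)
            if tree_cost(tree, m) <= tree_cost(alt, m):
                wins += 1
        assert wins >= int(0.8 * n_rep)


class TestCladeSummary:
    def test_single_leaf_clade_sd_flagged(self, quartet):
        m = build_matrix([Domainome(l, {"d"}) for l in "ABCD"])
        ledger = reconstruct(quartet, m)
        s = clade_summary(quartet, ledger, m.domainomes(), "A")
        assert s.n_genomes == 1
        assert s.extant_mean == 1.0
        assert s.extant_sd == 0.0 and not s.sd_defined

    def test_statistics_match_direct_recomputation(self):
        rng = np.random.default_rng(15)
        tree = random_tree(10, 77)
        m = random_matrix(tree, 60, rng)
        ledger = reconstruct(tree, m)
        domes = m.domainomes()
        clade = tree.root.children[0].name
        s = clade_summary(tree, ledger, domes, clade)
        sizes = [len(d) for d in domes if d.label in set(tree.subtree_leaves(clade))]
        assert s.extant_mean == pytest.approx(np.mean(sizes))
        if len(sizes) > 1:
            assert s.extant_sd == pytest.approx(np.std(sizes, ddof=1))
        assert s.present == len(ledger.present[clade])

    def test_gains_disjoint_from_parent_present(self):
        rng = np.random.default_rng(16)
        tree = random_tree(10, 55)
        m = random_matrix(tree, 60, rng)
        ledger = reconstruct(tree, m)
        for node in tree.preorder():
            if node.parent is None:
                continue
            assert not (ledger.gained[node.name] & ledger.present[node.parent.name])

    def test_unknown_clade_rejected(self, quartet):
        m = build_matrix([Domainome(l, {"d"}) for l in "ABCD"])
        ledger = reconstruct(quartet, m)
        with pytest.raises(KeyError):
            clade_summary(quartet, ledger, m.domainomes(), "NOPE")


class TestParsimonyBound:
    def test_inferred_cost_never_exceeds_truth(self):
        for rep in range(5):
            tree = random_tree(14, 500 + rep)
            truth = simulate_domain_evolution(
                SimConfig(tree=tree, n_domains=200, loss_prob=0.25, seed=600 + rep)
            )
            ledger = reconstruct(tree, truth.matrix())
            assert ledger.cost <= truth.total_events
            for acc in truth.observable_domains:
                h = ledger.histories[acc]
                assert tree.is_ancestor_or_self(truth.origin[acc], h.gain_node)
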