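"""GO layer: propagation, profiles, category flux, profile clustering."""

import numpy as np
import pytest

from domevol.domainome import Domainome, build_matrix
from domevol.dollo import reconstruct
from domevol.gofunc import (
    DomainGoMap,
    GoDag,
    GoTerm,
    category_flux,
    cluster_profiles,
    normalized_rf,
    profile,
    profile_coordinates,
    propagate,
)
from domevol.simulate import random_tree, simulate_go
from domevol.tree import RootedTree

from ._oracles import reachable_ancestors

ROOT, A, B, C, D = (f"GO:000000{i}" for i in range(1, 6))


class TestGoDag:
    def test_cycle_detected_and_named(self):
        terms = [GoTerm(t) for t in ("GO:1", "GO:2", "GO:3")]
        edges = [("GO:1", "GO:2"), ("GO:2", "GO:3"), ("GO:3", "GO:1")]
        with pytest.raises(ValueError, match="cyclic"):
            GoDag(terms, edges)

    def test_depth_is_longest_path(self, small_dag):
        assert small_dag.depth(ROOT) == 0
        assert small_dag.depth(A) == 1
        assert small_dag.depth(B) == 2
        assert small_dag.depth(C) == 1

    def test_ancestors(self, small_dag):
        assert small_dag.ancestors(B) == {A, ROOT}
        assert small_dag.ancestors(ROOT) == frozenset()
        assert ROOT in small_dag.ancestors(B, reflexive=False)
        assert B in small_dag.ancestors(B, reflexive=True)


class TestPropagate:
    def test_leaf_annotation_gains_all_ancestors(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        pmap = propagate(small_dag, gomap)
        assert pmap.terms_for("PF1") == {B, A, ROOT}

    def test_idempotent(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}, "PF2": {C, D}}, small_dag)
        once = propagate(small_dag, gomap)
        twice = propagate(small_dag, once)
        assert once.annotations == twice.annotations

    def test_matches_reachability_oracle_on_random_dag(self):
        dag, gomap, _ = simulate_go(40, 4, 100, seed=3)
        pmap = propagate(dag, gomap)
        for acc, terms in gomap.annotations.items():
            expected = set(terms)
            for t in terms:
                expected |= reachable_ancestors(dag.parents, t)
            assert pmap.terms_for(acc) == expected

    def test_unknown_terms_dropped_with_warning(self, small_dag, caplog):
        with caplog.at_level("WARNING"):
            gomap = DomainGoMap({"PF1": {B, "GO:9999999"}}, small_dag)
        assert gomap.terms_for("PF1") == {B}
        assert "unknown GO" in caplog.text


class TestProfile:
    def test_everything_annotated_to_term_gives_100(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}, "PF2": {D}}, small_dag)
        prof = profile(Domainome("g", {"PF1", "PF2"}), small_dag, gomap, [A])
        assert prof.fractions[A] == 100.0  # both propagate through a

    def test_unannotated_term_gives_0(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        prof = profile(Domainome("g", {"PF1"}), small_dag, gomap, [C])
        assert prof.fractions[C] == 0.0

    def test_counts_match_direct_oracle(self):
        dag, gomap, _ = simulate_go(30, 3, 200, seed=8)
        rng = np.random.default_rng(9)
        domains = sorted(gomap.annotations)
        pick = {domains[i] for i in rng.choice(len(domains), 50, replace=False)}
        pmap = propagate(dag, gomap)
        terms = sorted(dag.terms)[:10]
        prof = profile(Domainome("g", pick), dag, pmap, terms, propagated=True)
        annotated = [d for d in pick if pmap.terms_for(d)]
        for t in terms:
            expected = 100.0 * sum(1 for d in pick if t in pmap.terms_for(d)) / len(annotated)
            assert prof.fractions[t] == pytest.approx(expected)

    def test_child_fraction_never_exceeds_ancestor(self):
        dag, gomap, _ = simulate_go(30, 3, 200, seed=12)
        rng = np.random.default_rng(13)
        domains = sorted(gomap.annotations)
        pick = {domains[i] for i in rng.choice(len(domains), 60, replace=False)}
        prof = profile(Domainome("g", pick), dag, gomap, sorted(dag.terms))
        for child, parents in dag.parents.items():
            for p in parents:
                assert prof.fractions[child] <= prof.fractions[p] + 1e-9

    def test_zero_denominator_flagged(self, small_dag):
        gomap = DomainGoMap({}, small_dag)
        prof = profile(Domainome("g", {"PFX"}), small_dag, gomap, [A])
        assert prof.fractions[A] is None and not prof.defined[A]

    def test_invariant_to_accession_renaming(self, small_dag):
        gomap1 = DomainGoMap({"PF1": {B}, "PF2": {C}}, small_dag)
        gomap2 = DomainGoMap({"X1": {B}, "X2": {C}}, small_dag)
        p1 = profile(Domainome("g", {"PF1", "PF2"}), small_dag, gomap1, [A, C])
        p2 = profile(Domainome("g", {"X1", "X2"}), small_dag, gomap2, [A, C])
        assert p1.fractions == p2.fractions

    def test_unknown_term_rejected(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        with pytest.raises(KeyError):
            profile(Domainome("g", {"PF1"}), small_dag, gomap, ["GO:7777777"])


class TestCategoryFlux:
    @pytest.fixture
    def ledger_and_map(self, quartet, small_dag):
        m = build_matrix(
            [Domainome("A", {"r1", "m1"}), Domainome("B", {"r1"}),
             Domainome("C", {"m1", "m2"}), Domainome("D", {"r2"})]
        )
        ledger = reconstruct(quartet, m)
        gomap = DomainGoMap(
            {"r1": {B}, "r2": {B}, "m1": {C}, "m2": {C}}, small_dag
        )
        return ledger, gomap

    def test_empty_category_gives_zero(self, ledger_and_map, quartet, small_dag):
        ledger, gomap = ledger_and_map
        flux = category_flux(ledger, ["N1", "N2", "A"], small_dag, gomap, D)
        assert flux.mean_gains == 0.0 and flux.mean_losses == 0.0

    def test_single_branch_means_equal_counts(self, ledger_and_map, quartet, small_dag):
        ledger, gomap = ledger_and_map
        flux = category_flux(ledger, ["N1", "N2"], small_dag, gomap, A)
        assert flux.mean_gains == flux.gains_per_branch[0]
        assert flux.mean_losses == flux.losses_per_branch[0]

    def test_means_times_branch_count_equal_sums(self, ledger_and_map, small_dag):
        ledger, gomap = ledger_and_map
        flux = category_flux(ledger, ["N1", "N2", "A"], small_dag, gomap, ROOT)
        n = len(flux.branches)
        assert flux.mean_gains * n == pytest.approx(sum(flux.gains_per_branch))
        assert flux.mean_losses * n == pytest.approx(sum(flux.losses_per_branch))

    def test_disconnected_path_rejected(self, ledger_and_map, small_dag):
        ledger, gomap = ledger_and_map
        with pytest.raises(ValueError, match="connected"):
            category_flux(ledger, ["N1", "A"], small_dag, gomap, ROOT)

    def test_planted_category_bias_ordering(self, small_dag):
        """Gains drawn from a 'regulatory' pool and losses from a 'metabolic'
        pool must produce the corresponding mean ordering."""
        tree = RootedTree.from_newick("(((A,B),C),D);")  # N1 > N2 > N3=(A,B)
        reg = {f"r{i}" for i in range(6)}
        met = {f"m{i}" for i in range(6)}
        # regs gained at the (A,B) ancestor; mets (present at the root via
        # C and D) lost on the branch into it
        m = build_matrix(
            [Domainome("A", reg), Domainome("B", reg),
             Domainome("C", met), Domainome("D", met)]
        )
        ledger = reconstruct(tree, m)
        gomap = DomainGoMap(
            {**{r: {B} for r in reg}, **{mt: {C} for mt in met}}, small_dag
        )
        path = ["N1", "N2", "N3"]
        reg_flux = category_flux(ledger, path, small_dag, gomap, B)
        met_flux = category_flux(ledger, path, small_dag, gomap, C)
        assert reg_flux.mean_gains > reg_flux.mean_losses
        assert met_flux.mean_losses > met_flux.mean_gains


class TestCoordinatesAndClustering:
    def test_coordinates_extraction(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}, "PF2": {C}}, small_dag)
        prof = profile(Domainome("g", {"PF1", "PF2"}), small_dag, gomap, [B, C])
        rows = profile_coordinates([prof], B, C)
        assert rows == [("g", 50.0, 50.0)]

    def test_identical_domainomes_identical_coordinates(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        p1 = profile(Domainome("g1", {"PF1"}), small_dag, gomap, [B, C])
        p2 = profile(Domainome("g2", {"PF1"}), small_dag, gomap, [B, C])
        rows = profile_coordinates([p1, p2], B, C)
        assert rows[0][1:] == rows[1][1:]

    def test_missing_term_names_label(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        prof = profile(Domainome("gX", {"PF1"}), small_dag, gomap, [B])
        with pytest.raises(ValueError, match="gX"):
            profile_coordinates([prof], B, C)

    def test_identical_profiles_merge_first(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}, "PF2": {C}}, small_dag)
        same1 = profile(Domainome("L1", {"PF1"}), small_dag, gomap, [B, C])
        same2 = profile(Domainome("L2", {"PF1"}), small_dag, gomap, [B, C])
        other = profile(Domainome("L3", {"PF2"}), small_dag, gomap, [B, C])
        ref = RootedTree.from_newick("((L1,L2),L3);")
        res = cluster_profiles([same1, same2, other], ref)
        # first merge joins the two identical profiles at distance 0
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_outlier_joins_last(self, small_dag):
        gomap = DomainGoMap({f"PF{i}": {B} for i in range(1, 4)} | {"PFm": {C}}, small_dag)
        near1 = profile(Domainome("L1", {"PF1", "PF2"}), small_dag, gomap, [B, C])
        near2 = profile(Domainome("L2", {"PF2", "PF3"}), small_dag, gomap, [B, C])
        outlier = profile(Domainome("L3", {"PFm"}), small_dag, gomap, [B, C])
        ref = RootedTree.from_newick("((L1,L2),L3);")
        res = cluster_profiles([near1, near2, outlier], ref)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_mismatched_term_vectors_rejected(self, small_dag):
        gomap = DomainGoMap({"PF1": {B}}, small_dag)
        p1 = profile(Domainome("L1", {"PF1"}), small_dag, gomap, [B])
        p2 = profile(Domainome("L2", {"PF1"}), small_dag, gomap, [B, C])
        p3 = profile(Domainome("L3", {"PF1"}), small_dag, gomap, [B])
        ref = RootedTree.from_newick("((L1,L2),L3);")
        with pytest.raises(ValueError, match="term vector"):
            cluster_profiles([p1, p2, p3], ref)


class TestNormalizedRF:
    def test_identical_topologies_distance_zero(self):
        assert normalized_rf("((A,B),(C,D));", "((B,A),(D,C));") == 0.0

    def test_distance_bounded(self):
        d = normalized_rf("((A,B),(C,D),E);", "((A,C),(B,D),E);")
        assert 0.0 < d <= 1.0
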