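"""Rewrites (expd/cntr/phylo/shortcut removal), canonical constructions
(Hasse, cluster network), isomorphism, and the PCC map."""
import random

import pytest

import phyclus as pc
from phyclus import errors as E


class TestExpd:
    def test_expd_at_hybrid_with_single_child(self, fx):
        d1 = fx["F_D1"]
        e = pc.expd(d1, "h")
        assert len(e) == 8
        assert pc.clustering_system(e) == pc.clustering_system(d1)
        # the expanded hybrid still has outdegree 1, so the result is not
        # phylogenetic (the expansion criterion needs outdeg != 1)
        assert not e.is_phylogenetic()

    def test_expd_at_leaf_not_phylogenetic(self, fx):
        e = pc.expd(fx["F_T3"], "1")
        assert not e.is_phylogenetic()
        assert pc.clustering_system(e) == pc.clustering_system(fx["F_T3"])

    def test_expd_at_root(self, fx):
        e = pc.expd(fx["F_T3"], "r")
        assert e.root != "r"
        assert e.children(e.root) == {"r"}

    def test_expd_preserves_level_shortcuts_and_clusters(self, random_level1_nets):
        rng = random.Random(5)
        for net in random_level1_nets[:20]:
            w = rng.choice(sorted(net.vertices))
            e = pc.expd(net, w)
            assert e.level() == net.level()
            assert e.is_shortcut_free() == net.is_shortcut_free()
            assert pc.clustering_system(e) == pc.clustering_system(net)


class TestCntr:
    def test_inverse_of_expd(self, fx):
        d1 = fx["F_D1"]
        e = pc.expd(d1, "h")
        back = pc.cntr(e, ("h__exp1", "h"))
        assert pc.isomorphic(back, d1) is not None

    def test_refuses_shortcut(self, fx):
        with pytest.raises(E.ShortcutContraction):
            pc.cntr(fx["F_SC"], ("r", "h"))

    def test_unknown_arc(self, fx):
        with pytest.raises(E.UnknownArc):
            pc.cntr(fx["F_T3"], ("1", "r"))

    def test_contract_root_arc(self, fx):
        c = pc.cntr(fx["F_T3"], ("r", "a"))
        assert c.root == "a"
        assert c.children("a") == {"1", "2", "3"}

    def test_never_increases_level(self, random_level1_nets):
        rng = random.Random(9)
        for net in random_level1_nets[:20]:
            arcs = sorted(a for a in net.arcs if not net.is_shortcut(a))
            arc = rng.choice(arcs)
            assert pc.cntr(net, arc).level() <= net.level()


class TestPhyloReduce:
    def test_chain_collapses_to_leaf(self):
        n = pc.build_network([("r", "a"), ("a", "x")])
        red = pc.phylo_reduce(n)
        assert len(red) == 1 and red.labels == frozenset({"x"})

    def test_fixpoint_on_phylogenetic(self, fx):
        assert pc.phylo_reduce(fx["F_D1"]) is not None
        assert pc.isomorphic(pc.phylo_reduce(fx["F_D1"]), fx["F_D1"])

    def test_cntr_star_undoes_leaf_expansion(self, fx):
        e = pc.expd(fx["F_T3"], "1")
        restored = pc.cntr_star(e, ("1__exp1", "1"))
        assert pc.isomorphic(restored, fx["F_T3"]) is not None


class TestRemoveShortcut:
    def test_example(self, fx):
        sc = fx["F_SC"]
        red = pc.remove_shortcut(sc, ("r", "h"))
        assert red.vertices == sc.vertices
        for v in sc.vertices:
            assert red.cluster(v) == sc.cluster(v)
        assert red.shortcuts() == set()

    def test_refuses_non_shortcut(self, fx):
        with pytest.raises(E.NotAShortcut):
            pc.remove_shortcut(fx["F_D1"], ("r", "u"))


class TestHasse:
    def test_two_leaf_hierarchy(self, fx):
        h = pc.hasse(fx["F_CSA"])
        assert len(h) == 3
        assert h.children(h.root) == {"a", "b"}

    def test_tree_system_recovers_tree(self, fx):
        h = pc.hasse(pc.clustering_system(fx["F_T3"]))
        assert pc.isomorphic(h, fx["F_T3"]) is not None

    def test_cs12_hasse(self, fx):
        h = pc.hasse(fx["F_CS12"])
        assert len(h) == 10
        assert h.hybrids == {"x", "y", "z", "v"}  # the four singletons

    def test_hasse_is_regular_with_same_system(self, random_level1_systems):
        for cs in random_level1_systems[:25]:
            h = pc.hasse(cs)
            assert pc.clustering_system(h) == cs
            rec = pc.classify_regularity(h)
            assert rec.regular
            assert not any(h.outdeg(v) == 1 for v in h.vertices)

    def test_hasse_is_least_resolved(self, fx):
        """No single contraction of the Hasse network preserves its clusters
        (shortcut removal is impossible: it is shortcut-free)."""
        h = pc.hasse(pc.clustering_system(fx["F_D1"]))
        assert h.shortcuts() == set()
        cs = pc.clustering_system(h)
        for arc in sorted(h.arcs):
            contracted = pc.cntr(h, arc)
            assert pc.clustering_system(contracted) != cs


class TestRegularize:
    def test_diamond(self, fx):
        r = pc.regularize(fx["F_D1"])
        assert len(r) == 6
        assert pc.isomorphic(
            r, pc.hasse(pc.clustering_system(fx["F_D1"]))
        ) is not None

    def test_shortcut_triangle_reduces_to_tree(self, fx):
        r = pc.regularize(fx["F_SC"])
        assert len(r) == 3
        assert r.labels == frozenset({"x", "y"})
        assert not r.hybrids

    def test_hasse_is_fixpoint(self, fx):
        h = pc.hasse(fx["F_CS12"])
        assert pc.isomorphic(pc.regularize(h), h) is not None

    def test_requires_pcc(self, fx):
        with pytest.raises(E.PccViolation):
            pc.regularize(fx["F_P1"])

    def test_order_independence(self, random_level1_nets):
        """Applying the two reductions in random order reaches the same
        network as the deterministic schedule."""
        rng = random.Random(17)
        for net in random_level1_nets[:10]:
            reference = pc.regularize(net)
            for _ in range(2):
                current = net
                while True:
                    ops = [("sc", a) for a in sorted(current.shortcuts())]
                    ops += [
                        ("ct", (u, next(iter(current.children(u)))))
                        for u in sorted(current.vertices)
                        if current.outdeg(u) == 1
                    ]
                    if not ops:
                        break
                    kind, arc = rng.choice(ops)
                    current = (
                        pc.remove_shortcut(current, arc)
                        if kind == "sc"
                        else pc.cntr(current, arc)
                    )
                assert pc.isomorphic(current, reference) is not None


class TestClusterNetwork:
    def test_hierarchy_gives_its_tree(self, fx):
        n = pc.cluster_network_of(fx["F_CSA"])
        assert len(n) == 3 and not n.hybrids

    def test_diamond_system(self, fx):
        n = pc.cluster_network_of(pc.clustering_system(fx["F_D1"]))
        assert pc.isomorphic(n, fx["F_D1"]) is not None

    def test_cs12_counts(self, fx):
        n = pc.cluster_network_of(fx["F_CS12"])
        assert len(n) == 14
        assert len(n.hybrids) == 4
        assert len(n.omnians) == 5

    def test_class_membership_and_uniqueness(self, random_level1_systems):
        for cs in random_level1_systems[:20]:
            n = pc.cluster_network_of(cs)
            rec = pc.classify_regularity(n)
            assert rec.cluster_network
            assert pc.clustering_system(n) == cs

    def test_separated_witnesses_are_the_cluster_network(self, random_level1_nets):
        """Any generated separated phylogenetic shortcut-free network equals
        the cluster network of its clustering system (uniqueness)."""
        for net in random_level1_nets[:25]:
            if net.is_separated() and net.is_phylogenetic() and net.is_shortcut_free():
                rebuilt = pc.cluster_network_of(pc.clustering_system(net))
                assert pc.isomorphic(net, rebuilt) is not None


class TestIsomorphism:
    def test_identity(self, fx):
        phi = pc.isomorphic(fx["F_D1"], fx["F_D1"])
        assert phi is not None and phi.is_graph_isomorphism(fx["F_D1"], fx["F_D1"])

    def test_subdivision_not_isomorphic(self, fx):
        d1 = fx["F_D1"]
        arcs = (d1.arcs - {("h", "x")}) | {("h", "m"), ("m", "x")}
        sub = pc.build_network(arcs)
        assert pc.clustering_system(sub) == pc.clustering_system(d1)
        assert pc.isomorphic(sub, d1) is None

    def test_leaf_fixing_vs_free(self):
        t1 = pc.build_network([("r", "a"), ("r", "c"), ("a", "x"), ("a", "y")])
        t2 = pc.build_network([("r", "a"), ("r", "x"), ("a", "c"), ("a", "y")])
        assert pc.isomorphic(t1, t2, fix_leaves=True) is None
        assert pc.isomorphic(t1, t2, fix_leaves=False) is not None


class TestPhiPcc:
    def test_identity(self, fx):
        phi = pc.phi_pcc(fx["F_D1"], fx["F_D1"])
        assert phi.as_dict() == {v: v for v in fx["F_D1"].vertices}

    def test_multiset_mismatch(self, fx):
        with pytest.raises(E.MultisetMismatch):
            pc.phi_pcc(fx["F_D1"], fx["F_T3"])

    def test_requires_pcc(self, fx):
        with pytest.raises(E.PccViolation):
            pc.phi_pcc(fx["F_P1"], fx["F_P1"])

    def test_semi_regular_networks_with_equal_multisets(self, random_level1_systems):
        """Independently rebuilt semi-regular copies are matched by the PCC
        map, which is then a leaf-fixing graph isomorphism."""
        for i, cs in enumerate(random_level1_systems[:20]):
            net = pc.cluster_network_of(cs)
            renamed = net.relabeled(
                {v: f"w{i}_{j}" for j, v in enumerate(sorted(net.vertices - net.leaves))}
            )
            phi = pc.phi_pcc(net, renamed)
            assert phi.fixes_leaves
            assert phi.is_graph_isomorphism(net, renamed)


class TestLcaUnderContraction:
    def test_pairwise_lcas_survive_contraction(self, random_level1_nets):
        """Contracting an arc into a non-hybrid non-leaf vertex only renames
        the lca that used to be the suppressed parent."""
        import itertools

        rng = random.Random(23)
        for net in random_level1_nets[:10]:
            candidates = sorted(
                (u, v)
                for u, v in net.arcs
                if not net.is_hybrid(v) and not net.is_leaf(v)
            )
            if not candidates:
                continue
            v2, v = rng.choice(candidates)
            reduced = pc.cntr(net, (v2, v))
            for x, y in itertools.combinations(sorted(net.labels), 2):
                before = pc.lca_set(net, {x, y}).vertex
                after = pc.lca_set(reduced, {x, y}).vertex
                assert after == (v if before == v2 else before)
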