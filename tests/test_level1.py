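"""Level-1 theory: overlap-block sets, the closed+(L) characterization,
compatibility testing, and the galled/binary subclasses."""
import itertools
from collections import defaultdict

import pytest

import phyclus as pc
from phyclus import errors as E


def _hasse_blocks_as_clusters(cs):
    h = pc.hasse(cs)
    return sorted(
        sorted(sorted(h.cluster(v)) for v in b.vertices) for b in h.blocks()
    )


class TestOverlapBlockSets:
    def test_diamond_hybrid_cluster(self, fx):
        cs = pc.clustering_system(fx["F_D1"])
        obs = pc.overlap_block_sets(cs, {"x"})
        assert obs.b0 == frozenset(
            {frozenset({"x", "y"}), frozenset({"x", "z"})}
        )
        assert obs.u_set == frozenset({"x", "y", "z"})
        assert obs.top == frozenset({"x", "y", "z"})
        assert obs.bcal == obs.b0 | {frozenset({"x"}), obs.top}

    def test_tree_cluster_without_overlaps(self, fx):
        cs = pc.clustering_system(fx["F_T3"])
        obs = pc.overlap_block_sets(cs, {"1"})
        assert obs.b0 == frozenset()
        assert obs.top == frozenset({"1", "2"})

    def test_ground_set(self, fx):
        cs = pc.clustering_system(fx["F_T3"])
        obs = pc.overlap_block_sets(cs, cs.X)
        assert obs.top == cs.X and obs.dbar == frozenset()

    def test_partition_into_below_above(self, fx):
        cs = pc.clustering_system(fx["F_D1"])
        for c in cs.clusters:
            obs = pc.overlap_block_sets(cs, c)
            assert obs.d | obs.dbar | {c} == cs.clusters
            assert not (obs.d & obs.dbar)

    def test_not_a_cluster(self, fx):
        with pytest.raises(E.NotACluster):
            pc.overlap_block_sets(fx["F_CSA"], {"a", "q"})

    def test_b0_sets_pairwise_disjoint(self, random_level1_systems):
        for cs in random_level1_systems[:25]:
            seen = {}
            for c in cs.clusters:
                for member in pc.overlap_block_sets(cs, c).b0:
                    assert seen.setdefault(member, c) == c


class TestBlocksFromClusters:
    def test_diamond_block(self, fx):
        cs = pc.clustering_system(fx["F_D1"])
        blocks = pc.level1_blocks_from_clusters(cs)
        nontrivial = [b for b in blocks if len(b) > 2]
        assert nontrivial == [
            frozenset(
                {frozenset({"x"}), frozenset({"x", "y"}), frozenset({"x", "z"}),
                 frozenset({"x", "y", "z"})}
            )
        ]

    def test_hierarchy_all_trivial(self, fx):
        blocks = pc.level1_blocks_from_clusters(pc.clustering_system(fx["F_T3"]))
        assert all(len(b) == 2 for b in blocks)

    def test_matches_hasse_blocks(self, random_level1_systems):
        for cs in random_level1_systems[:40]:
            from_clusters = sorted(
                sorted(sorted(c) for c in b)
                for b in pc.level1_blocks_from_clusters(cs)
            )
            assert from_clusters == _hasse_blocks_as_clusters(cs)

    def test_precondition(self, fx):
        with pytest.raises(E.PreconditionViolated):
            pc.level1_blocks_from_clusters(fx["F_CS11"])  # not closed


class TestSystemPredicates:
    def test_examples(self, fx):
        cs_d1 = pc.clustering_system(fx["F_D1"])
        assert pc.is_level1_system(cs_d1)
        assert pc.is_galled_system(cs_d1)
        assert pc.is_binary_l1_system(cs_d1)
        assert not pc.is_level1_system(fx["F_CS12"])  # (L) fails
        assert not pc.is_galled_system(fx["F_CS12"])
        assert not pc.is_binary_l1_system(fx["F_CS12"])
        assert not pc.is_level1_system(fx["F_CS11"])  # not closed

    def test_characterization_roundtrip(self, random_level1_nets):
        """Clusters of a level-1 network pass the characterization, and the
        Hasse network built from them is level-1 and phylogenetic with the
        same clusters."""
        for net in random_level1_nets[:40]:
            cs = pc.clustering_system(net)
            assert pc.is_level1_system(cs)
            h = pc.hasse(cs)
            assert h.level() <= 1
            assert h.is_phylogenetic()
            assert pc.clustering_system(h) == cs

    def test_hierarchy_needs_hybrids_beyond_level1(self, random_level1_nets):
        """No generated phylogenetic shortcut-free level-1 non-tree has a
        hierarchy as its clustering system."""
        for net in random_level1_nets:
            if net.hybrids and net.is_shortcut_free():
                assert not pc.clustering_system(net).is_hierarchy()

    def test_children_overlap_iff_cycle_maximum(self, random_level1_nets):
        for net in random_level1_nets[:25]:
            if not net.is_shortcut_free():
                continue
            cycle_tops = {b.max_vertex for b in net.nontrivial_blocks()}
            for v in net.vertices:
                kids = sorted(net.children(v))
                has_overlap = any(
                    net.cluster(a) & net.cluster(b)
                    for a, b in itertools.combinations(kids, 2)
                )
                assert has_overlap == (v in cycle_tops)


class TestCompatibility:
    def test_incompatible_without_L(self, fx):
        res = pc.check_l1_compatibility(fx["F_CS12"])
        assert not res.compatible and res.network is None

    def test_four_cycle_witness(self):
        cs = pc.ClusteringSystem(
            "xyz", [{"x"}, {"y"}, {"z"}, {"x", "y"}, {"y", "z"}, {"x", "y", "z"}]
        )
        res = pc.check_l1_compatibility(cs)
        assert res.compatible
        net = res.network
        assert net.level() == 1 and net.is_separated() and net.is_phylogenetic()
        assert net.is_galled_tree()
        assert cs.clusters <= pc.clustering_system(net).clusters
        # the intersection {y} is already a singleton: nothing is added
        assert res.n_clusters_added == 0

    def test_hierarchy_gives_tree(self, fx):
        res = pc.check_l1_compatibility(fx["F_CSA"])
        assert res.compatible and not res.network.hybrids

    def test_non_closed_systems_gain_clusters(self, fx):
        res = pc.check_l1_compatibility(fx["F_CS11"])
        assert res.compatible and res.n_clusters_added == 1
        assert pc.clustering_system(res.network) == pc.intersection_closure(
            fx["F_CS11"]
        )

    def test_compatible_iff_L_on_random_systems(self, random_level1_systems):
        for cs in random_level1_systems[:30]:
            res = pc.check_l1_compatibility(cs)
            assert res.compatible == cs.satisfies_L()


class TestBinaryCompatibility:
    def test_four_cycle_binary(self):
        cs = pc.ClusteringSystem(
            "xyz", [{"x"}, {"y"}, {"z"}, {"x", "y"}, {"y", "z"}, {"x", "y", "z"}]
        )
        res = pc.binary_l1_compatible(cs)
        assert res.compatible
        assert res.network.is_binary() and res.network.level() == 1

    def test_cs12_rejected_by_indegree(self, fx):
        res = pc.binary_l1_compatible(fx["F_CS12"])
        assert not res.compatible

    def test_star_hierarchy_resolved_by_caterpillar(self):
        cs = pc.ClusteringSystem(
            "1234", [{"1"}, {"2"}, {"3"}, {"4"}, {"1", "2", "3", "4"}]
        )
        res = pc.binary_l1_compatible(cs)
        assert res.compatible
        assert res.network.is_binary()
        assert cs.clusters <= pc.clustering_system(res.network).clusters


class TestResolveToBinary:
    def test_star_tree(self):
        star = pc.build_network([("r", str(i)) for i in range(1, 5)])
        b = pc.resolve_to_binary(star)
        assert b.is_binary()
        assert pc.clustering_system(star).clusters <= pc.clustering_system(b).clusters

    def test_four_cycle_hasse(self):
        cs = pc.ClusteringSystem(
            "xyz", [{"x"}, {"y"}, {"z"}, {"x", "y"}, {"y", "z"}, {"x", "y", "z"}]
        )
        b = pc.resolve_to_binary(pc.hasse(cs))
        assert b.is_binary() and b.level() == 1

    def test_binary_input_is_fixpoint(self, fx):
        assert pc.isomorphic(pc.resolve_to_binary(fx["F_D1"]), fx["F_D1"])

    def test_rejects_high_indegree_hybrids(self, fx):
        with pytest.raises(E.HybridIndegreeTooHigh):
            pc.resolve_to_binary(pc.hasse(fx["F_CS12"]))

    def test_rejects_higher_level(self):
        # a binary-style level-2 block: all hybrids have indegree 2
        level2 = pc.build_network(
            [("r", "u1"), ("r", "u2"), ("u1", "h1"), ("u2", "h1"),
             ("u1", "h2"), ("h1", "h2"), ("h2", "x"), ("u2", "y")]
        )
        assert level2.level() == 2
        with pytest.raises(E.NotLevel1):
            pc.resolve_to_binary(level2)

    def test_random_galled_networks(self, random_level1_nets):
        for net in random_level1_nets[:20]:
            if all(net.indeg(h) == 2 for h in net.hybrids):
                b = pc.resolve_to_binary(net)
                assert b.is_binary() and b.level() <= 1
                assert (
                    pc.clustering_system(net).clusters
                    <= pc.clustering_system(b).clusters
                )


class TestLeastResolved:
    def test_examples(self, fx):
        assert len(pc.least_resolved_level1(fx["F_SC"])) == 3
        assert len(pc.least_resolved_level1(fx["F_D1"])) == 6
        h = pc.hasse(pc.clustering_system(fx["F_D1"]))
        assert pc.isomorphic(pc.least_resolved_level1(h), h) is not None

    def test_equals_hasse(self, random_level1_nets):
        for net in random_level1_nets[:15]:
            lr = pc.least_resolved_level1(net)
            assert pc.isomorphic(
                lr, pc.hasse(pc.clustering_system(net))
            ) is not None
            assert pc.classify_regularity(lr).regular

    def test_rejects_higher_level(self):
        with pytest.raises(E.NotLevel1):
            pc.least_resolved_level1(pc.gen_lemma15(4, 3))


class TestSmallEnumerationLaws:
    def test_multiset_encodes_on_three_leaves(self):
        nets = list(pc.enumerate_small_networks(["1", "2", "3"]))
        groups = defaultdict(list)
        for n in nets:
            groups[pc.cluster_multiset(n).canonical()].append(n)
        assert all(len(g) == 1 for g in groups.values())

    def test_unique_separated_shortcut_free_witness_per_system(self):
        """Within the quasi-binary universe on three leaves, each clustering
        system has exactly one separated shortcut-free representative."""
        nets = pc.enumerate_small_networks(
            ["1", "2", "3"], constraints={"shortcut_free": True}
        )
        by_cs = defaultdict(list)
        for n in nets:
            assert n.is_separated()  # quasi-binary networks are separated
            by_cs[pc.clustering_system(n)].append(n)
        for group in by_cs.values():
            assert len(group) == 1
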