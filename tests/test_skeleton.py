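"""Skeleton model: SWC I/O, tree morphometry, dendritic-root inference."""

import io

import networkx as nx
import numpy as np
import pytest

from mbx.skeleton import (
    NeuronSkeleton,
    SkeletonNode,
    SwcParseError,
    extract_axonlets,
    find_dendritic_root,
    geodesic_distance,
    read_swc,
    read_synapse_table,
    strahler_order,
    validate,
    write_swc,
)
from mbx.synth import SkeletonGenSpec, SynapseClassSpec, gen_skeleton

from conftest import build_skeleton, random_tree


class TestSwcIO:
    def test_three_node_chain(self):
        swc = "# comment\n1 0 0 0 0 1 -1\n2 0 0 0 5 1 1\n3 0 0 0 9 1 2\n"
        sk = read_swc(swc, name="chain")
        assert len(sk) == 3 and sk.root == 1
        assert sk.cable_length() == pytest.approx(9.0)
        assert sk.node_order == [1, 2, 3]

    def test_unit_scale_converts_to_nm(self):
        swc = "1 0 0 0 0 1 -1\n2 0 0 0 2 1 1\n"
        sk = read_swc(swc, unit_scale=1000.0)
        assert sk.cable_length() == pytest.approx(2000.0)

    @pytest.mark.parametrize("swc, message", [
        ("1 0 0 0 0 1 -1\n2 0 0 0 1 1 -1\n", "multiple roots"),
        ("1 0 0 0 0 1 -1\n1 0 0 0 1 1 1\n", "duplicate"),
        ("1 0 0 0 0 1 -1\n2 0 0 0 1 1 9\n", "missing parent"),
        ("1 0 0 0 0 1 2\n2 0 0 0 1 1 1\n", "cycle|no root"),
        ("1 0 0 0 0 1 -1\n2 0 0 0 1 1 3\n3 0 0 0 2 1 2\n", "cycle"),
        ("1 0 0 0 0 1\n", "7 columns"),
    ])
    def test_parse_errors(self, swc, message):
        with pytest.raises(SwcParseError, match=message):
            read_swc(swc)

    def test_round_trip_on_generated_skeletons(self):
        for seed in range(5):
            sk, _, _ = gen_skeleton(SkeletonGenSpec(n_nodes=120, seed=seed))
            text = write_swc(sk)
            again = read_swc(io.StringIO(text), name=sk.name)
            assert write_swc(again) == text
            assert again.node_order == sk.node_order
            assert again.cable_length() == pytest.approx(sk.cable_length(), rel=1e-6)


class TestStrahler:
    def test_path_graph_all_order_one(self, chain10):
        assert set(strahler_order(chain10).values()) == {1}

    def test_full_binary_tree_root_order(self, binary_depth3):
        order = strahler_order(binary_depth3)
        assert order[1] == 4  # 15 nodes: leaves at depth 3, orders 1..4
        assert all(order[i] == 1 for i in range(8, 16))

    def test_matches_naive_recursion_on_random_trees(self, rng):
        def naive(sk, nid):
            kids = sk.children[nid]
            if not kids:
                return 1
            orders = sorted((naive(sk, c) for c in kids), reverse=True)
            return orders[0] + 1 if len(orders) > 1 and orders[0] == orders[1] else orders[0]

        for _ in range(50):
            sk = random_tree(rng, int(rng.integers(2, 120)))
            got = strahler_order(sk)
            assert all(got[n] == naive(sk, n) for n in sk.nodes)

    def test_invariant_under_edge_subdivision(self, rng):
        sk = random_tree(rng, 40)
        order = strahler_order(sk)
        # subdivide every edge by inserting a pass-through node
        nodes = [SkeletonNode(n.node_id, n.parent_id, n.position)
                 for n in sk.nodes.values()]
        nid = 1000
        for n in list(nodes):
            if n.parent_id is not None:
                nodes.append(SkeletonNode(nid, n.parent_id, n.position / 2))
                n.parent_id = nid
                nid += 1
        sub = NeuronSkeleton("sub", nodes)
        sub_order = strahler_order(sub)
        assert all(sub_order[n] == order[n] for n in sk.nodes)


class TestGeodesic:
    def test_identity_and_symmetry(self, chain10):
        assert geodesic_distance(chain10, 4, 4) == 0.0
        assert geodesic_distance(chain10, 2, 9) == geodesic_distance(chain10, 9, 2)

    def test_chain_segment_sum(self):
        pos = {1: np.zeros(3), 2: np.array([2.0, 0, 0]), 3: np.array([5.0, 0, 0]),
               4: np.array([10.0, 0, 0])}
        sk = build_skeleton([(1, None), (2, 1), (3, 2), (4, 3)], positions=pos)
        assert geodesic_distance(sk, 1, 4) == pytest.approx(10.0)

    def test_unknown_node_raises(self, chain10):
        with pytest.raises(KeyError):
            geodesic_distance(chain10, 1, 99)

    def test_matches_dijkstra_oracle(self, rng):
        for _ in range(30):
            sk = random_tree(rng, int(rng.integers(3, 80)))
            g = nx.Graph()
            for nid, node in sk.nodes.items():
                if node.parent_id is not None:
                    g.add_edge(nid, node.parent_id, weight=sk.edge_length(nid))
            pairs = rng.integers(1, len(sk) + 1, size=(5, 2))
            for a, b in pairs:
                expected = nx.dijkstra_path_length(g, int(a), int(b))
                assert geodesic_distance(sk, int(a), int(b)) == pytest.approx(expected)

    def test_metric_properties(self, rng):
        sk = random_tree(rng, 60)
        ids = rng.integers(1, 61, size=(20, 3))
        for a, b, c in ids:
            a, b, c = int(a), int(b), int(c)
            dab = geodesic_distance(sk, a, b)
            assert dab >= 0
            assert geodesic_distance(sk, b, a) == pytest.approx(dab)
            assert dab <= (geodesic_distance(sk, a, c)
                           + geodesic_distance(sk, c, b) + 1e-9)


class TestDendriticRoot:
    def test_tag_passthrough(self):
        sk = build_skeleton([(1, None), (2, 1), (42, 2), (4, 42), (5, 42)],
                            tags={42: ["dendritic_root"]})
        assert find_dendritic_root(sk) == 42

    def test_no_synapses_no_tag_raises(self, binary_depth3):
        with pytest.raises(ValueError, match="synapses"):
            find_dendritic_root(binary_depth3, [])

    def test_no_branch_point_raises(self, chain10):
        with pytest.raises(ValueError, match="branch point"):
            find_dendritic_root(chain10, [])

    def test_recovers_planted_root(self):
        """Synapse-flow inference finds the planted axon/dendrite split in
        >= 99% of 200 seeded clean-separation instances."""
        classes = (
            SynapseClassSpec("KC_input", 40, "post", "dendrite", ("uniform",), "KC"),
            SynapseClassSpec("output", 40, "pre", "axon", ("uniform",), "target"),
        )
        hits = 0
        for seed in range(200):
            sk, table, truth = gen_skeleton(SkeletonGenSpec(
                n_nodes=120, seed=seed, synapse_classes=classes))
            sites = read_synapse_table(table)
            hits += find_dendritic_root(sk, sites) == truth["planted_dendritic_root"]
        assert hits >= 198


class TestAxonlets:
    @pytest.fixture
    def planted(self):
        classes = (
            SynapseClassSpec("KC_input", 60, "post", "dendrite", ("uniform",), "KC"),
            SynapseClassSpec("output", 30, "pre", "axon", ("uniform",), "target"),
        )
        spec = SkeletonGenSpec(n_nodes=200, seed=7, synapse_classes=classes,
                               n_axonlets=2, axonlet_nodes=6, axonlet_presynapses=5)
        sk, table, truth = gen_skeleton(spec)
        return sk, read_synapse_table(table), truth

    def test_planted_axonlets_recovered(self, planted):
        sk, sites, truth = planted
        root = truth["planted_dendritic_root"]
        found = extract_axonlets(sk, sites, root)
        for alet in truth["axonlets"]:
            containing = [a for a in found if set(alet["nodes"]) <= set(a.nodes)]
            assert len(containing) == 1
            assert containing[0].n_presynapses == len(alet["presynapse_connectors"])

    def test_mixed_polarity_subtree_excluded(self):
        # subtree at 5 = {5, 6}: 4 presynapses but also a postsynapse on its
        # tip -> neither it nor anything inside is "exclusively presynaptic"
        sk = build_skeleton([(1, None), (2, 1), (3, 2), (4, 3), (5, 3), (6, 5),
                             (7, 2), (8, 7)])
        import pandas as pd
        rows = [dict(connector_id=i, pre_neuron="test", pre_node=5 + i % 2,
                     post_neuron="x", post_node=1) for i in range(4)]
        rows += [dict(connector_id=10, pre_neuron="KC", pre_node=1,
                      post_neuron="test", post_node=6),
                 dict(connector_id=11, pre_neuron="KC", pre_node=1,
                      post_neuron="test", post_node=4)]
        sites = read_synapse_table(pd.DataFrame(rows))
        assert extract_axonlets(sk, sites, 2) == []

    def test_no_presynapses_gives_empty_list(self, chain10):
        assert extract_axonlets(chain10, [], 1) == []

    def test_cable_lengths_bounded_by_total(self, planted):
        sk, sites, truth = planted
        found = extract_axonlets(sk, sites, truth["planted_dendritic_root"])
        assert sum(a.cable_length_nm for a in found) <= sk.cable_length()


class TestValidate:
    def test_valid_tree_empty_report(self, binary_depth3):
        assert validate(binary_depth3) == []

    def test_orphan_and_cycle_detected(self):
        orphan = [SkeletonNode(1, None, np.zeros(3)), SkeletonNode(2, 7, np.ones(3))]
        assert any("missing parent" in v for v in validate(orphan))
        cycle = [SkeletonNode(1, 3, np.zeros(3)), SkeletonNode(2, 1, np.ones(3)),
                 SkeletonNode(3, 2, np.ones(3))]
        report = validate(cycle)
        assert any("cycle" in v for v in report)
        assert any("no root" in v for v in report)
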