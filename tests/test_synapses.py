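"""Synapse statistics: profiles, mixture fits, bounds, connectivity, layout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mbx.skeleton import find_dendritic_root, read_synapse_table
from mbx.synapses import (
    DetectionRates,
    compare_localization,
    connectivity_table,
    distance_profile,
    fit_distance_distribution,
    layout_dendrogram,
    synapse_count_bounds,
)
from mbx.synth import SkeletonGenSpec, SynapseClassSpec, gen_skeleton

from conftest import build_skeleton, random_tree


def _skeleton_with_sites(node_for_sites, n=3):
    sk = build_skeleton([(1, None), (2, 1), (3, 2), (4, 3), (5, 2)])
    rows = [dict(connector_id=i + 1, pre_neuron="KC", pre_node=1,
                 post_neuron="test", post_node=node_for_sites) for i in range(n)]
    return sk, read_synapse_table(pd.DataFrame(rows))


class TestDistanceProfile:
    def test_sites_at_root_give_zero(self):
        sk, sites = _skeleton_with_sites(node_for_sites=2)
        prof = distance_profile(sk, sites, "KC_input", dendritic_root=2)
        assert np.all(prof.distances == 0.0)

    def test_single_site_on_chain(self):
        pos = {1: np.zeros(3), 2: np.array([3.0, 0, 0]), 3: np.array([10.0, 0, 0])}
        sk = build_skeleton([(1, None), (2, 1), (3, 2)], positions=pos)
        rows = [dict(connector_id=1, pre_neuron="KC", pre_node=1,
                     post_neuron="test", post_node=3)]
        prof = distance_profile(sk, read_synapse_table(pd.DataFrame(rows)),
                                "KC_input", dendritic_root=2)
        assert prof.distances.tolist() == [7.0]

    def test_empty_class_raises(self):
        sk, sites = _skeleton_with_sites(2)
        with pytest.raises(ValueError, match="no sites"):
            distance_profile(sk, sites, "MVP2_input", 2)

    def test_planted_proximal_below_distal(self):
        classes = (
            SynapseClassSpec("proximal", 80, "post", "dendrite",
                             ("gaussian", 6000, 2000), "MVP2"),
            SynapseClassSpec("distal", 80, "post", "dendrite",
                             ("gaussian", 30000, 4000), "KC"),
        )
        sk, table, truth = gen_skeleton(SkeletonGenSpec(
            n_nodes=400, seed=3, synapse_classes=classes))
        sites = read_synapse_table(table)
        root = truth["planted_dendritic_root"]
        prox = distance_profile(sk, sites, "proximal", root, truth["class_of"])
        dist = distance_profile(sk, sites, "distal", root, truth["class_of"])
        assert prox.summary["median"] < dist.summary["median"]


class TestMixtureFit:
    def test_unimodal_recovery(self, rng):
        x = rng.normal(20000, 3000, size=500)
        fit = fit_distance_distribution(x, seed=0)
        assert fit.selected_model == "Gaussian"
        se = 3000 / np.sqrt(500)
        assert abs(fit.means[0] - 20000) < 3 * se

    def test_bimodal_recovery(self, rng):
        x = np.concatenate([rng.normal(10000, 2000, 250),
                            rng.normal(22000, 2000, 250)])
        fit = fit_distance_distribution(x, seed=0)
        assert fit.selected_model == "bimodal Gaussian"
        assert fit.means[0] < fit.means[1]
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_distance_distribution([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            fit_distance_distribution([5.0] * 20)

    def test_deterministic_at_fixed_seed(self, rng):
        x = rng.normal(100, 10, size=200)
        a = fit_distance_distribution(x, seed=1)
        b = fit_distance_distribution(x, seed=1)
        assert np.array_equal(a.means, b.means) and a.bic == b.bic


class TestCompareLocalization:
    def test_identical_samples_zero_median_difference(self, rng):
        x = rng.normal(10, 2, 50)
        res = compare_localization(x, x)
        assert res["median_difference"] == 0.0

    def test_shift_detected_with_sign(self, rng):
        a = rng.normal(100, 5, 100)
        b = a + 10.0
        res = compare_localization(a, b)
        assert res["median_difference"] == pytest.approx(-10.0)
        assert res["p"] < 0.05

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        ab, ba = compare_localization(a, b), compare_localization(b, a)
        assert ab["median_difference"] == pytest.approx(-ba["median_difference"])
        assert ab["p"] == pytest.approx(ba["p"])

    def test_degenerate_single_observations(self):
        res = compare_localization([3.0], [5.0])
        assert res["p"] == 1.0 and res["median_difference"] == -2.0


class TestCountBounds:
    @pytest.mark.parametrize("found, lower, upper", [
        (17, 16.6, 18.4),   # MVP2 -> M6R
        (16, 15.6, 17.3),   # MVP2 -> M6L
        (47, 46.0, 50.8),   # MVP2 -> M4beta'
        (0, 0.0, 0.0),
    ])
    def test_published_bounds_table(self, found, lower, upper):
        est = synapse_count_bounds(found)
        assert (est.lower, est.upper) == (lower, upper)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_ordering_and_linearity(self, found):
        est = synapse_count_bounds(found)
        assert est.lower <= est.found <= est.upper
        assert est.lower == pytest.approx(found * 0.978, abs=0.051)
        assert est.upper == pytest.approx(found * (1 + 0.083 * 0.978), abs=0.051)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            DetectionRates(post_found_rate=1.3)


class TestConnectivityTable:
    def test_polyadic_connector_counts_per_target(self):
        rows = [dict(connector_id=1, pre_neuron="A", pre_node=1,
                     post_neuron="B", post_node=2),
                dict(connector_id=1, pre_neuron="A", pre_node=1,
                     post_neuron="B", post_node=3)]
        sites = read_synapse_table(pd.DataFrame(rows))
        table = connectivity_table(["A", "B"], sites)
        assert table.loc["A", "B"] == 2

    def test_no_synapses_zero_matrix(self):
        assert connectivity_table(["A", "B"], []).values.sum() == 0

    def test_matches_brute_force_tally(self, rng):
        names = ["MVP2", "M4", "M6R", "M6L"]
        rows = []
        for cid in range(1, 200):
            pre = names[rng.integers(4)]
            for _ in range(int(rng.integers(1, 4))):
                rows.append(dict(connector_id=cid, pre_neuron=pre, pre_node=1,
                                 post_neuron=names[rng.integers(4)], post_node=2))
        df = pd.DataFrame(rows)
        table = connectivity_table(names, read_synapse_table(df))
        brute = df.groupby(["pre_neuron", "post_neuron"]).size()
        for (i, j), count in brute.items():
            assert table.loc[i, j] == count
        assert table.values.sum() == len(df)
        # row sums = total post-targets per presynaptic neuron
        assert (table.sum(axis=1) == df["pre_neuron"].value_counts()
                .reindex(names, fill_value=0)).all()

    def test_unknown_neuron_warns_with_zero_row(self):
        rows = [dict(connector_id=1, pre_neuron="ghost", pre_node=1,
                     post_neuron="A", post_node=2)]
        with pytest.warns(UserWarning, match="ghost"):
            table = connectivity_table(["A"], read_synapse_table(pd.DataFrame(rows)))
        assert table.values.sum() == 0


class TestDendrogramLayout:
    def test_chain_is_collinear(self, chain10):
        pos, edges, _ = layout_dendrogram(chain10)
        xs = {p[0] for p in pos.values()}
        assert len(xs) == 1
        assert [pos[n][1] for n in chain10.node_order] == [-i for i in range(10)]

    def test_edge_set_isomorphic_to_skeleton(self, rng):
        for _ in range(10):
            sk = random_tree(rng, int(rng.integers(5, 120)))
            pos, edges, _ = layout_dendrogram(sk)
            expected = {(sk.parent(n), n) for n in sk.nodes if sk.parent(n) is not None}
            assert set(edges) == expected
            assert set(pos) == set(sk.nodes)

    def test_marks_conserved(self, binary_depth3):
        marks_in = {i: "MVP2_input" for i in range(8, 14)} | {14: "output", 15: "output"}
        _, _, marks_out = layout_dendrogram(binary_depth3, marks_in)
        assert marks_out == marks_in

    def test_depth_encodes_topology_not_length(self):
        pos_far = {1: np.zeros(3), 2: np.array([1e6, 0, 0]), 3: np.array([1e6 + 1, 0, 0])}
        sk = build_skeleton([(1, None), (2, 1), (3, 2)], positions=pos_far)
        pos, _, _ = layout_dendrogram(sk)
        assert pos[2][1] == -1 and pos[3][1] == -2
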