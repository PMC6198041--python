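"""Study-condition evaluation runs.

Each function here reproduces one of the package's headline quantitative
checks under its standard conditions — oracle agreement for the tree
algorithms, planted-structure recovery rates for the placement and imaging
pipelines, the circuit model's behavioural phenotypes, and the T-maze
estimator calibration — and returns plain numbers.  The functions are
shared by the test suite and by ``scripts/acceptance.py`` so both report
the same computations.
"""

from __future__ import annotations

import numpy as np

from .behavior import ProtocolSpec, build_protocol, performance_index
from .circuit import CircuitState, make_odor_pair, run_protocol
from .imaging import analyze_cohort
from .skeleton import (
    NeuronSkeleton,
    SkeletonNode,
    find_dendritic_root,
    geodesic_distance,
    read_synapse_table,
    strahler_order,
)
from .synapses import compare_localization, distance_profile, fit_distance_distribution
from .synth import (
    BehaviorGenSpec,
    ImagingGenSpec,
    SkeletonGenSpec,
    SynapseClassSpec,
    gen_imaging_cohort,
    gen_skeleton,
    gen_tmaze_cohort,
)

__all__ = [
    "tree_oracle_agreement",
    "mixture_selector_accuracy",
    "localization_ordering_rate",
    "imaging_sign_recovery",
    "imaging_type_i_error",
    "circuit_phenotypes",
    "tmaze_estimator_error",
]


# ---------------------------------------------------------------------------
# Tree-algorithm oracles
# ---------------------------------------------------------------------------

def _random_tree(rng: np.random.Generator, n_nodes: int) -> NeuronSkeleton:
    nodes = [SkeletonNode(1, None, rng.uniform(-100, 100, 3))]
    for nid in range(2, n_nodes + 1):
        nodes.append(SkeletonNode(nid, int(rng.integers(1, nid)),
                                  rng.uniform(-100, 100, 3)))
    return NeuronSkeleton("random", nodes)


def _strahler_naive(sk: NeuronSkeleton) -> dict[int, int]:
    """Independent brute-force recursion (the textbook definition)."""
    out: dict[int, int] = {}

    def visit(nid: int) -> int:
        orders = sorted((visit(c) for c in sk.children[nid]), reverse=True)
        if not orders:
            out[nid] = 1
        elif len(orders) > 1 and orders[0] == orders[1]:
            out[nid] = orders[0] + 1
        else:
            out[nid] = orders[0]
        return out[nid]

    visit(sk.root)
    return out


def tree_oracle_agreement(n_trees: int = 1000, max_nodes: int = 200,
                          seed: int = 0, pairs_per_tree: int = 3) -> dict[str, float]:
    """Fraction of random trees on which Strahler order matches naive
    recursion and geodesic distance matches a Dijkstra shortest path."""
    import networkx as nx
    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, max_nodes + 100))
    rng = np.random.default_rng(seed)
    strahler_ok = geodesic_ok = 0
    try:
        for _ in range(n_trees):
            sk = _random_tree(rng, int(rng.integers(2, max_nodes + 1)))
            strahler_ok += strahler_order(sk) == _strahler_naive(sk)
            g = nx.Graph()
            g.add_node(sk.root)
            for nid, node in sk.nodes.items():
                if node.parent_id is not None:
                    g.add_edge(nid, node.parent_id, weight=sk.edge_length(nid))
            ok = True
            for a, b in rng.integers(1, len(sk) + 1, size=(pairs_per_tree, 2)):
                expected = nx.dijkstra_path_length(g, int(a), int(b))
                ok &= abs(geodesic_distance(sk, int(a), int(b)) - expected) < 1e-6
            geodesic_ok += ok
    finally:
        sys.setrecursionlimit(old)
    return {"strahler_agreement": strahler_ok / n_trees,
            "geodesic_agreement": geodesic_ok / n_trees,
            "n": n_trees}


# ---------------------------------------------------------------------------
# Synapse-placement recovery
# ---------------------------------------------------------------------------

#: Standard placement-recovery conditions: n=500 distances per instance,
#: component separation >= 5 sd for the bimodal plants.
_UNIMODAL = ("gaussian", 18000.0, 4000.0)
_BIMODAL = ("bimodal", 8000.0, 2400.0, 32000.0, 2400.0, 0.5)  # 10 sd apart


def _planted_distances(seed: int, distribution: tuple, n_sites: int = 500) -> np.ndarray:
    cls = SynapseClassSpec("KC_input", n_sites, "post", "dendrite",
                           distribution, "KC")
    sk, table, truth = gen_skeleton(SkeletonGenSpec(
        n_nodes=500, seed=seed, synapse_classes=(cls,)))
    prof = distance_profile(sk, read_synapse_table(table), "KC_input",
                            truth["planted_dendritic_root"], truth["class_of"])
    return prof.distances


def mixture_selector_accuracy(n_instances: int = 200, seed: int = 0) -> dict[str, float]:
    """Unimodal-vs-bimodal selection accuracy on seeded synthetic skeletons
    (half planted Gaussian, half well-separated bimodal Gaussian)."""
    rng = np.random.default_rng(seed)
    correct = 0
    for i in range(n_instances):
        bimodal = i % 2 == 1
        sub_seed = int(rng.integers(0, 2**31 - 1))
        x = _planted_distances(sub_seed, _BIMODAL if bimodal else _UNIMODAL)
        fit = fit_distance_distribution(x, seed=sub_seed)
        correct += fit.n_components == (2 if bimodal else 1)
    return {"accuracy": correct / n_instances, "n": n_instances}


def localization_ordering_rate(n_instances: int = 50, seed: int = 0) -> dict[str, float]:
    """Fraction of clean-separation skeletons on which the planted
    proximal-vs-distal ordering is recovered (signed median difference and
    a significant rank-sum test)."""
    rng = np.random.default_rng(seed)
    hits = 0
    classes = (
        SynapseClassSpec("proximal", 100, "post", "dendrite",
                         ("gaussian", 7000.0, 2000.0), "MVP2"),
        SynapseClassSpec("distal", 100, "post", "dendrite",
                         ("gaussian", 33000.0, 3000.0), "KC"),
    )
    for _ in range(n_instances):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sk, table, truth = gen_skeleton(SkeletonGenSpec(
            n_nodes=500, seed=sub_seed, synapse_classes=classes))
        sites = read_synapse_table(table)
        root = truth["planted_dendritic_root"]
        prox = distance_profile(sk, sites, "proximal", root, truth["class_of"])
        dist = distance_profile(sk, sites, "distal", root, truth["class_of"])
        res = compare_localization(prox, dist)
        hits += (res["median_difference"] < 0) and (res["p"] < 0.05)
    return {"recovery_rate": hits / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# Imaging recovery
# ---------------------------------------------------------------------------

def imaging_sign_recovery(csplus_multiplier: float, n_runs: int = 100,
                          n_flies: int = 15, seed: int = 0) -> dict[str, float]:
    """Fraction of seeded cohorts whose median paired CS+ − CS− difference
    carries the planted sign and reaches significance."""
    rng = np.random.default_rng(seed)
    want_negative = csplus_multiplier < 1.0
    hits = 0
    for _ in range(n_runs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traces, _ = gen_imaging_cohort(ImagingGenSpec(
            n_flies=n_flies, csplus_multiplier=csplus_multiplier, seed=sub_seed))
        res = analyze_cohort(traces)
        med = float(np.median(res.pairs[:, 0] - res.pairs[:, 1]))
        hits += ((med < 0) == want_negative) and res.p < 0.05
    return {"recovery_rate": hits / n_runs, "n": n_runs}


def imaging_type_i_error(n_runs: int = 1000, n_flies: int = 15,
                         seed: int = 0) -> dict[str, float]:
    """Rejection rate of the full pipeline on null cohorts (multiplier 1)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_runs):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        traces, _ = gen_imaging_cohort(ImagingGenSpec(
            n_flies=n_flies, csplus_multiplier=1.0, seed=sub_seed))
        rejections += analyze_cohort(traces).p < 0.05
    return {"type_i_error": rejections / n_runs, "n": n_runs}


# ---------------------------------------------------------------------------
# Circuit phenotypes
# ---------------------------------------------------------------------------

def circuit_phenotypes(seed: int = 0) -> dict[str, float]:
    """Model PIs across the standard scenarios on default parameters."""
    state = CircuitState.default()
    odors = make_odor_pair(state.n_kc, rng=seed)

    def scenario(n_reexposures=0, blocks=None, retrain=False):
        tl = build_protocol(ProtocolSpec(n_reexposures=n_reexposures, retrain=retrain))
        return run_protocol(state, tl, *odors, blocks=blocks)

    trained = scenario()
    extinguished = scenario(n_reexposures=2)
    g5_blocked = scenario(n_reexposures=2, blocks={"PAM_gamma5_DAN": (0.0, 1e9)})
    m4m6_blocked = scenario(n_reexposures=2, blocks={"M4M6_output": (0.0, 1e9)})
    retrained = scenario(n_reexposures=2, retrain=True)
    test_rec = [r for r in extinguished["trajectory"] if r["phase"] == "test"][0]
    plus, minus = test_rec["response_cs_plus"], test_rec["response_cs_minus"]
    return {
        "pi_naive": extinguished["trajectory"][0]["pi_model"],
        "pi_trained": trained["pi_model"],
        "pi_extinguished": extinguished["pi_model"],
        "pi_gamma5_dan_blocked": g5_blocked["pi_model"],
        "pi_m4m6_output_blocked": m4m6_blocked["pi_model"],
        "pi_retrained": retrained["pi_model"],
        "m6_axon_csplus_over_csminus_post_extinction": plus.m6_axon / minus.m6_axon,
    }


# ---------------------------------------------------------------------------
# T-maze estimator
# ---------------------------------------------------------------------------

def tmaze_estimator_error(true_pi: float = -0.4, n_flies: int = 100,
                          n_groups: int = 1000, seed: int = 0) -> dict[str, float]:
    """Mean observed PI over many groups vs the planted truth, in units of
    the binomial standard error of that mean."""
    counts = gen_tmaze_cohort(BehaviorGenSpec(true_pi=true_pi, n_flies=n_flies,
                                              n_groups=n_groups, seed=seed))
    pis = np.array([performance_index(c).pi for c in counts])
    se_mean = float(np.sqrt(1.0 - true_pi**2) / np.sqrt(n_flies * n_groups))
    return {"mean_pi": float(pis.mean()), "true_pi": true_pi,
            "error_in_se_units": float(abs(pis.mean() - true_pi) / se_mean),
            "n": n_groups}
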