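"""Seeded generators with planted ground truth.

Every analysis stage in this package is exercised against synthetic data
whose true structure is known by construction: tree skeletons with a
planted dendritic root, axon/dendrite domains and planted synapse-
placement distributions; imaging cohorts with planted CS+ depression or
potentiation; T-maze cohorts drawn at a known true performance index.
Identical spec + seed gives byte-identical output, and each generator
emits a ground-truth sidecar sufficient to score recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import TMazeCount
from .imaging import DEFAULT_SAMPLING_RATE_HZ, Epoch, FluorescenceTrace
from .skeleton import NeuronSkeleton, SkeletonNode

__all__ = [
    "SynapseClassSpec",
    "SkeletonGenSpec",
    "ImagingGenSpec",
    "BehaviorGenSpec",
    "gen_skeleton",
    "gen_imaging_cohort",
    "gen_tmaze_cohort",
    "substreams",
]


def substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out into independent per-component generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseClassSpec:
    """One planted synapse class.

    ``distribution`` is ``("uniform",)``, ``("gaussian", mu, sigma)`` or
    ``("bimodal", mu1, sigma1, mu2, sigma2, pi1)`` over geodesic distance
    (nm) from the planted dendritic root.  ``polarity`` is "post" (an
    input; the partner is presynaptic) or "pre" (an output).  ``domain``
    restricts candidate nodes to the dendritic or axonal arbor.
    """

    name: str
    count: int
    polarity: str = "post"
    domain: str = "dendrite"
    distribution: tuple = ("uniform",)
    partner: str = "partner"

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.polarity not in ("pre", "post"):
            raise ValueError("polarity must be 'pre' or 'post'")
        if self.domain not in ("dendrite", "axon"):
            raise ValueError("domain must be 'dendrite' or 'axon'")
        kind = self.distribution[0]
        if kind == "gaussian" and self.distribution[2] <= 0:
            raise ValueError("gaussian sigma must be positive")
        if kind == "bimodal":
            _, m1, s1, m2, s2, p1 = self.distribution
            if s1 <= 0 or s2 <= 0 or not 0 < p1 < 1:
                raise ValueError("improper bimodal distribution")


@dataclass(frozen=True)
class SkeletonGenSpec:
    """Parameters of the synthetic-neuron generator.

    The morphology mimics the traced MBONs at the level the analyses care
    about: a short primary neurite from the soma to a planted dendritic
    root, where the tree splits into a dendritic arbor (``dendritic_fraction``
    of the remaining nodes) and an axonal arbor; segment (edge) lengths are
    Gaussian in nm.  Optional presynapse-only "axonlets" hang off interior
    dendritic nodes.
    """

    name: str = "synthetic_mbon"
    n_nodes: int = 400
    branching_probability: float = 0.25
    segment_length_mean_nm: float = 1500.0
    segment_length_sd_nm: float = 300.0
    dendritic_fraction: float = 0.6
    trunk_nodes: int = 5
    synapse_classes: tuple[SynapseClassSpec, ...] = ()
    n_axonlets: int = 0
    axonlet_nodes: int = 6
    axonlet_presynapses: int = 3
    seed: int = 0


def _grow_domain(rng: np.random.Generator, nodes: list[SkeletonNode],
                 attach_root: int, n_new: int, spec: SkeletonGenSpec,
                 next_id: int, single_subtree: bool = False) -> tuple[list[int], int]:
    """Grow ``n_new`` nodes under ``attach_root`` by tip extension with
    occasional branching; returns the new node ids.

    With ``single_subtree`` the attach point itself never receives a second
    branch, so the created nodes form one subtree rooted at the first of
    them (needed for planted axonlets).
    """
    created: list[int] = []
    tips = [attach_root]
    members = [attach_root]
    for _ in range(n_new):
        branchable = created if single_subtree else members
        if len(branchable) > 1 and rng.random() < spec.branching_probability:
            parent = int(rng.choice(branchable))
        else:
            parent = tips[-1]
        length = max(spec.segment_length_mean_nm * 0.1,
                     rng.normal(spec.segment_length_mean_nm, spec.segment_length_sd_nm))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        parent_node = next(n for n in nodes if n.node_id == parent)
        nodes.append(SkeletonNode(
            node_id=next_id, parent_id=parent,
            position=parent_node.position + direction * length,
        ))
        created.append(next_id)
        members.append(next_id)
        if parent == tips[-1]:
            tips.append(next_id)
        next_id += 1
    return created, next_id


def _sample_distance(rng: np.random.Generator, dist: tuple, extent: float) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(0.0, extent))
    if kind == "gaussian":
        return float(rng.normal(dist[1], dist[2]))
    if kind == "bimodal":
        _, m1, s1, m2, s2, p1 = dist
        if rng.random() < p1:
            return float(rng.normal(m1, s1))
        return float(rng.normal(m2, s2))
    raise ValueError(f"unknown distribution {kind!r}")


def gen_skeleton(spec: SkeletonGenSpec,
                 ) -> tuple[NeuronSkeleton, pd.DataFrame, dict]:
    """Generate a skeleton, its synapse table, and the ground-truth sidecar.

    The synapse table has the standard columns (connector_id, pre_neuron,
    pre_node, post_neuron, post_node).  Planted distances are realized by
    snapping each sampled target distance to the nearest candidate node of
    the class's domain; targets outside the arbor's extent are resampled
    (with a warning), failing after 100 attempts.
    """
    if spec.n_nodes < max(4, spec.trunk_nodes + 3):
        raise ValueError("n_nodes too small to form a trunk plus two arbors")
    rng = np.random.default_rng(spec.seed)

    nodes: list[SkeletonNode] = [SkeletonNode(1, None, np.zeros(3), tags={"soma"})]
    next_id = 2
    # primary neurite: soma -> dendritic root
    for _ in range(spec.trunk_nodes):
        step = rng.normal(spec.segment_length_mean_nm, spec.segment_length_sd_nm)
        nodes.append(SkeletonNode(
            next_id, next_id - 1,
            nodes[-1].position + np.array([0.0, 0.0, max(150.0, step)])))
        next_id += 1
    planted_root = next_id - 1

    n_rest = spec.n_nodes - len(nodes) - spec.n_axonlets * spec.axonlet_nodes
    n_dend = max(1, int(round(n_rest * spec.dendritic_fraction)))
    n_axon = max(1, n_rest - n_dend)
    dend_ids, next_id = _grow_domain(rng, nodes, planted_root, n_dend, spec, next_id)
    axon_ids, next_id = _grow_domain(rng, nodes, planted_root, n_axon, spec, next_id)

    axonlet_truth = []
    for _ in range(spec.n_axonlets):
        interior = [n for n in dend_ids
                    if any(m.parent_id == n for m in nodes)] or dend_ids
        attach = int(rng.choice(interior))
        new_ids, next_id = _grow_domain(rng, nodes, attach, spec.axonlet_nodes,
                                        spec, next_id, single_subtree=True)
        axonlet_truth.append({"attach_node": attach, "root_node": new_ids[0],
                              "nodes": new_ids})

    skeleton = NeuronSkeleton(spec.name, nodes)
    domains = {1: "soma"}
    for nid in range(2, planted_root + 1):
        domains[nid] = "trunk"
    domains[planted_root] = "dendritic_root"
    for nid in dend_ids:
        domains[nid] = "dendrite"
    for nid in axon_ids:
        domains[nid] = "axon"
    for alet in axonlet_truth:
        for nid in alet["nodes"]:
            domains[nid] = "axonlet"

    root_dist = skeleton.distance_to_root(planted_root)
    dist_from_planted = {nid: skeleton.distance_to_root(nid) - root_dist
                         for nid in dend_ids}
    # axonal distances measured along the arbor through the planted root
    for nid in axon_ids:
        dist_from_planted[nid] = skeleton.distance_to_root(nid) - root_dist

    rows = []
    class_truth: dict[str, list[dict]] = {}
    connector_id = 1
    for cls in spec.synapse_classes:
        candidates = np.array(dend_ids if cls.domain == "dendrite" else axon_ids)
        cand_dist = np.array([dist_from_planted[n] for n in candidates])
        order = np.argsort(cand_dist, kind="stable")
        candidates, cand_dist = candidates[order], cand_dist[order]
        extent = float(cand_dist.max())
        placed = []
        for _ in range(cls.count):
            target = -1.0
            for attempt in range(100):
                target = _sample_distance(rng, cls.distribution, extent)
                if 0.0 <= target <= extent:
                    break
                if attempt == 99:
                    raise ValueError(
                        f"class {cls.name!r}: cannot place a site after 100 attempts "
                        f"(arbor extent {extent:.0f} nm)")
                warnings.warn(
                    f"class {cls.name!r}: target {target:.0f} nm outside arbor; resampling",
                    stacklevel=2)
            idx = int(np.searchsorted(cand_dist, target))
            best = min((i for i in (idx - 1, idx) if 0 <= i < len(candidates)),
                       key=lambda i: (abs(cand_dist[i] - target), candidates[i]))
            node = int(candidates[best])
            if cls.polarity == "post":
                rows.append({"connector_id": connector_id, "pre_neuron": cls.partner,
                             "pre_node": 1, "post_neuron": spec.name, "post_node": node})
            else:
                rows.append({"connector_id": connector_id, "pre_neuron": spec.name,
                             "pre_node": node, "post_neuron": cls.partner,
                             "post_node": 1})
            placed.append({"connector_id": connector_id, "node": node,
                           "target_distance_nm": target,
                           "realized_distance_nm": float(cand_dist[best])})
            connector_id += 1
        class_truth[cls.name] = placed

    for i, alet in enumerate(axonlet_truth):
        chosen = rng.choice(alet["nodes"], size=min(spec.axonlet_presynapses,
                                                    len(alet["nodes"])), replace=False)
        alet["presynapse_connectors"] = []
        for node in sorted(int(n) for n in chosen):
            rows.append({"connector_id": connector_id, "pre_neuron": spec.name,
                         "pre_node": node, "post_neuron": f"axonlet_target_{i}",
                         "post_node": 1})
            alet["presynapse_connectors"].append(connector_id)
            connector_id += 1

    synapse_table = pd.DataFrame(
        rows, columns=["connector_id", "pre_neuron", "pre_node",
                       "post_neuron", "post_node"])
    truth = {
        "planted_dendritic_root": planted_root,
        "domains": domains,
        "classes": class_truth,
        "class_of": {p["connector_id"]: name
                     for name, placed in class_truth.items() for p in placed},
        "axonlets": axonlet_truth,
        "spec": spec,
    }
    return skeleton, synapse_table, truth


# ---------------------------------------------------------------------------
# Imaging cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingGenSpec:
    """Parameters of the synthetic calcium-imaging cohort.

    Each fly's trace holds the test sequence: CS+, CS− and a novel odor
    (IAA) for 5 s each, interleaved with 30 s of clean air, sampled at the
    native 5.92-Hz frame rate.  Responses are a difference-of-exponentials
    kernel scaled by a per-fly gain and per-odor jitter; the planted CS+
    effect is ``csplus_multiplier`` (0.7 = 30% depression, 1.3 = 30%
    potentiation).  Noise is additive Gaussian on F.
    """

    n_flies: int = 15
    roi: str = "M6_axon"
    baseline_f: float = 100.0
    response_fraction: float = 0.6
    rise_tau_s: float = 0.3
    decay_tau_s: float = 1.5
    noise_sd: float = 2.0
    fly_gain_cv: float = 0.25
    odor_jitter_cv: float = 0.10
    csplus_multiplier: float = 1.0
    odor_duration_s: float = 5.0
    air_gap_s: float = 30.0
    lead_in_s: float = 10.0
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.csplus_multiplier <= 0:
            raise ValueError("csplus_multiplier must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


_ODOR_SEQUENCE = ("CS+", "CS-", "novel")


def gen_imaging_cohort(spec: ImagingGenSpec,
                       ) -> tuple[list[FluorescenceTrace], dict]:
    """Generate one trace per fly plus the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    # onsets snap to the sampling grid so every odor's response kernel is
    # sampled in phase (otherwise identical odors give unequal AUCs)
    onsets = [round((spec.lead_in_s + i * (spec.odor_duration_s + spec.air_gap_s))
                    * spec.sampling_rate) / spec.sampling_rate
              for i in range(len(_ODOR_SEQUENCE))]
    total_s = onsets[-1] + spec.odor_duration_s + spec.air_gap_s
    n_samples = int(round(total_s * spec.sampling_rate))
    t = np.arange(n_samples) / spec.sampling_rate

    def envelope(dt: np.ndarray) -> np.ndarray:
        """Exponential rise during the odor window, exponential decay after."""
        rise = 1.0 - np.exp(-np.clip(dt, 0.0, spec.odor_duration_s) / spec.rise_tau_s)
        decay = np.exp(-np.clip(dt - spec.odor_duration_s, 0.0, None) / spec.decay_tau_s)
        # truncate the (already ~e^-10) tail so successive trials are
        # exactly independent: the next trial's baseline sees clean air
        cutoff = dt <= spec.odor_duration_s + 10.0 * spec.decay_tau_s
        return np.where((dt >= 0) & cutoff, rise * decay, 0.0)

    traces = []
    truth = {"csplus_multiplier": spec.csplus_multiplier, "flies": []}
    for i in range(spec.n_flies):
        gain = float(rng.lognormal(0.0, spec.fly_gain_cv))
        f0 = spec.baseline_f * gain
        f = np.full(n_samples, f0)
        amps = {}
        for odor, onset in zip(_ODOR_SEQUENCE, onsets):
            jitter = float(rng.lognormal(0.0, spec.odor_jitter_cv))
            amp = f0 * spec.response_fraction * jitter
            if odor == "CS+":
                amp *= spec.csplus_multiplier
            amps[odor] = amp
            # integer-offset time base keeps dt bitwise identical across
            # odors, so equal amplitudes give exactly equal responses
            dt = (np.arange(n_samples) - round(onset * spec.sampling_rate)) \
                / spec.sampling_rate
            f += amp * envelope(dt)
        f += rng.normal(0.0, spec.noise_sd, size=n_samples)
        epochs = [Epoch(odor, onset, spec.odor_duration_s)
                  for odor, onset in zip(_ODOR_SEQUENCE, onsets)]
        traces.append(FluorescenceTrace(f, spec.sampling_rate, epochs,
                                        fly_id=f"fly_{i:02d}", roi=spec.roi))
        truth["flies"].append({"fly_id": f"fly_{i:02d}", "gain": gain,
                               "amplitudes": amps})
    return traces, truth


# ---------------------------------------------------------------------------
# T-maze cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorGenSpec:
    """Binomial T-maze choice model at a planted true performance index."""

    true_pi: float = -0.4
    n_flies: int = 100
    n_groups: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.true_pi) > 1:
            raise ValueError("|true_pi| cannot exceed 1")
        if self.n_flies <= 0:
            raise ValueError("n_flies must be positive")
        if self.n_groups <= 0:
            raise ValueError("n_groups must be positive")


def gen_tmaze_cohort(spec: BehaviorGenSpec) -> list[TMazeCount]:
    """Each fly independently picks the CS+ arm with p = (1 + true_pi)/2."""
    rng = np.random.default_rng(spec.seed)
    p = (1.0 + spec.true_pi) / 2.0
    counts = []
    for _ in range(spec.n_groups):
        n_plus = int(rng.binomial(spec.n_flies, p))
        counts.append(TMazeCount(n_plus, spec.n_flies - n_plus))
    return counts
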