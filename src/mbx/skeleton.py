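"""Rooted-tree data model for EM-reconstructed neuron skeletons.

A skeleton is a single rooted tree of 3-D nodes (coordinates in nanometres,
the FAFB convention) carrying optional tags such as ``"soma"`` or
``"dendritic_root"``.  Synaptic sites are directed connectors linking a
presynaptic node of one neuron to one or more postsynaptic nodes of others.
All morphometry downstream (Strahler order, geodesic distances, axonlet
extraction) operates on this model.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SkeletonNode",
    "NeuronSkeleton",
    "SynapseSite",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "read_synapse_table",
    "strahler_order",
    "geodesic_distance",
    "find_dendritic_root",
    "extract_axonlets",
    "Axonlet",
    "validate",
]


class SwcParseError(ValueError):
    """Raised when an SWC source violates the single-rooted-tree contract."""


@dataclass
class SkeletonNode:
    """One skeleton node: a 3-D point with a parent pointer.

    ``parent_id`` is ``None`` exactly for the root.  ``position`` is in
    nanometres; ``radius`` (nm) is optional metadata and takes no part in
    any morphometric computation here.
    """

    node_id: int
    parent_id: int | None
    position: np.ndarray
    radius: float = 0.0
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.node_id <= 0:
            raise ValueError("node_id must be a positive integer")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")


class NeuronSkeleton:
    """A named, single-rooted, acyclic tree of :class:`SkeletonNode`.

    Construction validates the tree invariants (exactly one root, every
    parent reference resolvable, no cycles).  File order of the nodes is
    preserved in :attr:`node_order`, which deterministic layouts rely on.
    """

    def __init__(self, name: str, nodes: Iterable[SkeletonNode]):
        self.name = name
        self.nodes: dict[int, SkeletonNode] = {}
        self.node_order: list[int] = []
        for node in nodes:
            if node.node_id in self.nodes:
                raise SwcParseError(f"duplicate node_id {node.node_id}")
            self.nodes[node.node_id] = node
            self.node_order.append(node.node_id)
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) == 0:
            raise SwcParseError(
                "no root node (parent cycle, or no -1/none parent anywhere)")
        if len(roots) > 1:
            raise SwcParseError(f"multiple roots: nodes {sorted(roots)}")
        self.root: int = roots[0]
        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise SwcParseError(
                        f"node {node.node_id} references missing parent {node.parent_id}"
                    )
                self.children[node.parent_id].append(node.node_id)
        self._assert_connected_acyclic()
        self._depth: dict[int, int] | None = None
        self._dist_to_root: dict[int, float] | None = None

    # -- invariants -----------------------------------------------------

    def _assert_connected_acyclic(self) -> None:
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SwcParseError(f"cycle detected at node {nid}")
            seen.add(nid)
            stack.extend(self.children[nid])
        if len(seen) != len(self.nodes):
            # every node has a parent, so an unreachable component is a cycle
            orphan = sorted(set(self.nodes) - seen)
            raise SwcParseError(f"cycle: nodes unreachable from root: {orphan}")

    # -- basic structure ------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, node_id: int) -> int | None:
        return self.nodes[node_id].parent_id

    def edge_length(self, node_id: int) -> float:
        """Euclidean length (nm) of the edge from ``node_id`` to its parent."""
        node = self.nodes[node_id]
        if node.parent_id is None:
            return 0.0
        return float(np.linalg.norm(node.position - self.nodes[node.parent_id].position))

    def cable_length(self) -> float:
        """Total cable length (nm): sum of all parent-edge lengths."""
        return sum(self.edge_length(nid) for nid in self.nodes)

    def leaves(self) -> list[int]:
        return [nid for nid in self.node_order if not self.children[nid]]

    def branch_points(self) -> list[int]:
        return [nid for nid in self.node_order if len(self.children[nid]) >= 2]

    def topological_order(self) -> list[int]:
        """Nodes in root-to-leaf (BFS) order."""
        order = []
        queue = [self.root]
        while queue:
            nid = queue.pop(0)
            order.append(nid)
            queue.extend(self.children[nid])
        return order

    def subtree(self, node_id: int) -> list[int]:
        """All nodes in the subtree rooted at ``node_id`` (inclusive)."""
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.children[nid])
        return out

    def depth(self, node_id: int) -> int:
        """Topological depth (edge count) from root."""
        if self._depth is None:
            d = {self.root: 0}
            for nid in self.topological_order():
                for c in self.children[nid]:
                    d[c] = d[nid] + 1
            self._depth = d
        return self._depth[node_id]

    def distance_to_root(self, node_id: int) -> float:
        """Geodesic (cable) distance (nm) from ``node_id`` to the root."""
        if self._dist_to_root is None:
            d = {self.root: 0.0}
            for nid in self.topological_order():
                for c in self.children[nid]:
                    d[c] = d[nid] + self.edge_length(c)
            self._dist_to_root = d
        return self._dist_to_root[node_id]

    def find_tagged(self, tag: str) -> list[int]:
        return [nid for nid in self.node_order if tag in self.nodes[nid].tags]


@dataclass
class SynapseSite:
    """A directed connector: one presynaptic node, >=1 postsynaptic targets.

    ``post_targets`` lists ``(post_neuron, post_node)`` pairs; a polyadic
    active zone contributes one entry per postsynaptic partner.
    """

    connector_id: int
    pre_neuron: str
    pre_node: int
    post_targets: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.post_targets:
            raise ValueError("a connector needs at least one postsynaptic target")


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(source: str | Path | io.TextIOBase, name: str | None = None,
             unit_scale: float = 1.0) -> NeuronSkeleton:
    """Parse an SWC file into a :class:`NeuronSkeleton`.

    SWC: 7 whitespace-separated columns ``id type x y z radius parent``
    with ``#`` comments; ``parent == -1`` marks the root.  Positions are
    multiplied by ``unit_scale`` so micrometre SWCs can be brought to the
    nanometre convention with ``unit_scale=1000``.

    Raises :class:`SwcParseError` naming the offending line for duplicate
    ids, multiple roots, dangling parent references, or cycles.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        text = path.read_text()
        inferred = path.stem
    elif isinstance(source, io.TextIOBase):
        text = source.read()
        inferred = "skeleton"
    else:
        text = str(source)
        inferred = "skeleton"

    nodes: list[SkeletonNode] = []
    seen_ids: set[int] = set()
    root_line: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            x, y, z, radius = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: {exc}") from None
        if nid in seen_ids:
            raise SwcParseError(f"line {lineno}: duplicate node_id {nid}")
        seen_ids.add(nid)
        if parent == -1:
            if root_line is not None:
                raise SwcParseError(
                    f"line {lineno}: multiple roots (first root on line {root_line})"
                )
            root_line = lineno
        nodes.append(SkeletonNode(
            node_id=nid,
            parent_id=None if parent == -1 else parent,
            position=np.array([x, y, z], dtype=float) * unit_scale,
            radius=radius * unit_scale,
        ))
    if not nodes:
        raise SwcParseError("empty SWC source")
    try:
        return NeuronSkeleton(name or inferred, nodes)
    except SwcParseError:
        raise


def write_swc(skeleton: NeuronSkeleton, target: str | Path | io.TextIOBase | None = None,
              unit_scale: float = 1.0) -> str:
    """Serialize to canonical SWC text (file node order preserved).

    ``unit_scale`` divides positions on the way out, mirroring
    :func:`read_swc`.  Returns the text; writes it if ``target`` is given.
    """
    lines = ["# id type x y z radius parent"]
    for nid in skeleton.node_order:
        node = skeleton.nodes[nid]
        x, y, z = node.position / unit_scale
        parent = -1 if node.parent_id is None else node.parent_id
        lines.append(f"{nid} 0 {x:.10g} {y:.10g} {z:.10g} "
                     f"{node.radius / unit_scale:.6g} {parent}")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    elif target is not None:
        target.write(text)
    return text


def read_synapse_table(source: str | Path | io.TextIOBase | pd.DataFrame) -> list[SynapseSite]:
    """Load a synapse-annotation CSV into connectors.

    Expected columns: ``connector_id, pre_neuron, pre_node, post_neuron,
    post_node`` — one row per postsynaptic target; rows sharing a
    connector_id are grouped into one polyadic :class:`SynapseSite`.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"connector_id", "pre_neuron", "pre_node", "post_neuron", "post_node"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"synapse table missing columns: {sorted(missing)}")
    sites = []
    for cid, grp in df.groupby("connector_id", sort=True):
        pre_neurons = grp["pre_neuron"].unique()
        if len(pre_neurons) > 1:
            raise ValueError(
                f"connector {cid}: more than one presynaptic neuron ({list(pre_neurons)})"
            )
        pre_nodes = grp["pre_node"].unique()
        if len(pre_nodes) > 1:
            raise ValueError(f"connector {cid}: inconsistent presynaptic node")
        sites.append(SynapseSite(
            connector_id=int(cid),
            pre_neuron=str(pre_neurons[0]),
            pre_node=int(pre_nodes[0]),
            post_targets=[(str(r.post_neuron), int(r.post_node)) for r in grp.itertuples()],
        ))
    return sites


# ---------------------------------------------------------------------------
# Tree morphometry
# ---------------------------------------------------------------------------

def strahler_order(skeleton: NeuronSkeleton) -> dict[int, int]:
    """Strahler (stream) order per node.

    Leaves are order 1.  An internal node takes the maximum of its
    children's orders, incremented by one when two or more children share
    that maximum.  The root carries the tree's maximal order.
    """
    if len(skeleton) == 0:
        raise ValueError("empty skeleton")
    order: dict[int, int] = {}
    for nid in reversed(skeleton.topological_order()):
        kids = skeleton.children[nid]
        if not kids:
            order[nid] = 1
        else:
            child_orders = [order[c] for c in kids]
            top = max(child_orders)
            order[nid] = top + 1 if child_orders.count(top) >= 2 else top
    return order


def geodesic_distance(skeleton: NeuronSkeleton, node_a: int, node_b: int) -> float:
    """Cable distance (nm) along the unique tree path between two nodes.

    Computed through the lowest common ancestor:
    ``d(a, b) = d(a, root) + d(b, root) − 2·d(lca, root)``.
    """
    for nid in (node_a, node_b):
        if nid not in skeleton.nodes:
            raise KeyError(f"unknown node id {nid}")
    if node_a == node_b:
        return 0.0
    lca = _lowest_common_ancestor(skeleton, node_a, node_b)
    return (skeleton.distance_to_root(node_a) + skeleton.distance_to_root(node_b)
            - 2.0 * skeleton.distance_to_root(lca))


def _lowest_common_ancestor(skeleton: NeuronSkeleton, a: int, b: int) -> int:
    da, db = skeleton.depth(a), skeleton.depth(b)
    while da > db:
        a = skeleton.parent(a)  # type: ignore[assignment]
        da -= 1
    while db > da:
        b = skeleton.parent(b)  # type: ignore[assignment]
        db -= 1
    while a != b:
        a = skeleton.parent(a)  # type: ignore[assignment]
        b = skeleton.parent(b)  # type: ignore[assignment]
    return a


# ---------------------------------------------------------------------------
# Synapse polarity bookkeeping
# ---------------------------------------------------------------------------

def _polarity_nodes(skeleton: NeuronSkeleton,
                    synapses: Sequence[SynapseSite]) -> tuple[list[int], list[int]]:
    """Nodes of *this* neuron carrying pre- resp. postsynaptic sites.

    A node is listed once per site it hosts (a node with two input
    connectors counts twice on the postsynaptic side).
    """
    pre, post = [], []
    for site in synapses:
        if site.pre_neuron == skeleton.name and site.pre_node in skeleton.nodes:
            pre.append(site.pre_node)
        for post_neuron, post_node in site.post_targets:
            if post_neuron == skeleton.name and post_node in skeleton.nodes:
                post.append(post_node)
    return pre, post


def find_dendritic_root(skeleton: NeuronSkeleton, synapses: Sequence[SynapseSite] = (),
                        annotated_tag: str = "dendritic_root") -> int:
    """Locate the dendritic root: where the main neurite splits into
    proximal dendrites and distal axon.

    An explicit node tag wins.  Otherwise the branch point maximizing the
    synapse-flow separation score is returned: for each child subtree of a
    branch point, score = (postsynapses inside + presynapses outside) / total
    sites, taken at its maximum over children and over the two polarity
    assignments (either side of the split may be the axon).  Ties break to
    the smallest node_id.
    """
    tagged = skeleton.find_tagged(annotated_tag)
    if tagged:
        return min(tagged)

    branch_pts = skeleton.branch_points()
    if not branch_pts:
        raise ValueError("no branch point and no annotated tag: dendritic root undefined")
    pre_nodes, post_nodes = _polarity_nodes(skeleton, synapses)
    total = len(pre_nodes) + len(post_nodes)
    if total == 0:
        raise ValueError("cannot infer dendritic root without synapses or a tag")

    pre_count = {nid: 0 for nid in skeleton.nodes}
    post_count = {nid: 0 for nid in skeleton.nodes}
    for nid in pre_nodes:
        pre_count[nid] += 1
    for nid in post_nodes:
        post_count[nid] += 1
    # subtree sums in leaf-to-root order
    pre_sub = dict(pre_count)
    post_sub = dict(post_count)
    for nid in reversed(skeleton.topological_order()):
        for c in skeleton.children[nid]:
            pre_sub[nid] += pre_sub[c]
            post_sub[nid] += post_sub[c]
    n_pre, n_post = len(pre_nodes), len(post_nodes)

    best_score, best_node = -1.0, None
    for b in branch_pts:
        for c in skeleton.children[b]:
            dendrite_in = post_sub[c] + (n_pre - pre_sub[c])
            axon_in = pre_sub[c] + (n_post - post_sub[c])
            score = max(dendrite_in, axon_in) / total
            if score > best_score or (score == best_score and b < best_node):
                best_score, best_node = score, b
    return best_node  # type: ignore[return-value]


@dataclass
class Axonlet:
    """A presynapse-only distal subtree arising within the dendritic field."""

    root_node: int
    nodes: list[int]
    cable_length_nm: float
    n_presynapses: int


def extract_axonlets(skeleton: NeuronSkeleton, synapses: Sequence[SynapseSite],
                     dendritic_root: int) -> list[Axonlet]:
    """Axonlets: maximal subtrees hanging off the dendritic field whose
    synaptic sites are all presynaptic (and at least one).

    The dendritic field is the set of nodes strictly under the dendritic
    root whose subtree still contains a postsynapse; a child subtree
    leaving that set with exclusively presynaptic sites is an axonlet.
    The dendritic root itself is excluded — its children are the primary
    dendritic and axonal branches, not neurites arising within the field.
    """
    if dendritic_root not in skeleton.nodes:
        raise KeyError(f"unknown dendritic root {dendritic_root}")
    pre_nodes, post_nodes = _polarity_nodes(skeleton, synapses)
    pre_count = {nid: 0 for nid in skeleton.nodes}
    post_count = {nid: 0 for nid in skeleton.nodes}
    for nid in pre_nodes:
        pre_count[nid] += 1
    for nid in post_nodes:
        post_count[nid] += 1
    pre_sub = dict(pre_count)
    post_sub = dict(post_count)
    for nid in reversed(skeleton.topological_order()):
        for c in skeleton.children[nid]:
            pre_sub[nid] += pre_sub[c]
            post_sub[nid] += post_sub[c]

    field_nodes = [n for n in skeleton.subtree(dendritic_root)
                   if post_sub[n] > 0 and n != dendritic_root]
    axonlets = []
    for fnode in sorted(field_nodes):
        for c in sorted(skeleton.children[fnode]):
            if post_sub[c] == 0 and pre_sub[c] >= 1:
                members = skeleton.subtree(c)
                cable = sum(skeleton.edge_length(m) for m in members)
                axonlets.append(Axonlet(
                    root_node=c, nodes=sorted(members),
                    cable_length_nm=cable, n_presynapses=pre_sub[c],
                ))
    return axonlets


def validate(skeleton_nodes: Iterable[SkeletonNode] | NeuronSkeleton,
             name: str = "skeleton") -> list[str]:
    """Check the rooted-tree invariants; return violations (empty = valid).

    Accepts either raw nodes (so broken collections can be diagnosed) or an
    already-built skeleton (always valid by construction).
    """
    if isinstance(skeleton_nodes, NeuronSkeleton):
        return []
    nodes = list(skeleton_nodes)
    report: list[str] = []
    ids: set[int] = set()
    for n in nodes:
        if n.node_id in ids:
            report.append(f"duplicate node_id {n.node_id}")
        ids.add(n.node_id)
    roots = [n.node_id for n in nodes if n.parent_id is None]
    if len(roots) == 0:
        report.append("no root node")
    elif len(roots) > 1:
        report.append(f"multiple roots: {sorted(roots)}")
    parent_of = {}
    for n in nodes:
        if n.parent_id is not None and n.parent_id not in ids:
            report.append(f"node {n.node_id} references missing parent {n.parent_id}")
        parent_of[n.node_id] = n.parent_id
    # brute-force cycle walk from every node
    flagged: set[int] = set()
    for start in parent_of:
        seen_path: set[int] = set()
        cur: int | None = start
        while cur is not None and cur in parent_of:
            if cur in seen_path:
                if cur not in flagged:
                    report.append(f"cycle through node {cur}")
                    flagged.add(cur)
                break
            seen_path.add(cur)
            cur = parent_of[cur]
    return report
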