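import numpy as np
import pytest
from hypothesis import settings

from mbx.skeleton import NeuronSkeleton, SkeletonNode

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def build_skeleton(edges, positions=None, name="test", tags=None):
    """Skeleton from (child, parent) pairs; parent None marks the root.

    Positions default to collinear 1-nm spacing by node id so cable
    lengths are easy to reason about in tests.
    """
    tags = tags or {}
    nodes = []
    for child, parent in edges:
        pos = (positions or {}).get(child, np.array([float(child), 0.0, 0.0]))
        nodes.append(SkeletonNode(child, parent, pos, tags=set(tags.get(child, ()))))
    return NeuronSkeleton(name, nodes)


def random_tree(rng, n_nodes, coord_scale=100.0):
    """Uniform random recursive tree with random 3-D positions."""
    nodes = [SkeletonNode(1, None, rng.uniform(-coord_scale, coord_scale, 3))]
    for nid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, nid))
        nodes.append(SkeletonNode(nid, parent, rng.uniform(-coord_scale, coord_scale, 3)))
    return NeuronSkeleton("random", nodes)


@pytest.fixture
def chain10():
    """Path graph of 10 nodes, unit spacing."""
    return build_skeleton([(1, None)] + [(i, i - 1) for i in range(2, 11)])


@pytest.fixture
def binary_depth3():
    """Full binary tree of depth 3 (15 nodes)."""
    edges = [(1, None)] + [(i, i // 2) for i in range(2, 16)]
    return build_skeleton(edges)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
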