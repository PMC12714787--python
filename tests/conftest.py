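"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: edge
construction by an explicit double loop over agent pairs, Gini by the O(n^2)
pairwise-difference double sum, and path statistics via networkx.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from socialcircles import (
    Placement,
    SocialCirclesNetwork,
    TorusSpace,
    torus_distance,
)


def brute_force_edges(placements, space, distance_mode="euclidean_real"):
    """Reference edge rule: exhaustive double loop, no vectorisation."""
    edges = set()
    for a, b in itertools.combinations(placements, 2):
        if min(a.sr, b.sr) >= torus_distance(a, b, space, distance_mode):
            i, j = sorted((a.agent_id, b.agent_id))
            edges.add((i, j))
    return edges


def brute_force_gini(values):
    """O(n^2) pairwise |x_i - x_j| double sum over 2 n^2 mean."""
    x = list(values)
    n = len(x)
    mean = sum(x) / n
    if mean == 0:
        return 0.0
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * n * mean)


def random_placements(n, space, seed, max_reach=40.0):
    """Random positions (collisions allowed — oracle input only) and reaches."""
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, space.width, n)
    ys = rng.integers(0, space.height, n)
    srs = rng.uniform(0, max_reach, n)
    return [Placement(i, int(xs[i]), int(ys[i]), float(srs[i])) for i in range(n)]


def network_from_nx(g):
    """Wrap a networkx graph (integer nodes, no attributes) for the metrics API."""
    placements = [Placement(int(v), 0, 0, 0.0) for v in sorted(g.nodes)]
    edges = {(min(int(u), int(v)), max(int(u), int(v))) for u, v in g.edges}
    return SocialCirclesNetwork(placements, edges)


@pytest.fixture
def space() -> TorusSpace:
    return TorusSpace(315, 315)


@pytest.fixture
def small_space() -> TorusSpace:
    return TorusSpace(50, 50)
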