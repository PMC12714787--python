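"""Social Circles spatial network generator.

Agents are placed uniformly at random on distinct cells of a wrapped
(toroidal) integer grid and each is assigned a *social reach* ``sr`` — the
radius within which it can perceive other agents.  An undirected edge forms
between a pair of agents exactly when the connection is reciprocal, i.e. each
agent lies within the other's reach::

    {i, j} is an edge  <=>  min(sr_i, sr_j) >= d(i, j)

where ``d`` is the Euclidean distance with per-axis wrap-around.  The reach
distribution across the population (a discrete value/proportion mixture, a
Poisson, or a continuous uniform) is the generator's main control knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TorusSpace",
    "ReachSpec",
    "Placement",
    "GeneratorConfig",
    "SocialCirclesNetwork",
    "ConfigurationError",
    "mixture_counts",
    "place_agents",
    "assign_reaches",
    "torus_distance",
    "build_edges",
    "generate_network",
]

DISTANCE_MODES = ("euclidean_real", "euclidean_truncated")


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass(frozen=True)
class TorusSpace:
    """A wrapped integer grid of ``width`` x ``height`` cells.

    Opposite edges are identified, so the largest attainable pair distance is
    ``sqrt((width/2)**2 + (height/2)**2)``.  The canonical space is 315 x 315
    (99,225 cells).
    """

    width: int = 315
    height: int = 315

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ConfigurationError(
                f"torus must be at least 2x2, got {self.width}x{self.height}"
            )

    @property
    def cells(self) -> int:
        return self.width * self.height

    @property
    def max_distance(self) -> float:
        """Largest wrapped distance between any two grid cells."""
        return math.hypot(self.width // 2, self.height // 2)


@dataclass(frozen=True)
class ReachSpec:
    """Population distribution of social reaches.

    Three variants:

    ``discrete_mixture``
        A small set of reach ``values`` held by fixed ``proportions`` of the
        population (the One/Two/Three Circles designs).  Counts are made exact
        per replicate by largest-remainder rounding.
    ``poisson``
        i.i.d. Poisson(``mean``) integer reaches.
    ``uniform``
        i.i.d. continuous uniform reaches on [``low``, ``high``].
    """

    variant: str
    values: tuple[float, ...] = ()
    proportions: tuple[float, ...] = ()
    mean: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "discrete_mixture":
            vals, props = self.values, self.proportions
            if not vals or len(vals) != len(props):
                raise ConfigurationError(
                    "discrete_mixture needs matching, nonempty values/proportions"
                )
            if any(v <= 0 for v in vals):
                raise ConfigurationError("reach values must be positive")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigurationError("reach values must be strictly increasing")
            if any(not 0 < p <= 1 for p in props):
                raise ConfigurationError("proportions must lie in (0, 1]")
            # 34/33/33-style designs only sum to 1 within rounding slack
            if abs(sum(props) - 1.0) > 0.01:
                raise ConfigurationError(
                    f"proportions sum to {sum(props):.4f}, expected 1 +/- 0.01"
                )
        elif self.variant == "poisson":
            if self.mean is None or self.mean <= 0:
                raise ConfigurationError("poisson variant needs a positive mean")
        elif self.variant == "uniform":
            if self.low is None or self.high is None or not 0 < self.low <= self.high:
                raise ConfigurationError("uniform variant needs 0 < low <= high")
        else:
            raise ConfigurationError(f"unknown reach variant {self.variant!r}")

    @classmethod
    def discrete(cls, values: Sequence[float], proportions: Sequence[float]) -> "ReachSpec":
        return cls("discrete_mixture", tuple(float(v) for v in values),
                   tuple(float(p) for p in proportions))

    @classmethod
    def poisson(cls, mean: float) -> "ReachSpec":
        return cls("poisson", mean=float(mean))

    @classmethod
    def uniform(cls, low: float, high: float) -> "ReachSpec":
        return cls("uniform", low=float(low), high=float(high))


@dataclass(frozen=True)
class Placement:
    """One agent: grid position plus social reach (``sr``)."""

    agent_id: int
    x: int
    y: int
    sr: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    space: TorusSpace = field(default_factory=TorusSpace)
    reach_spec: ReachSpec = field(default_factory=lambda: ReachSpec.discrete([15, 30], [0.75, 0.25]))
    seed: int = 0
    distance_mode: str = "euclidean_real"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("agent count must be positive")
        if self.n > self.space.cells:
            raise ConfigurationError(
                f"cannot place {self.n} agents on {self.space.cells} grid cells "
                "without collision"
            )
        if self.distance_mode not in DISTANCE_MODES:
            raise ConfigurationError(
                f"distance_mode must be one of {DISTANCE_MODES}, got {self.distance_mode!r}"
            )


@dataclass
class SocialCirclesNetwork:
    """Placements plus the undirected edge set derived from them.

    Edges are stored once as ``(i, j)`` tuples with ``i < j``; there are no
    self-loops and every endpoint id has a placement.
    """

    placements: list[Placement]
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        ids = {p.agent_id for p in self.placements}
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on agent {i}")
            if i not in ids or j not in ids:
                raise ValueError(f"edge ({i}, {j}) references unknown agent")

    @property
    def n(self) -> int:
        return len(self.placements)

    @property
    def agent_ids(self) -> list[int]:
        return [p.agent_id for p in self.placements]

    def degree(self) -> dict[int, int]:
        deg = {p.agent_id: 0 for p in self.placements}
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_igraph(self):
        """igraph view with vertex attributes agent_id, x, y, sr.

        Vertex k corresponds to ``placements[k]``; the mapping is recorded in
        the ``agent_id`` attribute so original ids survive subsetting.
        """
        import igraph as ig

        index = {p.agent_id: k for k, p in enumerate(self.placements)}
        g = ig.Graph(
            n=self.n,
            edges=[(index[i], index[j]) for i, j in sorted(self.edges)],
        )
        g.vs["agent_id"] = [p.agent_id for p in self.placements]
        g.vs["x"] = [p.x for p in self.placements]
        g.vs["y"] = [p.y for p in self.placements]
        g.vs["sr"] = [p.sr for p in self.placements]
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for p in self.placements:
            g.add_node(p.agent_id, x=p.x, y=p.y, sr=p.sr)
        g.add_edges_from(self.edges)
        return g


def mixture_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``n`` agents across mixture classes.

    Floors ``p_k * n`` and hands the leftover units to the classes with the
    largest fractional parts, so the counts always sum to exactly ``n``
    (e.g. 34/33/33% of 1000 -> 340/330/330).
    """
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - int(counts.sum())
    if short < 0 or short > len(proportions):
        raise ConfigurationError(
            f"proportions {list(proportions)} cannot be reconciled to n={n}"
        )
    # ties broken by class order, which is deterministic
    for k in np.argsort(-(raw - np.floor(raw)), kind="stable")[:short]:
        counts[k] += 1
    return [int(c) for c in counts]


def place_agents(n: int, space: TorusSpace, rng: np.random.Generator) -> list[Placement]:
    """Scatter ``n`` agents over distinct grid cells, uniformly at random.

    Cells are sampled without replacement, so no two agents share a position.
    """
    if n > space.cells:
        raise ConfigurationError(
            f"cannot place {n} agents on {space.cells} grid cells without collision"
        )
    cells = rng.choice(space.cells, size=n, replace=False)
    xs = cells % space.width
    ys = cells // space.width
    return [Placement(i, int(xs[i]), int(ys[i]), 0.0) for i in range(n)]


def assign_reaches(
    placements: Sequence[Placement],
    reach_spec: ReachSpec,
    rng: np.random.Generator,
) -> list[Placement]:
    """Assign a social reach to every placement.

    Discrete mixtures get *exact* class counts (largest-remainder rounding of
    the proportions) dealt to agents in uniformly random order; the continuous
    variants draw i.i.d. reaches per agent.
    """
    if not placements:
        raise ConfigurationError("no placements to assign reaches to")
    n = len(placements)
    if reach_spec.variant == "discrete_mixture":
        counts = mixture_counts(n, reach_spec.proportions)
        pool = np.repeat(reach_spec.values, counts)
        sr = pool[rng.permutation(n)]
    elif reach_spec.variant == "poisson":
        sr = rng.poisson(reach_spec.mean, size=n).astype(float)
    else:  # uniform
        sr = rng.uniform(reach_spec.low, reach_spec.high, size=n)
    return [replace(p, sr=float(sr[k])) for k, p in enumerate(placements)]


def torus_distance(
    a: Placement,
    b: Placement,
    space: TorusSpace,
    distance_mode: str = "euclidean_real",
) -> float:
    """Euclidean distance with per-axis wrap-around min(|d|, L - |d|)."""
    dx = abs(a.x - b.x)
    dy = abs(a.y - b.y)
    dx = min(dx, space.width - dx)
    dy = min(dy, space.height - dy)
    d = math.hypot(dx, dy)
    return float(math.floor(d)) if distance_mode == "euclidean_truncated" else d


def _pair_distances(placements: Sequence[Placement], space: TorusSpace) -> np.ndarray:
    x = np.array([p.x for p in placements])
    y = np.array([p.y for p in placements])
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    np.minimum(dx, space.width - dx, out=dx)
    np.minimum(dy, space.height - dy, out=dy)
    return np.hypot(dx, dy)


def build_edges(
    placements: Sequence[Placement],
    space: TorusSpace,
    distance_mode: str = "euclidean_real",
) -> set[tuple[int, int]]:
    """Form the reciprocal-reach edge set over all agent pairs.

    ``{i, j}`` is an edge iff ``min(sr_i, sr_j) >= d(i, j)`` — the tie
    (distance exactly equal to the shorter reach) counts as an edge.  The scan
    is the vectorised equivalent of the exhaustive all-pairs double loop.
    """
    for p in placements:
        if p.sr is None:
            raise ValueError(f"agent {p.agent_id} has no social reach assigned")
    d = _pair_distances(placements, space)
    if distance_mode == "euclidean_truncated":
        d = np.floor(d)
    sr = np.array([p.sr for p in placements])
    adj = np.minimum(sr[:, None], sr[None, :]) >= d
    ids = [p.agent_id for p in placements]
    ii, jj = np.nonzero(np.triu(adj, k=1))
    return {
        (ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i])
        for i, j in zip(ii.tolist(), jj.tolist())
    }


def generate_network(config: GeneratorConfig) -> SocialCirclesNetwork:
    """Run the full pipeline: place, assign reaches, build edges.

    Fully reproducible from the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    placements = place_agents(config.n, config.space, rng)
    placements = assign_reaches(placements, config.reach_spec, rng)
    edges = build_edges(placements, config.space, config.distance_mode)
    return SocialCirclesNetwork(placements, edges)
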