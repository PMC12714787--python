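"""Structural property battery, measured on the giant component.

Every summary statistic the generator study tracks: density, degree,
two degree-assortativity definitions, closeness / betweenness / eigenvector
centralities, local clustering and global transitivity, geodesics and
diameter — with the Gini coefficient as the dispersion measure throughout
(centrality distributions here are heavily skewed, so a variance would be
dominated by the tail).

Correlation-type measures are undefined on regular graphs (zero degree
variance); those return NaN as an explicit flag, never a silent 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .generator import Placement, SocialCirclesNetwork

__all__ = [
    "PropertySummary",
    "giant_component",
    "gini",
    "degree_stats",
    "assortativity_edge",
    "assortativity_neighbour_mean",
    "closeness_values",
    "betweenness_values",
    "eigenvector_values",
    "clustering_values",
    "transitivity",
    "geodesic_stats",
    "summarize",
]


@dataclass
class PropertySummary:
    """One network's full row of structural measurements.

    All fields except ``edges_total`` refer to the giant component.
    Correlation fields are NaN when undefined (zero variance).
    """

    n_giant: int
    edges: int
    density: float
    degree_mean: float
    degree_gini: float
    assortativity_edge: float
    assortativity_neighbour_mean: float
    closeness_mean: float
    closeness_gini: float
    betweenness_mean: float
    betweenness_gini: float
    eigenvector_mean: float
    eigenvector_gini: float
    clustering_mean: float
    clustering_gini: float
    transitivity: float
    geodesic_mean: float
    geodesic_gini: float
    diameter: int
    edges_total: int

    #: stable serialization order (giant-component columns first)
    COLUMNS = (
        "n_giant", "edges", "density", "degree_mean", "degree_gini",
        "assortativity_edge", "assortativity_neighbour_mean",
        "closeness_mean", "closeness_gini", "betweenness_mean",
        "betweenness_gini", "eigenvector_mean", "eigenvector_gini",
        "clustering_mean", "clustering_gini", "transitivity",
        "geodesic_mean", "geodesic_gini", "diameter", "edges_total",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.COLUMNS}

    def to_row(self, sep: str = ",") -> str:
        """Single delimited-text row in COLUMNS order (3-decimal reals)."""
        cells = []
        for name in self.COLUMNS:
            v = getattr(self, name)
            cells.append(str(v) if isinstance(v, int) else f"{v:.3f}")
        return sep.join(cells)


def _as_igraph(network):
    """Accept either a SocialCirclesNetwork or an igraph.Graph."""
    import igraph as ig

    if isinstance(network, ig.Graph):
        return network
    return network.to_igraph()


def giant_component(network: SocialCirclesNetwork) -> SocialCirclesNetwork:
    """Induced subnetwork on the largest connected component.

    Isolated agents count as singleton components.  Size ties are broken in
    favour of the component containing the smallest agent id.  Original agent
    ids are preserved.
    """
    if not network.placements:
        raise ValueError("cannot take the giant component of an empty network")
    g = network.to_igraph()
    comps = g.connected_components()
    best = None
    for comp in comps:
        size = len(comp)
        min_id = min(g.vs[v]["agent_id"] for v in comp)
        key = (-size, min_id)
        if best is None or key < best[0]:
            best = (key, comp)
    keep = {g.vs[v]["agent_id"] for v in best[1]}
    placements = [p for p in network.placements if p.agent_id in keep]
    edges = {(i, j) for i, j in network.edges if i in keep}
    return SocialCirclesNetwork(placements, edges)


def gini(values: Sequence[float]) -> float:
    """Gini coefficient: mean absolute pairwise difference over 2 * mean.

    ``G = sum_ij |x_i - x_j| / (2 n^2 xbar)``; 0 for perfect equality,
    approaching 1 as the distribution concentrates.  Scale-invariant.
    Returns 0 when the mean is 0 (all-zero input).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("gini of an empty sequence")
    if np.any(x < 0):
        raise ValueError("gini requires nonnegative values")
    total = x.sum()
    if total == 0:
        return 0.0
    x = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    # O(n log n) rank form of the pairwise-difference double sum
    return float(((2 * i - n - 1) * x).sum() / (n * total))


def degree_stats(network) -> tuple[float, float]:
    """Mean and Gini of the degree sequence."""
    g = _as_igraph(network)
    deg = np.array(g.degree(), dtype=float)
    return float(deg.mean()), gini(deg)


def assortativity_edge(network) -> float:
    """Newman degree assortativity: Pearson correlation over edge ends.

    Each edge contributes both orientations, so the correlation is symmetric.
    NaN if degrees have zero variance over edge ends (e.g. regular graphs).
    """
    g = _as_igraph(network)
    if g.ecount() < 2:
        return float("nan")
    deg = np.array(g.degree(), dtype=float)
    ends = np.array(g.get_edgelist())
    a = np.concatenate([deg[ends[:, 0]], deg[ends[:, 1]]])
    b = np.concatenate([deg[ends[:, 1]], deg[ends[:, 0]]])
    if np.ptp(a) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def assortativity_neighbour_mean(network) -> float:
    """Degree vs. mean neighbour degree correlation (Hamill–Gilbert variant).

    Pearson correlation across nodes between deg(v) and the average degree of
    v's neighbours.  Requires every node to have at least one neighbour; NaN
    on zero variance.
    """
    g = _as_igraph(network)
    deg = np.array(g.degree(), dtype=float)
    if np.any(deg == 0):
        raise ValueError("neighbour-mean assortativity needs minimum degree 1")
    nbr_mean = np.array([np.mean([deg[u] for u in g.neighbors(v)]) for v in range(g.vcount())])
    if np.ptp(deg) == 0 or np.ptp(nbr_mean) == 0:
        return float("nan")
    return float(np.corrcoef(deg, nbr_mean)[0, 1])


def _require_connected(g) -> None:
    if g.vcount() > 1 and not g.is_connected():
        raise ValueError(
            "input is disconnected; extract the giant component first "
            "(giant_component)"
        )


def closeness_values(network) -> np.ndarray:
    """Closeness centrality (n-1)/sum_u d(v,u) — reciprocal mean geodesic."""
    g = _as_igraph(network)
    _require_connected(g)
    return np.asarray(g.closeness(normalized=True), dtype=float)


def betweenness_values(network) -> np.ndarray:
    """Shortest-path betweenness, normalized by (n-1)(n-2)/2.

    Equally short paths split the pair's unit weight evenly.  All zeros for
    n < 3 (no possible intermediary).
    """
    g = _as_igraph(network)
    _require_connected(g)
    n = g.vcount()
    if n < 3:
        return np.zeros(n)
    raw = np.asarray(g.betweenness(), dtype=float)
    return raw / ((n - 1) * (n - 2) / 2)


def eigenvector_values(network) -> np.ndarray:
    """Principal adjacency eigenvector, nonnegative, unit Euclidean norm.

    Computed with a deterministic Lanczos start vector so repeated runs are
    bit-identical; dense decomposition for very small graphs.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.linalg import ArpackNoConvergence, eigsh

    g = _as_igraph(network)
    _require_connected(g)
    n = g.vcount()
    if n <= 3 or g.ecount() == 0:
        a = np.zeros((n, n))
        for i, j in g.get_edgelist():
            a[i, j] = a[j, i] = 1.0
        w, v = np.linalg.eigh(a)
        vec = v[:, np.argmax(w)]
    else:
        a = csr_matrix(
            (np.ones(2 * g.ecount()),
             (np.concatenate([np.array(g.get_edgelist()).T[0],
                              np.array(g.get_edgelist()).T[1]]),
              np.concatenate([np.array(g.get_edgelist()).T[1],
                              np.array(g.get_edgelist()).T[0]]))),
            shape=(n, n),
        )
        try:
            _, v = eigsh(a, k=1, which="LA", v0=np.ones(n), tol=1e-10)
        except ArpackNoConvergence as exc:
            raise ArithmeticError(
                f"eigenvector iteration failed to converge: {exc}"
            ) from exc
        vec = v[:, 0]
    # Perron–Frobenius: the principal eigenvector has one sign on a
    # connected graph; fix it to the nonnegative orthant
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    norm = np.linalg.norm(vec)
    if not np.isfinite(norm) or norm == 0:
        raise ArithmeticError("eigenvector computation returned a null vector")
    return vec / norm


def clustering_values(network) -> np.ndarray:
    """Local clustering coefficient; degree-<2 nodes contribute 0."""
    g = _as_igraph(network)
    return np.asarray(g.transitivity_local_undirected(mode="zero"), dtype=float)


def transitivity(network) -> float:
    """Global transitivity: 3 * triangles / connected triples.

    NaN when the graph has no connected triple.
    """
    g = _as_igraph(network)
    t = g.transitivity_undirected(mode="nan")
    return float("nan") if t is None or math.isnan(t) else float(t)


def geodesic_stats(network) -> tuple[float, float, int]:
    """(mean, Gini, diameter) of the unordered-pair shortest-path lengths."""
    g = _as_igraph(network)
    _require_connected(g)
    n = g.vcount()
    if n < 2:
        raise ValueError("geodesic statistics need at least two nodes")
    d = np.asarray(g.distances(), dtype=float)
    pair = d[np.triu_indices(n, k=1)]
    return float(pair.mean()), gini(pair), int(pair.max())


def summarize(network: SocialCirclesNetwork) -> PropertySummary:
    """Extract the giant component and measure every structural property."""
    edges_total = len(network.edges)
    giant = giant_component(network)
    g = giant.to_igraph()
    n = g.vcount()
    e = g.ecount()

    degree_mean, degree_gini = degree_stats(g)
    clo = closeness_values(g) if n > 1 else np.zeros(1)
    bet = betweenness_values(g)
    clu = clustering_values(g)
    if n > 1:
        geo_mean, geo_gini, diam = geodesic_stats(g)
        eig = eigenvector_values(g)
    else:
        geo_mean, geo_gini, diam = 0.0, 0.0, 0
        eig = np.ones(1)

    return PropertySummary(
        n_giant=n,
        edges=e,
        density=2 * e / (n * (n - 1)) if n > 1 else 0.0,
        degree_mean=degree_mean,
        degree_gini=degree_gini,
        assortativity_edge=assortativity_edge(g),
        assortativity_neighbour_mean=(
            assortativity_neighbour_mean(g) if n > 1 and e > 0 else float("nan")
        ),
        closeness_mean=float(clo.mean()),
        closeness_gini=gini(clo),
        betweenness_mean=float(bet.mean()),
        betweenness_gini=gini(bet),
        eigenvector_mean=float(eig.mean()),
        eigenvector_gini=gini(eig),
        clustering_mean=float(clu.mean()),
        clustering_gini=gini(clu),
        transitivity=transitivity(g),
        geodesic_mean=geo_mean,
        geodesic_gini=geo_gini,
        diameter=diam,
        edges_total=edges_total,
    )
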