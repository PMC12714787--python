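# Methods

## The generator

Social Circles is a spatial mechanism for synthesising social-contact
networks. `n` agents are scattered uniformly at random over distinct cells of
a wrapped integer grid (a torus, default 315 × 315 = 99,225 cells, so 1,000
agents occupy ≈1% of positions). Each agent carries a *social reach* `sr` —
the radius of the circle within which it can perceive others. An undirected
edge forms exactly when the tie is reciprocal:

    {i, j} ∈ E  ⇔  min(sr_i, sr_j) ≥ d(i, j),

with `d` the Euclidean distance using per-axis wrapped differences
`min(|Δ|, L − |Δ|)`. The largest attainable distance on the canonical grid is
`sqrt(2 · 157²) ≈ 222`, which sets the natural scale for reach values.

The reach distribution is the control surface. Three variants are supported:

* **discrete mixture** (One/Two/Three Circles): a short list of reach values
  with population proportions. Class counts are made *exact* per network by
  largest-remainder rounding (34/33/33% of 1,000 → 340/330/330); which agents
  receive which reach is randomised, not the counts. This keeps the mixture
  composition identical across replicates so across-replicate variation
  reflects placement randomness only.
* **Poisson(mean)**: i.i.d. integer reaches.
* **uniform(low, high)**: i.i.d. continuous reaches.

### Numerical and design choices

* **Distinct cells.** Agents are sampled without replacement, so no two share
  a position. Co-location is never needed at ≈1% occupancy and would make
  "distance 0" ties between agents ambiguous to interpret.
* **Non-strict inequality.** Distance exactly equal to the shorter reach
  counts as an edge. With integer coordinates such ties genuinely occur.
* **Distance arithmetic.** The default `euclidean_real` keeps exact
  real-valued distances. `euclidean_truncated` (floor of the distance before
  comparison) is provided as an explicit flag because some historical
  implementations appear to have compared integer distances; truncation only
  ever *adds* edges (floor(d) ≤ d). Empirically the real-valued convention
  reproduces the published edge counts, while truncation overshoots them by
  ≈10% on the sparsest design.
* **Edge construction.** The vectorised all-pairs scan is the reference
  implementation (≈5 × 10⁵ pair checks at n = 1,000 — milliseconds in
  numpy); the test suite proves it identical to an exhaustive double loop.
* **Seeding.** A single integer seeds one network. Replicate `r` of an
  experiment uses `base_seed + r`, so any replicate can be regenerated alone.
  All randomness flows through one `numpy` PCG64 stream per network, making
  placements, reaches and edge sets bit-reproducible across platforms.

## The measurement battery

All structural properties are measured on the **giant component** (size ties
broken toward the component containing the smallest agent id; original ids
are preserved). The per-network summary records: node and edge counts,
density, degree mean, closeness / betweenness / eigenvector centralities,
local clustering, global transitivity, geodesic statistics and diameter —
each distribution summarised by its mean and its **Gini coefficient**

    G = Σᵢⱼ |xᵢ − xⱼ| / (2 n² x̄),

computed via the O(n log n) rank form. The Gini is used as the dispersion
measure throughout because centrality distributions here are strongly
right-skewed; it is scale-invariant, which also makes the eigenvector
dispersion independent of the eigenvector normalisation convention.

Conventions, chosen where more than one is in circulation:

* **Closeness**: `(n − 1) / Σᵤ d(v, u)` — the reciprocal of a node's mean
  geodesic. This is the convention consistent with the published means
  (≈ 1 / geodesic mean).
* **Betweenness**: Brandes shortest-path betweenness with even splitting over
  equally short paths, normalised by `(n − 1)(n − 2)/2`.
* **Eigenvector**: principal adjacency eigenvector, nonnegative
  (Perron–Frobenius on a connected component), unit Euclidean norm. Computed
  by Lanczos iteration with a fixed all-ones start vector (tolerance 1e−10;
  dense decomposition below n = 4) so repeated runs are bit-identical.
  Published comparisons use only the Gini, which any scaling convention
  yields identically.
* **Clustering**: nodes with degree < 2 contribute 0 and are included in the
  mean.
* **Assortativity**, two definitions: the Newman edge-end correlation
  (Pearson over the 2E ordered endpoint degree pairs) and the
  degree-vs-mean-neighbour-degree correlation used in the original
  Social Circles study. Both are undefined on regular graphs; they return
  NaN as an explicit flag, and aggregation skips flagged replicates while
  recording the skip count.
* **Geodesics**: statistics over the n(n−1)/2 unordered pair distances;
  the diameter is their maximum.

Standard graph primitives (components, shortest paths, betweenness,
transitivity) are delegated to igraph's C core; the suite cross-checks every
one against networkx and against exhaustive BFS / double-loop oracles on
small random graphs.

## Experiments

Eight canonical designs at n = 1,000 (n = 2,000 supported), 30 replicates
each, organised as three sweeps:

| sweep | designs |
|---|---|
| vary values, 75/25 fixed | [15,30], [20,40], [30,50] |
| vary proportions, [20,40] fixed | 90/10, 75/25, 25/75 |
| three values [30,40,50] | 10/20/70, 34/33/33, 70/20/10 |

The [20,40] 75/25 design belongs to both two-value sweeps and is
materialised once. Aggregation is the arithmetic mean over replicates (NaN
correlation flags skipped and counted); standard deviations are stored
alongside. The aggregate diameter is the mean of per-replicate diameters,
displayed rounded to an integer in tables. A replicate whose giant component
has fewer than 3 nodes is excluded with a logged warning (this does not
occur in any canonical design).

## What the generator does and does not emulate

The generated networks show the qualitative signatures of real social
networks the mechanism was designed for: high clustering (≈0.56–0.61 across
all canonical designs, insensitive to the reach mixture), positive degree
assortativity, short paths, and right-skewed centrality distributions with
community structure around spatially close long-reach nodes. They do not
model degree heterogeneity beyond what the reach mixture induces (no
power-law tails), temporal dynamics, weighted or directed ties, or homophily
on non-spatial attributes. Passing property checks therefore validates the
generator's structural behaviour, not the realism of any particular
empirical contact network.

## Known limitations

* One published table prints a diameter of 8 for the [20,40] 75/25 design;
  both distance conventions here give ≈10 (30-replicate mean), which is the
  value consistent with that design's own geodesic mean (5.32, reproduced to
  three figures) and with the monotone trend across the neighbouring designs
  (≈13 → ≈10 → ≈8). The corresponding check is kept at the printed value and
  fails; the computed value is reported as-is.
* The degree-vs-neighbour-mean assortativity values published for the
  original NetLogo implementation (0.71/0.75) are not reproduction targets:
  they come from a different codebase whose distance arithmetic differs, so
  that statistic is verified on closed-form cases only.
* The continuous uniform reach variant is implemented and tested but has no
  published target values under real-valued distances.
* Problem sizes in the test suite: unit and property tests run on small
  grids (≤120²) and graphs (n ≤ 200); the full-scale checks run all eight
  canonical designs at n = 1,000 with 30 replicates, the published scale.
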