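# Methods

## The question the package answers

A structural connectome is a spatially embedded network: connection weights
fall off steeply with distance, so many "topological" findings — modules,
hubs, efficiency — may be nothing more than geometry wearing a graph-theory
costume. `geosurr` quantifies exactly how much of a weighted connectome's
organization is explained by spatial embedding alone, by comparing the
empirical graph against two null ensembles:

- **Geometric surrogates (W_geo)** preserve the node-strength distribution
  *and* the low-order relationship between edge weight and fiber distance,
  destroying everything else.
- **Random surrogates (W_rand)** preserve only the strength distribution.

A metric whose empirical value matches its geometric-surrogate value is
geometrically determined; the ratio `metric(W_emp) / mean(metric(W_geo))`
measures structure *beyond* geometry (1 = complete geometric determination).

## Surrogate construction

Given a symmetric nonnegative weight matrix `W` and fiber distances `F`
(mm), a geometric surrogate is built as:

1. **Trend fit.** Ordinary least squares of `log w_ij` (natural log) on
   `f_ij` with a cubic polynomial `g`; a parabola `h` is then fitted to the
   absolute residuals `|log w_ij − g(f_ij)|`, modeling heteroscedastic
   spread. `h` is floored at `max(1e-6 × median |residual|, 1e-8)` when
   evaluated; the absolute term guards the noiseless limit where residuals
   are pure float error. A signed-residual fit would be ill-defined as a
   normalizer, which is why the spread is fitted to magnitudes (squared
   residuals would behave similarly but weight outliers more).
2. **Detrend.** `r_ij = (log w_ij − g(f_ij)) / h(f_ij)` on strictly positive
   edges. Zero-weight pairs are excluded throughout (log undefined) and stay
   zero in every surrogate; the graphs this package targets are nearly fully
   connected, so the excluded count (reported on the fitted model) is
   marginal.
3. **Shuffle.** The residuals are permuted uniformly over the positive
   upper-triangle positions and mirrored, so surrogates are exactly
   symmetric.
4. **Retrend.** `log w'_ij = g(f_ij) + h(f_ij) · r_shuffled`.
5. **Rank-match.** The provisional weights are replaced by the *original*
   weight multiset through rank order, making the surrogate's marginal
   weight distribution exact.
6. **Strength restoration.** The sorted empirical strengths are assigned to
   nodes in the rank order of the surrogate's current strengths, then
   symmetric multiplicative sweeps `w_ij ← w_ij · sqrt((t_i/s_i)(t_j/s_j))`
   iterate the row sums toward those targets (default tolerance 1e-3
   relative, max 1000 sweeps; non-convergence is flagged in the diagnostics,
   never silent). This scheme preserves symmetry and nonnegativity by
   construction and is homogeneous in the targets.

Rank assignment — rather than pinning each node to its own empirical
strength — is essential: it lets the null decide *where* the strong nodes
sit. In a geometric surrogate the large strengths accumulate on
geometrically central nodes, which is precisely the prediction the
hub-peripherality analyses test against. Pinning strengths node-wise would
force surrogate hub sets to equal the empirical ones and void those
comparisons, while leaving the sorted strength sequence identical either
way.

Random surrogates shuffle the weights themselves (no distance transforms)
and restore strengths the same way.

Two properties of these nulls are worth knowing:

- The raw weights of a geometric surrogate are strongly rank-correlated
  with the empirical weights at fixed positions — necessarily so, since
  both carry the same steep distance trend. "Otherwise random" is a
  statement about the *detrended residuals*, whose surrogate-vs-empirical
  rank correlation is ≈ 0.
- A random surrogate is not perfectly distance-flat after restoration:
  because strengths are spatially graded (central nodes are stronger), the
  restoration factors re-impose a weak trend. On the default benchmark this
  footprint is ≈ 10% of the empirical trend span and matches, almost
  exactly, the trend obtained by restoring the same strengths on a
  *constant* weight matrix — a strength-only oracle the tests use to verify
  that nothing beyond the strength sequence survives the shuffle.

## Metrics

- **Modularity / Louvain.** Weighted Newman–Girvan Q; Louvain optimization
  (networkx implementation, seeded), resolution 1.0. Empirical graphs use
  best-of-5 restarts by default; surrogate ensemble members one run each,
  and the acceptance analyses use an *identical* restart budget on both
  sides of every ratio, since an asymmetric optimization budget alone biases
  `Q_emp/mean(Q_geo)` upward by ~2%. Consensus assignments take the
  per-node majority label across runs after aligning module labels to a
  reference partition by optimal assignment on the overlap contingency
  table (ties to the lowest label).
- **Centralities.** Strength (row sums); eigenvector centrality via
  shift-accelerated power iteration (the shift makes the leading eigenvalue
  strictly dominant, which plain power iteration needs on bipartite
  graphs); Guimerà–Amaral participation coefficients.
- **Hubs.** Top `round(0.15 N)` nodes by strength or eigenvector
  centrality; ties broken by index order with a warning.
- **Peripherality.** Euclidean distance from each hub to the
  volume-weighted center of mass of all nodes.
- **Neighbor distances.** `⟨D⟩_i` is offered weight-weighted
  (`Σ w f / Σ w`, the default — where a node's connectivity mass sits) and
  unweighted over connected neighbors (where the neighbors physically sit).
  The hub/feeder contrast uses the unweighted reading: in a near-fully
  connected graph it varies almost one-to-one with peripherality
  (correlation ≈ 0.99 on the benchmark), whereas the weighted variant is
  dominated by the steep weight decay and tracks local node spacing
  instead.
- **Efficiency.** Graphs are thresholded to a target edge density by
  keeping the top-weight node pairs (deterministic lexicographic
  tie-break, so the sweep is monotone); binary global and Latora–Marchiori
  local efficiency on the thresholded graphs, swept over 21 densities from
  0.05 to 1.0 by default. All-pairs BFS distances are computed by boolean
  matrix powers (exact; one dense matmul per BFS level), and neighborhood
  subgraphs resolve distance-1/2 pairs the same way with an explicit BFS
  fallback for remoter pairs.
- **Statistics.** Spearman/Pearson correlations (scipy, average ranks on
  ties), overall and restricted to division pairs split by laterality;
  per-bin one-sample t-tests of replicate profiles against a reference with
  Bonferroni correction over bins (Benjamini–Hochberg available); Tukey's
  range test (scipy `tukey_hsd`); two-sample permutation tests with
  `p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_perm)`.

Weight-distance profiles standardize log-weights to zero mean and unit
variance (population SD convention; the sample convention differs at
O(1/E) and is exposed via `ddof`) and bin them in 1 mm fiber-distance bins.

## The synthetic benchmark

Real mesoscale connectomes (tracer models, tractography graphs) are not
redistributable, so the package ships a generator that emulates their
statistical structure with known ground truth:

- **Layout.** `n = 286` regions: 143 sampled uniformly in the right half of
  a 5.7 × 4.1 × 3.3 mm semi-axis ellipsoid (mouse-brain scale) and mirrored
  across the midsagittal plane; homolog pairs share a log-normal volume
  (log-SD 0.6). Twelve spatially coherent bilateral divisions from k-means.
- **Fiber distances.** `f_ij = τ · ||x_i − x_j|| · exp(jitter · η_ij)` with
  τ = 1.4 (fiber paths are tortuous), jitter SD 0.05, floored at the
  Euclidean distance.
- **Weights.** `log w_ij = g(f_ij) + σ ε_ij` with a decreasing cubic g
  spanning ≈ 5 orders of magnitude (decimal) over the distance range —
  matching the dynamic range of real connectivity matrices — mild at short
  range, and σ = 0.5. All off-diagonal weights are positive (the real
  graphs are nearly fully connected).
- **Planted modules.** 4 modules by default, built as 2 spatial k-means
  clusters per hemisphere, mirrored with *distinct* labels per hemisphere.
  The generator has no homotopic (mirror-pair) coupling, so a module
  spanning both hemispheres would have nothing holding its halves together
  and Louvain correctly splits it; hemisphere-respecting modules are the
  internally consistent choice. Intra-module log-weights are boosted by
  β_m (= 1 in the benchmark), multiplicative in weight space so
  log-normality is preserved.
- **Planted hubs.** The top 15% of nodes by distance from the center of
  mass; every incident edge is multiplied by `exp(β_h)` per hub endpoint
  (β_h = 1), lifting each planted node's strength by ≈ e.

Mirror-symmetric noise is off by default; exact hemispheric weight symmetry
can instead be imposed post hoc with `enforce_hemispheric_symmetry`
(averaging mirrored entries — the unique symmetric, idempotent,
weight-conserving rule; summation available), mirroring how real tracer
graphs are symmetrized.

What the generator does **not** emulate: homotopic connectivity, true
anatomical division geometry, directed connectivity, broken mirror
symmetry, measurement-specific artifacts (tracer segmentation bias,
streamline seeding bias), or heavy-tailed strength distributions beyond
what the log-normal trend induces. Passing benchmark tests therefore show
that the *pipeline* behaves correctly on data with the stated statistical
structure — not that any particular empirical claim holds in real data.

A purely geometric benchmark (no plants) calibrates the null:
`Q_emp/mean(Q_geo)` ≈ 1 and hub peripherality matches the surrogates. The
planted benchmark reverses every signature: the Q ratio rises well above 1
(exceeding all 100 surrogate values), Louvain consensus recovers the
planted partition, strength hubs recover the planted hub set, and the
hub/feeder neighbor-distance ordering flips between empirical and
surrogate graphs.

## Problem sizes and runtime choices

Default analyses use 286-node graphs with ensembles of 100 surrogates per
kind — the scale the method is designed for. The pipeline-level determinism
test and the worked example use 60–100-node graphs and ensembles of 5–10,
and the acceptance script's cross-graph report uses 50+50 surrogates with a
10-point density grid; these smaller sizes exercise identical code paths
and were chosen to keep repeated end-to-end runs fast. Surrogate
construction itself is cheap (~10 ms per 286-node surrogate); Louvain
optimization dominates the budget, which is why ensemble members default to
a single seeded run.

## Degenerate inputs and tie rules

- Fewer than 10 positive edges → trend fitting refuses
  (insufficient-data error); fewer than 2 → z-scoring refuses.
- Zero-strength nodes get participation 0 (warned) and NaN neighbor
  distances; disconnected graphs use the largest component for eigenvector
  centrality (warned); disconnected pairs contribute 0 to efficiency and
  are excluded from mean path length.
- Threshold ties: lexicographic (i, j) order. Hub ties: index order,
  warned. Consensus ties: lowest label.
- Every stochastic operation takes an explicit integer seed; ensembles use
  consecutive per-member seeds derived from a base seed, and the pipeline
  derives disjoint seed blocks per graph from the master seed, so reports
  are byte-identical across reruns.

## Known limitations

- The strength-restoration sweeps have no convergence guarantee for targets
  unreachable on the given support (e.g., disconnected shuffles); such
  members are flagged, not repaired.
- Surrogate weights at fixed positions remain rank-correlated with
  empirical weights through the shared trend (see above); analyses that
  need fully independent nulls at fixed positions should use the random
  ensemble's *pre-restoration* matrices.
- Division-level correlations require both graphs on the same parcellation;
  no cross-parcellation mapping is provided.
- Directed graphs must be symmetrized first (`symmetrize_directed`); no
  directed surrogates or metrics are implemented.
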