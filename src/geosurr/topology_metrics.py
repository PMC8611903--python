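"""Weighted and binary graph-theory measures.

Modularity and its Louvain optimization, reference-aligned consensus
partitions, centralities (strength, eigenvector, participation), and binary
integration measures (global/local efficiency, clustering coefficient, mean
path length) — the metric layer applied identically to empirical graphs and
their surrogate ensembles.

Louvain optimization is delegated to networkx; everything downstream
(modularity evaluation, label alignment, consensus, agreement) is computed
here on plain numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix

from .graph_model import InvalidInputError

__all__ = [
    "ModulePartition",
    "CentralityVector",
    "modularity_score",
    "louvain_partition",
    "align_labels",
    "consensus_partition",
    "partition_agreement",
    "participation_coefficients",
    "eigenvector_centrality",
    "node_strengths",
    "global_efficiency",
    "local_efficiency",
    "clustering_and_path_length",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input (e.g. empty graph)."""


@dataclass(frozen=True)
class ModulePartition:
    """Node-to-module assignment with contiguous integer labels.

    ``Q`` is the modularity of this assignment on its source graph (None for
    derived partitions such as a consensus whose source is an ensemble).
    """

    assignment: np.ndarray
    n_modules: int
    Q: float | None = None
    source_seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.intp)
        object.__setattr__(self, "assignment", a)
        labels = np.unique(a)
        if a.min(initial=0) < 0 or a.max(initial=0) >= self.n_modules:
            raise InvalidInputError("module labels must lie in 0..n_modules-1")
        # freshly optimized partitions use every label; aligned partitions may
        # leave reference labels unused when they have fewer modules
        if len(labels) > self.n_modules:
            raise InvalidInputError("more distinct labels than n_modules")

    @property
    def n_nodes(self) -> int:
        return len(self.assignment)

    def relabeled(self, mapping: np.ndarray) -> "ModulePartition":
        """Apply a label mapping; the grouping itself is unchanged."""
        new = mapping[self.assignment]
        return ModulePartition(new, int(new.max()) + 1, self.Q, self.source_seed)


@dataclass(frozen=True)
class CentralityVector:
    """Per-node centrality values of one measure."""

    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)


def _as_partition(p) -> np.ndarray:
    if isinstance(p, ModulePartition):
        return p.assignment
    return np.asarray(p, dtype=np.intp)


def _contiguous(assignment: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel to contiguous ids ordered by first occurrence (deterministic)."""
    _, first_idx, inv = np.unique(assignment, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_idx))
    new = order[inv]
    return new, len(first_idx)


# ---------------------------------------------------------------------------
# modularity and Louvain
# ---------------------------------------------------------------------------

def modularity_score(W: np.ndarray, partition) -> float:
    """Newman–Girvan weighted modularity of a partition.

    Q = (1/2m) sum_ij [w_ij - s_i s_j / 2m] delta(c_i, c_j) with m the total
    edge weight and s the node strengths.
    """
    W = np.asarray(W, dtype=float)
    c = _as_partition(partition)
    s = W.sum(axis=1)
    two_m = s.sum()
    if two_m <= 0:
        raise UndefinedMetricError("modularity undefined for a zero-weight graph")
    q = 0.0
    for label in np.unique(c):
        idx = c == label
        w_in = W[np.ix_(idx, idx)].sum()
        s_in = s[idx].sum()
        q += w_in / two_m - (s_in / two_m) ** 2
    return float(q)


def louvain_partition(
    W: np.ndarray,
    seed: int,
    resolution: float = 1.0,
    restarts: int = 1,
) -> ModulePartition:
    """Louvain modularity optimization; deterministic given ``seed``.

    Runs ``restarts`` independent optimizations with seeds derived from
    ``seed`` and keeps the highest-Q partition.  The per-level trace is
    available via :func:`louvain_trace`.
    """
    W = np.asarray(W, dtype=float)
    if W.sum() <= 0:
        raise UndefinedMetricError("Louvain undefined for a zero-weight graph")
    G = nx.from_numpy_array(W)
    best: tuple[float, np.ndarray] | None = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=int(seed) + r
        )
        assignment = np.empty(W.shape[0], dtype=np.intp)
        for m, nodes in enumerate(comms):
            assignment[list(nodes)] = m
        q = modularity_score(W, assignment)
        if best is None or q > best[0]:
            best = (q, assignment)
    assignment, n_mod = _contiguous(best[1])
    return ModulePartition(assignment, n_mod, best[0], int(seed))


def louvain_trace(W: np.ndarray, seed: int, resolution: float = 1.0) -> list[float]:
    """Modularity at each Louvain aggregation level (nondecreasing by design)."""
    W = np.asarray(W, dtype=float)
    G = nx.from_numpy_array(W)
    qs = []
    for comms in nx.community.louvain_partitions(
        G, weight="weight", resolution=resolution, seed=int(seed)
    ):
        assignment = np.empty(W.shape[0], dtype=np.intp)
        for m, nodes in enumerate(comms):
            assignment[list(nodes)] = m
        qs.append(modularity_score(W, assignment))
    return qs


# ---------------------------------------------------------------------------
# label alignment, consensus, agreement
# ---------------------------------------------------------------------------

def align_labels(partition: ModulePartition, reference: ModulePartition) -> ModulePartition:
    """Relabel modules to maximize per-node label agreement with a reference.

    Solves optimal assignment on the module-overlap contingency table; the
    grouping itself is unchanged.  Surplus modules (beyond the reference's
    count) keep distinct labels above the reference label range.
    """
    a = partition.assignment
    b = reference.assignment
    if len(a) != len(b):
        raise InvalidInputError("partitions must share the node set")
    n_a = partition.n_modules
    n_b = reference.n_modules
    contingency = np.zeros((n_a, n_b), dtype=np.intp)
    np.add.at(contingency, (a, b), 1)
    rows, cols = linear_sum_assignment(contingency, maximize=True)
    mapping = np.full(n_a, -1, dtype=np.intp)
    mapping[rows] = cols
    nxt = n_b
    for m in range(n_a):
        if mapping[m] < 0:
            mapping[m] = nxt
            nxt += 1
    new = mapping[a]
    # reference labels are kept verbatim (agreement depends on exact ids);
    # when the partition has fewer modules than the reference, some reference
    # labels simply go unused
    n_mod = max(int(new.max()) + 1, n_b)
    return ModulePartition(new, n_mod, partition.Q, partition.source_seed)


def partition_agreement(p1: ModulePartition, p2: ModulePartition) -> float:
    """Percent of nodes with identical module labels (p1 aligned to p2)."""
    a = p1.assignment
    b = p2.assignment
    if len(a) != len(b):
        raise InvalidInputError("partitions must share the node set")
    return 100.0 * float(np.mean(a == b))


def consensus_partition(
    partitions: list[ModulePartition],
    reference: ModulePartition,
) -> ModulePartition:
    """Majority-vote module label per node across reference-aligned partitions.

    Each partition is first aligned to ``reference``; ties go to the lowest
    label id.  The consensus carries no Q (its source is an ensemble).
    """
    if not partitions:
        raise InvalidInputError("need at least one partition for a consensus")
    aligned = [align_labels(p, reference) for p in partitions]
    n = reference.n_nodes
    max_label = max(p.assignment.max() for p in aligned) + 1
    counts = np.zeros((n, max_label), dtype=np.intp)
    for p in aligned:
        counts[np.arange(n), p.assignment] += 1
    # argmax takes the first (lowest) label on ties; labels stay in the
    # reference-aligned space so the consensus remains comparable to it
    consensus = counts.argmax(axis=1).astype(np.intp)
    n_mod = max(int(consensus.max()) + 1, reference.n_modules)
    return ModulePartition(consensus, n_mod, None, None)


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------

def node_strengths(W: np.ndarray) -> CentralityVector:
    """Node strength: the sum of weights at each node."""
    W = np.asarray(W, dtype=float)
    return CentralityVector(W.sum(axis=1), "strength")


def participation_coefficients(W: np.ndarray, partition) -> CentralityVector:
    """Guimerà–Amaral participation coefficient P_i = 1 - sum_m (k_im/k_i)^2.

    0 means all weight stays within the node's own module; values approach 1
    as weight spreads uniformly over modules.  Zero-strength nodes get P = 0
    (with a warning reporting how many).
    """
    W = np.asarray(W, dtype=float)
    c = _as_partition(partition)
    labels = np.unique(c)
    onehot = (c[:, None] == labels[None, :]).astype(float)
    k_im = W @ onehot
    k = W.sum(axis=1)
    p = np.zeros(W.shape[0])
    ok = k > 0
    n_zero = int((~ok).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero-strength nodes assigned P=0", stacklevel=2)
    p[ok] = 1.0 - ((k_im[ok] / k[ok, None]) ** 2).sum(axis=1)
    return CentralityVector(p, "participation")


def eigenvector_centrality(W: np.ndarray, tol: float = 1e-10,
                           max_iter: int = 10_000) -> CentralityVector:
    """Leading eigenvector of the weight matrix, nonnegative, unit norm.

    Computed by power iteration on the largest connected component of the
    positive support (a warning is issued if the graph is disconnected;
    off-component nodes get 0).
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W > 0):
        raise UndefinedMetricError("eigenvector centrality undefined for zero matrix")
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components(csr_matrix(W > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        # restrict to the component with most total strength among largest
        main = int(np.argmax(sizes))
        warnings.warn(
            f"graph disconnected ({n_comp} components); using the largest",
            stacklevel=2,
        )
        mask = comp == main
    else:
        mask = np.ones(W.shape[0], dtype=bool)
    sub = W[np.ix_(mask, mask)].copy()
    # diagonal shift makes the leading eigenvalue strictly dominant (plain
    # power iteration oscillates on bipartite graphs); eigenvectors unchanged
    shift = sub.sum(axis=1).max()
    sub[np.diag_indices_from(sub)] += shift
    v = np.full(sub.shape[0], 1.0 / np.sqrt(sub.shape[0]))
    for _ in range(max_iter):
        nv = sub @ v
        nrm = np.linalg.norm(nv)
        if nrm == 0:
            raise UndefinedMetricError("power iteration collapsed to zero")
        nv /= nrm
        if np.max(np.abs(nv - v)) < tol:
            v = nv
            break
        v = nv
    out = np.zeros(W.shape[0])
    out[mask] = np.abs(v)
    out /= np.linalg.norm(out)
    return CentralityVector(out, "eigenvector")


# ---------------------------------------------------------------------------
# binary integration measures
# ---------------------------------------------------------------------------

def _binary_distances(A: np.ndarray) -> np.ndarray:
    """All-pairs BFS distances via boolean matrix powers (exact).

    Each step extends reachability by one hop with a single dense matmul,
    which is much faster than per-source traversal for the dense-ish graphs
    produced by density thresholding; unreachable pairs stay inf.
    """
    A = np.asarray(A) > 0
    n = A.shape[0]
    Af = A.astype(np.float32)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[A] = 1.0
    frontier = A  # pairs at the current exact distance
    step = 1
    while frontier.any():
        nxt = (frontier.astype(np.float32) @ Af) > 0
        newly = nxt & np.isinf(dist)
        if not newly.any():
            break  # remaining inf pairs are disconnected
        step += 1
        dist[newly] = step
        frontier = newly
    return dist


def global_efficiency(A: np.ndarray) -> float:
    """Average inverse shortest path length over all ordered node pairs.

    Disconnected pairs contribute 0 (1/inf).  Binary BFS distances.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if n < 2:
        raise UndefinedMetricError("global efficiency needs >= 2 nodes")
    d = _binary_distances(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(A: np.ndarray) -> CentralityVector:
    """Per-node efficiency of the subgraph induced on the node's neighbors.

    The Latora–Marchiori neighborhood reading: remove the node, keep its
    neighbors, and measure their mutual global efficiency (0 for nodes with
    fewer than 2 neighbors).

    Neighbor pairs at distance 1 or 2 are resolved by vectorized matrix
    products; only neighborhoods with remoter (or disconnected) pairs fall
    back to an explicit BFS, which keeps dense graphs fast without any
    approximation.
    """
    A = np.asarray(A) > 0
    n = A.shape[0]
    vals = np.zeros(n)
    Af = A.astype(np.float32)
    for i in range(n):
        nbrs = np.nonzero(A[i])[0]
        k = len(nbrs)
        if k < 2:
            continue
        B = A[np.ix_(nbrs, nbrs)]
        two_step = (Af[np.ix_(nbrs, nbrs)] @ Af[np.ix_(nbrs, nbrs)]) > 0
        off = ~np.eye(k, dtype=bool)
        resolved = B | two_step
        if np.all(resolved | ~off):
            inv = np.where(B, 1.0, np.where(two_step, 0.5, 0.0))
            vals[i] = float(inv[off].sum() / (k * (k - 1)))
        else:
            vals[i] = global_efficiency(B)
    return CentralityVector(vals, "local_efficiency")


def clustering_and_path_length(A: np.ndarray) -> tuple[float, float]:
    """Binary clustering coefficient (node average) and characteristic path
    length (mean shortest path over connected pairs; NaN if none)."""
    A = np.asarray(A, dtype=float)
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    d = _binary_distances(A > 0)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    path = float(d[finite].mean()) if finite.any() else float("nan")
    return float(c.mean()), path
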