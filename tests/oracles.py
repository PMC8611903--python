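"""Independent brute-force oracles used to validate the package's metrics.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, generic library solvers — and shares no code with the package
implementation paths it checks.
"""

import itertools

import networkx as nx
import numpy as np


def modularity_double_sum(W, labels):
    """Q via the explicit double sum over all node pairs."""
    W = np.asarray(W, float)
    n = W.shape[0]
    s = W.sum(axis=1)
    two_m = s.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += W[i, j] - s[i] * s[j] / two_m
    return q / two_m


def best_partition_exhaustive(W):
    """Highest-Q partition by enumerating all set partitions (tiny n only)."""
    n = W.shape[0]
    best_q, best_p = -np.inf, None
    for labels in _set_partitions(n):
        q = modularity_double_sum(W, labels)
        if q > best_q:
            best_q, best_p = q, labels
    return best_q, best_p


def _set_partitions(n):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    def rec(prefix, k):
        if len(prefix) == n:
            yield list(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([], 0)


def participation_loops(W, labels):
    W = np.asarray(W, float)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k_i = W[i].sum()
        if k_i <= 0:
            continue
        acc = 0.0
        for m in set(labels):
            k_im = sum(W[i, j] for j in range(n) if labels[j] == m)
            acc += (k_im / k_i) ** 2
        out[i] = 1.0 - acc
    return out


def eigenvector_dense(W):
    """Leading eigenvector by full symmetric eigendecomposition."""
    vals, vecs = np.linalg.eigh(np.asarray(W, float))
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return v / np.linalg.norm(v)


def global_efficiency_nx(A):
    G = nx.from_numpy_array(np.asarray(A))
    n = G.number_of_nodes()
    total = 0.0
    for u in G:
        lengths = nx.single_source_shortest_path_length(G, u)
        for v, d in lengths.items():
            if v != u:
                total += 1.0 / d
    return total / (n * (n - 1))


def local_efficiency_nx(A):
    A = np.asarray(A)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(A[i])[0]
        if len(nbrs) < 2:
            continue
        out[i] = global_efficiency_nx(A[np.ix_(nbrs, nbrs)])
    return out


def clustering_path_nx(A):
    G = nx.from_numpy_array(np.asarray(A))
    cc = np.mean(list(nx.clustering(G).values()))
    dists = []
    for u in G:
        for v, d in nx.single_source_shortest_path_length(G, u).items():
            if v != u:
                dists.append(d)
    return cc, (np.mean(dists) if dists else np.nan)


def spearman_via_ranks(x, y):
    """Rank both variables (average ranks on ties), then Pearson."""
    def ranks(a):
        a = np.asarray(a, float)
        order = np.argsort(a, kind="stable")
        r = np.empty(len(a))
        r[order] = np.arange(1, len(a) + 1)
        # average tied ranks
        for val in np.unique(a):
            sel = a == val
            r[sel] = r[sel].mean()
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def pearson_direct(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def binned_profile_loops(z_vals, f_vals, width):
    """Per-bin mean/SD/count by explicit looping over edges."""
    k_lo = int(np.floor(min(f_vals) / width))
    k_hi = int(np.floor(max(f_vals) / width))
    means, sds, counts = [], [], []
    for k in range(k_lo, k_hi + 1):
        sel = [z for z, f in zip(z_vals, f_vals)
               if k * width <= f < (k + 1) * width]
        counts.append(len(sel))
        if sel:
            means.append(np.mean(sel))
            sds.append(np.std(sel))
        else:
            means.append(np.nan)
            sds.append(np.nan)
    return np.array(means), np.array(sds), np.array(counts)


def best_label_permutation(labels, reference, n_labels):
    """Max agreement over all label permutations (small module counts)."""
    best = -1
    for perm in itertools.permutations(range(n_labels)):
        mapped = [perm[l] for l in labels]
        agree = sum(m == r for m, r in zip(mapped, reference))
        best = max(best, agree)
    return best
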