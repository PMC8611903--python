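"""Geometry-aware analyses and statistical tests.

Covers the comparisons that interrogate spatial embedding directly: z-scored
log-weight profiles binned by fiber distance, hub identification and their
distance to the brain's center of mass, weight-weighted mean neighbor fiber
distances, surrogate-normalized metric ratios, per-division hub strength,
and the statistical machinery (Spearman/Pearson correlations, one-sample
t-tests with multiple-comparison correction, Tukey's range test, permutation
tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .graph_model import InvalidInputError

__all__ = [
    "BinnedWeightProfile",
    "HubSet",
    "zscore_log_weights",
    "binned_weight_profile",
    "compare_profiles",
    "identify_hubs",
    "com_distances",
    "mean_neighbor_fiber_distance",
    "normalized_metric_ratio",
    "hub_strength_by_division",
    "spearman_rho",
    "pearson_r",
    "division_spearman",
    "tukey_range_test",
    "permutation_test",
]

DEFAULT_BIN_WIDTH_MM = 1.0
DEFAULT_HUB_FRACTION = 0.15


class DegenerateInputError(ValueError):
    """Raised when an input has no variability where some is required."""


def _positive_upper(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W = np.asarray(W, dtype=float)
    iu, ju = np.triu_indices(W.shape[0], k=1)
    keep = W[iu, ju] > 0
    return iu[keep], ju[keep]


# ---------------------------------------------------------------------------
# weight-distance profiles
# ---------------------------------------------------------------------------

def zscore_log_weights(W: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize log-weights to zero mean, unit variance over positive edges.

    Uses the population SD convention by default (``ddof=0``).  Returns a
    symmetric matrix of z-scores with NaN at zero-weight pairs and on the
    diagonal.  Invariant under multiplicative rescaling of W.
    """
    W = np.asarray(W, dtype=float)
    iu, ju = _positive_upper(W)
    if len(iu) < 2:
        raise DegenerateInputError("need >= 2 positive edges to z-score")
    logw = np.log(W[iu, ju])
    mu = logw.mean()
    sd = logw.std(ddof=ddof)
    if sd == 0:
        raise DegenerateInputError("log-weights have zero variance")
    Z = np.full_like(W, np.nan)
    z = (logw - mu) / sd
    Z[iu, ju] = z
    Z[ju, iu] = z
    return Z


@dataclass(frozen=True)
class BinnedWeightProfile:
    """Mean and SD of z-scored log-weights within fixed-width distance bins."""

    bin_edges: np.ndarray  # length B+1, mm
    bin_means: np.ndarray  # length B, NaN where empty
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    significant_bins: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_counts)

    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def binned_weight_profile(
    Z: np.ndarray, F: np.ndarray, width: float = DEFAULT_BIN_WIDTH_MM
) -> BinnedWeightProfile:
    """Bin z-scored log-weights by fiber distance (default 1 mm bins).

    Bin k covers ``[k*width, (k+1)*width)``; empty bins carry NaN mean/SD.
    """
    Z = np.asarray(Z, dtype=float)
    F = np.asarray(F, dtype=float)
    iu, ju = np.triu_indices(Z.shape[0], k=1)
    keep = np.isfinite(Z[iu, ju])
    z = Z[iu, ju][keep]
    f = F[iu, ju][keep]
    k_lo = int(np.floor(f.min() / width))
    k_hi = int(np.floor(f.max() / width))
    edges = np.arange(k_lo, k_hi + 2) * width
    idx = np.floor(f / width).astype(int) - k_lo
    nb = k_hi - k_lo + 1
    counts = np.bincount(idx, minlength=nb)
    means = np.full(nb, np.nan)
    sds = np.full(nb, np.nan)
    for b in range(nb):
        sel = idx == b
        if counts[b] > 0:
            means[b] = z[sel].mean()
            sds[b] = z[sel].std(ddof=0)
    return BinnedWeightProfile(edges, means, sds, counts)


def compare_profiles(
    profiles: list[BinnedWeightProfile],
    reference: BinnedWeightProfile,
    alpha: float = 0.01,
    correction: str = "bonferroni",
    field: str = "bin_means",
) -> np.ndarray:
    """Flag bins where replicate profiles differ from a reference profile.

    Per bin, a one-sample t-test of the replicates' bin values against the
    reference bin value; p-values corrected across tested bins (Bonferroni by
    default, ``correction='fdr_bh'`` for Benjamini–Hochberg).  Bins are tested
    only where the reference and at least 2 replicates have >= 2 observations.
    Returns a boolean flag array on the reference's bin grid.
    """
    if len(profiles) < 2:
        raise InvalidInputError("need >= 2 replicate profiles")
    nb = reference.n_bins
    vals = np.full((len(profiles), nb), np.nan)
    for r, prof in enumerate(profiles):
        # map replicate bins onto the reference grid by edge value
        offset = int(round((prof.bin_edges[0] - reference.bin_edges[0])
                           / (reference.bin_edges[1] - reference.bin_edges[0])))
        data = getattr(prof, field)
        for b in range(prof.n_bins):
            tb = b + offset
            if 0 <= tb < nb and prof.bin_counts[b] >= 2:
                vals[r, tb] = data[b]
    ref_vals = getattr(reference, field)
    testable = (
        (np.sum(np.isfinite(vals), axis=0) >= 2)
        & np.isfinite(ref_vals)
        & (reference.bin_counts >= 2)
    )
    flags = np.zeros(nb, dtype=bool)
    if alpha <= 0 or not testable.any():
        return flags
    pvals = []
    cols = np.nonzero(testable)[0]
    for b in cols:
        col = vals[:, b]
        col = col[np.isfinite(col)]
        if np.allclose(col, col[0]):
            # zero-variance replicates: p = 0 if shifted from reference else 1
            pvals.append(0.0 if col[0] != ref_vals[b] else 1.0)
            continue
        t, p = stats.ttest_1samp(col, ref_vals[b])
        pvals.append(float(p))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method=correction)
    flags[cols] = reject
    return flags


# ---------------------------------------------------------------------------
# hubs and spatial peripherality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HubSet:
    """Top-fraction node subset by a centrality measure."""

    indices: np.ndarray
    fraction: float
    measure: str
    threshold_value: float

    @property
    def n(self) -> int:
        return len(self.indices)

    def mask(self, n_nodes: int) -> np.ndarray:
        m = np.zeros(n_nodes, dtype=bool)
        m[self.indices] = True
        return m


def identify_hubs(values, fraction: float = DEFAULT_HUB_FRACTION,
                  measure: str | None = None) -> HubSet:
    """Select the top ``round(fraction * N)`` nodes by centrality.

    Ties at the threshold are broken by index order (stable sort), with a
    warning when tied values straddle the cutoff.
    """
    from .topology_metrics import CentralityVector

    if isinstance(values, CentralityVector):
        measure = measure or values.measure
        values = values.values
    v = np.asarray(values, dtype=float)
    n = len(v)
    k = int(round(fraction * n))
    order = np.argsort(-v, kind="stable")
    chosen = np.sort(order[:k])
    threshold = float(v[order[k - 1]]) if k > 0 else float("inf")
    if 0 < k < n and v[order[k]] == threshold:
        warnings.warn("centrality ties straddle the hub cutoff; "
                      "broken by index order", stacklevel=2)
    return HubSet(chosen, float(fraction), measure or "strength", threshold)


def center_of_mass(coords: np.ndarray, volumes: np.ndarray | None = None) -> np.ndarray:
    """Volume-weighted mean of node center coordinates (unweighted if None)."""
    coords = np.asarray(coords, dtype=float)
    if volumes is None:
        return coords.mean(axis=0)
    w = np.asarray(volumes, dtype=float)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


def com_distances(
    coords: np.ndarray,
    volumes: np.ndarray | None,
    subset: np.ndarray,
) -> np.ndarray:
    """Euclidean distance from each subset node to the brain's center of mass.

    The center of mass is the volume-weighted mean of ALL node coordinates.
    """
    subset = np.asarray(subset)
    if subset.dtype == bool:
        subset = np.nonzero(subset)[0]
    if len(subset) == 0:
        raise InvalidInputError("subset must be nonempty")
    com = center_of_mass(coords, volumes)
    return np.linalg.norm(np.asarray(coords, dtype=float)[subset] - com, axis=1)


def mean_neighbor_fiber_distance(
    W: np.ndarray, F: np.ndarray, weighted: bool = True
) -> np.ndarray:
    """Average fiber distance to each node's connected neighbors.

    ``weighted=True`` (default): <D>_i = sum_j w_ij f_ij / sum_j w_ij — where
    the node's connectivity MASS sits.  ``weighted=False``: plain mean of
    f_ij over neighbors with w_ij > 0 — where the node's neighbors physically
    sit, the reading used for the hub-peripherality contrast (the weighted
    variant is dominated by the steep weight-distance decay and tracks local
    node spacing rather than peripherality).  Zero-strength nodes get NaN.
    """
    W = np.asarray(W, dtype=float)
    F = np.asarray(F, dtype=float)
    out = np.full(W.shape[0], np.nan)
    if weighted:
        s = W.sum(axis=1)
        ok = s > 0
        out[ok] = (W * F).sum(axis=1)[ok] / s[ok]
    else:
        nbr = W > 0
        cnt = nbr.sum(axis=1)
        ok = cnt > 0
        out[ok] = np.where(nbr, F, 0.0).sum(axis=1)[ok] / cnt[ok]
    return out


def normalized_metric_ratio(empirical_value: float, ensemble_values) -> float:
    """Empirical metric divided by the surrogate-ensemble mean.

    A ratio of 1 means the surrogate null fully accounts for the metric
    (complete geometric determination, for a geometric ensemble).
    """
    ens = np.asarray(ensemble_values, dtype=float)
    m = ens.mean()
    if m == 0:
        raise InvalidInputError("ensemble mean is zero; ratio undefined")
    return float(empirical_value) / float(m)


def hub_strength_by_division(
    strengths: np.ndarray, hubs: HubSet, division: np.ndarray
) -> dict[str, float]:
    """Percent of total hub strength contained in each major brain division.

    Percentages are over ALL divisions present in the labels and sum to 100;
    sub-select afterwards for display.
    """
    s = np.asarray(strengths, dtype=float)
    division = np.asarray(division, dtype=object)
    hub_mask = hubs.mask(len(s))
    total = s[hub_mask].sum()
    if total <= 0:
        raise InvalidInputError("total hub strength must be positive")
    out = {}
    for div in dict.fromkeys(division):  # preserves first-appearance order
        sel = hub_mask & (division == div)
        out[str(div)] = 100.0 * float(s[sel].sum()) / float(total)
    return out


# ---------------------------------------------------------------------------
# correlations and tests
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    rho = stats.spearmanr(np.asarray(x, float), np.asarray(y, float)).statistic
    return float(rho)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation."""
    return float(stats.pearsonr(np.asarray(x, float), np.asarray(y, float)).statistic)


def division_spearman(
    Wa: np.ndarray,
    Wb: np.ndarray,
    division: np.ndarray,
    hemisphere: np.ndarray,
    min_edges: int = 3,
) -> dict[tuple[str, str, str], float]:
    """Spearman correlation of edge weights restricted to division pairs.

    For every ordered-free pair of divisions and laterality in
    {'ipsi', 'contra'}, correlates the two graphs' weights over edges whose
    endpoints lie in those divisions.  Keys are ``(div_a, div_b, laterality)``;
    pairs with fewer than ``min_edges`` edges are omitted.
    """
    Wa = np.asarray(Wa, float)
    Wb = np.asarray(Wb, float)
    division = np.asarray(division, dtype=object)
    hemisphere = np.asarray(hemisphere, dtype=object)
    iu, ju = np.triu_indices(Wa.shape[0], k=1)
    same_hemi = hemisphere[iu] == hemisphere[ju]
    out: dict[tuple[str, str, str], float] = {}
    divs = list(dict.fromkeys(division))
    for a_i, da in enumerate(divs):
        for db in divs[a_i:]:
            in_pair = (
                ((division[iu] == da) & (division[ju] == db))
                | ((division[iu] == db) & (division[ju] == da))
            )
            for lat, latmask in (("ipsi", same_hemi), ("contra", ~same_hemi)):
                sel = in_pair & latmask
                if sel.sum() >= min_edges:
                    out[(str(da), str(db), lat)] = spearman_rho(
                        Wa[iu[sel], ju[sel]], Wb[iu[sel], ju[sel]]
                    )
    return out


def tukey_range_test(groups: list[np.ndarray]) -> np.ndarray:
    """Tukey's range (HSD) test across group means.

    Returns the symmetric matrix of pairwise p-values from the studentized
    range distribution.
    """
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")
    res = stats.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    return np.asarray(res.pvalue)


def permutation_test(
    a,
    b,
    n_perm: int = 999,
    seed: int = 0,
    statistic=None,
) -> float:
    """Two-sample permutation test on the (absolute) mean difference.

    p = (1 + #{permuted |stat| >= observed |stat|}) / (1 + n_perm);
    deterministic for a given seed.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("samples must be nonempty")
    if statistic is None:
        statistic = lambda x, y: x.mean() - y.mean()
    rng = np.random.default_rng(seed)
    obs = abs(statistic(a, b))
    pooled = np.concatenate([a, b])
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:n_a], perm[n_a:])) >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)
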