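"""Geometric and random surrogate graphs for weighted spatial networks.

The geometric surrogate null asks: how much of a connectome's topology is
already implied by (a) its node-strength distribution and (b) the low-order
dependence of edge weight on fiber distance?  A geometric surrogate W_geo is
built from an empirical graph W_emp by

1. fitting a cubic trend g to log-weight vs fiber distance and a parabolic
   spread curve h to the absolute residuals (heteroscedasticity model),
2. detrending each positive edge to a normalized residual
   r_ij = (log w_ij - g(f_ij)) / h(f_ij),
3. shuffling the residuals uniformly over the positive edge positions,
4. re-imposing the trend (retrending) to get provisional log-weights,
5. replacing the provisional weights by the ORIGINAL weight multiset matched
   through rank order (so the marginal weight distribution is exact), and
6. iteratively rescaling rows/columns toward the empirical strength
   DISTRIBUTION: the sorted empirical strengths are assigned to nodes in the
   rank order of the surrogate's own (pre-restoration) strengths, then
   row/column sums are iterated toward those targets.

Rank assignment of strengths — rather than pinning each node to its own
empirical strength — is what lets the null make its own prediction about
WHERE strong nodes sit: in a geometric surrogate the geometrically central
nodes accumulate the large strengths.  Pinning strengths node-wise would
force surrogate hub sets to coincide with the empirical ones and the
hub-peripherality comparisons would be vacuous.

A random surrogate W_rand skips the distance transformations: it shuffles
the weights themselves and restores the strength distribution the same way,
preserving only the strength sequence (its sorted values).

Weights equal to zero are excluded from fitting and shuffling and remain
zero in every surrogate; the count of excluded pairs is recorded on the
fitted :class:`TrendModel`.  All operations are pure functions of their
inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import InvalidInputError, _check_symmetric_nonneg

__all__ = [
    "TrendModel",
    "SurrogateResult",
    "SurrogateEnsemble",
    "fit_trend",
    "detrend_weights",
    "retrend_weights",
    "restore_strength_sequence",
    "geometric_surrogate",
    "random_surrogate",
    "build_ensemble",
]

DEFAULT_STRENGTH_TOL = 1e-3
DEFAULT_MAX_ITER = 1000
#: relative floor applied to the fitted spread curve (fraction of the median
#: absolute residual), preventing division blow-ups where h dips near zero
SPREAD_FLOOR_FRACTION = 1e-6


class InsufficientDataError(ValueError):
    """Raised when too few positive edges are available to fit the trend."""


def _positive_upper_mask(W: np.ndarray) -> np.ndarray:
    mask = np.triu(W > 0, k=1)
    return mask


@dataclass(frozen=True)
class TrendModel:
    """Fitted low-order weight-distance structure of one graph.

    ``cubic_coeffs`` are the coefficients of the cubic trend g in decreasing
    degree order (numpy ``polyval`` convention), fitted to natural-log weight
    vs fiber distance.  ``spread_coeffs`` define the parabola h fitted to the
    absolute residuals of g, modeling how residual spread varies with
    distance; evaluation floors h at ``spread_floor``.
    """

    cubic_coeffs: np.ndarray
    spread_coeffs: np.ndarray
    spread_floor: float
    n_edges_fit: int
    excluded_zero_edges: int
    distance_range: tuple[float, float]

    def trend(self, f: np.ndarray) -> np.ndarray:
        """Evaluate g(f): expected natural-log weight at fiber distance f."""
        return np.polyval(self.cubic_coeffs, f)

    def spread(self, f: np.ndarray) -> np.ndarray:
        """Evaluate h(f), floored at ``spread_floor`` (strictly positive)."""
        return np.maximum(np.polyval(self.spread_coeffs, f), self.spread_floor)


def fit_trend(W: np.ndarray, F: np.ndarray) -> TrendModel:
    """Fit the cubic log-weight trend g and the parabolic residual spread h.

    Both fits are ordinary least squares over the strictly positive
    upper-triangle edges.  Residuals of g have zero mean by construction.
    """
    W = np.asarray(W, dtype=float)
    F = np.asarray(F, dtype=float)
    mask = _positive_upper_mask(W) & np.isfinite(F)
    n_pos = int(mask.sum())
    n_upper = W.shape[0] * (W.shape[0] - 1) // 2
    if n_pos < 10:
        raise InsufficientDataError(
            f"need >= 10 positive edges with finite distances, got {n_pos}"
        )
    f = F[mask]
    logw = np.log(W[mask])
    cubic = np.polyfit(f, logw, 3)
    resid = logw - np.polyval(cubic, f)
    abs_resid = np.abs(resid)
    spread = np.polyfit(f, abs_resid, 2)
    # absolute lower bound guards the all-but-noiseless case, where residuals
    # are pure float error and dividing by their median would amplify it
    floor = max(float(np.median(abs_resid)) * SPREAD_FLOOR_FRACTION, 1e-8)
    return TrendModel(
        cubic_coeffs=cubic,
        spread_coeffs=spread,
        spread_floor=floor,
        n_edges_fit=n_pos,
        excluded_zero_edges=n_upper - n_pos,
        distance_range=(float(f.min()), float(f.max())),
    )


def detrend_weights(W: np.ndarray, F: np.ndarray, model: TrendModel) -> np.ndarray:
    """Remove the fitted low-order weight-distance structure.

    Returns a symmetric matrix of normalized residuals
    ``r_ij = (log w_ij - g(f_ij)) / h(f_ij)`` on positive edges; zero-weight
    pairs and the diagonal carry NaN as a missing marker.
    """
    W = np.asarray(W, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.any(W < 0):
        raise InvalidInputError("weights must be nonnegative")
    R = np.full_like(W, np.nan)
    pos = W > 0
    np.fill_diagonal(pos, False)
    R[pos] = (np.log(W[pos]) - model.trend(F[pos])) / model.spread(F[pos])
    return R


def retrend_weights(R: np.ndarray, F: np.ndarray, model: TrendModel) -> np.ndarray:
    """Invert :func:`detrend_weights`: log w_ij = g(f_ij) + h(f_ij) * r_ij.

    Returns the natural-log weight matrix, NaN where R is missing.
    """
    R = np.asarray(R, dtype=float)
    F = np.asarray(F, dtype=float)
    if R.shape != F.shape:
        raise InvalidInputError("residual and distance matrices must share shape")
    return model.trend(F) + model.spread(F) * R


def restore_strength_sequence(
    W_shuf: np.ndarray,
    target_strengths: np.ndarray,
    tol: float = DEFAULT_STRENGTH_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float, bool]:
    """Iteratively rescale a symmetric matrix toward target row/column sums.

    Each sweep multiplies ``w_ij`` by ``sqrt((t_i/s_i)(t_j/s_j))`` where s is
    the current strength vector — a symmetric, nonnegativity-preserving
    analogue of iterative proportional fitting.  Stops when every node
    strength is within relative error ``tol`` of its target.

    Returns ``(matrix, iterations_used, final_max_rel_error, converged)``;
    non-convergence is flagged, never silent.
    """
    W = np.array(W_shuf, dtype=float)
    _check_symmetric_nonneg(W, "W_shuf")
    t = np.asarray(target_strengths, dtype=float)
    if t.shape != (W.shape[0],) or np.any(t <= 0):
        raise InvalidInputError("target strengths must be positive, length N")
    err = np.inf
    for it in range(max_iter + 1):
        s = W.sum(axis=1)
        if np.any(s <= 0):
            return W, it, np.inf, False
        err = float(np.max(np.abs(s - t) / t))
        if err <= tol:
            return W, it, err, True
        if it == max_iter:
            break
        c = np.sqrt(t / s)
        W *= np.outer(c, c)
        np.fill_diagonal(W, 0.0)
    return W, max_iter, err, False


@dataclass(frozen=True)
class SurrogateResult:
    """One surrogate matrix plus its convergence diagnostics."""

    matrix: np.ndarray
    kind: str
    seed: int
    strength_error: float
    iterations_used: int
    converged: bool
    prerestoration: np.ndarray | None = None


@dataclass
class SurrogateEnsemble:
    """A reproducible collection of surrogate matrices of one kind."""

    kind: str
    matrices: list = field(default_factory=list)
    seeds: list = field(default_factory=list)
    strength_error: list = field(default_factory=list)
    iterations_used: list = field(default_factory=list)
    converged: list = field(default_factory=list)

    def append(self, r: SurrogateResult) -> None:
        self.matrices.append(r.matrix)
        self.seeds.append(r.seed)
        self.strength_error.append(r.strength_error)
        self.iterations_used.append(r.iterations_used)
        self.converged.append(r.converged)

    @property
    def n(self) -> int:
        return len(self.matrices)

    def all_converged(self) -> bool:
        return all(self.converged)


def _shuffled_positions(W: np.ndarray, rng: np.random.Generator):
    mask = _positive_upper_mask(W)
    iu, ju = np.nonzero(mask)
    perm = rng.permutation(len(iu))
    return iu, ju, perm


def _rank_assigned_targets(S: np.ndarray, empirical_strengths: np.ndarray) -> np.ndarray:
    """Assign the sorted empirical strength multiset to nodes by the rank
    order of the surrogate's current strengths."""
    s_pre = S.sum(axis=1)
    targets = np.empty_like(s_pre)
    targets[np.argsort(s_pre, kind="stable")] = np.sort(empirical_strengths)
    return targets


def geometric_surrogate(
    W: np.ndarray,
    F: np.ndarray,
    seed: int,
    tol: float = DEFAULT_STRENGTH_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    model: TrendModel | None = None,
    keep_prerestoration: bool = False,
) -> SurrogateResult:
    """Build one geometric surrogate: distance trend and strengths preserved,
    all other topology destroyed.

    The intermediate (pre-restoration) matrix carries exactly the empirical
    weight multiset; the returned matrix additionally matches the empirical
    strength distribution — sorted surrogate strengths equal sorted empirical
    strengths within ``tol`` relative error (or the result is flagged
    non-converged).
    """
    W = np.asarray(W, dtype=float)
    _check_symmetric_nonneg(W, "weights")
    rng = np.random.default_rng(seed)
    if model is None:
        model = fit_trend(W, F)
    R = detrend_weights(W, F, model)
    iu, ju, perm = _shuffled_positions(W, rng)
    r_vals = R[iu, ju]
    shuf = np.full_like(W, np.nan)
    shuf[iu[perm], ju[perm]] = r_vals  # residuals moved to random positions
    logw = retrend_weights(shuf, F, model)
    # rank-match: original weight multiset through the surrogate rank order
    prov = logw[iu, ju]
    order = np.argsort(prov, kind="stable")
    new_w = np.zeros_like(prov)
    new_w[order] = np.sort(W[iu, ju])
    S = np.zeros_like(W)
    S[iu, ju] = new_w
    S += S.T
    pre = S.copy() if keep_prerestoration else None
    targets = _rank_assigned_targets(S, W.sum(axis=1))
    out, iters, err, ok = restore_strength_sequence(S, targets, tol, max_iter)
    return SurrogateResult(out, "geometric", int(seed), err, iters, ok, pre)


def random_surrogate(
    W: np.ndarray,
    seed: int,
    tol: float = DEFAULT_STRENGTH_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    keep_prerestoration: bool = False,
) -> SurrogateResult:
    """Build one random surrogate: weights shuffled over positive edge
    positions, then the strength distribution restored by rank assignment —
    no distance structure kept."""
    W = np.asarray(W, dtype=float)
    _check_symmetric_nonneg(W, "weights")
    rng = np.random.default_rng(seed)
    iu, ju, perm = _shuffled_positions(W, rng)
    S = np.zeros_like(W)
    S[iu[perm], ju[perm]] = W[iu, ju]
    S += S.T
    pre = S.copy() if keep_prerestoration else None
    targets = _rank_assigned_targets(S, W.sum(axis=1))
    out, iters, err, ok = restore_strength_sequence(S, targets, tol, max_iter)
    return SurrogateResult(out, "random", int(seed), err, iters, ok, pre)


def build_ensemble(
    W: np.ndarray,
    F: np.ndarray | None,
    n: int,
    kind: str,
    base_seed: int,
    tol: float = DEFAULT_STRENGTH_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SurrogateEnsemble:
    """Build ``n`` surrogates with per-member seeds ``base_seed .. base_seed+n-1``.

    Per-member non-convergence is recorded in the diagnostics, not raised.
    """
    if n < 1:
        raise InvalidInputError("ensemble size must be >= 1")
    if kind not in ("geometric", "random"):
        raise InvalidInputError("kind must be 'geometric' or 'random'")
    ens = SurrogateEnsemble(kind=kind)
    model = fit_trend(W, F) if kind == "geometric" else None
    for i in range(n):
        seed = int(base_seed) + i
        if kind == "geometric":
            res = geometric_surrogate(W, F, seed, tol, max_iter, model=model)
        else:
            res = random_surrogate(W, seed, tol, max_iter)
        ens.append(res)
    return ens
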