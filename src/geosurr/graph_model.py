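"""Spatially embedded weighted networks: containers, construction conventions, I/O.

A connectome here is a symmetric nonnegative weight matrix over parcellated
gray-matter regions, together with the spatial attributes the geometric
analyses need: region center-of-mass coordinates (mm), region volumes (mm3),
a pairwise fiber-distance matrix (mm), hemisphere labels and major-division
labels, plus an index pairing each region with its mirror homolog.

Matrices travel as dense labeled TSV (UTF-8, '.' decimal, region ids as both
header row and first column); the parcellation is a TSV with one row per
region.  Zero weights are stored as explicit zeros — these graphs are nearly
fully connected, and downstream log-space operations skip non-positive
entries explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpatialGraph",
    "Parcellation",
    "symmetrize_directed",
    "enforce_hemispheric_symmetry",
    "normalize_connection_density",
    "threshold_to_density",
    "read_spatial_graph",
    "write_spatial_graph",
    "write_edge_list",
]

#: tolerance used when validating matrix symmetry on input
SYMMETRY_ATOL = 1e-9
#: slack allowed in the fiber-distance >= Euclidean-distance check (mm)
EUCLIDEAN_SLACK = 1e-6


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class Parcellation:
    """Region table: ids, names, divisions, hemispheres and homolog pairing."""

    region_id: np.ndarray  # str
    name: np.ndarray  # str
    division: np.ndarray  # str
    hemisphere: np.ndarray  # 'L' / 'R'
    homolog_id: np.ndarray  # str, resolves to the mirror region

    def __post_init__(self) -> None:
        ids = np.asarray(self.region_id, dtype=object)
        if len(set(ids)) != len(ids):
            raise InvalidInputError("region_ids must be unique")
        index = {r: i for i, r in enumerate(ids)}
        for i, hid in enumerate(np.asarray(self.homolog_id, dtype=object)):
            j = index.get(hid)
            if j is None:
                raise InvalidInputError(f"homolog_id {hid!r} does not resolve")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise InvalidInputError(
                    f"homolog of {ids[i]!r} must lie in the opposite hemisphere"
                )

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def homolog_indices(self) -> np.ndarray:
        """Integer involution h with h[i] = index of region i's mirror partner."""
        index = {r: i for i, r in enumerate(self.region_id)}
        return np.array([index[h] for h in self.homolog_id], dtype=np.intp)


@dataclass
class SpatialGraph:
    """Weighted symmetric network with spatial embedding.

    Attributes
    ----------
    weights : (N, N) ndarray
        Symmetric nonnegative connectivity, zero diagonal.  Units are
        modality-specific (normalized connection density for tracer-style
        input, volume-normalized streamline counts for tractography-style).
    fiber_distances : (N, N) ndarray
        Symmetric pairwise fiber (pathway) distances in mm; zero diagonal,
        strictly positive off-diagonal wherever a weight is positive, and
        never shorter than the straight-line distance between region centers.
    coordinates : (N, 3) ndarray
        Region centers of mass, mm, RAS orientation.
    volumes : (N,) ndarray
        Region volumes, mm3, strictly positive.
    region_ids, hemisphere, division : (N,) object ndarrays
        Labels; hemisphere entries are 'L' or 'R', division one of the major
        brain divisions.
    homolog : (N,) intp ndarray
        Involution pairing mirror regions across hemispheres.
    """

    weights: np.ndarray
    fiber_distances: np.ndarray
    coordinates: np.ndarray
    volumes: np.ndarray
    region_ids: np.ndarray
    hemisphere: np.ndarray
    division: np.ndarray
    homolog: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.fiber_distances = np.asarray(self.fiber_distances, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.region_ids = np.asarray(self.region_ids, dtype=object)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        self.division = np.asarray(self.division, dtype=object)
        self.homolog = np.asarray(self.homolog, dtype=np.intp)
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        n = self.weights.shape[0]
        for name, arr, shape in [
            ("weights", self.weights, (n, n)),
            ("fiber_distances", self.fiber_distances, (n, n)),
            ("coordinates", self.coordinates, (n, 3)),
            ("volumes", self.volumes, (n,)),
            ("region_ids", self.region_ids, (n,)),
            ("hemisphere", self.hemisphere, (n,)),
            ("division", self.division, (n,)),
            ("homolog", self.homolog, (n,)),
        ]:
            if arr.shape != shape:
                raise InvalidInputError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        _check_symmetric_nonneg(self.weights, "weights")
        _check_symmetric(self.fiber_distances, "fiber_distances")
        if np.any(np.diag(self.fiber_distances) != 0):
            raise InvalidInputError("fiber_distances diagonal must be zero")
        pos = self.weights > 0
        np.fill_diagonal(pos, False)
        if np.any(self.fiber_distances[pos] <= 0):
            raise InvalidInputError(
                "fiber_distances must be strictly positive wherever weights are"
            )
        if np.any(self.volumes <= 0):
            raise InvalidInputError("volumes must be strictly positive")
        euclid = _pairwise_euclidean(self.coordinates)
        short = pos & (self.fiber_distances < euclid - EUCLIDEAN_SLACK)
        if np.any(short):
            i, j = np.argwhere(short)[0]
            raise InvalidInputError(
                f"fiber distance ({i},{j}) shorter than Euclidean distance"
            )
        h = self.homolog
        if not np.array_equal(h[h], np.arange(n)):
            raise InvalidInputError("homolog must be an involution")
        mism = self.hemisphere[h] == self.hemisphere
        if np.any(mism & (h != np.arange(n))):
            raise InvalidInputError("homolog pairs must span hemispheres")

    def euclidean_distances(self) -> np.ndarray:
        return _pairwise_euclidean(self.coordinates)

    def copy_with(self, **kw) -> "SpatialGraph":
        base = dict(
            weights=self.weights,
            fiber_distances=self.fiber_distances,
            coordinates=self.coordinates,
            volumes=self.volumes,
            region_ids=self.region_ids,
            hemisphere=self.hemisphere,
            division=self.division,
            homolog=self.homolog,
        )
        base.update(kw)
        return SpatialGraph(**{k: np.array(v, copy=True) if isinstance(v, np.ndarray) else v for k, v in base.items()})


def _pairwise_euclidean(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _check_symmetric(m: np.ndarray, name: str, atol: float = SYMMETRY_ATOL) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError(f"{name} must be square")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError(f"{name} contains non-finite values")
    asym = np.abs(m - m.T)
    if asym.max(initial=0.0) > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise InvalidInputError(
            f"{name} asymmetric beyond {atol} at indices ({i},{j})"
        )


def _check_symmetric_nonneg(m: np.ndarray, name: str) -> None:
    _check_symmetric(m, name)
    if np.any(m < 0):
        raise InvalidInputError(f"{name} must be nonnegative")
    if np.any(np.diag(m) != 0):
        raise InvalidInputError(f"{name} diagonal must be zero")


# ---------------------------------------------------------------------------
# construction conventions
# ---------------------------------------------------------------------------

def symmetrize_directed(W_dir: np.ndarray) -> np.ndarray:
    """Convert a directed weight matrix to undirected by summing both directions.

    ``out[i, j] = W_dir[i, j] + W_dir[j, i]`` off the diagonal; the diagonal
    is forced to zero.  This mirrors how anterograde tracer graphs are made
    comparable with inherently undirected tractography graphs.
    """
    W_dir = np.asarray(W_dir, dtype=float)
    if W_dir.ndim != 2 or W_dir.shape[0] != W_dir.shape[1]:
        raise InvalidInputError("directed weight matrix must be square")
    if not np.all(np.isfinite(W_dir)):
        raise InvalidInputError("directed weight matrix must be finite")
    if np.any(W_dir < 0):
        raise InvalidInputError("directed weight matrix must be nonnegative")
    out = W_dir + W_dir.T
    np.fill_diagonal(out, 0.0)
    return out


def enforce_hemispheric_symmetry(
    W: np.ndarray, homolog: np.ndarray, mode: str = "average"
) -> np.ndarray:
    """Impose exact mirror symmetry: ``out[i, j] == out[h(i), h(j)]``.

    Each entry is combined with its mirrored counterpart.  ``mode='average'``
    (default) keeps total weight fixed and is idempotent; ``mode='sum'`` adds
    the two mirrored entries instead.
    """
    W = np.asarray(W, dtype=float)
    _check_symmetric(W, "weights")
    h = np.asarray(homolog, dtype=np.intp)
    n = W.shape[0]
    if h.shape != (n,) or not np.array_equal(h[h], np.arange(n)):
        raise InvalidInputError("homolog must be an involution over node indices")
    mirrored = W[np.ix_(h, h)]
    if mode == "average":
        out = 0.5 * (W + mirrored)
    elif mode == "sum":
        out = W + mirrored
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    np.fill_diagonal(out, 0.0)
    return out


def normalize_connection_density(
    counts: np.ndarray, volumes: np.ndarray
) -> np.ndarray:
    """Normalized connection density: raw weight / product of the node volumes."""
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0) or not np.all(np.isfinite(volumes)):
        raise InvalidInputError("volumes must be strictly positive and finite")
    return counts / np.outer(volumes, volumes)


def threshold_to_density(W: np.ndarray, d: float) -> np.ndarray:
    """Binarize a weighted graph by keeping the top-weight fraction of node pairs.

    Retains the ``ceil(d * N(N-1)/2)`` largest-weight pairs as binary edges.
    Ties are broken by lexicographic (i, j) index order, which makes a density
    sweep deterministic and monotone: the edge set at a lower density is a
    subset of the edge set at any higher density.
    """
    W = np.asarray(W, dtype=float)
    _check_symmetric(W, "weights")
    if not (0.0 <= d <= 1.0):
        raise InvalidInputError("density must lie in [0, 1]")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    k = math.ceil(d * len(iu))
    A = np.zeros((n, n), dtype=np.int8)
    if k > 0:
        # stable sort on -weight keeps lexicographic order within tied weights
        order = np.argsort(-W[iu, ju], kind="stable")[:k]
        A[iu[order], ju[order]] = 1
        A[ju[order], iu[order]] = 1
    return A


# ---------------------------------------------------------------------------
# I/O — dense labeled TSV + parcellation table
# ---------------------------------------------------------------------------

PARCELLATION_COLUMNS = [
    "region_id",
    "name",
    "division",
    "hemisphere",
    "homolog_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "volume_mm3",
]


def _matrix_to_frame(m: np.ndarray, ids: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(m, index=ids, columns=ids)


def _read_matrix(path: Path, ids: np.ndarray, name: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    want = [str(r) for r in ids]
    if set(df.index) != set(want) or set(df.columns) != set(want):
        raise InvalidInputError(
            f"{name} matrix labels do not match the parcellation region_ids"
        )
    df = df.loc[want, want]  # reorder rows/columns to parcellation order
    m = df.to_numpy(dtype=float)
    if np.isnan(m).any():
        raise InvalidInputError(f"{name} matrix contains NaN")
    _check_symmetric(m, name)
    return m


def read_spatial_graph(
    weights_path: str | Path,
    distances_path: str | Path,
    parcellation_path: str | Path,
) -> SpatialGraph:
    """Load a :class:`SpatialGraph` from labeled TSV matrices and a parcellation.

    Matrix rows/columns are reordered to parcellation order; a label-set or
    dimension mismatch, NaN entries, or asymmetry beyond ``1e-9`` is rejected.
    """
    parc = pd.read_csv(parcellation_path, sep="\t", dtype={c: str for c in
                       ("region_id", "name", "division", "hemisphere", "homolog_id")})
    missing = [c for c in PARCELLATION_COLUMNS if c not in parc.columns]
    if missing:
        raise InvalidInputError(f"parcellation missing columns: {missing}")
    ids = parc["region_id"].to_numpy(dtype=object)
    p = Parcellation(
        region_id=ids,
        name=parc["name"].to_numpy(dtype=object),
        division=parc["division"].to_numpy(dtype=object),
        hemisphere=parc["hemisphere"].to_numpy(dtype=object),
        homolog_id=parc["homolog_id"].to_numpy(dtype=object),
    )
    W = _read_matrix(Path(weights_path), ids, "weights")
    F = _read_matrix(Path(distances_path), ids, "fiber_distances")
    return SpatialGraph(
        weights=W,
        fiber_distances=F,
        coordinates=parc[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        volumes=parc["volume_mm3"].to_numpy(dtype=float),
        region_ids=ids,
        hemisphere=p.hemisphere,
        division=p.division,
        homolog=p.homolog_indices(),
    )


def write_spatial_graph(g: SpatialGraph, out_dir: str | Path,
                        prefix: str = "graph") -> dict[str, Path]:
    """Write a graph as ``<prefix>_weights.tsv``, ``<prefix>_distances.tsv`` and
    ``<prefix>_parcellation.tsv`` under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": out / f"{prefix}_weights.tsv",
        "distances": out / f"{prefix}_distances.tsv",
        "parcellation": out / f"{prefix}_parcellation.tsv",
    }
    fmt = "%.17g"
    _matrix_to_frame(g.weights, g.region_ids).to_csv(
        paths["weights"], sep="\t", float_format=fmt)
    _matrix_to_frame(g.fiber_distances, g.region_ids).to_csv(
        paths["distances"], sep="\t", float_format=fmt)
    parc = pd.DataFrame({
        "region_id": g.region_ids,
        "name": g.region_ids,
        "division": g.division,
        "hemisphere": g.hemisphere,
        "homolog_id": g.region_ids[g.homolog],
        "x_mm": g.coordinates[:, 0],
        "y_mm": g.coordinates[:, 1],
        "z_mm": g.coordinates[:, 2],
        "volume_mm3": g.volumes,
    })
    parc.to_csv(paths["parcellation"], sep="\t", index=False, float_format=fmt)
    return paths


def write_edge_list(A: np.ndarray, ids: np.ndarray, path: str | Path) -> None:
    """Export a binary adjacency as a two-label-column TSV edge list."""
    A = np.asarray(A)
    iu, ju = np.triu_indices(A.shape[0], k=1)
    keep = A[iu, ju] > 0
    pd.DataFrame({
        "region_a": np.asarray(ids, dtype=object)[iu[keep]],
        "region_b": np.asarray(ids, dtype=object)[ju[keep]],
    }).to_csv(path, sep="\t", index=False)
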