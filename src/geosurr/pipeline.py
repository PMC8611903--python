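"""End-to-end analysis workflow and its configuration schema.

Orchestrates the full study design over one or more spatially embedded
graphs: build geometric and random surrogate ensembles, compare edge weights
and weight-distance profiles against a designated reference graph, quantify
modular structure (Louvain, consensus, surrogate-normalized Q), hub
organization (strength and eigenvector-centrality hubs, center-of-mass
peripherality, neighbor distances), and binary efficiency across a density
sweep — emitting a single deterministic, JSON-serializable report.

Every stochastic step derives its seed from the master seed, so a config
re-run is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import geometry_stats as gstats
from . import graph_model as gm
from . import surrogate_engine as se
from . import synthetic_data as syn
from . import topology_metrics as tm

__all__ = ["AnalysisConfig", "GraphSource", "run_analysis", "efficiency_sweep"]


@dataclass(frozen=True)
class GraphSource:
    """One input graph: either TSV paths or a synthetic benchmark spec."""

    name: str
    weights: str | None = None
    distances: str | None = None
    parcellation: str | None = None
    synthetic: dict | None = None  # kwargs for SyntheticSpec (seed offset applied)

    def load(self, master_seed: int) -> tuple[gm.SpatialGraph, syn.GroundTruth | None]:
        if self.synthetic is not None:
            kw = dict(self.synthetic)
            kw.setdefault("seed", 0)
            kw["seed"] = int(kw["seed"]) + master_seed
            g, truth = syn.make_benchmark(syn.SyntheticSpec(**kw))
            return g, truth
        if not (self.weights and self.distances and self.parcellation):
            raise gm.InvalidInputError(
                f"graph {self.name!r} needs weights/distances/parcellation paths "
                "or a synthetic spec"
            )
        return gm.read_spatial_graph(self.weights, self.distances,
                                     self.parcellation), None


@dataclass
class AnalysisConfig:
    """Resolved configuration for :func:`run_analysis`.

    All constants of the study design live here: ensemble sizes (100 of each
    kind), the hub fraction (0.15), the 1 mm profile bin width, the density
    grid for the efficiency sweep (21 points, 0.05..1.0), the significance
    level (0.01) and the Louvain settings.  ``louvain_restarts`` applies to
    empirical graphs; surrogates get ``surrogate_restarts`` each (the ratio
    denominators average over the ensemble, so extra per-member restarts buy
    little).
    """

    seed: int = 0
    graphs: list = field(default_factory=list)  # list[GraphSource]
    reference: str | None = None
    n_geometric: int = 100
    n_random: int = 100
    strength_tol: float = se.DEFAULT_STRENGTH_TOL
    max_iter: int = se.DEFAULT_MAX_ITER
    louvain_restarts: int = 5
    surrogate_restarts: int = 1
    resolution: float = 1.0
    hub_fraction: float = 0.15
    bin_width_mm: float = 1.0
    alpha: float = 0.01
    profile_replicates: int = 0  # extra noise realizations per synthetic graph
    densities: tuple = tuple(np.round(np.linspace(0.05, 1.0, 21), 4))
    consensus_runs: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        graphs = [GraphSource(**g) for g in raw.pop("graphs", [])]
        cfg = cls(graphs=graphs, **raw)
        return cfg

    def resolved(self) -> dict:
        d = asdict(self)
        d["graphs"] = [asdict(g) for g in self.graphs]
        d["densities"] = list(self.densities)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _exceedance_p(empirical: float, ensemble: np.ndarray, side: str = "ge") -> float:
    """Surrogate-data p-value: fraction of the ensemble at least as extreme."""
    ens = np.asarray(ensemble, dtype=float)
    if side == "ge":
        count = int((ens >= empirical).sum())
    else:
        count = int((ens <= empirical).sum())
    return (1 + count) / (1 + len(ens))


# ---------------------------------------------------------------------------
# efficiency sweep
# ---------------------------------------------------------------------------

def _density_prefix_adjacencies(W: np.ndarray, densities) -> list[np.ndarray]:
    """Thresholded binary adjacencies for every density, sharing one sort.

    Equivalent to ``threshold_to_density`` per density (same stable
    tie-break), but the pair ranking is computed once.
    """
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.argsort(-W[iu, ju], kind="stable")
    out = []
    for d in densities:
        k = int(np.ceil(d * len(iu)))
        A = np.zeros((n, n), dtype=np.int8)
        sel = order[:k]
        A[iu[sel], ju[sel]] = 1
        A[ju[sel], iu[sel]] = 1
        out.append(A)
    return out


def efficiency_sweep(
    W: np.ndarray,
    densities,
    ensembles: dict[str, se.SurrogateEnsemble] | None = None,
    include_local: bool = True,
) -> dict:
    """Binary global (and optionally local) efficiency across edge densities.

    For each density: threshold the weighted graphs to that density, measure
    efficiency for the empirical graph and every ensemble member, and report
    the empirical value normalized by each ensemble mean.
    """
    densities = [float(d) for d in densities]
    for d in densities:
        if not (0.0 < d <= 1.0):
            raise gm.InvalidInputError("densities must lie in (0, 1]")
    emp_adj = _density_prefix_adjacencies(W, densities)
    out: dict = {
        "densities": densities,
        "global_efficiency": [tm.global_efficiency(A) for A in emp_adj],
    }
    if include_local:
        out["local_efficiency_mean"] = [
            float(tm.local_efficiency(A).values.mean()) for A in emp_adj
        ]
    for label, ens in (ensembles or {}).items():
        per_member = np.empty((ens.n, len(densities)))
        for m, M in enumerate(ens.matrices):
            adjs = _density_prefix_adjacencies(M, densities)
            per_member[m] = [tm.global_efficiency(A) for A in adjs]
        mean = per_member.mean(axis=0)
        out[f"global_efficiency_{label}_mean"] = mean.tolist()
        out[f"global_efficiency_{label}_sd"] = per_member.std(axis=0).tolist()
        out[f"global_efficiency_{label}_normalized"] = (
            np.asarray(out["global_efficiency"]) / mean
        ).tolist()
        out[f"global_efficiency_{label}_p"] = [
            _exceedance_p(out["global_efficiency"][i], per_member[:, i], "ge")
            if out["global_efficiency"][i] >= mean[i]
            else _exceedance_p(out["global_efficiency"][i], per_member[:, i], "le")
            for i in range(len(densities))
        ]
    return out


# ---------------------------------------------------------------------------
# per-graph analysis
# ---------------------------------------------------------------------------

def _hub_analysis(g: gm.SpatialGraph, W: np.ndarray, cfg: AnalysisConfig,
                  ensembles: dict[str, se.SurrogateEnsemble]) -> dict:
    F = g.fiber_distances
    out = {}
    dnb_unw = gstats.mean_neighbor_fiber_distance(W, F, weighted=False)
    dnb_w = gstats.mean_neighbor_fiber_distance(W, F, weighted=True)
    for measure in ("strength", "eigenvector"):
        cv = (tm.node_strengths(W) if measure == "strength"
              else tm.eigenvector_centrality(W))
        hubs = gstats.identify_hubs(cv, cfg.hub_fraction)
        mask = hubs.mask(g.n_nodes)
        dists = gstats.com_distances(g.coordinates, g.volumes, hubs.indices)
        section = {
            "members": [str(r) for r in g.region_ids[hubs.indices]],
            "com_distance_mean": float(dists.mean()),
            "com_distances": dists.tolist(),
            "division_percent": gstats.hub_strength_by_division(
                cv.values if measure == "strength" else W.sum(axis=1),
                hubs, g.division),
            "dnb_hub_mean": float(np.nanmean(dnb_unw[mask])),
            "dnb_feeder_mean": float(np.nanmean(dnb_unw[~mask])),
            "dnb_weighted_hub_mean": float(np.nanmean(dnb_w[mask])),
            "dnb_weighted_feeder_mean": float(np.nanmean(dnb_w[~mask])),
        }
        # surrogate comparison: per-ensemble hub COM distances and <D> split
        for label, ens in ensembles.items():
            sur_com = []
            sur_hub_dnb = []
            sur_feed_dnb = []
            for M in ens.matrices:
                c2 = (tm.node_strengths(M) if measure == "strength"
                      else tm.eigenvector_centrality(M))
                h2 = gstats.identify_hubs(c2, cfg.hub_fraction)
                m2 = h2.mask(g.n_nodes)
                sur_com.append(gstats.com_distances(
                    g.coordinates, g.volumes, h2.indices))
                d2 = gstats.mean_neighbor_fiber_distance(M, F, weighted=False)
                sur_hub_dnb.append(float(np.nanmean(d2[m2])))
                sur_feed_dnb.append(float(np.nanmean(d2[~m2])))
            pooled = np.concatenate(sur_com)
            tukey_p = float(gstats.tukey_range_test([dists, pooled])[0, 1])
            section[f"{label}_com_distance_mean"] = float(pooled.mean())
            section[f"{label}_com_tukey_p"] = tukey_p
            section[f"{label}_dnb_hub_mean"] = float(np.mean(sur_hub_dnb))
            section[f"{label}_dnb_feeder_mean"] = float(np.mean(sur_feed_dnb))
        out[measure] = section
    return out


def _module_analysis(W: np.ndarray, cfg: AnalysisConfig, seed: int,
                     ensembles: dict[str, se.SurrogateEnsemble],
                     reference_partition: tm.ModulePartition | None) -> dict:
    emp = tm.louvain_partition(W, seed=seed, resolution=cfg.resolution,
                               restarts=cfg.louvain_restarts)
    ref = reference_partition if reference_partition is not None else emp
    runs = [tm.louvain_partition(W, seed=seed + 1 + r, resolution=cfg.resolution)
            for r in range(cfg.consensus_runs)]
    consensus = tm.consensus_partition(runs, ref)
    out = {
        "Q": emp.Q,
        "n_modules": emp.n_modules,
        "louvain_restarts": cfg.louvain_restarts,
        "consensus_assignment": consensus.assignment.tolist(),
        "consensus_agreement_with_reference": tm.partition_agreement(
            consensus, ref),
        "participation": tm.participation_coefficients(W, emp).values.tolist(),
    }
    for label, ens in ensembles.items():
        qs = []
        parts = []
        for m, M in enumerate(ens.matrices):
            p = tm.louvain_partition(M, seed=seed + 5000 + m,
                                     resolution=cfg.resolution,
                                     restarts=cfg.surrogate_restarts)
            qs.append(p.Q)
            parts.append(p)
        qs = np.asarray(qs)
        out[f"Q_{label}_mean"] = float(qs.mean())
        out[f"Q_{label}_sd"] = float(qs.std())
        out[f"Q_{label}_normalized"] = gstats.normalized_metric_ratio(emp.Q, qs)
        out[f"Q_{label}_p"] = _exceedance_p(emp.Q, qs, "ge")
        cons_s = tm.consensus_partition(parts, ref)
        out[f"consensus_agreement_{label}"] = tm.partition_agreement(cons_s, ref)
    return out, emp


def run_analysis(config: AnalysisConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow and return the analysis report.

    Deterministic per master seed; per-surrogate non-convergence is recorded
    in the report's diagnostics rather than raised.  When ``out_dir`` is
    given, the report is written as ``report.json``.
    """
    if not config.graphs:
        raise gm.InvalidInputError("config must name at least one graph")
    master = int(config.seed)
    loaded: dict[str, tuple[gm.SpatialGraph, syn.GroundTruth | None]] = {}
    src_by_name: dict[str, GraphSource] = {}
    for src in config.graphs:
        loaded[src.name] = src.load(master)
        src_by_name[src.name] = src
    ref_name = config.reference or config.graphs[0].name
    if ref_name not in loaded:
        raise gm.InvalidInputError(f"reference graph {ref_name!r} not in config")

    report: dict = {
        "config": config.resolved(),
        "reference": ref_name,
        "graphs": {},
    }

    # reference analyzed first so others can compare against it
    order = [ref_name] + [n for n in loaded if n != ref_name]
    ref_partition = None
    ref_profile = None
    ref_graph = loaded[ref_name][0]
    for gi, name in enumerate(order):
        g, truth = loaded[name]
        W, F = g.weights, g.fiber_distances
        gsec: dict = {"n_nodes": g.n_nodes}
        seed_base = master + 104729 * (gi + 1)  # disjoint per-graph seed blocks

        ensembles: dict[str, se.SurrogateEnsemble] = {}
        if config.n_geometric > 0:
            ensembles["geo"] = se.build_ensemble(
                W, F, config.n_geometric, "geometric", seed_base,
                config.strength_tol, config.max_iter)
        if config.n_random > 0:
            ensembles["rand"] = se.build_ensemble(
                W, None, config.n_random, "random", seed_base + config.n_geometric,
                config.strength_tol, config.max_iter)
        gsec["surrogate_diagnostics"] = {
            label: {
                "n": ens.n,
                "all_converged": ens.all_converged(),
                "max_strength_error": float(max(ens.strength_error)),
                "seeds": [ens.seeds[0], ens.seeds[-1]],
            } for label, ens in ensembles.items()
        }

        # weight-distance structure
        model = se.fit_trend(W, F)
        gsec["trend"] = {
            "cubic_coeffs": model.cubic_coeffs.tolist(),
            "spread_coeffs": model.spread_coeffs.tolist(),
            "n_edges_fit": model.n_edges_fit,
            "excluded_zero_edges": model.excluded_zero_edges,
        }
        Z = gstats.zscore_log_weights(W)
        profile = gstats.binned_weight_profile(Z, F, config.bin_width_mm)
        gsec["profile"] = {
            "bin_edges": profile.bin_edges.tolist(),
            "bin_means": profile.bin_means.tolist(),
            "bin_sds": profile.bin_sds.tolist(),
            "bin_counts": profile.bin_counts.tolist(),
        }
        if name == ref_name:
            ref_profile = profile
        elif (config.profile_replicates >= 2 and src_by_name[name].synthetic
              and ref_profile is not None):
            # replicate noise realizations of this graph's generative spec,
            # tested bin-by-bin against the reference profile
            rep_profiles = []
            for k in range(config.profile_replicates):
                kw = dict(src_by_name[name].synthetic)
                kw["seed"] = int(kw.get("seed", 0)) + master + 9001 + k
                g_rep, _ = syn.make_benchmark(syn.SyntheticSpec(**kw))
                rep_profiles.append(gstats.binned_weight_profile(
                    gstats.zscore_log_weights(g_rep.weights),
                    g_rep.fiber_distances, config.bin_width_mm))
            flags = gstats.compare_profiles(rep_profiles, ref_profile,
                                            alpha=config.alpha)
            gsec["profile"]["significant_bins_vs_reference"] = flags.tolist()

        # weight agreement with the reference graph
        if name != ref_name and g.n_nodes == ref_graph.n_nodes:
            iu, ju = np.triu_indices(g.n_nodes, k=1)
            gsec["weight_comparison"] = {
                "spearman_overall": gstats.spearman_rho(
                    W[iu, ju], ref_graph.weights[iu, ju]),
                "by_division": {
                    "|".join(k): v for k, v in gstats.division_spearman(
                        W, ref_graph.weights, g.division, g.hemisphere).items()
                },
            }

        # modules
        if truth is not None and truth.true_partition is not None:
            ref_partition_for_graph = tm.ModulePartition(
                truth.true_partition, int(truth.true_partition.max()) + 1)
        elif name != ref_name and ref_partition is not None \
                and g.n_nodes == ref_graph.n_nodes:
            ref_partition_for_graph = ref_partition
        else:
            ref_partition_for_graph = None
        mod_sec, emp_part = _module_analysis(
            W, config, seed_base + 31, ensembles, ref_partition_for_graph)
        gsec["modules"] = mod_sec
        if name == ref_name:
            ref_partition = emp_part

        # hubs & geometry
        gsec["hubs"] = _hub_analysis(g, W, config, ensembles)
        if truth is not None and truth.true_hub_set is not None:
            hubs = gstats.identify_hubs(tm.node_strengths(W), config.hub_fraction)
            planted = set(int(i) for i in truth.true_hub_set)
            gsec["planted_hub_recovery"] = (
                len(planted & set(int(i) for i in hubs.indices)) / len(planted))

        # efficiency
        if config.densities:
            gsec["efficiency"] = efficiency_sweep(
                W, config.densities, ensembles, include_local=True)
            # supplementary binary topology at mid density
            mid = gm.threshold_to_density(W, 0.3)
            cc, pl = tm.clustering_and_path_length(mid)
            gsec["binary_topology_density_0.3"] = {
                "clustering_coefficient": cc, "mean_path_length": pl}

        report["graphs"][name] = gsec

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Serialize a report deterministically (sorted keys, plain types)."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=1)
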