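"""End-to-end recipes: conformer analysis and trajectory analysis.

Two orchestrations over the library modules, driven by a single validated
configuration: the crystal-ensemble recipe (read → equivalences → filter →
invariant core → superpose → PCA → projections → contributions → clustering
→ RMSF/B-factor) and the trajectory recipe (core fit → projection onto the
ensemble PCs → DCCM → network/communities/betweenness → contact events and
segmentation → per-segment DCCM/network → geometric traces).  Every number
in the summary JSON is recomputable by calling the constituent operations
directly; runs with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .contact_events import (event_activity, hysteretic_contacts,
                             pair_distance_series, segment_by_activity)
from .core_fit import find_invariant_core, fit_ensemble, rmsd
from .dccm_network import (betweenness_and_critical_nodes, build_network,
                           contact_adjacency, dccm, detect_communities)
from .ensemble_io import (build_equivalences, ensemble_from_chains,
                          filter_structures, read_structure, read_trajectory,
                          write_exclusion_report)
from .geometry_metrics import docking_state, protrusion
from .pca_conformers import (bfactor_correlation, cluster_conformers,
                             covariance, pca, project,
                             residue_contributions, rmsf)

__all__ = ["AnalysisConfig", "run_conformer_analysis",
           "run_trajectory_analysis"]


@dataclass
class AnalysisConfig:
    """Validated parameters for both recipes.

    All thresholds carry the defaults of the kinesin recipe: 4.5 Å/75%
    contact criterion, 6.5/7.5 Å dual event cutoffs, K = 3 clusters over
    the first five PCs, 8 Å docking cutoff.  The median-filter half-width
    is in frames (14 ns at 20 ps sampling is 700 frames).
    """

    structures: list[str] = field(default_factory=list)
    trajectory: str | None = None
    topology: str | None = None
    outdir: str = "ensdyn_run"
    seed: int = 0
    required_regions: dict[str, list[int]] = field(default_factory=dict)
    core_stop_volume: float = 0.5
    n_pcs: int = 5
    n_clusters: int = 3
    contact_cutoff: float = 4.5
    contact_occupancy: float = 0.75
    event_on: float = 6.5
    event_off: float = 7.5
    half_width: int = 700
    kernel_sigma: float | None = None
    prominence: float = 0.3
    docking_cutoff: float = 8.0
    stride: int = 1
    dt: float | None = None

    def __post_init__(self) -> None:
        checks = [
            (self.contact_cutoff > 0, "contact cutoff must be positive"),
            (0 < self.contact_occupancy <= 1,
             "contact occupancy must lie in (0, 1]"),
            (self.event_on < self.event_off,
             "event on-cutoff must be below off-cutoff"),
            (self.n_pcs >= 1, "need at least one PC"),
            (self.n_clusters >= 1, "need at least one cluster"),
            (self.half_width >= 1, "half-width must be at least 1 frame"),
            (self.docking_cutoff > 0, "docking cutoff must be positive"),
            (self.core_stop_volume > 0, "core stop volume must be positive"),
            (self.stride >= 1, "stride must be at least 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config; an ``include`` list of files is merged first."""
        data = _load_with_includes(Path(path))
        return cls(**data)


def _load_with_includes(path: Path) -> dict:
    raw = yaml.safe_load(path.read_text()) or {}
    merged: dict = {}
    for inc in raw.pop("include", []):
        inc_path = Path(inc)
        if not inc_path.is_absolute():
            inc_path = path.parent / inc_path
        merged.update(_load_with_includes(inc_path))
    merged.update(raw)
    return merged


def _manifest(config: AnalysisConfig, inputs: list[str]) -> dict:
    from . import __version__
    hashes = {}
    for p in inputs:
        pp = Path(p)
        if pp.exists():
            hashes[p] = hashlib.sha256(pp.read_bytes()).hexdigest()
    return {"version": __version__, "config": asdict(config),
            "input_hashes": hashes}


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Conformer recipe
# ---------------------------------------------------------------------------

def run_conformer_analysis(config: AnalysisConfig, chains=None) -> dict:
    """Crystal-ensemble conformer analysis.

    ``chains`` may be passed directly (e.g. synthetic ChainRecords);
    otherwise every path in ``config.structures`` is read.  Returns the
    intermediate objects plus a machine-readable summary, all artifacts
    written under ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        if chains is None:
            chains = []
            for p in config.structures:
                chains.extend(read_structure(p))
        if len(chains) < 2:
            raise ValueError("need at least 2 structures")

        stage = "equivalences"
        eqmap = build_equivalences(chains)

        stage = "filter"
        report: list[dict] = []
        if config.required_regions:
            chains, report = filter_structures(
                chains, eqmap, config.required_regions)
        write_exclusion_report(report, out / "exclusions.tsv")

        stage = "ensemble"
        ens = ensemble_from_chains(chains, eqmap)

        stage = "core"
        if ens.n_frames >= 3:
            core = find_invariant_core(ens, config.core_stop_volume)
            core_cols = core.columns
        else:
            core, core_cols = None, np.arange(ens.n_positions)
        if core is not None:
            core.to_tsv(out / "core.tsv", ens.residue_numbers)

        stage = "superpose"
        sup = fit_ensemble(ens, core_cols)

        stage = "pca"
        model = pca(covariance(sup))
        n_pcs = min(config.n_pcs, model.eigenvectors.shape[1])
        proj = project(sup, model, n_pcs)
        proj.to_tsv(out / "projections.tsv")
        contrib = residue_contributions(model, 0)

        stage = "cluster"
        K = min(config.n_clusters, ens.n_frames)
        clusters = cluster_conformers(proj, K, n_pcs)
        (out / "clusters.tsv").write_text("\n".join(
            f"{lab}\t{c}" for lab, c in zip(proj.labels, clusters.labels)
        ) + "\n")

        stage = "fluctuations"
        prof = rmsf(sup)
        r2 = (bfactor_correlation(prof, ens.bfactors)
              if ens.bfactors is not None and np.ptp(prof) > 0 else None)
    except Exception as exc:
        raise RuntimeError(f"conformer analysis failed at stage "
                           f"'{stage}': {exc}") from exc

    cum = model.cumulative
    summary = {
        "n_input_chains": len(chains) + len(report),
        "n_retained": ens.n_frames,
        "n_excluded": len(report),
        "core_size": int(len(core_cols)),
        "cumulative_variance": {
            "2": float(cum[1]) if len(cum) > 1 else 1.0,
            "3": float(cum[2]) if len(cum) > 2 else 1.0,
            "5": float(cum[4]) if len(cum) > 4 else 1.0,
        },
        "cluster_sizes": np.bincount(clusters.labels)[1:].tolist(),
        "bfactor_r2": r2,
    }
    _write_json(summary, out / "summary.json")
    _write_json(_manifest(config, config.structures), out / "manifest.json")
    return {"ensemble": ens, "superposed": sup, "core": core,
            "model": model, "projections": proj, "clusters": clusters,
            "contributions": contrib, "rmsf": prof, "summary": summary,
            "exclusions": report}


# ---------------------------------------------------------------------------
# Trajectory recipe
# ---------------------------------------------------------------------------

def run_trajectory_analysis(config: AnalysisConfig, ensemble=None,
                            model=None, core_columns=None) -> dict:
    """Trajectory analysis against an ensemble PCA model.

    With ``model=None`` and structures configured, the conformer recipe is
    run first to supply the crystallographic PCs and invariant core; with
    neither, the trajectory's own PCA is used.  Snapshots are superposed
    on the core, projected onto the leading PCs, and analysed for
    correlations, network communities, contact events and geometry.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        if ensemble is None:
            ensemble = read_trajectory(config.topology, config.trajectory,
                                       stride=config.stride, dt=config.dt)
        if model is None and config.structures:
            conf = run_conformer_analysis(AnalysisConfig(
                structures=config.structures,
                outdir=str(out / "conformers"),
                required_regions=config.required_regions,
                core_stop_volume=config.core_stop_volume,
                n_pcs=config.n_pcs, n_clusters=config.n_clusters))
            model = conf["model"]
            if core_columns is None and conf["core"] is not None:
                core_columns = conf["core"].columns

        stage = "superpose"
        fit_cols = (core_columns if core_columns is not None
                    else np.arange(ensemble.n_positions))
        sup = fit_ensemble(ensemble, fit_cols)

        stage = "pca-projection"
        if model is None:
            model = pca(covariance(sup))
        n_pcs = min(config.n_pcs, model.eigenvectors.shape[1])
        proj = project(sup, model, n_pcs)
        proj.to_tsv(out / "projections.tsv")

        stage = "fluctuations"
        rmsd_trace = np.array([rmsd(sup.frames[f], sup.frames[0])
                               for f in range(sup.n_frames)])
        prof = rmsf(sup)

        stage = "dccm"
        C = dccm(sup)
        C.to_tsv(out / "dccm.tsv")

        stage = "network"
        adj = contact_adjacency(sup, config.contact_cutoff,
                                config.contact_occupancy)
        net = build_network(C, adj)
        partition = detect_communities(net)
        bc, critical = betweenness_and_critical_nodes(net, partition)
        net.to_edge_tsv(out / "network_edges.tsv")

        stage = "events"
        dists, pairs = pair_distance_series(sup)
        states = hysteretic_contacts(dists, pairs, config.event_on,
                                     config.event_off, dt=sup.dt)
        half_width = min(config.half_width, max(sup.n_frames // 4, 1))
        events = event_activity(states, half_width, config.kernel_sigma)
        segments = segment_by_activity(events, config.prominence)
        events.to_tsv(out / "activity.tsv")

        stage = "segments"
        seg_dccms = []
        for a, b in segments:
            if b - a >= 1:
                seg_frames = sup.frames[a:b + 1]
                seg_dccms.append(dccm(seg_frames, segment=f"{a}-{b}"))

        stage = "geometry"
        regions = getattr(ensemble, "regions", {}) or {}
        geometry: dict = {}
        if {"alpha4", "beta3"} <= regions.keys():
            tr = protrusion(sup, regions["alpha4"], regions["beta3"])
            geometry["protrusion_distance_mean"] = float(tr.distance.mean())
            geometry["protrusion_angle_mean"] = float(tr.angle.mean())
        if {"neck", "alpha4", "loop13"} <= regions.keys():
            pairs_dock = [
                (int(regions["neck"][2]), int(regions["alpha4"][3]), "CB"),
                (int(regions["neck"][2]), int(regions["alpha4"][6]), "CB"),
                (int(regions["neck"][2]), int(regions["loop13"][1]), "CB"),
            ]
            dock = docking_state(sup, pairs_dock, config.docking_cutoff)
            geometry["docked_fraction"] = float(dock.docked.mean())
            geometry["first_undocked"] = dock.first_undocked
    except Exception as exc:
        raise RuntimeError(f"trajectory analysis failed at stage "
                           f"'{stage}': {exc}") from exc

    summary = {
        "n_frames": sup.n_frames,
        "n_positions": sup.n_positions,
        "rmsd_final": float(rmsd_trace[-1]),
        "rmsf_mean": float(prof.mean()),
        "n_communities": len(partition),
        "community_sizes": sorted(len(c) for c in partition),
        "critical_nodes": [int(n) for n in critical],
        "n_events": int(events.total.sum()),
        "segments": [[int(a), int(b)] for a, b in segments],
        "geometry": geometry,
    }
    _write_json(summary, out / "summary.json")
    _write_json(_manifest(config, [p for p in
                                   [config.trajectory, config.topology,
                                    *config.structures] if p]),
                out / "manifest.json")
    return {"superposed": sup, "model": model, "projections": proj,
            "rmsd_trace": rmsd_trace, "rmsf": prof, "dccm": C,
            "network": net, "partition": partition, "betweenness": bc,
            "critical_nodes": critical, "events": events,
            "segments": segments, "segment_dccms": seg_dccms,
            "summary": summary}
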