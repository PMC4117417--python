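"""End-to-end orchestration of the analysis stages.

``run_analysis`` drives the stages in dependency order for each labeled
model (I/O -> geometry -> convergence clustering / structure annotation ->
essential dynamics -> local feature analysis and the communication
network), then the cross-model segment clustering.  Replica handling
mirrors common practice: deviation/fluctuation profiles are computed per
trajectory, while the mode analysis runs on the concatenated productive
portions; both behaviors are configurable.

All randomness flows from ``AnalysisConfig.seed``; rerunning an identical
configuration reproduces the bundle exactly (tables hash-equal).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import annotation, clustering, geometry, modes, network
from .topology import (Selection, Topology, Trajectory, load_topology,
                       load_trajectory, parse_selection_string,
                       BACKBONE_ATOMS, CN_BACKBONE_ATOMS)

log = logging.getLogger("allodyn.pipeline")


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``inputs`` maps a model label to either a Trajectory or a list of
    multi-model PDB paths.  ``segments`` maps segment names to selection
    strings (``"560-570:CA"``).  ``trim`` optionally keeps a frame range
    (productive portion) per label.
    """

    inputs: dict = field(default_factory=dict)
    time_step_ps: float = 1.0
    segments: dict = field(default_factory=dict)
    trim: dict = field(default_factory=dict)          # label -> (start, stop)
    exclude_segment: str | None = None                # e.g. engineered linker
    # clustering / convergence
    cluster_cutoff_r: float = 2.5
    cluster_repeats: int = 5
    cross_model_segment: str | None = None
    cross_model_cutoff_d: float = 2.5
    # annotation
    hbond_dist_cut: float = 3.5
    hbond_angle_cut: float = 120.0
    hbond_stride: int = 100
    ss_stride: int = 1
    monitor_stride: int = 10
    # essential dynamics / LFA
    mode_fraction: float = 0.8
    # communication network
    ct_cut: float | str = "calibrate"
    ct_target_fraction: float = 0.20
    contact_cut: float = 3.9
    persistence: float = 0.5
    d_cut: float = 3.6
    hub_threshold: float = 0.10
    network_stride: int = 1
    with_neighbors: bool = False
    # reproducibility
    seed: int = 0

    def validate(self):
        errors = []
        if not self.inputs:
            errors.append("no input trajectories configured")
        if self.cluster_cutoff_r <= 0:
            errors.append("cluster_cutoff_r must be positive")
        if self.cluster_repeats < 1:
            errors.append("cluster_repeats must be >= 1")
        if not 0 < self.mode_fraction <= 1:
            errors.append("mode_fraction must be in (0, 1]")
        if not 0 < self.persistence <= 1:
            errors.append("persistence must be in (0, 1]")
        if not 0 < self.hub_threshold < 1:
            errors.append("hub_threshold must be in (0, 1)")
        if self.cross_model_segment is not None and \
                self.cross_model_segment not in self.segments:
            errors.append(
                f"cross_model_segment {self.cross_model_segment!r} "
                "not among segments")
        for stride_name in ("hbond_stride", "ss_stride", "monitor_stride",
                            "network_stride"):
            if getattr(self, stride_name) < 1:
                errors.append(f"{stride_name} must be >= 1")
        if errors:
            raise ValueError("invalid configuration:\n  " +
                             "\n  ".join(errors))

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "inputs"}
        payload["inputs"] = sorted(str(k) for k in self.inputs)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ModelReport:
    label: str
    rmsd: pd.DataFrame | None = None
    rmsf: pd.DataFrame | None = None
    monitors: pd.DataFrame | None = None
    cluster_report: clustering.ClusterReport | None = None
    convergence_c: float | None = None
    ss_profile: pd.DataFrame | None = None
    hbond_occupancy: pd.DataFrame | None = None
    eigen_spectrum: pd.DataFrame | None = None
    n_modes_80: int | None = None
    ids: list | None = None
    comm_graph: network.CommGraph | None = None
    pathway_annotation: pd.DataFrame | None = None
    hubs: list | None = None
    hub_table: pd.DataFrame | None = None


@dataclass
class ReportBundle:
    config_hash: str
    seed: int
    models: dict = field(default_factory=dict)
    cross_model: pd.DataFrame | None = None


def _load_input(value, time_step_ps) -> Trajectory:
    if isinstance(value, Trajectory):
        return value
    paths = list(value)
    top = load_topology(paths[0])
    return load_trajectory(paths, top, time_step_ps=time_step_ps)


def _resolve(topology: Topology, spec: str) -> Selection:
    return parse_selection_string(topology, spec)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Required stages (loading, geometry, clustering, modes, network) abort
    on failure; optional stages (H-bonds and secondary structure, which
    need hydrogens or complete backbones) log and are marked absent.
    """
    config.validate()
    bundle = ReportBundle(config_hash=config.hash(), seed=config.seed)
    trajs = {}
    for label, value in config.inputs.items():
        traj = _load_input(value, config.time_step_ps)
        if label in config.trim:
            start, stop = config.trim[label]
            traj = Trajectory(traj.topology, traj.coords[start:stop],
                              traj.time_step_ps)
        trajs[label] = traj

    for label, traj in trajs.items():
        log.info("analyzing model %s (%d frames)", label, traj.n_frames)
        top = traj.topology
        report = ModelReport(label=label)
        backbone = _select_names(top, BACKBONE_ATOMS)
        cn_backbone = _select_names(top, CN_BACKBONE_ATOMS)
        ca = _select_names(top, {"CA"})

        series = geometry.rmsd_series(traj, backbone)
        report.rmsd = series.to_frame()
        residues, values = geometry.rmsf(traj, cn_backbone)
        report.rmsf = pd.DataFrame({"residue": residues, "rmsf": values})

        monitor_rows = []
        for name, spec in config.segments.items():
            try:
                seg = _resolve(top, spec)
            except Exception as exc:
                log.warning("segment %s unresolvable: %s", name, exc)
                continue
            s = geometry.rmsd_series(traj, seg)
            df = s.to_frame()
            df["name"] = f"rmsd_{name}"
            monitor_rows.append(df)
        if monitor_rows:
            report.monitors = pd.concat(monitor_rows, ignore_index=True)

        c, reports = clustering.run_convergence_analysis(
            traj, ca, config.cluster_cutoff_r,
            n_repeats=config.cluster_repeats, seed=config.seed)
        report.convergence_c = c
        report.cluster_report = clustering.best_reference_set(reports)

        try:
            report.ss_profile = annotation.ss_occupancy_profile(
                traj, stride=config.ss_stride)
        except Exception as exc:
            log.warning("model %s: secondary structure skipped (%s)",
                        label, exc)
        try:
            occ = annotation.hbond_occupancy(
                traj, stride=config.hbond_stride,
                dist_cut=config.hbond_dist_cut,
                angle_cut=config.hbond_angle_cut)
            if len(occ):
                report.hbond_occupancy = occ
        except Exception as exc:
            log.warning("model %s: H-bond occupancy skipped (%s)", label, exc)

        modeset = modes.compute_pca(traj, ca)
        report.eigen_spectrum = modes.eigen_spectrum_frame(modeset)
        n80 = modes.modes_for_fraction(modeset, config.mode_fraction)
        report.n_modes_80 = n80
        lfa = network.lfa_transform(modeset, max(n80, 1),
                                    residue_numbers=top.residues)
        network.calibrate_pcut(lfa)
        report.ids = network.build_ids(lfa)

        graph = network.build_comm_graph(
            traj, ca, ct_cut=config.ct_cut,
            target_fraction=config.ct_target_fraction,
            contact_cut=config.contact_cut, persistence=config.persistence,
            d_cut=config.d_cut, stride=config.network_stride,
            with_neighbors=config.with_neighbors)
        graph.hub_threshold = config.hub_threshold
        report.comm_graph = graph
        report.pathway_annotation = network.classify_pathways(
            graph, modeset.mean_structure)
        report.hubs, report.hub_table = network.find_hubs(graph)
        bundle.models[label] = report

    if config.cross_model_segment is not None and len(trajs) >= 2:
        spec = config.segments[config.cross_model_segment]
        bundle.cross_model = clustering.cross_model_cluster(
            list(trajs.items()),
            lambda top: _resolve(top, spec),
            d=config.cross_model_cutoff_d,
            repeats=config.cluster_repeats, seed=config.seed)
    return bundle


def _select_names(top: Topology, names) -> Selection:
    from .topology import select
    first, last = int(top.residues[0]), int(top.residues[-1])
    return select(top, [(first, last)], names)
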