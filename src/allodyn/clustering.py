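"""Ensemble-based reference clustering and the convergence criterion.

The clustering scheme extracts representative conformations from a
trajectory: (i) a reference frame is drawn uniformly at random from the
remaining ensemble and every conformation with best-fit RMSD < r to it is
removed; this repeats until the ensemble is exhausted, yielding references
that are pairwise at least r apart; (ii) all frames are then assigned to
their nearest reference by RMSD; (iii) each reference cluster's membership
is split by trajectory half.

A reference is *lone* when only one half of the trajectory populates its
cluster.  The convergence criterion over N repeats of the procedure is

    c = 1 - mean_runs(N_lone / N_total),   0 <= c <= 1,

so that c = 1 corresponds to optimal convergence (every reference visited in
both halves) and c = 0 to disjoint halves.  Because the references are
random, the procedure is repeated (5 times by default) and the repeat whose
clusters are most evenly populated across halves may be retained for
downstream structural analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import batch_rmsd
from .topology import Selection, Trajectory


@dataclass(frozen=True)
class ReferenceSet:
    cutoff: float
    reference_frames: tuple
    seed: int


@dataclass
class Cluster:
    reference_frame: int
    members: np.ndarray
    first_half_count: int
    second_half_count: int

    @property
    def lone(self) -> bool:
        return self.first_half_count == 0 or self.second_half_count == 0


@dataclass
class ClusterReport:
    refset: ReferenceSet
    clusters: list
    n_frames: int

    @property
    def n_lone(self) -> int:
        return sum(c.lone for c in self.clusters)

    @property
    def n_total(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reference_frame": [c.reference_frame for c in self.clusters],
            "size": [len(c.members) for c in self.clusters],
            "first_half": [c.first_half_count for c in self.clusters],
            "second_half": [c.second_half_count for c in self.clusters],
            "lone": [c.lone for c in self.clusters],
        })


def pick_references(traj: Trajectory, sel: Selection, r: float,
                    seed: int = 0) -> ReferenceSet:
    """Randomly draw reference frames until every frame lies within r of one.

    Frames with RMSD strictly below ``r`` of a drawn reference are popped;
    boundary frames (RMSD == r) remain candidates, so references end up
    pairwise at least ``r`` apart.
    """
    if r <= 0:
        raise ValueError("cutoff r must be positive")
    rng = np.random.default_rng(seed)
    idx = sel.array
    frames = traj.coords[:, idx, :]
    remaining = np.arange(traj.n_frames)
    refs = []
    while len(remaining) > 0:
        pick = remaining[rng.integers(len(remaining))]
        refs.append(int(pick))
        d = batch_rmsd(frames[remaining], frames[pick])
        # the reference itself is always popped, so termination is
        # guaranteed even for r below numerical RMSD noise
        remaining = remaining[(d >= r) & (remaining != pick)]
    return ReferenceSet(cutoff=float(r), reference_frames=tuple(refs),
                        seed=int(seed))


def assign_clusters(traj: Trajectory, sel: Selection,
                    refset: ReferenceSet,
                    half_boundary: int | None = None) -> ClusterReport:
    """Assign every frame to its nearest reference (best-fit RMSD).

    Ties go to the lowest reference index.  Half membership is decided by
    frame position relative to ``half_boundary`` (default: n_frames // 2).
    """
    idx = sel.array
    frames = traj.coords[:, idx, :]
    refs = refset.reference_frames
    if len(refs) == 0:
        raise ValueError("reference set is empty")
    dists = np.stack([batch_rmsd(frames, frames[r]) for r in refs])
    nearest = np.argmin(dists, axis=0)  # first (lowest) index wins ties
    boundary = traj.n_frames // 2 if half_boundary is None else half_boundary
    clusters = []
    for k, ref in enumerate(refs):
        members = np.nonzero(nearest == k)[0]
        first = int((members < boundary).sum())
        clusters.append(Cluster(reference_frame=ref, members=members,
                                first_half_count=first,
                                second_half_count=len(members) - first))
    return ClusterReport(refset=refset, clusters=clusters,
                         n_frames=traj.n_frames)


def convergence_criterion(reports) -> float:
    """c = 1 - mean over repeats of (lone references / total references)."""
    reports = list(reports)
    if len(reports) == 0:
        raise ValueError("need at least one clustering report")
    ratios = []
    for rep in reports:
        if rep.n_total == 0:
            raise ValueError("report with zero clusters")
        ratios.append(rep.n_lone / rep.n_total)
    return float(1.0 - np.mean(ratios))


def _imbalance(report: ClusterReport) -> float:
    """Summed per-cluster absolute half-count imbalance, normalized."""
    total = 0.0
    for c in report.clusters:
        size = len(c.members)
        if size == 0:
            continue
        total += abs(c.first_half_count - c.second_half_count) / size
    return total


def best_reference_set(reports) -> ClusterReport:
    """The repeat whose clusters are most evenly populated across halves.

    Deterministic tie-break: first repeat in input order wins.
    """
    reports = list(reports)
    if len(reports) == 0:
        raise ValueError("need at least one clustering report")
    scores = [_imbalance(r) for r in reports]
    return reports[int(np.argmin(scores))]


def run_convergence_analysis(traj: Trajectory, sel: Selection, r: float,
                             n_repeats: int = 5, seed: int = 0):
    """Full repeated clustering: returns ``(c, reports)``.

    Repeat ``k`` uses RNG seed ``seed + k`` so repeats are independent but
    the whole analysis is reproducible.
    """
    reports = []
    for k in range(n_repeats):
        refset = pick_references(traj, sel, r, seed=seed + k)
        reports.append(assign_clusters(traj, sel, refset))
    return convergence_criterion(reports), reports


def cross_model_cluster(trajs, sel_builder, d: float, repeats: int = 5,
                        seed: int = 0) -> pd.DataFrame:
    """Cluster concatenated conformations from several labeled models.

    Parameters
    ----------
    trajs
        Iterable of ``(label, Trajectory)``.  Topologies must resolve the
        same selection (same atom count).
    sel_builder
        Either a Selection valid for all trajectories or a callable
        ``topology -> Selection``.
    d
        RMSD cutoff for reference picking (e.g. 2.5 Å for an activation
        loop, 4 Å for a more mobile switch segment).

    Returns a tidy table: one row per (repeat, cluster) with per-model
    member counts.
    """
    trajs = list(trajs)
    if len(trajs) == 0:
        raise ValueError("no trajectories given")
    segments = []
    labels = []
    n_sel = None
    for label, traj in trajs:
        sel = sel_builder if isinstance(sel_builder, Selection) \
            else sel_builder(traj.topology)
        coords = traj.coords[:, sel.array, :]
        if n_sel is None:
            n_sel = coords.shape[1]
        elif coords.shape[1] != n_sel:
            raise ValueError(f"selection size mismatch for model {label!r}")
        segments.append(coords)
        labels.extend([label] * coords.shape[0])
    all_coords = np.concatenate(segments, axis=0)
    labels = np.array(labels)
    rows = []
    model_names = [lbl for lbl, _ in trajs]
    for k in range(repeats):
        rng = np.random.default_rng(seed + k)
        remaining = np.arange(len(all_coords))
        refs = []
        while len(remaining) > 0:
            pick = remaining[rng.integers(len(remaining))]
            refs.append(int(pick))
            dist = batch_rmsd(all_coords[remaining], all_coords[pick])
            remaining = remaining[(dist >= d) & (remaining != pick)]
        dists = np.stack([batch_rmsd(all_coords, all_coords[r])
                          for r in refs])
        nearest = np.argmin(dists, axis=0)
        for ci, ref in enumerate(refs):
            members = labels[nearest == ci]
            row = {"repeat": k, "cluster": ci, "reference_frame": ref}
            for m in model_names:
                row[m] = int((members == m).sum())
            rows.append(row)
    return pd.DataFrame(rows)
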