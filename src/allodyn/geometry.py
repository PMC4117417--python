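"""Superposition and scalar monitors.

Least-squares rigid-body superposition (Kabsch), RMSD time series against the
initial structure, per-residue RMSF about the iteratively fitted ensemble
average, center-of-mass distances and angles between named segments, the
mean-smallest-distance residue matrix used as the neighbor criterion of the
communication analysis, and generic inter-atomic distance monitors.

Default monitor strides follow the source trajectories' recording
conventions (frames stored every 1 ps; distances/angles sampled every 10
frames, H-bonds every 100, secondary structure every frame); all strides are
arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .topology import Selection, Topology, Trajectory


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class MonitorSeries:
    """A named per-frame scalar monitor (Å or degrees)."""

    name: str
    stride: int
    values: np.ndarray
    time_step_ps: float = 1.0

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.stride * self.time_step_ps

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"frame_time_ps": self.times_ps,
                             "name": self.name, "value": self.values})


# ---------------------------------------------------------------------------
# superposition

def _check_pair(mobile, reference):
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("expected (n_atoms, 3) coordinate arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a unique superposition")
    return mobile, reference


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``mobile @ rotation.T + translation`` best fits the reference in the
    least-squares sense and the rotation is proper (det = +1).
    """
    mobile, reference = _check_pair(mobile, reference)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(diag) @ u.T
    translation = rc - rot @ mc
    ssd = (x * x).sum() + (y * y).sum() - 2.0 * (s * diag).sum()
    rmsd = float(np.sqrt(max(ssd, 0.0) / mobile.shape[0]))
    return rot, translation, rmsd


def batch_rmsd(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Best-fit RMSD of every frame ``(F, A, 3)`` against one reference."""
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    x = frames - frames.mean(axis=1, keepdims=True)
    y = reference - reference.mean(axis=0)
    h = np.einsum("fai,aj->fij", x, y)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", vt.transpose(0, 2, 1),
                                  u.transpose(0, 2, 1)))
    s_corr = s.copy()
    s_corr[:, -1] *= np.sign(det)
    ssd = (x * x).sum(axis=(1, 2)) + (y * y).sum() - 2.0 * s_corr.sum(axis=1)
    return np.sqrt(np.clip(ssd, 0.0, None) / frames.shape[1])


def superposed_coords(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Each frame rigid-body fitted onto the reference (same selection)."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for i, fr in enumerate(frames):
        rot, trans, _ = superpose(fr, reference)
        out[i] = fr @ rot.T + trans
    return out


def iterative_mean_structure(frames: np.ndarray, tol: float = 1e-4,
                             max_iter: int = 10) -> np.ndarray:
    """Self-consistent ensemble average: fit -> average -> refit.

    Iterates until the average structure moves by less than ``tol`` Å RMSD
    or ``max_iter`` rounds.
    """
    mean = np.asarray(frames[0], dtype=float)
    for _ in range(max_iter):
        fitted = superposed_coords(frames, mean)
        new_mean = fitted.mean(axis=0)
        _, _, shift = superpose(new_mean, mean)
        mean = new_mean
        if shift < tol:
            break
    return mean


# ---------------------------------------------------------------------------
# RMSD / RMSF

def rmsd_series(traj: Trajectory, sel: Selection, reference=None,
                stride: int = 1) -> MonitorSeries:
    """Per-frame best-fit RMSD on a selection, against the initial frame
    (or an explicit reference frame's coordinates)."""
    idx = sel.array
    frames = traj.coords[::stride, idx, :]
    if reference is None:
        ref = traj.coords[0, idx, :]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == traj.topology.n_atoms:
            ref = ref[idx, :]
    if ref.shape != frames.shape[1:]:
        raise ValueError("reference incompatible with selection")
    if frames.shape[1] < 3:
        raise ValueError("need at least 3 atoms")
    vals = batch_rmsd(frames, ref)
    return MonitorSeries("rmsd", stride, vals, traj.time_step_ps)


def rmsf(traj: Trajectory, sel: Selection):
    """Per-residue RMSF (Å) on a selection.

    Frames are first superposed onto the iteratively converged average
    structure of the selection; the per-atom fluctuation
    sqrt(<|x - <x>|^2>) is then averaged over each residue's selected atoms.

    Returns ``(residue_numbers, values)``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for a single frame")
    idx = sel.array
    frames = traj.coords[:, idx, :]
    mean = iterative_mean_structure(frames)
    fitted = superposed_coords(frames, mean)
    avg = fitted.mean(axis=0)
    fluct = np.sqrt(((fitted - avg) ** 2).sum(axis=2).mean(axis=0))
    res = traj.topology.residue_numbers[idx]
    residues = res[np.concatenate(([True], res[1:] != res[:-1]))]
    values = np.array([fluct[res == r].mean() for r in residues])
    return residues, values


# ---------------------------------------------------------------------------
# centers of mass

def com(frame: np.ndarray, topology: Topology, sel: Selection,
        mass_weighted: bool = True) -> np.ndarray:
    """(Mass-weighted) center of a selection in one frame."""
    idx = sel.array
    pts = np.asarray(frame, dtype=float)[idx]
    if mass_weighted:
        w = topology.masses[idx]
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    return pts.mean(axis=0)


def com_distance(frame, topology, sel_a: Selection, sel_b: Selection,
                 mass_weighted: bool = True) -> float:
    a = com(frame, topology, sel_a, mass_weighted)
    b = com(frame, topology, sel_b, mass_weighted)
    return float(np.linalg.norm(a - b))


def com_angle(frame, topology, sel_a: Selection, sel_b: Selection,
              sel_c: Selection, mass_weighted: bool = True) -> float:
    """Angle (degrees) at the CoM of ``sel_b`` formed with ``sel_a``/``sel_c``."""
    a = com(frame, topology, sel_a, mass_weighted)
    b = com(frame, topology, sel_b, mass_weighted)
    c = com(frame, topology, sel_c, mass_weighted)
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError("coincident centers of mass in angle")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def com_series(traj: Trajectory, sels, kind: str, name: str,
               stride: int = 10, mass_weighted: bool = True) -> MonitorSeries:
    """Monitor a CoM distance (2 selections) or angle (3 selections)."""
    vals = []
    for frame in traj.coords[::stride]:
        if kind == "distance":
            vals.append(com_distance(frame, traj.topology, *sels,
                                     mass_weighted=mass_weighted))
        elif kind == "angle":
            vals.append(com_angle(frame, traj.topology, *sels,
                                  mass_weighted=mass_weighted))
        else:
            raise ValueError(f"unknown monitor kind {kind!r}")
    return MonitorSeries(name, stride, np.array(vals), traj.time_step_ps)


# ---------------------------------------------------------------------------
# distance matrices and pair monitors

def mean_smallest_distance_matrix(traj: Trajectory,
                                  stride: int = 1) -> np.ndarray:
    """Residue matrix of time-averaged smallest heavy-atom distances (Å).

    Entry (i, j) is the average over frames of the minimum distance between
    any heavy atom of residue i and any heavy atom of residue j.
    """
    top = traj.topology
    heavy = top.heavy_atom_indices()
    residues = top.residues
    n_res = len(residues)
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    res_of_heavy = top.residue_numbers[heavy]
    groups = []
    for r in residues:
        g = np.nonzero(res_of_heavy == r)[0]
        if len(g) == 0:
            raise ValueError(f"residue {r} has no heavy atoms")
        groups.append(g)
    # order heavy atoms by residue blocks for a block-min reduction
    order = np.concatenate(groups)
    sizes = np.array([len(g) for g in groups])
    starts = np.concatenate(([0], np.cumsum(sizes)))
    acc = np.zeros((n_res, n_res))
    frames = traj.coords[::stride]
    for frame in frames:
        pts = frame[heavy][order]
        d = cdist(pts, pts)
        dmin = np.empty((n_res, n_res))
        # reduce blocks; residue counts are small so a python loop over
        # residues (not pairs) is acceptable
        row_min = np.minimum.reduceat(d, starts[:-1], axis=0)
        dmin = np.minimum.reduceat(row_min, starts[:-1], axis=1)
        acc += dmin
    acc /= len(frames)
    np.fill_diagonal(acc, 0.0)
    return (acc + acc.T) / 2.0


def pair_distance_series(traj: Trajectory, atom_a: int, atom_b: int,
                         stride: int = 10) -> MonitorSeries:
    """Euclidean distance between two atoms, sampled every ``stride`` frames."""
    n = traj.topology.n_atoms
    for a in (atom_a, atom_b):
        if not 0 <= a < n:
            raise IndexError(f"atom index {a} out of range")
    if atom_a == atom_b:
        import warnings
        warnings.warn("identical atoms: distance series is zero")
    d = np.linalg.norm(traj.coords[::stride, atom_a, :] -
                       traj.coords[::stride, atom_b, :], axis=1)
    return MonitorSeries("pair_distance", stride, d, traj.time_step_ps)
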