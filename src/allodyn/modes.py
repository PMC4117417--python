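"""Essential dynamics: PCA of positional fluctuations and mode metrics.

Frames are superposed onto the iteratively converged average structure of
the selection, the covariance matrix of the Cartesian deviations is
diagonalized, and the eigenvectors (modes) are ordered by decreasing
eigenvalue (Å^2).  On top of the mode set the module provides:

* the number of leading modes needed to reach a target fraction of the
  total fluctuation (e.g. the 80% rule used to truncate the mode space for
  the local feature analysis),
* per-atom contributions alpha_i of a domain D in mode m, normalized so
  that sum_i alpha_i^2 = 1 over the domain,
* the degree of collectivity k of a domain in a mode, using the
  exponential-entropy (Bruschweiler) form
      k = (1/n) * exp(-sum_i alpha_i^2 ln alpha_i^2),
  bounded by 1/n (one atom moves) and 1 (all atoms move equally); the
  weighted variant multiplies by the mode's share of the total fluctuation
  lambda_m / sum(lambda),
* a domain's percentage contribution to the global motion of a mode, and
* the norm of the resultant (vector sum) of a domain's per-atom mode
  components, optionally weighted — a measure of concerted net displacement
  that vanishes when motions cancel pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import iterative_mean_structure, superposed_coords
from .topology import Selection, Trajectory


@dataclass
class ModeSet:
    mean_structure: np.ndarray    # (A, 3) fitted average of the selection
    eigenvectors: np.ndarray      # (3A, M), columns unit norm, lambda-sorted
    eigenvalues: np.ndarray       # (M,), Å^2, descending, non-negative
    selection: Selection
    n_frames: int

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def mode_vectors(self, m: int) -> np.ndarray:
        """Per-atom 3-vectors of mode ``m`` (1-based), shape (A, 3)."""
        return self.eigenvectors[:, m - 1].reshape(-1, 3)


def compute_pca(traj: Trajectory, sel: Selection) -> ModeSet:
    """Diagonalize the coordinate covariance after best-fit superposition."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    frames = traj.coords[:, sel.array, :]
    mean = iterative_mean_structure(frames)
    fitted = superposed_coords(frames, mean)
    mean = fitted.mean(axis=0)
    dev = (fitted - mean).reshape(traj.n_frames, -1)
    cov = dev.T @ dev / traj.n_frames
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    return ModeSet(mean_structure=mean, eigenvectors=vecs,
                   eigenvalues=vals, selection=sel, n_frames=traj.n_frames)


def modes_for_fraction(modeset: ModeSet, fraction: float) -> int:
    """Smallest m whose cumulative eigenvalue share reaches ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    lam = modeset.eigenvalues
    total = lam.sum()
    if total == 0:
        return 0
    cum = np.cumsum(lam) / total
    if fraction == 1.0:
        return int((lam > 0).sum())
    return int(np.searchsorted(cum, fraction) + 1)


def _domain_positions(modeset: ModeSet, domain) -> np.ndarray:
    """Positions (within the mode selection) of the domain's atoms."""
    if domain is None:
        return np.arange(modeset.n_atoms)
    if isinstance(domain, Selection):
        sel_idx = {a: p for p, a in enumerate(modeset.selection.indices)}
        try:
            return np.array([sel_idx[a] for a in domain.indices])
        except KeyError as exc:
            raise ValueError(
                f"domain atom {exc} not in the mode selection") from exc
    return np.asarray(domain, dtype=int)


def atomic_contribution(modeset: ModeSet, m: int, domain=None) -> np.ndarray:
    """alpha_i: amplitude of atom i in mode m, unit-normalized over D.

    Returns zeros (with no error) when the domain has no amplitude at all
    in the mode; callers can detect this as sum(alpha^2) == 0.
    """
    pos = _domain_positions(modeset, domain)
    v = modeset.mode_vectors(m)[pos]
    amp = np.linalg.norm(v, axis=1)
    norm = np.sqrt((amp ** 2).sum())
    if norm == 0.0:
        return np.zeros(len(pos))
    return amp / norm


def collectivity(modeset: ModeSet, m: int, domain=None,
                 weighted: bool = False) -> float:
    """Degree of collectivity k of a domain in mode m.

    Plain form: k = (1/n) exp(-sum alpha_i^2 ln alpha_i^2) in [1/n, 1].
    Weighted form multiplies by lambda_m / sum(lambda), the contribution of
    the mode to the total fluctuations.
    """
    alpha = atomic_contribution(modeset, m, domain)
    n = len(alpha)
    a2 = alpha ** 2
    if a2.sum() == 0.0:
        raise ValueError(f"domain has zero amplitude in mode {m}")
    nz = a2[a2 > 0]
    k = float(np.exp(-(nz * np.log(nz)).sum()) / n)
    if weighted:
        total = modeset.eigenvalues.sum()
        k *= float(modeset.eigenvalues[m - 1] / total) if total > 0 else 0.0
    return k


def domain_contribution(modeset: ModeSet, m: int, domain=None) -> float:
    """Percentage of mode m's global motion carried by the domain:
    100 * sum_{i in D} |v_i|^2 / sum_all |v_i|^2."""
    pos = _domain_positions(modeset, domain)
    v = modeset.mode_vectors(m)
    total = (v ** 2).sum()
    if total == 0:
        return 0.0
    return float(100.0 * (v[pos] ** 2).sum() / total)


def resultant_norm(modeset: ModeSet, m: int, domain=None,
                   weight_by_mode_share: bool = False,
                   exclude=None) -> float:
    """Norm of the vector sum of the domain's per-atom components in mode m.

    ``weight_by_mode_share`` multiplies by lambda_m / sum(lambda).
    ``exclude`` (a Selection or position array) optionally masks residues
    (e.g. an engineered linker) from the *weighting*: the resultant is then
    additionally scaled by the contribution of the non-excluded atoms to
    the mode.
    """
    pos = _domain_positions(modeset, domain)
    v = modeset.mode_vectors(m)
    out = float(np.linalg.norm(v[pos].sum(axis=0)))
    if weight_by_mode_share:
        total = modeset.eigenvalues.sum()
        out *= float(modeset.eigenvalues[m - 1] / total) if total > 0 else 0.0
    if exclude is not None:
        ex = set(_domain_positions(modeset, exclude).tolist())
        keep = np.array([p for p in range(modeset.n_atoms) if p not in ex])
        out *= domain_contribution(modeset, m, keep) / 100.0
    return out


def eigen_spectrum_frame(modeset: ModeSet):
    """Eigen-spectrum as a tidy DataFrame (mode, eigenvalue, share)."""
    import pandas as pd
    lam = modeset.eigenvalues
    total = lam.sum() or 1.0
    return pd.DataFrame({"mode": np.arange(1, len(lam) + 1),
                         "eigenvalue": lam,
                         "cumulative_share": np.cumsum(lam) / total})
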