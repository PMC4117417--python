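"""Synthetic trajectory and geometry generators.

These generators produce ensembles with *planted* statistical structure so
that every analysis stage can be exercised and validated without real MD
output: Gaussian fluctuations around a reference backbone, blocks of locally
concerted residues (recoverable as independent dynamic segments), stiff
chains of residue pairs with tiny distance variance (recoverable as
communication pathways), two-basin ensembles with a controllable half-mixing
fraction (driving the convergence criterion between its extremes),
switchable donor-H-acceptor geometries (driving H-bond occupancy), and ideal
helix/sheet fragments (driving secondary-structure assignment).

Chemistry is poly-alanine backbone (N, CA, C, O) throughout, except the
H-bond fixtures which carry explicit amide hydrogens.  All randomness flows
through ``numpy.random.default_rng(seed)``: a fixed seed reproduces the
trajectory bit-for-bit on one platform and to floating-point stream
accuracy across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Selection, Topology, Trajectory, make_topology_from_arrays

# backbone internal coordinates (Engh-Huber-like standard values)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8

ALPHA_PHI_PSI = (-57.0, -47.0)
THREE_TEN_PHI_PSI = (-49.0, -26.0)
STRAND_PHI_PSI = (-120.0, 130.0)
# two-residue turn closing an antiparallel hairpin in H-bond register
HAIRPIN_TURN = ((55.0, 35.0), (95.0, 10.0))


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d from the three previous atoms."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_backbone_coords(phi_psi) -> np.ndarray:
    """Backbone coordinates (N, CA, C, O per residue) for given dihedrals.

    Parameters
    ----------
    phi_psi
        Sequence of ``(phi, psi)`` pairs in degrees, one per residue.
        Omega is fixed at 180 (trans).

    Returns an ``(4 * n_residues, 3)`` array in Å.
    """
    phi_psi = list(phi_psi)
    n = len(phi_psi)
    if n < 2:
        raise ValueError("need at least 2 residues")
    coords = []
    # first residue placed explicitly
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append([n0, ca0, c0, None])  # O filled later
    for i in range(1, n):
        phi_prev, psi_prev = phi_psi[i - 1]
        phi, _ = phi_psi[i]
        n_prev, ca_prev, c_prev, _ = coords[i - 1]
        ni = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi_prev)
        cai = _place_atom(ca_prev, c_prev, ni, _B_N_CA, _A_C_N_CA, 180.0)
        ci = _place_atom(c_prev, ni, cai, _B_CA_C, _A_N_CA_C, phi)
        coords.append([ni, cai, ci, None])
    # carbonyl oxygens: dihedral psi + 180 about N-CA-C
    for i in range(n):
        ni, cai, ci, _ = coords[i]
        psi = phi_psi[i][1]
        coords[i][3] = _place_atom(ni, cai, ci, _B_C_O, _A_CA_C_O, psi + 180.0)
    return np.array([a for res in coords for a in res])


def make_topology(n_residues: int, gap_range=None,
                  chain_id: str = "A") -> Topology:
    """Poly-alanine backbone topology with author numbering.

    ``gap_range=(lo, hi)`` removes residues numbered lo..hi (inclusive) from
    the numbering, emulating an engineered deletion: numbering jumps over
    the gap while the chain remains contiguous in space.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    numbers = []
    num = 1
    while len(numbers) < n_residues:
        if gap_range is not None and gap_range[0] <= num <= gap_range[1]:
            num += 1
            continue
        numbers.append(num)
        num += 1
    if gap_range is not None and gap_range[0] > numbers[-1]:
        raise ValueError("gap lies entirely outside the residue range")
    names, res_nums = [], []
    for rn in numbers:
        for nm in ("N", "CA", "C", "O"):
            names.append(nm)
            res_nums.append(rn)
    return make_topology_from_arrays(
        names, res_nums, chain_ids=[chain_id] * len(names))


def helix_mean_structure(n_residues: int, gap_range=None):
    """Topology + ideal alpha-helical mean coordinates for n residues."""
    top = make_topology(n_residues, gap_range=gap_range)
    coords = ideal_backbone_coords([ALPHA_PHI_PSI] * n_residues)
    return top, coords


@dataclass
class GaussianEnsembleSpec:
    """Specification of a correlated-Gaussian synthetic ensemble.

    Residue displacements are Gaussian around ``mean_coords``; all atoms of
    a residue move rigidly together.  ``blocks`` plant locally concerted
    groups (shared latent factor with internal correlation ``rho``);
    ``stiff_chains`` plant near-rigid groups whose pairwise distance
    variance is suppressed by a factor ``epsilon`` relative to background
    (realized as a shared factor with weight 1 - epsilon, which is the
    factor-model equivalent of sampling from a stiffened precision matrix).
    Blocks and chains must be disjoint.
    """

    topology: Topology
    mean_coords: np.ndarray
    sigma: float | np.ndarray = 0.5
    blocks: list = field(default_factory=list)       # [(residue_numbers, rho)]
    stiff_chains: list = field(default_factory=list)  # [(residue_numbers, eps)]
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        self.mean_coords = np.asarray(self.mean_coords, dtype=float)
        if self.mean_coords.shape != (self.topology.n_atoms, 3):
            raise ValueError("mean_coords shape does not match topology")
        seen = set()
        for group, coef in list(self.blocks) + list(self.stiff_chains):
            if not 0.0 <= coef <= 1.0:
                raise ValueError(f"correlation/epsilon {coef} outside [0, 1]")
            g = set(group)
            if g & seen:
                raise ValueError("planted blocks/chains are not disjoint")
            seen |= g


def sample_gaussian_trajectory(spec: GaussianEnsembleSpec,
                               time_step_ps: float = 1.0) -> Trajectory:
    """Draw frames from the spec's correlated Gaussian displacement model."""
    top = spec.topology
    residues = top.residues
    n_res = len(residues)
    res_pos = {r: i for i, r in enumerate(residues)}
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (n_res,))
    rng = np.random.default_rng(spec.seed)
    f = spec.n_frames
    # independent part
    z = rng.standard_normal((f, n_res, 3))
    shared_w = np.zeros(n_res)     # weight of the shared factor per residue
    group_id = np.full(n_res, -1)
    groups = []
    for group, rho in spec.blocks:
        gi = [res_pos[r] for r in group]
        shared_w[gi] = np.sqrt(rho)
        group_id[gi] = len(groups)
        groups.append(gi)
    for group, eps in spec.stiff_chains:
        gi = [res_pos[r] for r in group]
        shared_w[gi] = np.sqrt(1.0 - eps)
        group_id[gi] = len(groups)
        groups.append(gi)
    g_factors = rng.standard_normal((f, len(groups), 3)) if groups else None
    disp = z * np.sqrt(1.0 - shared_w ** 2)[None, :, None]
    for gid, gi in enumerate(groups):
        disp[:, gi, :] += shared_w[gi][None, :, None] * \
            g_factors[:, gid, :][:, None, :]
    disp *= sigma[None, :, None]
    # residue displacement -> rigid translation of the residue's atoms
    atom_res = np.array([res_pos[r] for r in top.residue_numbers])
    coords = spec.mean_coords[None] + disp[:, atom_res, :]
    return Trajectory(top, coords, time_step_ps=time_step_ps)


def displaced_basin(topology: Topology, mean_coords: np.ndarray,
                    residue_numbers, shift) -> np.ndarray:
    """A second conformational basin: the listed residues rigidly displaced.

    Because only part of the structure moves, the two basins differ by an
    internal deformation that survives best-fit superposition (a global
    rigid transform would not).
    """
    coords = np.asarray(mean_coords, dtype=float).copy()
    mask = np.isin(topology.residue_numbers, list(residue_numbers))
    coords[mask] += np.asarray(shift, dtype=float)
    return coords


def make_two_regime_trajectory(topology: Topology, basin_a: np.ndarray,
                               basin_b: np.ndarray, mixing: float,
                               n_frames: int = 1000, sigma: float = 0.3,
                               seed: int = 0) -> Trajectory:
    """Two-basin ensemble with a controllable half-mixing fraction.

    ``mixing = 0``: first half samples only basin A, second half only B
    (worst convergence).  ``mixing = 1``: both halves sample A and B equally
    (ideal convergence).  Intermediate values interpolate the minority
    fraction linearly.  Frames carry isotropic Gaussian jitter of scale
    ``sigma`` (Å) per atom.
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    basin_a = np.asarray(basin_a, dtype=float)
    basin_b = np.asarray(basin_b, dtype=float)
    if basin_a.shape != basin_b.shape or \
            basin_a.shape != (topology.n_atoms, 3):
        raise ValueError("basin coordinates incompatible with topology")
    rng = np.random.default_rng(seed)
    half = n_frames // 2
    n2 = n_frames - half
    minority = mixing / 2.0
    labels = np.zeros(n_frames, dtype=int)  # 0 = A, 1 = B
    n_b_first = int(round(minority * half))
    n_a_second = int(round(minority * n2))
    first = np.zeros(half, dtype=int)
    first[:n_b_first] = 1
    rng.shuffle(first)
    second = np.ones(n2, dtype=int)
    second[:n_a_second] = 0
    rng.shuffle(second)
    labels[:half] = first
    labels[half:] = second
    base = np.where(labels[:, None, None] == 0, basin_a[None], basin_b[None])
    coords = base + sigma * rng.standard_normal((n_frames,
                                                 topology.n_atoms, 3))
    return Trajectory(topology, coords)


def planted_study_spec(n_residues: int = 150, n_frames: int = 1000,
                       seed: int = 0):
    """The canonical planted-structure study system.

    A kinase-sized helical chain with heterogeneous mobility, emulating the
    statistical features the communication analysis consumes:

    * a quiet scaffold (sigma = 0.25 Å per residue),
    * three mobile loops (correlated blocks, rho = 0.6, sigma = 1.0 Å) -
      stand-ins for flexible regulatory segments, which dominate the
      leading PCA modes the way real loops do,
    * two strongly concerted blocks of 11 residues (rho = 0.9,
      sigma = 1.2 Å) - the planted independent dynamic segments,
    * one stiff 6-residue fiber with sequence spacing 4 (consecutive
      members in helix contact), distance-variance suppression
      epsilon = 0.02 - the planted communication pathway.

    Returns ``(spec, truth)`` where ``truth`` maps feature names to residue
    numbers.
    """
    if n_residues < 80:
        raise ValueError("the planted layout needs at least 80 residues")
    top, mean = helix_mean_structure(n_residues)
    sigma = np.full(n_residues, 0.25)

    def span(frac, length):
        start = max(2, int(round(frac * n_residues)))
        return list(range(start, min(start + length, n_residues)))

    loops = [span(0.03, 8), span(0.46, 8), span(0.92, 8)]
    blocks = [span(0.16, 11), span(0.32, 11)]
    fiber_start = int(round(0.63 * n_residues))
    fiber = [fiber_start + 4 * k for k in range(6)]
    for loop in loops:
        sigma[[r - 1 for r in loop]] = 1.0
    for block in blocks:
        sigma[[r - 1 for r in block]] = 1.2
    spec = GaussianEnsembleSpec(
        topology=top, mean_coords=mean, sigma=sigma,
        blocks=[(b, 0.9) for b in blocks] + [(l, 0.6) for l in loops],
        stiff_chains=[(fiber, 0.02)],
        n_frames=n_frames, seed=seed)
    truth = {"blocks": blocks, "loops": loops, "fiber": fiber}
    return spec, truth


# ---------------------------------------------------------------------------
# H-bond fixtures

def hbond_triad_coords(distance_da: float, angle_dha: float) -> np.ndarray:
    """Donor/hydrogen/acceptor geometry with exact D...A distance and
    D-H...A angle.

    Atom order matches :func:`make_hbond_topology`:
    residue 1 = acceptor side (C, O), residue 2 = donor side (N, H, CA).
    The D-H bond length is 1.0 Å.
    """
    alpha = np.radians(angle_dha)
    r2 = distance_da ** 2 - np.sin(alpha) ** 2
    if r2 < 0:
        raise ValueError("distance/angle combination is not realizable")
    r_ha = np.cos(alpha) + np.sqrt(r2)
    h = np.zeros(3)
    a = np.array([r_ha, 0.0, 0.0])
    d = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    c = a + np.array([_B_C_O, 0.6, 0.0])  # carbonyl C next to O
    ca = d + np.array([-0.9, 1.2, 0.0])   # donor's CA, out of the way
    return np.array([c, a, d, h, ca])


def make_hbond_topology() -> Topology:
    """Minimal two-residue topology for the donor-H-acceptor fixture."""
    names = ["C", "O", "N", "H", "CA"]
    res_nums = [1, 1, 2, 2, 2]
    elements = ["C", "O", "N", "H", "C"]
    return make_topology_from_arrays(names, res_nums, elements=elements)


def make_hbond_toggle_trajectory(on_fraction: float, n_frames: int,
                                 seed: int = 0,
                                 on_geometry=(2.9, 170.0),
                                 off_geometry=(4.5, 170.0)) -> Trajectory:
    """Bernoulli(on_fraction) toggle between H-bonded and broken geometry."""
    if not 0.0 <= on_fraction <= 1.0:
        raise ValueError("on_fraction must be in [0, 1]")
    top = make_hbond_topology()
    on = hbond_triad_coords(*on_geometry)
    off = hbond_triad_coords(*off_geometry)
    rng = np.random.default_rng(seed)
    states = rng.random(n_frames) < on_fraction
    coords = np.where(states[:, None, None], on[None], off[None])
    return Trajectory(top, coords)


# ---------------------------------------------------------------------------
# ideal secondary-structure fixtures

def hairpin_phi_psi(n_per_strand: int = 6):
    """Dihedral sequence of an antiparallel beta-hairpin: two strands
    closed by a two-residue turn whose geometry brings the strands into
    H-bond register."""
    return [STRAND_PHI_PSI] * n_per_strand + list(HAIRPIN_TURN) + \
        [STRAND_PHI_PSI] * n_per_strand


def build_ideal_secondary_structures() -> dict:
    """Geometry fixtures: ideal helices and an antiparallel beta-hairpin.

    Returns a dict name -> (Topology, coords).  The hairpin is a single
    continuous chain; its interior strand residues carry the cross-strand
    ladder H-bonds of an antiparallel sheet.
    """
    out = {}
    for name, pp, n in (("alpha_helix", ALPHA_PHI_PSI, 14),
                        ("310_helix", THREE_TEN_PHI_PSI, 10)):
        top = make_topology(n)
        out[name] = (top, ideal_backbone_coords([pp] * n))
    pp = hairpin_phi_psi(6)
    top = make_topology(len(pp))
    out["hairpin"] = (top, ideal_backbone_coords(pp))
    return out
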