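"""H-bond detection with time occupancy and DSSP-style secondary structure.

H-bonds D-H...A are geometric: donor...acceptor distance <= 3.5 Å and
D-H...A angle >= 120 deg (both cutoffs inclusive and configurable).
Occupancy of an interaction is the fraction of sampled frames in which it is
present; by default identity is residue-level (any donor/acceptor atom pair
between the two residues).

Secondary structure follows the Kabsch-Sander scheme: backbone H-bonds are
scored with the electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond being assigned when E < -0.5 kcal/mol, with amide hydrogens
reconstructed from the preceding peptide unit when absent.  Helices come
from consecutive n -> n+3/n+4/n+5 turns, strands from parallel/antiparallel
bridge ladders.  Full DSSP letters are reduced to the five reported classes:
G -> 3_10-helix, H/I -> alpha-helix, E/B -> beta, T -> turn, else coil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import Selection, Topology, Trajectory

SS_CLASSES = ("310", "alpha", "beta", "turn", "coil")

_REDUCE = {"G": "310", "H": "alpha", "I": "alpha",
           "E": "beta", "B": "beta", "T": "turn"}


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    donor_residue: int
    acceptor_residue: int
    distance: float   # D...A, Å
    angle: float      # D-H...A, degrees


def _hydrogen_donor_pairs(topology: Topology, frame: np.ndarray,
                          max_dh: float = 1.25):
    """Pair each hydrogen with its covalently bonded donor heavy atom.

    A hydrogen belongs to the nearest donor-flagged heavy atom of its own
    residue within ``max_dh`` Å; unpaired hydrogens (and donors without
    hydrogens) are silently skipped.
    """
    pairs = []
    h_idx = np.nonzero(topology.elements == "H")[0]
    donors = np.nonzero(topology.is_donor)[0]
    for h in h_idx:
        res = topology.residue_numbers[h]
        cand = donors[topology.residue_numbers[donors] == res]
        if len(cand) == 0:
            continue
        d = np.linalg.norm(frame[cand] - frame[h], axis=1)
        k = np.argmin(d)
        if d[k] <= max_dh:
            pairs.append((int(cand[k]), int(h)))
    return pairs


def detect_hbonds(frame: np.ndarray, topology: Topology,
                  dist_cut: float = 3.5, angle_cut: float = 120.0,
                  allow_intra_residue: bool = False):
    """All donor-H-acceptor triples meeting the geometric criterion.

    Both cutoffs are inclusive; a tiny float guard (1e-9) keeps geometries
    constructed exactly at the boundary on the accepted side.
    """
    frame = np.asarray(frame, dtype=float)
    pairs = _hydrogen_donor_pairs(topology, frame)
    acceptors = np.nonzero(topology.is_acceptor)[0]
    out = []
    for d_atom, h_atom in pairs:
        dv = frame[acceptors] - frame[d_atom]
        da = np.linalg.norm(dv, axis=1)
        ok = da <= dist_cut + 1e-9
        for a_atom, dist in zip(acceptors[ok], da[ok]):
            if a_atom == d_atom:
                continue
            if not allow_intra_residue and \
                    topology.residue_numbers[a_atom] == \
                    topology.residue_numbers[d_atom]:
                continue
            v1 = frame[d_atom] - frame[h_atom]
            v2 = frame[a_atom] - frame[h_atom]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            ang = np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2),
                                               -1.0, 1.0)))
            if ang >= angle_cut - 1e-9:
                out.append(HBond(
                    donor_atom=d_atom, hydrogen_atom=h_atom,
                    acceptor_atom=int(a_atom),
                    donor_residue=int(topology.residue_numbers[d_atom]),
                    acceptor_residue=int(topology.residue_numbers[a_atom]),
                    distance=float(dist), angle=float(ang)))
    return out


def hbond_occupancy(traj: Trajectory, pair=None, stride: int = 1,
                    dist_cut: float = 3.5, angle_cut: float = 120.0,
                    level: str = "residue"):
    """Time occupancy of H-bond interactions.

    Parameters
    ----------
    pair
        ``(residue_a, residue_b)`` author numbers for a single interaction
        (order-insensitive at residue level), or None to tabulate all
        interactions observed in the sampled frames.
    level
        ``"residue"``: any donor/acceptor atom combination between the two
        residues counts as the same interaction.  ``"atom"``: identity is
        the exact donor/acceptor atom pair.

    Returns a float for a single pair, otherwise a DataFrame with one row
    per interaction.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if pair is not None:
        for r in pair:
            if r not in traj.topology.residue_numbers:
                raise KeyError(f"unknown residue {r}")
    counts: dict = {}
    frames = traj.coords[::stride]
    for frame in frames:
        seen = set()
        for hb in detect_hbonds(frame, traj.topology, dist_cut, angle_cut):
            if level == "residue":
                key = tuple(sorted((hb.donor_residue, hb.acceptor_residue)))
            else:
                key = (hb.donor_atom, hb.acceptor_atom)
            seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    n = len(frames)
    if pair is not None:
        key = tuple(sorted(pair))
        return counts.get(key, 0) / n
    rows = [{"interaction": k, "occupancy": v / n, "stride": stride}
            for k, v in sorted(counts.items())]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DSSP-style assignment

_Q1Q2F = 0.084 * 332.0  # kcal/mol x Å, Kabsch-Sander coupling constant
_E_CUT = -0.5           # kcal/mol
_BREAK_CN = 2.5         # Å, peptide-bond C-N distance beyond which the
                        # chain is considered broken


def _backbone_table(topology: Topology):
    """Per-residue backbone atom indices (N, CA, C, O; -1 when missing)."""
    residues = topology.residues
    table = np.full((len(residues), 4), -1, dtype=int)
    chain = np.empty(len(residues), dtype=object)
    for ri, r in enumerate(residues):
        idx = topology.atoms_of_residue(r)
        chain[ri] = topology.chain_ids[idx[0]]
        for k, nm in enumerate(("N", "CA", "C", "O")):
            hit = idx[topology.names[idx] == nm]
            if len(hit):
                table[ri, k] = hit[0]
        hit = idx[topology.names[idx] == "H"]
    return residues, table, chain


def kabsch_sander_hbonds(frame: np.ndarray, topology: Topology) -> np.ndarray:
    """Boolean matrix hb[i, j]: CO of residue i accepts the NH of residue j.

    Amide hydrogens are reconstructed on N(j) one Å along the C(j-1)->O(j-1)
    inverse carbonyl direction when no explicit H is present; chain-start
    residues (and prolines, which carry no amide H) cannot donate.
    """
    frame = np.asarray(frame, dtype=float)
    residues, bb, chain = _backbone_table(topology)
    n = len(residues)
    valid = (bb >= 0).all(axis=1)
    # bonded predecessor: same chain and peptide C-N distance < 2.5 Å
    has_prev = np.zeros(n, dtype=bool)
    for i in range(1, n):
        if chain[i] != chain[i - 1]:
            continue
        if not (valid[i] and valid[i - 1]):
            continue
        if np.linalg.norm(frame[bb[i, 0]] - frame[bb[i - 1, 2]]) < _BREAK_CN:
            has_prev[i] = True
    # hydrogen positions
    h_pos = np.full((n, 3), np.nan)
    can_donate = np.zeros(n, dtype=bool)
    for j in range(n):
        if not valid[j]:
            continue
        idx = topology.atoms_of_residue(residues[j])
        explicit = idx[(topology.names[idx] == "H")]
        if len(explicit):
            h_pos[j] = frame[explicit[0]]
            can_donate[j] = True
        elif has_prev[j] and topology.residue_names[bb[j, 0]] != "PRO":
            c_prev, o_prev = frame[bb[j - 1, 2]], frame[bb[j - 1, 3]]
            d = c_prev - o_prev
            h_pos[j] = frame[bb[j, 0]] + d / np.linalg.norm(d)
            can_donate[j] = True
    hb = np.zeros((n, n), dtype=bool)
    donors = np.nonzero(can_donate & valid)[0]
    acceptors = np.nonzero(valid)[0]
    for j in donors:
        npos, hpos = frame[bb[j, 0]], h_pos[j]
        for i in acceptors:
            if abs(i - j) < 2 and chain[i] == chain[j]:
                continue
            cpos, opos = frame[bb[i, 2]], frame[bb[i, 3]]
            r_on = np.linalg.norm(opos - npos)
            if r_on > 5.2:  # energy cannot reach -0.5 beyond this
                continue
            r_ch = np.linalg.norm(cpos - hpos)
            r_oh = np.linalg.norm(opos - hpos)
            r_cn = np.linalg.norm(cpos - npos)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                hb[i, j] = True  # clash limit: treated as bonded in DSSP
                continue
            e = _Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _E_CUT:
                hb[i, j] = True
    return hb


def _assign_from_hbonds(hb: np.ndarray) -> np.ndarray:
    """DSSP letters from the backbone H-bond matrix."""
    n = hb.shape[0]
    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if hb[i, i + k]:
                turn[k][i] = True
    labels = np.array([" "] * n, dtype=object)

    def mark_helix(k, letter):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                for j in range(i, i + k):
                    if labels[j] == " " or (letter == "H"):
                        labels[j] = letter

    # bridges
    para = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (hb[i - 1, j] and hb[j, i + 1]) or \
                    (hb[j - 1, i] and hb[i, j + 1]):
                para[i, j] = para[j, i] = True
            if (hb[i, j] and hb[j, i]) or \
                    (hb[i - 1, j + 1] and hb[j - 1, i + 1]):
                anti[i, j] = anti[j, i] = True
    bridge = para | anti
    has_bridge = bridge.any(axis=1)
    in_ladder = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in np.nonzero(bridge[i])[0]:
            # ladder: an adjacent residue bridges an adjacent partner
            for di in (-1, 1):
                ii = i + di
                if 0 <= ii < n and has_bridge[ii] and \
                        any(abs(jj - j) <= 1 for jj in np.nonzero(bridge[ii])[0]):
                    in_ladder[i] = True

    mark_helix(4, "H")
    for i in range(n):
        if labels[i] == " " and has_bridge[i]:
            labels[i] = "E" if in_ladder[i] else "B"
    mark_helix(3, "G")
    mark_helix(5, "I")
    for k in (3, 4, 5):
        for i in np.nonzero(turn[k])[0]:
            for j in range(i + 1, i + k):
                if labels[j] == " ":
                    labels[j] = "T"
    return labels.astype(str)


def assign_secondary_structure(frame: np.ndarray, topology: Topology,
                               reduce: bool = False) -> np.ndarray:
    """Per-residue DSSP letters (or reduced class names) for one frame.

    Residues with missing backbone atoms are labeled coil.
    """
    labels = _assign_from_hbonds(kabsch_sander_hbonds(frame, topology))
    if reduce:
        return np.array([_REDUCE.get(l, "coil") for l in labels])
    return labels


def ss_occupancy_profile(traj: Trajectory, stride: int = 1) -> pd.DataFrame:
    """Percentage of sampled simulation time per residue and SS class.

    Rows are residues (author numbering); columns the five reduced classes;
    values are percentages summing to 100 per residue.
    """
    residues = traj.topology.residues
    counts = pd.DataFrame(0.0, index=residues, columns=list(SS_CLASSES))
    frames = traj.coords[::stride]
    for frame in frames:
        lab = assign_secondary_structure(frame, traj.topology, reduce=True)
        for r, l in zip(residues, lab):
            counts.loc[r, l] += 1
    profile = counts * (100.0 / len(frames))
    profile.index.name = "residue"
    return profile


def ss_block(traj: Trajectory, stride: int = 1) -> list:
    """Per-frame SS strings (one row per sampled frame)."""
    return ["".join(assign_secondary_structure(f, traj.topology))
            for f in traj.coords[::stride]]
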