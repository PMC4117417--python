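"""Modular communication-network analysis of a trajectory.

Two complementary descriptions are combined:

* **Local Feature Analysis (LFA)** turns the leading PCA modes (enough to
  cover ~80% of the Cα fluctuation) into local modes.  The projection
  kernel of the retained mode subspace gives residual correlations P(i, j)
  between residues; a threshold P_cut is calibrated so that about 1.0-1.2%
  of the cross-correlations exceed it.  Seed residues are picked by greedy
  kernel sparsification (largest residual local variance, then deflation),
  and each seed plus the residues correlated with it above P_cut forms an
  *independent dynamic segment* (IDS) - a cluster of residues fluctuating
  together and largely decoupled from the rest.

* **Commute times (CT)**: CT(i, j) is the variance over frames of the
  Cα(i)-Cα(j) distance (Å^2); a small CT means the two residues communicate
  efficiently.  A threshold CT_cut is either fixed or calibrated so that
  the most connected residue communicates with about 20% of the residues.

*Communication pathways* (CPs) are chains of residues in which adjacent
members share a persistent non-bonded interaction (heavy-atom contact
<= 3.9 Å, sequence separation >= 2, present in >= 50% of frames) and every
member pair has CT <= CT_cut.  Pathways are classified by length (short
2-3, intermediate 4-5, long > 5 residues) and span (local / extended at a
10 Å end-to-end Cα distance, with 10 Å itself counted as extended), and a
residue connected through pathways to more than 10% of the protein's
residues is a *hub*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import cdist

from .modes import ModeSet
from .topology import Selection, Trajectory


# ---------------------------------------------------------------------------
# Local Feature Analysis

@dataclass
class LFAResult:
    n_modes: int
    residues: np.ndarray          # author residue numbers
    kernel: np.ndarray            # residue-level unnormalized kernel
    correlations: np.ndarray      # P(i, j), unit diagonal
    output_matrix: np.ndarray     # 3A x n_modes, sqrt(lambda)-scaled modes
    p_cut: float | None = None
    fraction_above: float | None = None
    seeds: np.ndarray | None = None


@dataclass
class IDS:
    seed: int                     # author residue number
    members: tuple                # author residue numbers, seed included
    label: str = ""


def lfa_transform(modeset: ModeSet, n_modes: int,
                  residue_numbers=None) -> LFAResult:
    """Local-mode residual correlations from the top ``n_modes`` PCA modes.

    The retained eigenvector block V (3A x n) defines the LFA output
    matrix O = V sqrt(Lambda) and the subspace projection kernel K = V V^T.
    K is reduced to residue level by the Euclidean norm of the three
    Cartesian diagonal components of each residue block, then normalized to
    unit diagonal, giving the residual correlation matrix P.
    """
    if n_modes < 1:
        raise ValueError("need at least one mode")
    if n_modes > modeset.n_modes:
        raise ValueError(f"{n_modes} modes requested, "
                         f"{modeset.n_modes} available")
    v = modeset.eigenvectors[:, :n_modes]              # (3A, n)
    lam = modeset.eigenvalues[:n_modes]
    output = v * np.sqrt(lam)[None, :]
    n_atoms = modeset.n_atoms
    # per-residue blocks: diagonal 3-component reduction of K = V V^T
    vres = v.reshape(n_atoms, 3, n_modes)
    # K[3i+d, 3j+d] = vres[i, d] . vres[j, d]
    comp = np.einsum("idm,jdm->ijd", vres, vres)
    kernel = np.sqrt((comp ** 2).sum(axis=2))
    diag = np.sqrt(np.clip(np.diag(kernel), 1e-30, None))
    corr = kernel / np.outer(diag, diag)
    np.fill_diagonal(corr, 1.0)
    if residue_numbers is None:
        residue_numbers = np.arange(n_atoms)
    return LFAResult(n_modes=n_modes,
                     residues=np.asarray(residue_numbers),
                     kernel=kernel, correlations=corr, output_matrix=output)


def calibrate_pcut(lfa: LFAResult, band=(0.010, 0.012)) -> float:
    """P_cut leaving a within-band fraction of cross-correlations above it.

    Targets the band midpoint: with M off-diagonal pairs, the cut is placed
    between the k-th and (k+1)-th largest |P| where k = round(mid * M).
    """
    n = lfa.correlations.shape[0]
    if n < 10:
        raise ValueError("need at least 10 residues to calibrate")
    iu = np.triu_indices(n, k=1)
    vals = np.sort(np.abs(lfa.correlations[iu]))[::-1]
    if vals[0] - vals[-1] < 1e-12:
        raise ValueError("degenerate correlations: calibration impossible")
    m = len(vals)
    mid = 0.5 * (band[0] + band[1])
    k = int(round(mid * m))
    k = max(1, min(k, m - 1))
    p_cut = 0.5 * (vals[k - 1] + vals[k])
    if vals[k - 1] == vals[k]:  # ties: nudge below the k-th value
        p_cut = np.nextafter(vals[k - 1], -np.inf)
    lfa.p_cut = float(p_cut)
    lfa.fraction_above = float((vals > p_cut).sum() / m)
    return lfa.p_cut


def build_ids(lfa: LFAResult, p_cut: float | None = None,
              merge_overlapping: bool = False,
              merge_jaccard: float = 0.5):
    """Seed selection by greedy kernel sparsification, then IDS clusters.

    Seeds are picked one per retained mode: repeatedly take the residue
    with the largest remaining diagonal of the residue kernel and deflate
    the kernel by its Schur complement.  Each IDS is a seed plus all
    residues whose residual correlation with it exceeds ``p_cut``.  Seeds
    falling in an already-explained region produce singleton or duplicated
    segments, which is meaningful (locally duplicated segments do occur);
    merging of heavily overlapping segments is available but off by
    default.
    """
    if p_cut is None:
        p_cut = lfa.p_cut
    if p_cut is None:
        raise ValueError("P_cut not calibrated")
    resid = lfa.kernel.astype(float).copy()
    n = resid.shape[0]
    seeds = []
    for _ in range(min(lfa.n_modes, n)):
        diag = np.diag(resid).copy()
        diag[seeds] = -np.inf
        s = int(np.argmax(diag))
        if diag[s] <= 1e-12:
            break
        seeds.append(s)
        col = resid[:, s].copy()
        resid -= np.outer(col, col) / resid[s, s]
    lfa.seeds = np.array(seeds)
    segments = []
    for s in seeds:
        members = np.nonzero(lfa.correlations[s] > p_cut)[0]
        members = sorted(set(members.tolist()) | {s})
        segments.append(IDS(seed=int(lfa.residues[s]),
                            members=tuple(int(lfa.residues[m])
                                          for m in members)))
    if merge_overlapping:
        segments = _merge_ids(segments, merge_jaccard)
    for i, seg in enumerate(segments):
        seg.label = f"S{i + 1}"
    return segments


def _merge_ids(segments, jaccard):
    merged = []
    for seg in segments:
        placed = False
        for other in merged:
            a, b = set(seg.members), set(other.members)
            if len(a & b) / len(a | b) > jaccard:
                other.members = tuple(sorted(a | b))
                if seg.seed < other.seed:
                    other.seed = seg.seed
                placed = True
                break
        if not placed:
            merged.append(IDS(seed=seg.seed, members=seg.members))
    return merged


# ---------------------------------------------------------------------------
# commute times

def commute_time_matrix(traj: Trajectory, sel: Selection,
                        chunk: int = 250) -> np.ndarray:
    """CT(i, j): variance over frames of the atom_i-atom_j distance (Å^2).

    The selection is one atom per residue (Cα).  Accumulated in chunks so
    memory stays linear in the number of residue pairs.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = sel.array
    n = len(idx)
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    count = 0
    for start in range(0, traj.n_frames, chunk):
        block = traj.coords[start:start + chunk, idx, :]
        diff = block[:, :, None, :] - block[:, None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=3))
        s1 += d.sum(axis=0)
        s2 += (d ** 2).sum(axis=0)
        count += block.shape[0]
    mean = s1 / count
    var = s2 / count - mean ** 2
    var = np.clip(var, 0.0, None)
    np.fill_diagonal(var, 0.0)
    return (var + var.T) / 2.0


def calibrate_ctcut(ct: np.ndarray, target_fraction: float = 0.20) -> float:
    """CT_cut such that the most connected residue communicates with about
    ``target_fraction`` of the residues.

    Searches the sorted grid of off-diagonal CT values for the smallest cut
    at which the maximum per-residue count of partners with CT <= cut
    reaches round(target_fraction * n).
    """
    n = ct.shape[0]
    target = int(round(target_fraction * n))
    iu = np.triu_indices(n, k=1)
    grid = np.unique(ct[iu])
    if len(grid) < 2:
        raise ValueError("degenerate commute times: calibration impossible")

    def max_count(cut):
        off = (ct <= cut)
        np.fill_diagonal(off, False)
        return off.sum(axis=1).max()

    lo, hi = 0, len(grid) - 1
    if max_count(grid[hi]) < target:
        raise ValueError("target fraction unattainable")
    while lo < hi:
        mid = (lo + hi) // 2
        if max_count(grid[mid]) >= target:
            hi = mid
        else:
            lo = mid + 1
    return float(grid[lo])


def efficient_partner_counts(ct: np.ndarray, ct_cut: float) -> np.ndarray:
    """Per-residue number of partners with CT at or below the threshold."""
    off = ct <= ct_cut
    np.fill_diagonal(off, False)
    return off.sum(axis=1)


# ---------------------------------------------------------------------------
# interaction and neighbor graphs

def contact_persistence(traj: Trajectory, contact_cut: float = 3.9,
                        stride: int = 1) -> np.ndarray:
    """Fraction of sampled frames in which residue pairs share a heavy-atom
    contact within ``contact_cut`` Å."""
    top = traj.topology
    heavy = top.heavy_atom_indices()
    residues = top.residues
    n_res = len(residues)
    res_of_heavy = top.residue_numbers[heavy]
    groups = [np.nonzero(res_of_heavy == r)[0] for r in residues]
    order = np.concatenate(groups)
    starts = np.concatenate(([0], np.cumsum([len(g) for g in groups])))
    frames = traj.coords[::stride]
    acc = np.zeros((n_res, n_res))
    for frame in frames:
        pts = frame[heavy][order]
        d = cdist(pts, pts)
        row_min = np.minimum.reduceat(d, starts[:-1], axis=0)
        dmin = np.minimum.reduceat(row_min, starts[:-1], axis=1)
        acc += dmin <= contact_cut
    return acc / len(frames)


def interaction_graph(traj: Trajectory, contact_cut: float = 3.9,
                      persistence: float = 0.5, min_seq_sep: int = 2,
                      stride: int = 1) -> np.ndarray:
    """Boolean residue matrix of persistent non-bonded interactions.

    An edge requires at least one heavy-atom pair within ``contact_cut`` in
    at least ``persistence`` of the frames, and a sequence separation of at
    least ``min_seq_sep`` so covalent/peptide adjacency never counts.
    """
    pers = contact_persistence(traj, contact_cut, stride)
    n = pers.shape[0]
    edges = pers >= persistence
    for k in range(min_seq_sep):
        edges &= ~np.eye(n, k=k, dtype=bool) & ~np.eye(n, k=-k, dtype=bool)
    return edges


# ---------------------------------------------------------------------------
# the communication graph and pathways

@dataclass
class CommGraph:
    residues: np.ndarray            # author residue numbers (Cα order)
    ct: np.ndarray                  # commute-time matrix
    ct_cut: float
    interactions: np.ndarray        # boolean persistent-interaction matrix
    neighbor: np.ndarray | None = None  # mean-smallest-distance <= d_cut
    pathways: list = field(default_factory=list)  # tuples of positions
    hub_threshold: float = 0.10

    def pathway_residues(self):
        """Pathways as tuples of author residue numbers."""
        return [tuple(int(self.residues[p]) for p in pw)
                for pw in self.pathways]


def grow_pathways(interactions: np.ndarray, ct: np.ndarray, ct_cut: float,
                  max_pathways: int = 200000) -> list:
    """Enumerate maximal communication chains.

    A chain starts from any interaction edge whose CT is within CT_cut and
    grows at either end by residues that (a) interact with the current end
    and (b) have CT <= CT_cut to *every* chain member.  Maximal chains are
    deduplicated against reversals and contiguous sub-chains; output order
    is deterministic (lexicographic by residue position).
    """
    n = interactions.shape[0]
    fast = ct <= ct_cut
    np.fill_diagonal(fast, False)
    seed_edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if interactions[i, j] and fast[i, j]]
    maximal = set()
    seen_states = set()

    def canonical(chain):
        return min(chain, chain[::-1])

    stack = [tuple(e) for e in seed_edges]
    while stack:
        chain = stack.pop()
        state = canonical(chain)
        if state in seen_states:
            continue
        seen_states.add(state)
        if len(seen_states) > 50 * max_pathways:
            break
        members = set(chain)
        extended = False
        for end, build in ((chain[-1], lambda c: chain + (c,)),
                           (chain[0], lambda c: (c,) + chain)):
            cand = np.nonzero(interactions[end] & fast[end])[0]
            for c in cand:
                if c in members:
                    continue
                if all(fast[c, m] for m in members):
                    stack.append(build(int(c)))
                    extended = True
        if not extended:
            maximal.add(canonical(chain))
            if len(maximal) >= max_pathways:
                break
    # drop contiguous sub-chains of longer pathways
    chains = sorted(maximal, key=lambda c: (-len(c), c))
    kept = []
    for c in chains:
        is_sub = False
        for big in kept:
            if len(c) < len(big) and (_is_subchain(c, big) or
                                      _is_subchain(c[::-1], big)):
                is_sub = True
                break
        if not is_sub:
            kept.append(c)
    return sorted(kept)


def _is_subchain(small, big):
    ls, lb = len(small), len(big)
    return any(big[i:i + ls] == small for i in range(lb - ls + 1))


def build_comm_graph(traj: Trajectory, ca_sel: Selection,
                     ct_cut: float | str = "calibrate",
                     target_fraction: float = 0.20,
                     contact_cut: float = 3.9, persistence: float = 0.5,
                     d_cut: float = 3.6, stride: int = 1,
                     with_neighbors: bool = True,
                     max_pathways: int = 200000) -> CommGraph:
    """Assemble the full communication graph for one trajectory.

    ``ct_cut`` is either a fixed threshold (Å^2 of distance variance) or
    ``"calibrate"`` for the 20%-connectivity procedure.  The neighbor
    matrix (mean smallest inter-residue distance <= d_cut) is an auxiliary
    product and can be skipped.
    """
    from .geometry import mean_smallest_distance_matrix
    ct = commute_time_matrix(traj, ca_sel)
    if ct_cut == "calibrate":
        ct_cut_val = calibrate_ctcut(ct, target_fraction)
    else:
        ct_cut_val = float(ct_cut)
    interactions = interaction_graph(traj, contact_cut, persistence,
                                     stride=stride)
    neighbor_matrix = None
    if with_neighbors:
        msd = mean_smallest_distance_matrix(traj, stride=max(stride, 1))
        neighbor_matrix = msd <= d_cut
    pathways = grow_pathways(interactions, ct, ct_cut_val, max_pathways)
    residues = traj.topology.residue_numbers[ca_sel.array]
    graph = CommGraph(residues=residues, ct=ct, ct_cut=ct_cut_val,
                      interactions=interactions, neighbor=neighbor_matrix,
                      pathways=pathways)
    verify_pathways(graph)
    return graph


def verify_pathways(graph: CommGraph) -> None:
    """Re-assert the growth constraints on every stored pathway."""
    fast = graph.ct <= graph.ct_cut
    for pw in graph.pathways:
        for a, b in zip(pw[:-1], pw[1:]):
            if not graph.interactions[a, b]:
                raise AssertionError(
                    f"pathway {pw}: adjacent pair ({a}, {b}) lacks an "
                    "interaction edge")
        for i, a in enumerate(pw):
            for b in pw[i + 1:]:
                if not fast[a, b]:
                    raise AssertionError(
                        f"pathway {pw}: members ({a}, {b}) exceed CT_cut")


# ---------------------------------------------------------------------------
# classification, hubs, export

def classify_pathways(graph: CommGraph, coords_ca: np.ndarray) -> pd.DataFrame:
    """Annotate each pathway with length class, span class and end distance.

    ``coords_ca`` are representative (e.g. ensemble-average) Cα coordinates
    in the same order as ``graph.residues``.  Lengths 2-3 are short, 4-5
    intermediate, > 5 long; end-to-end distance < 10 Å is local, >= 10 Å
    extended.
    """
    rows = []
    for pw in graph.pathways:
        if len(pw) < 2:
            raise ValueError(f"invalid pathway of length {len(pw)}")
        dist = float(np.linalg.norm(coords_ca[pw[0]] - coords_ca[pw[-1]]))
        length_class = ("short" if len(pw) <= 3 else
                        "intermediate" if len(pw) <= 5 else "long")
        rows.append({
            "pathway": tuple(int(graph.residues[p]) for p in pw),
            "n_residues": len(pw),
            "length_class": length_class,
            "end_to_end": dist,
            "span_class": "local" if dist < 10.0 else "extended",
        })
    return pd.DataFrame(rows)


def communication_partners(graph: CommGraph) -> dict:
    """Per residue position: set of residues sharing at least one pathway."""
    partners = {i: set() for i in range(len(graph.residues))}
    for pw in graph.pathways:
        s = set(pw)
        for p in pw:
            partners[p] |= s - {p}
    return partners


def find_hubs(graph: CommGraph, threshold: float | None = None,
              mode: str = "pathways"):
    """Highly communicating residues and per-residue connectivity counts.

    ``mode="pathways"`` (default): a residue is a hub when the residues it
    shares a pathway with exceed ``threshold`` (10%) of all residues.
    ``mode="direct"``: counts direct partners with CT <= CT_cut instead.

    Returns ``(hub_residues, table)`` where the table has per-residue
    pathway counts and connected-residue counts.
    """
    if threshold is None:
        threshold = graph.hub_threshold
    n = len(graph.residues)
    if mode == "pathways":
        partners = communication_partners(graph)
        connected = np.array([len(partners[i]) for i in range(n)])
    elif mode == "direct":
        connected = efficient_partner_counts(graph.ct, graph.ct_cut)
    else:
        raise ValueError(f"unknown hub mode {mode!r}")
    cp_count = np.zeros(n, dtype=int)
    for pw in graph.pathways:
        for p in pw:
            cp_count[p] += 1
    is_hub = connected > threshold * n
    table = pd.DataFrame({
        "residue": graph.residues,
        "n_pathways": cp_count,
        "n_connected": connected,
        "hub": is_hub,
    })
    hubs = [int(r) for r, h in zip(graph.residues, is_hub) if h]
    return hubs, table


def export_graph(graph: CommGraph, graphml_path, edgelist_path=None) -> None:
    """Write the communication graph as GraphML (+ optional TSV edge list).

    Nodes carry the author residue number and communication efficiency
    (number of residues reachable through pathways); edges carry their type
    (``interaction`` or ``pathway-step``) and commute time.
    """
    g = nx.Graph()
    partners = communication_partners(graph)
    for i, r in enumerate(graph.residues):
        g.add_node(int(r), communication_efficiency=int(len(partners[i])))
    n = len(graph.residues)
    for i in range(n):
        for j in range(i + 1, n):
            if graph.interactions[i, j]:
                g.add_edge(int(graph.residues[i]), int(graph.residues[j]),
                           type="interaction", ct=float(graph.ct[i, j]))
    for pw in graph.pathways:
        for a, b in zip(pw[:-1], pw[1:]):
            u, v = int(graph.residues[a]), int(graph.residues[b])
            g.add_edge(u, v, type="pathway-step", ct=float(graph.ct[a, b]))
    nx.write_graphml(g, str(graphml_path))
    if edgelist_path is not None:
        rows = [{"residue_a": u, "residue_b": v, "type": d["type"],
                 "ct": d["ct"]} for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows).to_csv(str(edgelist_path), sep="\t", index=False)
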