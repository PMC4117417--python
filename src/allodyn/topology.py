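"""Topology, trajectory and atom-selection data model.

The public coordinate system is *author* residue numbering as it appears in
the PDB file (1-based, possibly with gaps, e.g. a kinase construct in which
a disordered insert domain was replaced by a short linker so numbering jumps
from 693 to 754).  Internal 0-based atom indices are an implementation
detail and never appear in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a topology/trajectory."""


class EmptySelectionError(ValueError):
    """Raised when an atom selection resolves to zero atoms."""


#: Standard atomic masses (u) for mass-weighted centers of mass.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45,
}

# Donor/acceptor chemistry: backbone N-H donates, backbone O accepts, plus
# the standard polar side-chain groups (hydroxyls, amines/amides, carboxylates,
# His ring nitrogens, Trp indole NH).
_SIDECHAIN_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"), ("GLN", "NE2"),
    ("TRP", "NE1"),
}
_SIDECHAIN_ACCEPTORS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

#: Atom-name sets for the conventional backbone selections.  The fluctuation
#: analysis uses carbon and nitrogen backbone atoms only (no carbonyl O).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
CN_BACKBONE_ATOMS = frozenset({"C", "CA", "N"})


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    is_donor: bool = False
    is_acceptor: bool = False


class Topology:
    """Static atom/residue description of a single-chain protein model.

    Parameters
    ----------
    atoms
        Atoms in file order.  Atom indices must be contiguous from 0 and
        residue numbers non-decreasing within a chain (author numbering,
        gaps allowed).
    """

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise PDBParseError("topology contains zero atoms")
        for i, a in enumerate(atoms):
            if a.index != i:
                raise ValueError(f"atom indices not contiguous at position {i}")
        self.atoms = tuple(atoms)
        self.names = np.array([a.name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.residue_numbers = np.array([a.residue_number for a in atoms])
        self.residue_names = np.array([a.residue_name for a in atoms])
        self.chain_ids = np.array([a.chain_id for a in atoms])
        self.is_donor = np.array([a.is_donor for a in atoms], dtype=bool)
        self.is_acceptor = np.array([a.is_acceptor for a in atoms], dtype=bool)
        # residue numbers must be strictly increasing within a chain,
        # at the granularity of residue blocks
        for cid in np.unique(self.chain_ids):
            nums = self.residue_numbers[self.chain_ids == cid]
            block_starts = np.concatenate(([True], nums[1:] != nums[:-1]))
            blocks = nums[block_starts]
            if np.any(np.diff(blocks) <= 0):
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {cid!r}"
                )
        self.masses = np.array(
            [ATOMIC_MASSES.get(e.upper(), 12.011) for e in self.elements]
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> np.ndarray:
        """Author residue numbers, in chain order, one entry per residue."""
        nums = self.residue_numbers
        keep = np.concatenate(([True], nums[1:] != nums[:-1]))
        return nums[keep]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atoms_of_residue(self, residue_number: int) -> np.ndarray:
        idx = np.nonzero(self.residue_numbers == residue_number)[0]
        if len(idx) == 0:
            raise KeyError(f"no residue numbered {residue_number}")
        return idx

    def heavy_atom_indices(self) -> np.ndarray:
        return np.nonzero(self.elements != "H")[0]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Topology {self.n_atoms} atoms, {self.n_residues} residues>"


@dataclass(frozen=True)
class Selection:
    """A resolved, ordered set of atom indices with its provenance."""

    indices: tuple
    provenance: str = ""

    def __post_init__(self):
        if len(self.indices) == 0:
            raise EmptySelectionError(f"empty selection ({self.provenance})")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate atom indices")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


class Trajectory:
    """A frame-indexed coordinate ensemble bound to a topology.

    Coordinates are in Å, shape ``(n_frames, n_atoms, 3)``.
    """

    def __init__(self, topology: Topology, coords: np.ndarray,
                 time_step_ps: float = 1.0):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coordinate array has shape {coords.shape}, "
                             "expected (n_frames, n_atoms, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame has {coords.shape[1]} atoms, topology has "
                f"{topology.n_atoms}")
        if coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(coords)):
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise ValueError(f"non-finite coordinate in frame {bad[0]}")
        self.topology = topology
        self.coords = coords
        self.time_step_ps = float(time_step_ps)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<Trajectory {self.n_frames} frames x "
                f"{self.topology.n_atoms} atoms, dt={self.time_step_ps} ps>")


def _annotate_donors_acceptors(name, res_name, element):
    """Classify one atom as H-bond donor heavy atom and/or acceptor."""
    is_donor = (name == "N" and element == "N") or \
        ((res_name, name) in _SIDECHAIN_DONORS)
    is_acceptor = (name == "O" and element == "O") or name == "OXT" or \
        ((res_name, name) in _SIDECHAIN_ACCEPTORS)
    return is_donor, is_acceptor


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name.lstrip("0123456789")
    if name[:1] == "H":
        return "H"
    return name[:1]


def _topology_from_atom_array(arr) -> Topology:
    atoms = []
    for i in range(arr.array_length()):
        el = arr.element[i] if arr.element[i] else _guess_element(arr.atom_name[i])
        d, a = _annotate_donors_acceptors(arr.atom_name[i], arr.res_name[i], el)
        atoms.append(Atom(index=i, name=str(arr.atom_name[i]),
                          element=str(el),
                          residue_number=int(arr.res_id[i]),
                          residue_name=str(arr.res_name[i]),
                          chain_id=str(arr.chain_id[i]),
                          is_donor=d, is_acceptor=a))
    return Topology(atoms)


def make_topology_from_arrays(names, res_numbers, res_names=None,
                              chain_ids=None, elements=None) -> Topology:
    """Assemble a Topology from parallel arrays (used by the generators)."""
    n = len(names)
    res_names = ["ALA"] * n if res_names is None else list(res_names)
    chain_ids = ["A"] * n if chain_ids is None else list(chain_ids)
    if elements is None:
        elements = [_guess_element(nm) for nm in names]
    atoms = []
    for i in range(n):
        d, a = _annotate_donors_acceptors(names[i], res_names[i], elements[i])
        atoms.append(Atom(index=i, name=names[i], element=elements[i],
                          residue_number=int(res_numbers[i]),
                          residue_name=res_names[i], chain_id=chain_ids[i],
                          is_donor=d, is_acceptor=a))
    return Topology(atoms)


def load_topology(path) -> Topology:
    """Read the topology from the first model of a (multi-model) PDB file."""
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various parse errors
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"{path} contains no ATOM records")
    return _topology_from_atom_array(arr)


def load_trajectory(paths, topology: Topology,
                    time_step_ps: float = 1.0) -> Trajectory:
    """Read and concatenate frames from one or more multi-model PDB files."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    chunks = []
    for path in paths:
        try:
            pdb = PDBFile.read(str(path))
            coord = pdb.get_coord()  # (models, atoms, 3)
        except Exception as exc:
            raise PDBParseError(f"cannot parse {path}: {exc}") from exc
        if coord.ndim == 2:
            coord = coord[None]
        if coord.shape[1] != topology.n_atoms:
            raise ValueError(
                f"{path}: frames have {coord.shape[1]} atoms, topology has "
                f"{topology.n_atoms}")
        chunks.append(np.asarray(coord, dtype=np.float64))
    if not chunks:
        raise ValueError("no input files given")
    return Trajectory(topology, np.concatenate(chunks, axis=0),
                      time_step_ps=time_step_ps)


def select(topology: Topology, residue_ranges, atom_names=None,
           provenance: str | None = None) -> Selection:
    """Resolve residue ranges (author numbering) + an atom-name filter.

    Parameters
    ----------
    residue_ranges
        Iterable of inclusive ``(first, last)`` author-numbered ranges.
        Ranges spanning a numbering gap simply select the residues that
        exist.
    atom_names
        Set of atom names to keep, or None for all atoms.
    """
    ranges = [(int(lo), int(hi)) for lo, hi in residue_ranges]
    mask = np.zeros(topology.n_atoms, dtype=bool)
    for lo, hi in ranges:
        mask |= (topology.residue_numbers >= lo) & \
                (topology.residue_numbers <= hi)
    if atom_names is not None:
        mask &= np.isin(topology.names, list(atom_names))
    idx = np.nonzero(mask)[0]
    if provenance is None:
        names = "*" if atom_names is None else ",".join(sorted(atom_names))
        provenance = ";".join(f"{lo}-{hi}:{names}" for lo, hi in ranges)
    return Selection(indices=tuple(int(i) for i in idx), provenance=provenance)


def parse_selection_string(topology: Topology, spec: str) -> Selection:
    """Resolve a config-style selection string such as ``"560-570:CA"``."""
    ranges, names = [], set()
    for token in spec.split(","):
        token = token.strip()
        if ":" in token:
            rng, nm = token.split(":", 1)
            names.update(n for n in nm.split("+") if n)
        else:
            rng = token
        lo, _, hi = rng.partition("-")
        ranges.append((int(lo), int(hi or lo)))
    return select(topology, ranges, atom_names=names or None, provenance=spec)


def write_frames(trajectory: Trajectory, frame_indices, path) -> None:
    """Write selected frames as a MODEL/ENDMDL-delimited multi-model PDB."""
    frame_indices = list(frame_indices)
    if len(frame_indices) == 0:
        raise ValueError("no frames to write")
    for i in frame_indices:
        if not (0 <= i < trajectory.n_frames):
            raise IndexError(f"frame index {i} out of range "
                             f"(0..{trajectory.n_frames - 1})")
    top = trajectory.topology
    arr = struc.AtomArray(top.n_atoms)
    arr.atom_name = top.names.copy()
    arr.res_id = top.residue_numbers.copy()
    arr.res_name = top.residue_names.copy()
    arr.chain_id = top.chain_ids.copy()
    arr.element = top.elements.copy()
    frames = []
    for i in frame_indices:
        a = arr.copy()
        a.coord = np.asarray(trajectory.coords[i], dtype=np.float32)
        frames.append(a)
    stack = struc.stack(frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
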