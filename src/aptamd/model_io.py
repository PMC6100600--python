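"""Multi-model PDB trajectory I/O and chemical role assignment.

Trajectories are snapshot series of a receptor--ligand(--water/ion) complex,
one PDB ``MODEL`` per snapshot.  Atoms are partitioned into receptor, ligand,
water and ion sets by residue name, and each atom is tagged with the
functional roles the interaction detectors need: hydrogen-bond donor heavy
atom, acceptor, hydrophobic carbon, aromatic-ring member, water oxygen and
water hydrogen.

Coordinates are Angstroms throughout, residue ids keep the file's 1-based
numbering, and role assignment is derived from frame-0 topology so flags are
identical across all frames of one trajectory.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "Ring",
    "TrajectoryError",
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "assign_roles",
    "assign_roles_trajectory",
    "DEFAULT_WATER_RESNAMES",
    "ION_ELEMENTS",
]

# Residue names treated as solvent by default (PDB, GROMACS, CHARMM habits).
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC"})

# Monoatomic species treated as ions when they form single-atom residues.
ION_ELEMENTS = frozenset(
    {"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "BR", "I", "LI", "CS", "F", "RB"}
)

# Covalent-bond inference cutoffs (Angstrom): parameter-free and adequate for
# all-atom MD snapshots; see docs/methods.md.
COVALENT_HEAVY_MAX = 1.9
COVALENT_XH_MAX = 1.25

# Aromatic ring templates for the standard nucleobases.  Purines carry a
# fused 6- and 5-membered ring, pyrimidines a single 6-ring.
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINE_6RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINE_5RING = ("C4", "C5", "N7", "C8", "N9")

RING_TEMPLATES: dict[str, dict[str, tuple[str, ...]]] = {}
for _name in ("A", "G", "DA", "DG", "ADE", "GUA"):
    RING_TEMPLATES[_name] = {"ring6": _PURINE_6RING, "ring5": _PURINE_5RING}
for _name in ("C", "T", "U", "DC", "DT", "DU", "CYT", "THY", "URA"):
    RING_TEMPLATES[_name] = {"ring6": _PYRIMIDINE_RING}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "K": 39.098, "CL": 35.45, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "FE": 55.845, "BR": 79.904, "F": 18.998,
}


class TrajectoryError(ValueError):
    """Raised for malformed trajectory input or infeasible I/O requests."""


@dataclass
class Atom:
    """One atom record of a snapshot; coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str
    coords: np.ndarray
    role_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise TrajectoryError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise TrajectoryError(f"atom {self.serial}: empty element after inference")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_id, self.residue_name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def mass(self) -> float:
        return _ELEMENT_MASSES.get(self.element.upper(), 12.011)


@dataclass
class Ring:
    """An aromatic ring: member atom indices within one residue."""

    residue_key: tuple[str, int, str]
    name: str
    atom_indices: tuple[int, ...]


@dataclass
class Frame:
    """One trajectory snapshot with its receptor/ligand/water/ion partition."""

    index: int
    atoms: list[Atom]
    partition: dict[str, frozenset[int]]
    time_ps: float | None = None
    rings: list[Ring] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        covered: set[int] = set()
        total = 0
        for key in ("receptor", "ligand", "water", "ion"):
            members = self.partition.get(key, frozenset())
            total += len(members)
            covered |= set(members)
        if covered != set(range(n)) or total != n:
            raise TrajectoryError("partition sets must be disjoint and cover all atoms")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise TrajectoryError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    def indices(self, part: str) -> tuple[int, ...]:
        return tuple(sorted(self.partition.get(part, frozenset())))

    def residues(self, part: str = "receptor") -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for i in self.indices(part):
            seen.setdefault(self.atoms[i].residue_key)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology (atom names/residues of frame 0)."""

    frames: list[Frame]
    topology_hash: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise TrajectoryError("a trajectory needs at least one frame")
        ref = _topology_digest(self.frames[0])
        if not self.topology_hash:
            self.topology_hash = ref
        for fr in self.frames:
            if _topology_digest(fr) != self.topology_hash:
                raise TrajectoryError(f"frame {fr.index} does not match frame-0 topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0].atoms)


def _topology_digest(frame: Frame) -> str:
    h = hashlib.sha1()
    for a in frame.atoms:
        h.update(f"{a.name}|{a.residue_name}|{a.residue_id}|{a.chain};".encode())
    return h.hexdigest()


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Element from a PDB atom name, used when columns 77-78 are blank.

    Follows PDB convention: names are right-justified on the element, so a
    leading digit (e.g. ``1H5'``) marks a hydrogen, and two-letter elements
    only occur for ions/metals which we match against a known list.
    """
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        return name[1].upper() if len(name) > 1 else ""
    two = name[:2].upper()
    if two in ION_ELEMENTS and residue_name.strip().upper() in (two, name.upper()):
        return two
    return name[0].upper()


def _partition_indices(
    atoms: Sequence[Atom],
    ligand_resnames: frozenset[str],
    water_resnames: frozenset[str],
) -> dict[str, frozenset[int]]:
    parts: dict[str, set[int]] = {"receptor": set(), "ligand": set(), "water": set(), "ion": set()}
    # count atoms per residue for the single-atom ion heuristic
    residue_sizes: dict[tuple[str, int, str], int] = {}
    for a in atoms:
        residue_sizes[a.residue_key] = residue_sizes.get(a.residue_key, 0) + 1
    for i, a in enumerate(atoms):
        rname = a.residue_name.upper()
        if rname in water_resnames:
            parts["water"].add(i)
        elif rname in ligand_resnames:
            parts["ligand"].add(i)
        elif residue_sizes[a.residue_key] == 1 and a.element.upper() in ION_ELEMENTS:
            parts["ion"].add(i)
        else:
            parts["receptor"].add(i)
    return {k: frozenset(v) for k, v in parts.items()}


def read_pdb_trajectory(
    path: str | Path,
    ligand_resnames: Iterable[str] = ("LIG", "EST", "E2"),
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    One frame per ``MODEL`` record; a file without ``MODEL`` records yields a
    single-frame trajectory.  Elements come from columns 77-78 when present,
    otherwise from the atom name.  Raises :class:`TrajectoryError` on missing
    files, zero atoms, or frames with differing atom counts.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.is_file():
        raise TrajectoryError(f"cannot read trajectory: {path} does not exist")
    lig = frozenset(r.upper() for r in ligand_resnames)
    wat = frozenset(r.upper() for r in water_resnames)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises on ragged models / garbage input
        raise TrajectoryError(f"unreadable PDB trajectory {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise TrajectoryError(f"{path} contains zero atoms")

    frames: list[Frame] = []
    partition: dict[str, frozenset[int]] | None = None
    for fidx in range(stack.stack_depth()):
        arr = stack[fidx]
        atoms: list[Atom] = []
        for i in range(arr.array_length()):
            elem = str(arr.element[i]).strip().upper()
            name = str(arr.atom_name[i])
            resname = str(arr.res_name[i])
            if not elem:
                elem = infer_element(name, resname)
            atoms.append(
                Atom(
                    serial=i + 1,
                    name=name,
                    element=elem,
                    residue_name=resname,
                    residue_id=int(arr.res_id[i]),
                    chain=str(arr.chain_id[i]) or "A",
                    coords=np.array(arr.coord[i], dtype=float),
                )
            )
        if partition is None:
            partition = _partition_indices(atoms, lig, wat)
        frames.append(Frame(index=fidx, atoms=atoms, partition=partition))
    return Trajectory(frames=frames)


def write_pdb_trajectory(traj: Trajectory, path: str | Path, remarks: Sequence[str] = ()) -> Path:
    """Write a trajectory as a standard multi-model PDB (MODEL/ENDMDL pairs)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    n = traj.n_atoms
    arrays = []
    for fr in traj.frames:
        arr = struc.AtomArray(n)
        arr.coord = fr.coords
        arr.atom_name = np.array([a.name for a in fr.atoms])
        arr.res_name = np.array([a.residue_name for a in fr.atoms])
        arr.res_id = np.array([a.residue_id for a in fr.atoms])
        arr.chain_id = np.array([a.chain for a in fr.atoms])
        arr.element = np.array([a.element for a in fr.atoms])
        arr.hetero = np.array([False] * n)
        arrays.append(arr)
    for a in traj.frames[0].atoms:
        if len(a.name) > 4:
            raise TrajectoryError(f"atom name {a.name!r} exceeds the 4-character PDB field")
    allc = np.concatenate([arr.coord for arr in arrays])
    if np.any(allc >= 10000.0) or np.any(allc <= -1000.0):
        raise TrajectoryError("coordinates overflow the PDB 8.3 fixed-point field")
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    if remarks:
        remark_lines = [f"REMARK 250 {r}" for r in remarks]
        pdb.lines = remark_lines + pdb.lines
    pdb.write(str(path))
    return path


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def _bond_adjacency(atoms: Sequence[Atom]) -> list[set[int]]:
    """Distance-based covalent bonds: heavy-heavy <= 1.9 A, X-H <= 1.25 A."""
    xyz = np.array([a.coords for a in atoms])
    tree = cKDTree(xyz)
    adj: list[set[int]] = [set() for _ in atoms]
    for i, j in tree.query_pairs(COVALENT_HEAVY_MAX):
        hi, hj = atoms[i].is_hydrogen, atoms[j].is_hydrogen
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if hi and hj:
            continue  # H-H never bonded
        if (hi or hj) and d > COVALENT_XH_MAX:
            continue
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _planar_cycles(
    atoms: Sequence[Atom], indices: Sequence[int], adj: list[set[int]], rms_max: float = 0.2
) -> list[tuple[int, ...]]:
    """5/6-membered near-planar cycles among the given heavy atoms."""
    import networkx as nx

    heavy = [i for i in indices if not atoms[i].is_hydrogen]
    g = nx.Graph()
    g.add_nodes_from(heavy)
    for i in heavy:
        for j in adj[i]:
            if j in heavy and i < j:
                g.add_edge(i, j)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        xyz = np.array([atoms[i].coords for i in cycle])
        centered = xyz - xyz.mean(axis=0)
        _, s, _ = np.linalg.svd(centered, full_matrices=False)
        rms_dev = s[2] / math.sqrt(len(cycle))
        if rms_dev <= rms_max:
            rings.append(tuple(sorted(cycle)))
    return rings


def assign_roles(frame: Frame, config=None) -> Frame:
    """Tag every atom with its interaction roles (in place; returns the frame).

    Donor heavy atoms are N/O with at least one covalently bonded hydrogen
    (strict mode); in lenient heavy-atom mode every N/O is treated as a
    potential donor.  All N/O are acceptors.  Hydrophobic carbons bond only
    to carbon or hydrogen.  Aromatic membership comes from nucleobase ring
    templates, ligand ring templates in the config, or a generic planar-cycle
    search as fallback.
    """
    from .interactions import InteractionConfig  # local import to avoid a cycle

    if config is None:
        config = InteractionConfig()
    atoms = frame.atoms
    adj = _bond_adjacency(atoms)
    strict = config.strict_hydrogens
    has_any_h = any(a.is_hydrogen for a in atoms)
    if strict and not has_any_h:
        raise TrajectoryError(
            "strict mode requires explicit hydrogens; use lenient mode for heavy-atom models"
        )

    water_idx = frame.partition.get("water", frozenset())
    for i, a in enumerate(atoms):
        flags = a.role_flags
        flags.clear()
        if a.is_hydrogen:
            flags.add("hydrogen")
            if i in water_idx:
                flags.add("water-hydrogen")
            continue
        if i in water_idx and a.element == "O":
            flags.add("water-oxygen")
        if a.element in ("N", "O"):
            bonded_h = any(atoms[j].is_hydrogen for j in adj[i])
            if bonded_h or not strict:
                flags.add("donor-heavy")
            flags.add("acceptor")
        elif a.element == "C":
            if all(atoms[j].element in ("C", "H") for j in adj[i]):
                flags.add("hydrophobic-carbon")

    # aromatic rings: templates first, planar-cycle fallback for the rest
    frame.rings = []
    by_residue: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(atoms):
        by_residue.setdefault(a.residue_key, []).append(i)
    ligand_templates = getattr(config, "ligand_rings", {}) or {}
    for key, members in by_residue.items():
        resname = key[2].upper()
        name_to_idx = {atoms[i].name: i for i in members}
        template = RING_TEMPLATES.get(resname)
        custom = ligand_templates.get(resname) or ligand_templates.get(key[2])
        if custom:
            template = {str(k): tuple(v) for k, v in custom.items()}
        if template:
            for ring_name, atom_names in template.items():
                idx = [name_to_idx[n] for n in atom_names if n in name_to_idx]
                if len(idx) == len(atom_names):
                    frame.rings.append(Ring(key, ring_name, tuple(idx)))
        else:
            for k, cycle in enumerate(_planar_cycles(atoms, members, adj)):
                frame.rings.append(Ring(key, f"cycle{k}", cycle))
    for ring in frame.rings:
        for i in ring.atom_indices:
            atoms[i].role_flags.add("aromatic-member")
    return frame


def assign_roles_trajectory(traj: Trajectory, config=None) -> Trajectory:
    """Assign roles from frame-0 topology and copy them to every frame.

    Guarantees identical flags and ring definitions across frames even if
    thermal motion perturbs individual bond distances in later snapshots.
    """
    assign_roles(traj.frames[0], config)
    ref = traj.frames[0]
    for fr in traj.frames[1:]:
        for atom, ref_atom in zip(fr.atoms, ref.atoms):
            atom.role_flags = set(ref_atom.role_flags)
        fr.rings = [replace(r) for r in ref.rings]
    return traj
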