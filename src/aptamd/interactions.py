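"""Per-frame geometric detection of non-covalent ligand-receptor interactions.

Four classes are detected, following the PLIP family of geometric criteria:

* hydrogen bonds — donor-acceptor distance and D-H...A angle;
* water-mediated hydrogen bonds — a donor-H...O_water leg plus a
  water...acceptor leg, qualified by the donor angle theta and the angle
  omega at the water oxygen between the donor hydrogen and the acceptor;
* pi-stacking — ring-centroid distance, lateral offset and interplanar
  angle, typed "parallel" or "T-shaped";
* hydrophobic contacts — apolar carbon pairs within a distance cutoff,
  reduced to one contact per (receptor residue, ligand atom).

All thresholds live in :class:`InteractionConfig`; the shipped presets are
published PLIP defaults plus a stricter textbook set for sensitivity checks.
Distances are Angstrom, angles degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import Atom, Frame, Ring, Trajectory, assign_roles, assign_roles_trajectory

__all__ = [
    "InteractionConfig",
    "InteractionRecord",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_pistacking",
    "detect_hydrophobic",
    "fit_ring_plane",
    "profile_trajectory",
    "records_to_dataframe",
    "write_records_tsv",
    "read_records_tsv",
    "RECORD_COLUMNS",
]

INTERACTION_CLASSES = ("hbond", "water_bridge", "pistack", "hydrophobic")

RECORD_COLUMNS = [
    "frame", "class", "chain", "resid", "resname", "rec_atom", "lig_atom",
    "water_id", "d1", "d2", "a1", "a2", "chem_type", "donor_side",
]


@dataclass
class InteractionConfig:
    """Geometric thresholds and atom-classification rules.

    Defaults follow published PLIP criteria (the tool the detection scheme
    mirrors); the ``strict`` preset carries textbook hydrogen-bond values and
    the ``gromacs-like`` preset the conventions of GROMACS ``hbond`` used for
    intramolecular counting.
    """

    hbond_da_max: float = 4.1          # A, donor-acceptor
    hbond_angle_min: float = 100.0     # deg, D-H...A
    hydrophobic_max: float = 4.0       # A, C...C
    pistack_center_max: float = 5.5    # A, centroid-centroid
    pistack_offset_max: float = 2.0    # A, lateral offset
    pistack_parallel_angle_max: float = 30.0       # deg
    pistack_tshape_angle_window: tuple[float, float] = (60.0, 90.0)  # deg
    waterbridge_dist_min: float = 2.5  # A, each bridge leg
    waterbridge_dist_max: float = 4.1  # A
    waterbridge_omega_window: tuple[float, float] = (71.0, 140.0)  # deg at water O
    waterbridge_theta_min: float = 100.0           # deg at donor H
    strict_hydrogens: bool = True
    ligand_rings: dict = field(default_factory=dict)  # resname -> {ring name: [atom names]}

    PRESETS = ("plip-default", "strict", "gromacs-like")

    def __post_init__(self) -> None:
        for name in ("hbond_da_max", "hydrophobic_max", "pistack_center_max",
                     "pistack_offset_max", "waterbridge_dist_min", "waterbridge_dist_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.pistack_tshape_angle_window, self.waterbridge_omega_window):
            if not (0 <= lo < hi <= 180):
                raise ValueError("angle windows must satisfy 0 <= min < max <= 180")
        if self.waterbridge_dist_min >= self.waterbridge_dist_max:
            raise ValueError("waterbridge_dist_min must be below waterbridge_dist_max")
        for name in ("hbond_angle_min", "pistack_parallel_angle_max", "waterbridge_theta_min"):
            if not (0 <= getattr(self, name) <= 180):
                raise ValueError(f"{name} must lie in [0, 180]")
        self.pistack_tshape_angle_window = tuple(self.pistack_tshape_angle_window)
        self.waterbridge_omega_window = tuple(self.waterbridge_omega_window)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "InteractionConfig":
        if name == "plip-default":
            return cls(**overrides)
        if name == "strict":
            params = dict(hbond_da_max=3.5, hbond_angle_min=120.0)
            params.update(overrides)
            return cls(**params)
        if name == "gromacs-like":
            params = dict(hbond_da_max=3.5, hbond_angle_min=150.0)
            params.update(overrides)
            return cls(**params)
        raise ValueError(f"unknown preset {name!r}; available: {cls.PRESETS}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["pistack_tshape_angle_window"] = list(self.pistack_tshape_angle_window)
        payload["waterbridge_omega_window"] = list(self.waterbridge_omega_window)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "InteractionConfig":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        payload = json.loads(text)
        payload["pistack_tshape_angle_window"] = tuple(payload["pistack_tshape_angle_window"])
        payload["waterbridge_omega_window"] = tuple(payload["waterbridge_omega_window"])
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class InteractionRecord:
    """One detected interaction in one frame."""

    frame_index: int
    iclass: str
    receptor_residue: tuple[str, int, str]  # (chain, residue_id, residue_name)
    ligand_atom: str
    receptor_atom: str
    chem_type: str
    donor_side: str                          # receptor | ligand | water | none
    water_id: int | None = None
    distances: dict[str, float] = field(default_factory=dict)
    angles: dict[str, float] = field(default_factory=dict)
    lenient: bool = False
    hydrogen_atom: str = ""  # donor hydrogen name (hbond / water_bridge)

    def __post_init__(self) -> None:
        if (self.water_id is not None) != (self.iclass == "water_bridge"):
            raise ValueError("water_id must be present iff iclass == 'water_bridge'")

    def sort_key(self) -> tuple:
        return (
            self.frame_index,
            INTERACTION_CLASSES.index(self.iclass),
            self.receptor_residue[0],
            self.receptor_residue[1],
            self.ligand_atom,
            self.receptor_atom,
            self.water_id if self.water_id is not None else -1,
        )


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def _bonded_hydrogens(frame: Frame, donor_idx: int) -> list[int]:
    """Hydrogens covalently bonded to a donor heavy atom (X-H <= 1.25 A)."""
    from .model_io import COVALENT_XH_MAX

    d = frame.atoms[donor_idx].coords
    out = []
    for i, a in enumerate(frame.atoms):
        if a.is_hydrogen and _dist(a.coords, d) <= COVALENT_XH_MAX:
            out.append(i)
    return out


def _donors(frame: Frame, part: str) -> list[int]:
    return [i for i in frame.indices(part) if "donor-heavy" in frame.atoms[i].role_flags]


def _acceptors(frame: Frame, part: str) -> list[int]:
    return [i for i in frame.indices(part) if "acceptor" in frame.atoms[i].role_flags]


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def detect_hbonds(
    frame: Frame,
    config: InteractionConfig,
    between: tuple[str, str] = ("ligand", "receptor"),
    exclude_same_residue: bool | None = None,
) -> list[InteractionRecord]:
    """Hydrogen bonds between two partitions of one frame.

    Donors are taken from both partitions, acceptors from the opposite one.
    Each donor hydrogen is paired with at most its nearest qualifying
    acceptor (ties broken by lower atom serial).  With identical partitions
    (intramolecular counting) same-residue pairs are excluded by default.
    """
    part_a, part_b = between
    if not frame.indices(part_a) or not frame.indices(part_b):
        raise ValueError(f"partition(s) {between} empty; nothing to detect")
    if exclude_same_residue is None:
        exclude_same_residue = part_a == part_b
    records: list[InteractionRecord] = []
    sides = [(part_a, part_b)] if part_a == part_b else [(part_a, part_b), (part_b, part_a)]
    for donor_part, acceptor_part in sides:
        acc = _acceptors(frame, acceptor_part)
        if not acc:
            continue
        acc_xyz = np.array([frame.atoms[i].coords for i in acc])
        for d_idx in _donors(frame, donor_part):
            d_atom = frame.atoms[d_idx]
            hydrogens = _bonded_hydrogens(frame, d_idx)
            if config.strict_hydrogens and not hydrogens:
                continue
            dists = np.linalg.norm(acc_xyz - d_atom.coords, axis=1)
            h_list = hydrogens if hydrogens else [None]
            for h_idx in h_list:
                best: tuple[float, int, int] | None = None  # (dist, serial, acc index)
                for k, a_idx in enumerate(acc):
                    if a_idx == d_idx:
                        continue
                    a_atom = frame.atoms[a_idx]
                    if exclude_same_residue and a_atom.residue_key == d_atom.residue_key:
                        continue
                    da = float(dists[k])
                    if da > config.hbond_da_max or da < 1e-6:
                        continue
                    if h_idx is not None:
                        ang = _angle(d_atom.coords, frame.atoms[h_idx].coords, a_atom.coords)
                        if ang < config.hbond_angle_min:
                            continue
                    cand = (da, a_atom.serial, a_idx)
                    if best is None or cand < best:
                        best = cand
                if best is None:
                    continue
                da, _, a_idx = best
                a_atom = frame.atoms[a_idx]
                lenient = h_idx is None
                ang = (
                    _angle(d_atom.coords, frame.atoms[h_idx].coords, a_atom.coords)
                    if h_idx is not None
                    else float("nan")
                )
                ha = _dist(frame.atoms[h_idx].coords, a_atom.coords) if h_idx is not None else float("nan")
                if donor_part == "ligand":
                    rec_res, lig_atom, rec_atom, side = a_atom.residue_key, d_atom.name, a_atom.name, "ligand"
                elif acceptor_part == "ligand":
                    rec_res, lig_atom, rec_atom, side = d_atom.residue_key, a_atom.name, d_atom.name, "receptor"
                else:  # intramolecular: acceptor defines the "receptor" residue
                    rec_res, lig_atom, rec_atom, side = a_atom.residue_key, d_atom.name, a_atom.name, "receptor"
                records.append(
                    InteractionRecord(
                        frame_index=frame.index,
                        iclass="hbond",
                        receptor_residue=rec_res,
                        ligand_atom=lig_atom,
                        receptor_atom=rec_atom,
                        chem_type=f"{d_atom.element}–H⋯{a_atom.element}",
                        donor_side=side,
                        distances={"D-A": da, "H-A": ha},
                        angles={"D-H-A": ang},
                        lenient=lenient,
                        hydrogen_atom=frame.atoms[h_idx].name if h_idx is not None else "",
                    )
                )
    records.sort(key=InteractionRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# Water bridges
# ---------------------------------------------------------------------------

def detect_water_bridges(frame: Frame, config: InteractionConfig) -> list[InteractionRecord]:
    """Water-mediated hydrogen bonds between ligand and receptor.

    One record per (donor, water oxygen, acceptor) triple with the donor on
    one side and the acceptor on the other, both legs inside the bridge
    distance window, theta = angle D-H...O_w at the donor hydrogen above its
    minimum, and omega = angle (H_donor, O_w, acceptor) at the water oxygen
    inside its window.
    """
    waters = [i for i in frame.indices("water") if "water-oxygen" in frame.atoms[i].role_flags]
    if not waters:
        return []
    lo, hi = config.waterbridge_dist_min, config.waterbridge_dist_max
    om_lo, om_hi = config.waterbridge_omega_window
    records: list[InteractionRecord] = []
    for donor_part, acceptor_part in (("ligand", "receptor"), ("receptor", "ligand")):
        donors = _donors(frame, donor_part)
        acceptors = _acceptors(frame, acceptor_part)
        if not donors or not acceptors:
            continue
        for w_idx in waters:
            w = frame.atoms[w_idx].coords
            for d_idx in donors:
                d_atom = frame.atoms[d_idx]
                d1 = _dist(d_atom.coords, w)
                if not (lo <= d1 <= hi):
                    continue
                hydrogens = _bonded_hydrogens(frame, d_idx)
                if config.strict_hydrogens and not hydrogens:
                    continue
                for a_idx in acceptors:
                    a_atom = frame.atoms[a_idx]
                    d2 = _dist(w, a_atom.coords)
                    if not (lo <= d2 <= hi):
                        continue
                    lenient = not hydrogens
                    theta = omega = float("nan")
                    h_name = ""
                    if hydrogens:
                        ok = False
                        for h_idx in hydrogens:
                            h = frame.atoms[h_idx].coords
                            th = _angle(d_atom.coords, h, w)
                            if th < config.waterbridge_theta_min:
                                continue
                            om = _angle(h, w, a_atom.coords)
                            if not (om_lo <= om <= om_hi):
                                continue
                            theta, omega, ok = th, om, True
                            h_name = frame.atoms[h_idx].name
                            break
                        if not ok:
                            continue
                    if donor_part == "ligand":
                        rec_res, lig_atom, rec_atom = a_atom.residue_key, d_atom.name, a_atom.name
                    else:
                        rec_res, lig_atom, rec_atom = d_atom.residue_key, a_atom.name, d_atom.name
                    records.append(
                        InteractionRecord(
                            frame_index=frame.index,
                            iclass="water_bridge",
                            receptor_residue=rec_res,
                            ligand_atom=lig_atom,
                            receptor_atom=rec_atom,
                            chem_type=f"{d_atom.element}–H⋯O–H⋯{a_atom.element}",
                            donor_side=donor_part,
                            water_id=frame.atoms[w_idx].residue_id,
                            distances={"D-Ow": d1, "Ow-A": d2},
                            angles={"theta": theta, "omega": omega},
                            lenient=lenient,
                            hydrogen_atom=h_name,
                        )
                    )
    records.sort(key=InteractionRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# Pi-stacking
# ---------------------------------------------------------------------------

def fit_ring_plane(atoms: Sequence[Atom] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a ring: (centroid, unit normal).

    The normal is sign-canonicalized toward +z, ties broken toward +x then
    +y.  Raises ``ValueError`` for fewer than three or collinear atoms.
    """
    if isinstance(atoms, np.ndarray):
        xyz = np.asarray(atoms, dtype=float)
    else:
        xyz = np.array([a.coords for a in atoms], dtype=float)
    if xyz.shape[0] < 3:
        raise ValueError("ring plane needs at least 3 atoms")
    centroid = xyz.mean(axis=0)
    centered = xyz - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("collinear atoms: ring plane undefined")
    normal = vt[2]
    tol = 1e-10
    if normal[2] < -tol:
        normal = -normal
    elif abs(normal[2]) <= tol:
        if normal[0] < -tol or (abs(normal[0]) <= tol and normal[1] < 0):
            normal = -normal
    return centroid, normal / np.linalg.norm(normal)


def _ring_geometry(frame: Frame, ring: Ring) -> tuple[np.ndarray, np.ndarray]:
    return fit_ring_plane(np.array([frame.atoms[i].coords for i in ring.atom_indices]))


def detect_pistacking(frame: Frame, config: InteractionConfig) -> list[InteractionRecord]:
    """Pi-stacking between ligand and receptor aromatic rings.

    A ring pair stacks when the centroid distance and the lateral offset
    (minimum of each centroid's in-plane projection distance onto the other
    ring) are inside their maxima and the interplanar angle is either small
    (parallel) or near perpendicular (T-shaped).
    """
    lig_idx = set(frame.indices("ligand"))
    rec_idx = set(frame.indices("receptor"))
    lig_rings = [r for r in frame.rings if set(r.atom_indices) <= lig_idx]
    rec_rings = [r for r in frame.rings if set(r.atom_indices) <= rec_idx]
    records: list[InteractionRecord] = []
    for lring in lig_rings:
        lc, ln = _ring_geometry(frame, lring)
        for rring in rec_rings:
            rc, rn = _ring_geometry(frame, rring)
            d = _dist(lc, rc)
            if d > config.pistack_center_max:
                continue
            sep = rc - lc
            off_l = float(np.linalg.norm(sep - np.dot(sep, ln) * ln))
            off_r = float(np.linalg.norm(-sep - np.dot(-sep, rn) * rn))
            offset = min(off_l, off_r)
            if offset > config.pistack_offset_max:
                continue
            ang = float(np.degrees(np.arccos(np.clip(abs(np.dot(ln, rn)), 0.0, 1.0))))
            if ang <= config.pistack_parallel_angle_max:
                chem = "parallel"
            elif config.pistack_tshape_angle_window[0] <= ang <= config.pistack_tshape_angle_window[1]:
                chem = "T-shaped"
            else:
                continue
            records.append(
                InteractionRecord(
                    frame_index=frame.index,
                    iclass="pistack",
                    receptor_residue=rring.residue_key,
                    ligand_atom=lring.name,
                    receptor_atom=rring.name,
                    chem_type=chem,
                    donor_side="none",
                    distances={"centroid": d, "offset": offset},
                    angles={"planes": ang},
                )
            )
    records.sort(key=InteractionRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# Hydrophobic contacts
# ---------------------------------------------------------------------------

def detect_hydrophobic(frame: Frame, config: InteractionConfig) -> list[InteractionRecord]:
    """Apolar carbon contacts, one record per (receptor residue, ligand atom).

    All (ligand hydrophobic C, receptor hydrophobic C) pairs within the
    cutoff are reduced to the minimum-distance pair per group, ties broken by
    lower receptor atom serial.
    """
    lig = [i for i in frame.indices("ligand") if "hydrophobic-carbon" in frame.atoms[i].role_flags]
    rec = [i for i in frame.indices("receptor") if "hydrophobic-carbon" in frame.atoms[i].role_flags]
    best: dict[tuple, tuple[float, int, int]] = {}
    for li in lig:
        lcoord = frame.atoms[li].coords
        for ri in rec:
            r_atom = frame.atoms[ri]
            d = _dist(lcoord, r_atom.coords)
            if d > config.hydrophobic_max:
                continue
            key = (r_atom.residue_key, frame.atoms[li].name)
            cand = (d, r_atom.serial, ri)
            if key not in best or cand < best[key]:
                best[key] = cand
    records = []
    for (rec_res, lig_name), (d, _, ri) in best.items():
        records.append(
            InteractionRecord(
                frame_index=frame.index,
                iclass="hydrophobic",
                receptor_residue=rec_res,
                ligand_atom=lig_name,
                receptor_atom=frame.atoms[ri].name,
                chem_type="C⋯C",
                donor_side="none",
                distances={"C-C": d},
            )
        )
    records.sort(key=InteractionRecord.sort_key)
    return records


# ---------------------------------------------------------------------------
# Trajectory-level profiling
# ---------------------------------------------------------------------------

def profile_frame(frame: Frame, config: InteractionConfig) -> list[InteractionRecord]:
    """All four detectors on one frame (roles must already be assigned)."""
    records: list[InteractionRecord] = []
    if frame.indices("ligand") and frame.indices("receptor"):
        records += detect_hbonds(frame, config, ("ligand", "receptor"))
        records += detect_water_bridges(frame, config)
        records += detect_pistacking(frame, config)
        records += detect_hydrophobic(frame, config)
    records.sort(key=InteractionRecord.sort_key)
    return records


def profile_trajectory(traj: Trajectory, config: InteractionConfig | None = None) -> list[InteractionRecord]:
    """Ligand-receptor interaction records over all frames, in a
    deterministic (frame, class, residue, atom) order."""
    if config is None:
        config = InteractionConfig()
    assign_roles_trajectory(traj, config)
    records: list[InteractionRecord] = []
    for fr in traj.frames:
        records += profile_frame(fr, config)
    return records


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

_D1 = {"hbond": "D-A", "water_bridge": "D-Ow", "pistack": "centroid", "hydrophobic": "C-C"}
_D2 = {"hbond": "H-A", "water_bridge": "Ow-A", "pistack": "offset"}
_A1 = {"hbond": "D-H-A", "water_bridge": "theta", "pistack": "planes"}
_A2 = {"water_bridge": "omega"}


def records_to_dataframe(records: Iterable[InteractionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "frame": r.frame_index,
                "class": r.iclass,
                "chain": r.receptor_residue[0],
                "resid": r.receptor_residue[1],
                "resname": r.receptor_residue[2],
                "rec_atom": r.receptor_atom,
                "lig_atom": r.ligand_atom,
                "water_id": r.water_id if r.water_id is not None else "",
                "d1": round(r.distances.get(_D1.get(r.iclass, ""), float("nan")), 4),
                "d2": round(r.distances.get(_D2.get(r.iclass, ""), float("nan")), 4),
                "a1": round(r.angles.get(_A1.get(r.iclass, ""), float("nan")), 2),
                "a2": round(r.angles.get(_A2.get(r.iclass, ""), float("nan")), 2),
                "chem_type": r.chem_type,
                "donor_side": r.donor_side,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_tsv(records: Iterable[InteractionRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_dataframe(records).to_csv(path, sep="\t", index=False)
    return path


def read_records_tsv(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"water_id": "object"})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file {path} lacks columns: {sorted(missing)}")
    out: list[InteractionRecord] = []
    for row in df.to_dict("records"):
        iclass = str(row["class"])
        wid = row["water_id"]
        water_id = (
            int(float(wid))
            if iclass == "water_bridge" and wid not in ("", None) and not pd.isna(wid)
            else None
        )
        distances, angles = {}, {}
        if iclass in _D1 and not pd.isna(row["d1"]):
            distances[_D1[iclass]] = float(row["d1"])
        if iclass in _D2 and not pd.isna(row["d2"]):
            distances[_D2[iclass]] = float(row["d2"])
        if iclass in _A1 and not pd.isna(row["a1"]):
            angles[_A1[iclass]] = float(row["a1"])
        if iclass in _A2 and not pd.isna(row["a2"]):
            angles[_A2[iclass]] = float(row["a2"])
        out.append(
            InteractionRecord(
                frame_index=int(row["frame"]),
                iclass=iclass,
                receptor_residue=(str(row["chain"]), int(row["resid"]), str(row["resname"])),
                ligand_atom=str(row["lig_atom"]),
                receptor_atom=str(row["rec_atom"]),
                chem_type=str(row["chem_type"]),
                donor_side=str(row["donor_side"]),
                water_id=water_id,
                distances=distances,
                angles=angles,
            )
        )
    return out
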