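"""Synthetic receptor-ligand-water test systems with planted interactions.

The generator builds small, geometrically exact complexes: a diol ligand
with one aromatic ring (an estradiol mimic with hydroxyl anchors ``O3`` and
``O17``), nucleobase residues approaching it along separated axes, and
optional decoy waters.  Each planted interaction satisfies its class's
default detection thresholds with at least a 10% margin, and in frames
where it is switched off the partner is retracted far beyond threshold, so
profiling the trajectory must recover exactly the planted (class, frame)
multiset — no false positives, no false negatives.

These are geometric test articles, not physically realistic DNA dynamics:
residues are bare bases on idealized ring templates, and frame-to-frame
motion is rigid-body (plus optional Gaussian jitter) rather than simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .interactions import InteractionConfig, profile_trajectory
from .model_io import Atom, Frame, Trajectory, infer_element, write_pdb_trajectory

__all__ = [
    "FixtureSpec",
    "PlantedInteraction",
    "FixtureError",
    "make_complex",
    "make_rigid_trajectory",
    "make_paired_helix",
    "default_fixture_config",
    "default_param_table",
    "random_rigid_transforms",
]


class FixtureError(ValueError):
    """Infeasible fixture request (conflicting or unverifiable planting)."""


def default_fixture_config(**overrides) -> InteractionConfig:
    """Detector config matching the fixture ligand (ring template for EST)."""
    cfg = InteractionConfig(
        ligand_rings={"EST": {"A-ring": ["C1", "C2", "C3", "C4", "C5", "C10"]}},
        **overrides,
    )
    return cfg


# ---------------------------------------------------------------------------
# Templates (local coordinates, Angstrom; rings in the local xy-plane)
# ---------------------------------------------------------------------------

def _hexagon(names_at_deg: dict[str, float], radius: float = 1.39) -> dict[str, np.ndarray]:
    out = {}
    for name, deg in names_at_deg.items():
        th = math.radians(deg)
        out[name] = np.array([radius * math.cos(th), radius * math.sin(th), 0.0])
    return out


def _radial(deg: float, r: float, z: float = 0.0) -> np.ndarray:
    th = math.radians(deg)
    return np.array([r * math.cos(th), r * math.sin(th), z])


def _pyrimidine(extra: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    ring = _hexagon({"N1": 270, "C2": 330, "N3": 30, "C4": 90, "C5": 150, "C6": 210})
    ring.update(extra)
    return ring


def _thymine() -> dict[str, np.ndarray]:
    t = _pyrimidine(
        {
            "O2": _radial(330, 2.61),
            "H3": _radial(30, 2.42),
            "O4": _radial(90, 2.61),
            "C7": _radial(150, 2.89),
            "H6": _radial(210, 2.47),
            "H1": _radial(270, 2.42),
        }
    )
    # methyl hydrogens slightly out of plane
    for i, dz in enumerate((0.9, -0.45, -0.45)):
        dxy = 0.62 if dz < 0 else 0.0
        t[f"H7{i + 1}"] = t["C7"] + _radial(150 + (0 if dz > 0 else (60 if i == 1 else -60)), dxy, dz)
    return t


def _cytosine() -> dict[str, np.ndarray]:
    return _pyrimidine(
        {
            "O2": _radial(330, 2.61),
            "N4": _radial(90, 2.74),
            "H41": _radial(80, 3.70),
            "H42": _radial(100, 3.70),
            "H5": _radial(150, 2.47),
            "H6": _radial(210, 2.47),
            "H1": _radial(270, 2.42),
        }
    )


def _purine(extra: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    ring = _hexagon({"N1": 90, "C2": 150, "N3": 210, "C4": 270, "C5": 330, "C6": 30})
    # regular pentagon fused on the C4-C5 edge, outside the hexagon
    c4, c5 = ring["C4"], ring["C5"]
    mid = (c4 + c5) / 2
    u = (c5 - c4) / np.linalg.norm(c5 - c4)
    n = np.array([u[1], -u[0], 0.0])
    if np.dot(n, mid) < 0:
        n = -n
    side = 1.39
    apothem = side / (2 * math.tan(math.pi / 5))
    circum = side / (2 * math.sin(math.pi / 5))
    center = mid + apothem * n
    ang_c4 = math.atan2(c4[1] - center[1], c4[0] - center[0])
    step = 2 * math.pi / 5
    ring["N9"] = center + circum * np.array([math.cos(ang_c4 + step), math.sin(ang_c4 + step), 0.0])
    ring["C8"] = center + circum * np.array([math.cos(ang_c4 + 2 * step), math.sin(ang_c4 + 2 * step), 0.0])
    ring["N7"] = center + circum * np.array([math.cos(ang_c4 + 3 * step), math.sin(ang_c4 + 3 * step), 0.0])
    ring["H8"] = ring["C8"] + 1.08 * (ring["C8"] - center) / np.linalg.norm(ring["C8"] - center)
    ring["H9"] = ring["N9"] + 1.01 * (ring["N9"] - center) / np.linalg.norm(ring["N9"] - center)
    ring.update(extra)
    return ring


def _adenine() -> dict[str, np.ndarray]:
    return _purine(
        {
            "N6": _radial(30, 2.74),
            "H61": _radial(22, 3.72),
            "H62": _radial(38, 3.72),
            "H2": _radial(150, 2.47),
        }
    )


def _guanine() -> dict[str, np.ndarray]:
    return _purine(
        {
            "O6": _radial(30, 2.61),
            "H1": _radial(90, 2.42),
            "N2": _radial(150, 2.74),
            "H21": _radial(142, 3.72),
            "H22": _radial(158, 3.72),
        }
    )


BASE_TEMPLATES = {"DT": _thymine(), "DC": _cytosine(), "DA": _adenine(), "DG": _guanine()}

# Estradiol-mimic ligand: aromatic A-ring with a 3-hydroxyl, aliphatic chain
# to a 17-hydroxyl, and a methyl branch as a hydrophobic probe.
_LIGAND_TEMPLATE: dict[str, np.ndarray] = {
    **_hexagon({"C3": 180, "C2": 120, "C1": 60, "C10": 0, "C5": 300, "C4": 240}),
    "O3": np.array([-2.75, 0.0, 0.0]),
    "HO3": np.array([-3.71, 0.0, 0.0]),
    "H1": _radial(60, 2.47),
    "H2": _radial(120, 2.47),
    "H4": _radial(240, 2.47),
    "C9": np.array([2.84, 0.40, 0.0]),
    "C11": np.array([4.29, 0.00, 0.0]),
    "C13": np.array([5.74, 0.40, 0.0]),
    "C16": np.array([7.19, 0.00, 0.0]),
    "C17": np.array([8.64, 0.40, 0.0]),
    "O17": np.array([8.64, 1.83, 0.0]),
    "HO17": np.array([8.64, 2.79, 0.0]),
    "C18": np.array([5.74, -1.13, 0.0]),
}

_WATER_TEMPLATE = {
    "OW": np.array([0.0, 0.0, 0.0]),
    "HW1": np.array([0.96, 0.0, 0.0]),
    "HW2": np.array([-0.24, 0.0, 0.93]),
}


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation mapping unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:  # antiparallel: rotate 180 deg about a fixed perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _rot_z(deg: float) -> np.ndarray:
    th = math.radians(deg)
    return np.array(
        [[math.cos(th), -math.sin(th), 0], [math.sin(th), math.cos(th), 0], [0, 0, 1]]
    )


def _place_residue(
    template: dict[str, np.ndarray],
    probe: str,
    target: np.ndarray,
    approach: np.ndarray,
    spin: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Rigidly place a template so its probe atom sits at ``target`` and the
    residue body extends along ``approach`` (unit vector away from target)."""
    local = dict(template)
    if spin is not None:
        local = {k: spin @ v for k, v in local.items()}
    probe_dir = local[probe] / np.linalg.norm(local[probe])
    rot = _rotation_between(-probe_dir, approach / np.linalg.norm(approach))
    placed = {k: rot @ v for k, v in local.items()}
    shift = target - placed[probe]
    return {k: v + shift for k, v in placed.items()}


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

# per class: (partner template, probe atom, target point, approach direction,
#             retraction direction for "off" frames)
_PLANT_GEOMETRY: dict[str, dict] = {
    "hbond": dict(
        resname="DC",
        probe="O2",
        distance=2.9,       # D-A, vs max 4.1 (planted <= 3.69 for the 10% margin)
    ),
    "water_bridge": dict(
        resname="DG",
        probe="O6",
        distance=2.8,       # each leg, window 2.5-4.1 (margin band 2.75-3.69)
        omega=115.0,        # window 71-140 (margin band 78.1-126)
    ),
    "pistack": dict(
        resname="DT",
        distance=4.6,       # centroid, vs max 5.5; also > 4.4 so stacked-ring
                            # carbons stay clear of the hydrophobic cutoff
    ),
    "hydrophobic": dict(
        resname="DT",
        probe="C7",
        distance=3.5,       # C-C, vs max 4.0 (margin bound 3.6)
    ),
}

_RETRACT = 10.0  # A, partner pull-back in "off" frames


@dataclass
class PlantedInteraction:
    """One planted interaction: class and the frames it is present in."""

    iclass: str
    frames: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.iclass not in _PLANT_GEOMETRY:
            raise FixtureError(f"cannot plant interaction class {self.iclass!r}")
        self.frames = tuple(int(f) for f in self.frames)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic complex trajectory (deterministic given seed)."""

    seed: int = 0
    n_frames: int = 1
    planted: list[PlantedInteraction] = field(default_factory=list)
    n_decoy_waters: int = 0
    extra_residues: int = 0
    rigid_motion: bool = False
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        classes = [p.iclass for p in self.planted]
        if len(classes) != len(set(classes)):
            raise FixtureError("at most one planted interaction per class (one partner slot each)")
        for p in self.planted:
            if any(f < 0 or f >= self.n_frames for f in p.frames):
                raise FixtureError("planted frames outside trajectory range")

    @classmethod
    def from_json(cls, source: str | Path) -> "FixtureSpec":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        payload = json.loads(text)
        planted = [PlantedInteraction(p["iclass"], tuple(p["frames"])) for p in payload.pop("planted", [])]
        return cls(planted=planted, **payload)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "planted": [{"iclass": p.iclass, "frames": list(p.frames)} for p in self.planted],
            "n_decoy_waters": self.n_decoy_waters,
            "extra_residues": self.extra_residues,
            "rigid_motion": self.rigid_motion,
            "noise_sigma": self.noise_sigma,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _partner_coords(iclass: str) -> tuple[dict[str, np.ndarray], np.ndarray, list[dict[str, np.ndarray]]]:
    """Partner residue coordinates in the 'on' state, the retraction vector,
    and any companion molecules (the bridge water)."""
    geo = _PLANT_GEOMETRY[iclass]
    template = BASE_TEMPLATES[geo["resname"]]
    lig = _LIGAND_TEMPLATE
    if iclass == "hbond":
        # acceptor O2 collinear with the ligand O3-H donor, along -x
        target = lig["O3"] + geo["distance"] * np.array([-1.0, 0.0, 0.0])
        coords = _place_residue(template, geo["probe"], target, np.array([-1.0, 0.0, 0.0]))
        return coords, np.array([-_RETRACT, 0.0, 0.0]), []
    if iclass == "water_bridge":
        d = geo["distance"]
        water_o = lig["O17"] + d * np.array([0.0, 1.0, 0.0])
        water = {k: v + water_o for k, v in _WATER_TEMPLATE.items()}
        omega = math.radians(geo["omega"])
        # acceptor direction at omega degrees from the water->donor-H vector
        acc_dir = np.array([math.sin(omega), -math.cos(omega), 0.0])
        target = water_o + d * acc_dir
        coords = _place_residue(template, geo["probe"], target, acc_dir)
        return coords, _RETRACT * np.array([0.0, 1.0, 0.0]), [water]
    if iclass == "pistack":
        # parallel stack above the ligand A-ring; methyl spun toward +x,
        # away from the O3 hydroxyl
        coords = {k: _rot_z(-150.0) @ v + np.array([0.0, 0.0, geo["distance"]]) for k, v in template.items()}
        return coords, np.array([0.0, 0.0, _RETRACT]), []
    if iclass == "hydrophobic":
        target = lig["C18"] + geo["distance"] * np.array([0.0, -1.0, 0.0])
        coords = _place_residue(template, geo["probe"], target, np.array([0.0, -1.0, 0.0]))
        return coords, np.array([0.0, -_RETRACT, 0.0]), []
    raise FixtureError(iclass)


def _assert_margins() -> None:
    """Static sanity check that planted numbers keep their 10% safety bands."""
    cfg = InteractionConfig()
    g = _PLANT_GEOMETRY
    assert g["hbond"]["distance"] <= 0.9 * cfg.hbond_da_max
    assert 1.1 * cfg.waterbridge_dist_min <= g["water_bridge"]["distance"] <= 0.9 * cfg.waterbridge_dist_max
    lo, hi = cfg.waterbridge_omega_window
    assert 1.1 * lo <= g["water_bridge"]["omega"] <= 0.9 * hi
    assert g["pistack"]["distance"] <= 0.9 * cfg.pistack_center_max
    assert g["pistack"]["distance"] >= 1.1 * cfg.hydrophobic_max
    assert g["hydrophobic"]["distance"] <= 0.9 * cfg.hydrophobic_max


_assert_margins()


def _atoms_from_coords(
    coords: dict[str, np.ndarray], resname: str, resid: int, chain: str, serial_start: int
) -> list[Atom]:
    atoms = []
    for i, (name, xyz) in enumerate(sorted(coords.items())):
        atoms.append(
            Atom(
                serial=serial_start + i,
                name=name,
                element=infer_element(name, resname),
                residue_name=resname,
                residue_id=resid,
                chain=chain,
                coords=np.array(xyz, dtype=float),
            )
        )
    return atoms


def random_rigid_transforms(n: int, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """n random (rotation, translation) pairs; translations within +-5 A."""
    from scipy.spatial.transform import Rotation

    out = []
    for _ in range(n):
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-5.0, 5.0, size=3)
        out.append((rot, trans))
    return out


def make_complex(spec: FixtureSpec, validate: bool = True) -> Trajectory:
    """Build the synthetic complex trajectory described by ``spec``.

    Deterministic given the seed.  With ``validate`` (default) the result is
    profiled with the default config and must reproduce exactly the planted
    (class, frame) multiset, else :class:`FixtureError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    lig_coords = {k: np.array(v) for k, v in _LIGAND_TEMPLATE.items()}

    partner_on: list[tuple[PlantedInteraction, dict, np.ndarray, list]] = []
    for planted in spec.planted:
        coords, retract, companions = _partner_coords(planted.iclass)
        partner_on.append((planted, coords, retract, companions))

    # static topology: receptor partners, extra inert residues, ligand, waters
    atom_specs: list[tuple[str, str, int, str]] = []  # bookkeeping only

    def build_frame(findex: int) -> list[Atom]:
        serial = 1
        atoms: list[Atom] = []
        resid = 1
        for planted, coords, retract, companions in partner_on:
            on = findex in planted.frames
            shift = np.zeros(3) if on else retract
            placed = {k: v + shift for k, v in coords.items()}
            res_atoms = _atoms_from_coords(placed, _PLANT_GEOMETRY[planted.iclass]["resname"], resid, "A", serial)
            atoms += res_atoms
            serial += len(res_atoms)
            resid += 1
        for k in range(spec.extra_residues):
            resname = ("DA", "DT", "DG", "DC")[k % 4]
            center = np.array([k * 12.0 - 12.0, 25.0, 0.0])
            placed = {n: v + center for n, v in BASE_TEMPLATES[resname].items()}
            res_atoms = _atoms_from_coords(placed, resname, resid, "A", serial)
            atoms += res_atoms
            serial += len(res_atoms)
            resid += 1
        lig_atoms = _atoms_from_coords(lig_coords, "EST", resid, "B", serial)
        atoms += lig_atoms
        serial += len(lig_atoms)
        resid += 1
        for planted, coords, retract, companions in partner_on:
            on = findex in planted.frames
            shift = np.zeros(3) if on else retract
            for comp in companions:
                placed = {k: v + shift for k, v in comp.items()}
                res_atoms = _atoms_from_coords(placed, "HOH", resid, "W", serial)
                atoms += res_atoms
                serial += len(res_atoms)
                resid += 1
        return atoms, serial, resid

    # decoy water positions: fixed across frames, drawn once, kept >= 6 A
    # from every non-decoy atom of every frame state (on and off)
    ref_points = []
    for state_frame in ({p.frames[0] if p.frames else 0 for p, *_ in partner_on} | {-1}):
        frame_atoms, _, _ = build_frame(state_frame if state_frame >= 0 else -1)
        ref_points.append(np.array([a.coords for a in frame_atoms]))
    ref_points = np.vstack(ref_points) if ref_points else np.zeros((0, 3))
    decoys = []
    attempts = 0
    while len(decoys) < spec.n_decoy_waters:
        attempts += 1
        if attempts > 1000 * max(spec.n_decoy_waters, 1):
            raise FixtureError("cannot place decoy waters with 6 A clearance")
        pos = rng.uniform(-30.0, 40.0, size=3)
        pts = ref_points if not decoys else np.vstack([ref_points, np.array(decoys)])
        if pts.size and np.min(np.linalg.norm(pts - pos, axis=1)) < 6.0:
            continue
        decoys.append(pos)

    transforms = (
        random_rigid_transforms(spec.n_frames, rng)
        if spec.rigid_motion
        else [(np.eye(3), np.zeros(3))] * spec.n_frames
    )

    frames: list[Frame] = []
    partition: dict[str, frozenset[int]] | None = None
    for findex in range(spec.n_frames):
        atoms, serial, resid = build_frame(findex)
        for d, pos in enumerate(decoys):
            placed = {k: v + pos for k, v in _WATER_TEMPLATE.items()}
            datoms = _atoms_from_coords(placed, "HOH", resid + d, "W", serial)
            atoms += datoms
            serial += len(datoms)
        rot, trans = transforms[findex]
        xyz = np.array([a.coords for a in atoms]) @ rot.T + trans
        if spec.noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sigma, size=xyz.shape)
        for a, row in zip(atoms, xyz):
            a.coords = row
        if partition is None:
            from .model_io import _partition_indices

            partition = _partition_indices(
                atoms, frozenset({"EST"}), frozenset({"HOH"})
            )
        frames.append(Frame(index=findex, atoms=atoms, partition=partition))
    traj = Trajectory(frames=frames)

    if validate and spec.noise_sigma == 0.0:
        expected = sorted((p.iclass, f) for p in spec.planted for f in p.frames)
        config = default_fixture_config()
        found = sorted((r.iclass, r.frame_index) for r in profile_trajectory(traj, config))
        if found != expected:
            raise FixtureError(
                f"planting not recoverable: expected {expected}, detected {found}"
            )
    return traj


def write_fixture(spec: FixtureSpec, path: str | Path) -> Path:
    traj = make_complex(spec)
    return write_pdb_trajectory(traj, path, remarks=[f"aptamd fixture seed={spec.seed}"])


def make_rigid_trajectory(
    base_frame: Frame,
    transforms: Sequence[tuple[np.ndarray, np.ndarray]],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Frames = rigid transforms of a base frame plus optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    base_xyz = base_frame.coords
    frames = []
    for i, (rot, trans) in enumerate(transforms):
        xyz = base_xyz @ np.asarray(rot).T + np.asarray(trans)
        if noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, noise_sigma, size=xyz.shape)
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_id, a.chain, row)
            for a, row in zip(base_frame.atoms, xyz)
        ]
        frames.append(Frame(index=i, atoms=atoms, partition=base_frame.partition))
    return Trajectory(frames=frames)


def make_paired_helix(n_pairs: int = 6, n_frames: int = 1, separation: float = 0.0) -> Trajectory:
    """Receptor-only fixture with Watson-Crick-like geometry base pairs.

    Each pair carries exactly two near-linear N-H...O hydrogen bonds at
    2.9 A donor-acceptor distance, so the intramolecular count per frame is
    ``2 * n_pairs``.  ``separation`` pulls the strands apart (20 A breaks
    every bond).
    """
    frames = []
    for findex in range(n_frames):
        atoms: list[Atom] = []
        serial = 1
        for k in range(n_pairs):
            z = 10.0 * k
            sep = np.array([separation, 0.0, 0.0])
            left = {
                "N1": np.array([0.0, 0.0, z]),
                "H1": np.array([1.0, 0.0, z]),
                "O2": np.array([0.0, -2.0, z]),
            }
            right = {
                "O4": np.array([2.9, 0.0, z]) + sep,
                "N3": np.array([2.9, -2.0, z]) + sep,
                "H3": np.array([1.9, -2.0, z]) + sep,
            }
            for resname, rid, coords in (("DA", 2 * k + 1, left), ("DT", 2 * k + 2, right)):
                res_atoms = _atoms_from_coords(coords, resname, rid, "A", serial)
                atoms += res_atoms
                serial += len(res_atoms)
        partition = {
            "receptor": frozenset(range(len(atoms))),
            "ligand": frozenset(),
            "water": frozenset(),
            "ion": frozenset(),
        }
        frames.append(Frame(index=findex, atoms=atoms, partition=partition))
    return Trajectory(frames=frames)


def default_param_table():
    """Toy charge/LJ parameters covering every fixture atom type (TSV-ready).

    Charges are chemically plausible signs (polar O/N negative, their
    hydrogens positive, carbons slightly positive); LJ values are generic
    element classes in GROMACS units (sigma nm, epsilon kJ/mol).
    """
    import pandas as pd

    from .energy import ParamTable

    by_element = {
        "O": (-0.50, 0.296, 0.879),
        "N": (-0.40, 0.325, 0.711),
        "C": (0.12, 0.340, 0.457),
        "H": (0.30, 0.107, 0.066),
    }
    rows = []
    for resname, template in list(BASE_TEMPLATES.items()) + [("EST", _LIGAND_TEMPLATE), ("HOH", _WATER_TEMPLATE)]:
        for atom in template:
            elem = infer_element(atom, resname)
            q, s, e = by_element[elem]
            rows.append({"resname": resname, "atom": atom, "charge": q, "sigma": s, "epsilon": e})
    return ParamTable(pd.DataFrame(rows))
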