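"""Shared fixtures and independent brute-force oracles for the test suite.

The oracle functions re-derive each detector's output by plain exhaustive
enumeration of candidate tuples with the thresholds applied literally; they
share no code with the detectors beyond numpy.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from aptamd.interactions import InteractionConfig
from aptamd.model_io import Atom, Frame

XH_MAX = 1.25  # covalent X-H attachment rule, mirrored from the I/O contract


@pytest.fixture
def config() -> InteractionConfig:
    return InteractionConfig()


# ---------------------------------------------------------------------------
# Random polar/apolar frame builder
# ---------------------------------------------------------------------------

def _atom(serial, name, element, resname, resid, chain, xyz, flags=()):
    a = Atom(serial, name, element, resname, resid, chain, np.asarray(xyz, float))
    a.role_flags = set(flags)
    return a


def random_polar_frame(
    rng: np.random.Generator,
    n_lig: int = 4,
    n_rec: int = 10,
    n_wat: int = 6,
    box: float = 10.0,
    with_hydrophobic: bool = False,
) -> Frame:
    """Random donors (O with one H), acceptors, waters and optionally apolar
    carbons in a cubic box; roles assigned directly."""
    atoms: list[Atom] = []
    serial = 1
    resid = 1

    def add_polar(n, chain, resname):
        nonlocal serial, resid
        for k in range(n):
            pos = rng.uniform(0, box, 3)
            if rng.random() < 0.6:  # donor-capable hydroxyl O
                atoms.append(_atom(serial, f"O{serial}", "O", resname, resid, chain, pos,
                                   {"donor-heavy", "acceptor"}))
                serial += 1
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                atoms.append(_atom(serial, f"H{serial}", "H", resname, resid, chain,
                                   pos + 0.97 * direction, {"hydrogen"}))
                serial += 1
            else:
                atoms.append(_atom(serial, f"N{serial}", "N", resname, resid, chain, pos,
                                   {"acceptor"}))
                serial += 1
            resid += 1

    add_polar(n_lig, "B", "LIG")
    n_lig_atoms = len(atoms)
    add_polar(n_rec, "A", "RES")
    n_rec_atoms = len(atoms) - n_lig_atoms
    n_carbon = 0
    if with_hydrophobic:
        for chain, resname, n in (("B", "LIG", 3), ("A", "RES", 6)):
            for _ in range(n):
                atoms.append(_atom(serial, f"C{serial}", "C", resname, resid, chain,
                                   rng.uniform(0, box, 3), {"hydrophobic-carbon"}))
                serial += 1
                if chain == "A":
                    resid += 1
            if chain == "B":
                resid += 1
        n_carbon = 9
    wat_start = len(atoms)
    for _ in range(n_wat):
        pos = rng.uniform(0, box, 3)
        atoms.append(_atom(serial, "OW", "O", "HOH", resid, "W", pos,
                           {"water-oxygen", "acceptor", "donor-heavy"}))
        serial += 1
        resid += 1

    lig_idx, rec_idx = set(), set()
    for i, a in enumerate(atoms[:wat_start]):
        (lig_idx if a.chain == "B" else rec_idx).add(i)
    partition = {
        "ligand": frozenset(lig_idx),
        "receptor": frozenset(rec_idx),
        "water": frozenset(range(wat_start, len(atoms))),
        "ion": frozenset(),
    }
    return Frame(index=0, atoms=atoms, partition=partition)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _angle_deg(a, b, c):
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def attached_hydrogens(frame: Frame, i: int) -> list[int]:
    d = frame.atoms[i].coords
    return [
        j
        for j, a in enumerate(frame.atoms)
        if a.element == "H" and np.linalg.norm(a.coords - d) <= XH_MAX
    ]


def brute_hbonds(frame: Frame, cfg: InteractionConfig, between=("ligand", "receptor")):
    """(donor serial, H serial, acceptor serial) set by literal enumeration,
    with the nearest-acceptor-per-donor-H reduction applied afterwards."""
    out = set()
    part_a, part_b = between
    sides = [(part_a, part_b)] if part_a == part_b else [(part_a, part_b), (part_b, part_a)]
    for dp, ap in sides:
        for i in frame.indices(dp):
            if "donor-heavy" not in frame.atoms[i].role_flags:
                continue
            hs = attached_hydrogens(frame, i)
            for h in hs:
                candidates = []
                for j in frame.indices(ap):
                    aj = frame.atoms[j]
                    if "acceptor" not in aj.role_flags or j == i:
                        continue
                    if dp == ap and aj.residue_key == frame.atoms[i].residue_key:
                        continue
                    da = np.linalg.norm(aj.coords - frame.atoms[i].coords)
                    if da > cfg.hbond_da_max or da < 1e-6:
                        continue
                    ang = _angle_deg(frame.atoms[i].coords, frame.atoms[h].coords, aj.coords)
                    if ang < cfg.hbond_angle_min:
                        continue
                    candidates.append((da, aj.serial, j))
                if candidates:
                    _, _, j = min(candidates)
                    out.add((frame.atoms[i].serial, frame.atoms[h].serial, frame.atoms[j].serial))
    return out


def brute_water_bridges(frame: Frame, cfg: InteractionConfig):
    """(donor serial, water serial, acceptor serial) triples by enumeration."""
    out = set()
    lo, hi = cfg.waterbridge_dist_min, cfg.waterbridge_dist_max
    om_lo, om_hi = cfg.waterbridge_omega_window
    waters = [i for i in frame.indices("water")
              if "water-oxygen" in frame.atoms[i].role_flags]
    for dp, ap in (("ligand", "receptor"), ("receptor", "ligand")):
        for i in frame.indices(dp):
            if "donor-heavy" not in frame.atoms[i].role_flags:
                continue
            hs = attached_hydrogens(frame, i)
            if not hs:
                continue
            for w in waters:
                d1 = np.linalg.norm(frame.atoms[w].coords - frame.atoms[i].coords)
                if not (lo <= d1 <= hi):
                    continue
                for j in frame.indices(ap):
                    aj = frame.atoms[j]
                    if "acceptor" not in aj.role_flags:
                        continue
                    d2 = np.linalg.norm(aj.coords - frame.atoms[w].coords)
                    if not (lo <= d2 <= hi):
                        continue
                    ok = False
                    for h in hs:
                        th = _angle_deg(frame.atoms[i].coords, frame.atoms[h].coords,
                                        frame.atoms[w].coords)
                        om = _angle_deg(frame.atoms[h].coords, frame.atoms[w].coords, aj.coords)
                        if th >= cfg.waterbridge_theta_min and om_lo <= om <= om_hi:
                            ok = True
                            break
                    if ok:
                        out.add((frame.atoms[i].serial, frame.atoms[w].serial, aj.serial))
    return out


def brute_hydrophobic(frame: Frame, cfg: InteractionConfig):
    """{(receptor residue key, ligand atom name): (min dist, receptor serial)}"""
    pairs = {}
    for i in frame.indices("ligand"):
        ai = frame.atoms[i]
        if "hydrophobic-carbon" not in ai.role_flags:
            continue
        for j in frame.indices("receptor"):
            aj = frame.atoms[j]
            if "hydrophobic-carbon" not in aj.role_flags:
                continue
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d > cfg.hydrophobic_max:
                continue
            key = (aj.residue_key, ai.name)
            cand = (d, aj.serial)
            if key not in pairs or cand < pairs[key]:
                pairs[key] = cand
    return pairs


def plane_normal_eig(xyz: np.ndarray) -> np.ndarray:
    """Independent plane fit: smallest-eigenvalue eigenvector of the
    covariance of centered coordinates."""
    centered = xyz - xyz.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    n = v[:, 0]
    return n / np.linalg.norm(n)
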