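"""Gas-phase molecular-mechanics interaction energies, per receptor residue.

Computes the two molecular-mechanics terms of an MM/PBSA-style analysis —
Coulomb electrostatics and Lennard-Jones van der Waals — summed over all
(ligand atom, receptor atom) pairs and grouped by receptor residue.  Each
ligand-residue pair energy is assigned wholly to that residue.

Units follow GROMACS conventions: nm, kJ/mol, elementary charge.  Input
coordinates arrive in Angstrom and are converted at this module's boundary.
The polar (Poisson-Boltzmann) and non-polar (SASA) solvation terms of a
full MM/PBSA free energy are deliberately not computed; the report carries
explicit markers so the gas-phase decomposition cannot be mistaken for a
binding free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import Trajectory

__all__ = [
    "ParamTable",
    "EnergyDecomposition",
    "ParameterError",
    "coulomb_pair",
    "lj_pair",
    "decompose",
    "COULOMB_CONSTANT",
    "ANGSTROM_TO_NM",
]

# f = 1/(4 pi eps0), kJ mol^-1 nm e^-2 (GROMACS electric conversion factor)
COULOMB_CONSTANT = 138.935485
ANGSTROM_TO_NM = 0.1


class ParameterError(KeyError):
    """An atom lacks charge/LJ parameters; never silently defaulted to zero."""


def coulomb_pair(q1: float, q2: float, r: float, dielectric: float = 1.0) -> float:
    """Coulomb pair energy f*q1*q2/(eps_r*r) in kJ/mol; r in nm, q in e."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    return COULOMB_CONSTANT * q1 * q2 / (dielectric * r)


def lj_pair(sigma: float, epsilon: float, r: float) -> float:
    """Lennard-Jones 12-6 energy 4*eps*[(sigma/r)^12 - (sigma/r)^6] in kJ/mol."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


@dataclass
class ParamTable:
    """Per-atom partial charges (e) and LJ sigma (nm) / epsilon (kJ/mol).

    Keyed by (residue name, atom name); combined with Lorentz-Berthelot
    rules (arithmetic sigma, geometric epsilon).
    """

    table: pd.DataFrame  # columns: resname, atom, charge, sigma, epsilon

    def __post_init__(self) -> None:
        required = {"resname", "atom", "charge", "sigma", "epsilon"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parameter table lacks columns: {sorted(missing)}")
        if (self.table["epsilon"] < 0).any():
            raise ValueError("epsilon must be >= 0")
        if (self.table["sigma"] <= 0).any():
            raise ValueError("sigma must be > 0")
        self._index = {
            (str(r.resname), str(r.atom)): (float(r.charge), float(r.sigma), float(r.epsilon))
            for r in self.table.itertuples(index=False)
        }
        if len(self._index) != len(self.table):
            raise ValueError("duplicate (resname, atom) rows in parameter table")

    def lookup(self, resname: str, atom: str) -> tuple[float, float, float]:
        try:
            return self._index[(resname, atom)]
        except KeyError:
            raise ParameterError(f"no parameters for atom {atom!r} of residue {resname!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParamTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> Path:
        self.table.to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class EnergyDecomposition:
    """Per-residue and total gas-phase interaction energies (kJ/mol)."""

    per_residue: pd.DataFrame   # index: residue label; E_vdw/E_ele/E_total means + sem
    per_frame: pd.DataFrame     # per-frame totals: frame, E_vdw, E_ele, E_total
    totals: dict                # {"E_vdw": {"mean":, "sem":}, ...}
    polar_solv: str = "not computed (out of scope)"
    nonpolar_solv: str = "not computed (out of scope)"

    def to_tsv(self, path: str | Path) -> Path:
        self.per_residue.to_csv(path, sep="\t")
        return Path(path)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def decompose(
    traj: Trajectory,
    params: ParamTable,
    cutoff: float | None = None,
    dielectric: float = 1.0,
) -> EnergyDecomposition:
    """Ligand-receptor Coulomb + LJ energies grouped by receptor residue.

    ``cutoff`` (nm) applies a hard pair-distance cutoff; ``None`` sums all
    pairs.  Missing parameters raise :class:`ParameterError`.  Residue sums
    are accumulated in fixed residue order so totals equal the per-residue
    sum exactly.
    """
    frame0 = traj.frames[0]
    lig_idx = list(frame0.indices("ligand"))
    rec_idx = list(frame0.indices("receptor"))
    if not lig_idx or not rec_idx:
        raise ValueError("both ligand and receptor partitions must be non-empty")

    def param_arrays(indices: Sequence[int]):
        q, s, e = [], [], []
        for i in indices:
            a = frame0.atoms[i]
            qi, si, ei = params.lookup(a.residue_name, a.name)
            q.append(qi)
            s.append(si)
            e.append(ei)
        return np.array(q), np.array(s), np.array(e)

    ql, sl, el = param_arrays(lig_idx)
    qr, sr, er = param_arrays(rec_idx)
    # Lorentz-Berthelot combination, (n_lig, n_rec)
    sig = (sl[:, None] + sr[None, :]) / 2.0
    eps = np.sqrt(el[:, None] * er[None, :])
    qq = ql[:, None] * qr[None, :]

    residues = [frame0.atoms[i].residue_key for i in rec_idx]
    res_labels: list[str] = []
    res_of_col = np.empty(len(rec_idx), dtype=int)
    seen: dict[tuple[str, int, str], int] = {}
    for col, key in enumerate(residues):
        if key not in seen:
            seen[key] = len(res_labels)
            res_labels.append(f"{key[2]}{key[1]}")
        res_of_col[col] = seen[key]
    n_res = len(res_labels)

    per_frame_res_vdw = np.zeros((traj.n_frames, n_res))
    per_frame_res_ele = np.zeros((traj.n_frames, n_res))
    for f, fr in enumerate(traj.frames):
        xyz = fr.coords * ANGSTROM_TO_NM
        lx = xyz[lig_idx]
        rx = xyz[rec_idx]
        diff = lx[:, None, :] - rx[None, :, :]
        r = np.sqrt((diff**2).sum(axis=2))
        if np.any(r <= 0):
            raise ValueError(f"zero inter-atomic distance in frame {fr.index}")
        sr6 = (sig / r) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
        ele = COULOMB_CONSTANT * qq / (dielectric * r)
        if cutoff is not None:
            mask = r <= cutoff
            vdw = vdw * mask
            ele = ele * mask
        for k in range(n_res):
            cols = res_of_col == k
            per_frame_res_vdw[f, k] = vdw[:, cols].sum()
            per_frame_res_ele[f, k] = ele[:, cols].sum()

    res_vdw_mean = per_frame_res_vdw.mean(axis=0)
    res_ele_mean = per_frame_res_ele.mean(axis=0)
    per_residue = pd.DataFrame(
        {
            "E_vdw": res_vdw_mean,
            "E_vdw_sem": [_sem(per_frame_res_vdw[:, k]) for k in range(n_res)],
            "E_ele": res_ele_mean,
            "E_ele_sem": [_sem(per_frame_res_ele[:, k]) for k in range(n_res)],
            "E_total": res_vdw_mean + res_ele_mean,
        },
        index=pd.Index(res_labels, name="residue"),
    )
    frame_vdw = per_frame_res_vdw.sum(axis=1)
    frame_ele = per_frame_res_ele.sum(axis=1)
    per_frame = pd.DataFrame(
        {
            "frame": [fr.index for fr in traj.frames],
            "E_vdw": frame_vdw,
            "E_ele": frame_ele,
            "E_total": frame_vdw + frame_ele,
        }
    )
    totals = {
        "E_vdw": {"mean": float(frame_vdw.mean()), "sem": _sem(frame_vdw)},
        "E_ele": {"mean": float(frame_ele.mean()), "sem": _sem(frame_ele)},
        "E_total": {"mean": float((frame_vdw + frame_ele).mean()), "sem": _sem(frame_vdw + frame_ele)},
    }
    return EnergyDecomposition(per_residue=per_residue, per_frame=per_frame, totals=totals)
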