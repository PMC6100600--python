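"""Trajectory stability analytics: Rg, Kabsch RMSD, RMSF, H-bond counts.

The quantities follow the conventions of the GROMACS analysis tools:
radius of gyration is mass-weighted by default, RMSD is computed after
least-squares (Kabsch) superposition onto a reference frame, and RMSF is
the per-atom fluctuation about the trajectory-mean structure after fitting
every frame onto frame 0.  All values are Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionConfig, detect_hbonds
from .model_io import Frame, Trajectory, assign_roles_trajectory

__all__ = [
    "StatSeries",
    "RMSFProfile",
    "radius_of_gyration",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf_profile",
    "intramolecular_hbond_series",
    "rg_series",
]


@dataclass
class StatSeries:
    """A per-frame scalar series with summary statistics."""

    name: str
    frame_index: list[int]
    values: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)
    min: float = field(init=False)
    max: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.mean = float(v.mean())
        self.sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        self.min = float(v.min())
        self.max = float(v.max())

    def to_tsv(self, path: str | Path, times_ps: Sequence[float] | None = None) -> Path:
        df = pd.DataFrame({"frame": self.frame_index, "value": self.values})
        if times_ps is not None:
            df.insert(1, "time_ps", list(times_ps))
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


@dataclass
class RMSFProfile:
    """Per-atom RMSF plus per-region means (regions are residue-id ranges)."""

    per_atom: list[tuple[int, float]]
    per_region: list[tuple[str, str, float]]  # (label, range text, mean RMSF)
    per_residue: dict[int, float] = field(default_factory=dict)

    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_region, columns=["region", "base_range", "rmsf_mean_A"])


def _selection(frame: Frame, selection: Sequence[int] | None) -> np.ndarray:
    if selection is None:
        return np.arange(len(frame.atoms))
    sel = np.asarray(sorted(selection), dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    return sel


def radius_of_gyration(
    frame: Frame, selection: Sequence[int] | None = None, mass_weighted: bool = True
) -> float:
    """Rg = sqrt( sum m_i |r_i - r_com|^2 / sum m_i ), Angstrom."""
    sel = _selection(frame, selection)
    xyz = frame.coords[sel]
    m = (
        np.array([frame.atoms[i].mass for i in sel])
        if mass_weighted
        else np.ones(len(sel))
    )
    com = (xyz * m[:, None]).sum(axis=0) / m.sum()
    sq = ((xyz - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * sq).sum() / m.sum()))


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: Sequence[int] | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD over the
    selection.  Only proper rotations are produced (reflection corrected by
    sign flip of the smallest singular direction).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    idx = np.arange(len(mobile)) if selection is None else np.asarray(sorted(selection), dtype=int)
    if idx.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    p = mobile[idx]
    q = reference[idx]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    fitted = p @ rot.T + trans
    rmsd = float(np.sqrt(((fitted - q) ** 2).sum() / idx.size))
    return rot, trans, rmsd


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Sequence[int] | None = None,
    superpose: bool = True,
    paired: Trajectory | None = None,
) -> StatSeries:
    """Per-frame RMSD versus a reference frame (or a paired trajectory).

    Default mode fits every frame onto ``reference_frame`` with Kabsch
    superposition; ``paired`` mode compares frame i against frame i of a
    second, topology-identical trajectory instead.  ``superpose=False``
    computes the raw coordinate RMSD without fitting.
    """
    sel = _selection(traj.frames[0], selection)
    values = []
    if paired is not None:
        if paired.topology_hash != traj.topology_hash or paired.n_frames != traj.n_frames:
            raise ValueError("paired mode requires matching topology and frame count")
        pairs = [(fr.coords, other.coords) for fr, other in zip(traj.frames, paired.frames)]
    else:
        if not (0 <= reference_frame < traj.n_frames):
            raise ValueError(f"reference frame {reference_frame} out of range")
        ref = traj.frames[reference_frame].coords
        pairs = [(fr.coords, ref) for fr in traj.frames]
    for mob, ref in pairs:
        if superpose:
            _, _, rmsd = kabsch_superpose(mob, ref, sel)
        else:
            rmsd = float(np.sqrt(((mob[sel] - ref[sel]) ** 2).sum() / sel.size))
        values.append(rmsd)
    return StatSeries("RMSD", [fr.index for fr in traj.frames], values)


def rg_series(
    traj: Trajectory, selection: Sequence[int] | None = None, mass_weighted: bool = True
) -> StatSeries:
    values = [radius_of_gyration(fr, selection, mass_weighted) for fr in traj.frames]
    return StatSeries("Rg", [fr.index for fr in traj.frames], values)


def rmsf_profile(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    regions: Sequence[tuple[str, Sequence[int]]] = (),
    superpose: bool = True,
    fit_selection: Sequence[int] | None = None,
) -> RMSFProfile:
    """Per-atom RMSF about the trajectory-mean structure.

    Every frame is first superposed onto frame 0 (one fitting pass, using
    ``fit_selection`` or the reporting selection), the mean structure is
    taken, and RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>).  Regions are
    ``(label, residue-id collection)`` pairs averaged over member atoms;
    per-residue means are also reported.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = _selection(traj.frames[0], selection)
    fit_sel = sel if fit_selection is None else np.asarray(sorted(fit_selection), dtype=int)
    ref = traj.frames[0].coords
    stacked = []
    for fr in traj.frames:
        xyz = fr.coords
        if superpose:
            rot, trans, _ = kabsch_superpose(xyz, ref, fit_sel)
            xyz = xyz @ rot.T + trans
        stacked.append(xyz[sel])
    arr = np.array(stacked)                      # (frames, atoms, 3)
    mean = arr.mean(axis=0)
    rmsf = np.sqrt(((arr - mean) ** 2).sum(axis=2).mean(axis=0))
    per_atom = [(int(i), float(v)) for i, v in zip(sel, rmsf)]

    atoms0 = traj.frames[0].atoms
    per_res_vals: dict[int, list[float]] = {}
    for i, v in per_atom:
        per_res_vals.setdefault(atoms0[i].residue_id, []).append(v)
    per_residue = {rid: float(np.mean(v)) for rid, v in per_res_vals.items()}

    per_region = []
    for label, rid_range in regions:
        rid_set = set(int(r) for r in rid_range)
        member = [v for i, v in per_atom if atoms0[i].residue_id in rid_set]
        if not member:
            raise ValueError(f"region {label!r} selects no atoms")
        rng = _range_text(sorted(rid_set))
        per_region.append((label, rng, float(np.mean(member))))
    return RMSFProfile(per_atom=per_atom, per_region=per_region, per_residue=per_residue)


def _range_text(rids: Sequence[int]) -> str:
    runs: list[list[int]] = []
    for r in rids:
        if runs and r == runs[-1][-1] + 1:
            runs[-1].append(r)
        else:
            runs.append([r])
    return ", ".join(f"{run[0]}-{run[-1]}" if len(run) > 1 else str(run[0]) for run in runs)


def intramolecular_hbond_series(
    traj: Trajectory, config: InteractionConfig | None = None
) -> StatSeries:
    """Per-frame receptor-receptor hydrogen-bond count.

    Uses the GROMACS-like preset (D-A <= 3.5 A, near-linear angle) unless a
    config is given; pairs within the same residue are excluded.
    """
    if config is None:
        config = InteractionConfig.from_preset("gromacs-like")
    if not traj.frames[0].indices("receptor"):
        raise ValueError("receptor partition is empty")
    assign_roles_trajectory(traj, config)
    values = []
    for fr in traj.frames:
        recs = detect_hbonds(fr, config, ("receptor", "receptor"), exclude_same_residue=True)
        values.append(float(len(recs)))
    return StatSeries("HBondCount", [fr.index for fr in traj.frames], values)
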