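"""Minimum inter-residue distance maps and secondary-structure annotation.

The distance map gives, for every residue pair (optionally including the
ligand as a final entry), the minimum inter-atomic distance in Angstrom
under a heavy-atom or all-atom metric — the standard contact-map view used
to check which base pairs of a folded aptamer have actually formed.

Secondary structure is taken as given (dot-bracket string or explicit
base-pair list, 1-based) and annotated into the elements of a stem-loop
architecture: 5'/3' tails, stems, interior loops, hairpin stems and hairpin
loops.  Pseudoknotted (crossing) pair sets are rejected rather than
silently flattened.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import Frame

__all__ = [
    "DistanceMap",
    "SSEAnnotation",
    "PseudoknotError",
    "distance_map",
    "parse_secondary_structure",
    "annotate_sse",
    "verify_sse_formation",
]

FINE_LABELS = (
    "tail5", "stem", "interior-loop", "hairpin-stem", "hairpin-loop", "tail3", "unpaired-other",
)

# Coarse labels merge the hairpin-closing stem into the hairpin loop, the
# convention used when regions are reported as contiguous base ranges.
_COARSE = {
    "tail5": "tail5",
    "stem": "stem",
    "interior-loop": "interior-loop",
    "hairpin-stem": "hairpin-loop",
    "hairpin-loop": "hairpin-loop",
    "tail3": "tail3",
    "unpaired-other": "unpaired-other",
}


class PseudoknotError(ValueError):
    """Crossing base pairs: the nested-structure annotation refuses to guess."""


@dataclass
class DistanceMap:
    """Symmetric residue-by-residue minimum-distance matrix (Angstrom)."""

    labels: list[str]
    matrix: np.ndarray
    metric: str  # min-heavy-atom | min-all-atom
    residue_ids: list[int] = field(default_factory=list)

    def value(self, label_i: str, label_j: str) -> float:
        i = self.labels.index(label_i)
        j = self.labels.index(label_j)
        return float(self.matrix[i, j])

    def by_residue_id(self, rid_i: int, rid_j: int) -> float:
        i = self.residue_ids.index(rid_i)
        j = self.residue_ids.index(rid_j)
        return float(self.matrix[i, j])

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(np.round(self.matrix, 4), index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t")
        return Path(path)

    def plot(self, path: str | Path, cmap: str = "viridis_r") -> Path:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.matrix, cmap=cmap, origin="lower")
        ax.set_xticks(range(len(self.labels)))
        ax.set_yticks(range(len(self.labels)))
        ax.set_xticklabels(self.labels, rotation=90, fontsize=5)
        ax.set_yticklabels(self.labels, fontsize=5)
        fig.colorbar(im, ax=ax, label="min distance [Å]")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)


def distance_map(
    frame: Frame, include_ligand: bool = False, metric: str = "min-heavy-atom"
) -> DistanceMap:
    """Minimum inter-atomic distance between every pair of receptor residues.

    ``metric`` selects heavy atoms only (default) or all atoms including
    hydrogens; with ``include_ligand`` the ligand is appended as the final
    row/column (all its residues merged into one entry).
    """
    if metric not in ("min-heavy-atom", "min-all-atom"):
        raise ValueError(f"unknown metric {metric!r}")
    heavy_only = metric == "min-heavy-atom"

    groups: list[tuple[str, int, np.ndarray]] = []
    for key in frame.residues("receptor"):
        idx = [
            i
            for i in frame.indices("receptor")
            if frame.atoms[i].residue_key == key
            and not (heavy_only and frame.atoms[i].is_hydrogen)
        ]
        if idx:
            groups.append((f"{key[2]}{key[1]}", key[1], frame.coords[idx]))
    if include_ligand:
        idx = [
            i
            for i in frame.indices("ligand")
            if not (heavy_only and frame.atoms[i].is_hydrogen)
        ]
        if idx:
            resname = frame.atoms[idx[0]].residue_name
            lig_rid = max(rid for _, rid, _ in groups) + 1 if groups else 1
            groups.append((resname, lig_rid, frame.coords[idx]))
    if len(groups) < 2:
        raise ValueError("distance map needs at least 2 residues")
    n = len(groups)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(cdist(groups[i][2], groups[j][2]).min())
            mat[i, j] = mat[j, i] = d
    return DistanceMap(
        labels=[g[0] for g in groups],
        matrix=mat,
        metric=metric,
        residue_ids=[g[1] for g in groups],
    )


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def parse_secondary_structure(
    spec: str | Iterable[tuple[int, int]], length: int | None = None
) -> list[tuple[int, int]]:
    """Canonical sorted base-pair list from dot-bracket text or a pair list.

    Indices are 1-based.  Dot-bracket uses ``(``/``)``/``.``; explicit pairs
    may come in either order.  Raises on unbalanced brackets, duplicated
    indices, or out-of-range pairs when a length is given.
    """
    pairs: list[tuple[int, int]] = []
    if isinstance(spec, str):
        stack: list[int] = []
        for pos, ch in enumerate(spec.strip(), start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        if length is None:
            length = len(spec.strip())
    else:
        for i, j in spec:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"a base cannot pair with itself ({i})")
            pairs.append((min(i, j), max(i, j)))
    seen: set[int] = set()
    for i, j in pairs:
        if i < 1 or (length is not None and j > length):
            raise ValueError(f"pair ({i},{j}) outside sequence of length {length}")
        for k in (i, j):
            if k in seen:
                raise ValueError(f"base {k} appears in more than one pair")
            seen.add(k)
    return sorted(pairs)


@dataclass
class SSEAnnotation:
    """Per-residue secondary-structure labels plus the underlying pairs."""

    per_residue: dict[int, str]           # fine labels
    pairs: list[tuple[int, int]]
    coarse: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.coarse:
            self.coarse = {rid: _COARSE[lab] for rid, lab in self.per_residue.items()}

    def regions(self, coarse: bool = True) -> list[tuple[str, str]]:
        """Contiguous (label, range-text) runs in residue order."""
        labels = self.coarse if coarse else self.per_residue
        out: list[tuple[str, list[int]]] = []
        for rid in sorted(labels):
            lab = labels[rid]
            if out and out[-1][0] == lab and rid == out[-1][1][-1] + 1:
                out[-1][1].append(rid)
            else:
                out.append((lab, [rid]))
        return [
            (lab, f"{run[0]}-{run[-1]}" if len(run) > 1 else str(run[0]))
            for lab, run in out
        ]

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "residue_id": sorted(self.per_residue),
                "fine": [self.per_residue[r] for r in sorted(self.per_residue)],
                "coarse": [self.coarse[r] for r in sorted(self.per_residue)],
            }
        )
        df.to_csv(path, sep="\t", index=False)
        return Path(path)


def _check_nested(pairs: Sequence[tuple[int, int]]) -> None:
    for a in range(len(pairs)):
        i, j = pairs[a]
        for b in range(a + 1, len(pairs)):
            k, l = pairs[b]
            if i < k < j < l:
                raise PseudoknotError(f"pairs ({i},{j}) and ({k},{l}) cross (pseudoknot)")


def annotate_sse(pairs: Sequence[tuple[int, int]], length: int) -> SSEAnnotation:
    """Label every residue of a nested structure with its element.

    Unpaired 5'/3' ends become tails; helices whose innermost pair encloses
    no further pairs are hairpin stems with their enclosed residues a
    hairpin loop; unpaired residues enclosed by a pair that still contains
    other pairs form interior loops; remaining unpaired residues outside
    any pair are ``unpaired-other``.
    """
    pairs = parse_secondary_structure(pairs, length)
    _check_nested(pairs)
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def contains_pairs(i: int, j: int) -> bool:
        return any(i < k < l < j for k, l in pairs)

    labels: dict[int, str] = {}
    # paired residues: hairpin-stem when the helix's innermost pair closes a
    # pair-free region, plain stem otherwise
    for i, j in pairs:
        # walk inward through stacked pairs to this helix's innermost pair
        k, l = i, j
        while (k + 1, l - 1) in set(pairs):
            k, l = k + 1, l - 1
        lab = "hairpin-stem" if not contains_pairs(k, l) else "stem"
        labels[i] = labels[j] = lab

    paired_pos = sorted(partner)
    first_paired = paired_pos[0] if paired_pos else None
    last_paired = paired_pos[-1] if paired_pos else None
    for rid in range(1, length + 1):
        if rid in labels:
            continue
        if first_paired is None or rid < first_paired:
            labels[rid] = "tail5" if first_paired is not None else "unpaired-other"
            continue
        if rid > last_paired:
            labels[rid] = "tail3"
            continue
        # innermost enclosing pair
        enclosing = [(i, j) for i, j in pairs if i < rid < j]
        if not enclosing:
            labels[rid] = "unpaired-other"
            continue
        i, j = max(enclosing, key=lambda p: p[0])
        labels[rid] = "interior-loop" if contains_pairs(i, j) else "hairpin-loop"
    return SSEAnnotation(per_residue=labels, pairs=list(pairs))


def verify_sse_formation(
    dmap: DistanceMap, annotation: SSEAnnotation, pair_threshold: float = 3.0
) -> pd.DataFrame:
    """Flag each annotated base pair as formed iff its map distance is within
    the threshold.  Returns columns (i, j, distance_A, formed)."""
    rows = []
    for i, j in annotation.pairs:
        if i not in dmap.residue_ids or j not in dmap.residue_ids:
            raise ValueError(f"distance map lacks residues for pair ({i},{j})")
        d = dmap.by_residue_id(i, j)
        rows.append({"i": i, "j": j, "distance_A": round(d, 4), "formed": d <= pair_threshold})
    return pd.DataFrame(rows, columns=["i", "j", "distance_A", "formed"])
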