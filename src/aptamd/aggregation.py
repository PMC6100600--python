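"""Trajectory-level summaries of per-frame interaction records.

Two counting semantics coexist and are named explicitly:

* frame-presence (per-base tables): the percentage of frames in which a
  base forms at least one interaction of a class — a base engaged ten
  times in one snapshot still counts once for that snapshot;
* raw record counts (per-anchor tables): absolute numbers of detected
  interactions attributed to a ligand anchor group, with relative shares
  within each class column.

Anchors name the ligand functional-group positions (for an estradiol-like
diol: the 3- and 17-beta hydroxyls plus the aromatic A-ring).  Percentages
are exact count ratios internally and rounded half-up to 2 decimals only at
presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .interactions import INTERACTION_CLASSES, InteractionRecord

__all__ = [
    "AnchorMap",
    "FrequencyReport",
    "per_base_table",
    "per_anchor_table",
    "combination_shares",
    "bound_fraction",
    "chem_type_distribution",
    "build_frequency_report",
    "round2",
]

SPECIFIC_CLASSES = ("hbond", "water_bridge", "pistack")

_CLASS_TITLES = {
    "hbond": "H-Bond",
    "pistack": "π-Stacking",
    "water_bridge": "Water-Mediated H-Bond",
    "hydrophobic": "Hydrophobic",
}


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (presentation only)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class AnchorMap:
    """Ligand atom (or ring) name -> anchor label; unmapped names -> 'other'."""

    mapping: dict[str, str] = field(default_factory=dict)
    default: str = "other"

    def __post_init__(self) -> None:
        if len(self.mapping) != len(set(self.mapping)):
            raise ValueError("duplicate ligand atom names in anchor map")

    def anchor_of(self, record: InteractionRecord) -> str:
        return self.mapping.get(record.ligand_atom, self.default)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.mapping.values():
            seen.setdefault(v)
        return list(seen)

    @classmethod
    def from_json(cls, source: str | Path) -> "AnchorMap":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        payload = json.loads(text)
        return cls(mapping=dict(payload.get("mapping", payload)), default=payload.get("default", "other") if isinstance(payload, dict) and "mapping" in payload else "other")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"mapping": self.mapping, "default": self.default}, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# Default anchors for the estradiol-mimic ligand shipped with the fixtures.
DEFAULT_ANCHORS = AnchorMap(mapping={"O3": "3", "O17": "17-β", "A-ring": "A-ring"})


def _base_label(residue: tuple[str, int, str]) -> str:
    return f"{residue[2]}{residue[1]}"


def _check_frames(records: Iterable[InteractionRecord], n_frames: int) -> None:
    bad = [r.frame_index for r in records if not (0 <= r.frame_index < n_frames)]
    if bad:
        raise ValueError(f"records reference frames outside 0..{n_frames - 1}: {sorted(set(bad))[:5]}")


def per_base_table(records: Sequence[InteractionRecord], n_frames: int) -> pd.DataFrame:
    """Frame-presence frequencies per base (percent of frames).

    For every base and interaction class: the percentage of frames with at
    least one record of that class involving the base.  ``total_rel`` is the
    percentage of frames with any class present (union over classes, not the
    column sum).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    _check_frames(records, n_frames)
    frames_by: dict[str, dict[str, set[int]]] = {}
    order: dict[str, tuple[int, str]] = {}
    for r in records:
        base = _base_label(r.receptor_residue)
        order.setdefault(base, (r.receptor_residue[1], r.receptor_residue[0]))
        frames_by.setdefault(base, {}).setdefault(r.iclass, set()).add(r.frame_index)
    rows = []
    for base in sorted(frames_by, key=lambda b: order[b]):
        by_class = frames_by[base]
        row = {"base": base}
        union: set[int] = set()
        for cls in INTERACTION_CLASSES:
            present = by_class.get(cls, set())
            union |= present
            row[f"{cls}_rel"] = round2(100.0 * len(present) / n_frames)
        row["total_rel"] = round2(100.0 * len(union) / n_frames)
        rows.append(row)
    cols = ["base"] + [f"{c}_rel" for c in INTERACTION_CLASSES] + ["total_rel"]
    return pd.DataFrame(rows, columns=cols)


def per_anchor_table(
    records: Sequence[InteractionRecord],
    anchors: AnchorMap | None = None,
    classes: Sequence[str] = ("hbond", "water_bridge"),
) -> pd.DataFrame:
    """Absolute and relative interaction counts per ligand anchor.

    Relative percentages are computed within each class column (share of
    that class's records attributed to each anchor) and for the row totals;
    a final sum row closes each column at 100%.
    """
    if anchors is None:
        anchors = DEFAULT_ANCHORS
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        if r.iclass not in classes:
            continue
        counts.setdefault(anchors.anchor_of(r), {}).setdefault(r.iclass, 0)
        counts[anchors.anchor_of(r)][r.iclass] += 1
    anchor_order = [a for a in anchors.labels if a in counts] + sorted(
        a for a in counts if a not in anchors.labels
    )
    class_totals = {c: sum(counts[a].get(c, 0) for a in counts) for c in classes}
    grand_total = sum(class_totals.values())
    rows = []
    for a in anchor_order:
        row = {"anchor": a}
        row_total = 0
        for c in classes:
            n = counts[a].get(c, 0)
            row_total += n
            row[f"{c}_abs"] = n
            row[f"{c}_rel"] = round2(100.0 * n / class_totals[c]) if class_totals[c] else 0.0
        row["total_abs"] = row_total
        row["total_rel"] = round2(100.0 * row_total / grand_total) if grand_total else 0.0
        rows.append(row)
    sum_row = {"anchor": "∑"}
    for c in classes:
        sum_row[f"{c}_abs"] = class_totals[c]
        sum_row[f"{c}_rel"] = round2(100.0) if class_totals[c] else 0.0
    sum_row["total_abs"] = grand_total
    sum_row["total_rel"] = round2(100.0) if grand_total else 0.0
    rows.append(sum_row)
    cols = ["anchor"] + [f"{c}_{k}" for c in classes for k in ("abs", "rel")] + ["total_abs", "total_rel"]
    return pd.DataFrame(rows, columns=cols)


def _frame_labels(
    records: Sequence[InteractionRecord], n_frames: int, classes: Sequence[str]
) -> list[frozenset[str]]:
    _check_frames(records, n_frames)
    per_frame: list[set[str]] = [set() for _ in range(n_frames)]
    for r in records:
        if r.iclass in classes:
            per_frame[r.frame_index].add(r.iclass)
    return [frozenset(s) for s in per_frame]


def combination_shares(
    records: Sequence[InteractionRecord],
    n_frames: int,
    classes: Sequence[str] = SPECIFIC_CLASSES,
) -> dict:
    """Percent of frames per interaction-class combination.

    Each frame is labeled with the subset of the given classes present;
    returns per-subset shares (keys like ``"hbond+pistack"``), per-cardinality
    shares (exactly one/two/three classes), and the unbound share.  Only the
    specific classes are admitted (hydrophobic contacts are non-specific and
    excluded from combination accounting).
    """
    bad = set(classes) - set(SPECIFIC_CLASSES)
    if bad:
        raise ValueError(f"classes must be specific interaction types, got {sorted(bad)}")
    labels = _frame_labels(records, n_frames, classes)
    subset_counts: dict[frozenset[str], int] = {}
    for lab in labels:
        subset_counts[lab] = subset_counts.get(lab, 0) + 1
    by_subset = {}
    by_cardinality = {k: 0.0 for k in range(1, len(classes) + 1)}
    unbound = 0.0
    for subset, n in sorted(subset_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        pct = 100.0 * n / n_frames
        if not subset:
            unbound = pct
            continue
        key = "+".join(sorted(subset, key=list(classes).index))
        by_subset[key] = round2(pct)
        by_cardinality[len(subset)] += pct
    return {
        "by_subset": by_subset,
        "by_cardinality": {f"exactly-{k}": round2(v) for k, v in by_cardinality.items()},
        "unbound": round2(unbound),
    }


def bound_fraction(
    records: Sequence[InteractionRecord],
    n_frames: int,
    classes: Sequence[str] = SPECIFIC_CLASSES,
) -> float:
    """Percent of frames with at least one record of any listed class."""
    labels = _frame_labels(records, n_frames, classes)
    return round2(100.0 * sum(1 for s in labels if s) / n_frames)


def chem_type_distribution(
    records: Sequence[InteractionRecord], anchors: AnchorMap | None = None
) -> pd.DataFrame:
    """Counts and shares of chemical-type labels per (anchor, class)."""
    if anchors is None:
        anchors = DEFAULT_ANCHORS
    counts: dict[tuple[str, str, str], int] = {}
    for r in records:
        key = (anchors.anchor_of(r), r.iclass, r.chem_type)
        counts[key] = counts.get(key, 0) + 1
    totals: dict[tuple[str, str], int] = {}
    for (a, c, _), n in counts.items():
        totals[(a, c)] = totals.get((a, c), 0) + n
    rows = [
        {
            "anchor": a,
            "class": c,
            "chem_type": t,
            "count": n,
            "pct": round2(100.0 * n / totals[(a, c)]),
        }
        for (a, c, t), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["anchor", "class", "chem_type", "count", "pct"])


@dataclass
class FrequencyReport:
    """Bundle of all aggregation products for one record set."""

    per_base: pd.DataFrame
    per_anchor: pd.DataFrame
    combos: dict
    bound_fraction: float
    chem_types: pd.DataFrame
    n_frames: int


def build_frequency_report(
    records: Sequence[InteractionRecord],
    n_frames: int,
    anchors: AnchorMap | None = None,
    combo_classes: Sequence[str] = SPECIFIC_CLASSES,
) -> FrequencyReport:
    return FrequencyReport(
        per_base=per_base_table(records, n_frames),
        per_anchor=per_anchor_table(records, anchors),
        combos=combination_shares(records, n_frames, combo_classes),
        bound_fraction=bound_fraction(records, n_frames, combo_classes),
        chem_types=chem_type_distribution(records, anchors),
        n_frames=n_frames,
    )
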