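"""Cross-unit standardization of annotation boundaries.

Units estimate marker thresholds independently; to give every unit a
common annotation system, the number of boundaries per marker is fixed by
majority vote across units (overridable by a supervised list), standard
locations are rank-wise medians over conforming units, and every
non-conforming unit is reconciled by distance matching: surplus
boundaries farthest from the standards are deleted and missing ones are
imputed at the standard location shifted by the unit's mean matched
offset.  With an imputation hierarchy, matching first uses standards from
units of the same hierarchy class and falls back to global standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BoundarySpec",
    "MarkerStandard",
    "vote_gate_count",
    "compute_standards",
    "reconcile_unit",
    "standardize_all",
]

_TIE_SEP = 1e-9


def vote_gate_count(counts, override: int | None = None) -> int:
    """Most frequent boundary count; ties favour the smaller count."""
    if override is not None:
        return int(override)
    counts = [int(c) for c in counts if c is not None]
    if not counts:
        raise ValueError("no unit reports a boundary count")
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])  # np.unique sorts: ties -> smaller


def compute_standards(conforming, k: int):
    """Rank-wise medians of the boundary locations of conforming units."""
    conforming = [tuple(c) for c in conforming if c is not None and len(c) == k]
    if not conforming:
        raise ValueError("no conforming unit to compute standards from")
    arr = np.array(conforming, dtype=float)
    return tuple(float(v) for v in np.median(arr, axis=0))


def reconcile_unit(unit_locs, standards):
    """Match a unit's boundaries to the standards by distance.

    Greedy matching on ascending pairwise distance; surplus boundaries
    are deleted, unmatched standards are imputed at the standard shifted
    by the unit's mean matched offset.  Returns (locations, provenance)
    with provenance entries 'estimated' or 'imputed'.
    """
    standards = tuple(float(s) for s in standards)
    k = len(standards)
    unit_locs = tuple(float(b) for b in (unit_locs or ()))
    if not unit_locs:
        return standards, ("imputed",) * k
    # each boundary prefers its nearest standard; per standard only the
    # closest such boundary is kept, the rest are deleted (no rematching),
    # and standards left unmatched are imputed
    s_used = {}
    for i, b in enumerate(unit_locs):
        j = int(np.argmin([abs(b - s) for s in standards]))
        if j not in s_used or abs(b - standards[j]) < abs(
            unit_locs[s_used[j]] - standards[j]
        ):
            s_used[j] = i
    offsets = [unit_locs[i] - standards[j] for j, i in s_used.items()]
    shift = float(np.mean(offsets)) if offsets else 0.0
    locs = []
    prov = []
    for j in range(k):
        if j in s_used:
            locs.append(unit_locs[s_used[j]])
            prov.append("estimated")
        else:
            locs.append(standards[j] + shift)
            prov.append("imputed")
    order = np.argsort(locs, kind="stable")
    locs = [locs[i] for i in order]
    prov = [prov[i] for i in order]
    # enforce strictly increasing locations
    span = max(abs(v) for v in locs) or 1.0
    for i in range(1, k):
        if locs[i] <= locs[i - 1]:
            locs[i] = locs[i - 1] + _TIE_SEP * span
    return tuple(locs), tuple(prov)


@dataclass
class MarkerStandard:
    marker: str
    n_gates: int
    standards: tuple
    per_unit: dict = field(default_factory=dict)  # unit -> (locs, provenance)

    def locations(self, unit: str):
        return self.per_unit[unit][0]


@dataclass
class BoundarySpec:
    """Standardized annotation thresholds for all selected markers."""

    markers: dict = field(default_factory=dict)  # marker -> MarkerStandard

    def __contains__(self, marker):
        return marker in self.markers

    def unit_boundaries(self, unit: str, marker: str):
        return self.markers[marker].locations(unit)

    def n_levels(self, marker: str) -> int:
        return self.markers[marker].n_gates + 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, std in self.markers.items():
            for unit, (locs, prov) in std.per_unit.items():
                for rank, (loc, pv) in enumerate(zip(locs, prov), 1):
                    rows.append(
                        dict(marker=m, unit=unit, rank=rank,
                             location=loc, provenance=pv)
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BoundarySpec":
        spec = cls()
        for m, g in df.groupby("marker", sort=False):
            per_unit = {}
            for unit, gu in g.groupby("unit", sort=False):
                gu = gu.sort_values("rank")
                per_unit[str(unit)] = (
                    tuple(gu["location"]), tuple(gu["provenance"])
                )
            k = max(len(v[0]) for v in per_unit.values())
            all_locs = np.array(
                [v[0] for v in per_unit.values() if len(v[0]) == k]
            )
            spec.markers[m] = MarkerStandard(
                marker=m, n_gates=k,
                standards=tuple(np.median(all_locs, axis=0)),
                per_unit=per_unit,
            )
        return spec


def standardize_all(unit_boundaries, hierarchy=None,
                    overrides=None) -> BoundarySpec:
    """Standardize boundaries for every marker across units.

    Parameters
    ----------
    unit_boundaries : dict marker -> dict unit -> tuple-or-None
        Estimated boundary locations per unit (None where the marker was
        never gated in the unit).
    hierarchy : dict unit -> class label (default: one shared class).
    overrides : dict marker -> {"n_gates": int, "locations": tuple}
        Supervised boundary list entries; either key may be omitted.
    """
    overrides = overrides or {}
    spec = BoundarySpec()
    for marker, per_unit in unit_boundaries.items():
        units = list(per_unit)
        hier = {u: (hierarchy or {}).get(u, "all") for u in units}
        ov = overrides.get(marker, {})
        counts = [len(b) for b in per_unit.values() if b]
        if not counts and "n_gates" not in ov and "locations" not in ov:
            raise ValueError(
                f"marker {marker!r}: no unit estimated boundaries and no "
                f"supervised override supplied"
            )
        if "locations" in ov:
            k = len(ov["locations"])
        else:
            k = vote_gate_count(counts or [0], ov.get("n_gates"))
        conforming = [b for b in per_unit.values() if b and len(b) == k]
        if "locations" in ov:
            global_std = tuple(float(v) for v in ov["locations"])
        else:
            global_std = compute_standards(conforming, k)
        std = MarkerStandard(marker=marker, n_gates=k, standards=global_std)
        # class-level standards where a class has conforming units
        class_std = {}
        for cls in set(hier.values()):
            members = [
                per_unit[u]
                for u in units
                if hier[u] == cls and per_unit[u] and len(per_unit[u]) == k
            ]
            if members:
                class_std[cls] = compute_standards(members, k)
        for u in units:
            target = class_std.get(hier[u], global_std)
            std.per_unit[u] = reconcile_unit(per_unit[u], target)
        spec.markers[marker] = std
    return spec
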