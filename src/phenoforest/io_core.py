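"""Data model, readers, experiment design, and marker expression bounds.

The pipeline operates on per-sample expression matrices (cells x markers,
pre-gated and pre-transformed intensities), grouped into experimental
units by a design table.  Events outside a per-marker (low, high) bound
pair are kept but flagged "default low"/"default high": they are excluded
from density estimation and dip testing and are assigned to the extreme
children when gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._fcs import read_fcs

__all__ = [
    "ExpressionMatrix",
    "ExperimentDesign",
    "MarkerBoundaryMatrix",
    "read_sample",
    "default_boundary_matrix",
    "effective_sample_size",
    "boundary_flags",
]


@dataclass
class ExpressionMatrix:
    """One sample's cells x markers intensity matrix."""

    sample_id: str
    markers: list
    values: np.ndarray
    unit_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"{self.sample_id}: values must be 2-D")
        if self.values.shape[0] < 1:
            raise ValueError(f"{self.sample_id}: no cells")
        if len(self.markers) != self.values.shape[1]:
            raise ValueError(
                f"{self.sample_id}: {len(self.markers)} marker names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"{self.sample_id}: duplicate marker names")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"{self.sample_id}: missing/non-finite value at cell {r}, "
                f"marker {self.markers[c]!r}"
            )
        if not self.unit_id:
            self.unit_id = self.sample_id

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.markers.index(marker)]

    def subset(self, markers) -> "ExpressionMatrix":
        idx = [self.markers.index(m) for m in markers]
        return ExpressionMatrix(
            sample_id=self.sample_id,
            markers=list(markers),
            values=self.values[:, idx],
            unit_id=self.unit_id,
        )


@dataclass
class ExperimentDesign:
    """Sample-to-unit map plus optional hierarchy labels and covariates.

    ``table`` must contain a ``sample`` column; optional columns are
    ``unit`` (default: sample id), ``hierarchy`` (default: one shared
    class) and any covariates (e.g. responder status, subject, time).
    """

    table: pd.DataFrame
    active_markers: list = field(default_factory=list)
    starting_population: str = "root"

    def __post_init__(self):
        t = self.table.copy()
        if "sample" not in t.columns:
            raise ValueError("design table needs a 'sample' column")
        t["sample"] = t["sample"].astype(str)
        if t["sample"].duplicated().any():
            dup = t.loc[t["sample"].duplicated(), "sample"].iloc[0]
            raise ValueError(f"duplicate sample in design: {dup!r}")
        if "unit" not in t.columns:
            t["unit"] = t["sample"]
        if "hierarchy" not in t.columns:
            t["hierarchy"] = "all"
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path, **kw) -> "ExperimentDesign":
        return cls(pd.read_csv(path, dtype={"sample": str}), **kw)

    @property
    def samples(self) -> list:
        return list(self.table["sample"])

    @property
    def units(self) -> list:
        return list(dict.fromkeys(self.table["unit"]))

    def unit_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample, "unit"]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in design")
        return row.iloc[0]

    def samples_in_unit(self, unit: str) -> list:
        return list(self.table.loc[self.table["unit"] == unit, "sample"])

    def hierarchy_of(self, unit: str) -> str:
        row = self.table.loc[self.table["unit"] == unit, "hierarchy"]
        if row.empty:
            raise KeyError(f"unit {unit!r} not in design")
        return row.iloc[0]

    def covariate(self, name: str) -> pd.Series:
        return self.table.set_index("sample")[name]


class MarkerBoundaryMatrix(dict):
    """Per-marker (low, high) expression bounds; behaves as a dict."""

    def __init__(self, bounds=()):
        super().__init__(bounds)
        for m, (lo, hi) in self.items():
            if not lo < hi:
                raise ValueError(
                    f"marker {m!r}: lower bound {lo} must be below upper "
                    f"bound {hi}; a constant marker should be excluded "
                    f"from the active set"
                )

    def low(self, marker):
        return self[marker][0]

    def high(self, marker):
        return self[marker][1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: {"low": lo, "high": hi} for m, (lo, hi) in self.items()}
        )


def read_sample(path, fmt: str | None = None, markers=None,
                sample_id: str | None = None,
                unit_id: str = "") -> ExpressionMatrix:
    """Read one sample from an FCS file or a delimited text file.

    ``fmt`` is inferred from the suffix when omitted ('fcs', 'csv',
    'tsv').  ``markers`` optionally selects and orders a subset of
    columns; missing markers are an error naming the sample.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"fcs": "fcs", "csv": "csv", "tsv": "tsv", "txt": "tsv"}.get(
            suffix
        )
        if fmt is None:
            raise ValueError(f"cannot infer format of {path.name!r}")
    sid = sample_id or path.stem
    if fmt == "fcs":
        names, values, _ = read_fcs(path)
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = int(df.index[df[col].isna()][0])
            raise ValueError(
                f"{sid}: missing value at row {row}, column {col!r}"
            )
        names, values = list(df.columns), df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    em = ExpressionMatrix(sample_id=sid, markers=names, values=values,
                          unit_id=unit_id)
    if markers is not None:
        missing = [m for m in markers if m not in names]
        if missing:
            raise ValueError(
                f"{sid}: markers {missing} not present (file has {names})"
            )
        em = em.subset(markers)
    return em


def default_boundary_matrix(samples) -> MarkerBoundaryMatrix:
    """Data-driven expression bounds.

    Per marker, the lower bound is the 5th percentile of the per-sample
    1st percentiles and the upper bound the 95th percentile of the
    per-sample 99th percentiles.
    """
    if not samples:
        raise ValueError("need at least one sample")
    markers = samples[0].markers
    for s in samples[1:]:
        if s.markers != markers:
            raise ValueError(
                f"marker mismatch between {samples[0].sample_id!r} and "
                f"{s.sample_id!r}"
            )
    bounds = {}
    for j, m in enumerate(markers):
        p01 = [np.percentile(s.values[:, j], 1) for s in samples]
        p99 = [np.percentile(s.values[:, j], 99) for s in samples]
        lo = float(np.percentile(p01, 5))
        hi = float(np.percentile(p99, 95))
        if not lo < hi:
            raise ValueError(
                f"marker {m!r} is constant across samples (bounds "
                f"{lo} == {hi}); exclude it from the active markers"
            )
        bounds[m] = (lo, hi)
    return MarkerBoundaryMatrix(bounds)


def boundary_flags(x: np.ndarray, bounds) -> np.ndarray:
    """-1 for events at/below the low bound, +1 at/above the high bound,
    0 for events strictly inside (the effective sample)."""
    lo, hi = bounds
    flags = np.zeros(x.shape[0], dtype=np.int8)
    flags[x <= lo] = -1
    flags[x >= hi] = 1
    return flags


def effective_sample_size(x: np.ndarray, bounds) -> int:
    """Number of events strictly between the marker bounds."""
    return int(np.sum(boundary_flags(x, bounds) == 0))
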