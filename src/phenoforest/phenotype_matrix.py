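"""Phenotype down-selection and the sample x phenotype count matrix.

Discovered phenotypes are matched across experimental units by exact
annotation-string equality.  Phenotypes are retained when they occur in
at least a threshold number of units; with more than four samples the
threshold is set automatically at the elbow of the greatest convex
minorant (GCM) of the occurrence distribution.  Counts are exact per-cell
tallies from the thresholded annotations, so the same thresholds can
extract counts for pre-specified (possibly partial) phenotypes on new
data -- the targeted approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discovery import LEVELS, UNASSIGNED_LABEL, _level_index
from .standardization import BoundarySpec

__all__ = [
    "CountMatrix",
    "occurrence_counts",
    "gcm_elbow_threshold",
    "build_count_matrix",
    "target_phenotypes",
    "stim_differential_features",
]


@dataclass
class CountMatrix:
    """Samples x selected phenotypes cell counts with per-sample totals."""

    counts: pd.DataFrame  # rows = samples, columns = phenotype strings
    totals: pd.Series
    occurrence: dict = field(default_factory=dict)
    threshold: int = 1

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)

    def to_csv(self, path):
        out = self.counts.copy()
        out.insert(0, "total", self.totals)
        out.to_csv(path, index_label="sample")


def occurrence_counts(per_unit_phenotypes) -> dict:
    """Number of units whose discovery list contains each phenotype.

    ``per_unit_phenotypes`` maps unit -> iterable of annotation strings;
    duplicates within a unit count once.
    """
    occ: dict = {}
    for _unit, phenos in per_unit_phenotypes.items():
        for p in set(phenos):
            occ[p] = occ.get(p, 0) + 1
    return occ


def _gcm_of_curve(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Greatest convex minorant of (xs, ys) evaluated at each xs."""
    hull = [0]
    for j in range(1, len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (ys[b] - ys[a]) * (xs[j] - xs[a]) >= (ys[j] - ys[a]) * (
                xs[b] - xs[a]
            ):
                hull.pop()
            else:
                break
        hull.append(j)
    out = np.empty_like(ys, dtype=float)
    for a, b in zip(hull[:-1], hull[1:]):
        seg = slice(a, b + 1)
        out[seg] = ys[a] + (ys[b] - ys[a]) * (xs[seg] - xs[a]) / (
            xs[b] - xs[a]
        )
    return out


def gcm_elbow_threshold(occurrence, n_samples: int) -> int:
    """Automatic phenotype occurrence threshold.

    With four or fewer samples every discovered phenotype is kept
    (threshold 1).  Otherwise the occurrence distribution (number of
    phenotypes at each occurrence value, normalized) is restricted to
    [max(2, 0.05 n), min(n - 1, 0.95 n)], its GCM is formed, and the knot
    with the largest vertical distance to the chord joining the curve
    endpoints is returned.
    """
    if n_samples <= 4:
        return 1
    lo = max(2.0, 0.05 * n_samples)
    hi = min(n_samples - 1.0, 0.95 * n_samples)
    occs = np.array(sorted(occurrence.values() if isinstance(occurrence, dict)
                           else occurrence))
    in_range = occs[(occs >= lo) & (occs <= hi)]
    if in_range.size == 0:
        return int(np.ceil(lo))
    # the occurrence curve runs over the observed support within the range
    grid = np.arange(int(max(np.ceil(lo), in_range.min())),
                     int(min(np.floor(hi), in_range.max())) + 1)
    if grid.size == 0:
        return int(np.ceil(lo))
    ys = np.array([(occs == o).sum() for o in grid], dtype=float)
    ys /= ys.sum()
    gcm = _gcm_of_curve(grid.astype(float), ys)
    chord = gcm[0] + (gcm[-1] - gcm[0]) * (grid - grid[0]) / max(
        grid[-1] - grid[0], 1
    )
    return int(grid[int(np.argmax(chord - gcm))])


def build_count_matrix(per_sample_annotations, selected_phenotypes,
                       occurrence=None, threshold: int = 1) -> CountMatrix:
    """Exact per-sample counts for the selected phenotypes.

    ``per_sample_annotations`` maps sample -> array of per-cell
    annotation strings.  Cells with unselected phenotypes contribute to
    the totals only.
    """
    phenos = list(selected_phenotypes)
    pset = set(phenos)
    rows = {}
    totals = {}
    for sample, ann in per_sample_annotations.items():
        ann = np.asarray(ann, dtype=object)
        totals[sample] = int(ann.size)
        vals, cnts = np.unique(ann.astype(str), return_counts=True)
        d = dict(zip(vals, cnts))
        rows[sample] = [int(d.get(p, 0)) for p in phenos]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=phenos)
    return CountMatrix(
        counts=counts,
        totals=pd.Series(totals),
        occurrence=dict(occurrence or {}),
        threshold=threshold,
    )


def _allowed_level_indices(marker: str, allowed_levels, n_gates: int):
    labels = LEVELS[n_gates]
    missing = set(allowed_levels) - set(labels)
    if missing:
        raise ValueError(
            f"marker {marker!r}: levels {sorted(missing)} not among "
            f"{labels} (marker has {n_gates} boundaries)"
        )
    return {i for i, lab in enumerate(labels) if lab in set(allowed_levels)}


def target_phenotypes(samples, spec: BoundarySpec, targets) -> CountMatrix:
    """Counts of cells matching pre-specified (partial) phenotypes.

    ``targets`` maps a target name to {marker: iterable of allowed level
    labels}; a cell matches when every condition holds.  Markers absent
    from the threshold specification are an error.
    """
    names = list(targets)
    rows = {}
    totals = {}
    for em in samples:
        n = em.n_cells
        totals[em.sample_id] = n
        row = []
        for name in names:
            cond = targets[name]
            mask = np.ones(n, dtype=bool)
            for marker, levels in cond.items():
                if marker not in spec:
                    raise ValueError(
                        f"target {name!r}: marker {marker!r} has no "
                        f"standardized thresholds"
                    )
                k = spec.markers[marker].n_gates
                allowed = _allowed_level_indices(marker, levels, k)
                bnds = spec.unit_boundaries(em.unit_id, marker)
                li = _level_index(em.values[:, em.markers.index(marker)], bnds)
                mask &= np.isin(li, list(allowed))
            row.append(int(mask.sum()))
        rows[em.sample_id] = row
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return CountMatrix(counts=counts, totals=pd.Series(totals))


def stim_differential_features(stim: CountMatrix, unstim: CountMatrix,
                               pairing, activation_marker: str,
                               negative_level: str = "-") -> pd.DataFrame:
    """Stimulation-differential feature table.

    ``pairing`` maps subject -> (stimulated sample, unstimulated sample).
    Phenotypes annotated negative for the activation marker contribute
    their unstimulated frequency; activation-positive phenotypes
    contribute the stimulated-minus-unstimulated frequency difference.
    """
    phenos = list(unstim.counts.columns)
    neg_tag = f"{activation_marker}{negative_level}"
    f_stim = stim.frequencies
    f_unstim = unstim.frequencies
    rows = {}
    for subject, (s_stim, s_unstim) in pairing.items():
        if s_stim not in f_stim.index or s_unstim not in f_unstim.index:
            raise ValueError(f"subject {subject!r}: unpaired sample")
        row = []
        for p in phenos:
            is_neg = neg_tag in p.split(" ")
            if is_neg:
                row.append(float(f_unstim.loc[s_unstim, p]))
            else:
                fs = float(f_stim.loc[s_stim, p]) if p in f_stim.columns else 0.0
                row.append(fs - float(f_unstim.loc[s_unstim, p]))
        rows[subject] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=phenos)
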