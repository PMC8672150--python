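"""Phenotype discovery: random partition forests, leaf scoring and
selection, and annotation against standardized thresholds.

Partition trees split like the annotation forest but without a depth
limit: at each node one marker is drawn uniformly at random from those
whose dip test rejects unimodality, and splitting continues until every
leaf is unimodal in all selected markers or holds fewer than 25 cells.
Leaves are scored by size times a per-margin homogeneity factor built
from the dip p-value and trimmed (t=1) sample L-moment ratios; a greedy
weighted set packing selects a disjoint high-scoring subset of leaves
across the forest, and each selected leaf is annotated by comparing its
margin medians with the unit's standardized thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .density import dip_screen, dip_test, gates_from_density, taut_string_density
from .io_core import ExpressionMatrix, boundary_flags
from .standardization import BoundarySpec

__all__ = [
    "PartitionLeaf",
    "LEVELS",
    "grow_partition_tree",
    "grow_discovery_forest",
    "trimmed_lmoment_ratios",
    "shape_score",
    "select_leaves",
    "annotate_leaf",
    "annotate_cells",
    "annotation_string",
    "UNASSIGNED_LABEL",
]

MIN_LEAF = 25
DIP_THRESHOLD = 0.25
MAX_GATES = 4
#: L-kurtosis of the Gaussian distribution, the reference value for a
#: homogeneous (single-component) margin in the shape score.
GAUSS_TAU4 = 0.1226
#: Reserved label for cells whose phenotype was filtered out.
UNASSIGNED_LABEL = "0_0_0_0_0"

LEVELS = {
    1: ("-", "+"),
    2: ("-", "dim", "bright"),
    3: ("-", "dim", "bright", "ultra"),
    4: ("-", "faint", "dim", "bright", "ultra"),
}


@dataclass
class PartitionLeaf:
    unit_id: str
    tree_id: int
    leaf_id: int
    idx: np.ndarray
    shape_score: float = 0.0

    @property
    def size(self) -> int:
        return int(self.idx.size)


def grow_partition_tree(unit: ExpressionMatrix, selected_markers, bounds,
                        rng, tree_id: int = 0,
                        dip_threshold: float = DIP_THRESHOLD,
                        min_leaf: int = MIN_LEAF,
                        max_gates: int = MAX_GATES) -> list:
    """One random partition tree; returns its leaves (which partition the
    unit's cells)."""
    X = unit.values
    cols = {m: unit.markers.index(m) for m in selected_markers}
    flags = {
        m: boundary_flags(X[:, cols[m]], bounds[m]) for m in selected_markers
    }
    leaves: list[PartitionLeaf] = []

    def recurse(idx):
        if idx.size < min_leaf:
            leaves.append(_leaf(idx))
            return
        candidates = []
        for m in selected_markers:
            inside = idx[flags[m][idx] == 0]
            if inside.size < max(4, min_leaf):
                continue
            if dip_screen(X[inside, cols[m]], dip_threshold)[0]:
                candidates.append(m)
        rng.shuffle(candidates)
        for m in candidates:
            x = X[idx, cols[m]]
            inside = flags[m][idx] == 0
            dens = taut_string_density(x[inside])
            gates = gates_from_density(dens)
            if len(gates) == 0 or len(gates) > max_gates:
                continue
            cuts = np.concatenate([[-np.inf], gates, [np.inf]])
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                recurse(idx[(x > lo) & (x <= hi)])
            return
        leaves.append(_leaf(idx))

    def _leaf(idx):
        return PartitionLeaf(unit_id=unit.unit_id, tree_id=tree_id,
                             leaf_id=len(leaves), idx=idx)

    recurse(np.arange(unit.n_cells))
    return leaves


def grow_discovery_forest(unit, selected_markers, bounds, n_trees: int,
                          seed: int, min_leaf: int = MIN_LEAF) -> list:
    """Forest of seeded random partition trees; returns all scored leaves."""
    all_leaves = []
    for t in range(n_trees):
        rng = np.random.default_rng((seed, t))
        leaves = grow_partition_tree(unit, selected_markers, bounds, rng,
                                     tree_id=t, min_leaf=min_leaf)
        for leaf in leaves:
            leaf.shape_score = shape_score(unit, leaf, selected_markers)
        all_leaves.extend(leaves)
    return all_leaves


def _order_stat_expectations(x_sorted: np.ndarray, m: int,
                             lg: np.ndarray) -> np.ndarray:
    """E[X_{(j:m)}] estimators for j = 1..m from a sorted sample.

    ``lg`` caches gammaln(0..n+1) for the weight computation.
    """
    n = x_sorted.size
    i = np.arange(1, n + 1)
    out = np.empty(m)
    log_cnm = lg[n] - lg[m] - lg[n - m]
    for j in range(1, m + 1):
        lw = (
            lg[i - 1] - lg[j - 1] - np.where(i - j >= 0, lg[np.maximum(i - j, 0)], np.inf)
            + lg[n - i] - lg[m - j]
            - np.where(n - i - (m - j) >= 0,
                       lg[np.maximum(n - i - (m - j), 0)], np.inf)
            - log_cnm
        )
        w = np.where((i >= j) & (n - i >= m - j), np.exp(lw), 0.0)
        out[j - 1] = float(w @ x_sorted)
    return out


def trimmed_lmoment_ratios(x) -> tuple:
    """Trimmed (t=1) sample L-skewness and L-kurtosis (tau3, tau4)."""
    x = np.sort(np.asarray(x, dtype=float))
    if x.size < 6:
        raise ValueError("trimmed L-moment ratios require n >= 6")
    lg = gammaln(np.arange(0, x.size + 2, dtype=float) + 1.0)  # lg[k]=ln k!
    e4 = _order_stat_expectations(x, 4, lg)
    e5 = _order_stat_expectations(x, 5, lg)
    e6 = _order_stat_expectations(x, 6, lg)
    lam2 = 0.5 * (e4[2] - e4[1])
    lam3 = (e5[3] - 2.0 * e5[2] + e5[1]) / 3.0
    lam4 = (e6[4] - 3.0 * e6[3] + 3.0 * e6[2] - e6[1]) / 4.0
    if lam2 == 0.0:
        return 0.0, 0.0
    return float(lam3 / lam2), float(lam4 / lam2)


def shape_score(unit: ExpressionMatrix, leaf: PartitionLeaf,
                selected_markers) -> float:
    """Leaf size times the product of per-margin homogeneity factors.

    Each margin contributes  p_dip * exp(-|tau3|) * exp(-|tau4 - 0.1226|):
    unimodal, symmetric, Gaussian-tailed margins score highest.
    """
    if leaf.size < 6:
        return 0.0
    score = float(leaf.size)
    for m in selected_markers:
        x = unit.values[leaf.idx, unit.markers.index(m)]
        p = dip_test(x).p_value if x.size >= 4 else 1.0
        tau3, tau4 = trimmed_lmoment_ratios(x)
        score *= p * np.exp(-abs(tau3)) * np.exp(-abs(tau4 - GAUSS_TAU4))
    return float(score)


def select_leaves(leaves, n_cells: int) -> list:
    """Greedy weighted set packing of leaves across trees.

    Leaves are taken in decreasing shape score (ties: larger leaf, then
    tree/leaf id) and accepted when disjoint from all accepted leaves.
    """
    order = sorted(
        leaves, key=lambda l: (-l.shape_score, -l.size, l.tree_id, l.leaf_id)
    )
    taken = np.zeros(n_cells, dtype=bool)
    chosen = []
    for leaf in order:
        if leaf.size == 0 or np.any(taken[leaf.idx]):
            continue
        taken[leaf.idx] = True
        chosen.append(leaf)
    return chosen


def _level_index(values, boundaries) -> np.ndarray:
    """Interval index of each value w.r.t. increasing boundaries; a value
    exactly on a boundary takes the lower level."""
    return np.searchsorted(np.asarray(boundaries), values, side="left")


def annotation_string(markers, level_indices, n_gates_per_marker) -> str:
    parts = []
    for m, li in zip(markers, level_indices):
        labels = LEVELS[n_gates_per_marker[m]]
        parts.append(f"{m}{labels[li]}")
    return " ".join(parts)


def annotate_leaf(unit: ExpressionMatrix, leaf: PartitionLeaf,
                  spec: BoundarySpec, selected_markers) -> str:
    """Phenotype label of a leaf: margin medians versus the unit's
    standardized thresholds."""
    levels = []
    n_gates = {m: spec.markers[m].n_gates for m in selected_markers}
    for m in selected_markers:
        med = float(np.median(unit.values[leaf.idx, unit.markers.index(m)]))
        bnds = spec.unit_boundaries(unit.unit_id, m)
        levels.append(int(_level_index(np.array([med]), bnds)[0]))
    return annotation_string(selected_markers, levels, n_gates)


def annotate_cells(unit: ExpressionMatrix, spec: BoundarySpec,
                   selected_markers) -> np.ndarray:
    """Phenotype label of every cell by direct per-marker thresholding
    (independent of leaf membership)."""
    n_gates = {m: spec.markers[m].n_gates for m in selected_markers}
    idx_mat = np.empty((unit.n_cells, len(selected_markers)), dtype=np.int64)
    for j, m in enumerate(selected_markers):
        bnds = spec.unit_boundaries(unit.unit_id, m)
        idx_mat[:, j] = _level_index(
            unit.values[:, unit.markers.index(m)], bnds
        )
    # build label strings via a per-marker lookup to stay vectorised
    lookup = [
        np.array([f"{m}{lab}" for lab in LEVELS[n_gates[m]]])
        for m in selected_markers
    ]
    parts = [lookup[j][idx_mat[:, j]] for j in range(len(selected_markers))]
    if not parts:
        return np.full(unit.n_cells, "", dtype=object)
    out = parts[0].astype(object)
    for p in parts[1:]:
        out = out + " " + p
    return out
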