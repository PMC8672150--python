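"""Landmark-anchored transformation for annotation embeddings.

To visualise annotated data so that embedding "islands" coincide with
phenotypes, each marker gets an equispaced landmark grid with one
landmark per expression level.  Expression values are winsorized at the
1st/99th percentiles (clipped values perturbed by seeded N(0, 0.01)
noise to break ties in rare groups), standardized to mean zero and unit
variance within each annotation group, rescaled by a single per-marker
factor so that no group's support can span half the landmark spacing,
and translated to the landmark of the group's level.  The caller feeds
the transformed matrix to any dimensionality-reduction method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discovery import _level_index
from .io_core import ExpressionMatrix
from .standardization import BoundarySpec

__all__ = ["LandmarkLayout", "prepare_annotation_embedding"]

LANDMARK_SPACING = 10.0
SAFETY = 0.9
_NOISE_SD = 0.1  # N(0, 0.01)


@dataclass
class LandmarkLayout:
    spacing: float
    markers: list
    scale: dict = field(default_factory=dict)  # marker -> final scale
    landmarks: dict = field(default_factory=dict)  # marker -> level positions
    group_levels: dict = field(default_factory=dict)  # annotation -> levels


def prepare_annotation_embedding(
    em: ExpressionMatrix,
    spec: BoundarySpec,
    selected_markers,
    seed: int = 0,
    annotations=None,
    spacing: float = LANDMARK_SPACING,
    safety: float = SAFETY,
):
    """Transform one sample for an annotation embedding.

    Returns (transformed values, per-cell annotation labels, layout).
    When ``annotations`` is omitted, every cell is annotated from the
    standardized thresholds (selected and filtered phenotypes alike).
    """
    rng = np.random.default_rng(seed)
    markers = list(selected_markers)
    idx_mat = np.empty((em.n_cells, len(markers)), dtype=np.int64)
    for j, m in enumerate(markers):
        bnds = spec.unit_boundaries(em.unit_id, m)
        idx_mat[:, j] = _level_index(em.values[:, em.markers.index(m)], bnds)
    if annotations is None:
        keys = [tuple(row) for row in idx_mat]
        labels = np.array(["|".join(map(str, k)) for k in keys], dtype=object)
    else:
        labels = np.asarray(annotations, dtype=object)
        if labels.shape[0] != em.n_cells:
            raise ValueError("one annotation per cell is required")
        if any(not a for a in labels):
            raise ValueError("unannotated rows are not allowed")
    # 1-2: winsorize and perturb the clipped values
    X = np.empty((em.n_cells, len(markers)))
    for j, m in enumerate(markers):
        x = em.values[:, em.markers.index(m)].astype(float).copy()
        lo, hi = np.percentile(x, [1, 99])
        clipped = (x <= lo) | (x >= hi)
        x = np.clip(x, lo, hi)
        x[clipped] += rng.normal(0.0, _NOISE_SD, int(clipped.sum()))
        X[:, j] = x
    # 3-4: standardize within annotation groups, track extremes
    out = np.empty_like(X)
    group_of = {}
    for g, lab in enumerate(dict.fromkeys(labels)):
        group_of[lab] = g
    gidx = np.array([group_of[lab] for lab in labels])
    extremes = np.zeros(len(markers))
    standardized = {}
    for g in range(len(group_of)):
        rows = np.nonzero(gidx == g)[0]
        sub = X[rows]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        z = (sub - mu) / np.where(sd > 0, sd, 1.0)
        z[:, sd == 0] = 0.0
        standardized[g] = (rows, z)
        extremes = np.maximum(extremes, np.max(np.abs(z), axis=0, initial=0.0))
    # 5: one final scale per marker so supports fit half the spacing
    scale = np.where(
        extremes > 0, safety * (spacing / 2.0) / extremes, 1.0
    )
    layout = LandmarkLayout(spacing=spacing, markers=markers)
    for j, m in enumerate(markers):
        n_levels = spec.markers[m].n_gates + 1
        layout.scale[m] = float(scale[j])
        layout.landmarks[m] = [spacing * l for l in range(n_levels)]
    # 6: translate each group to its landmarks
    lab_list = list(group_of)
    for g, lab in enumerate(lab_list):
        rows, z = standardized[g]
        # modal level per marker within the group (groups derived from the
        # thresholds share identical levels; user-supplied labels may not)
        levels = np.array(
            [np.bincount(idx_mat[rows, j]).argmax()
             for j in range(len(markers))]
        )
        layout.group_levels[lab] = tuple(int(v) for v in levels)
        out[rows] = z * scale[None, :] + levels[None, :] * spacing
    return out, labels, layout
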