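"""Exhaustive depth-limited gating forests, depth scores, and per-unit
annotation boundaries.

For each experimental unit the annotation forest enumerates every gating
strategy of at most three markers: at each node, every active marker not
already on the path whose dip test rejects unimodality (p < 0.25) is
gated at the antimode midpoints of its taut-string density, and the
children (event subsets between consecutive gates) are expanded
recursively while they hold enough events.  Each gating event is scored
by

    omega(N) = Q(N) * P(N) * D(N)

where Q is the product of (1 - dip p-value) along the strategy, P the
node's share of the marker's effective root population, and D the
reciprocal of the number of gatings at the node's depth.  The normalized
per-marker sum of omega is the depth score used for marker selection,
and the omega-weighted average of gate locations over the dominant
gate-count class gives the unit's annotation boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import dip_screen, gates_from_density, taut_string_density
from .io_core import ExpressionMatrix, MarkerBoundaryMatrix, boundary_flags

__all__ = [
    "ForestNode",
    "AnnotationForest",
    "DepthScoreTable",
    "UnitBoundaries",
    "grow_annotation_forest",
    "node_quality",
    "depth_scores",
    "select_markers",
    "estimate_unit_boundaries",
]

DIP_THRESHOLD = 0.25
MIN_NODE_EVENTS = 500
MAX_DEPTH = 3
MAX_GATES = 4


@dataclass(frozen=True)
class ForestNode:
    """One gating event: marker ``marker`` gated in a parent node."""

    unit_id: str
    marker: str
    depth: int  # 0 = root, 1 = child, 2 = grandchild
    path: tuple  # ((marker, (lo, hi)), ...) constraints leading here
    ancestor_pvalues: tuple  # dip p of the gated marker at each ancestor
    p_value: float  # dip p of ``marker`` in this node
    event_count: int  # events in the node (flagged ones included)
    gates: tuple  # strictly increasing gate locations (1..4)


@dataclass
class AnnotationForest:
    unit_id: str
    nodes: list = field(default_factory=list)
    d_counts: tuple = (0, 0, 0)
    pm: dict = field(default_factory=dict)  # marker -> effective root size
    root_count: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def nodes_for(self, marker: str) -> list:
        return [n for n in self.nodes if n.marker == marker]

    def summary(self) -> dict:
        per_depth = [0, 0, 0]
        for n in self.nodes:
            per_depth[n.depth] += 1
        return {
            "unit": self.unit_id,
            "gatings_per_depth": per_depth,
            "gated_markers": sorted({n.marker for n in self.nodes}),
            "root_count": self.root_count,
        }


@dataclass
class DepthScoreTable:
    unit_id: str
    raw: dict
    scores: dict  # normalized to [0, 1]; best marker(s) score 1
    d_counts: tuple

    def score(self, marker: str) -> float:
        return self.scores.get(marker, 0.0)


@dataclass
class UnitBoundaries:
    unit_id: str
    marker: str
    n_gates: int
    locations: tuple
    score_mass: float


def node_quality(p_values) -> float:
    """Quality of a gating strategy: product of (1 - dip p-value) along
    the strategy, the last entry being the p-value of the marker gated at
    the node itself.  Lies in [0, 1]."""
    p_values = tuple(p_values)
    if not p_values:
        raise ValueError("node quality needs at least one dip p-value")
    q = 1.0
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"dip p-value {p} outside [0, 1]")
        q *= 1.0 - p
    return q


def _gate_marker(x, inside, dip_threshold, max_gates):
    """Dip-screen and taut-string gate a single margin.

    Returns (p_value, gates) where gates is () when the marker is not
    gateable here (unimodal, too few in-bound events, or too many modes).
    """
    xin = x[inside]
    if xin.size < max(4, 25):
        return 1.0, ()
    multimodal, p = dip_screen(xin, dip_threshold)
    if not multimodal:
        return p, ()
    dens = taut_string_density(xin)
    gates = gates_from_density(dens)
    if len(gates) == 0 or len(gates) > max_gates:
        return p, ()
    return p, tuple(float(g) for g in gates)


def grow_annotation_forest(
    unit: ExpressionMatrix,
    active_markers,
    bounds: MarkerBoundaryMatrix,
    dip_threshold: float = DIP_THRESHOLD,
    min_events: int = MIN_NODE_EVENTS,
    max_depth: int = MAX_DEPTH,
    max_gates: int = MAX_GATES,
) -> AnnotationForest:
    """Grow the exhaustive annotation forest of one experimental unit."""
    X = unit.values
    cols = {m: unit.markers.index(m) for m in active_markers}
    flags = {m: boundary_flags(X[:, cols[m]], bounds[m]) for m in active_markers}
    pm = {m: int(np.sum(flags[m] == 0)) for m in active_markers}
    forest = AnnotationForest(
        unit_id=unit.unit_id, pm=pm, root_count=unit.n_cells
    )
    d_counts = [0, 0, 0]

    def recurse(idx, depth, path, path_pvals, remaining):
        if idx.size < min_events or depth >= max_depth:
            return
        for m in remaining:
            x = X[idx, cols[m]]
            inside = flags[m][idx] == 0
            p, gates = _gate_marker(x, inside, dip_threshold, max_gates)
            if not gates:
                continue
            d_counts[depth] += 1
            forest.nodes.append(
                ForestNode(
                    unit_id=unit.unit_id,
                    marker=m,
                    depth=depth,
                    path=path,
                    ancestor_pvalues=path_pvals,
                    p_value=p,
                    event_count=int(idx.size),
                    gates=gates,
                )
            )
            cuts = (-np.inf,) + gates + (np.inf,)
            nxt = tuple(mm for mm in remaining if mm != m)
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                child = idx[(x > lo) & (x <= hi)]
                recurse(
                    child,
                    depth + 1,
                    path + ((m, (lo, hi)),),
                    path_pvals + (p,),
                    nxt,
                )

    recurse(
        np.arange(unit.n_cells), 0, (), (), tuple(active_markers)
    )
    forest.d_counts = tuple(d_counts)
    return forest


def depth_scores(forest: AnnotationForest) -> DepthScoreTable:
    """Per-marker depth scores of one unit's annotation forest."""
    delta = [1.0 / d if d > 0 else 0.0 for d in forest.d_counts]
    raw = {m: 0.0 for m in forest.pm}
    for node in forest.nodes:
        q = node_quality(node.ancestor_pvalues + (node.p_value,))
        pm = forest.pm.get(node.marker, 0)
        p_share = node.event_count / pm if pm > 0 else 0.0
        raw[node.marker] = raw.get(node.marker, 0.0) + (
            q * p_share * delta[node.depth]
        )
    top = max(raw.values(), default=0.0)
    if top <= 0.0:
        scores = {m: 0.0 for m in raw}
    else:
        scores = {m: v / top for m, v in raw.items()}
    return DepthScoreTable(
        unit_id=forest.unit_id, raw=raw, scores=scores,
        d_counts=forest.d_counts,
    )


def omega(node: ForestNode, forest: AnnotationForest) -> float:
    """Score mass of a single gating event (Q * P * D)."""
    delta = [1.0 / d if d > 0 else 0.0 for d in forest.d_counts]
    q = node_quality(node.ancestor_pvalues + (node.p_value,))
    pm = forest.pm.get(node.marker, 0)
    p_share = node.event_count / pm if pm > 0 else 0.0
    return q * p_share * delta[node.depth]


def select_markers(tables, quantile: float = 0.5,
                   threshold: float = 0.01) -> list:
    """Markers whose cross-unit depth-score quantile exceeds the threshold.

    ``tables`` is an iterable of per-unit :class:`DepthScoreTable`;
    markers missing from a unit contribute a score of zero there.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no depth-score tables supplied")
    markers = sorted({m for t in tables for m in t.scores})
    selected = []
    for m in markers:
        vals = [t.scores.get(m, 0.0) for t in tables]
        if float(np.quantile(vals, quantile)) > threshold:
            selected.append(m)
    return selected


def estimate_unit_boundaries(
    forest: AnnotationForest, marker: str, max_gates: int = MAX_GATES
) -> UnitBoundaries | None:
    """Annotation boundaries of one marker in one unit.

    Gating events are grouped by their number of gates; the class with
    the largest total omega wins (ties favour fewer gates), and each
    boundary is the omega-weighted average of the corresponding gate
    locations.  Returns None when the marker was never gated in the unit
    (the standardization step then imputes it).
    """
    nodes = forest.nodes_for(marker)
    if not nodes:
        return None
    mass = {}
    for n in nodes:
        k = len(n.gates)
        mass[k] = mass.get(k, 0.0) + omega(n, forest)
    best_k = max(sorted(mass), key=lambda k: (mass[k], -k))
    members = [n for n in nodes if len(n.gates) == best_k]
    w = np.array([omega(n, forest) for n in members])
    if w.sum() <= 0:
        w = np.ones(len(members))
    gmat = np.array([n.gates for n in members])
    locs = tuple(float(v) for v in (w @ gmat) / w.sum())
    return UnitBoundaries(
        unit_id=forest.unit_id,
        marker=marker,
        n_gates=best_k,
        locations=locs,
        score_mass=float(mass[best_k]),
    )
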