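"""Annotation forest growth, depth scores, and unit boundaries."""

import numpy as np
import pytest

from phenoforest.annotation_forest import (
    AnnotationForest,
    ForestNode,
    depth_scores,
    estimate_unit_boundaries,
    grow_annotation_forest,
    node_quality,
    omega,
    select_markers,
)
from phenoforest.io_core import ExpressionMatrix, MarkerBoundaryMatrix


def _bounds(markers, lo=-6.0, hi=14.0):
    return MarkerBoundaryMatrix({m: (lo, hi) for m in markers})


def _mixture_unit(rng, n=4000, bimodal=(True, True, False)):
    """Unit whose markers are bimodal (0/8) or unimodal per the mask."""
    cols = []
    for bi in bimodal:
        if bi:
            lab = rng.random(n) < 0.5
            x = np.where(lab, rng.normal(0, 1, n), rng.normal(8, 1, n))
        else:
            x = rng.normal(3, 1.5, n)
        cols.append(x)
    markers = [f"m{i}" for i in range(len(bimodal))]
    return ExpressionMatrix("u", markers, np.column_stack(cols))


class TestNodeQuality:
    def test_grandchild_with_threshold_pvalues(self):
        # three ancestral dip p-values of 0.25 give (3/4)^3 = 27/64
        assert node_quality([0.25, 0.25, 0.25]) == pytest.approx(27 / 64)
        assert node_quality([0.25, 0.25, 0.25]) == pytest.approx(0.421875)

    def test_clear_separation_approaches_one(self):
        assert node_quality([1e-12]) == pytest.approx(1.0, abs=1e-9)

    def test_child_product(self):
        assert node_quality([0.1, 0.2]) == pytest.approx(0.72)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            node_quality([])
        with pytest.raises(ValueError):
            node_quality([1.5])


class TestGrowForest:
    def test_bimodal_markers_gated_at_root(self):
        rng = np.random.default_rng(0)
        em = _mixture_unit(rng, 4000, (True, True, False))
        f = grow_annotation_forest(em, em.markers, _bounds(em.markers))
        assert not f.is_empty
        root_markers = {n.marker for n in f.nodes if n.depth == 0}
        assert root_markers == {"m0", "m1"}
        assert f.d_counts[0] == 2

    def test_small_unit_yields_empty_forest(self):
        rng = np.random.default_rng(1)
        em = _mixture_unit(rng, 400, (True,))
        f = grow_annotation_forest(em, em.markers, _bounds(em.markers))
        assert f.is_empty

    def test_single_marker_unit_depth_one(self):
        rng = np.random.default_rng(2)
        em = _mixture_unit(rng, 3000, (True,))
        f = grow_annotation_forest(em, em.markers, _bounds(em.markers))
        assert len(f.nodes) == 1
        node = f.nodes[0]
        assert node.depth == 0 and node.marker == "m0"
        assert 2.5 < node.gates[0] < 5.5

    def test_children_partition_parent_events(self):
        rng = np.random.default_rng(3)
        em = _mixture_unit(rng, 3000, (True,))
        f = grow_annotation_forest(em, em.markers, _bounds(em.markers))
        node = f.nodes[0]
        x = em.values[:, 0]
        cuts = (-np.inf,) + node.gates + (np.inf,)
        sizes = [np.sum((x > a) & (x <= b)) for a, b in zip(cuts, cuts[1:])]
        assert sum(sizes) == node.event_count == em.n_cells

    def test_unimodal_markers_give_no_forest(self):
        rng = np.random.default_rng(4)
        em = _mixture_unit(rng, 3000, (False, False))
        f = grow_annotation_forest(em, em.markers, _bounds(em.markers))
        assert f.is_empty
        t = depth_scores(f)
        assert all(v == 0.0 for v in t.scores.values())


class TestDepthScores:
    def _forest(self, nodes, d_counts, pm, unit="u"):
        f = AnnotationForest(unit_id=unit, pm=pm, root_count=1000)
        f.nodes = nodes
        f.d_counts = d_counts
        return f

    def test_hand_built_arithmetic(self):
        """Three gatings with known Q, P, D reproduce the hand-computed
        normalized scores."""
        nodes = [
            ForestNode("u", "a", 0, (), (), 0.0, 1000, (4.0,)),
            ForestNode("u", "b", 1, (("a", (-np.inf, 4.0)),), (0.0,), 0.2,
                       500, (3.0,)),
            ForestNode("u", "b", 1, (("a", (4.0, np.inf)),), (0.0,), 0.1,
                       500, (5.0,)),
        ]
        f = self._forest(nodes, (1, 2, 0), {"a": 1000, "b": 1000})
        t = depth_scores(f)
        raw_a = 1.0 * 1.0 * 1.0  # Q=1, P=1, D=1/d1
        raw_b = (0.8 * 0.5 * 0.5) + (0.9 * 0.5 * 0.5)
        assert t.raw["a"] == pytest.approx(raw_a)
        assert t.raw["b"] == pytest.approx(raw_b)
        assert t.scores["a"] == pytest.approx(1.0)
        assert t.scores["b"] == pytest.approx(raw_b / raw_a)

    def test_single_gated_marker_scores_one(self):
        nodes = [ForestNode("u", "a", 0, (), (), 0.1, 800, (4.0,))]
        f = self._forest(nodes, (1, 0, 0), {"a": 900, "b": 900})
        t = depth_scores(f)
        assert t.scores["a"] == 1.0
        assert t.scores["b"] == 0.0

    def test_duplicating_nodes_preserves_normalized_scores(self):
        nodes = [
            ForestNode("u", "a", 0, (), (), 0.1, 800, (4.0,)),
            ForestNode("u", "b", 0, (), (), 0.2, 800, (3.0,)),
        ]
        f1 = self._forest(nodes, (2, 0, 0), {"a": 900, "b": 900})
        f2 = self._forest(nodes + nodes, (4, 0, 0), {"a": 900, "b": 900})
        t1, t2 = depth_scores(f1), depth_scores(f2)
        for m in ("a", "b"):
            assert t1.scores[m] == pytest.approx(t2.scores[m])


class TestSelectMarkers:
    def _table(self, unit, scores):
        from phenoforest.annotation_forest import DepthScoreTable

        return DepthScoreTable(unit, dict(scores), dict(scores), (1, 0, 0))

    def test_always_top_marker_selected(self):
        tables = [self._table(f"u{i}", {"a": 1.0, "b": 0.0})
                  for i in range(4)]
        assert select_markers(tables) == ["a"]

    def test_median_quantile_threshold(self):
        ds = [0.0, 0.0, 0.02, 0.5, 1.0]
        tables = [self._table(f"u{i}", {"a": v}) for i, v in enumerate(ds)]
        assert select_markers(tables, quantile=0.5, threshold=0.01) == ["a"]
        assert select_markers(tables, quantile=0.5, threshold=0.05) == []


class TestUnitBoundaries:
    def test_weighted_average_of_constant_gates(self):
        nodes = [
            ForestNode("u", "a", 0, (), (), 0.0, 1000, (4.0,)),
            ForestNode("u", "a", 0, (), (), 0.0, 1000, (4.0,)),
        ]
        f = AnnotationForest("u", nodes, (2, 0, 0), {"a": 1000}, 1000)
        ub = estimate_unit_boundaries(f, "a")
        assert ub.n_gates == 1
        assert ub.locations == (4.0,)

    def test_omega_weighted_average(self):
        # two one-gate nodes with event counts 250 and 750 (p = 0) have
        # omega in ratio 1:3; gates 2.0 and 6.0 average to 5.0
        nodes = [
            ForestNode("u", "a", 0, (), (), 0.0, 250, (2.0,)),
            ForestNode("u", "a", 0, (), (), 0.0, 750, (6.0,)),
        ]
        f = AnnotationForest("u", nodes, (2, 0, 0), {"a": 1000}, 1000)
        ub = estimate_unit_boundaries(f, "a")
        assert ub.locations == (pytest.approx(5.0),)

    def test_gate_count_class_with_larger_mass_wins(self):
        nodes = [
            ForestNode("u", "a", 0, (), (), 0.3, 1000, (4.0,)),
            ForestNode("u", "a", 0, (), (), 0.0, 900, (3.0, 6.0)),
        ]
        f = AnnotationForest("u", nodes, (2, 0, 0), {"a": 1000}, 1000)
        assert omega(nodes[1], f) > omega(nodes[0], f)
        ub = estimate_unit_boundaries(f, "a")
        assert ub.n_gates == 2
        assert ub.locations == (pytest.approx(3.0), pytest.approx(6.0))

    def test_never_gated_marker_returns_none(self):
        f = AnnotationForest("u", [], (0, 0, 0), {"a": 1000}, 1000)
        assert estimate_unit_boundaries(f, "a") is None
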