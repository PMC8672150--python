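"""Partition trees, shape scores, leaf selection, and annotation."""

import itertools

import numpy as np
import pytest

from phenoforest.discovery import (
    PartitionLeaf,
    annotate_cells,
    annotate_leaf,
    annotation_string,
    grow_discovery_forest,
    grow_partition_tree,
    select_leaves,
    shape_score,
    trimmed_lmoment_ratios,
)
from phenoforest.io_core import ExpressionMatrix, MarkerBoundaryMatrix
from phenoforest.simulation import adjusted_rand_index
from phenoforest.standardization import standardize_all


def _bounds(markers):
    return MarkerBoundaryMatrix({m: (-6.0, 14.0) for m in markers})


def _two_cluster_unit(rng, n=2000):
    lab = rng.random(n) < 0.5
    x0 = np.where(lab, rng.normal(0, 1, n), rng.normal(8, 1, n))
    x1 = rng.normal(3, 1, n)
    em = ExpressionMatrix("u", ["m0", "m1"], np.column_stack([x0, x1]))
    return em, lab.astype(int)


class TestPartitionTree:
    def test_unimodal_unit_single_leaf(self):
        rng = np.random.default_rng(0)
        em = ExpressionMatrix("u", ["m0"],
                              np.random.default_rng(1).normal(size=(1000, 1)))
        leaves = grow_partition_tree(em, ["m0"], _bounds(["m0"]), rng)
        assert len(leaves) == 1
        assert leaves[0].size == 1000

    def test_two_cluster_unit_recovers_components(self):
        rng = np.random.default_rng(2)
        em, truth = _two_cluster_unit(rng)
        leaves = grow_partition_tree(em, em.markers, _bounds(em.markers),
                                     np.random.default_rng(3))
        pred = np.empty(em.n_cells, dtype=int)
        for i, leaf in enumerate(leaves):
            pred[leaf.idx] = i
        assert adjusted_rand_index(pred, truth) > 0.9

    def test_leaves_partition_the_unit(self):
        rng = np.random.default_rng(4)
        em, _ = _two_cluster_unit(rng)
        leaves = grow_partition_tree(em, em.markers, _bounds(em.markers),
                                     np.random.default_rng(5))
        allidx = np.concatenate([l.idx for l in leaves])
        assert np.array_equal(np.sort(allidx), np.arange(em.n_cells))

    def test_same_seed_identical_tree(self):
        rng = np.random.default_rng(6)
        em, _ = _two_cluster_unit(rng)
        l1 = grow_partition_tree(em, em.markers, _bounds(em.markers),
                                 np.random.default_rng(7))
        l2 = grow_partition_tree(em, em.markers, _bounds(em.markers),
                                 np.random.default_rng(7))
        assert len(l1) == len(l2)
        for a, b in zip(l1, l2):
            assert np.array_equal(a.idx, b.idx)


class TestTrimmedLmoments:
    def test_symmetric_sample_has_zero_skewness(self):
        x = np.concatenate([np.arange(1, 30.0), -np.arange(1, 30.0)])
        tau3, _ = trimmed_lmoment_ratios(x)
        assert tau3 == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_near_trimmed_reference(self):
        rng = np.random.default_rng(8)
        t4s = [trimmed_lmoment_ratios(rng.normal(size=4000))[1]
               for _ in range(10)]
        # trimmed (t=1) Gaussian L-kurtosis is ~0.06
        assert np.mean(t4s) == pytest.approx(0.062, abs=0.02)

    def test_heavy_tails_raise_kurtosis(self):
        rng = np.random.default_rng(9)
        t4_norm = trimmed_lmoment_ratios(rng.normal(size=4000))[1]
        t4_cauchy = trimmed_lmoment_ratios(rng.standard_cauchy(4000))[1]
        assert t4_cauchy > t4_norm


class TestShapeScore:
    def test_score_linear_in_leaf_size(self, monkeypatch):
        """With the margin factors pinned, the score is size times a
        constant, so doubling the leaf doubles the score."""
        import phenoforest.discovery as disc

        class _P:
            p_value = 0.8

        monkeypatch.setattr(disc, "dip_test", lambda x: _P)
        rng = np.random.default_rng(10)
        x = rng.normal(size=(200, 1))
        em = ExpressionMatrix("u", ["m0"], np.vstack([x, x]))
        small = PartitionLeaf("u", 0, 0, np.arange(200))
        big = PartitionLeaf("u", 0, 1, np.arange(400))
        s_small = shape_score(em, small, ["m0"])
        s_big = shape_score(em, big, ["m0"])
        # the duplicated sample shares the empirical distribution, so the
        # margin factors agree up to the O(1/n) bias of the finite-sample
        # L-moment weights
        assert s_big == pytest.approx(2 * s_small, rel=1e-3)

    def test_bimodal_margin_collapses_score(self):
        rng = np.random.default_rng(11)
        uni = rng.normal(size=(500, 1))
        bim = np.concatenate([rng.normal(0, 1, 250),
                              rng.normal(8, 1, 250)])[:, None]
        em_u = ExpressionMatrix("u", ["m0"], uni)
        em_b = ExpressionMatrix("u", ["m0"], bim)
        leaf = PartitionLeaf("u", 0, 0, np.arange(500))
        assert shape_score(em_b, leaf, ["m0"]) < 0.01 * shape_score(
            em_u, leaf, ["m0"]
        )

    def test_tiny_leaf_scores_zero(self):
        em = ExpressionMatrix("u", ["m0"], np.random.default_rng(0)
                              .normal(size=(10, 1)))
        leaf = PartitionLeaf("u", 0, 0, np.arange(4))
        assert shape_score(em, leaf, ["m0"]) == 0.0


class TestSelectLeaves:
    def test_single_tree_all_leaves_kept(self):
        leaves = [
            PartitionLeaf("u", 0, 0, np.arange(0, 50), 5.0),
            PartitionLeaf("u", 0, 1, np.arange(50, 100), 3.0),
        ]
        chosen = select_leaves(leaves, 100)
        assert len(chosen) == 2

    def test_duplicate_trees_deduplicated(self):
        mk = lambda t: [
            PartitionLeaf("u", t, 0, np.arange(0, 50), 5.0),
            PartitionLeaf("u", t, 1, np.arange(50, 100), 3.0),
        ]
        chosen = select_leaves(mk(0) + mk(1), 100)
        assert len(chosen) == 2
        assert all(l.tree_id == 0 for l in chosen)

    def test_greedy_matches_bruteforce_on_toy_instance(self):
        leaves = [
            PartitionLeaf("u", 0, 0, np.arange(0, 60), 10.0),
            PartitionLeaf("u", 1, 0, np.arange(40, 100), 8.0),
            PartitionLeaf("u", 2, 0, np.arange(60, 100), 5.0),
        ]
        chosen = select_leaves(leaves, 100)
        best_val, best_set = -1.0, None
        for r in range(1, 4):
            for combo in itertools.combinations(leaves, r):
                cells = np.concatenate([l.idx for l in combo])
                if len(np.unique(cells)) != len(cells):
                    continue
                v = sum(l.shape_score for l in combo)
                if v > best_val:
                    best_val, best_set = v, combo
        assert sum(l.shape_score for l in chosen) == pytest.approx(best_val)
        assert {id(l) for l in chosen} == {id(l) for l in best_set}

    def test_selected_leaves_pairwise_disjoint(self):
        rng = np.random.default_rng(12)
        leaves = []
        for t in range(6):
            perm = rng.permutation(200)
            cuts = np.sort(rng.choice(np.arange(1, 200), 3, replace=False))
            for i, part in enumerate(np.split(perm, cuts)):
                leaves.append(
                    PartitionLeaf("u", t, i, part, float(rng.random()))
                )
        chosen = select_leaves(leaves, 200)
        allidx = np.concatenate([l.idx for l in chosen])
        assert len(np.unique(allidx)) == len(allidx)


class TestAnnotation:
    def _spec(self, per_marker):
        ub = {m: {"u": locs} for m, locs in per_marker.items()}
        return standardize_all(ub)

    def test_leaf_levels_against_boundaries(self):
        spec = self._spec({"m0": (4.0,), "m1": (3.0, 6.0)})
        em = ExpressionMatrix(
            "u", ["m0", "m1"],
            np.array([[2.0, 5.0]] * 30), unit_id="u",
        )
        leaf = PartitionLeaf("u", 0, 0, np.arange(30))
        assert annotate_leaf(em, leaf, spec, ["m0", "m1"]) == "m0- m1dim"

    def test_median_on_boundary_takes_lower_level(self):
        spec = self._spec({"m0": (4.0,)})
        em = ExpressionMatrix("u", ["m0"], np.full((10, 1), 4.0),
                              unit_id="u")
        leaf = PartitionLeaf("u", 0, 0, np.arange(10))
        assert annotate_leaf(em, leaf, spec, ["m0"]) == "m0-"

    def test_cell_annotation_thresholds(self):
        spec = self._spec({"m0": (4.0,), "m1": (4.0,)})
        em = ExpressionMatrix("u", ["m0", "m1"],
                              np.array([[2.0, 9.0], [5.0, 1.0]]),
                              unit_id="u")
        ann = annotate_cells(em, spec, ["m0", "m1"])
        assert list(ann) == ["m0- m1+", "m0+ m1-"]

    def test_identical_cells_identical_labels_and_conservation(self):
        rng = np.random.default_rng(13)
        spec = self._spec({"m0": (4.0,)})
        em = ExpressionMatrix("u", ["m0"], rng.normal(4, 3, (500, 1)),
                              unit_id="u")
        ann = annotate_cells(em, spec, ["m0"])
        vals, counts = np.unique(ann.astype(str), return_counts=True)
        assert counts.sum() == 500
        assert set(vals) <= {"m0-", "m0+"}

    def test_annotation_string_levels(self):
        s = annotation_string(["a", "b"], [1, 2], {"a": 1, "b": 2})
        assert s == "a+ bbright"


class TestForest:
    def test_forest_annotation_matches_truth(self):
        rng = np.random.default_rng(14)
        em, truth = _two_cluster_unit(rng)
        em.unit_id = "u"
        leaves = grow_discovery_forest(em, ["m0"], _bounds(em.markers),
                                       n_trees=3, seed=1)
        chosen = select_leaves(leaves, em.n_cells)
        spec = self._spec = standardize_all({"m0": {"u": (4.0,)}})
        phenos = {annotate_leaf(em, l, spec, ["m0"]) for l in chosen}
        assert phenos == {"m0-", "m0+"}
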