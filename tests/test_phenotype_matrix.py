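"""Occurrence counting, GCM elbow, count matrix, targeted extraction."""

import numpy as np
import pandas as pd
import pytest

from phenoforest.discovery import UNASSIGNED_LABEL
from phenoforest.io_core import ExpressionMatrix
from phenoforest.phenotype_matrix import (
    build_count_matrix,
    gcm_elbow_threshold,
    occurrence_counts,
    stim_differential_features,
    target_phenotypes,
)
from phenoforest.standardization import standardize_all


class TestOccurrence:
    def test_counts_units_not_repeats(self):
        per_unit = {
            "u1": ["a", "b", "b"],
            "u2": ["a"],
            "u3": ["a", "c"],
        }
        occ = occurrence_counts(per_unit)
        assert occ == {"a": 3, "b": 1, "c": 1}


class TestGcmElbow:
    def test_four_or_fewer_samples_keep_everything(self):
        assert gcm_elbow_threshold({"p": 3}, n_samples=3) == 1
        assert gcm_elbow_threshold({"p": 3}, n_samples=4) == 1

    def test_range_bounds_at_hundred_samples(self):
        # with n = 100 the restricted range is [5, 95]; a threshold must
        # come from it
        occ = {f"p{i}": v for i, v in enumerate([5, 5, 5, 50, 95] * 4)}
        thr = gcm_elbow_threshold(occ, n_samples=100)
        assert 5 <= thr <= 95

    def test_elbow_matches_bruteforce_distance_maximisation(self):
        rng = np.random.default_rng(0)
        n = 30
        lo, hi = max(2, int(np.ceil(0.05 * n))), min(n - 1, int(0.95 * n))
        for _ in range(10):
            occs = rng.integers(1, n + 1, size=60)
            occ = {f"p{i}": int(v) for i, v in enumerate(occs)}
            thr = gcm_elbow_threshold(occ, n_samples=n)
            # brute force: normalized occurrence curve, GCM by direct
            # lower-hull evaluation, chord distance maximised over knots
            inr = occs[(occs >= lo) & (occs <= hi)]
            if inr.size == 0:
                assert thr == lo
                continue
            grid = np.arange(max(lo, inr.min()), min(hi, inr.max()) + 1)
            ys = np.array([(occs == o).sum() for o in grid], float)
            ys /= ys.sum()
            gcm = np.empty_like(ys)
            for i, o in enumerate(grid):
                best = ys[i]
                for a in range(len(grid)):
                    for b in range(a + 1, len(grid)):
                        if grid[a] <= o <= grid[b]:
                            v = ys[a] + (ys[b] - ys[a]) * (o - grid[a]) / (
                                grid[b] - grid[a]
                            )
                            best = min(best, v)
                gcm[i] = best
            chord = gcm[0] + (gcm[-1] - gcm[0]) * (grid - grid[0]) / (
                grid[-1] - grid[0]
            )
            dist = chord - gcm
            # the returned knot must attain the maximal chord distance
            # (plateaus of the GCM make the argmax non-unique)
            assert lo <= thr <= hi
            if thr in grid:
                assert dist[thr - grid[0]] == pytest.approx(
                    dist.max(), abs=1e-12
                )

    def test_piecewise_linear_elbow(self):
        # curve linear on [5,7] and [7,25] with a convex kink at 7
        n = 30
        occ = {}
        i = 0
        for o in range(5, 26):
            reps = max(1, 40 - 5 * o) if o <= 7 else max(1, 8 - (o - 7) // 4)
            for _ in range(reps):
                occ[f"p{i}"] = o
                i += 1
        thr = gcm_elbow_threshold(occ, n_samples=n)
        assert 6 <= thr <= 9


class TestCountMatrix:
    def test_single_phenotype_column_equals_total(self):
        ann = {"s1": np.array(["a"] * 7)}
        cm = build_count_matrix(ann, ["a"])
        assert cm.counts.loc["s1", "a"] == 7
        assert cm.totals["s1"] == 7

    def test_absent_phenotype_column_present_with_zero(self):
        ann = {"s1": np.array(["a", "a"]), "s2": np.array(["b", "b"])}
        cm = build_count_matrix(ann, ["a", "b"])
        assert cm.counts.loc["s1", "b"] == 0
        assert cm.counts.loc["s2", "a"] == 0

    def test_conservation_with_unselected_remainder(self):
        ann = {"s1": np.array(["a", "b", UNASSIGNED_LABEL, "a"])}
        cm = build_count_matrix(ann, ["a", "b"])
        assert cm.counts.loc["s1"].sum() + 1 == cm.totals["s1"]


class TestTargets:
    def _sample_and_spec(self):
        spec = standardize_all({"m0": {"u": (4.0,)}, "m1": {"u": (4.0,)}})
        vals = np.array([
            [1.0, 1.0],
            [5.0, 1.0],
            [5.0, 2.0],
            [9.0, 9.0],
            [3.0, 8.0],
            [6.0, 0.5],
        ])
        em = ExpressionMatrix("s1", ["m0", "m1"], vals, unit_id="u")
        return em, spec

    def test_empty_target_matches_everything(self):
        em, spec = self._sample_and_spec()
        cm = target_phenotypes([em], spec, {"all": {}})
        assert cm.counts.loc["s1", "all"] == 6

    def test_exhaustive_targets_sum_to_total(self):
        em, spec = self._sample_and_spec()
        cm = target_phenotypes(
            [em], spec,
            {"neg": {"m0": ["-"]}, "pos": {"m0": ["+"]}},
        )
        assert cm.counts.loc["s1"].sum() == 6

    def test_conjunction_matches_bruteforce_filter(self):
        em, spec = self._sample_and_spec()
        cm = target_phenotypes([em], spec,
                               {"t": {"m0": ["+"], "m1": ["-"]}})
        manual = sum(
            1 for r in em.values if r[0] > 4.0 and r[1] <= 4.0
        )
        assert cm.counts.loc["s1", "t"] == manual == 3

    def test_unknown_marker_is_an_error(self):
        em, spec = self._sample_and_spec()
        with pytest.raises(ValueError, match="m9"):
            target_phenotypes([em], spec, {"t": {"m9": ["+"]}})

    def test_coarsened_level_set_is_a_union(self):
        spec = standardize_all({"m0": {"u": (3.0, 6.0)}})
        vals = np.array([[1.0], [4.0], [5.0], [7.0], [9.0]])
        em = ExpressionMatrix("s1", ["m0"], vals, unit_id="u")
        cm = target_phenotypes(
            [em], spec,
            {"pos": {"m0": ["dim", "bright"]}, "bright": {"m0": ["bright"]}},
        )
        assert cm.counts.loc["s1", "pos"] == 4
        assert cm.counts.loc["s1", "bright"] == 2
        assert cm.counts.loc["s1", "pos"] >= cm.counts.loc["s1", "bright"]


class TestStimFeatures:
    def _cm(self, rows):
        counts = pd.DataFrame(rows).T
        totals = pd.Series({s: 100 for s in counts.index})
        from phenoforest.phenotype_matrix import CountMatrix

        return CountMatrix(counts=counts, totals=totals)

    def test_identical_samples_zero_differences(self):
        phenos = {"cd154+ x-": 10, "cd154- x+": 20}
        stim = self._cm({"s_a": phenos, "s_b": phenos})
        unstim = self._cm({"u_a": phenos, "u_b": phenos})
        feats = stim_differential_features(
            stim, unstim, {"a": ("s_a", "u_a"), "b": ("s_b", "u_b")},
            activation_marker="cd154",
        )
        assert feats.loc["a", "cd154+ x-"] == pytest.approx(0.0)
        assert feats.loc["a", "cd154- x+"] == pytest.approx(0.2)

    def test_hand_built_arithmetic(self):
        stim = self._cm({"s_a": {"cd154+ y-": 30, "cd154- y-": 10}})
        unstim = self._cm({"u_a": {"cd154+ y-": 12, "cd154- y-": 40}})
        feats = stim_differential_features(
            stim, unstim, {"a": ("s_a", "u_a")}, activation_marker="cd154"
        )
        assert feats.loc["a", "cd154+ y-"] == pytest.approx(0.18)
        assert feats.loc["a", "cd154- y-"] == pytest.approx(0.40)

    def test_unpaired_sample_is_an_error(self):
        stim = self._cm({"s_a": {"p": 1}})
        unstim = self._cm({"u_a": {"p": 1}})
        with pytest.raises(ValueError, match="unpaired"):
            stim_differential_features(
                stim, unstim, {"a": ("s_a", "missing")},
                activation_marker="cd154",
            )
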