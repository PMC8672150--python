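"""Binomial GLMM, PFDA, and multiplicity adjustment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from phenoforest.stats_models import (
    adjust_pvalues,
    fit_binomial_glmm,
    pfda_test,
)
from scipy.special import expit


def _simulate_counts(rng, n_sub=20, n_total=1000, b0=-3.0, b1=0.0,
                     sigma=0.5):
    y = np.array([0] * (n_sub // 2) + [1] * (n_sub - n_sub // 2))
    eta = b0 + b1 * y + sigma * rng.normal(size=n_sub)
    c = rng.binomial(n_total, expit(eta))
    return c, np.full(n_sub, n_total), y


class TestGlmmFit:
    def test_half_counts_give_zero_intercept(self):
        rng = np.random.default_rng(0)
        c = np.full(20, 500)
        n = np.full(20, 1000)
        y = np.array([0, 1] * 10)
        res = fit_binomial_glmm(c, n, y)
        assert res.intercept == pytest.approx(0.0, abs=0.05)
        assert res.effect == pytest.approx(0.0, abs=0.05)

    def test_recovers_known_effect(self):
        rng = np.random.default_rng(1)
        ests = []
        for _ in range(10):
            c, n, y = _simulate_counts(rng, n_sub=40, b1=0.8, sigma=0.4)
            ests.append(fit_binomial_glmm(c, n, y).effect)
        assert np.mean(ests) == pytest.approx(0.8, abs=0.15)

    def test_type_one_error_near_nominal_under_null(self):
        """Wald test of the responder effect under a simulated null
        (overdispersed binomial, no class difference)."""
        rng = np.random.default_rng(2)
        rej = 0
        reps = 250
        for _ in range(reps):
            c, n, y = _simulate_counts(rng, b1=0.0, sigma=0.5)
            res = fit_binomial_glmm(c, n, y)
            if np.isfinite(res.p_value) and res.p_value < 0.05:
                rej += 1
        assert 0.015 <= rej / reps <= 0.105

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        c, n, y = _simulate_counts(rng, b1=0.5)
        r1 = fit_binomial_glmm(c, n, y)
        r2 = fit_binomial_glmm(c, n, y)
        assert r1.effect == r2.effect and r1.p_value == r2.p_value

    def test_extreme_separation_never_crashes(self):
        c = np.array([0] * 10 + [1000] * 10)
        n = np.full(20, 1000)
        y = np.array([0] * 10 + [1] * 10)
        res = fit_binomial_glmm(c, n, y)  # must not raise
        assert res.method in ("glmm", "betabinomial")

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_binomial_glmm([10], [5], [1])
        with pytest.raises(ValueError):
            fit_binomial_glmm([1, 2], [5, 5], [1, 1])

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript unavailable")
    def test_matches_lme4_on_shared_data(self, tmp_path):
        """Independent cross-check: lme4's Laplace fit on the same data
        gives the same fixed effects to a loose tolerance."""
        rng = np.random.default_rng(4)
        c, n, y = _simulate_counts(rng, n_sub=30, b1=0.7, sigma=0.5)
        df = pd.DataFrame({"c": c, "n": n, "y": y,
                           "id": np.arange(len(c))})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(cbind(c, n - c) ~ y + (1 | id), data = d,
                       family = binomial)
            cat(fixef(m)["y"], "\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lme4_effect = float(out.stdout.strip().split()[-1])
        ours = fit_binomial_glmm(c, n, y).effect
        assert ours == pytest.approx(lme4_effect, abs=0.08)


class TestPfda:
    def _matching_counts(self, rng, n_sub=20, k=4, base=-4.0, effect=0.0,
                         sigma=0.4):
        y = np.array([0] * (n_sub // 2) + [1] * (n_sub - n_sub // 2))
        totals = pd.Series(np.full(n_sub, 2000),
                           index=[f"s{i}" for i in range(n_sub)])
        cols = {}
        for j in range(k):
            eta = base + effect * y + sigma * rng.normal(size=n_sub)
            cols[f"p{j}"] = rng.binomial(2000, expit(eta))
        counts = pd.DataFrame(cols, index=totals.index)
        responder = dict(zip(totals.index, y))
        return counts, totals, responder

    def test_single_phenotype_collapses_to_univariate_direction(self):
        rng = np.random.default_rng(5)
        counts, totals, resp = self._matching_counts(rng, k=1, effect=1.0)
        res = pfda_test(counts, totals, resp)
        uni = fit_binomial_glmm(
            counts.iloc[:, 0].to_numpy(), totals.to_numpy(),
            np.array(list(resp.values())),
        )
        assert res.k == 1
        assert res.contrast == pytest.approx(uni.effect, abs=0.1)

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(6)
        rej, reps = 0, 120
        for _ in range(reps):
            counts, totals, resp = self._matching_counts(rng, k=3,
                                                         effect=0.0)
            res = pfda_test(counts, totals, resp)
            if np.isfinite(res.p_value) and res.p_value < 0.05:
                rej += 1
        assert 0.005 <= rej / reps <= 0.12

    def test_contrast_invariant_to_phenotype_order(self):
        rng = np.random.default_rng(7)
        counts, totals, resp = self._matching_counts(rng, k=4, effect=0.6)
        r1 = pfda_test(counts, totals, resp)
        r2 = pfda_test(counts[counts.columns[::-1]], totals, resp)
        assert r1.contrast == pytest.approx(r2.contrast, abs=1e-3)

    def test_joint_model_gains_power_over_single_weak_effects(self):
        """Uniform weak enrichment across matching phenotypes: the joint
        one-sided test rejects more often than a single-phenotype test."""
        rng = np.random.default_rng(8)
        joint, single = 0, 0
        reps = 40
        for _ in range(reps):
            counts, totals, resp = self._matching_counts(
                rng, n_sub=20, k=6, effect=0.35, sigma=0.4
            )
            res = pfda_test(counts, totals, resp)
            if np.isfinite(res.p_value) and res.p_value < 0.05:
                joint += 1
            uni = fit_binomial_glmm(
                counts.iloc[:, 0].to_numpy(), totals.to_numpy(),
                np.array(list(resp.values())),
            )
            # one-sided version of the univariate test
            if np.isfinite(uni.p_value) and uni.effect > 0 and (
                uni.p_value / 2 < 0.05
            ):
                single += 1
        assert joint > single

    def test_empty_match_is_an_error(self):
        with pytest.raises(ValueError, match="match"):
            pfda_test(pd.DataFrame(index=["s1"]), pd.Series({"s1": 10}),
                      {"s1": 1})


class TestAdjust:
    def test_bonferroni(self):
        np.testing.assert_allclose(adjust_pvalues([0.01], "bonferroni"),
                                   [0.01])
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02], "bonferroni"), [0.02, 0.04]
        )

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.random(50)
        for method in ("bonferroni", "bh"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0)
        bh = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert np.all(np.diff(bh[order]) >= -1e-12)
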