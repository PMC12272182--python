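"""Hierarchical Bayesian behavioural models and Bayes factors."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit
from scipy.stats import norm

from riftkit.inference import (
    MCMCConfig,
    accuracy_table,
    bayes_factor_01,
    fit_hier_linear,
    fit_hier_logistic,
    sensitivity_analysis,
)
from riftkit.synthmeg import simulate_behavior

pytestmark = pytest.mark.filterwarnings("ignore:MCMC convergence flagged")


def _table(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "block_condition", "correct_side",
                       "response_side", "timeout"]
    )


class TestAccuracyTable:
    def test_simple_proportion(self):
        rows = [("s1", "c", "left", "left" if i < 7 else "right", False) for i in range(10)]
        out = accuracy_table(_table(rows))
        assert out.loc[0, "accuracy"] == pytest.approx(0.7)

    def test_timeouts_excluded_from_denominator(self):
        rows = [("s1", "c", "left", "none", True)] * 2
        rows += [("s1", "c", "left", "left", False)] * 4
        rows += [("s1", "c", "left", "right", False)] * 4
        out = accuracy_table(_table(rows))
        assert out.loc[0, "n_responded"] == 8
        assert out.loc[0, "accuracy"] == pytest.approx(0.5)

    def test_single_trial_cell_dropped_from_summary_not_model(self):
        rows = [("s1", "c", "left", "left", False)]
        rows += [("s2", "c", "left", "left", False), ("s2", "c", "right", "right", False)]
        table = _table(rows)
        out = accuracy_table(table)
        assert set(out["subject_id"]) == {"s2"}
        post = fit_hier_logistic(table, mcmc=MCMCConfig(seed=0, burn=100, draws=100))
        assert set(post.subject_effects["subject_id"]) == {"s1", "s2"}

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table(_table([]))


class TestHierLogistic:
    def test_null_simulation_beta_near_zero(self):
        table = simulate_behavior(12, 150, 0.5, 0.0, seed=21, conditions=("c",))
        post = fit_hier_logistic(table, mcmc=MCMCConfig(seed=22))
        assert abs(post.mean("beta")) < 0.15
        bf = bayes_factor_01(post)
        assert bf.bf01 > 3.0

    def test_strong_effect_recovers_coded_logit(self):
        """At accuracy p the sensitivity converges to 2*logit(p)."""
        table = simulate_behavior(12, 300, 0.75, 0.0, seed=23, conditions=("c",))
        post = fit_hier_logistic(table, mcmc=MCMCConfig(seed=24))
        assert post.mean("beta") == pytest.approx(2 * logit(0.75), abs=0.2)
        bf = bayes_factor_01(post)
        assert bf.bf01 < 1 / 3

    def test_label_swap_symmetry(self):
        table = simulate_behavior(8, 60, 0.6, 0.03, seed=25, conditions=("c",))
        swap = {"left": "right", "right": "left", "none": "none"}
        swapped = table.assign(
            correct_side=table["correct_side"].map(swap),
            response_side=table["response_side"].map(swap),
        )
        p1 = fit_hier_logistic(table, mcmc=MCMCConfig(seed=26))
        p2 = fit_hier_logistic(swapped, mcmc=MCMCConfig(seed=26))
        assert p2.mean("beta") == pytest.approx(p1.mean("beta"), abs=0.1)
        assert p2.mean("alpha") == pytest.approx(-p1.mean("alpha"), abs=0.1)

    def test_prior_only_fit_gives_unit_bayes_factor(self):
        """With no data the posterior equals the prior (Savage-Dickey identity)."""
        empty = _table([])
        post = fit_hier_logistic(empty, mcmc=MCMCConfig(seed=27, draws=2000))
        bf = bayes_factor_01(post)
        assert bf.bf01 == pytest.approx(1.0, rel=0.15)

    def test_reports_rhat_for_every_parameter(self):
        table = simulate_behavior(6, 20, 0.5, 0.0, seed=28, conditions=("c",))
        post = fit_hier_logistic(table, mcmc=MCMCConfig(seed=29, burn=200, draws=300))
        assert set(post.rhat) == {"alpha", "beta", "sd_subject_alpha", "sd_subject_beta"}
        assert all(np.isfinite(v) for v in post.rhat.values())

    def test_seed_reproducible(self):
        table = simulate_behavior(6, 20, 0.5, 0.0, seed=30, conditions=("c",))
        a = fit_hier_logistic(table, mcmc=MCMCConfig(seed=31, burn=150, draws=150))
        b = fit_hier_logistic(table, mcmc=MCMCConfig(seed=31, burn=150, draws=150))
        np.testing.assert_array_equal(a.draws["beta"], b.draws["beta"])

    def test_calibration_null_coverage(self):
        """~95% of null replicates should have beta's 95% CI covering zero."""
        cover = 0
        n_rep = 100
        for rep in range(n_rep):
            ss = np.random.SeedSequence(77, spawn_key=(rep,))
            s1, s2 = (int(x) for x in ss.generate_state(2) % 2**31)
            table = simulate_behavior(8, 30, 0.5, 0.05, seed=s1, conditions=("c",))
            post = fit_hier_logistic(
                table, mcmc=MCMCConfig(seed=s2, nwalkers=16, burn=150, draws=250)
            )
            lo, hi = np.percentile(post.flat("beta"), [2.5, 97.5])
            cover += lo <= 0.0 <= hi
        assert 0.90 <= cover / n_rep <= 1.0


class TestHierLinear:
    @staticmethod
    def _long(values_by_cond):
        rows = []
        for cond, vals in values_by_cond.items():
            for i, v in enumerate(vals):
                rows.append({"subject_id": f"s{i}", "condition": cond, "value": v})
        return pd.DataFrame(rows)

    def test_exact_null_centers_on_zero(self):
        vals = np.array([1.0, 2.0, 1.5, 0.5, 2.5, 1.2])
        df = self._long({"a": vals, "b": vals})
        post, bf = fit_hier_linear(df, contrast=("a", "b"), mcmc=MCMCConfig(seed=40))
        assert abs(post.mean("contrast")) < 0.2
        assert bf.bf01 > 1.0

    def test_recovers_injected_difference(self):
        rng = np.random.default_rng(41)
        base = rng.normal(0.0, 1.0, 12)
        df = self._long(
            {"a": base + rng.normal(0, 0.5, 12), "b": base + 3.0 + rng.normal(0, 0.5, 12)}
        )
        post, bf = fit_hier_linear(df, contrast=("a", "b"), mcmc=MCMCConfig(seed=42))
        assert post.mean("contrast") == pytest.approx(3.0, abs=0.5)
        assert bf.bf10 > 3.0

    def test_subject_label_permutation_invariance(self):
        rng = np.random.default_rng(43)
        df = self._long({"a": rng.normal(0, 1, 8), "b": rng.normal(0.4, 1, 8)})
        perm = {f"s{i}": f"s{(i + 3) % 8}" for i in range(8)}
        df2 = df.assign(subject_id=df["subject_id"].map(perm))
        p1, _ = fit_hier_linear(df, contrast=("a", "b"), mcmc=MCMCConfig(seed=44))
        p2, _ = fit_hier_linear(df2, contrast=("a", "b"), mcmc=MCMCConfig(seed=44))
        np.testing.assert_array_equal(p1.draws["contrast"], p2.draws["contrast"])

    def test_needs_two_subjects(self):
        df = self._long({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError, match="2 subjects"):
            fit_hier_linear(df, contrast=("a", "b"), mcmc=MCMCConfig(seed=45))


class TestSensitivityAnalysis:
    def test_reduced_run_shapes_and_lookup(self):
        res = sensitivity_analysis(
            grid=(0.40, 0.50, 0.60), n_sims=2, n_subjects=6, n_trials=20, seed=50
        )
        assert res.bf01.shape == (3, 2)
        assert res.n_failures == 0
        assert len(res.quad_coeffs) == 3
        # the null level has the most null evidence; lookup inverts the curve
        top = res.median.max()
        lo, hi = res.lookup(top)
        assert lo <= 0.5 <= hi
        assert res.lookup(np.inf) is None

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            sensitivity_analysis(grid=(0.0, 0.5), n_sims=2, seed=51)
        with pytest.raises(ValueError):
            sensitivity_analysis(n_sims=1, seed=52)


class TestBayesFactor:
    def test_savage_dickey_identity_on_synthetic_draws(self):
        """If the 'posterior' draws are the prior, BF01 is 1 by construction."""
        from riftkit.inference import PosteriorSummary

        rng = np.random.default_rng(60)
        draws = rng.normal(0.0, 2.5, size=(4, 5000))
        post = PosteriorSummary(
            draws={"beta": draws}, rhat={"beta": 1.0}, prior_scales={"beta": 2.5}
        )
        bf = bayes_factor_01(post)
        assert bf.bf01 == pytest.approx(1.0, rel=0.1)
        assert bf.prior_density_at_0 == pytest.approx(norm.pdf(0, 0, 2.5))
        assert bf.bf10 == pytest.approx(1.0 / bf.bf01)
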