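"""Tests of probit ML fitting, hierarchical estimation, the condition
model, parameter recovery and performance metrics."""

import numpy as np
import pandas as pd
import pytest

from explorebandit import (
    TaskConfig,
    Weights,
    fit_condition_model,
    fit_probit_hierarchical,
    fit_probit_ml,
    generate_task,
    grid_performance,
    parameter_recovery,
    performance,
    performance_by_trial,
    simulate_dataset,
)
from explorebandit.fit import _nll, _policy_design, _usable, fit_probit_design


@pytest.fixture(scope="module")
def big_sim():
    cfg = TaskConfig(n_subjects=31, seed=301)
    return cfg, simulate_dataset(cfg, "hybrid", (0.2, 0.2, 0.01))


class TestFitProbitML:
    def test_recovers_generating_weights_large_n(self, big_sim):
        """MLE consistency: ~10k trials recover the truth within 3 SE."""
        _, data = big_sim
        res = fit_probit_ml(data, "hybrid")
        assert res.converged
        truth = np.array([0.2, 0.2, 0.01])
        assert np.all(np.abs(res.weights - truth) < 3 * res.se)

    def test_null_data_gives_null_weights(self):
        cfg = TaskConfig(n_subjects=10, seed=302)
        data = simulate_dataset(cfg, "hybrid", (0.0, 0.0, 0.0))
        res = fit_probit_ml(data, "hybrid")
        assert np.all(np.abs(res.weights) < 3 * res.se)
        assert np.all(res.pvalues > 1e-4)

    def test_loglik_at_mle_beats_truth(self, big_sim):
        _, data = big_sim
        res = fit_probit_ml(data, "hybrid")
        usable = _usable(data)
        X, _ = _policy_design(usable, "hybrid", False)
        s = np.where(usable["choice"] == 1, 1.0, -1.0)
        assert res.loglik >= -_nll(np.array([0.2, 0.2, 0.01]), X, s)

    def test_information_criteria_identities(self, big_sim):
        _, data = big_sim
        res = fit_probit_ml(data, "ucb")
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik, abs=1e-12)
        assert res.bic == pytest.approx(
            res.n_params * np.log(res.n_obs) - 2 * res.loglik, abs=1e-12
        )
        assert res.deviance == pytest.approx(-2 * res.loglik, abs=1e-12)
        assert res.loglik <= 0

    def test_rescaling_equivariance(self, big_sim):
        """Multiplying a regressor by c divides its fitted weight by c."""
        _, data = big_sim
        res = fit_probit_ml(data, "hybrid")
        scaled = data.copy()
        scaled["RU"] = scaled["RU"] * 10.0
        res2 = fit_probit_ml(scaled, "hybrid")
        assert res2.coef("RU") == pytest.approx(res.coef("RU") / 10.0, rel=1e-5)
        assert res2.coef("V") == pytest.approx(res.coef("V"), rel=1e-5)

    def test_matches_statsmodels_oracle(self, big_sim):
        """Independent cross-check against statsmodels' probit MLE."""
        sm = pytest.importorskip("statsmodels.api")
        _, data = big_sim
        res = fit_probit_ml(data, "hybrid")
        usable = _usable(data)
        X, _ = _policy_design(usable, "hybrid", False)
        y = (usable["choice"] == 1).astype(float)
        oracle = sm.Probit(y, X).fit(disp=0, method="lbfgs", maxiter=500)
        assert res.loglik >= oracle.llf - 1e-4
        assert np.allclose(res.weights, oracle.params, atol=5e-4)

    def test_complete_separation_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        data = pd.DataFrame(
            {"V": x, "RU": rng.normal(size=200), "VoverTU": rng.normal(size=200),
             "choice": np.where(x > 0, 1.0, 2.0), "timeout": False}
        )
        res = fit_probit_ml(data, "hybrid")
        assert any("separation" in w for w in res.warnings)

    def test_timeouts_excluded(self):
        cfg = TaskConfig(n_subjects=5, seed=303, timeout_rate=0.2)
        data = simulate_dataset(cfg, "hybrid", (0.2, 0.2, 0.01))
        res = fit_probit_ml(data, "hybrid")
        assert res.n_obs == int((~data["timeout"]).sum())

    def test_no_usable_trials_errors(self):
        data = pd.DataFrame(
            {"V": [1.0], "RU": [0.0], "VoverTU": [0.1], "choice": [np.nan],
             "timeout": [True]}
        )
        with pytest.raises(ValueError, match="usable"):
            fit_probit_ml(data, "hybrid")

    def test_all_zero_column_flagged(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=100), np.zeros(100)])
        res = fit_probit_design(X, rng.random(100) < 0.5, ["a", "b"])
        assert np.isnan(res.coef("b"))
        assert res.n_params == 1


class TestHierarchical:
    def test_homogeneous_subjects_degenerate_variances(self):
        """Shared truth: fixed effects ~ truth, random-effect vars ~ 0."""
        cfg = TaskConfig(n_subjects=8, seed=304)
        data = simulate_dataset(cfg, "hybrid", (0.2, 0.3, 0.02))
        res = fit_probit_hierarchical(data, "hybrid")
        assert res.converged
        truth = np.array([0.2, 0.3, 0.02])
        assert np.all(np.abs(res.weights - truth) < 4 * np.maximum(res.se, 1e-3))
        assert np.all(res.random_effect_vars < 1e-3)
        assert np.all(res.random_effect_vars > 0)

    def test_heterogeneous_subjects_recovered(self):
        cfg = TaskConfig(n_subjects=12, seed=305)
        rng = np.random.default_rng(7)
        bandits = generate_task(cfg)
        wbar = np.array([0.2, 0.3, 0.02])
        frames = []
        for j in range(cfg.n_subjects):
            wj = wbar + rng.normal(0, [0.1, 0.15, 0.0], 3)
            frames.append(
                simulate_dataset(cfg, "hybrid", Weights.from_sequence(wj),
                                 bandits=bandits[bandits["subject"] == j + 1])
            )
        data = pd.concat(frames, ignore_index=True)
        res = fit_probit_hierarchical(data, "hybrid")
        assert np.all(np.abs(res.weights - wbar) < [0.15, 0.2, 0.02])
        assert res.random_effect_vars[0] > 1e-4  # w1 spread detected
        assert res.per_subject_effects.shape == (12, 3)
        # conditional modes spread around the fixed effect
        assert res.per_subject_effects["V"].std() > 0.02

    def test_single_subject_reduces_to_ml(self):
        cfg = TaskConfig(n_subjects=1, seed=306)
        data = simulate_dataset(cfg, "hybrid", (0.2, 0.2, 0.01))
        h = fit_probit_hierarchical(data, "hybrid")
        m = fit_probit_ml(data, "hybrid")
        assert np.allclose(h.weights, m.weights)
        assert h.per_subject_effects is not None


class TestConditionModel:
    def test_softmax_simulant_has_null_intercepts(self):
        """Without uncertainty weights the intercepts center on zero."""
        cfg = TaskConfig(n_subjects=40, seed=307)
        data = simulate_dataset(cfg, "hybrid", (0.2, 0.0, 0.0))
        fit = fit_condition_model(data)
        s = fit.summary
        for j in ("RS", "SR", "RR", "SS"):
            assert abs(s.loc[j, "intercept"]) < 4 * s.loc[j, "intercept_se"]

    def test_directed_exploration_shifts_intercepts(self):
        """w2 > 0 biases choice toward the risky arm: intercept(RS) > 0 >
        intercept(SR)."""
        cfg = TaskConfig(n_subjects=60, seed=308)
        data = simulate_dataset(cfg, "hybrid", (0.166, 0.3, 0.0))
        s = fit_condition_model(data).summary
        assert s.loc["RS", "intercept"] > 3 * s.loc["RS", "intercept_se"]
        assert s.loc["SR", "intercept"] < -3 * s.loc["SR", "intercept_se"]

    def test_random_exploration_flattens_rr_slope(self):
        """w3 > 0 makes choices more stochastic under high total
        uncertainty: slope(RR) < slope(SS)."""
        cfg = TaskConfig(n_subjects=60, seed=309)
        data = simulate_dataset(cfg, "hybrid", (0.166, 0.0, 0.01))
        s = fit_condition_model(data).summary
        gap_se = np.hypot(s.loc["RR", "slope_se"], s.loc["SS", "slope_se"])
        assert s.loc["RR", "slope"] < s.loc["SS", "slope"] - 2 * gap_se


class TestParameterRecovery:
    def test_small_run_shapes_and_bookkeeping(self):
        cfg = TaskConfig(n_subjects=3)
        rec = parameter_recovery(5, cfg, seed=3)
        assert rec.generated.shape == rec.recovered.shape == (5, 3)
        assert rec.n_failed == 0
        frame = rec.to_frame()
        assert len(frame) == 5 and frame.shape[1] == 6

    def test_signs_recovered(self):
        """Even where magnitudes saturate, the sign of every generated
        weight is recovered (choices pin the direction of each effect)."""
        cfg = TaskConfig(n_subjects=8)
        rec = parameter_recovery(12, cfg, seed=4)
        big = np.abs(rec.generated) > 1.0
        assert np.all(np.sign(rec.recovered[big]) == np.sign(rec.generated[big]))

    def test_degenerate_prior_reported(self):
        cfg = TaskConfig(n_subjects=2)
        rec = parameter_recovery(3, cfg, weight_prior_sd=0.0, seed=5)
        assert np.all(np.isnan(rec.per_coef_r))
        assert any("degenerate" in n for n in rec.notes)
        assert np.all(np.abs(rec.recovered) < 0.5)


class TestPerformance:
    def test_perfect_and_random_choosers(self):
        cfg = TaskConfig(n_subjects=4, seed=310)
        data = simulate_dataset(cfg, "hybrid", (0.0, 0.0, 0.0))
        better = np.where(data["mu1"] > data["mu2"], 1.0, 2.0)
        perfect = data.copy()
        perfect["choice"] = better
        assert performance(perfect) == 1.0
        p = performance(data)
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(len(data))

    def test_hybrid_beats_value_only_simulant(self):
        """Uncertainty-guided exploration earns more than value-only choice
        at matched value weight."""
        cfg = TaskConfig(n_subjects=31, seed=311)
        bandits = generate_task(cfg)
        hybrid = simulate_dataset(cfg, "hybrid", (0.166, 0.175, 0.005), bandits=bandits)
        softmax = simulate_dataset(cfg, "softmax", (0.166,), bandits=bandits)
        assert performance(hybrid) > performance(softmax)

    def test_learning_curve_rises(self, sim_data):
        curve = performance_by_trial(sim_data)
        assert curve.loc[10] > curve.loc[1]

    def test_tied_means_excluded(self):
        data = pd.DataFrame(
            {"trial": [1, 2], "choice": [1.0, 1.0], "mu1": [1.0, 2.0], "mu2": [1.0, 0.0]}
        )
        assert performance(data) == 1.0  # tied row dropped


class TestGridPerformance:
    def test_scaled_grid_orders_corners(self):
        """Value weight 0 performs at chance; the high-w1 corner beats it."""
        cfg = TaskConfig(n_subjects=4)
        grid = grid_performance(cfg, grid_points=2, iterations=2, seed=6)
        assert len(grid) == 8
        origin = grid.query("w1 == 0 and w2 == 0 and w3 == 0")["performance"].iloc[0]
        corner = grid.query("w1 == 1 and w2 == 0 and w3 == 0")["performance"].iloc[0]
        assert abs(origin - 0.5) < 0.1
        assert corner > origin + 0.1

    def test_performance_nondecreasing_in_value_weight(self):
        cfg = TaskConfig(n_subjects=6)
        grid = grid_performance(cfg, grid_points=4, iterations=2, seed=7)
        axis = grid.query("w2 == 0 and w3 == 0").sort_values("w1")["performance"].to_numpy()
        assert np.all(np.diff(axis) > -0.03)
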