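"""Scenario registry, outcome simulation and closed-form R^2 machinery."""

from dataclasses import replace

import numpy as np
import pytest

from expobench import (SCENARIOS, CorrelationModel, adjusted_r2,
                       calibrate_sigma, expected_r2, make_true_model, ols_fit,
                       resolve_sigma, select_true_predictors,
                       simulate_exposures, simulate_outcome, simulate_study,
                       true_model_sensitivity)
from expobench.scenarios import variance_of_mean_function


def _toy_model(R, **kw):
    R = np.asarray(R, float)
    return CorrelationModel(matrix=R, family_labels=np.zeros(len(R), int),
                            high_block=kw.get("high_block", ()),
                            low_block=kw.get("low_block", ()))


def _cs(p, rho):
    return np.full((p, p), rho) + (1 - rho) * np.eye(p)


class TestRegistry:
    def test_all_specs_valid(self):
        for spec in SCENARIOS.values():
            spec.validate()

    def test_structure_by_scenario_family(self):
        for sid, spec in SCENARIOS.items():
            n = spec.n_interactions
            assert n == {"1": 0, "2": 1, "3": 2}[sid[0]]
            if n == 0:
                assert spec.gamma12 == spec.gamma13 == 0.0
            if n >= 1:
                assert abs(spec.gamma12) == (1.0 if spec.interaction_size
                                             == "strong" else 0.5)
            if n < 2:
                assert spec.gamma13 == 0.0

    def test_only_2i_needs_calibration(self):
        assert SCENARIOS["2i"].sigma is None
        assert all(s.sigma is not None for k, s in SCENARIOS.items()
                   if k != "2i")


class TestPredictorSelection:
    def test_high_mode_draws_from_high_block(self, default_model):
        preds = select_true_predictors(default_model, "high", seed=11)
        assert set(preds) <= set(default_model.high_block)
        sub = np.abs(default_model.matrix[np.ix_(preds, preds)])
        assert sub[~np.eye(5, dtype=bool)].min() >= 0.62

    def test_low_mode_draws_from_low_block(self, default_model):
        preds = select_true_predictors(default_model, "low", seed=11)
        assert set(preds) <= set(default_model.low_block)

    def test_toy_forced_selection(self):
        model = _toy_model(np.eye(5))
        assert sorted(select_true_predictors(model, "mixed", 0)) == list(range(5))

    def test_deterministic(self, default_model):
        a = select_true_predictors(default_model, "mixed", seed=42)
        b = select_true_predictors(default_model, "mixed", seed=42)
        assert a == b

    def test_high_block_draw_concentration(self, default_model):
        """Mean pairwise r of 'high' draws concentrates on the block mean."""
        means = []
        for s in range(300):
            preds = select_true_predictors(default_model, "high", seed=s)
            sub = default_model.matrix[np.ix_(preds, preds)]
            means.append(sub[~np.eye(5, dtype=bool)].mean())
        hb = np.asarray(default_model.high_block)
        block = default_model.matrix[np.ix_(hb, hb)]
        block_mean = block[~np.eye(13, dtype=bool)].mean()
        assert np.median(means) == pytest.approx(block_mean, abs=0.03)


class TestTrueModel:
    def test_one_strong_interaction(self):
        preds = (3, 9, 21, 40, 100)
        tm = make_true_model(SCENARIOS["2e"], preds)
        assert tm.gammas == (((3, 9), 1.0),)
        assert len(tm.terms) == 6

    def test_no_interaction_model_size_five(self):
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        assert tm.gammas == ()
        assert len(tm.terms) == 5

    def test_two_interactions_share_x1(self):
        tm = make_true_model(SCENARIOS["3h"], (5, 6, 7, 8, 9))
        assert tm.gammas == (((5, 6), -0.5), ((5, 7), -0.5))
        assert len(tm.terms) == 7

    def test_wrong_predictor_count_rejected(self):
        with pytest.raises(ValueError):
            make_true_model(SCENARIOS["1a"], (1, 2, 3))


class TestOutcomeSimulation:
    def test_noise_free_limit(self):
        model = _toy_model(np.eye(6))
        E = simulate_exposures(model, 100, seed=0)
        tm = make_true_model(SCENARIOS["2e"], (0, 1, 2, 3, 4), sigma=0.0)
        # sigma=0 must be honoured even though the spec tabulates 12
        tm = replace(tm, sigma=0.0)
        y = simulate_outcome(E, tm, seed=1)
        assert np.allclose(y, tm.mean_function(E))

    def test_determinism(self):
        model = _toy_model(np.eye(6))
        E = simulate_exposures(model, 50, seed=0)
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        assert np.array_equal(simulate_outcome(E, tm, 7),
                              simulate_outcome(E, tm, 7))

    def test_linearity_in_coefficients(self):
        model = _toy_model(_cs(5, 0.3))
        E = simulate_exposures(model, 200, seed=3)
        tm = make_true_model(SCENARIOS["2g"], tuple(range(5)), sigma=1.0)
        tm0 = replace(tm, sigma=0.0)
        doubled = replace(tm0, betas=(tm.betas[0],) + tuple(
            2 * b for b in tm.betas[1:]),
            gammas=tuple(((i, j), 2 * g) for (i, j), g in tm.gammas))
        y1 = simulate_outcome(E, tm0, 0) - tm.betas[0]
        y2 = simulate_outcome(E, doubled, 0) - tm.betas[0]
        assert np.allclose(y2, 2 * y1)

    def test_outcome_variance_matches_isserlis(self):
        R = _cs(5, 0.78)
        model = _toy_model(R)
        E = simulate_exposures(model, 100_000, seed=9)
        tm = make_true_model(SCENARIOS["2e"], tuple(range(5)))  # sigma 12
        y = simulate_outcome(E, tm, seed=10)
        expected = variance_of_mean_function(tm, R) + tm.sigma ** 2
        assert np.var(y) == pytest.approx(expected, rel=0.02)


class TestExpectedR2:
    def test_high_correlation_main_effects(self):
        """Five equicorrelated (0.78) mains, sigma 13 -> R^2 ~ 0.109."""
        model = _toy_model(_cs(5, 0.78))
        r2 = expected_r2(SCENARIOS["1c"], model, tuple(range(5)))
        var_f = 5 + 20 * 0.78
        assert r2 == pytest.approx(var_f / (var_f + 169), abs=1e-12)
        assert r2 == pytest.approx(0.109, abs=0.001)

    def test_independent_predictors_noiseless_limit(self):
        model = _toy_model(np.eye(5))
        r2 = expected_r2(SCENARIOS["1a"], model, tuple(range(5)),
                         sigma=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_pure_interaction_product_normal_variance(self):
        """gamma=1 only, independent pair: Var(X1X2)=1 -> R^2 = 0.5."""
        model = _toy_model(np.eye(5))
        spec = replace(SCENARIOS["2e"], sigma=1.0,
                       betas=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
        r2 = expected_r2(spec, model, tuple(range(5)))
        assert r2 == pytest.approx(0.5, abs=1e-12)

    def test_two_interaction_covariance_terms(self):
        """Isserlis cross-covariance Cov(X1X2, X1X3) = rho23 + rho12 rho13."""
        rho = 0.78
        model = _toy_model(_cs(5, rho))
        tm = make_true_model(SCENARIOS["3g"], tuple(range(5)))
        vf = variance_of_mean_function(tm, model.matrix)
        mains = 5 + 20 * rho
        var_i = 1 + rho ** 2
        cov_i = rho + rho * rho
        expected = mains + 0.25 * (2 * var_i + 2 * cov_i)
        assert vf == pytest.approx(expected, abs=1e-12)


class TestSigmaCalibration:
    def test_recovers_tabulated_sigma_1c(self, default_model):
        sigma = calibrate_sigma(SCENARIOS["1c"], default_model)
        assert sigma == pytest.approx(13.0, rel=0.05)

    def test_recovers_tabulated_sigma_2e(self, default_model):
        sigma = calibrate_sigma(SCENARIOS["2e"], default_model)
        assert sigma == pytest.approx(12.0, rel=0.05)

    def test_algebraic_identity(self):
        """VarF = 1 and target 0.5 give sigma = 1 exactly."""
        model = _toy_model(np.eye(5))
        spec = replace(SCENARIOS["2e"], correlation_mode="mixed",
                       sigma=None, target_r2=0.5, betas=(0.0,) * 6)
        assert calibrate_sigma(spec, model) == pytest.approx(1.0, abs=1e-12)

    def test_resolve_sigma_calibrates_2i(self, default_model):
        sigma = resolve_sigma(SCENARIOS["2i"], default_model)
        # low-correlation block, Var F ~ 6 -> sigma ~ sqrt(6*9) ~ 7.3
        assert 5.0 < sigma < 10.0

    def test_invalid_target_rejected(self, default_model):
        with pytest.raises(ValueError):
            calibrate_sigma(SCENARIOS["1c"], default_model, target_r2=1.5)


class TestTrueModelSensitivity:
    def test_tiny_noise_gives_full_sensitivity(self):
        model = _toy_model(np.eye(5))
        spec = replace(SCENARIOS["1a"], sigma=1e-8)
        assert true_model_sensitivity(spec, model, 3, seed=0,
                                      n_train=100) == 1.0

    def test_power_closed_form(self):
        """Independent predictors with sigma set for per-term power 0.9."""
        from scipy.stats import norm

        n = 1200
        sigma = np.sqrt(n) / (norm.ppf(0.975) + norm.ppf(0.9))
        model = _toy_model(np.eye(5))
        spec = replace(SCENARIOS["1a"], sigma=float(sigma))
        sens = true_model_sensitivity(spec, model, 60, seed=4, n_train=n)
        assert sens == pytest.approx(0.9, abs=0.04)

    def test_null_model_type_one_error(self):
        model = _toy_model(np.eye(5))
        spec = replace(SCENARIOS["1a"], sigma=1.0, betas=(0.0,) * 6)
        sens = true_model_sensitivity(spec, model, 200, seed=5, n_train=100)
        assert sens == pytest.approx(0.05, abs=0.03)


class TestSimulatedStudy:
    def test_shapes_and_shared_truth(self, default_model):
        st = simulate_study(SCENARIOS["2e"], default_model, 0, seed=3,
                            n_train=200, n_valid=500)
        assert st.train_exposures.values.shape == (200, 237)
        assert st.valid_exposures.values.shape == (500, 237)
        assert len(st.train_outcome) == 200
        assert len(st.valid_outcome) == 500
        assert set(st.true_model.predictor_indices) <= set(
            default_model.high_block)

    def test_empirical_adjusted_r2_matches_closed_form(self, default_model):
        """OLS on the true terms reproduces the analytic R^2 (40 reps)."""
        for sid in ("1c", "2e"):
            spec = SCENARIOS[sid]
            adj, exp = [], []
            for r in range(40):
                st = simulate_study(spec, default_model, r, seed=8,
                                    n_train=1200, n_valid=10)
                fit = ols_fit(st.train_exposures, st.train_outcome,
                              st.true_model.terms)
                y = st.train_outcome
                r2 = 1 - np.sum((y - fit.predict(st.train_exposures)) ** 2) \
                    / np.sum((y - y.mean()) ** 2)
                adj.append(adjusted_r2(r2, 1200, len(st.true_model.terms)))
                exp.append(expected_r2(spec, default_model,
                                       st.true_model.predictor_indices))
            assert np.mean(adj) == pytest.approx(np.mean(exp), abs=0.02)
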