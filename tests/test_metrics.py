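"""Performance measures: worked examples, invariances, availability."""

import numpy as np
import pytest

from expobench import (SCENARIOS, CorrelationModel, SelectedModel,
                       SelectionComparison, evaluate, inter, main,
                       make_true_model, quad, r2_relative, simulate_study)
from expobench.metrics import (alt_fdp, alt_sensitivity, fdp_terms,
                               fdp_variables, relative_model_size,
                               relative_number_of_variables,
                               sensitivity_interactions, sensitivity_terms,
                               sensitivity_variables)
from expobench.selectors.base import SelectionResults


def _toy_corr(p, entries=()):
    R = np.eye(p)
    for i, j, v in entries:
        R[i, j] = R[j, i] = v
    return R


def _sel(terms, **kw):
    defaults = dict(method="test", has_single_model=True, predicts=True,
                    searches_interactions=True, has_terms=True)
    defaults.update(kw)
    return SelectedModel(terms=frozenset(terms), **defaults)


def _cmp(selected, tm, corr):
    return SelectionComparison.from_models(selected, tm, corr)


@pytest.fixture
def scenario2_truth():
    """True model X0..X4 with one interaction X0*X1 (strong positive)."""
    return make_true_model(SCENARIOS["2e"], (0, 1, 2, 3, 4))


class TestCountsAndSizes:
    def test_worked_size_example(self, scenario2_truth):
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        fitted = _sel({main(0), main(1), quad(0), inter(0, 1)})
        assert relative_model_size(fitted, tm) == pytest.approx(4 / 5)
        assert relative_number_of_variables(fitted, tm) == pytest.approx(2 / 5)

    def test_identity_and_empty(self, scenario2_truth):
        tm = scenario2_truth
        same = _sel(tm.terms)
        assert relative_model_size(same, tm) == 1.0
        assert relative_number_of_variables(same, tm) == 1.0
        empty = _sel(set())
        assert relative_model_size(empty, tm) == 0.0
        assert relative_number_of_variables(empty, tm) == 0.0


class TestSensitivities:
    def test_superset_gives_one(self, scenario2_truth):
        tm = scenario2_truth
        fitted = _sel(set(tm.terms) | {main(10)})
        cmp = _cmp(fitted, tm, _toy_corr(20))
        assert sensitivity_terms(cmp) == 1.0
        assert sensitivity_variables(cmp) == 1.0
        assert sensitivity_interactions(cmp) == 1.0

    def test_mains_only_on_interaction_truth(self, scenario2_truth):
        tm = scenario2_truth
        fitted = _sel({main(i) for i in range(5)})
        cmp = _cmp(fitted, tm, _toy_corr(10))
        assert sensitivity_terms(cmp) == pytest.approx(5 / 6)
        assert sensitivity_interactions(cmp) == 0.0
        assert sensitivity_variables(cmp) == 1.0

    def test_interaction_matching_is_unordered(self, scenario2_truth):
        fitted = _sel({inter(1, 0)})
        cmp = _cmp(fitted, scenario2_truth, _toy_corr(10))
        assert sensitivity_interactions(cmp) == 1.0

    def test_quad_is_false_term_but_true_variable(self, scenario2_truth):
        tm = scenario2_truth
        fitted = _sel({quad(0)})
        cmp = _cmp(fitted, tm, _toy_corr(10))
        assert sensitivity_terms(cmp) == 0.0
        assert sensitivity_variables(cmp) == pytest.approx(1 / 5)
        assert fdp_terms(cmp) == 1.0
        assert fdp_variables(cmp) == 0.0


class TestAlternativeMeasures:
    def test_perfect_proxies_graded_at_their_correlation(self):
        """Each true predictor missed but proxied at |r|=0.9."""
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        corr = _toy_corr(10, [(i, i + 5, 0.9) for i in range(5)])
        fitted = _sel({main(i + 5) for i in range(5)})
        cmp = _cmp(fitted, tm, corr)
        assert alt_sensitivity(cmp) == pytest.approx(0.9)
        assert sensitivity_terms(cmp) == 0.0
        assert alt_fdp(cmp) == pytest.approx(0.1)
        assert fdp_variables(cmp) == 1.0

    def test_detected_predictors_score_one(self, scenario2_truth):
        tm = scenario2_truth
        fitted = _sel(set(tm.terms))
        cmp = _cmp(fitted, tm, _toy_corr(10))
        assert alt_sensitivity(cmp) == 1.0
        assert alt_fdp(cmp) == 0.0

    def test_uncorrelated_selection_scores_zero(self):
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        fitted = _sel({main(7)})
        cmp = _cmp(fitted, tm, _toy_corr(10))
        assert alt_sensitivity(cmp) == 0.0
        assert alt_fdp(cmp) == 1.0

    def test_negative_correlations_count_in_absolute_value(self):
        tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
        corr = _toy_corr(10, [(i, i + 5, -0.9) for i in range(5)])
        fitted = _sel({main(i + 5) for i in range(5)})
        cmp = _cmp(fitted, tm, corr)
        assert alt_sensitivity(cmp) == pytest.approx(0.9)

    def test_relabeling_invariance(self, rng):
        """Permuting exposure labels leaves every measure unchanged."""
        tm = make_true_model(SCENARIOS["2e"], (0, 1, 2, 3, 4))
        corr = np.eye(12)
        corr[0, 7] = corr[7, 0] = 0.8
        fitted = _sel({main(0), main(7), inter(0, 7)})
        base = evaluate(fitted, _study_stub(tm), corr)

        perm = rng.permutation(12)
        inv = np.argsort(perm)
        corr_p = corr[np.ix_(inv, inv)]
        tm_p = make_true_model(
            SCENARIOS["2e"], tuple(int(perm[i]) for i in (0, 1, 2, 3, 4)))
        fitted_p = _sel({main(int(perm[0])), main(int(perm[7])),
                         inter(int(perm[0]), int(perm[7]))})
        permuted = evaluate(fitted_p, _study_stub(tm_p), corr_p)
        for k, v in base.as_dict().items():
            if k == "r2_rel":
                continue
            got = permuted.as_dict()[k]
            assert (np.isnan(v) and np.isnan(got)) or got == pytest.approx(v)

    def test_alt_sens_dominates_sens(self, rng):
        """AltSens >= Sensvar because self-correlation is 1."""
        for s in range(20):
            r = np.random.default_rng(s)
            A = r.standard_normal((8, 8))
            corr = np.corrcoef(A @ A.T + 8 * np.eye(8))
            tm = make_true_model(SCENARIOS["1a"], (0, 1, 2, 3, 4))
            picked = r.choice(8, size=r.integers(1, 6), replace=False)
            fitted = _sel({main(int(i)) for i in picked})
            cmp = _cmp(fitted, tm, corr)
            assert alt_sensitivity(cmp) >= sensitivity_variables(cmp) - 1e-12
            assert alt_fdp(cmp) <= fdp_variables(cmp) + 1e-12


def _study_stub(tm):
    class _S:
        true_model = tm
    return _S()


class TestR2Relative:
    def _study(self, default_model, sid="1c", rep=0):
        return simulate_study(SCENARIOS[sid], default_model, rep, seed=4,
                              n_train=600, n_valid=5000)

    def test_true_model_scores_one(self, default_model):
        from expobench import ols_fit

        st = self._study(default_model)
        fit = ols_fit(st.train_exposures, st.train_outcome,
                      st.true_model.terms)
        res = SelectionResults(_sel(st.true_model.terms), predictor=fit.predict)
        assert r2_relative(res, st) == pytest.approx(1.0, abs=1e-9)

    def test_empty_model_scores_zero(self, default_model):
        st = self._study(default_model)
        mu = float(st.train_outcome.mean())
        res = SelectionResults(
            _sel(set()), predictor=lambda E: np.full(E.values.shape[0], mu))
        assert abs(r2_relative(res, st)) < 0.05

    def test_proxy_attenuation(self):
        """A single 0.9-proxy of the only effective predictor -> ~0.81."""
        from expobench import ols_fit, simulate_exposures
        from expobench.scenarios import make_true_model, simulate_outcome
        from dataclasses import replace

        R = _toy_corr(6, [(0, 5, 0.9)])
        model = CorrelationModel(matrix=R, family_labels=np.zeros(6, int),
                                 high_block=(), low_block=())
        spec = replace(SCENARIOS["1a"], sigma=1.0,
                       betas=(0.0, 1.0, 0.0, 0.0, 0.0, 0.0))
        tm = make_true_model(spec, (0, 1, 2, 3, 4))
        E_tr = simulate_exposures(model, 5000, seed=1)
        y_tr = simulate_outcome(E_tr, tm, seed=2)
        E_va = simulate_exposures(model, 50000, seed=3)
        y_va = simulate_outcome(E_va, tm, seed=4)

        class _St:
            train_exposures, train_outcome = E_tr, y_tr
            valid_exposures, valid_outcome = E_va, y_va
            true_model = tm
        proxy_fit = ols_fit(E_tr, y_tr, [main(5)])
        res = SelectionResults(_sel({main(5)}), predictor=proxy_fit.predict)
        assert r2_relative(res, _St()) == pytest.approx(0.81, abs=0.03)


class TestEvaluateAvailability:
    def test_screening_method_lacks_r2rel(self, default_model):
        st = simulate_study(SCENARIOS["2e"], default_model, 0, seed=1,
                            n_train=200, n_valid=100)
        sel = _sel({main(0)}, has_single_model=False, predicts=False)
        rep = evaluate(sel, st, default_model)
        assert np.isnan(rep.r2_rel)
        assert np.isfinite(rep.sens)
        assert np.isfinite(rep.rms)

    def test_mains_only_method_lacks_interaction_measures(self, default_model):
        st = simulate_study(SCENARIOS["2e"], default_model, 0, seed=1,
                            n_train=200, n_valid=100)
        sel = _sel({main(0)}, searches_interactions=False)
        rep = evaluate(sel, st, default_model)
        assert np.isnan(rep.sens2) and np.isnan(rep.fdp2)
        assert np.isnan(rep.alt_sens2) and np.isnan(rep.alt_fdp2)

    def test_tree_ensemble_lacks_term_measures(self, default_model):
        st = simulate_study(SCENARIOS["1c"], default_model, 0, seed=1,
                            n_train=200, n_valid=100)
        sel = _sel({main(int(st.true_model.predictor_indices[0]))},
                   has_terms=False, searches_interactions=False)
        rep = evaluate(sel, st, default_model)
        assert np.isnan(rep.rms) and np.isnan(rep.sens) and np.isnan(rep.fdp)
        assert np.isfinite(rep.rnv)
        assert np.isfinite(rep.alt_sens) and np.isfinite(rep.sens_var)

    def test_true_model_self_evaluation(self, default_model):
        from expobench import ols_fit

        st = simulate_study(SCENARIOS["2e"], default_model, 0, seed=2,
                            n_train=600, n_valid=2000)
        fit = ols_fit(st.train_exposures, st.train_outcome,
                      st.true_model.terms)
        res = SelectionResults(_sel(st.true_model.terms),
                               predictor=fit.predict)
        rep = evaluate(res, st, default_model)
        assert rep.sens == rep.sens_var == 1.0
        assert rep.fdp == rep.fdp_var == 0.0
        assert rep.rms == rep.rnv == 1.0
        assert rep.r2_rel == pytest.approx(1.0, abs=1e-9)
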