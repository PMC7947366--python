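"""Logistic regression, nomogram construction/scoring and concordance."""

import numpy as np
import pandas as pd
import pytest

from t2nomo import (LogisticFit, build_nomogram, c_index, fit_logistic,
                    or_forest_table, roc_auc, score_nomogram)
from t2nomo.errors import (CollinearityError, DegenerateLabelsError,
                           SchemaError, StateError)


def _table_2x2_data(a, b, c, d):
    """Binary predictor/outcome data reproducing a 2x2 table."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return pd.DataFrame({"flag": x}), y.astype(int)


class TestFitLogistic:
    def test_single_predictor_matches_2x2_closed_form(self):
        """OR = ad/bc and Wald CI = exp(ln OR +/- 1.96*sqrt(sum 1/n_ij))."""
        X, y = _table_2x2_data(42, 24, 6, 18)
        fit = fit_logistic(X, y)
        assert fit.converged
        assert fit.or_[0] == pytest.approx(42 * 18 / (24 * 6), rel=1e-6)
        se = np.sqrt(1 / 42 + 1 / 24 + 1 / 6 + 1 / 18)
        lo, hi = np.exp(np.log(5.25) + np.r_[-1, 1] * 1.959964 * se)
        assert fit.ci95[0, 0] == pytest.approx(lo, rel=1e-4)   # ~1.83
        assert fit.ci95[0, 1] == pytest.approx(hi, rel=1e-4)   # ~15.02
        assert fit.max_score_residual < 1e-8

    def test_null_predictor_recovers_zero(self, rng):
        n = 10_000
        x = rng.integers(0, 2, n)
        y = rng.permutation(np.repeat([0, 1], n // 2))
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_parameter_recovery_at_large_n(self, rng):
        n = 100_000
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        lp = -3.5 + 2.5 * x1 + 1.5 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = fit_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y)
        assert fit.converged
        assert abs(fit.beta[0] - 2.5) < 3 * fit.se[0]
        assert abs(fit.beta[1] - 1.5) < 3 * fit.se[1]
        assert abs(fit.intercept + 3.5) < 3 * fit.intercept_se

    def test_score_equations_vanish_at_convergence(self, rng):
        n = 500
        X = pd.DataFrame(rng.integers(0, 2, (n, 3)), columns=list("abc"))
        y = (rng.random(n) < 0.4).astype(int)
        fit = fit_logistic(X, y)
        assert fit.converged
        assert fit.max_score_residual < 1e-8

    def test_perfect_separation_flagged_not_raised(self):
        X = pd.DataFrame({"x": [0, 0, 0, 1, 1, 1]})
        y = np.array([0, 0, 0, 1, 1, 1])
        fit = fit_logistic(X, y)
        assert not fit.converged

    def test_constant_column_raises_collinearity(self):
        X = pd.DataFrame({"x": [1.0] * 6})
        with pytest.raises(CollinearityError):
            fit_logistic(X, [0, 1, 0, 1, 0, 1])

    def test_duplicated_column_raises_collinearity(self):
        x = [0, 1, 0, 1, 1, 0]
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(CollinearityError):
            fit_logistic(X, [0, 1, 0, 1, 1, 0])

    def test_single_class_outcome_raises(self):
        with pytest.raises(DegenerateLabelsError):
            fit_logistic(pd.DataFrame({"x": [0, 1, 0]}), [1, 1, 1])


class TestForestTable:
    def test_rows_preserve_design_order_and_or_equals_exp_beta(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, (300, 3)),
                         columns=["p95", "skewness", "entropy"])
        y = (rng.random(300) < 0.5).astype(int)
        fit = fit_logistic(X, y)
        tab = or_forest_table(fit)
        assert list(tab["predictor"]) == ["p95", "skewness", "entropy"]
        assert np.allclose(tab["or"], np.exp(tab["beta"]))

    def test_wald_p_consistent_with_likelihood_ratio(self, rng):
        """Wald and LR tests agree within an order of magnitude on a
        well-conditioned fit."""
        import statsmodels.api as sm
        n = 2000
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        full = sm.Logit(y, np.column_stack([np.ones(n), x])).fit(disp=0)
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        from scipy.stats import chi2
        lr_p = chi2.sf(2 * (full.llf - null.llf), 1)
        wald_p = fit.p_values[0]
        assert 0.1 < wald_p / lr_p < 10 or (wald_p < 1e-12 and lr_p < 1e-12)

    def test_none_raises_state_error(self):
        with pytest.raises(StateError):
            or_forest_table(None)


def _printed_fit():
    """The published three-predictor model: betas for p95>88.1, skewness>0.31,
    entropy>3.41 with intercept -3.518."""
    return LogisticFit(
        names=["p95", "skewness", "entropy"],
        beta=np.array([2.491, 1.476, 1.37]),
        se=np.array([0.566, 0.265, 0.278]),
        intercept=-3.518, intercept_se=0.467,
        converged=True, n_iterations=5, n_obs=90, max_score_residual=0.0)


class TestNomogram:
    def test_baseline_probability_from_printed_intercept(self):
        nomo = build_nomogram(_printed_fit())
        points, prob = score_nomogram(nomo, {"p95": 0, "skewness": 0,
                                             "entropy": 0})
        assert points == 0.0
        assert prob == pytest.approx(1 / (1 + np.exp(3.518)), abs=1e-12)
        assert prob == pytest.approx(0.0288, abs=5e-4)

    def test_full_positive_probability_from_printed_betas(self):
        nomo = build_nomogram(_printed_fit())
        _, prob = score_nomogram(nomo, {"p95": 1, "skewness": 1, "entropy": 1})
        # lp = -3.518 + 2.491 + 1.476 + 1.37 = 1.819
        assert prob == pytest.approx(1 / (1 + np.exp(-1.819)), abs=1e-12)
        assert prob == pytest.approx(0.860, abs=5e-4)

    def test_exactly_one_predictor_attains_100_points(self):
        nomo = build_nomogram(_printed_fit())
        pts = sorted(nomo.points_per_unit.values())
        assert pts[-1] == pytest.approx(100.0)
        assert pts[-2] < 100.0
        assert nomo.points_per_unit["p95"] == pytest.approx(100.0)

    def test_points_invariant_to_beta_rescaling(self):
        fit = _printed_fit()
        scaled = LogisticFit(names=fit.names, beta=2 * fit.beta, se=fit.se,
                             intercept=fit.intercept,
                             intercept_se=fit.intercept_se, converged=True,
                             n_iterations=5, n_obs=90, max_score_residual=0.0)
        a = build_nomogram(fit).points_per_unit
        b = build_nomogram(scaled).points_per_unit
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-12)

    def test_scoring_equals_direct_logistic_on_lattice(self):
        fit = _printed_fit()
        nomo = build_nomogram(fit)
        for x1 in (0, 1):
            for x2 in (0, 1):
                for x3 in (0, 1):
                    _, prob = score_nomogram(
                        nomo, {"p95": x1, "skewness": x2, "entropy": x3})
                    direct = fit.predict_proba(np.array([[x1, x2, x3]]))[0]
                    assert prob == pytest.approx(direct, abs=1e-9)

    def test_scoring_equals_logistic_on_random_fits(self, rng):
        for _ in range(100):
            k = int(rng.integers(1, 5))
            fit = LogisticFit(
                names=[f"x{i}" for i in range(k)],
                beta=rng.uniform(0.1, 3.0, k), se=np.full(k, 0.3),
                intercept=float(rng.normal(-2, 1)), intercept_se=0.4,
                converged=True, n_iterations=4, n_obs=100,
                max_score_residual=0.0)
            nomo = build_nomogram(fit)
            x = rng.integers(0, 2, k)
            _, prob = score_nomogram(nomo, dict(zip(fit.names, x)))
            assert prob == pytest.approx(fit.predict_proba(x[None, :])[0],
                                         abs=1e-9)

    def test_probability_monotone_in_positive_predictors(self):
        nomo = build_nomogram(_printed_fit())
        probs = [score_nomogram(nomo, {"p95": a, "skewness": b, "entropy": c})[1]
                 for a, b, c in [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)]]
        assert np.all(np.diff(probs) > 0)

    def test_negative_beta_recorded_as_sign_warning(self):
        fit = LogisticFit(names=["a", "b"], beta=np.array([1.2, -0.4]),
                          se=np.array([0.3, 0.3]), intercept=-1.0,
                          intercept_se=0.3, converged=True, n_iterations=3,
                          n_obs=50, max_score_residual=0.0)
        nomo = build_nomogram(fit)
        assert any("b" in w for w in nomo.warnings)
        # identity with the logistic model still holds
        _, prob = score_nomogram(nomo, {"a": 1, "b": 1})
        assert prob == pytest.approx(fit.predict_proba([[1, 1]])[0], abs=1e-9)

    def test_non_converged_fit_rejected(self):
        fit = _printed_fit()
        fit.converged = False
        with pytest.raises(StateError):
            build_nomogram(fit)

    def test_unknown_predictor_name_raises_schema_error(self):
        nomo = build_nomogram(_printed_fit())
        with pytest.raises(SchemaError):
            score_nomogram(nomo, {"p95": 1, "skewness": 0, "bogus": 1})

    def test_json_round_trip_preserves_scoring(self):
        from t2nomo import NomogramModel
        nomo = build_nomogram(_printed_fit())
        back = NomogramModel.from_json(nomo.to_json())
        vals = {"p95": 1, "skewness": 0, "entropy": 1}
        assert score_nomogram(back, vals) == pytest.approx(
            score_nomogram(nomo, vals))


class TestCIndex:
    def test_perfect_ranking(self):
        assert c_index([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_equals_rank_auc(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40).round(1)
        assert c_index(p, y) == pytest.approx(roc_auc(p, y).auc, abs=1e-12)

    def test_matches_all_pairs_brute_force(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        p = rng.random(40).round(1)
        pos, neg = p[y == 1], p[y == 0]
        brute = np.mean((pos[:, None] > neg[None, :])
                        + 0.5 * (pos[:, None] == neg[None, :]))
        assert c_index(p, y) == pytest.approx(brute, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            c_index([0.5, 0.6], [1, 1])
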