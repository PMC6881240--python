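"""FIML engine: moment algebra, objective, optimizer, score tests."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lcsm.builders import BuilderConfig, build_univariate_lcs
from lcsm.data import LongitudinalTable
from lcsm.estimation import (
    CompiledModel,
    _make_patterns,
    fiml_loglik,
    fit,
    implied_moments,
    modification_indices,
    saturated_and_null_fits,
    start_values,
)
from lcsm.model import PathModel, edit_parameters, free
from lcsm.simulate import DomainTruth, TrueParameters, simulate_dataset

from conftest import simulate_small_lcs

TRUTH_SMALL = {
    "mu_I:g": 50.0, "mu_S:g": -0.5, "var_I:g": 4.0, "var_S:g": 0.09,
    "cov_IS:g": 0.0,
    "evar:g:y:t0": 1.0, "evar:g:y:t1": 1.0, "evar:g:y:t2": 1.0,
    "evar:g:y:t3": 1.0,
}


def saturated_path_model(variables: list[str]) -> PathModel:
    """Free means and full covariance: the saturated model as a PathModel."""
    p = len(variables)
    A = np.full((p, p), 0.0, dtype=object)
    S = np.empty((p, p), dtype=object)
    M = np.empty(p, dtype=object)
    for i in range(p):
        M[i] = f"m{i}"
        for j in range(p):
            a, b = min(i, j), max(i, j)
            S[i, j] = f"s{a}_{b}"
    return PathModel(list(variables), p, A, S, M)


def growth_curve_model() -> PathModel:
    """Linear latent growth curve on y_t0..y_t3: the reparameterization
    oracle for the constant-change LCS model."""
    names = ["y_t0", "y_t1", "y_t2", "y_t3", "I", "S"]
    n = len(names)
    A = np.full((n, n), 0.0, dtype=object)
    S = np.full((n, n), 0.0, dtype=object)
    M = np.full(n, 0.0, dtype=object)
    for t in range(4):
        A[t, 4] = 1.0
        A[t, 5] = float(t)
        S[t, t] = f"evar:g:y:t{t}"
    S[4, 4] = "var_I:g"
    S[5, 5] = "var_S:g"
    S[4, 5] = S[5, 4] = "cov_IS:g"
    M[4] = "mu_I:g"
    M[5] = "mu_S:g"
    return PathModel(names, 4, A, S, M)


class TestImpliedMoments:
    def test_no_directed_edges_is_identity_case(self):
        model = saturated_path_model(["a", "b", "c"])
        est = {f"m{i}": float(i) for i in range(3)}
        est.update({f"s{i}_{j}": (2.0 if i == j else 0.5)
                    for i in range(3) for j in range(i, 3)})
        Sigma, mu = implied_moments(model, est)
        expect = np.full((3, 3), 0.5)
        np.fill_diagonal(expect, 2.0)
        assert np.allclose(Sigma, expect)
        assert np.allclose(mu, [0.0, 1.0, 2.0])

    def test_matches_brute_force_simulation(self, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        Sigma, mu = implied_moments(model, TRUTH_SMALL)
        big = simulate_small_lcs(
            200_000, seed=12, sd_i=2.0, sd_s=0.3, cov_is=0.0, resid_sd=1.0
        )
        X = big.to_numpy()
        n = X.shape[0]
        mu_hat = X.mean(axis=0)
        S_hat = np.cov(X.T, bias=True)
        # Monte-Carlo standard errors for each moment
        se_mu = np.sqrt(np.diag(Sigma) / n)
        assert np.all(np.abs(mu_hat - mu) < 4 * se_mu)
        for i in range(4):
            for j in range(i, 4):
                se = math.sqrt(
                    (Sigma[i, i] * Sigma[j, j] + Sigma[i, j] ** 2) / n
                )
                assert abs(S_hat[i, j] - Sigma[i, j]) < 4 * se

    def test_growth_curve_reparameterization_same_moments(self, small_lcs_config):
        lcs = build_univariate_lcs(small_lcs_config)
        lgc = growth_curve_model()
        S1, m1 = implied_moments(lcs, TRUTH_SMALL)
        S2, m2 = implied_moments(lgc, TRUTH_SMALL)
        assert np.allclose(S1, S2, atol=1e-10)
        assert np.allclose(m1, m2, atol=1e-10)

    def test_singular_structure_rejected(self):
        names = ["y", "eta"]
        A = np.array([[0.0, 1.0], [0.0, 1.0]], dtype=object)  # eta -> eta unit
        S = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=object)
        M = np.array([0.0, 0.0], dtype=object)
        model = PathModel(names, 1, A, S, M)
        with pytest.raises(ValueError, match="singular"):
            implied_moments(model, {})


class TestFimlObjective:
    def test_complete_data_equals_multivariate_normal(self, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        df = simulate_small_lcs(80, seed=3)
        Sigma, mu = implied_moments(model, TRUTH_SMALL)
        expected = stats.multivariate_normal(mu, Sigma).logpdf(
            df.to_numpy()
        ).sum()
        assert fiml_loglik(model, TRUTH_SMALL, df) == pytest.approx(expected)

    def test_univariate_missing_closed_form(self):
        model = PathModel(
            ["x", "z"], 2,
            np.full((2, 2), 0.0, dtype=object),
            np.array([["v", 0.0], [0.0, "vz"]], dtype=object),
            np.array(["m", "mz"], dtype=object),
        )
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 2.0, size=40)
        x[::2] = np.nan  # half missing
        z = rng.normal(0.0, 1.0, size=40)
        df = pd.DataFrame({"x": x, "z": z})
        est = {"m": 1.1, "v": 3.5, "mz": 0.0, "vz": 1.0}
        obs = x[~np.isnan(x)]
        expected = stats.norm(1.1, math.sqrt(3.5)).logpdf(obs).sum() + stats.norm(
            0.0, 1.0
        ).logpdf(z).sum()
        assert fiml_loglik(model, est, df) == pytest.approx(expected)

    def test_marginalization_property(self, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        df = simulate_small_lcs(50, seed=9)
        base = fiml_loglik(model, TRUTH_SMALL, df)
        extra = pd.DataFrame(
            {"y_t0": [49.0], "y_t1": [np.nan], "y_t2": [np.nan], "y_t3": [np.nan]}
        )
        aug = pd.concat([df, extra], ignore_index=True)
        Sigma, mu = implied_moments(model, TRUTH_SMALL)
        marginal = stats.norm(mu[0], math.sqrt(Sigma[0, 0])).logpdf(49.0)
        assert fiml_loglik(model, TRUTH_SMALL, aug) == pytest.approx(
            base + marginal
        )

    def test_nonpositive_definite_penalized_and_recorded(self, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        df = simulate_small_lcs(30, seed=1)
        bad = dict(TRUTH_SMALL, **{"evar:g:y:t0": -8.0, "var_I:g": 0.01})
        violations: list = []
        ll = fiml_loglik(model, bad, df, violations=violations)
        assert ll < -1e7
        assert violations

    def test_analytic_gradient_matches_finite_differences(self, small_lcs_data,
                                                          small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        cm = CompiledModel(model)
        X = small_lcs_data.matrix(model.observed_names)
        pats = _make_patterns(X)
        theta = start_values(model, small_lcs_data)
        _, g = cm.loglik_grad(theta, pats)
        for i in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (
                cm.loglik_grad(tp, pats, want_grad=False)[0]
                - cm.loglik_grad(tm, pats, want_grad=False)[0]
            ) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestFit:
    def test_saturated_model_reproduces_sample_moments(self):
        df = simulate_small_lcs(120, seed=21)
        model = saturated_path_model(list(df.columns))
        res = fit(model, df, compute_se=False)
        assert res.converged
        X = df.to_numpy()
        assert np.allclose(res.mu, X.mean(axis=0), atol=1e-4)
        assert np.allclose(res.sigma, np.cov(X.T, bias=True), atol=1e-3)
        sat, _ = saturated_and_null_fits(df, list(df.columns))
        chi2 = 2.0 * (sat.log_likelihood - res.log_likelihood)
        assert abs(chi2) < 1e-4
        assert res.df == 0

    def test_parameter_recovery_univariate(self, small_lcs_config):
        df = simulate_small_lcs(500, seed=42, sd_i=2.0, sd_s=0.3, resid_sd=1.0)
        model = build_univariate_lcs(small_lcs_config)
        res = fit(model, df)
        assert res.converged
        for lab, truth in TRUTH_SMALL.items():
            se = res.standard_errors[lab]
            assert abs(res.estimates[lab] - truth) < 3.5 * se, lab

    def test_zero_slope_variance_boundary(self, small_lcs_config):
        df = simulate_small_lcs(250, seed=6, sd_s=0.0)
        model = build_univariate_lcs(small_lcs_config)
        with pytest.warns(UserWarning, match="Heywood"):
            loose = fit(model, df, compute_se=False)
        assert "var_S:g" in loose.heywood_flags
        fixed = fit(model, df, compute_se=False, heywood_fix=True)
        assert fixed.converged
        assert fixed.estimates.get("var_S:g") is None  # fixed to 0, not free
        assert fixed.df == loose.df + 1
        assert loose.log_likelihood - fixed.log_likelihood < 2.0

    def test_growth_curve_and_lcs_fits_agree(self, small_lcs_data, small_lcs_config):
        lcs_fit = fit(build_univariate_lcs(small_lcs_config), small_lcs_data,
                      compute_se=False)
        lgc_fit = fit(growth_curve_model(), small_lcs_data, compute_se=False)
        assert lcs_fit.converged and lgc_fit.converged
        assert lcs_fit.log_likelihood == pytest.approx(
            lgc_fit.log_likelihood, abs=1e-4
        )
        for lab in ("mu_I:g", "mu_S:g", "var_I:g", "var_S:g"):
            assert lcs_fit.estimates[lab] == pytest.approx(
                lgc_fit.estimates[lab], abs=1e-3
            )

    def test_invariant_to_row_order_and_column_permutation(
        self, small_lcs_data, small_lcs_config
    ):
        model = build_univariate_lcs(small_lcs_config)
        base = fit(model, small_lcs_data, compute_se=False)
        df = small_lcs_data.df
        shuffled = df.sample(frac=1.0, random_state=3)[list(df.columns)[::-1]]
        other = fit(model, LongitudinalTable(shuffled), compute_se=False)
        assert other.log_likelihood == pytest.approx(
            base.log_likelihood, abs=1e-5
        )

    def test_indicator_rescaling_preserves_chi_square(self):
        # measurement scale changes move estimates predictably but not fit
        truth = TrueParameters(
            domains=(
                DomainTruth(
                    domain="q",
                    indicators=("a", "b", "c"),
                    loadings=(1.0, 0.8, 1.2),
                    intercepts=(0.0, 1.0, -1.0),
                    residual_sd=(1.0, 1.0, 1.0),
                    icept_mean=10.0, icept_sd=2.0,
                    slope_mean=-0.3, slope_sd=0.3,
                ),
            ),
            occasions=(0, 1, 2), phantom=(), covariates=(),
            cell_missing_rate=0.0, covariate_missing_rate=0.0,
        )
        tab, _ = simulate_dataset(truth, 250, schedule=None, seed=8)
        cfg = BuilderConfig(
            domain="q", indicators=("a", "b", "c"), occasions=(0, 1, 2),
            phantom=(), covariates=(),
        )
        model = build_univariate_lcs(cfg)
        res1 = fit(model, tab, compute_se=False)
        scaled = tab.df.copy()
        for col in scaled.columns:
            if col.startswith("b_t"):
                scaled[col] = scaled[col] * 100.0
        res2 = fit(model, LongitudinalTable(scaled), compute_se=False)
        sat1, _ = saturated_and_null_fits(tab, model.observed_names)
        sat2, _ = saturated_and_null_fits(
            LongitudinalTable(scaled), model.observed_names
        )
        chi1 = 2 * (sat1.log_likelihood - res1.log_likelihood)
        chi2 = 2 * (sat2.log_likelihood - res2.log_likelihood)
        assert chi1 == pytest.approx(chi2, abs=0.02)
        assert res2.estimates["lam:q:b"] == pytest.approx(
            100.0 * res1.estimates["lam:q:b"], rel=1e-3
        )

    def test_unidentified_model_rejected(self):
        model = saturated_path_model(["a", "b"])
        extra = edit_parameters(
            model, [(model.by_name("A", "a", "b"), free())]
        )
        with pytest.raises(ValueError, match="identified"):
            fit(extra, pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 1.5]}))


class TestSaturatedAndNull:
    def test_complete_data_saturated_equals_sample_moments(self):
        df = simulate_small_lcs(90, seed=33)
        sat, null = saturated_and_null_fits(df, list(df.columns))
        X = df.to_numpy()
        assert np.allclose(sat.mu, X.mean(axis=0))
        assert np.allclose(sat.sigma, np.cov(X.T, bias=True))
        p = X.shape[1]
        assert null.df - sat.df == p * (p - 1) // 2

    def test_independent_variables_converge_per_observation(self):
        rng = np.random.default_rng(2)

        def gap(n):
            df = pd.DataFrame(
                {"u": rng.standard_normal(n), "v": rng.standard_normal(n)}
            )
            sat, null = saturated_and_null_fits(df, ["u", "v"])
            return (sat.log_likelihood - null.log_likelihood) / n

        assert gap(4000) < gap(150) or gap(4000) < 0.01

    def test_saturated_monotone_over_any_model(self, small_lcs_data, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        res = fit(model, small_lcs_data, compute_se=False)
        sat, _ = saturated_and_null_fits(
            small_lcs_data, model.observed_names
        )
        assert sat.log_likelihood >= res.log_likelihood - 1e-6


def _planted_intercept_setup(drift: float, seed: int):
    ps = DomainTruth(
        domain="q",
        indicators=("a", "b", "c"),
        loadings=(1.0, 0.9, 1.1),
        intercepts=(0.0, 1.0, -1.0),
        residual_sd=(1.0, 1.0, 1.0),
        icept_mean=10.0, icept_sd=2.0, slope_mean=-0.3, slope_sd=0.3,
        intercept_drift=(("b", 1.0, drift), ("b", 2.0, drift)),
    )
    truth = TrueParameters(
        domains=(ps,), occasions=(0, 1, 2), phantom=(), covariates=(),
        cell_missing_rate=0.0, covariate_missing_rate=0.0,
    )
    tab, _ = simulate_dataset(truth, 350, schedule=None, seed=seed)
    cfg = BuilderConfig(
        domain="q", indicators=("a", "b", "c"), occasions=(0, 1, 2),
        phantom=(), covariates=(),
    )
    return tab, cfg


class TestModificationIndices:
    def test_null_indices_near_central_chi2(self):
        tab, cfg = _planted_intercept_setup(drift=0.0, seed=4)
        res = fit(build_univariate_lcs(cfg), tab)
        table = modification_indices(res)
        vals = table["mi"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        assert len(vals) >= 4
        # central chi2(1): mean 1; loose band for a single dataset
        assert 0.05 < vals.mean() < 3.0

    def test_planted_intercept_attains_max_index(self):
        tab, cfg = _planted_intercept_setup(drift=1.2, seed=6)
        model = build_univariate_lcs(cfg)
        res = fit(model, tab)
        candidates = [
            model.by_name("M", f"{ind}_t{t}")
            for ind in ("b", "c")
            for t in (0, 1, 2)
        ]
        table = modification_indices(res, candidates)
        top = table.loc[table["mi"].idxmax()]
        assert top["row"].startswith("b_t")

    def test_freeing_top_cell_recovers_index_as_chi2_drop(self):
        tab, cfg = _planted_intercept_setup(drift=1.2, seed=6)
        model = build_univariate_lcs(cfg)
        res = fit(model, tab)
        table = modification_indices(res)
        top = table.loc[table["mi"].idxmax()]
        cell = model.by_name("M", top["row"])
        freed = edit_parameters(model, [(cell, free())])
        res2 = fit(freed, tab, compute_se=False)
        drop = 2.0 * (res2.log_likelihood - res.log_likelihood)
        assert drop > 0
        assert drop == pytest.approx(top["mi"], rel=0.5)

    def test_requires_converged_fit(self, small_lcs_data, small_lcs_config):
        model = build_univariate_lcs(small_lcs_config)
        res = fit(model, small_lcs_data, compute_se=False)
        res.converged = False
        with pytest.raises(ValueError, match="converged"):
            modification_indices(res)
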