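"""Beta and one-inflated beta regression: likelihood, MLE, diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import kstest

from qolnorm._util import (
    ConvergenceError,
    PerfectFitWarning,
    SeparationWarning,
    ValidationError,
    sigmoid,
)
from qolnorm.design import DesignSpec
from qolnorm.betareg import (
    beta_logpdf,
    cox_snell_r2,
    fit_beta_regression,
    fit_logistic,
    fit_one_inflated,
    gamlss_sigma_to_phi,
    phi_to_gamlss_sigma,
    rq_residuals,
)


def simulate_beta(n, coefs, phi, seed, x_dist="binary"):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.4, n).astype(float) if x_dist == "binary" else rng.uniform(0, 1, n)
    mu = sigmoid(coefs[0] + coefs[1] * x)
    y = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-12, 1 - 1e-12)
    return pd.DataFrame({"x": x, "y": y})


class TestDensity:
    def test_uniform_case(self, rng):
        # mu=0.5, phi=2 is Beta(1,1): log-density 0 everywhere
        y = rng.random(50)
        assert np.allclose(beta_logpdf(y, 0.5, 2.0), 0.0)

    def test_beta22_closed_form(self):
        # mu=0.5, phi=4 is Beta(2,2): density 6 y (1-y); at y=0.5 -> 1.5
        assert beta_logpdf(0.5, 0.5, 4.0) == pytest.approx(np.log(1.5), abs=1e-12)

    def test_normalisation(self):
        val, _ = integrate.quad(lambda y: np.exp(beta_logpdf(y, 0.3, 7.0)), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_boundary_rejected(self):
        with pytest.raises(ValidationError):
            beta_logpdf(0.0, 0.5, 2.0)

    def test_gamlss_sigma_mapping_roundtrips(self):
        phi = np.array([0.5, 2.0, 10.0, 123.4])
        assert np.allclose(gamlss_sigma_to_phi(phi_to_gamlss_sigma(phi)), phi)
        # variance identity: var = mu(1-mu) sigma^2
        assert phi_to_gamlss_sigma(3.0) ** 2 == pytest.approx(1 / 4)


class TestBetaMle:
    def test_matches_statsmodels_oracle(self):
        """Independent cross-check against the statsmodels beta MLE."""
        from statsmodels.othermod.betareg import BetaModel

        df = simulate_beta(400, (0.8, -0.5), 6.0, seed=5)
        spec = DesignSpec.from_formula("y ~ x")
        fit = fit_beta_regression(spec, df["y"].to_numpy(), data=df)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        sm = BetaModel(df["y"], X).fit(disp=0)
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-6)
        assert np.allclose(fit.coefs.to_numpy(), sm.params[:2], atol=1e-5)
        assert fit.phi == pytest.approx(np.exp(sm.params[-1]), rel=1e-4)

    def test_gradient_matches_finite_differences(self, rng):
        from qolnorm.betareg import _beta_ll_grad_hess
        from qolnorm._util import logit

        df = simulate_beta(60, (0.3, 0.7), 4.0, seed=7)
        X = np.column_stack([np.ones(60), df["x"]])
        y = df["y"].to_numpy()
        ystar = logit(y)
        log1my = np.log1p(-y)
        for _ in range(5):
            beta = rng.normal(0, 0.5, 2)
            tau = rng.normal(1, 0.3)
            _, grad, _ = _beta_ll_grad_hess(beta, tau, X, y, ystar, log1my)
            num = np.empty(3)
            h = 1e-6
            theta = np.append(beta, tau)
            for j in range(3):
                up, dn = theta.copy(), theta.copy()
                up[j] += h
                dn[j] -= h
                lu, _, _ = _beta_ll_grad_hess(up[:2], up[2], X, y, ystar, log1my, want_hess=False)
                ld, _, _ = _beta_ll_grad_hess(dn[:2], dn[2], X, y, ystar, log1my, want_hess=False)
                num[j] = (lu - ld) / (2 * h)
            assert np.allclose(grad, num, rtol=1e-5, atol=1e-4)

    def test_loglik_trace_monotone(self):
        df = simulate_beta(300, (1.2, -0.8), 3.0, seed=11)
        fit = fit_beta_regression(DesignSpec.from_formula("y ~ x"), df["y"].to_numpy(), data=df)
        assert (np.diff(fit.trace) >= -1e-12).all()

    def test_parameter_recovery_large_n(self):
        """Quadratic-age truth recovered within 3 reported SEs at n=5000."""
        rng = np.random.default_rng(13)
        n = 5000
        age = rng.uniform(0, 99, n)
        truth = np.array([1.25, 0.03, -0.0003])
        mu = sigmoid(truth[0] + truth[1] * age + truth[2] * age**2)
        y = np.clip(rng.beta(mu * 10, (1 - mu) * 10), 1e-12, 1 - 1e-12)
        df = pd.DataFrame({"age": age, "y": y})
        fit = fit_beta_regression(
            DesignSpec.from_formula("y ~ age + I(age**2)"), y, data=df
        )
        assert np.all(np.abs(fit.coefs.to_numpy() - truth) < 3 * fit.se().to_numpy())

    def test_constant_response_perfect_fit_warning(self):
        y = np.full(80, 0.37)
        df = pd.DataFrame({"y": y})
        with pytest.warns(PerfectFitWarning):
            fit = fit_beta_regression(DesignSpec.from_formula("y ~ 1"), y, data=df)
        assert sigmoid(fit.coefs.iloc[0]) == pytest.approx(0.37, abs=1e-3)

    def test_rank_deficient_design_names_aliased_column(self):
        df = simulate_beta(100, (0.5, 0.5), 4.0, seed=17)
        df["x2"] = df["x"]  # perfect alias
        with pytest.raises(ValidationError, match="x2|x"):
            fit_beta_regression(DesignSpec.from_formula("y ~ x + x2"), df["y"].to_numpy(), data=df)

    def test_interior_outcome_required(self):
        df = pd.DataFrame({"y": [0.2, 1.0, 0.4], "x": [0.0, 1.0, 0.5]})
        with pytest.raises(ValidationError):
            fit_beta_regression(DesignSpec.from_formula("y ~ x"), df["y"].to_numpy(), data=df)


@pytest.fixture(scope="module")
def inflated_data():
    rng = np.random.default_rng(23)
    n = 1200
    x = rng.binomial(1, 0.5, n).astype(float)
    p1 = sigmoid(0.4 - 0.8 * x)
    is_one = rng.random(n) < p1
    mu = sigmoid(0.9 + 0.5 * x)
    y = np.where(is_one, 1.0, np.clip(rng.beta(mu * 5, (1 - mu) * 5), 1e-12, 1 - 1e-12))
    return pd.DataFrame({"x": x, "y": y})


@pytest.fixture(scope="module")
def inflated_fit_and_y():
    rng = np.random.default_rng(31)
    n = 600
    x = rng.uniform(0, 1, n)
    p1 = sigmoid(-0.3 + 0.6 * x)
    is_one = rng.random(n) < p1
    mu = sigmoid(0.8 - 0.4 * x)
    y = np.where(is_one, 1.0, np.clip(rng.beta(mu * 6, (1 - mu) * 6), 1e-12, 1 - 1e-12))
    d = pd.DataFrame({"x": x, "y": y})
    fit = fit_one_inflated(
        DesignSpec.from_formula("y ~ x"),
        DesignSpec.from_formula("y ~ x"),
        y,
        data=d,
    )
    return fit, y


class TestOneInflated:
    def test_factorised_loglik_identity(self, inflated_data):
        d = inflated_data
        spec_nu = DesignSpec.from_formula("y ~ x")
        spec_mu = DesignSpec.from_formula("y ~ x")
        fit = fit_one_inflated(spec_nu, spec_mu, d["y"].to_numpy(), data=d)
        assert fit.loglik == pytest.approx(fit.nu.loglik + fit.mu.loglik, abs=1e-12)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)

    def test_intercept_only_nu_equals_one_fraction(self, inflated_data):
        d = inflated_data
        fit = fit_one_inflated(
            DesignSpec.from_formula("y ~ 1"),
            DesignSpec.from_formula("y ~ x"),
            d["y"].to_numpy(),
            data=d,
        )
        frac = (d["y"] == 1.0).mean()
        assert sigmoid(fit.nu.coefs.iloc[0]) == pytest.approx(frac, abs=1e-9)

    def test_degenerate_mixture_errors(self):
        d = pd.DataFrame({"y": np.full(20, 1.0), "x": np.zeros(20)})
        with pytest.raises(ValidationError, match="degenerate mixture"):
            fit_one_inflated(
                DesignSpec.from_formula("y ~ 1"),
                DesignSpec.from_formula("y ~ 1"),
                d["y"].to_numpy(),
                data=d,
            )
        d2 = pd.DataFrame({"y": np.linspace(0.1, 0.9, 20)})
        with pytest.raises(ValidationError, match="degenerate mixture"):
            fit_one_inflated(
                DesignSpec.from_formula("y ~ 1"),
                DesignSpec.from_formula("y ~ 1"),
                d2["y"].to_numpy(),
                data=d2,
            )

    def test_separation_warning(self):
        """A covariate that perfectly predicts the one-mass must warn."""
        n = 200
        x = np.repeat([0.0, 1.0], n // 2)
        y = np.where(x == 1, 1.0, np.linspace(0.2, 0.8, n))
        d = pd.DataFrame({"x": x, "y": y})
        with pytest.warns(SeparationWarning):
            fit_logistic(DesignSpec.from_formula("y ~ x"), (d["y"] == 1.0).astype(float), data=d)


class TestPredict:
    def test_vas_prediction_consistent_with_fitted_mean(self):
        """Forward transform then predict on the training rows reproduces the
        fitted mean on the original 0-100 scale."""
        from qolnorm.betareg import predict_vas
        from qolnorm.scoring import TransformSpec, inverse_shrink, transform_vas

        rng = np.random.default_rng(41)
        n = 300
        age = rng.uniform(0, 99, n)
        mu = sigmoid(1.0 + 0.02 * age - 0.0002 * age**2)
        vas = 100 * np.clip(rng.beta(mu * 9, (1 - mu) * 9), 1e-12, 1 - 1e-12)
        spec = TransformSpec(n=n)
        df = pd.DataFrame({"age": age, "vas_t": transform_vas(vas, spec)})
        fit = fit_beta_regression(
            DesignSpec.from_formula("vas_t ~ age + I(age**2)"), df["vas_t"].to_numpy(), data=df
        )
        pred = predict_vas(fit, df, spec)
        assert np.allclose(pred, inverse_shrink(fit.mu(), spec.n) * 100.0, atol=1e-10)
        assert np.all((pred >= 0) & (pred <= 100))

    def test_intercept_only_nu_predicts_constant_one_fraction(self, inflated_data):
        from qolnorm.betareg import predict_eq5d
        from qolnorm.scoring import TransformSpec

        d = inflated_data
        fit = fit_one_inflated(
            DesignSpec.from_formula("y ~ 1"),
            DesignSpec.from_formula("y ~ x"),
            d["y"].to_numpy(),
            data=d,
        )
        spec = TransformSpec(n=len(d), min_index=-0.074, max_index=0.817)
        out = predict_eq5d(fit, d.head(10), spec)
        frac = (d["y"] == 1.0).mean()
        assert np.allclose(out["p_one"], frac, atol=1e-9)
        assert np.all(out["mean_index"] <= 1.0)


class TestDiagnostics:
    def test_cox_snell_values(self):
        assert cox_snell_r2(-100.0, -100.0, 50) == 0.0
        assert cox_snell_r2(-90.0, -100.0, 100) == pytest.approx(1 - np.exp(-0.2), abs=1e-12)
        with pytest.raises(ValidationError):
            cox_snell_r2(-90.0, -100.0, 0)
        with pytest.raises(ValidationError):
            cox_snell_r2(-101.0, -100.0, 10)

    def test_residual_zero_at_fitted_median(self):
        df = simulate_beta(150, (0.3, 0.4), 5.0, seed=29)
        fit = fit_beta_regression(DesignSpec.from_formula("y ~ x"), df["y"].to_numpy(), data=df)
        from scipy.stats import beta as beta_dist

        mu = fit.mu()
        y_med = beta_dist.ppf(0.5, mu * fit.phi, (1 - mu) * fit.phi)
        res = rq_residuals(fit, y_med, rng=1)
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_residuals_deterministic_given_seed(self, inflated_fit_and_y):
        fit, y = inflated_fit_and_y
        r1 = rq_residuals(fit, y, rng=7)
        r2 = rq_residuals(fit, y, rng=7)
        assert np.array_equal(r1, r2)
        r3 = rq_residuals(fit, y, rng=8)
        assert not np.array_equal(r1, r3)

    def test_residuals_standard_normal_under_correct_model(self):
        """KS distance below the 5% critical value in >= 90% of seeds."""
        n = 10_000
        passes = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            x = rng.binomial(1, 0.5, n).astype(float)
            mu = sigmoid(0.6 - 0.4 * x)
            y = np.clip(rng.beta(mu * 8, (1 - mu) * 8), 1e-12, 1 - 1e-12)
            d = pd.DataFrame({"x": x, "y": y})
            fit = fit_beta_regression(DesignSpec.from_formula("y ~ x"), y, data=d)
            res = rq_residuals(fit, y, rng=seed)
            if kstest(res, "norm").pvalue > 0.05:
                passes += 1
        assert passes >= 90
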