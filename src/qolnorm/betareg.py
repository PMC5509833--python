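"""Maximum-likelihood beta regression and one-inflated beta regression.

Model.  For an outcome y in the open interval (0, 1),

    y ~ Beta(mu * phi, (1 - mu) * phi),      logit(mu) = x' beta,

so E[y] = mu and Var[y] = mu (1 - mu) / (1 + phi); phi > 0 is a common
precision parameter estimated on the log scale.  (gamlss reports the same
dispersion as sigma with sigma^2 = 1 / (1 + phi); see
:func:`phi_to_gamlss_sigma`.)

For a one-inflated outcome (a point mass at exactly 1 plus a continuous
part on (0, 1)), the likelihood factorises:

    P(y = 1) = p1,                 logit(p1) = x_nu' beta_nu     ("nu model")
    y | y < 1 ~ Beta(mu, phi),     logit(mu) = x_mu' beta_mu     ("mu model")

so the nu part is exactly a logistic regression of the one-indicator and
the mu part a beta regression on the non-one rows; the joint log-likelihood
is their sum.  This is how health-utility indices with a large
perfect-health share are modelled.

Estimation is Newton ascent with analytic gradient and Hessian, step
halving to keep the log-likelihood monotone, and the observed-information
inverse as the variance-covariance matrix.  Bootstrap pooling (see
``qolnorm.pooling``) is the authoritative variance route in the survey
pipeline; the analytic vcov drives per-dataset Wald tests for selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import beta as beta_dist
from scipy.stats import chi2, norm

from ._util import (
    ConvergenceError,
    PerfectFitWarning,
    SeparationWarning,
    ValidationError,
    logit,
    sigmoid,
)
from .design import Design, DesignSpec
from .scoring import TransformSpec, inverse_shrink, inverse_transform_eq5d

_MU_EPS = 1e-10
_TAU_MAX = np.log(1e6)


def _trigamma(x):
    return polygamma(1, x)


# ---------------------------------------------------------------------------
# beta density


def beta_logpdf(y, mu, phi):
    """Log-density of Beta(mu*phi, (1-mu)*phi) in the mean/precision form."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValidationError("beta_logpdf requires y strictly inside (0, 1)")
    if np.any((mu <= 0) | (mu >= 1)) or phi <= 0:
        raise ValidationError("beta_logpdf requires mu in (0, 1) and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def phi_to_gamlss_sigma(phi):
    """Map precision phi to the gamlss dispersion sigma: sigma^2 = 1/(1+phi)."""
    if np.any(np.asarray(phi) <= 0):
        raise ValidationError("phi must be > 0")
    return np.sqrt(1.0 / (1.0 + np.asarray(phi, dtype=float)))


def gamlss_sigma_to_phi(sigma):
    sigma = np.asarray(sigma, dtype=float)
    if np.any((sigma <= 0) | (sigma >= 1)):
        raise ValidationError("sigma must be in (0, 1)")
    return 1.0 / sigma**2 - 1.0


# ---------------------------------------------------------------------------
# fits


@dataclass
class BetaFit:
    """MLE of a beta regression: mean coefficients plus log-precision."""

    coefs: pd.Series
    log_phi: float
    loglik: float
    vcov: pd.DataFrame  # over (coefs..., log_phi)
    n: int
    design: Design | None = None
    n_iter: int = 0
    converged: bool = True
    trace: list = field(default_factory=list)

    @property
    def phi(self) -> float:
        return float(np.exp(self.log_phi))

    @property
    def k(self) -> int:
        return len(self.coefs) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def mu(self, X=None) -> np.ndarray:
        X = self.design.X if X is None else np.asarray(X)
        return sigmoid(X @ self.coefs.to_numpy())

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov))[: len(self.coefs)], index=self.coefs.index)

    def wald_pvalues(self) -> pd.Series:
        z = self.coefs / self.se()
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.coefs.index)

    def term_pvalue(self, term: str) -> float:
        return _term_pvalue(self.coefs.to_numpy(), self.vcov.to_numpy(), self.design, term)


@dataclass
class LogisticFit:
    """MLE of a Bernoulli GLM with logit link (the nu model)."""

    coefs: pd.Series
    loglik: float
    vcov: pd.DataFrame
    n: int
    design: Design | None = None
    n_iter: int = 0
    converged: bool = True
    separation: bool = False

    @property
    def k(self) -> int:
        return len(self.coefs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def prob(self, X=None) -> np.ndarray:
        X = self.design.X if X is None else np.asarray(X)
        return sigmoid(X @ self.coefs.to_numpy())

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.coefs.index)

    def wald_pvalues(self) -> pd.Series:
        z = self.coefs / self.se()
        return pd.Series(2.0 * norm.sf(np.abs(z)), index=self.coefs.index)

    def term_pvalue(self, term: str) -> float:
        return _term_pvalue(self.coefs.to_numpy(), self.vcov.to_numpy(), self.design, term)


@dataclass
class OneInflatedFit:
    """Factorised one-inflated beta regression: nu (logistic) + mu (beta)."""

    nu: LogisticFit
    mu: BetaFit

    @property
    def loglik(self) -> float:
        return self.nu.loglik + self.mu.loglik

    @property
    def k(self) -> int:
        return self.nu.k + self.mu.k

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k


def _term_pvalue(coefs, vcov, design: Design | None, term: str) -> float:
    """Joint Wald test of all columns belonging to one design term."""
    if design is None:
        raise ValidationError("fit carries no design; term tests unavailable")
    if term not in design.term_slices:
        raise ValidationError(f"term {term!r} not in design")
    slc = design.term_slices[term]
    b = coefs[slc]
    V = vcov[slc, slc]
    stat = float(b @ np.linalg.solve(V, b))
    return float(chi2.sf(stat, len(b)))


# ---------------------------------------------------------------------------
# beta regression internals


def _beta_ll_grad_hess(beta, tau, X, y, ystar, log1my, want_hess=True):
    phi = np.exp(tau)
    eta = X @ beta
    mu = np.clip(sigmoid(eta), _MU_EPS, 1.0 - _MU_EPS)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = float(
        np.sum(gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * np.log(y) + (b - 1.0) * log1my)
    )
    mustar = digamma(a) - digamma(b)
    dl_dmu = phi * (ystar - mustar)
    w = mu * (1.0 - mu)
    g_beta = X.T @ (dl_dmu * w)
    dl_dphi = mu * (ystar - mustar) + log1my - digamma(b) + digamma(phi)
    g_tau = phi * float(np.sum(dl_dphi))
    grad = np.append(g_beta, g_tau)
    if not want_hess:
        return ll, grad, None
    psi1a = _trigamma(a)
    psi1b = _trigamma(b)
    l_mumu = -(phi**2) * (psi1a + psi1b)
    d2_eta = l_mumu * w**2 + dl_dmu * w * (1.0 - 2.0 * mu)
    H_bb = X.T @ (X * d2_eta[:, None])
    l_muphi = (ystar - mustar) - phi * (mu * psi1a - (1.0 - mu) * psi1b)
    H_btau = X.T @ (l_muphi * w * phi)
    l_phiphi = _trigamma(phi) - mu**2 * psi1a - (1.0 - mu) ** 2 * psi1b
    H_tautau = float(np.sum(phi**2 * l_phiphi + phi * dl_dphi))
    k = X.shape[1]
    H = np.empty((k + 1, k + 1))
    H[:k, :k] = H_bb
    H[:k, k] = H_btau
    H[k, :k] = H_btau
    H[k, k] = H_tautau
    return ll, grad, H


def _start_values(X, y):
    ystar = logit(np.clip(y, 1e-6, 1 - 1e-6))
    beta, *_ = np.linalg.lstsq(X, ystar, rcond=None)
    mu0 = np.clip(sigmoid(X @ beta), 1e-4, 1 - 1e-4)
    resid_var = float(np.var(y - mu0))
    if resid_var <= 0:
        phi0 = 50.0
    else:
        phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 0.5)
    return beta, np.log(min(phi0, 1e4))


def fit_beta_regression(
    design: Design | DesignSpec,
    y,
    data: pd.DataFrame | None = None,
    start: tuple[np.ndarray, float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    check_rank: bool = True,
) -> BetaFit:
    """Fit logit-mean / log-precision beta regression by Newton ascent.

    ``design`` may be a built :class:`Design` or a :class:`DesignSpec` plus
    ``data``.  ``start`` (coefficients, log_phi) enables warm starts for
    bootstrap refits.  Raises :class:`ConvergenceError` (carrying the
    log-likelihood trace) if the optimiser does not converge.
    """
    if isinstance(design, DesignSpec):
        if data is None:
            raise ValidationError("DesignSpec given without data")
        design = design.build(data)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != design.n:
        raise ValidationError("outcome length does not match design")
    if np.any((y <= 0) | (y >= 1)) or np.any(~np.isfinite(y)):
        raise ValidationError("beta regression requires y strictly inside (0, 1)")
    if check_rank:
        design.check_full_rank()

    X = design.X
    ystar = logit(y)
    log1my = np.log1p(-y)
    if start is None:
        beta, tau = _start_values(X, y)
    else:
        beta = np.asarray(start[0], dtype=float).copy()
        tau = float(start[1])

    ll, grad, H = _beta_ll_grad_hess(beta, tau, X, y, ystar, log1my)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta = np.append(beta, tau)
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = grad / (np.abs(np.diag(H)).max() + 1.0)
        # step-halving line search keeps the log-likelihood monotone
        scale = 1.0
        for _ in range(40):
            cand = theta + scale * step
            ll_new, grad_new, H_new = _beta_ll_grad_hess(
                cand[:-1], cand[-1], X, y, ystar, log1my
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            # line search stalled: accept as a numerical optimum only if the
            # previous iteration's gain was already negligible
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < 1e-6 * (abs(ll) + 1.0):
                converged = True
            break
        beta, tau = cand[:-1], float(cand[-1])
        improved = ll_new - ll
        ll, grad, H = ll_new, grad_new, H_new
        trace.append(ll)
        if tau > _TAU_MAX:
            warnings.warn(
                "precision diverging: outcome is (near-)degenerate, perfect fit",
                PerfectFitWarning,
            )
            converged = True
            break
        if abs(improved) < tol * (abs(ll) + 1.0):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"beta regression did not converge in {it} iterations", trace=trace
        )

    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; using pseudo-inverse")
        vcov = np.linalg.pinv(-H)
    names = list(design.columns) + ["log_phi"]
    return BetaFit(
        coefs=pd.Series(beta, index=list(design.columns)),
        log_phi=tau,
        loglik=ll,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n=design.n,
        design=design,
        n_iter=it,
        converged=converged,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# logistic regression (nu model)


def fit_logistic(
    design: Design | DesignSpec,
    y,
    data: pd.DataFrame | None = None,
    ridge: float = 0.0,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    check_rank: bool = True,
) -> LogisticFit:
    """Bernoulli-logit MLE by Newton ascent with separation detection.

    ``ridge`` adds an L2 penalty (excluding nothing) used by the imputation
    engine to stabilise separated fits; 0 gives the plain MLE.
    """
    if isinstance(design, DesignSpec):
        if data is None:
            raise ValidationError("DesignSpec given without data")
        design = design.build(data)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("logistic outcome must be binary 0/1")
    if check_rank:
        design.check_full_rank()
    X = design.X
    beta = np.zeros(design.k) if start is None else np.asarray(start, dtype=float).copy()

    def ll_grad_hess(b):
        eta = X @ b
        p = np.clip(sigmoid(eta), 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))) - 0.5 * ridge * float(
            b @ b
        )
        g = X.T @ (y - p) - ridge * b
        w = p * (1 - p)
        H = -(X.T @ (X * w[:, None])) - ridge * np.eye(len(b))
        return ll, g, H

    ll, g, H = ll_grad_hess(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(-H + 1e-12 * np.eye(len(beta)), g)
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, g_new, H_new = ll_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = cand
        improved = ll_new - ll
        ll, g, H = ll_new, g_new, H_new
        if abs(improved) < tol * (abs(ll) + 1.0):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"logistic fit did not converge in {it} iterations")

    p = sigmoid(X @ beta)
    separation = False
    if ridge == 0.0 and np.max(np.abs(beta)) > 8.0:
        classified = np.all((p > 0.5) == (y == 1.0)) if 0 < y.mean() < 1 else False
        extreme = np.any(p[y == 1.0] > 1 - 1e-6) or np.any(p[y == 0.0] < 1e-6)
        if classified or extreme:
            separation = True
            warnings.warn(
                "(quasi-)complete separation detected: coefficients unreliable, "
                "consider ridge stabilisation",
                SeparationWarning,
            )

    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(-H)
    return LogisticFit(
        coefs=pd.Series(beta, index=list(design.columns)),
        loglik=ll + 0.5 * ridge * float(beta @ beta),
        vcov=pd.DataFrame(vcov, index=list(design.columns), columns=list(design.columns)),
        n=design.n,
        design=design,
        n_iter=it,
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# one-inflated model


def fit_one_inflated(
    design_nu: Design | DesignSpec,
    design_mu: Design | DesignSpec,
    y,
    data: pd.DataFrame | None = None,
    start_nu: np.ndarray | None = None,
    start_mu: tuple[np.ndarray, float] | None = None,
) -> OneInflatedFit:
    """Fit the factorised one-inflated beta model.

    ``y`` is the transformed outcome: exact 1.0 for the inflated mass,
    strictly interior values otherwise.  The nu design applies to all rows,
    the mu design to the non-one rows only.
    """
    y = np.asarray(y, dtype=float)
    is_one = y == 1.0
    if is_one.all() or not is_one.any():
        raise ValidationError(
            "degenerate mixture: outcome is all ones or has no ones; "
            "fit a single-component model instead"
        )
    interior = y[~is_one]
    if np.unique(interior).size < 2:
        raise ValidationError("need at least two distinct non-one interior values")

    if isinstance(design_nu, DesignSpec):
        if data is None:
            raise ValidationError("DesignSpec given without data")
        design_nu = design_nu.build(data)
    if isinstance(design_mu, DesignSpec):
        if data is None:
            raise ValidationError("DesignSpec given without data")
        design_mu_full = design_mu.build(data)
    else:
        design_mu_full = design_mu
    sub = Design(
        X=design_mu_full.X[~is_one],
        columns=design_mu_full.columns,
        term_slices=design_mu_full.term_slices,
        design_info=design_mu_full.design_info,
    )
    nu_fit = fit_logistic(design_nu, is_one.astype(float), start=start_nu)
    mu_fit = fit_beta_regression(sub, interior, start=start_mu)
    return OneInflatedFit(nu=nu_fit, mu=mu_fit)


# ---------------------------------------------------------------------------
# diagnostics


def cox_snell_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Cox-Snell pseudo-R^2: 1 - exp(-(2/n) (l_full - l_null))."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise ValidationError("full-model log-likelihood below the null's")
    return float(1.0 - np.exp(-2.0 / n * (loglik_full - loglik_null)))


def rq_residuals(fit, y, rng=None) -> np.ndarray:
    """Randomised quantile residuals; standard normal under a correct model.

    For interior y the residual is the normal quantile of the fitted beta
    CDF; for the inflated mass at 1 a uniform draw over the mass interval
    (1 - p1, 1) randomises the residual.  Deterministic given ``rng``.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(fit, BetaFit):
        mu = fit.mu()
        u = beta_dist.cdf(y, mu * fit.phi, (1 - mu) * fit.phi)
    elif isinstance(fit, OneInflatedFit):
        is_one = y == 1.0
        p1 = fit.nu.prob()
        mu = sigmoid(fit.mu.design.X @ fit.mu.coefs.to_numpy())
        u = np.empty_like(y)
        u[~is_one] = (1.0 - p1[~is_one]) * beta_dist.cdf(
            y[~is_one], mu * fit.mu.phi, (1 - mu) * fit.mu.phi
        )
        u[is_one] = 1.0 - p1[is_one] * rng.random(int(is_one.sum()))
    else:
        raise ValidationError(f"unsupported fit type {type(fit).__name__}")
    if np.any((u <= 0) | (u >= 1)):
        warnings.warn("CDF reached 0/1 numerically; clamping residuals")
        u = np.clip(u, 1e-12, 1 - 1e-12)
    return norm.ppf(u)


def outlier_flags(residuals, threshold: float = 3.5) -> np.ndarray:
    return np.abs(np.asarray(residuals)) > threshold


# ---------------------------------------------------------------------------
# prediction on the original outcome scale


def predict_vas(fit: BetaFit, data: pd.DataFrame, spec: TransformSpec) -> np.ndarray:
    """Fitted mean VAS on the original 0-100 scale for new rows."""
    X = fit.design.matrix_for(data)
    return inverse_shrink(sigmoid(X @ fit.coefs.to_numpy()), spec.n) * 100.0


def predict_eq5d(
    fit: OneInflatedFit, data: pd.DataFrame, spec: TransformSpec
) -> dict[str, np.ndarray]:
    """p1, the conditional non-one index mean, and the overall index mean."""
    X_nu = fit.nu.design.matrix_for(data)
    X_mu = fit.mu.design.matrix_for(data)
    p1 = sigmoid(X_nu @ fit.nu.coefs.to_numpy())
    cond_z = sigmoid(X_mu @ fit.mu.coefs.to_numpy())
    cond_index = inverse_transform_eq5d(cond_z, spec)
    return {
        "p_one": p1,
        "cond_mean_index": cond_index,
        "mean_index": p1 * 1.0 + (1.0 - p1) * cond_index,
    }
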