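"""Bootstrap coefficient variances and Rubin's-rules pooling.

Per imputed dataset, coefficients and their variance-covariance matrix
come from B nonparametric bootstrap replicates (respondent rows resampled
with replacement; the per-dataset estimate is the mean over replicates and
the per-dataset vcov the empirical covariance over replicates).  Across
the m imputed datasets, Rubin's rules combine the per-dataset estimates
Q_d with within variances U_d:

    Qbar = mean(Q_d)
    W    = mean(U_d)                      (within-imputation variance)
    B    = sample variance of the Q_d     (between-imputation variance)
    T    = W + (1 + 1/m) B                (total variance)
    lambda = (1 + 1/m) B / T              (fraction due to missingness)

Confidence intervals use a t reference with Barnard-Rubin adjusted
degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from ._util import ValidationError, spawn_seeds


@dataclass
class BootstrapResult:
    """Replicate coefficient draws for one dataset."""

    estimates: np.ndarray  # (B_ok, k) successful replicate coefficient vectors
    mean: np.ndarray
    cov: np.ndarray
    n_failed: int
    names: tuple[str, ...]


def bootstrap_coefficients(
    data,
    fit_fn,
    B: int = 500,
    seed: int = 0,
    max_failure_rate: float = 0.10,
) -> BootstrapResult:
    """Row-resampling bootstrap of a fit.

    ``fit_fn(data, row_indices)`` must refit the model on the given rows of
    ``data`` and return a pandas Series of coefficients (warm starting is
    the callee's business).  Failed replicates are recorded and excluded;
    more than ``max_failure_rate`` of failures aborts.
    """
    if B < 2:
        raise ValidationError("bootstrap needs B >= 2")
    n = len(data)
    rng = np.random.default_rng(seed)
    full = fit_fn(data, np.arange(n))
    names = tuple(full.index)
    draws = []
    n_failed = 0
    for _ in range(B):
        rows = rng.integers(0, n, n)
        try:
            est = fit_fn(data, rows)
            draws.append(np.asarray(est, dtype=float))
        except Exception:
            n_failed += 1
            if n_failed > max_failure_rate * B:
                raise RuntimeError(
                    f"bootstrap aborted: {n_failed} of {B} replicate fits failed"
                )
    est = np.vstack(draws)
    return BootstrapResult(
        estimates=est,
        mean=est.mean(axis=0),
        cov=np.cov(est, rowvar=False, ddof=1),
        n_failed=n_failed,
        names=names,
    )


@dataclass
class PooledCoefficient:
    """One Rubin-pooled coefficient with its variance decomposition."""

    term: str
    estimate: float
    W: float
    B: float
    T: float
    lam: float
    df: float
    ll: float
    ul: float


def _barnard_rubin_df(m: int, lam: float, n_com: float | None, k: int) -> float:
    """Barnard-Rubin adjusted degrees of freedom for the pooled t interval."""
    lam = min(max(lam, 1e-12), 1 - 1e-12)
    df_old = (m - 1) / lam**2
    if n_com is None or not np.isfinite(n_com):
        return df_old
    nu_com = max(n_com - k, 1.0)
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    return 1.0 / (1.0 / df_old + 1.0 / nu_obs)


def rubin_pool(
    estimates,
    variances,
    names=None,
    n_com: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pool m per-dataset estimates and variances with Rubin's rules.

    ``estimates`` and ``variances`` are (m, k) arrays (or (m,) vectors for a
    single coefficient).  Returns a DataFrame with columns
    term, estimate, ll, ul, W, B, T, lambda, df.
    """
    Q = np.atleast_2d(np.asarray(estimates, dtype=float))
    U = np.atleast_2d(np.asarray(variances, dtype=float))
    if Q.ndim == 2 and Q.shape[0] == 1 and Q.shape[1] > 1 and np.asarray(estimates).ndim == 1:
        Q = Q.T
        U = U.T
    if Q.shape != U.shape:
        raise ValidationError("estimates and variances must have identical shape")
    m, k = Q.shape
    if m < 2:
        raise ValidationError("Rubin pooling needs m >= 2 datasets")
    if np.any(U < 0):
        raise ValidationError("variances must be non-negative")
    names = list(names) if names is not None else [f"b{j}" for j in range(k)]

    Qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(T > 0, (1.0 + 1.0 / m) * B / T, 0.0)
    rows = []
    for j in range(k):
        df = _barnard_rubin_df(m, lam[j], n_com, k)
        half = t_dist.ppf(1 - alpha / 2.0, df) * np.sqrt(T[j]) if T[j] > 0 else 0.0
        rows.append(
            {
                "term": names[j],
                "estimate": Qbar[j],
                "ll": Qbar[j] - half,
                "ul": Qbar[j] + half,
                "W": W[j],
                "B": B[j],
                "T": T[j],
                "lambda": lam[j],
                "df": df,
            }
        )
    return pd.DataFrame(rows)


def pool_bootstrap_fits(
    stacks: list,
    fit_fn,
    B: int = 500,
    seed: int = 0,
    n_com: float | None = None,
) -> tuple[pd.DataFrame, list[BootstrapResult]]:
    """Bootstrap each imputed dataset, then Rubin-pool the per-dataset results."""
    seeds = spawn_seeds(seed, len(stacks))
    results = [
        bootstrap_coefficients(data, fit_fn, B=B, seed=s) for data, s in zip(stacks, seeds)
    ]
    names = results[0].names
    Q = np.vstack([r.mean for r in results])
    U = np.vstack([np.diag(r.cov) for r in results])
    pooled = rubin_pool(Q, U, names=names, n_com=n_com)
    return pooled, results
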