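"""Age-based population-norm curves with bootstrap confidence bands.

Population norms are the expected HRQoL outcome in the general population
as a function of age in years — the healthy-baseline input of cost-utility
analyses.  Two variants are produced, mirroring the survey analysis:

* age-only models: beta (VAS) or one-inflated beta (EQ-5D) regression on
  intercept + age + age^2 in every submodel;
* marginal norms from the full determinant models: row-level predictions
  averaged within each observed age.

Confidence bands are percentile bands over B bootstrap refits per imputed
dataset (m x B replicate curves pooled), so they reflect both sampling
and imputation uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError, sigmoid, spawn_seeds
from .design import Design, DesignSpec
from .betareg import fit_beta_regression, fit_logistic
from .models import fit_mu, fit_nu, fit_vas
from .scoring import TransformSpec, inverse_shrink, inverse_transform_eq5d

AGE_ONLY_VAS = DesignSpec.from_formula("vas_t ~ age + I(age**2)", forced=("age", "I(age**2)"))
AGE_ONLY_NU = DesignSpec.from_formula("is_one ~ age + I(age**2)", forced=("age", "I(age**2)"))
AGE_ONLY_MU = DesignSpec.from_formula("eq5d_t ~ age + I(age**2)", forced=("age", "I(age**2)"))


@dataclass
class NormCurve:
    """Point prediction and bootstrap percentile band on the original scale."""

    outcome: str  # "vas" | "eq5d_p_one" | "eq5d_cond_mean" | "eq5d_mean"
    ages: np.ndarray
    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "point": self.point, "lo": self.lo, "hi": self.hi}
        )


def fit_age_norms(datasets: list[pd.DataFrame], outcome: str) -> list:
    """Per-imputed-dataset age-only fits (intercept + age + age^2).

    ``outcome`` is "vas" or "eq5d"; for "eq5d" each element is a
    (nu_fit, mu_fit) pair.
    """
    if outcome == "vas":
        return [fit_vas(AGE_ONLY_VAS, d) for d in datasets]
    if outcome == "eq5d":
        return [(fit_nu(AGE_ONLY_NU, d), fit_mu(AGE_ONLY_MU, d)) for d in datasets]
    raise ValidationError("outcome must be 'vas' or 'eq5d'")


def _age_grid_matrix(ages):
    ages = np.asarray(ages, dtype=float)
    return np.column_stack([np.ones_like(ages), ages, ages**2])


def _check_grid(datasets, ages):
    observed = np.concatenate([d["age"].to_numpy(dtype=float) for d in datasets])
    if ages.min() < observed.min() or ages.max() > observed.max():
        warnings.warn("age grid extrapolates beyond the observed age range")


def predict_norms_ci(
    datasets: list[pd.DataFrame],
    outcome: str,
    spec: TransformSpec,
    ages=None,
    B: int = 500,
    seed: int = 0,
    max_failure_rate: float = 0.10,
) -> dict[str, NormCurve]:
    """Bootstrap-banded age-only norm curves on the original outcome scale.

    Returns {"vas": curve} or, for EQ-5D, curves for the perfect-health
    probability ("eq5d_p_one"), the conditional non-one index mean
    ("eq5d_cond_mean") and the overall index mean ("eq5d_mean").
    The point curve is the mean over the m x B replicate curves, so it lies
    inside the percentile band by construction.
    """
    if outcome not in ("vas", "eq5d"):
        raise ValidationError("outcome must be 'vas' or 'eq5d'")
    ages = np.arange(0, 100.0) if ages is None else np.asarray(ages, dtype=float)
    _check_grid(datasets, ages)
    G = _age_grid_matrix(ages)
    seeds = spawn_seeds(seed, len(datasets))

    curves: dict[str, list[np.ndarray]] = (
        {"vas": []} if outcome == "vas" else {"eq5d_p_one": [], "eq5d_cond_mean": [], "eq5d_mean": []}
    )
    for d, s in zip(datasets, seeds):
        rng = np.random.default_rng(s)
        if outcome == "vas":
            design = AGE_ONLY_VAS.build(d)
            y = d["vas_t"].to_numpy(dtype=float)
            full = fit_beta_regression(design, y)
            start = (full.coefs.to_numpy(), full.log_phi)
        else:
            design_nu = AGE_ONLY_NU.build(d)
            design_mu = AGE_ONLY_MU.build(d)
            y1 = d["is_one"].to_numpy(dtype=float)
            yt = d["eq5d_t"].to_numpy(dtype=float)
            non_one = yt < 1.0
            full_nu = fit_logistic(design_nu, y1)
            full_mu = fit_beta_regression(
                Design(design_mu.X[non_one], design_mu.columns, design_mu.term_slices, design_mu.design_info),
                yt[non_one],
            )
            start_nu = full_nu.coefs.to_numpy()
            start_mu = (full_mu.coefs.to_numpy(), full_mu.log_phi)
        n = len(d)
        failed = 0
        done = 0
        while done < B:
            rows = rng.integers(0, n, n)
            try:
                if outcome == "vas":
                    sub = Design(design.X[rows], design.columns, design.term_slices, design.design_info)
                    fit = fit_beta_regression(sub, y[rows], start=start, check_rank=False)
                    curves["vas"].append(
                        inverse_shrink(sigmoid(G @ fit.coefs.to_numpy()), spec.n) * 100.0
                    )
                else:
                    sub_nu = Design(design_nu.X[rows], design_nu.columns, design_nu.term_slices, design_nu.design_info)
                    fit_nu_b = fit_logistic(sub_nu, y1[rows], start=start_nu, check_rank=False)
                    sel = non_one[rows]
                    sub_mu = Design(design_mu.X[rows][sel], design_mu.columns, design_mu.term_slices, design_mu.design_info)
                    fit_mu_b = fit_beta_regression(sub_mu, yt[rows][sel], start=start_mu, check_rank=False)
                    p1 = sigmoid(G @ fit_nu_b.coefs.to_numpy())
                    cond = inverse_transform_eq5d(sigmoid(G @ fit_mu_b.coefs.to_numpy()), spec)
                    curves["eq5d_p_one"].append(p1)
                    curves["eq5d_cond_mean"].append(cond)
                    curves["eq5d_mean"].append(p1 + (1 - p1) * cond)
                done += 1
            except Exception:
                failed += 1
                if failed > max_failure_rate * B:
                    raise RuntimeError(f"norm bootstrap aborted: {failed} replicate failures")

    out = {}
    for name, reps in curves.items():
        arr = np.vstack(reps)
        out[name] = NormCurve(
            outcome=name,
            ages=ages,
            point=arr.mean(axis=0),
            lo=np.percentile(arr, 2.5, axis=0),
            hi=np.percentile(arr, 97.5, axis=0),
        )
    return out


def marginal_norms(
    datasets: list[pd.DataFrame],
    predictions_fn,
    ages=None,
) -> pd.DataFrame:
    """Norms from a full determinant model, marginalised over covariates.

    ``predictions_fn(data) -> np.ndarray`` must return a row-level
    prediction on the original scale; predictions are averaged within each
    integer age, then across the m datasets.
    """
    ages = np.arange(0, 100.0) if ages is None else np.asarray(ages, dtype=float)
    per_dataset = []
    for d in datasets:
        pred = np.asarray(predictions_fn(d), dtype=float)
        age = np.round(d["age"].to_numpy(dtype=float))
        s = pd.Series(pred).groupby(age).mean()
        per_dataset.append(s.reindex(ages))
    avg = pd.concat(per_dataset, axis=1).mean(axis=1)
    return pd.DataFrame({"age": ages, "point": avg.to_numpy()})
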