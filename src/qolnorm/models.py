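"""Survey model frames and fit adapters.

Block-restricted covariates enter the regressions as indicator main
effects plus indicator-by-variable dummies (a child cannot have an adult
education level), so :func:`prepare_model_frame` derives the numeric
columns the final survey models use — block indicators, the merged
4-level education dummies (reference: secondary), the sick-child
interaction, the smoker dummy, and the transformed outcomes:

* ``vas_t``   — VAS / 100 pushed strictly inside (0, 1)
* ``eq5d_t``  — EQ-5D index: exact 1 kept as the inflated mass, non-one
  values min-max normalised then pushed inside (0, 1)
* ``is_one``  — perfect-health indicator

The ``fit_*`` adapters close over a :class:`~qolnorm.scoring.TransformSpec`
and give selection, pooling and the norms module one uniform signature
``(design, data) -> fit``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import ValidationError
from .betareg import BetaFit, LogisticFit, OneInflatedFit, fit_beta_regression, fit_logistic
from .design import DesignSpec
from .schema import subgroup_mask
from .scoring import TransformSpec, transform_eq5d, transform_vas

#: final-model formulas in the layout of the pooled-coefficient tables
VAS_FORMULA = (
    "vas_t ~ age + I(age**2) + exp_severe_self + exp_severe_family + pets"
    " + household_size + child + sick + child_sick + disabled + work_health"
    " + educ_none_primary + educ_higher + educ_student + elderly + living_elderly_home"
)
NU_FORMULA = (
    "is_one ~ age + I(age**2) + sick + exp_severe_self + exp_severe_family + pets"
    " + adult_or_elder + educ_none_primary + educ_higher + educ_student + work_health"
)
MU_FORMULA = (
    "eq5d_t ~ age + exp_severe_self + exp_severe_family + household_size"
    " + I(household_size**2) + child + not_school + adult + disabled"
    " + alcohol_rarely + smoking_smoker + exp_caring_no + work_health"
)

FORCED_AGE = ("age", "I(age**2)")


def prepare_model_frame(data: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Add derived model columns and transformed outcomes to a completed table."""
    d = data.copy()
    age = d["age"].to_numpy(dtype=float)
    d["child"] = subgroup_mask(age, "child").astype(float)
    d["adult"] = subgroup_mask(age, "adult").astype(float)
    d["elderly"] = subgroup_mask(age, "elderly").astype(float)
    d["adult_or_elder"] = subgroup_mask(age, "adult_elderly").astype(float)
    if "sick" in d:
        d["child_sick"] = d["child"] * d["sick"].astype(float)
    if "education" in d:
        d["educ_none_primary"] = d["education"].isin(["none", "primary"]).astype(float)
        d["educ_higher"] = (d["education"] == "higher").astype(float)
        d["educ_student"] = (d["education"] == "student").astype(float)
    if "school" in d:
        d["not_school"] = (d["school"] == "no_school").astype(float)
    if "smoking_adult" in d:
        d["smoking_smoker"] = (d["smoking_adult"] == "smoker").astype(float)
    if "exp_severe_caring" in d:
        d["exp_caring_no"] = d["adult_or_elder"] * (
            1.0 - d["exp_severe_caring"].astype(float)
        )
    if "vas" in d:
        d["vas_t"] = transform_vas(d["vas"].to_numpy(dtype=float), spec)
    if "eq5d_index" in d:
        eq_t, is_one = transform_eq5d(d["eq5d_index"].to_numpy(dtype=float), spec)
        d["eq5d_t"] = eq_t
        d["is_one"] = is_one.astype(float)
    return d


def fit_vas(design: DesignSpec, data: pd.DataFrame, **kw) -> BetaFit:
    """Beta regression of the transformed VAS."""
    return fit_beta_regression(design, data[design.outcome].to_numpy(), data=data, **kw)


def fit_nu(design: DesignSpec, data: pd.DataFrame, **kw) -> LogisticFit:
    """Logistic regression of the perfect-health indicator (nu model)."""
    return fit_logistic(design, data[design.outcome].to_numpy(), data=data, **kw)


def fit_mu(design: DesignSpec, data: pd.DataFrame, **kw) -> BetaFit:
    """Beta regression of the non-one transformed EQ-5D index (mu model)."""
    y = data[design.outcome].to_numpy(dtype=float)
    keep = y < 1.0
    if keep.sum() < 2:
        raise ValidationError("fewer than two non-one rows for the mu model")
    return fit_beta_regression(design, y[keep], data=data.loc[keep], **kw)


def fit_eq5d(design_nu: DesignSpec, design_mu: DesignSpec, data: pd.DataFrame) -> OneInflatedFit:
    """Joint one-inflated fit; equals fit_nu + fit_mu by factorisation."""
    from .betareg import fit_one_inflated

    return fit_one_inflated(design_nu, design_mu, data[design_mu.outcome].to_numpy(), data=data)


def make_bootstrap_fn(design: DesignSpec, data: pd.DataFrame, kind: str):
    """Row-resampling refit closure for ``pooling.bootstrap_coefficients``.

    Builds the design once on the full dataset and warm-starts every
    replicate from the full-data fit, so a replicate costs only a couple of
    Newton steps.  ``kind`` in {"vas", "nu", "mu"}.
    """
    fitter = {"vas": fit_vas, "nu": fit_nu, "mu": fit_mu}[kind]
    built = design.build(data)
    y = data[design.outcome].to_numpy(dtype=float)
    if kind == "mu":
        keep = y < 1.0
        X_all, y_all = built.X[keep], y[keep]
    else:
        X_all, y_all = built.X, y
    from .design import Design

    def refit(_data, rows):
        if kind == "mu":
            # rows index the full dataset; keep the resampled non-one rows
            sel = y[rows] < 1.0
            Xb, yb = built.X[rows][sel], y[rows][sel]
        else:
            Xb, yb = built.X[rows], y[rows]
        sub = Design(Xb, built.columns, built.term_slices, built.design_info)
        if kind in ("vas", "mu"):
            fit = fit_beta_regression(
                sub, yb, start=refit.start, check_rank=False
            )
            return pd.concat([fit.coefs, pd.Series({"log_phi": fit.log_phi})])
        fit = fit_logistic(sub, yb, start=refit.start_nu, check_rank=False)
        return fit.coefs

    # warm starts from the full-data fit
    full_design = Design(X_all, built.columns, built.term_slices, built.design_info)
    if kind in ("vas", "mu"):
        full = fit_beta_regression(full_design, y_all, check_rank=True)
        refit.start = (full.coefs.to_numpy(), full.log_phi)
        refit.start_nu = None
    else:
        full = fit_logistic(full_design, y_all, check_rank=True)
        refit.start_nu = full.coefs.to_numpy()
        refit.start = None
    refit.full_fit = full
    return refit
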