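"""Fit beta and one-inflated beta regressions with diagnostics.

VAS is modelled as Beta(mu*phi, (1-mu)*phi) with logit(mu) = x'beta.  The
EQ-5D index has a point mass at 1 (perfect health), so it gets a mixture:
a logistic "nu model" for P(index = 1) and a beta "mu model" for the
index when below 1.  Randomised quantile residuals and the Cox-Snell
pseudo-R^2 assess fit.
"""

import numpy as np

from qolnorm import TransformSpec, TruthConfig, cox_snell_r2, generate_cohort, rq_residuals
from qolnorm.design import DesignSpec
from qolnorm.models import (
    MU_FORMULA,
    NU_FORMULA,
    VAS_FORMULA,
    FORCED_AGE,
    fit_mu,
    fit_nu,
    fit_vas,
    prepare_model_frame,
)
from qolnorm.betareg import OneInflatedFit

table = generate_cohort(TruthConfig(n=1774), seed=7)
spec = TransformSpec.from_data(len(table), table["eq5d_index"].to_numpy())
frame = prepare_model_frame(table, spec)

vas_fit = fit_vas(DesignSpec.from_formula(VAS_FORMULA, forced=FORCED_AGE), frame)
print("VAS beta regression (logit scale):")
for term in ("Intercept", "age", "exp_severe_self", "sick"):
    print(f"  {term:<18} {vas_fit.coefs[term]: .3f}  (Wald p = {vas_fit.wald_pvalues()[term]:.2g})")
print(f"  precision phi = {vas_fit.phi:.1f}  (gamlss sigma^2 = {1/(1+vas_fit.phi):.4f})")

nu_fit = fit_nu(DesignSpec.from_formula(NU_FORMULA, forced=FORCED_AGE), frame)
mu_fit = fit_mu(DesignSpec.from_formula(MU_FORMULA, forced=("age",)), frame)
eq_fit = OneInflatedFit(nu=nu_fit, mu=mu_fit)
print(f"\none-inflated EQ-5D: joint loglik {eq_fit.loglik:.1f} "
      f"= nu {nu_fit.loglik:.1f} + mu {mu_fit.loglik:.1f}")

null_vas = fit_vas(DesignSpec(outcome="vas_t", terms=()), frame)
r2 = cox_snell_r2(vas_fit.loglik, null_vas.loglik, vas_fit.n)
print(f"Cox-Snell pseudo-R^2 (VAS model): {r2:.2f}")

res = rq_residuals(eq_fit, frame["eq5d_t"].to_numpy(), rng=1)
print(f"randomised quantile residuals: mean {res.mean():.2f}, sd {res.std():.2f} "
      f"(should be ~N(0,1)); outliers |r|>3.5: {(np.abs(res) > 3.5).sum()}")
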