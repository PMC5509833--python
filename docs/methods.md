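# Methods

This note documents the statistical machinery in qolnorm: the models, the
choices that were genuinely open, and what the synthetic-data tests do and do
not establish.

## Outcomes and transforms

Two HRQoL outcomes are modelled per respondent: the VAS self-rating on
[0, 100] and the EQ-5D-3L utility index, obtained by applying an additive
country tariff to the five dimension levels. Tariffs are additive in an
any-problem constant, an optional any-level-3 constant, and per
(dimension, level) decrements; `(1,1,1,1,1)` scores 1 by construction. The
package ships a **synthetic** Belgian-like tariff calibrated only to
reproduce the Belgian index range [−0.074, 1] over the 243 profiles; real
value sets are licensed data and must be supplied by the user.

Beta likelihoods need outcomes strictly inside (0, 1):

* VAS is divided by 100 and shrunk: `y' = (y·(N−1) + 0.5)/N`, where N is the
  number of respondent rows in the dataset being transformed — counted after
  row filtering and before imputation, and reused unchanged for every imputed
  dataset, so all m analyses share one transform. (The alternative, counting
  only rows with an observed outcome, would make the transform depend on the
  missingness pattern.)
* Non-one EQ-5D index values are first normalised linearly so the observed
  minimum maps to 0 and the observed maximum non-one value to 1, then shrunk
  the same way. Exact ones keep their point mass. The (min, max, N) triple is
  frozen in a `TransformSpec` so predictions invert consistently.

Both maps are strictly increasing with exact inverses; fitted means are
always reported on the original scale.

## Regression models

**VAS — beta regression.** `y ~ Beta(μφ, (1−μ)φ)` with `logit(μ) = x'β` and a
single precision φ estimated on the log scale. Mean/precision
parameterisation: `E[y] = μ`, `Var[y] = μ(1−μ)/(1+φ)`. gamlss reports the
same dispersion as σ with σ² = 1/(1+φ); `phi_to_gamlss_sigma` round-trips the
mapping exactly.

**EQ-5D — one-inflated beta.** A point mass at 1 with `logit(P(y=1)) =
x'β_ν` (the *nu model*) and, conditionally on y < 1, a beta regression for
the transformed index (the *mu model*). The likelihood factorises, so the nu
part is exactly a logistic regression of the one-indicator and the mu part a
beta regression on the non-one rows; the joint log-likelihood is their sum,
an identity asserted in the tests. The inflation probability uses a logit
link directly (some implementations parameterise the mass as an odds with a
log link — the fitted probabilities are identical; only the coefficient scale
differs).

**Estimation.** Newton ascent with analytic gradient and Hessian
(observed information), step-halving so the log-likelihood trace is
monotone, convergence at a relative log-likelihood change below 1e-8, at
most 200 iterations. Starting values: least squares on the link-transformed
outcome for β, method-of-moments for φ, zero for the logistic part. The
observed-information inverse supplies per-dataset Wald tests; it is *not*
the headline variance — bootstrap pooling is (below). Degenerate cases are
guarded: a (near-)constant outcome drives φ → ∞ and triggers a perfect-fit
warning at φ > 10⁶; rank-deficient designs raise an error naming the aliased
columns; (quasi-)complete separation in a logistic component — a realistic
hazard when a block indicator almost determines perfect health — is detected
and warned about rather than silently reported as a huge coefficient.

**Covariate coding.** Covariates measured only for children, adults and/or
elderly enter as a block indicator main effect plus indicator-restricted
dummies (`child`, `child_sick`, `not_school`, the education dummies, …), so a
child contributes nothing to adult-only terms. Age and household size get
second-order polynomials; the age polynomial and block indicators are
forced-in terms that model selection may never remove.

**Diagnostics.** Randomised quantile residuals (normal quantile of the
fitted CDF; for the one-mass, a uniform draw over the mass interval,
deterministic given the seed), QQ and residual-versus-age plots, outlier
flags at |r| > 3.5 (flagged and kept by default), and the Cox–Snell
pseudo-R² `1 − exp(−(2/n)(ℓ_full − ℓ_null))` against intercept-only nulls.

## Multiple imputation (FCS)

Each incomplete variable is regressed on all others and redrawn, sweeping
variables in ascending-missingness order (a convention; the order is not
identified by theory) for a burn-in of 5 iterations, m = 5 independent
chains. Conditional models by type: logistic (binary), polytomous logistic
(>2 levels), predictive mean matching (continuous; donor pool k = 5, the
conventional default), and an optional classification tree. Parameter
uncertainty enters by refitting each conditional model on a bootstrap
resample of the observed rows (the "boot" flavour of FCS). Logistic
conditionals carry a ridge penalty so sparse binaries cannot derail a chain
through separation — this removes the need to switch methods per variable
when a subgroup's logistic imputer fails.

Block handling: categorical block-restricted variables hold the literal
category `"irrelevant"` outside their block and are never imputed there;
continuous block-restricted variables are imputed during the sweep but
blanked outside the block afterwards and excluded as predictors. PMM imputes
only observed values, which preserves the EQ-5D one-mass in imputed cells.

Convergence is monitored on per-chain means of the imputed cells: a variable
is flagged when every chain's last-half means move strictly monotonically in
the same direction. With 5-iteration chains this all-chains rule separates
genuine drift (an injected linear trend always flags) from noise (default
runs almost never flag).

The generator's missingness is MCAR at the survey's per-variable rates by
default, with an MAR-on-age switch (slope on the logit of the rate), because
FCS validity assumes MAR and the real mechanism is unknown; neither option
claims fidelity to the survey's actual mechanism.

## Model selection

Step 1, backward elimination: a term is removable when its joint Wald test
(whole factor block, not per dummy) gives p > 0.05 in **all** m imputed
datasets; each round removes, among removable terms, the one whose smallest
p-value across datasets is largest, with lexicographic tie-breaks, so reruns
replay identically. The phrase "not significant in any dataset" is genuinely
ambiguous between this reading and remove-if-nonsignificant-in-*any*; the
latter is available as `rule="any"`. Selection is per-dataset by design —
eliminating on Rubin-pooled Wald tests would require bootstrap pooling
inside every elimination round.

Step 2, recategorisation: many-level factors are compared against merged
codings by mean AIC across the m datasets, candidates enumerated from
pairwise non-significant adjacent level effects (or supplied explicitly,
standing in for subject knowledge), merges accepted greedily while the mean
AIC drops. The full model's AIC is verified to be invariant to the reference
category before merging, since releveling is a pure reparameterisation.

## Bootstrap and Rubin pooling

Per imputed dataset, coefficients are estimated as the mean over B = 500
nonparametric bootstrap replicates (respondent rows resampled with
replacement, unstratified; stratification by age block is available) and the
per-dataset covariance as the empirical covariance over the replicates —
the plain empirical variance, with no bias correction. Replicates warm-start
from the full-data fit; failures fall back to a cold start and are excluded
with a count, aborting above a 10% failure rate. Across datasets, Rubin's
rules give `Q̄`, within-variance W, between-variance B,
`T = W + (1 + 1/m)B` and `λ = (1 + 1/m)B/T`; intervals use a t reference
with Barnard–Rubin adjusted degrees of freedom (no df rule is canonical for
bootstrap within-variances; the adjusted rule is the standard finite-sample
choice).

## Population norms

Two variants, both reported: (i) age-only models — intercept + age + age² in
every submodel — with percentile bands from B bootstrap refits per imputed
dataset pooled over the m × B replicate curves (the point curve is the
replicate mean, so it lies inside its band by construction); (ii) marginal
norms from the full determinant models, obtained by averaging row-level
predictions within each integer age and then across datasets — the
marginalisation convention had to be fixed somewhere, and averaging over the
observed covariate distribution per age is the declared choice. A sensitivity
branch repeats the entire analysis on adults + elderly only; block terms that
become constant in that subset (the child indicators) are pruned from the
designs automatically.

## Synthetic cohort: what it emulates, and what it does not

The generator draws ages 0–99 with 18% under 13 and 20% over 60 (the
surveyed mix), block-restricted covariates at survey-like prevalences with
mild age confounding (pet owners younger, disease experience increasing with
age, students concentrated under 24), VAS as 100·Beta(μφ, (1−μ)φ) with
φ = 10 (matching a ≈11-point VAS SD at μ ≈ 0.85), and the EQ-5D index as a
one-inflated beta with φ = 8 mapped onto the survey's non-one range
[−0.074, 0.817]. Default coefficients are the rounded pooled estimates of
the fitted survey models, with one repair: the published nu-model
intercept/adult-indicator pair shows quasi-separation (−10.13 / +11.03),
which would give children a perfect-health probability of ~0; the default
truth re-centres the pair to (+1.40, −0.50), preserving their sum (the adult
baseline) and a realistic 80–85% for children. Dimension levels are derived
from the index by nearest-tariff-profile lookup as a realism layer for the
scoring code; model-based tests use the continuous index column.

Not emulated: quota sampling and household recruitment, integer rounding of
VAS, proxy-response effects, genuinely MNAR missingness, and any dependence
between dimension-level patterns and covariates beyond what the index
carries. Passing recovery tests therefore shows the chain is consistent when
its model family is correct; it cannot certify behaviour under the real
survey's unknown missingness mechanism or reporting quirks.

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to balance resolution against a
single-CPU test run: the recovery/coverage study uses 100 replicates of
n = 2000 cohorts with m = 5 and B = 100 (coverage asserted within the
binomial band [0.90, 0.99]; bias within half the replicate SD); residual
normality uses 100 seeds at n = 10 000; the acceptance script runs the full
default cohort (n = 1774) at the analysis settings m = 5, burn-in 5,
B = 500.

## Known limitations

* The EQ-5D-3L index takes 243 discrete values; modelling it as continuous
  (plus a one-mass) is an approximation shared with the beta-regression
  approach generally.
* The same data select determinants, recategorise factors and estimate
  coefficients — selection-induced optimism is not corrected.
* Age-only norm curves are quadratic in age; they under-fit the extremes of
  the age range, which is why the full-model marginal norms are reported
  alongside.
* The analytic observed-information vcov can be unreliable near separation or
  tiny mixture cells; bootstrap pooling is the authoritative variance route.
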