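"""Synthetic survey cohort with known ground truth.

Emulates a population HRQoL survey: ages 0-99 with roughly 18% children
(< 13) and 20% elderly (60+), questionnaire blocks with block-restricted
covariates, a beta-distributed VAS (0-100), a one-inflated EQ-5D index
(point mass at 1 for perfect health, beta-distributed otherwise) and
per-variable missingness at survey-like rates.

The generating regression coefficients live in :class:`TruthConfig`, so
every downstream stage (imputation, fitting, selection, pooling, norms)
can be tested against a known truth.  Defaults are rounded pooled
estimates on the scale of the fitted survey models, so default runs
resemble the real analysis; every coefficient is overridable.

Ground-truth linear predictors are on the logit scale.  VAS is drawn as
100 * Beta(mu*phi, (1-mu)*phi) with mu = logistic(x'beta).  The EQ-5D
index equals exactly 1 with probability logistic(x'beta_nu); otherwise a
beta draw on (0,1) is mapped linearly onto ``index_range`` (the survey's
non-one index range).  EQ-5D dimension levels are derived from the index
by nearest-tariff-profile lookup — a realism layer for the scoring code;
model-based tests use the continuous index column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import schema
from ._util import ConfigurationError, ValidationError, logit, sigmoid, spawn_seeds
from .schema import IRRELEVANT, subgroup_mask
from .scoring import all_profiles, example_tariff

# ---------------------------------------------------------------------------
# ground-truth linear-predictor terms

_CATEGORICAL_TERMS = {
    "educ_none_primary": ("education", ("none", "primary")),
    "educ_higher": ("education", ("higher",)),
    "educ_student": ("education", ("student",)),
    "not_school": ("school", ("no_school",)),
    "smoking_smoker": ("smoking_adult", ("smoker",)),
}

_GROUP_TERMS = {
    "child": "child",
    "adult": "adult",
    "elderly": "elderly",
    "adult_or_elder": "adult_elderly",
}


def term_column(table: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric column for one linear-predictor term of the truth model."""
    age = table["age"].to_numpy(dtype=float)
    if term == "intercept":
        return np.ones(len(table))
    if term == "age":
        return age
    if term == "age2":
        return age**2
    if term == "household_size2":
        return table["household_size"].to_numpy(dtype=float) ** 2
    if term in _GROUP_TERMS:
        return subgroup_mask(age, _GROUP_TERMS[term]).astype(float)
    if term == "child_sick":
        return subgroup_mask(age, "child") * table["sick"].to_numpy(dtype=float)
    if term == "exp_caring_no":
        ae = subgroup_mask(age, "adult_elderly")
        return ae * (1.0 - table["exp_severe_caring"].to_numpy(dtype=float))
    if term in _CATEGORICAL_TERMS:
        col, levels = _CATEGORICAL_TERMS[term]
        return table[col].isin(levels).to_numpy(dtype=float)
    if term in table.columns:
        return np.nan_to_num(table[term].to_numpy(dtype=float))
    raise ConfigurationError(f"unknown truth term {term!r}")


def linear_predictor(table: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(table))
    for term, beta in coefs.items():
        eta += beta * term_column(table, term)
    if not np.isfinite(eta).all():
        raise ConfigurationError("non-finite linear predictor from truth coefficients")
    return eta


# ---------------------------------------------------------------------------
# configuration

#: rounded pooled estimates of the survey's final VAS model (logit scale)
DEFAULT_VAS_COEFS = {
    "intercept": 1.25,
    "age": 0.03,
    "age2": -0.0003,
    "exp_severe_self": -0.45,
    "exp_severe_family": -0.20,
    "pets": -0.16,
    "household_size": 0.03,
    "child": -0.07,
    "sick": -0.87,
    "child_sick": -1.12,
    "disabled": -0.79,
    "work_health": 0.16,
    "educ_none_primary": -0.19,
    "educ_higher": 0.02,
    "educ_student": 0.36,
    "elderly": 0.10,
    "living_elderly_home": -0.33,
}

#: probability of perfect health (EQ-5D index = 1), logit scale.  The fitted
#: survey model shows quasi-separation between its intercept and the
#: adult-or-elder indicator; the default truth re-centres that pair while
#: preserving the adult baseline (their sum), so children get a realistic
#: 80-85% perfect-health probability.
DEFAULT_NU_COEFS = {
    "intercept": 1.40,
    "age": 0.04,
    "age2": -0.0007,
    "sick": -1.66,
    "exp_severe_self": -1.03,
    "exp_severe_family": -0.45,
    "pets": -0.37,
    "adult_or_elder": -0.50,
    "educ_none_primary": -0.90,
    "educ_higher": 0.42,
    "educ_student": 1.14,
    "work_health": -0.36,
}

#: conditional mean of the EQ-5D index when not in perfect health
DEFAULT_MU_COEFS = {
    "intercept": 2.63,
    "age": -0.02,
    "exp_severe_self": -0.22,
    "exp_severe_family": 0.25,
    "household_size": 0.17,
    "household_size2": -0.02,
    "child": -0.96,
    "not_school": -0.83,
    "adult": -0.52,
    "disabled": -0.91,
    "alcohol_rarely": -0.43,
    "smoking_smoker": -0.27,
    "exp_caring_no": 0.17,
    "work_health": 0.16,
}


@dataclass
class TruthConfig:
    """Generative configuration for one synthetic cohort."""

    n: int = 1774
    age_mix: tuple[float, float, float] = (0.18, 0.62, 0.20)  # child, adult, elderly
    vas_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VAS_COEFS))
    vas_precision: float = 10.0
    nu_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NU_COEFS))
    mu_coefs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU_COEFS))
    eq5d_precision: float = 8.0
    index_range: tuple[float, float] = (-0.074, 0.817)
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(schema.DEFAULT_MISSING_RATES)
    )
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.age_mix) - 1.0) > 1e-9:
            raise ConfigurationError("age_mix must sum to 1")
        if self.vas_precision <= 0 or self.eq5d_precision <= 0:
            raise ConfigurationError("beta precision must be > 0")
        for name, rate in self.missing_rates.items():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"missing rate for {name} outside [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# generation


def _draw_covariates(n: int, age_mix, rng: np.random.Generator) -> pd.DataFrame:
    group = rng.choice(3, size=n, p=list(age_mix))
    age = np.empty(n, dtype=float)
    age[group == 0] = rng.integers(0, 13, size=(group == 0).sum())
    age[group == 1] = rng.integers(13, 60, size=(group == 1).sum())
    age[group == 2] = rng.integers(60, 100, size=(group == 2).sum())

    child = subgroup_mask(age, "child")
    adult = subgroup_mask(age, "adult")
    elderly = subgroup_mask(age, "elderly")
    adult_elderly = subgroup_mask(age, "adult_elderly")

    hh_mean = np.where(child, 3.0, np.where(adult, 2.0, 1.0))
    household = np.clip(1 + rng.poisson(hh_mean), 1, 12).astype(float)

    tab = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "group": np.where(child, "child", np.where(adult, "adult", "elderly")),
            "gender": rng.binomial(1, 0.54, n).astype(float),
            "household_size": household,
            "exp_severe_self": rng.binomial(1, sigmoid(-2.6 + 0.02 * age)).astype(float),
            "exp_severe_family": rng.binomial(1, sigmoid(-0.5 + 0.01 * age)).astype(float),
            "n_parents": rng.binomial(1, 0.76, n).astype(float),
            "pets": rng.binomial(1, sigmoid(0.8 - 0.015 * (age - 40))).astype(float),
            "sick": rng.binomial(1, 0.03, n).astype(float),
        }
    )

    # block-restricted covariates: 0 / "irrelevant" outside the block
    def binary_in(mask, p):
        out = np.zeros(n)
        out[mask] = rng.binomial(1, p, mask.sum())
        return out

    def categorical_in(mask, levels, probs):
        out = np.full(n, IRRELEVANT, dtype=object)
        out[mask] = rng.choice(levels, size=mask.sum(), p=probs)
        return out

    tab["school"] = categorical_in(
        child,
        ["kindergarten", "primary_school", "other_school", "no_school"],
        [0.29, 0.41, 0.05, 0.25],
    )
    tab["smoking_adult"] = categorical_in(
        adult, ["non_smoker", "ex_smoker", "smoker"], [0.64, 0.19, 0.17]
    )
    # education: young adults are mostly students, which ties education to age
    educ = np.full(n, IRRELEVANT, dtype=object)
    young = adult_elderly & (age < 24)
    student = young & (rng.random(n) < 0.65)
    educ[student] = "student"
    rest = adult_elderly & ~student
    educ[rest] = rng.choice(
        ["none", "primary", "lower_secondary", "higher_secondary", "higher"],
        size=rest.sum(),
        p=[0.011, 0.077, 0.220, 0.253, 0.439],
    )
    tab["education"] = educ
    tab["work_health"] = binary_in(adult_elderly, 0.22)
    tab["disabled"] = binary_in(adult_elderly, 0.02)
    tab["exp_severe_caring"] = binary_in(adult_elderly, 0.11)
    tab["living_elderly_home"] = binary_in(elderly, 0.14)
    tab["alcohol_rarely"] = binary_in(elderly, 0.35)
    tab["smoking_elderly"] = categorical_in(
        elderly,
        ["smoker", "quit_before_30", "quit_30_50", "quit_after_50", "never"],
        [0.12, 0.08, 0.16, 0.13, 0.51],
    )
    ayc = np.full(n, np.nan)
    ayc[elderly] = rng.integers(13, 75, size=elderly.sum()).astype(float)
    tab["age_youngest_child"] = ayc
    return tab


def _beta_draw(mu, phi, rng):
    z = rng.beta(mu * phi, (1.0 - mu) * phi)
    return np.clip(z, 1e-12, 1.0 - 1e-12)


def _profiles_for_index(index, is_one, rng):
    """Nearest-tariff-profile EQ-5D dimension levels for each index value."""
    tariff = example_tariff()
    profiles = all_profiles()
    scores = np.array([tariff.score(p) for p in profiles])
    order = np.argsort(scores)
    sorted_scores = scores[order]
    dims = np.ones((len(index), 5), dtype=int)
    non_one = ~is_one
    pos = np.searchsorted(sorted_scores, index[non_one])
    pos = np.clip(pos, 1, len(sorted_scores) - 1)
    left_closer = np.abs(index[non_one] - sorted_scores[pos - 1]) <= np.abs(
        sorted_scores[pos] - index[non_one]
    )
    chosen = np.where(left_closer, pos - 1, pos)
    prof_arr = np.array(profiles)[order]
    dims[non_one] = prof_arr[chosen]
    return dims


def generate_cohort(cfg: TruthConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a complete (no missingness) cohort table from the truth config."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tab = _draw_covariates(cfg.n, cfg.age_mix, rng)

    mu_vas = sigmoid(linear_predictor(tab, cfg.vas_coefs))
    tab["vas"] = 100.0 * _beta_draw(mu_vas, cfg.vas_precision, rng)

    p_one = sigmoid(linear_predictor(tab, cfg.nu_coefs))
    is_one = rng.random(cfg.n) < p_one
    mu_eq = sigmoid(linear_predictor(tab, cfg.mu_coefs))
    z = _beta_draw(mu_eq, cfg.eq5d_precision, rng)
    lo, hi = cfg.index_range
    index = np.where(is_one, 1.0, z * (hi - lo) + lo)
    tab["eq5d_index"] = index

    dims = _profiles_for_index(index, is_one, rng)
    for j in range(5):
        tab[f"eq5d_dim{j + 1}"] = dims[:, j]
    return tab


def inject_missingness(
    table: pd.DataFrame,
    missing_rates: dict[str, float] | None = None,
    seed: int = 0,
    mechanism: str = "mcar",
    mar_age_slope: float = 0.0,
) -> pd.DataFrame:
    """Blank cells at per-variable rates; block-irrelevant cells never masked.

    ``mechanism="mcar"`` masks independently at the variable's rate;
    ``mechanism="mar_age"`` tilts the masking probability with age on the
    logit scale (slope 0 reduces to MCAR).
    """
    if mechanism not in ("mcar", "mar_age"):
        raise ConfigurationError(f"unknown missingness mechanism {mechanism!r}")
    rates = dict(schema.DEFAULT_MISSING_RATES) if missing_rates is None else dict(missing_rates)
    out = table.copy()
    rng = np.random.default_rng(seed)
    age = out["age"].to_numpy(dtype=float)

    def draw_mask(rate, rows):
        if mechanism == "mar_age" and mar_age_slope != 0.0:
            p = sigmoid(logit(np.full(rows.sum(), rate)) + mar_age_slope * (age[rows] - age.mean()))
        else:
            p = np.full(rows.sum(), rate)
        return rng.random(rows.sum()) < p

    for name, rate in rates.items():
        if rate == 0:
            continue
        if name == "eq5d_dims":
            rows = np.ones(len(out), dtype=bool)
            hit = np.flatnonzero(rows)[draw_mask(rate, rows)]
            for j in range(1, 6):
                out.loc[out.index[hit], f"eq5d_dim{j}"] = np.nan
            out.loc[out.index[hit], "eq5d_index"] = np.nan
            continue
        if name not in out.columns:
            raise ConfigurationError(f"missing rate given for unknown variable {name!r}")
        var = schema.VARIABLES.get(name)
        rows = subgroup_mask(age, var.subgroup if var is not None else "all")
        hit = np.flatnonzero(rows)[draw_mask(rate, rows)]
        if out[name].dtype == object:
            out.loc[out.index[hit], name] = np.nan
        else:
            col = out[name].astype(float)
            col.iloc[hit] = np.nan
            out[name] = col
    return out


def simulate(cfg: TruthConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort and apply the configured missingness in one call."""
    base_seed = cfg.seed if seed is None else seed
    gen_seed, miss_seed = spawn_seeds(base_seed, 2)
    complete = generate_cohort(cfg, seed=gen_seed)
    return inject_missingness(complete, cfg.missing_rates, seed=miss_seed)
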