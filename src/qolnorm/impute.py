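"""Fully conditional specification (FCS) multiple imputation.

Each variable with missing cells is regressed on all other variables and
imputed from that conditional model; sweeping over the variables (in
ascending-missingness order) for a burn-in number of iterations, m times
with independent random streams, yields m completed datasets.  Conditional
models follow the variable type: logistic for binary, polytomous logistic
for factors with more than two levels, predictive mean matching (PMM) for
continuous variables, with an optional classification tree.  Parameter
uncertainty enters by fitting each conditional model on a nonparametric
bootstrap resample of the observed rows (the "boot" flavour of FCS).

Questionnaire-block handling: categorical variables restricted to a block
carry the literal category ``"irrelevant"`` outside it and are never
imputed there; block-restricted continuous variables are imputed during
the sweep but blanked outside their block in post-processing and are not
used as predictors for other variables.

Logistic conditional models carry a ridge penalty, which keeps imputation
going under (quasi-)complete separation — the failure mode that otherwise
forces ad-hoc method switches for sparsely observed binaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from ._util import ConfigurationError, ValidationError, spawn_seeds
from .schema import IRRELEVANT, subgroup_mask

_EXCLUDED_COLUMNS = ("id", "group")


@dataclass
class ImputationPlan:
    """Per-variable methods and chain settings.

    methods maps variable name to one of {"logistic", "polytomous", "pmm",
    "tree"}; variables not listed get a type-based default.  burn_in is the
    number of FCS sweeps per chain (default 5), m the number of completed
    datasets (default 5), donor_k the PMM donor-pool size (default 5).
    """

    methods: dict[str, str] = field(default_factory=dict)
    burn_in: int = 5
    m: int = 5
    donor_k: int = 5
    ridge: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.burn_in < 1:
            raise ConfigurationError("burn_in must be >= 1")
        if self.m < 2:
            raise ConfigurationError("m must be >= 2")
        if self.donor_k < 1:
            raise ConfigurationError("donor_k must be >= 1")
        for name, method in self.methods.items():
            if method not in ("logistic", "polytomous", "pmm", "tree"):
                raise ConfigurationError(f"unknown imputation method {method!r} for {name}")


@dataclass
class ImputedStack:
    """m completed datasets sharing all observed cells, plus the chain trace."""

    datasets: list[pd.DataFrame]
    trace: dict[str, np.ndarray]  # variable -> (m, burn_in) chain means
    plan: ImputationPlan
    seeds: list[int] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)


def _variable_kind(col: pd.Series) -> str:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        observed = col.dropna()
        return "polytomous" if observed.nunique() > 2 else "logistic"
    observed = col.dropna().unique()
    if set(np.unique(observed)).issubset({0.0, 1.0}):
        return "logistic"
    return "pmm"


def _scope_mask(name: str, age: np.ndarray, n: int) -> np.ndarray:
    var = schema.VARIABLES.get(name)
    if var is None or age is None:
        return np.ones(n, dtype=bool)
    return subgroup_mask(age, var.subgroup)


def _is_block_continuous(name: str) -> bool:
    var = schema.VARIABLES.get(name)
    return var is not None and var.kind == "continuous" and var.subgroup != "all"


def _encode_predictors(
    working: pd.DataFrame, target: str, excluded: set[str]
) -> np.ndarray:
    """Design matrix of all other variables (one-hot factors, intercept)."""
    parts = [np.ones((len(working), 1))]
    for name in working.columns:
        if name == target or name in excluded:
            continue
        col = working[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                parts.append((col == lev).to_numpy(dtype=float)[:, None])
        else:
            x = col.to_numpy(dtype=float)
            sd = np.nanstd(x)
            x = (x - np.nanmean(x)) / (sd if sd > 0 else 1.0)
            parts.append(np.nan_to_num(x)[:, None])
    return np.hstack(parts)


def pmm_draw(
    observed_values: np.ndarray,
    observed_pred: np.ndarray,
    missing_pred: np.ndarray,
    donor_k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: for each missing case take the observed
    value of one of the ``donor_k`` donors whose predictions are closest to
    the case's prediction, chosen uniformly at random (ties broken by donor
    order)."""
    observed_values = np.asarray(observed_values, dtype=float)
    observed_pred = np.asarray(observed_pred, dtype=float)
    missing_pred = np.asarray(missing_pred, dtype=float)
    n_donors = len(observed_values)
    if n_donors == 0:
        raise ValidationError("PMM requires at least one observed donor")
    k = donor_k
    if n_donors < donor_k:
        warnings.warn(
            f"only {n_donors} donors available; reducing PMM pool from {donor_k}"
        )
        k = n_donors
    out = np.empty(len(missing_pred))
    for i, pred in enumerate(missing_pred):
        dist = np.abs(observed_pred - pred)
        pool = np.argsort(dist, kind="stable")[:k]
        out[i] = observed_values[pool[rng.integers(0, len(pool))]]
    return out


def _fit_predict_proba(X_obs, y_obs, X_mis, method: str, ridge: float, rng):
    """Class probabilities for missing rows from a bootstrap-refitted model."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.tree import DecisionTreeClassifier

    classes = np.unique(y_obs)
    if len(classes) == 1:
        warnings.warn("observed values constant; imputing the constant")
        return np.ones((len(X_mis), 1)), classes
    boot = rng.integers(0, len(y_obs), len(y_obs))
    yb = y_obs[boot]
    if len(np.unique(yb)) == 1:  # degenerate resample: fall back to observed rows
        boot = np.arange(len(y_obs))
        yb = y_obs
    Xb = X_obs[boot]
    if method == "tree":
        model = DecisionTreeClassifier(min_samples_leaf=5, random_state=int(rng.integers(2**31)))
    else:
        model = LogisticRegression(C=1.0 / max(ridge, 1e-8), max_iter=200)
    model.fit(Xb[:, 1:], yb)  # sklearn adds its own intercept
    return model.predict_proba(X_mis[:, 1:]), model.classes_


def _impute_variable(working, name, miss_rows, scope, method, plan, rng):
    """One FCS step: refit the conditional model and redraw missing cells."""
    excluded = {c for c in working.columns if _is_block_continuous(c) and c != name}
    excluded.update(c for c in _EXCLUDED_COLUMNS if c in working.columns)
    X = _encode_predictors(working, name, excluded)
    col = working[name]
    obs_rows = scope & ~miss_rows
    if method == "pmm":
        y_obs = col.to_numpy(dtype=float)[obs_rows]
        boot = rng.integers(0, obs_rows.sum(), obs_rows.sum())
        Xo = X[obs_rows]
        coef, _, rank, _ = np.linalg.lstsq(Xo[boot], y_obs[boot], rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                f"collinear predictors while imputing {name!r}; dropped via least squares"
            )
        values = pmm_draw(y_obs, Xo @ coef, X[miss_rows] @ coef, plan.donor_k, rng)
        out = col.to_numpy(dtype=float).copy()
        out[miss_rows] = values
        working[name] = out
        return np.mean(values) if len(values) else np.nan
    # classification methods
    y_obs = col[obs_rows].to_numpy()
    proba, classes = _fit_predict_proba(
        X[obs_rows], y_obs, X[miss_rows], method, plan.ridge, rng
    )
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(proba))[:, None]
    picks = classes[np.argmax(u < cum, axis=1)]
    if col.dtype == object:
        out = col.to_numpy(dtype=object).copy()
        out[miss_rows] = picks
        working[name] = out
        top = pd.Series(y_obs).mode().iloc[0]
        return float(np.mean(picks == top)) if len(picks) else np.nan
    out = col.to_numpy(dtype=float).copy()
    out[miss_rows] = picks.astype(float)
    working[name] = out
    return float(np.mean(picks.astype(float))) if len(picks) else np.nan


def impute(
    table: pd.DataFrame,
    plan: ImputationPlan | None = None,
    columns: list[str] | None = None,
) -> ImputedStack:
    """Run FCS and return m completed datasets.

    ``columns`` restricts which variables participate (as targets and
    predictors); by default every column except identifiers.  Observed
    cells are bitwise identical across the m outputs.
    """
    plan = plan or ImputationPlan()
    cols = [c for c in (columns or table.columns) if c not in _EXCLUDED_COLUMNS]
    frame = table[cols]
    age = table["age"].to_numpy(dtype=float) if "age" in table.columns else None
    n = len(table)

    # determine what needs imputing, inside each variable's block only
    targets: dict[str, np.ndarray] = {}
    scopes: dict[str, np.ndarray] = {}
    methods: dict[str, str] = {}
    for name in cols:
        scope = (
            np.ones(n, dtype=bool)
            if _is_block_continuous(name)  # imputed everywhere, blanked afterwards
            else _scope_mask(name, age, n)
        )
        miss = frame[name].isna().to_numpy() & scope
        if not miss.any():
            continue
        targets[name] = miss
        scopes[name] = scope
        if name in plan.methods:
            methods[name] = plan.methods[name]
        else:
            methods[name] = _variable_kind(frame[name])
        if (scope & ~miss).sum() == 0:
            raise ConfigurationError(f"variable {name!r} has no observed values to learn from")

    order = sorted(targets, key=lambda v: (targets[v].sum(), v))  # ascending missingness
    seeds = spawn_seeds(plan.seed, plan.m)
    datasets = []
    trace: dict[str, np.ndarray] = {v: np.full((plan.m, plan.burn_in), np.nan) for v in order}

    for d, chain_seed in enumerate(seeds):
        rng = np.random.default_rng(chain_seed)
        working = frame.copy()
        # initial fill: random draws from the observed pool
        for name in order:
            obs = working[name][scopes[name] & ~targets[name]]
            fill = obs.sample(
                n=int(targets[name].sum()), replace=True, random_state=int(rng.integers(2**31))
            ).to_numpy()
            col = working[name].copy()
            col.iloc[np.flatnonzero(targets[name])] = fill
            working[name] = col
        for it in range(plan.burn_in):
            for name in order:
                chain_mean = _impute_variable(
                    working, name, targets[name], scopes[name], methods[name], plan, rng
                )
                trace[name][d, it] = chain_mean
        completed = table.copy()
        for name in order:
            completed[name] = working[name]
        # post-processing: block-restricted continuous variables stay blank
        # outside their block
        for name in cols:
            if _is_block_continuous(name):
                outside = ~_scope_mask(name, age, n)
                col = completed[name].astype(float)
                col[outside] = np.nan
                completed[name] = col
        datasets.append(completed)

    return ImputedStack(datasets=datasets, trace=trace, plan=plan, seeds=seeds)


@dataclass
class ConvergenceReport:
    flagged: dict[str, bool]
    drift: dict[str, float]

    @property
    def any_flagged(self) -> bool:
        return any(self.flagged.values())


def check_convergence(trace: dict[str, np.ndarray], min_agree: float = 1.0) -> ConvergenceReport:
    """Flag variables whose chain means drift monotonically.

    A variable is flagged when, over the last half of the iterations, at
    least ``min_agree`` of the chains move strictly monotonically in the
    same direction (default: all of them — with the short 5-iteration
    default chains, sign agreement across every chain separates drift from
    noise).  A constant trace never flags; an injected linear drift always
    does.
    """
    flagged = {}
    drift = {}
    for name, chains in trace.items():
        chains = np.asarray(chains, dtype=float)
        if chains.ndim != 2 or chains.shape[1] < 2:
            raise ValidationError("trace needs >= 2 iterations per chain")
        half = chains[:, chains.shape[1] // 2 :] if chains.shape[1] > 2 else chains
        diffs = np.diff(half, axis=1)
        up = np.all(diffs > 1e-12, axis=1)
        down = np.all(diffs < -1e-12, axis=1)
        frac = max(up.mean(), down.mean()) if diffs.size else 0.0
        flagged[name] = bool(frac >= min_agree)
        drift[name] = float(np.nanmean(half[:, -1] - half[:, 0]))
    return ConvergenceReport(flagged=flagged, drift=drift)
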