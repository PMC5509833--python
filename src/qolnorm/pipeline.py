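"""End-to-end survey analysis driver.

Stages: load (or simulate) the cohort -> score the EQ-5D index from
dimension levels if needed -> freeze the outcome transforms -> multiply
impute -> fit the final beta (VAS) and one-inflated beta (EQ-5D) models ->
bootstrap + Rubin-pool the coefficients -> age-based norm curves with
bootstrap bands -> diagnostics.  Every stage's outputs land in the run
directory together with a manifest (seeds, sizes, stage summaries) that
makes a rerun byte-identical.

An optional sensitivity branch repeats everything on the adult + elderly
rows only (child proxy reports excluded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ValidationError, spawn_seeds
from . import __version__
from .betareg import cox_snell_r2, outlier_flags, rq_residuals
from .cohort import TruthConfig, generate_cohort, inject_missingness
from .design import DesignSpec
from .impute import ImputationPlan, ImputedStack, check_convergence, impute
from .models import (
    FORCED_AGE,
    MU_FORMULA,
    NU_FORMULA,
    VAS_FORMULA,
    fit_mu,
    fit_nu,
    fit_vas,
    make_bootstrap_fn,
    prepare_model_frame,
)
from .norms import fit_age_norms, marginal_norms, predict_norms_ci
from .pooling import pool_bootstrap_fits
from .scoring import TransformSpec, load_tariff, score_table


def completion_rate(completed: int, approached: int) -> float:
    """Survey completion percentage from recruitment counts."""
    if approached <= 0 or completed < 0 or completed > approached:
        raise ValidationError("need 0 <= completed <= approached, approached > 0")
    return 100.0 * completed / approached


@dataclass
class PipelineConfig:
    """Settings for one full run; all seeds are recorded in the manifest."""

    input_path: str | None = None  # cohort CSV; None -> simulate
    tariff_path: str | None = None
    out_dir: str = "qolnorm_run"
    include_children: bool = True
    sensitivity_no_children: bool = False
    m: int = 5
    burn_in: int = 5
    B: int = 500
    seed: int = 0
    impute_columns: list[str] | None = None
    make_plots: bool = False

    vas_formula: str = VAS_FORMULA
    nu_formula: str = NU_FORMULA
    mu_formula: str = MU_FORMULA


@dataclass
class PipelineResult:
    out_dir: Path
    transform_spec: TransformSpec
    stack: ImputedStack
    pooled: dict[str, pd.DataFrame]
    norms: dict
    diagnostics: dict
    manifest: dict


_MODEL_COLUMNS = [
    "age",
    "gender",
    "household_size",
    "exp_severe_self",
    "exp_severe_family",
    "n_parents",
    "pets",
    "sick",
    "school",
    "smoking_adult",
    "education",
    "work_health",
    "disabled",
    "exp_severe_caring",
    "living_elderly_home",
    "alcohol_rarely",
    "vas",
    "eq5d_index",
]


def _prune_constant_terms(design: DesignSpec, frame: pd.DataFrame) -> DesignSpec:
    built = design.build(frame)
    for term, slc in built.term_slices.items():
        if term == "Intercept":
            continue
        cols = built.X[:, slc]
        if np.all(np.ptp(cols, axis=0) == 0):
            design = design.drop(term)
    return design


def _load_or_simulate(cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    if cfg.input_path is None:
        truth = TruthConfig()
        table = generate_cohort(truth, seed=seed)
        return inject_missingness(table, truth.missing_rates, seed=seed + 1)
    return pd.read_csv(cfg.input_path)


def _analyse(
    table: pd.DataFrame, cfg: PipelineConfig, seeds: list[int], out: Path
) -> PipelineResult:
    out.mkdir(parents=True, exist_ok=True)

    # EQ-5D scoring from dimension levels where the index is absent
    if cfg.tariff_path is not None and "eq5d_dim1" in table.columns:
        tariff = load_tariff(cfg.tariff_path)
        scored = score_table(table, tariff)
        if "eq5d_index" not in table.columns:
            table["eq5d_index"] = scored
        else:
            need = table["eq5d_index"].isna() & ~np.isnan(scored)
            table.loc[need, "eq5d_index"] = scored[need]

    spec = TransformSpec.from_data(len(table), table["eq5d_index"].to_numpy(dtype=float))

    columns = cfg.impute_columns or [c for c in _MODEL_COLUMNS if c in table.columns]
    plan = ImputationPlan(m=cfg.m, burn_in=cfg.burn_in, seed=seeds[0])
    stack = impute(table, plan, columns=columns)
    convergence = check_convergence(stack.trace)
    frames = [prepare_model_frame(d, spec) for d in stack.datasets]
    for i, d in enumerate(stack.datasets, 1):
        d.to_csv(out / f"imputed_{i}.csv", index=False)

    designs = {
        "vas": DesignSpec.from_formula(cfg.vas_formula, forced=FORCED_AGE),
        "nu": DesignSpec.from_formula(cfg.nu_formula, forced=FORCED_AGE),
        "mu": DesignSpec.from_formula(cfg.mu_formula, forced=("age",)),
    }
    # terms that are constant in this cohort (e.g. child indicators after the
    # child-excluded sensitivity subset) carry no information and would break
    # the design rank
    designs = {k: _prune_constant_terms(v, frames[0]) for k, v in designs.items()}
    fitters = {"vas": fit_vas, "nu": fit_nu, "mu": fit_mu}

    pooled: dict[str, pd.DataFrame] = {}
    fits: dict[str, list] = {}
    for model_idx, (name, design) in enumerate(designs.items()):
        fits[name] = [fitters[name](design, f) for f in frames]
        fns = [make_bootstrap_fn(design, f, name) for f in frames]
        frame_index = {id(f): i for i, f in enumerate(frames)}
        pooled_df, _ = pool_bootstrap_fits(
            frames,
            lambda data, rows, _fns=fns, _idx=frame_index: _fns[_idx[id(data)]](data, rows),
            B=cfg.B,
            seed=(seeds[1] + 97 * model_idx) % (2**31),
            n_com=len(table),
        )
        pooled[name] = pooled_df
        pooled_df.to_csv(out / f"pooled_{name}.csv", index=False)

    # diagnostics on the first imputed dataset
    rng = np.random.default_rng(seeds[2])
    frame0 = frames[0]
    vas_fit = fits["vas"][0]
    null_vas = fit_vas(DesignSpec(outcome="vas_t", terms=()), frame0)
    from .betareg import OneInflatedFit

    eq_fit = OneInflatedFit(nu=fits["nu"][0], mu=fits["mu"][0])
    null_eq = OneInflatedFit(
        nu=fit_nu(DesignSpec(outcome="is_one", terms=()), frame0),
        mu=fit_mu(DesignSpec(outcome="eq5d_t", terms=()), frame0),
    )
    res_vas = rq_residuals(vas_fit, frame0["vas_t"].to_numpy(dtype=float), rng)
    res_eq = rq_residuals(eq_fit, frame0["eq5d_t"].to_numpy(dtype=float), rng)
    diagnostics = {
        "cox_snell_r2_vas": cox_snell_r2(vas_fit.loglik, null_vas.loglik, vas_fit.n),
        "cox_snell_r2_eq5d": cox_snell_r2(eq_fit.loglik, null_eq.loglik, len(frame0)),
        "n_outliers_vas": int(outlier_flags(res_vas).sum()),
        "n_outliers_eq5d": int(outlier_flags(res_eq).sum()),
        "imputation_flagged": convergence.flagged,
    }

    # age-only norms with bootstrap bands + marginal norms from the full models
    ages = np.arange(
        float(np.nanmin(table["age"])), float(np.nanmax(table["age"])) + 1
    )
    norms = {}
    norms.update(predict_norms_ci(frames, "vas", spec, ages=ages, B=cfg.B, seed=seeds[3]))
    norms.update(predict_norms_ci(frames, "eq5d", spec, ages=ages, B=cfg.B, seed=seeds[4]))
    for name, curve in norms.items():
        curve.to_frame().to_csv(out / f"norms_{name}.csv", index=False)
    from .betareg import predict_eq5d, predict_vas

    norms["vas_full_model"] = marginal_norms(
        frames, lambda d: predict_vas(vas_fit, d, spec), ages=ages
    )
    norms["eq5d_full_model"] = marginal_norms(
        frames, lambda d: predict_eq5d(eq_fit, d, spec)["mean_index"], ages=ages
    )
    norms["vas_full_model"].to_csv(out / "norms_vas_full_model.csv", index=False)
    norms["eq5d_full_model"].to_csv(out / "norms_eq5d_full_model.csv", index=False)

    if cfg.make_plots:
        _plots(out, norms, res_vas, res_eq, frame0)

    manifest = {
        "qolnorm_version": __version__,
        "config": {k: v for k, v in asdict(_cfg_public(cfg)).items()},
        "seeds": seeds,
        "n_rows": int(len(table)),
        "transform": {"n": spec.n, "min_index": spec.min_index, "max_index": spec.max_index},
        "imputation_seeds": stack.seeds,
        "diagnostics": diagnostics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return PipelineResult(
        out_dir=out,
        transform_spec=spec,
        stack=stack,
        pooled=pooled,
        norms=norms,
        diagnostics=diagnostics,
        manifest=manifest,
    )


def _cfg_public(cfg: PipelineConfig) -> PipelineConfig:
    return cfg


def _plots(out: Path, norms, res_vas, res_eq, frame0):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm as normal

    for name in ("vas", "eq5d_p_one", "eq5d_mean"):
        if name not in norms:
            continue
        c = norms[name]
        fig, ax = plt.subplots()
        ax.fill_between(c.ages, c.lo, c.hi, alpha=0.3)
        ax.plot(c.ages, c.point)
        ax.set_xlabel("age (years)")
        ax.set_ylabel(name)
        fig.savefig(out / f"norms_{name}.png", dpi=100)
        plt.close(fig)
    for label, res in (("vas", res_vas), ("eq5d", res_eq)):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        q = normal.ppf((np.arange(1, len(res) + 1) - 0.5) / len(res))
        axes[0].plot(q, np.sort(res), ".", ms=2)
        axes[0].plot(q, q, "-", lw=1)
        axes[0].set_title("QQ")
        axes[1].plot(frame0["age"], res, ".", ms=2)
        axes[1].set_title("residuals vs age")
        fig.savefig(out / f"diagnostics_{label}.png", dpi=100)
        plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis; returns the result and writes the run directory."""
    seeds = spawn_seeds(cfg.seed, 12)
    table = _load_or_simulate(cfg, seeds[10])
    if not cfg.include_children:
        table = table[table["age"] >= 13].reset_index(drop=True)
    out = Path(cfg.out_dir)
    result = _analyse(table.copy(), cfg, seeds[:5], out)
    if cfg.sensitivity_no_children and cfg.include_children:
        sub = table[table["age"] >= 13].reset_index(drop=True)
        _analyse(sub.copy(), cfg, seeds[5:10], out / "no_children")
    return result
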