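"""FCS multiple imputation: mechanics, PMM, convergence, pooled equivalence."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from qolnorm.cohort import TruthConfig, generate_cohort, inject_missingness
from qolnorm.design import DesignSpec
from qolnorm.impute import ImputationPlan, check_convergence, impute, pmm_draw
from qolnorm.models import fit_nu, prepare_model_frame
from qolnorm.pooling import rubin_pool
from qolnorm.scoring import TransformSpec

IMPUTE_COLS = ["age", "gender", "exp_severe_self", "pets", "vas", "eq5d_index"]


class TestPmm:
    def test_unique_nearest_donor_is_deterministic(self, rng):
        obs_vals = np.array([10.0, 20.0, 30.0])
        obs_pred = np.array([1.0, 2.0, 3.0])
        out = pmm_draw(obs_vals, obs_pred, np.array([2.1]), donor_k=1, rng=rng)
        assert out[0] == 20.0

    def test_identical_predictions_draw_uniformly(self):
        """With all predictions equal the donor choice is uniform (chi-square)."""
        rng = np.random.default_rng(3)
        obs_vals = np.arange(8, dtype=float)
        obs_pred = np.zeros(8)
        draws = pmm_draw(obs_vals, obs_pred, np.zeros(10_000), donor_k=8, rng=rng)
        counts = np.bincount(draws.astype(int), minlength=8)
        assert chisquare(counts).pvalue > 0.001

    def test_imputed_values_subset_of_observed_support(self, rng):
        obs_vals = rng.choice([1.5, 2.5, 7.0], size=40)
        obs_pred = rng.normal(size=40)
        out = pmm_draw(obs_vals, obs_pred, rng.normal(size=200), donor_k=5, rng=rng)
        assert set(np.unique(out)) <= {1.5, 2.5, 7.0}

    def test_small_donor_pool_warns_and_shrinks(self, rng):
        with pytest.warns(UserWarning, match="donors"):
            out = pmm_draw(np.array([4.0, 6.0]), np.array([0.0, 1.0]), np.array([0.2]), 5, rng)
        assert out[0] in (4.0, 6.0)


class TestImpute:
    def test_complete_table_returns_identical_copies(self, small_cohort):
        stack = impute(small_cohort, ImputationPlan(m=3, seed=1), columns=IMPUTE_COLS)
        assert stack.m == 3
        for d in stack.datasets:
            pd.testing.assert_frame_equal(d, small_cohort)

    def test_observed_cells_preserved_and_no_missing_left(self, small_cohort_missing):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = impute(small_cohort_missing, ImputationPlan(m=3, seed=2), columns=IMPUTE_COLS)
        for col in IMPUTE_COLS:
            obs = small_cohort_missing[col].notna()
            for d in stack.datasets:
                assert d[col].notna().all()
                assert (d.loc[obs, col] == small_cohort_missing.loc[obs, col]).all()

    def test_block_continuous_blanked_outside_block(self, small_cohort_missing):
        cols = IMPUTE_COLS + ["age_youngest_child"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = impute(small_cohort_missing, ImputationPlan(m=2, seed=3), columns=cols)
        d = stack.datasets[0]
        assert d.loc[d["age"] < 60, "age_youngest_child"].isna().all()
        assert d.loc[d["age"] >= 60, "age_youngest_child"].notna().all()

    def test_same_seed_reproducible(self, small_cohort_missing):
        a = impute(small_cohort_missing, ImputationPlan(m=2, seed=5), columns=IMPUTE_COLS)
        b = impute(small_cohort_missing, ImputationPlan(m=2, seed=5), columns=IMPUTE_COLS)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_burn_in_insensitivity_of_chain_means(self):
        """Chain means agree between short and long burn-in (converged chain)."""
        cfg = TruthConfig(n=2500)
        tab = inject_missingness(generate_cohort(cfg, seed=8), {"vas": 0.10}, seed=9)
        means = []
        for burn in (5, 20):
            stack = impute(tab, ImputationPlan(m=3, burn_in=burn, seed=10), columns=IMPUTE_COLS)
            imputed = [
                d.loc[tab["vas"].isna(), "vas"].mean() for d in stack.datasets
            ]
            means.append(np.mean(imputed))
        # Monte-Carlo noise of a mean of ~250 imputed VAS values across 3 chains
        assert abs(means[0] - means[1]) < 2.0

    def test_zero_missingness_pipeline_equals_complete_data_fit(self, small_cohort, eq5d_spec):
        """impute -> fit -> pool on complete data gives B=0 and the single fit."""
        stack = impute(small_cohort, ImputationPlan(m=5, seed=11), columns=IMPUTE_COLS)
        design = DesignSpec.from_formula("is_one ~ age + exp_severe_self")
        fits = [fit_nu(design, prepare_model_frame(d, eq5d_spec)) for d in stack.datasets]
        Q = np.vstack([f.coefs.to_numpy() for f in fits])
        U = np.vstack([np.diag(f.vcov.to_numpy()) for f in fits])
        pooled = rubin_pool(Q, U, names=fits[0].coefs.index)
        single = fit_nu(design, prepare_model_frame(small_cohort, eq5d_spec))
        assert np.allclose(pooled["B"], 0.0)
        assert np.allclose(pooled["lambda"], 0.0)
        assert np.allclose(pooled["estimate"], single.coefs.to_numpy())


class TestConvergence:
    def test_constant_trace_not_flagged(self):
        trace = {"v": np.full((5, 6), 2.0)}
        assert not check_convergence(trace).flagged["v"]

    def test_injected_linear_drift_flagged(self):
        drift = np.tile(np.linspace(0, 1, 8), (5, 1))
        rng = np.random.default_rng(0)
        noisy = drift + rng.normal(0, 1e-4, drift.shape)
        assert check_convergence({"v": noisy}).flagged["v"]

    def test_default_run_rarely_flags(self, small_cohort):
        flags = 0
        n_seeds = 10
        for seed in range(n_seeds):
            tab = inject_missingness(small_cohort, seed=200 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stack = impute(tab, ImputationPlan(m=5, burn_in=5, seed=seed), columns=IMPUTE_COLS)
            if check_convergence(stack.trace).any_flagged:
                flags += 1
        assert flags <= 1

    def test_short_trace_rejected(self):
        with pytest.raises(Exception):
            check_convergence({"v": np.ones((3, 1))})
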