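"""Backward elimination across imputed datasets and AIC recategorisation."""

import numpy as np
import pandas as pd
import pytest

from qolnorm._util import ValidationError, sigmoid
from qolnorm.design import DesignSpec
from qolnorm.models import fit_vas
from qolnorm.selection import backward_eliminate, recategorize_aic


def make_datasets(seed, m=3, n=800, noise_cols=("z",), beta_x=0.6):
    """m pseudo-imputed datasets: same truth, independent noise columns."""
    rng = np.random.default_rng(seed)
    base_x = rng.binomial(1, 0.5, n).astype(float)
    age = rng.uniform(0, 99, n)
    mu = sigmoid(0.8 + 0.01 * age - 0.0001 * age**2 + beta_x * base_x)
    y = np.clip(rng.beta(mu * 8, (1 - mu) * 8), 1e-12, 1 - 1e-12)
    out = []
    for _ in range(m):
        d = pd.DataFrame({"vas_t": y, "age": age, "x": base_x})
        for c in noise_cols:
            d[c] = rng.normal(size=n)
        out.append(d)
    return out


class TestBackwardElimination:
    def test_no_removal_when_all_terms_significant(self):
        datasets = make_datasets(1, noise_cols=())
        design = DesignSpec.from_formula(
            "vas_t ~ age + I(age**2) + x", forced=("age", "I(age**2)")
        )
        state = backward_eliminate(datasets, design, fit_vas)
        assert state.removed == []
        assert state.design.terms == design.terms

    def test_noise_term_removed_and_forced_kept(self):
        datasets = make_datasets(2)
        design = DesignSpec.from_formula(
            "vas_t ~ age + I(age**2) + x + z", forced=("age", "I(age**2)")
        )
        state = backward_eliminate(datasets, design, fit_vas)
        assert "z" in state.removed
        assert "x" in state.design.terms
        assert "age" in state.design.terms and "I(age ** 2)" in state.design.terms

    def test_forced_terms_never_dropped_even_if_nonsignificant(self):
        datasets = make_datasets(3, beta_x=0.0)
        design = DesignSpec.from_formula(
            "vas_t ~ age + I(age**2) + x", forced=("age", "I(age**2)")
        )
        state = backward_eliminate(datasets, design, fit_vas)
        assert "age" in state.design.terms and "I(age ** 2)" in state.design.terms

    def test_deterministic_replay(self):
        datasets = make_datasets(4, noise_cols=("z1", "z2", "z3"))
        design = DesignSpec.from_formula("vas_t ~ age + x + z1 + z2 + z3", forced=("age",))
        s1 = backward_eliminate(datasets, design, fit_vas)
        s2 = backward_eliminate(datasets, design, fit_vas)
        assert s1.removed == s2.removed
        assert s1.design.terms == s2.design.terms

    def test_rule_any_removes_more_aggressively(self):
        """A term significant in one dataset only survives 'all' but not 'any'."""
        datasets = make_datasets(6, noise_cols=("z",))
        design = DesignSpec.from_formula("vas_t ~ age + x + z", forced=("age",))
        kept_all = backward_eliminate(datasets, design, fit_vas, rule="all").design.terms
        kept_any = backward_eliminate(datasets, design, fit_vas, rule="any").design.terms
        assert set(kept_any) <= set(kept_all)

    def test_elimination_can_empty_to_intercept_only(self):
        rng = np.random.default_rng(7)
        n = 300
        y = np.clip(rng.beta(4, 4, n), 1e-9, 1 - 1e-9)
        datasets = [
            pd.DataFrame({"vas_t": y, "z": rng.normal(size=n)}) for _ in range(2)
        ]
        design = DesignSpec.from_formula("vas_t ~ z")
        with pytest.warns(UserWarning, match="intercept-only"):
            state = backward_eliminate(datasets, design, fit_vas)
        assert state.design.terms == ()


class TestRecategorize:
    @staticmethod
    def factor_datasets(seed, effects, m=3, n=1200):
        """Beta outcome with a 4-level factor whose true effects are given."""
        rng = np.random.default_rng(seed)
        levels = list(effects)
        lab = rng.choice(levels, size=n)
        mu = sigmoid(0.5 + np.array([effects[l] for l in lab]))
        y = np.clip(rng.beta(mu * 10, (1 - mu) * 10), 1e-12, 1 - 1e-12)
        return [pd.DataFrame({"vas_t": y, "edu": lab}) for _ in range(m)]

    def test_full_model_aic_invariant_to_reference_category(self):
        datasets = self.factor_datasets(11, {"a": 0.0, "b": 0.0, "c": 0.4, "d": 0.8})
        design = DesignSpec.from_formula("vas_t ~ C(edu)")
        fits = []
        for ref in "abcd":
            d = datasets[0].copy()
            spec = DesignSpec.from_formula(f"vas_t ~ C(edu, Treatment('{ref}'))")
            fits.append(fit_vas(spec, d).aic)
        assert max(fits) - min(fits) < 1e-6

    def test_merging_equal_effect_levels_drops_aic_by_two_per_parameter(self):
        datasets = self.factor_datasets(12, {"a": 0.0, "b": 0.0, "c": 0.5, "d": 1.0})
        design = DesignSpec.from_formula("vas_t ~ C(edu)")
        full = fit_vas(design, datasets[0])
        merged_d = datasets[0].copy()
        merged_d["edu"] = merged_d["edu"].replace({"b": "a"})
        merged = fit_vas(design, merged_d)
        # identical true effects: delta loglik ~ 0, AIC drop ~ 2 per dropped parameter
        assert merged.aic < full.aic
        assert full.aic - merged.aic == pytest.approx(2.0, abs=1.5)

    def test_recategorize_merges_equal_levels_only(self):
        datasets = self.factor_datasets(13, {"a": 0.0, "b": 0.0, "c": 0.6, "d": 1.2})
        design = DesignSpec.from_formula("vas_t ~ C(edu)")
        result = recategorize_aic(datasets, design, "edu", fit_vas)
        merged_pairs = set(result["mapping"].items())
        assert ("b", "a") in merged_pairs or ("a", "b") in merged_pairs
        assert result["mean_aic_after"] < result["mean_aic_before"]
        # clearly distinct levels stay distinct
        assert "d" not in result["mapping"] or result["mapping"].get("d") not in ("a", "b")

    def test_user_supplied_merge_list(self):
        datasets = self.factor_datasets(14, {"a": 0.0, "b": 0.05, "c": 0.6, "d": 1.2})
        design = DesignSpec.from_formula("vas_t ~ C(edu)")
        result = recategorize_aic(
            datasets, design, "edu", fit_vas, candidate_merges=[{"b": "a"}]
        )
        assert result["mapping"] in ({}, {"b": "a"})

    def test_too_few_levels_rejected(self):
        datasets = self.factor_datasets(15, {"a": 0.0, "b": 0.5})
        design = DesignSpec.from_formula("vas_t ~ C(edu)")
        with pytest.raises(ValidationError):
            recategorize_aic(datasets, design, "edu", fit_vas)
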