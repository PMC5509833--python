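"""Two-step model selection over multiply imputed datasets.

Step 1 — backward elimination: a term is removable when it is
non-significant (joint Wald p > alpha) in *all* m imputed datasets; each
round drops, among the removable terms, the one whose best (smallest)
p-value across datasets is largest, and stops when every remaining term is
significant in at least one dataset.  Forced-in terms (the age polynomial,
questionnaire-block indicators) are never dropped.  The opposite
reading — remove when non-significant in *any* dataset — is available via
``rule="any"``.

Step 2 — recategorisation: factors with many levels are compared against
merged codings by mean AIC across the m datasets; the coding with the
lowest mean AIC wins, and the full-model AIC is verified to be invariant
to the reference category (a pure reparameterisation).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError
from .design import DesignSpec


@dataclass
class SelectionState:
    """Final design plus a replayable elimination history."""

    design: DesignSpec
    history: list[dict] = field(default_factory=list)
    pvalues: pd.DataFrame | None = None  # final per-dataset term p-values

    @property
    def removed(self) -> list[str]:
        return [h["term"] for h in self.history]


def _term_pvalue_table(fits, terms) -> pd.DataFrame:
    """(m, n_terms) table of per-dataset joint Wald p-values."""
    rows = {}
    for term in terms:
        rows[term] = [f.term_pvalue(term) for f in fits]
    return pd.DataFrame(rows)


def backward_eliminate(
    datasets: list[pd.DataFrame],
    design: DesignSpec,
    fit_fn,
    alpha: float = 0.05,
    rule: str = "all",
) -> SelectionState:
    """Backward-eliminate terms across m imputed datasets.

    ``fit_fn(design, data)`` fits the model and must return an object with a
    ``term_pvalue(term)`` method (a :class:`~qolnorm.betareg.BetaFit`,
    ``LogisticFit``, or an adapter around ``OneInflatedFit``).
    """
    if rule not in ("all", "any"):
        raise ValidationError("rule must be 'all' or 'any'")
    state = SelectionState(design=design)
    current = design
    while True:
        fits = [fit_fn(current, data) for data in datasets]
        ptab = _term_pvalue_table(fits, current.removable())
        if ptab.empty:
            state.pvalues = ptab
            break
        if rule == "all":
            removable = [t for t in ptab.columns if (ptab[t] > alpha).all()]
        else:
            removable = [t for t in ptab.columns if (ptab[t] > alpha).any()]
        if not removable:
            state.pvalues = ptab
            break
        # drop the term whose best (smallest) p-value across datasets is
        # largest; lexicographic tie-break keeps runs replayable
        best_p = {t: float(ptab[t].min()) for t in removable}
        victim = sorted(best_p.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        state.history.append(
            {"term": victim, "pvalues": ptab[victim].tolist(), "min_p": best_p[victim]}
        )
        current = current.drop(victim)
        if not current.terms:
            warnings.warn("backward elimination emptied the model; intercept-only returned")
            state.pvalues = pd.DataFrame()
            break
    state.design = current
    return state


# ---------------------------------------------------------------------------
# AIC-guided factor recategorisation


def _apply_merge(datasets, column, mapping):
    """Relabel a factor column in every dataset according to ``mapping``."""
    out = []
    for data in datasets:
        d = data.copy()
        d[column] = d[column].map(lambda v: mapping.get(v, v))
        out.append(d)
    return out


def _mean_aic(datasets, design, fit_fn) -> float:
    return float(np.mean([fit_fn(design, data).aic for data in datasets]))


def enumerate_candidate_merges(
    datasets, design: DesignSpec, column: str, fit_fn, alpha: float = 0.05
) -> list[dict]:
    """Candidate level merges from pairwise coefficient non-significance.

    Levels are ordered by their fitted coefficient (first dataset); adjacent
    levels whose coefficients do not differ significantly (Wald, pooled
    first-dataset vcov) become merge candidates.
    """
    fit = fit_fn(design, datasets[0])
    des = fit.design
    # columns of this factor (patsy one-hot names contain "column[")
    idx = [j for j, name in enumerate(des.columns) if f"{column}[" in name or f"C({column})[" in name]
    if len(idx) < 1:
        raise ValidationError(f"no factor columns found for {column!r}")
    coefs = fit.coefs.to_numpy()
    V = fit.vcov.to_numpy()
    levels = []
    for j in idx:
        name = des.columns[j]
        lev = name.split("[T.")[-1].rstrip("]") if "[T." in name else name
        levels.append((lev, coefs[j], j))
    # reference level has implicit coefficient 0
    all_obs = sorted(set(datasets[0][column].dropna()) - {"irrelevant"})
    ref = [l for l in all_obs if l not in {lev for lev, _, _ in levels}]
    if ref:
        levels.append((ref[0], 0.0, None))
    levels.sort(key=lambda t: t[1])
    candidates = []
    for (l1, b1, j1), (l2, b2, j2) in itertools.pairwise(levels):
        var = 0.0
        if j1 is not None:
            var += V[j1, j1]
        if j2 is not None:
            var += V[j2, j2]
        if j1 is not None and j2 is not None:
            var -= 2 * V[j1, j2]
        z = (b2 - b1) / np.sqrt(var) if var > 0 else np.inf
        from scipy.stats import norm

        if 2 * norm.sf(abs(z)) > alpha:
            candidates.append({l2: l1})
    return candidates


def recategorize_aic(
    datasets: list[pd.DataFrame],
    design: DesignSpec,
    column: str,
    fit_fn,
    candidate_merges: list[dict] | None = None,
    check_reference_invariance: bool = True,
) -> dict:
    """Choose the factor coding minimising mean AIC across datasets.

    ``candidate_merges`` is a list of ``{old_level: new_level}`` mappings; if
    omitted, candidates are enumerated from pairwise non-significant
    adjacent levels.  Merges are applied greedily while the mean AIC keeps
    dropping.  Returns the chosen overall mapping and the AIC bookkeeping.
    """
    levels = set(datasets[0][column].dropna()) - {"irrelevant"}
    if len(levels) < 3:
        raise ValidationError(f"factor {column!r} needs >= 3 levels to recategorise")

    if check_reference_invariance:
        aics = []
        for lev in sorted(levels):
            releveled = []
            for data in datasets[:1]:
                d = data.copy()
                order = [lev] + sorted(levels - {lev}) + (
                    ["irrelevant"] if (data[column] == "irrelevant").any() else []
                )
                d[column] = pd.Categorical(d[column], categories=order)
                releveled.append(d)
            aics.append(_mean_aic(releveled, design, fit_fn))
        if max(aics) - min(aics) > 1e-6:
            raise ValidationError("full-model AIC depends on the reference category")

    base_aic = _mean_aic(datasets, design, fit_fn)
    mapping: dict = {}
    current = datasets
    current_aic = base_aic
    aic_trail = [{"mapping": {}, "mean_aic": base_aic}]
    while True:
        cands = (
            candidate_merges
            if candidate_merges is not None
            else enumerate_candidate_merges(current, design, column, fit_fn)
        )
        cands = [c for c in cands if not set(c) <= set(mapping)]
        best = None
        for cand in cands:
            merged = _apply_merge(current, column, cand)
            if merged[0][column].dropna().nunique() < 2:
                warnings.warn(f"merge {cand} empties factor {column!r}; skipped")
                continue
            aic = _mean_aic(merged, design, fit_fn)
            aic_trail.append({"mapping": dict(cand), "mean_aic": aic})
            if aic < current_aic - 1e-9 and (best is None or aic < best[1]):
                best = (cand, aic, merged)
        if best is None:
            break
        cand, current_aic, current = best
        mapping.update(cand)
        if candidate_merges is not None:
            break  # user-supplied list: single pass
    return {
        "column": column,
        "mapping": mapping,
        "mean_aic_before": base_aic,
        "mean_aic_after": current_aic,
        "trail": aic_trail,
    }
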