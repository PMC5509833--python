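"""Variable dictionary for the survey-like cohort table.

One row per respondent.  Three questionnaire blocks exist: children
(< 13 years, answered by a proxy), adults (13-59) and elderly (60+); some
variables are asked of adults and elderly together.  Variables restricted
to a block are "irrelevant" outside it: categorical ones carry the literal
category ``"irrelevant"`` there (and are never imputed there), continuous
ones are blank by design and are excluded as imputation predictors.

``missing_rate`` defaults mirror the survey's per-variable missingness
percentages (0-30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUBGROUPS = ("all", "child", "adult", "elderly", "adult_elderly")

IRRELEVANT = "irrelevant"


@dataclass(frozen=True)
class Variable:
    name: str
    kind: str  # "binary" | "categorical" | "continuous" | "count"
    subgroup: str = "all"
    levels: tuple[str, ...] = ()  # categorical only
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical variable {self.name} needs levels")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


#: covariates of the cohort table, in survey order
COVARIATES: tuple[Variable, ...] = (
    Variable("gender", "binary", "all", missing_rate=0.00),
    Variable("household_size", "count", "all", missing_rate=0.02),
    Variable("exp_severe_self", "binary", "all", missing_rate=0.07),
    Variable("exp_severe_family", "binary", "all", missing_rate=0.10),
    Variable("n_parents", "binary", "all", missing_rate=0.05),
    Variable("pets", "binary", "all", missing_rate=0.01),
    Variable("sick", "binary", "all", missing_rate=0.01),
    Variable(
        "school",
        "categorical",
        "child",
        ("kindergarten", "primary_school", "other_school", "no_school"),
        missing_rate=0.01,
    ),
    Variable(
        "smoking_adult",
        "categorical",
        "adult",
        ("non_smoker", "ex_smoker", "smoker"),
        missing_rate=0.00,
    ),
    Variable(
        "education",
        "categorical",
        "adult_elderly",
        ("none", "primary", "lower_secondary", "higher_secondary", "higher", "student"),
        missing_rate=0.01,
    ),
    Variable("work_health", "binary", "adult_elderly", missing_rate=0.01),
    Variable("disabled", "binary", "adult_elderly", missing_rate=0.01),
    Variable("exp_severe_caring", "binary", "adult_elderly", missing_rate=0.30),
    Variable("living_elderly_home", "binary", "elderly", missing_rate=0.01),
    Variable("alcohol_rarely", "binary", "elderly", missing_rate=0.02),
    Variable(
        "smoking_elderly",
        "categorical",
        "elderly",
        ("smoker", "quit_before_30", "quit_30_50", "quit_after_50", "never"),
        missing_rate=0.03,
    ),
    Variable("age_youngest_child", "continuous", "elderly", missing_rate=0.05),
)

OUTCOMES: tuple[Variable, ...] = (
    Variable("vas", "continuous", "all", missing_rate=0.05),
    Variable("eq5d_index", "continuous", "all", missing_rate=0.02),
)

ALL_VARIABLES: tuple[Variable, ...] = COVARIATES + OUTCOMES

VARIABLES: dict[str, Variable] = {v.name: v for v in ALL_VARIABLES}

#: default per-variable missingness probabilities
DEFAULT_MISSING_RATES: dict[str, float] = {
    v.name: v.missing_rate for v in ALL_VARIABLES if v.missing_rate > 0
}
# the five dimension items share one joint 1% missingness event (their index
# then gains an extra 1% on top, giving the index's 2% total)
DEFAULT_MISSING_RATES["eq5d_dims"] = 0.01
DEFAULT_MISSING_RATES["eq5d_index"] = 0.01


def subgroup_mask(age, subgroup: str):
    """Boolean mask of rows belonging to a questionnaire block."""
    import numpy as np

    age = np.asarray(age, dtype=float)
    if subgroup == "all":
        return np.ones(age.shape, dtype=bool)
    if subgroup == "child":
        return age < 13
    if subgroup == "adult":
        return (age >= 13) & (age < 60)
    if subgroup == "elderly":
        return age >= 60
    if subgroup == "adult_elderly":
        return age >= 13
    raise ValueError(f"unknown subgroup {subgroup!r}")
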