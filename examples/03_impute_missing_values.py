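"""Multiply impute missing survey values by fully conditional specification.

Each incomplete variable is regressed on all others (logistic, polytomous
or predictive mean matching by type) and redrawn over 5 burn-in sweeps;
m independent chains give m completed datasets.  The chain-mean trace is
checked for monotone drift, the tell-tale of a non-converged chain.
"""

import warnings

from qolnorm import ImputationPlan, TruthConfig, check_convergence, generate_cohort, impute, inject_missingness

cfg = TruthConfig(n=1000)
table = inject_missingness(generate_cohort(cfg, seed=3), cfg.missing_rates, seed=4)

plan = ImputationPlan(m=5, burn_in=5, donor_k=5, seed=5)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    stack = impute(
        table,
        plan,
        columns=["age", "gender", "household_size", "exp_severe_self",
                 "exp_severe_family", "pets", "sick", "education",
                 "work_health", "vas", "eq5d_index"],
    )

print(f"{stack.m} completed datasets; observed cells identical across all of them")
d0 = stack.datasets[0]
miss = table["vas"].isna()
print(f"VAS cells imputed: {int(miss.sum())}; "
      f"mean of imputed values: {d0.loc[miss, 'vas'].mean():.1f} "
      f"(observed mean {table['vas'].mean():.1f})")
ones = (d0.loc[table['eq5d_index'].isna(), 'eq5d_index'] == 1).mean()
print(f"PMM keeps the one-inflation: {ones:.0%} of imputed EQ-5D values are exactly 1")

report = check_convergence(stack.trace)
print("variables flagged for monotone chain drift:",
      [v for v, f in report.flagged.items() if f] or "none")
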