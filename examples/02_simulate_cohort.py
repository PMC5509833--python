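"""Simulate a survey-like HRQoL cohort with known ground truth.

The generator draws ages 0-99 (about 18% children, 20% elderly),
block-restricted covariates, a beta-distributed VAS and a one-inflated
EQ-5D index from logit-scale coefficient dictionaries, then blanks cells
at survey-like missingness rates.  Because the generating coefficients
are known, every downstream stage can be validated against them.
"""

from qolnorm import TruthConfig, generate_cohort, inject_missingness

cfg = TruthConfig(n=1774)  # defaults mirror the fitted survey models
complete = generate_cohort(cfg, seed=1)
table = inject_missingness(complete, cfg.missing_rates, seed=2)

print(f"cohort: {len(table)} respondents")
print(f"  children (<13): {(table.age < 13).mean():.1%}   "
      f"elderly (60+): {(table.age >= 60).mean():.1%}")
print(f"  perfect health (EQ-5D = 1): {(complete.eq5d_index == 1).mean():.1%}")
print(f"  mean VAS: {complete.vas.mean():.1f}")
print("\nper-variable missingness after injection:")
for col in ("vas", "eq5d_index", "exp_severe_self", "exp_severe_family", "household_size"):
    print(f"  {col:<20} {table[col].isna().mean():.1%}")
print("\nblock restriction: education of a child is 'irrelevant', never missing:")
print(table.loc[table.age < 13, "education"].unique())
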