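"""Predict the 3-way change category with staged multinomial models.

Predictors enter in the fixed sequence null -> baseline severity ->
+ socio-demographics -> + functioning/context -> + support receipt; stages
are compared to the full model by deviance (LR) tests and AIC.  "No
change" is the reference category, continuous predictors are standardized
within the analysis sample, and a planted effect makes the demonstration
informative.
"""

from sdqchange import CohortConfig, classify_cohort, generate, staged_comparison
from sdqchange.multinomial import ModelSpec, fit_multinomial, significance_policy

cfg = CohortConfig(
    n=9074,
    seed=1,
    effect_log_odds={"t1_emotional": (0.6, -0.2), "support_other": (0.0, 0.5)},
)
records = generate(cfg)
results = classify_cohort(records)

stages = staged_comparison(records, results, "full")
print(stages[["stage", "n_params", "aic", "lr_vs_full", "df", "p"]].to_string(index=False))

fit = fit_multinomial(ModelSpec.for_stage("full"), records, results)
alpha = significance_policy("full")
summary = fit.summary_frame(alpha=alpha)
flagged = summary[summary["significant"]]
print(f"\nfull model: n={fit.n}, AIC={fit.aic:.1f}, McFadden R2={fit.mcfadden_r2:.4f}")
print(f"\ncoefficients with p < {alpha}:")
print(
    flagged[["contrast", "term", "odds_ratio", "ci_low", "ci_high", "p"]]
    .round(3)
    .to_string(index=False)
)
print(
    "\nThe planted effects surface where they should: baseline emotional\n"
    "problems raise the odds of reliable improvement (OR > 1, improvement\n"
    "contrast) and 'other' support raises the odds of deterioration.  ORs\n"
    "are per SD for continuous terms; CIs are Wald, exp-transformed."
)
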