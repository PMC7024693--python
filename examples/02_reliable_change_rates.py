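"""Classify reliable change and tabulate rates by clinical threshold.

A case reliably improves if any of the emotional/conduct/hyperactivity
subscales drops by 3+ points and none rises by 3+; any 3+ rise is reliable
deterioration regardless of improvement elsewhere.  The cohort is split at
the clinical cuts (conduct 5, emotional 6, hyperactivity 7) into an
above-threshold band and its complement.
"""

from sdqchange import (
    CohortConfig,
    above_threshold_decomposition,
    classify_cohort,
    generate,
    rate_table,
    split_by_threshold,
)

records = generate(CohortConfig(n=9074, seed=1))
results = classify_cohort(records)
halves = split_by_threshold(records)
index = {id(r): res for r, res in zip(records, results)}
above_res = [index[id(r)] for r in halves["above"]]
below_res = [index[id(r)] for r in halves["below"]]

table = rate_table(results, above_res, below_res)
print(table.to_text())

decomp = above_threshold_decomposition(halves["above"], above_res)
pct = decomp.percentages()
print(
    f"\nAmong the {decomp.n_improved} above-threshold improvers, "
    f"{decomp.improved_on_elevated} ({pct['improved_on_elevated_pct_of_improved']:.0f}%) "
    "improved on a subscale that was elevated at baseline and "
    f"{decomp.improved_on_other} ({pct['improved_on_other_pct_of_improved']:.0f}%) "
    "only on subscales that were not."
)
print(
    "\nPercentages carry Wilson 95% CIs.  Above-threshold cases improve at\n"
    "several times the below-threshold rate - regression to the mean plus\n"
    "the floor effect (scores under 3 cannot drop by 3 points)."
)
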