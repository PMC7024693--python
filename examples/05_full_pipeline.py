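"""One reproducible end-to-end run with differential attrition.

Generates a T1 cohort of 14,296, applies the attrition mechanism (~63%
follow-up, biased against male/FSM/Black or Other-ethnicity/more
symptomatic students), then classifies, tabulates, models and grows trees,
writing every artifact plus a manifest under ./pipeline_demo.
"""

import json

from sdqchange import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(
    cohort=CohortConfig(n=14_296),
    out_dir="pipeline_demo",
    seed=11,
    log_level="WARNING",
)
manifest = run_pipeline(cfg)

print(json.dumps(manifest["artifacts"], indent=2))
print(f"\nanalysable after attrition: {manifest['n_analysable']} "
      f"({manifest['n_analysable'] / 14_296:.1%} of T1)")
print(f"config hash: {manifest['config_hash'][:16]}...")
print(
    "\nRe-running with the same config and seed reproduces every file\n"
    "byte-for-byte; attrition.csv holds the Welch t comparison showing\n"
    "followed-up students score lower at T1 on every subscale."
)
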