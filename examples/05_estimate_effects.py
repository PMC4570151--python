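"""Full matched analysis on a synthetic bundle with known effects.

Runs the whole chain -- SIRS phenotyping, cohort construction, propensity
matching, outcome adjudication, unadjusted and APS-adjusted odds ratios --
and prints the effect table.  ORs are oriented balanced-relative-to-saline,
so values below 1 favor the balanced crystalloid; the generator plants a
mortality OR of 0.38.
"""

import sirsfluids as sf

cfg = sf.default_config(n_patients=8000, seed=41)
cfg.treatment["intercept"] = sf.synth._logit(0.10)
bundle, truth = sf.simulate_bundle(cfg)

result = sf.run_study(bundle, seed=41)
print("funnel:", result.funnel.as_dict())
print(f"matched pairs: {result.match.n_pairs}\n")

t = result.effect_table
t = t[t["n_saline"] + t["n_balanced"] > 0]
cols = ["outcome", "pct_saline", "pct_balanced", "or_unadjusted",
        "ci_low_unadjusted", "ci_high_unadjusted", "or_adjusted"]
print(t[cols].round(3).to_string(index=False))
# At this scale the matched balanced arm is a few hundred patients, so
# rare outcomes carry wide intervals; the mortality OR should sit near
# the planted 0.38 and low-potassium-with-replacement near 0.50.
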