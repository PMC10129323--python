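"""Association between household exposure and gaze shift rate.

Generates participant x year x load cell means with a known negative
exposure effect, builds the baseline mixed model by forward selection,
augments it with the exposure score, and prints the reported fit.
"""

import pandas as pd

from gazecog import synth, assoc

truth = synth.SynthTruth(household_offsets={})  # beta_aqi_shift = -7e-4
cells = synth.generate_shift_cells(200, truth, seed=3)
coded, coding_report = assoc.code_predictors(cells)

spec, baseline, log = assoc.build_baseline("shift_rate", ["Year:SES"], coded)
fit, comparison = assoc.add_air_quality(
    spec, pd.DataFrame(columns=["household_id", "exposure_score"]), coded)

print("baseline terms:", spec.fixed_terms)
print("selection log: ", log)
print()
print(fit.coef.round(4).to_string())
print()
w = fit.wald.round(4)
print(w.to_string())
print()
lrt = comparison["baseline_vs_augmented"]
print(f"baseline vs augmented: chi2({lrt['df']}) = {lrt['chi2']:.2f}, "
      f"p = {lrt['p']:.4f}")
# The AQI row is the change in shift rate (shifts/s) per centered AQI
# unit; a negative, significant estimate reproduces the ledger's truth
# (beta_aqi_shift = -7e-4). DF are Satterthwaite approximations; the Wald
# table gives the type-3 chi-square and partial eta-squared per term.
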