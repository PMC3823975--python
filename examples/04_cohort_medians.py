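"""Cohort tables: stack per-sample summaries and reproduce published medians.

First builds a small simulated cohort and prints its median row, then runs
the transcribed published per-patient columns through the same median
computation.
"""

import aldhgate as ag

# -- a 3-sample simulated cohort -------------------------------------------
rows = []
for seed in (10, 11, 12):
    scenario = ag.preset_scenario("aml_cd34pos", {"n_events": 50_000, "seed": seed})
    pair, _ = ag.simulate_sample_pair(scenario)
    rows.append(ag.analyze_sample_pair(pair).summary)

cohort = ag.build_cohort_table(rows)
print("simulated cohort medians:")
for key in ("pct_cd34cd38neg_in_aldh_bright", "marker_pos_pct_low", "fold"):
    print(f"  {key}: {cohort.medians[key]:.2f}")

# -- published per-patient columns -----------------------------------------
# Missing entries ('-' in the originals) are excluded from medians, never
# treated as zero; only that convention reproduces the printed values.
print("\npublished cohort medians (recomputed from per-patient values):")
for which, label in (("cd34pos", "CD34-positive AML"), ("cd34neg", "CD34-negative AML")):
    frame = ag.load_reference_cohort(which)
    b = ag.column_median(list(frame["pct_bright"]))
    mb = ag.column_median(list(frame["marker_pct_bright"]))
    ml = ag.column_median(list(frame["marker_pct_low"]))
    print(f"  {label}: %CD34+CD38- in bright = {b:g}, "
          f"marker+ in bright = {mb:g}, marker+ in low = {ml:g}")
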