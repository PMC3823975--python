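"""Discriminate HSC from LSC by ALDH activity in a simulated AML sample.

Runs the full pipeline: DEAB-derived ALDH threshold, bright/low split of
the CD34+CD38- stem gate, lymphocyte-standardized MFIs and the HSC/LSC
fold difference.
"""

import aldhgate as ag

scenario = ag.preset_scenario("aml_cd34pos", {"n_events": 100_000, "seed": 2})
pair, truth = ag.simulate_sample_pair(scenario)
result = ag.analyze_sample_pair(pair)

s = result.summary
print(f"sample {s.sample_id}: {s.cd34_status}")
print(f"ALDH threshold (0.99 quantile of DEAB aliquot): "
      f"{result.threshold.value:.1f} "
      f"[{result.threshold.n_reference_events} reference events]")
stem = result.labels.indices("blast_CD34pos_CD38neg")
bright_pct = 100 * result.bright[stem].mean()
print(f"CD34+CD38- gate: {stem.size} events, {bright_pct:.1f}% ALDH-bright")
print(f"HSC standardized MFI: {s.hsc_std_mfi:.2f}  "
      f"LSC standardized MFI: {s.lsc_std_mfi:.2f}")
print(f"HSC/LSC ALDH fold difference: {s.fold:.2f} "
      f"(scenario injected {scenario.aldh_fold})")
print(f"marker+ in bright/low stem compartments: "
      f"{s.marker_pos_pct_bright:.1f}% / {s.marker_pos_pct_low:.1f}%")

# The fold difference is the core readout: normal HSC carry severalfold
# higher ALDH activity than co-existing LSC, here recovered from the
# simulated sample by the same computation a real sample would get.
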