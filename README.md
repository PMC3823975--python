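# aldhgate

Discrimination of normal hematopoietic stem cells (HSC) from leukemic stem
cells (LSC) in AML bone-marrow flow cytometry, using ALDH enzymatic
activity together with aberrant-marker expression and lymphocyte-referenced
light-scatter ratios.

## The problem

Normal HSC and leukemic stem cells co-exist in the bone marrow of acute
myeloid leukemia (AML) patients and share the CD34+CD38− surface
phenotype, so surface markers alone cannot separate them in every patient.
ALDH (aldehyde dehydrogenase) activity — measured per cell with the
Aldefluor assay, with a DEAB-inhibited aliquot of the same specimen as the
assay background — provides a functional discriminator: CD34+CD38− HSC are
ALDH^bright while LSC are ALDH^low, in both CD34-positive and
CD34-negative AML. This package implements that analysis as a tested,
reusable pipeline for researchers working with paired native/DEAB
cytometry samples (FCS 3.0/3.1 or CSV), plus a synthetic-data generator so
every stage is testable without patient material.

## The scheme

For a paired sample (native aliquot *N*, DEAB-treated aliquot *D*):

1. **Gate** lymphocytes (CD45^bright SSC^low, the internal negative
   reference), CD45dim blasts, and CD34/CD38 sub-compartments within the
   blasts, with data-driven thresholds referenced to the lymphocytes.
2. **ALDH threshold**: the 0.99 quantile of the DEAB aliquot's ALDH
   signal, scoped to the compartment being split. Native events above it
   are ALDH^bright, the rest ALDH^low.
3. **Standardized MFI**: for a population *P*,
   `MFI*(P) = MFI_ALDH(P) / MFI_ALDH(lymphocytes)`; the HSC/LSC **fold
   difference** is `MFI*(HSC) / MFI*(LSC)`.
4. **Scatter ratios**: `median FSC(P)/median FSC(lymph)` and likewise for
   SSC; scatter-low means ≤1.4 (FSC) and ≤1.7 (SSC), scatter-high
   otherwise.
5. **Classify**: sample-level CD34 status (CD34-negative iff CD34+ blasts
   < 1%), per-event HSC/LSC calls (ALDH first; conflicting evidence is
   reported as *ambiguous*, never silently resolved), sample-level ALDH
   positivity (Cheung: ALDH+ > 5% of the sample) and the rare / numerous /
   negative pattern of the ALDH+ compartment (Pearce).
6. **Summarize**: one row per sample; cohorts stack rows and append
   per-column medians (missing values excluded).

## Worked example

```python
import aldhgate as ag

scenario = ag.preset_scenario("aml_cd34pos", {"n_events": 100_000, "seed": 2})
pair, truth = ag.simulate_sample_pair(scenario)
result = ag.analyze_sample_pair(pair)
s = result.summary
print(s.cd34_status, round(s.fold, 2), round(s.marker_pos_pct_low, 1))
```

prints

```
CD34_positive 7.16 75.5
```

meaning: the sample is CD34-positive AML; the CD34+CD38− ALDH^bright
cells (HSC) have 7.16-fold higher lymphocyte-standardized ALDH activity
than the CD34+CD38− ALDH^low cells (LSC) — the scenario injected a
6.9-fold effect — and 75.5% of the ALDH^low stem-gate events carry the
aberrant marker, against the 75% the generator encoded. The
`examples/` directory holds one short script per capability (gating, ALDH
discrimination, sample classification, cohort medians), each printing the
numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
aldhgate simulate --scenario aml_cd34pos --n 100000 --seed 2 --out-dir sim/
aldhgate run --native sim/native.csv --deab sim/deab.csv --panel panel.yaml --out out/
aldhgate cohort --in runs/ --out cohort.tsv
```

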