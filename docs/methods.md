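# Methods

## Data model

The pipeline's currency is the `EventTable`: an `n_events x 7` matrix of
nonnegative, finite, linear-scale intensities whose columns are the seven
fixed roles FSC, SSC, CD45, CD34, CD38, MARKER (the sample's aberrant
marker, e.g. CLL-1, CD7, CD56) and ALDH (the Aldefluor substrate signal,
FITC channel). A `PanelConfig` maps roles to instrument channel names so
that downstream code never sees instrument-specific naming. A `SamplePair`
couples the native aliquot with its DEAB-treated companion from the same
specimen; the inhibited aliquot defines the assay's fluorescence
background.

FCS 3.0/3.1 input honours the file's `$PnE` amplification (log-stored
channels are decoded to linear via `f2 * 10^(decades*x/PnR)`); values
without a declared amplification are taken as linear, since no scaling
convention can be recovered from the data itself. CSV input may declare a
per-role `log10-like` transform that is inverted on read. Events with a
negative or non-finite value in any mapped channel are dropped (not
clipped) and counted: MFI ratios require a positive linear scale, and
baseline-subtracted negatives carry no usable intensity. Spillover
compensation, FCS 2.0 and Gating-ML are out of scope.

## Gating

The published analysis was gated by hand; this package substitutes
deterministic, data-driven rules so the same analysis runs unattended:

* **Lymphocytes** — CD45 above the whole-sample 0.75 quantile AND SSC
  below the whole-sample 0.35 quantile. Lymphocytes are the internal
  reference for everything downstream, so an empty gate is an error, not
  an empty result.
* **Blasts** — CD45 within `[0.05, 0.6]` times the lymphocyte CD45
  median (the CD45dim band), excluding lymphocyte-gated events.
* **CD34/CD38 partition** — within blasts, positivity against thresholds
  derived from the lymphocytes as negative reference: the 0.995 quantile
  of a log-normal fitted to the reference intensities by median and MAD.
  The robust fit is deliberate: an automated lymphocyte gate can carry a
  few percent of antigen-positive contaminants, which would dominate a
  raw empirical 99.5th percentile but leave median/MAD unaffected.
* Ties exactly at any threshold count as negative (strict `>` for
  positivity) — a fixed convention for reproducibility.

All other quantile thresholds (lymphocyte gate, DEAB threshold) use the
plain order-statistic quantile: the smallest observed value `v` with at
least `q*n` values `<= v`. Thresholds are therefore always observed
intensities and monotone in `q`.

These gates are validated against the synthetic generator's ground truth
(compartment recovery ≥ 90% per population), not against the original
manual gates, which are unrecoverable.

## ALDH activity

The bright/low threshold is the 0.99 order-statistic quantile of the DEAB
aliquot's ALDH intensities, scoped to the same compartment being split
(falling back to the whole DEAB sample when the scoped gate holds fewer
than 25 events). A quantile of the inhibited control is preferred over
valley-finding on the native bimodal histogram because it makes no
modality assumption and stays stable at low event counts. By
construction it leaves ~1% of genuinely background events above itself;
every derived test and oracle accounts for that rate rather than
pretending the threshold is exact.

MFI is the arithmetic mean on the linear scale (a geometric option exists
in the config). Standardization divides a population's ALDH MFI by the
lymphocyte ALDH MFI of the same sample; since both MFIs in a fold
difference share that denominator, the fold equals the raw MFI ratio —
asserted algebraically in the tests. Per-sample MFIs are only reported
for call sets with at least the reporting floor of events (25): a handful
of stray sub-threshold events is not an LSC compartment, so a normal
marrow sample reports its fold as missing rather than as noise.

## Classification rules

* **CD34 status**: CD34-negative iff CD34+ cells are strictly under 1% of
  the blast gate ("less than 1%" is the published wording, hence strict).
* **Scatter**: population medians over lymphocyte medians; low iff
  FSC-ratio ≤ 1.4 and SSC-ratio ≤ 1.7. The boundary belongs to "low"
  because "high" is defined strictly as *more than* the bound. Sub-unit
  ratios classify as low without further flagging.
* **Per-event HSC/LSC calls** (stem candidates = the CD34+CD38− gate,
  plus CD34− blasts in CD34-negative samples): ALDH-bright and
  marker-negative → HSC; ALDH-low → LSC; ALDH-bright but marker-positive →
  ambiguous. ALDH outranks marker and scatter — the scheme's premise is
  that ALDH discriminates even without aberrancies — but conflicting
  evidence is surfaced as `ambiguous` instead of silently resolved, so QC
  problems remain visible. Scatter is recorded as evidence only.
  Whether a CD34− ALDH-bright marker-negative event in CD34-negative AML
  is HSC-lineage or a normal progenitor cannot be decided without
  molecular data; such events stay `ambiguous`.
* **Cheung class**: ALDH+ share of the total sample strictly above 5% →
  positive.
* **Pearce pattern**: the published rare/numerous/negative classification
  is visual; the computable rendering here uses three knobs, all
  config-exposed and none of them published values: negative below 0.1%
  ALDH+, rare below 5% ALDH+ with at least 80% of ALDH+ events SSC-confined
  (SSC ≤ 1.7× the lymphocyte SSC median), numerous otherwise. The one
  stated logical consequence — every sample-level ALDH-positive case has
  the numerous pattern — holds by construction (rare requires < 5%).

Cohort medians exclude missing entries (never zero-fill) and use the
midpoint for even counts; low-count values enter at face value with the
count carried as a flag. These conventions are exactly the ones that
reproduce the published cohort medians from the per-patient columns, and
the transcribed columns ship with the package as the reference fixture.

## Synthetic data

The generator emulates the population structure the analysis assumes.
Per-channel intensities are log-normal — the standard immunofluorescence
model, and the reason cytograms are log-displayed. Locations are
arbitrary units; only ratios matter. Anchors, chosen once:

| population | key parameters |
|---|---|
| lymphocytes | FSC 100 / SSC 80 / CD45 500; ALDH background; the reference |
| monocytes/granulocytes | CD45dim (150), SSC 400, CD34− |
| HSC (CD34+CD38−) | scatter 1.2×/1.35× lymphocytes (inside the 1.4/1.7 band); ALDH bright; marker− |
| LSC (CD34+ or CD34−) | scatter 1.6×/2.0× (outside the band); ALDH low; 75% marker+ |
| progenitors (CD34+CD38+) | ALDH bright, normal phenotype |
| leukemic CD34+CD38+ bulk | ALDH low, marker-mixture, CD34-positive AML only |

Log-scale SDs are 0.2–0.35 per channel. The ALDH-low and background
levels share one location (standardized LSC MFI ≈ 1), and bright
populations sit at `aldh_fold` times the low level, so the generator's
`aldh_fold` is exactly the effect size the pipeline should recover. The
preset folds are 6.9 (CD34-positive AML) and 4.3 (CD34-negative AML), the
published cohort medians; normal bone marrow uses the 6.9 level for its
HSC. Preset compositions put CD34+ cells at 0.6% of blasts in the
CD34-negative preset (under the 1% rule) and ~79% in the CD34-positive
preset.

The DEAB aliquot shares the native aliquot's population counts and event
order (one specimen split in two) with all intensities redrawn and every
population's ALDH signal collapsed to the shared background — which is
what the inhibitor does. Incomplete inhibition, seen in a minority of
real samples, is available as `deab_escape_fraction` (default 0).

What the generator does **not** model: doublets and debris, dead cells
(no viability dye), spectral spillover, acquisition-time drift,
multi-level ALDH^low substructure, and between-patient variability in
gate positions. Passing tests therefore demonstrate that the *rules* are
implemented correctly and recover known effects under the assumed
population structure — not that the automated gates would match expert
manual gates on any particular real specimen.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use 100 000 events per
aliquot and five seeds — enough that a 1% stem compartment holds ~1000
events and binomial noise on its fractions is well under the tolerances
being checked. All randomness flows through a single
`numpy.random.Generator` seeded from the scenario, so output is
bit-reproducible. Empty denominators yield explicitly missing fractions
(never 0/0 artifacts); degenerate inputs (empty gates, all-constant
channels, zero reference MFI) raise typed errors naming the failing
reference.

## Known limitations

* The FCS reader is minimal by design (TEXT segment, datatypes F/D/I,
  `$PnE` decoding); it does not parse the ANALYSIS segment, delimiter
  escaping inside TEXT values, or multi-dataset files.
* Quantile-based automated gates are a stated substitute for expert
  manual gating and inherit its validation limits (see above).
* The Pearce operationalization reproduces the one published logical
  constraint but cannot be validated beyond it.
* Molecular confirmation (FLT3-ITD / mutated NPM1) is outside the
  pipeline; it appears only as the reason some per-event calls are
  `ambiguous` rather than decidable.
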