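"""Synthetic paired native/DEAB cytometry samples with known ground truth.

The generator emulates the population structure that the ALDH-based
HSC/LSC discrimination scheme assumes in AML and normal bone marrow:

* **lymphocytes** — the internal ALDH-negative reference, CD45-bright and
  SSC-low;
* **CD45dim myeloid cells / blasts** — the gateable bulk;
* **CD34+CD38- HSC** — ALDH-bright, aberrant-marker-negative, scatter-low;
* **CD34+CD38- and/or CD34- LSC** — ALDH-low, partly marker-positive,
  scatter-high;
* **CD34+CD38+ progenitors** — normal, ALDH-bright.

Per-channel intensities are log-normal (the standard immunofluorescence
model; fluorescence cytograms are log-displayed for the same reason).
All location parameters are arbitrary units — only ratios between
populations are meaningful.  The DEAB-treated companion aliquot has the
same population structure with every population's ALDH signal collapsed
to the shared assay-background distribution, which is what the inhibitor
does to the Aldefluor substrate signal.

Three presets encode the study conditions: ``normal_bm`` (no LSC, all
CD34+CD38- cells ALDH-bright), ``aml_cd34pos`` (co-existing CD34+CD38-
HSC and LSC, HSC/LSC ALDH fold 6.9) and ``aml_cd34neg`` (CD34+ cells
under 1% of blasts and all normal; LSC are CD34-, fold 4.3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io_flow import ROLES, EventTable, PanelConfig, SamplePair

TRUTH_LABELS = (
    "lymphocyte",
    "monocyte_granulocyte",
    "HSC",
    "LSC_cd34pos",
    "LSC_cd34neg",
    "progenitor",
    "other",
)

COMPARTMENTS = (
    "lymphocyte",
    "blast_CD34pos_CD38neg",
    "blast_CD34pos_CD38pos",
    "blast_CD34neg",
    "other",
)

ALDH_STATES = ("bright", "low", "background")


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated cell population.

    ``channel_loc``/``channel_scale`` give the log-normal median and
    log-space standard deviation per role.  The ALDH channel is special:
    its location follows ``aldh_state`` and the scenario-level fold (see
    :class:`ScenarioSpec`), so ``channel_loc`` need not contain it.
    ``marker_pos_fraction`` of events draw their MARKER intensity from
    ``marker_pos_loc`` instead of ``channel_loc["MARKER"]`` — marker
    expression on LSC is partial, not uniform.
    """

    name: str
    frequency: float
    channel_loc: Dict[str, float]
    channel_scale: Dict[str, float]
    aldh_state: str
    truth_label: str
    expected_compartment: str
    marker_pos_fraction: float = 0.0
    marker_pos_loc: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency of {self.name} must be in [0, 1]")
        if self.aldh_state not in ALDH_STATES:
            raise ValueError(f"aldh_state must be one of {ALDH_STATES}")
        if self.truth_label not in TRUTH_LABELS:
            raise ValueError(f"truth_label must be one of {TRUTH_LABELS}")
        if self.expected_compartment not in COMPARTMENTS:
            raise ValueError(f"expected_compartment must be one of {COMPARTMENTS}")
        if any(s <= 0 for s in self.channel_scale.values()):
            raise ValueError(f"channel scales of {self.name} must be > 0")
        if not 0.0 <= self.marker_pos_fraction <= 1.0:
            raise ValueError("marker_pos_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """A complete simulation scenario.

    ``aldh_fold`` is the target ratio of the ALDH-bright populations'
    central intensity to the ALDH-low level — the effect size that the
    pipeline's fold-difference estimate should recover.
    ``deab_escape_fraction`` > 0 leaves that fraction of bright-population
    events uninhibited in the DEAB aliquot (incomplete inhibition is seen
    in a minority of real samples; off by default).
    """

    populations: Tuple[PopulationSpec, ...]
    n_events: int = 100_000
    aldh_fold: float = 6.9
    seed: int = 0
    aldh_background_loc: float = 10.0
    aldh_low_loc: float = 10.0
    aldh_scale: float = 0.35
    deab_escape_fraction: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if self.aldh_fold <= 0:
            raise ValueError("aldh_fold must be > 0")
        total = sum(p.frequency for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population frequencies sum to {total}, not 1")

    def frequency_of(self, truth_label: str) -> float:
        return sum(p.frequency for p in self.populations if p.truth_label == truth_label)

    def aldh_loc(self, state: str) -> float:
        if state == "bright":
            return self.aldh_fold * self.aldh_low_loc
        if state == "low":
            return self.aldh_low_loc
        return self.aldh_background_loc


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

# Shared per-channel base parameters (arbitrary units).  Lymphocytes anchor
# the scatter scale: HSC sit at 1.2x/1.35x the lymphocyte FSC/SSC location
# (inside the 1.4/1.7 scatter-low band), LSC and leukemic bulk at 1.6x/2.0x
# (outside it).
_LYMPH = dict(
    channel_loc={"FSC": 100.0, "SSC": 80.0, "CD45": 500.0, "CD34": 4.0,
                 "CD38": 6.0, "MARKER": 4.0},
    channel_scale={"FSC": 0.25, "SSC": 0.25, "CD45": 0.2, "CD34": 0.3,
                   "CD38": 0.3, "MARKER": 0.3, "ALDH": 0.35},
)

_MYELOID_SCALE = {"FSC": 0.25, "SSC": 0.3, "CD45": 0.3, "CD34": 0.3,
                  "CD38": 0.3, "MARKER": 0.3, "ALDH": 0.35}
_BLAST_SCALE = {"FSC": 0.25, "SSC": 0.25, "CD45": 0.3, "CD34": 0.3,
                "CD38": 0.3, "MARKER": 0.3, "ALDH": 0.35}


def _pop(name, freq, loc, scale, state, label, compartment, **kw) -> PopulationSpec:
    return PopulationSpec(
        name=name, frequency=freq, channel_loc=loc, channel_scale=scale,
        aldh_state=state, truth_label=label, expected_compartment=compartment, **kw,
    )


def _lymphocytes(freq: float) -> PopulationSpec:
    return _pop("lymphocytes", freq, _LYMPH["channel_loc"], _LYMPH["channel_scale"],
                "background", "lymphocyte", "lymphocyte")


def _granulocytes(freq: float) -> PopulationSpec:
    loc = {"FSC": 180.0, "SSC": 400.0, "CD45": 150.0, "CD34": 2.5,
           "CD38": 30.0, "MARKER": 2.5}
    return _pop("monocytes_granulocytes", freq, loc, _MYELOID_SCALE,
                "background", "monocyte_granulocyte", "blast_CD34neg")


def _hsc(freq: float) -> PopulationSpec:
    loc = {"FSC": 120.0, "SSC": 108.0, "CD45": 120.0, "CD34": 150.0,
           "CD38": 4.0, "MARKER": 2.5}
    return _pop("HSC", freq, loc, _BLAST_SCALE, "bright", "HSC",
                "blast_CD34pos_CD38neg")


def _progenitors(freq: float) -> PopulationSpec:
    loc = {"FSC": 130.0, "SSC": 120.0, "CD45": 150.0, "CD34": 150.0,
           "CD38": 60.0, "MARKER": 2.5}
    return _pop("progenitors", freq, loc, _BLAST_SCALE, "bright", "progenitor",
                "blast_CD34pos_CD38pos")


def _lsc_cd34pos(freq: float, marker_pos: float) -> PopulationSpec:
    loc = {"FSC": 160.0, "SSC": 160.0, "CD45": 150.0, "CD34": 150.0,
           "CD38": 4.0, "MARKER": 2.5}
    return _pop("LSC_cd34pos", freq, loc, _BLAST_SCALE, "low", "LSC_cd34pos",
                "blast_CD34pos_CD38neg", marker_pos_fraction=marker_pos)


def _lsc_cd34neg(freq: float, marker_pos: float) -> PopulationSpec:
    loc = {"FSC": 160.0, "SSC": 160.0, "CD45": 150.0, "CD34": 2.5,
           "CD38": 30.0, "MARKER": 2.5}
    return _pop("LSC_cd34neg", freq, loc, _BLAST_SCALE, "low", "LSC_cd34neg",
                "blast_CD34neg", marker_pos_fraction=marker_pos)


def _leukemic_progenitors(freq: float, marker_pos: float) -> PopulationSpec:
    # CD34+CD38+ leukemic bulk of CD34-positive AML
    loc = {"FSC": 160.0, "SSC": 160.0, "CD45": 150.0, "CD34": 150.0,
           "CD38": 60.0, "MARKER": 2.5}
    return _pop("leukemic_CD34pos_CD38pos", freq, loc, _BLAST_SCALE, "low",
                "other", "blast_CD34pos_CD38pos", marker_pos_fraction=marker_pos)


#: Fraction of LSC events carrying elevated aberrant-marker intensity.
DEFAULT_MARKER_POS_FRACTION = 0.75

PRESETS = ("normal_bm", "aml_cd34pos", "aml_cd34neg")


def preset_scenario(name: str, overrides: Optional[dict] = None) -> ScenarioSpec:
    """Build one of the three preset scenarios.

    ``overrides`` may set any :class:`ScenarioSpec` field (``n_events``,
    ``seed``, ``aldh_fold``, ``deab_escape_fraction``, ...) and the key
    ``marker_pos_fraction`` to change the marker-positive share of LSC.
    """
    overrides = dict(overrides or {})
    marker_pos = float(overrides.pop("marker_pos_fraction", DEFAULT_MARKER_POS_FRACTION))
    if name == "normal_bm":
        pops = (
            _lymphocytes(0.25),
            _granulocytes(0.72),
            _hsc(0.01),
            _progenitors(0.02),
        )
        fold = 6.9
    elif name == "aml_cd34pos":
        pops = (
            _lymphocytes(0.20),
            _granulocytes(0.09),
            _hsc(0.01),
            _lsc_cd34pos(0.05, marker_pos),
            _progenitors(0.02),
            _leukemic_progenitors(0.55, marker_pos),
            _lsc_cd34neg(0.08, marker_pos),
        )
        fold = 6.9
    elif name == "aml_cd34neg":
        pops = (
            _lymphocytes(0.20),
            _granulocytes(0.08),
            _hsc(0.002),
            _progenitors(0.004),
            _lsc_cd34neg(0.714, marker_pos),
        )
        fold = 4.3
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    spec = ScenarioSpec(populations=pops, aldh_fold=fold, name=name)
    if overrides:
        spec = replace(spec, **overrides)
    return spec


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_population(
    rng: np.random.Generator,
    pop: PopulationSpec,
    n: int,
    scenario: ScenarioSpec,
    deab: bool,
) -> np.ndarray:
    """Draw an (n, 7) block of intensities for one population."""
    out = np.empty((n, len(ROLES)))
    for j, role in enumerate(ROLES):
        if role == "ALDH":
            continue
        loc = pop.channel_loc[role]
        scale = pop.channel_scale[role]
        out[:, j] = rng.lognormal(np.log(loc), scale, size=n)
    # MARKER mixture: a fraction of events carries elevated intensity
    if pop.marker_pos_fraction > 0:
        hot = rng.random(n) < pop.marker_pos_fraction
        j = ROLES.index("MARKER")
        out[hot, j] = rng.lognormal(
            np.log(pop.marker_pos_loc), pop.channel_scale["MARKER"], size=int(hot.sum())
        )
    # ALDH: state-dependent in the native aliquot, background under DEAB
    j = ROLES.index("ALDH")
    scale = pop.channel_scale.get("ALDH", scenario.aldh_scale)
    if deab:
        vals = rng.lognormal(np.log(scenario.aldh_background_loc), scale, size=n)
        if pop.aldh_state == "bright" and scenario.deab_escape_fraction > 0:
            escape = rng.random(n) < scenario.deab_escape_fraction
            vals[escape] = rng.lognormal(
                np.log(scenario.aldh_loc("bright")), scale, size=int(escape.sum())
            )
        out[:, j] = vals
    else:
        out[:, j] = rng.lognormal(np.log(scenario.aldh_loc(pop.aldh_state)), scale, size=n)
    return out


def _simulate_table(
    rng: np.random.Generator,
    scenario: ScenarioSpec,
    treatment: str,
    source_id: str,
    counts: np.ndarray,
    perm: np.ndarray,
) -> Tuple[EventTable, pd.DataFrame]:
    blocks, truth_rows = [], []
    for pop, n in zip(scenario.populations, counts):
        blocks.append(_draw_population(rng, pop, int(n), scenario, treatment == "DEAB"))
        truth_rows.append(
            pd.DataFrame(
                {
                    "population": pop.name,
                    "truth_label": pop.truth_label,
                    "expected_compartment": pop.expected_compartment,
                    "aldh_state": pop.aldh_state,
                },
                index=range(int(n)),
            )
        )
    values = np.vstack(blocks)
    truth = pd.concat(truth_rows, ignore_index=True)
    values = values[perm]
    truth = truth.iloc[perm].reset_index(drop=True)
    table = EventTable(values=values, source_id=source_id, treatment=treatment)
    return table, truth


def simulate_sample_pair(
    scenario: ScenarioSpec, source_id: Optional[str] = None
) -> Tuple[SamplePair, pd.DataFrame]:
    """Simulate a native/DEAB aliquot pair plus per-event truth labels.

    Returns the pair and a DataFrame of per-event ground truth with columns
    ``population``, ``truth_label``, ``expected_compartment`` and
    ``aldh_state``.  Both aliquots share the same population counts and
    event order (they model one specimen split in two), so the truth table
    is aligned with the native *and* the DEAB aliquot; intensities are
    independent draws.  A fixed ``scenario.seed`` gives bit-identical
    output.
    """
    if source_id is None:
        source_id = f"sim-{scenario.name}-seed{scenario.seed}"
    rng = np.random.default_rng(scenario.seed)
    freqs = np.array([p.frequency for p in scenario.populations])
    counts = rng.multinomial(scenario.n_events, freqs)
    perm = rng.permutation(scenario.n_events)
    native, truth = _simulate_table(rng, scenario, "native", source_id, counts, perm)
    deab, _ = _simulate_table(rng, scenario, "DEAB", source_id, counts, perm)
    return SamplePair(native=native, deab=deab), truth


def simulation_panel(marker_name: str = "marker") -> PanelConfig:
    """Identity panel (role names double as channel names) for simulated data."""
    return PanelConfig(channel_roles={r: r for r in ROLES}, marker_name=marker_name)
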