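"""Shared fixtures: simulated sample pairs with ground truth.

The three preset scenarios are simulated once per session at n=100k and
analysed with default configuration; most behavioural tests read from
these instead of re-simulating.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pytest
from hypothesis import settings

import aldhgate as ag

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_events(treatment: str = "native", **columns) -> ag.EventTable:
    """Build a small EventTable from per-role value lists; unspecified
    roles default to 1.0."""
    n = max((len(v) for v in columns.values()), default=0)
    values = np.ones((n, len(ag.ROLES)))
    for role, vals in columns.items():
        values[:, ag.ROLES.index(role)] = vals
    return ag.EventTable(values=values, treatment=treatment)


@pytest.fixture(scope="session")
def cfg() -> ag.ClassifierConfig:
    return ag.ClassifierConfig()


class AnalysedPreset:
    """A simulated preset with its truth table and pipeline result."""

    def __init__(self, name: str, seed: int, cfg: ag.ClassifierConfig, **overrides):
        self.scenario = ag.preset_scenario(name, {"n_events": 100_000, "seed": seed, **overrides})
        self.pair, self.truth = ag.simulate_sample_pair(self.scenario)
        self.result = ag.analyze_sample_pair(self.pair, cfg)

    @property
    def labels(self) -> ag.GateLabels:
        return self.result.labels

    def truth_mask(self, *labels: str) -> np.ndarray:
        return self.truth["truth_label"].isin(labels).to_numpy()


@pytest.fixture(scope="session")
def normal_bm(cfg) -> AnalysedPreset:
    return AnalysedPreset("normal_bm", seed=11, cfg=cfg)


@pytest.fixture(scope="session")
def aml_cd34pos(cfg) -> AnalysedPreset:
    return AnalysedPreset("aml_cd34pos", seed=12, cfg=cfg)


@pytest.fixture(scope="session")
def aml_cd34neg(cfg) -> AnalysedPreset:
    return AnalysedPreset("aml_cd34neg", seed=13, cfg=cfg)


@pytest.fixture(scope="session")
def all_presets(normal_bm, aml_cd34pos, aml_cd34neg) -> Dict[str, AnalysedPreset]:
    return {"normal_bm": normal_bm, "aml_cd34pos": aml_cd34pos, "aml_cd34neg": aml_cd34neg}
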