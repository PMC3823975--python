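"""Numeric thresholds of the HSC/LSC discrimination scheme.

All decision rules of the pipeline are parameterised here so that a single
config object (or YAML file) fully determines an analysis.  Defaults follow
the published scheme where it states a number (1% CD34 cutoff, 1.4/1.7
lymphocyte-referenced scatter bounds, 5% sample-level ALDH positivity,
25-cell reporting floor) and otherwise use documented, data-driven
conventions (quantile-based antigen thresholds against an internal
lymphocyte reference).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import yaml


@dataclass(frozen=True)
class ClassifierConfig:
    """All tunable thresholds of the gating and classification scheme.

    Attributes
    ----------
    cd34_pos_cutoff:
        Percentage of CD34+ cells within the blast gate below which a sample
        is called CD34-negative AML (strict ``<``, default 1.0).
    fsc_ratio_max, ssc_ratio_max:
        Upper bounds of the scatter-low (HSC-like) band, expressed as the
        population median over the lymphocyte median.  Values above either
        bound classify as scatter-high (LSC-like).
    aldh_pos_sample_cutoff:
        Sample-level ALDH positivity threshold in percent (strict ``>`` for
        a positive call).
    deab_quantile:
        Quantile of the DEAB-treated aliquot's ALDH intensities used as the
        bright/low threshold.
    min_reportable_events:
        Reporting floor; fractions whose numerator has fewer events carry a
        low-count flag (values are flagged, never suppressed).
    pearce_rare_max_pct, pearce_negative_max_pct, pearce_ssc_confinement:
        Operational knobs of the rare/numerous/negative ALDH-pattern call.
        These make a qualitative visual classification computable and are
        not published numbers.
    antigen_threshold_quantile:
        Quantile of the lymphocyte reference used as the positivity
        threshold for CD34, CD38 and the aberrant marker.
    cd45dim_band:
        Blast gate: CD45 within ``band * lymphocyte CD45 median``.
    lymph_cd45_quantile, lymph_ssc_quantile:
        Whole-sample quantiles defining the lymphocyte gate
        (CD45 above the first, SSC below the second).
    mfi_statistic:
        "arithmetic" (default) or "geometric" mean for MFI computations.
    """

    cd34_pos_cutoff: float = 1.0
    fsc_ratio_max: float = 1.4
    ssc_ratio_max: float = 1.7
    aldh_pos_sample_cutoff: float = 5.0
    deab_quantile: float = 0.99
    min_reportable_events: int = 25
    pearce_rare_max_pct: float = 5.0
    pearce_negative_max_pct: float = 0.1
    pearce_ssc_confinement: float = 0.8
    antigen_threshold_quantile: float = 0.995
    cd45dim_band: Tuple[float, float] = (0.05, 0.6)
    lymph_cd45_quantile: float = 0.75
    lymph_ssc_quantile: float = 0.35
    mfi_statistic: str = "arithmetic"

    def __post_init__(self) -> None:
        if not 0 < self.cd34_pos_cutoff < 100:
            raise ValueError("cd34_pos_cutoff must lie in (0, 100)")
        for name in (
            "fsc_ratio_max",
            "ssc_ratio_max",
            "aldh_pos_sample_cutoff",
            "pearce_rare_max_pct",
            "pearce_negative_max_pct",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.deab_quantile < 1:
            raise ValueError("deab_quantile must lie in (0, 1)")
        if not 0 < self.antigen_threshold_quantile < 1:
            raise ValueError("antigen_threshold_quantile must lie in (0, 1)")
        if not 0 < self.pearce_ssc_confinement <= 1:
            raise ValueError("pearce_ssc_confinement must lie in (0, 1]")
        if self.min_reportable_events < 0:
            raise ValueError("min_reportable_events must be >= 0")
        lo, hi = self.cd45dim_band
        if not 0 <= lo < hi:
            raise ValueError("cd45dim_band must satisfy 0 <= low < high")
        if self.mfi_statistic not in ("arithmetic", "geometric"):
            raise ValueError("mfi_statistic must be 'arithmetic' or 'geometric'")

    def replace(self, **kwargs) -> "ClassifierConfig":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cd45dim_band"] = list(self.cd45dim_band)
        return d


def load_config(path: str | Path) -> ClassifierConfig:
    """Read a :class:`ClassifierConfig` from a YAML file.

    Unknown keys raise, so typos in a config file never silently fall back
    to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ClassifierConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "cd45dim_band" in raw:
        raw["cd45dim_band"] = tuple(raw["cd45dim_band"])
    return ClassifierConfig(**raw)


def save_config(cfg: ClassifierConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
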