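"""Lymphocyte-referenced light-scatter profile of a cell population.

Normal HSC sit at 1-1.4 times the lymphocyte forward scatter and 1-1.7
times the lymphocyte side scatter (scatter-low); LSC exceed at least one
of those bounds (scatter-high).  The population statistic is the median —
robust at the tens-of-events sizes stem-cell gates often have.  Values at
exactly the bound classify as low: "high" is defined strictly as *more
than* the bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassifierConfig
from .io_flow import EventTable


class UndefinedRatioError(ValueError):
    """Raised when a scatter ratio cannot be formed (empty subset/reference)."""


@dataclass(frozen=True)
class ScatterRatios:
    """Median FSC and SSC of a population over the lymphocyte medians."""

    fsc_ratio: float
    ssc_ratio: float

    def __post_init__(self) -> None:
        for name, v in (("fsc_ratio", self.fsc_ratio), ("ssc_ratio", self.ssc_ratio)):
            if not np.isfinite(v) or v <= 0:
                raise UndefinedRatioError(f"{name} must be finite and > 0, got {v}")


def scatter_ratios(
    events: EventTable, subset: np.ndarray, lymphocytes: np.ndarray
) -> ScatterRatios:
    """Median-over-median FSC and SSC ratios of ``subset`` vs lymphocytes."""
    subset = np.asarray(subset)
    lymphocytes = np.asarray(lymphocytes)
    if subset.size == 0 or lymphocytes.size == 0:
        raise UndefinedRatioError("scatter ratios need nonempty subset and reference")
    fsc = events.column("FSC")
    ssc = events.column("SSC")
    return ScatterRatios(
        fsc_ratio=float(np.median(fsc[subset]) / np.median(fsc[lymphocytes])),
        ssc_ratio=float(np.median(ssc[subset]) / np.median(ssc[lymphocytes])),
    )


def classify_scatter(r: ScatterRatios, cfg: ClassifierConfig) -> str:
    """``"low"`` iff both ratios are within their bounds, else ``"high"``."""
    if r.fsc_ratio <= cfg.fsc_ratio_max and r.ssc_ratio <= cfg.ssc_ratio_max:
        return "low"
    return "high"
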