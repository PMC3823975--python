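"""ALDH activity: DEAB-derived threshold, bright/low split, standardized MFI.

The DEAB-treated aliquot defines the Aldefluor assay background: the
bright/low threshold is a high quantile (default 0.99) of the DEAB
events' ALDH intensities, taken over the same compartment that is being
split (with a whole-sample fallback when that compartment is too small).
A quantile of the inhibited aliquot is preferred over valley-finding on
the native bimodal histogram because it needs no modality assumption and
stays stable at low event counts — the control aliquot is the assay's own
definition of "no ALDH activity".

Mean fluorescence intensities are standardized by dividing by the
lymphocyte ALDH MFI of the same sample: lymphocytes are ALDH-negative, so
their MFI is the per-sample background level, which cancels instrument
and staining differences between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ClassifierConfig
from .gating import FractionReport, ReferencePopulationError, empirical_quantile
from .io_flow import EventTable


@dataclass(frozen=True)
class AldhThreshold:
    """Bright/low ALDH intensity threshold derived from the DEAB aliquot."""

    value: float
    quantile_used: float
    n_reference_events: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold must be >= 0")
        if not 0 < self.quantile_used < 1:
            raise ValueError("quantile_used must lie in (0, 1)")


@dataclass(frozen=True)
class StandardizedMfi:
    """ALDH MFI of a population divided by the lymphocyte ALDH MFI."""

    raw_mfi: float
    lymph_mfi: float
    ratio: float


def deab_threshold(
    deab: EventTable, scope: np.ndarray, cfg: ClassifierConfig
) -> AldhThreshold:
    """The ``deab_quantile`` order statistic of scoped DEAB ALDH intensities."""
    scope = np.asarray(scope)
    if scope.size == 0:
        raise ReferencePopulationError("empty DEAB scope; cannot derive threshold")
    if deab.treatment != "DEAB":
        raise ValueError("threshold must be derived from the DEAB-treated aliquot")
    vals = deab.column("ALDH")[scope]
    return AldhThreshold(
        value=empirical_quantile(vals, cfg.deab_quantile),
        quantile_used=cfg.deab_quantile,
        n_reference_events=int(scope.size),
    )


def split_aldh_compartments(
    native: EventTable, subset: np.ndarray, thr: AldhThreshold
) -> np.ndarray:
    """Boolean array aligned with ``subset``: True = bright (ALDH > threshold)."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("cannot split an empty subset")
    return native.column("ALDH")[subset] > thr.value


def _mfi(values: np.ndarray, statistic: str) -> float:
    if statistic == "geometric":
        return float(np.exp(np.mean(np.log(np.maximum(values, np.finfo(float).tiny)))))
    return float(np.mean(values))


def standardized_mfi(
    native: EventTable,
    subset: np.ndarray,
    lymphocytes: np.ndarray,
    statistic: str = "arithmetic",
) -> StandardizedMfi:
    """ALDH MFI of ``subset`` over the lymphocyte ALDH MFI (same sample)."""
    subset = np.asarray(subset)
    lymphocytes = np.asarray(lymphocytes)
    if subset.size == 0 or lymphocytes.size == 0:
        raise ReferencePopulationError("MFI needs nonempty subset and lymphocytes")
    aldh = native.column("ALDH")
    lymph_mfi = _mfi(aldh[lymphocytes], statistic)
    if lymph_mfi <= 0:
        raise ReferencePopulationError("lymphocyte ALDH MFI is zero")
    raw = _mfi(aldh[subset], statistic)
    return StandardizedMfi(raw_mfi=raw, lymph_mfi=lymph_mfi, ratio=raw / lymph_mfi)


def fold_difference(hsc: StandardizedMfi, lsc: StandardizedMfi) -> float:
    """HSC-over-LSC ratio of standardized ALDH MFIs.

    Because both MFIs are standardized against the same lymphocyte MFI,
    this equals the raw MFI ratio of the two subsets.
    """
    if lsc.ratio <= 0:
        raise ValueError("LSC standardized MFI must be > 0")
    return hsc.ratio / lsc.ratio


def aldh_positive_fraction(
    native: EventTable,
    scope: np.ndarray,
    thr: AldhThreshold,
    cfg: ClassifierConfig,
) -> FractionReport:
    """Percentage of scoped native events with ALDH above the threshold."""
    scope = np.asarray(scope)
    vals = native.column("ALDH")[scope]
    return FractionReport.from_counts(int((vals > thr.value).sum()), scope.size, cfg)
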