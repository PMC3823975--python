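"""Compartment gating: lymphocytes, CD45dim blasts, CD34/CD38 subsets.

The published scheme was gated manually; here every threshold is a
data-driven quantile of a designated reference so that the same rules run
unattended on any sample.  Lymphocytes act as the internal negative
reference for CD34, CD38 and the aberrant marker (isotype-control
normalisation is not available post hoc, and lymphocytes are negative for
all three).  Ties exactly at a threshold count as negative — positivity is
strict ``>`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
from scipy.stats import norm

from .config import ClassifierConfig
from .io_flow import EventTable

COMPARTMENT_NAMES = (
    "lymphocyte",
    "blast_CD34pos_CD38neg",
    "blast_CD34pos_CD38pos",
    "blast_CD34neg",
    "other",
)

BLAST_COMPARTMENTS = (
    "blast_CD34pos_CD38neg",
    "blast_CD34pos_CD38pos",
    "blast_CD34neg",
)


class ReferencePopulationError(ValueError):
    """Raised when a reference gate (e.g. lymphocytes) comes out empty."""


def empirical_quantile(values: np.ndarray, q: float) -> float:
    """Order-statistic quantile: the smallest value v with #{x <= v} >= q*n.

    Used for every data-driven threshold in the pipeline so thresholds are
    always observed intensities (robust at low event counts, monotone in q).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("cannot take a quantile of an empty set")
    if not 0 < q <= 1:
        raise ValueError("quantile must lie in (0, 1]")
    k = min(n - 1, max(0, int(np.ceil(q * n)) - 1))
    return float(np.partition(values, k)[k])


@dataclass
class FractionReport:
    """A percentage with its counts and a low-count flag.

    ``fraction`` is in percent, or ``None`` when the denominator is empty
    (undefined fraction).  ``low_count_flag`` is set when the numerator is
    below the reporting floor; values are flagged, never suppressed.
    """

    fraction: Optional[float]
    numerator: int
    denominator: int
    low_count_flag: bool

    @classmethod
    def from_counts(
        cls, numerator: int, denominator: int, cfg: ClassifierConfig
    ) -> "FractionReport":
        frac = 100.0 * numerator / denominator if denominator > 0 else None
        return cls(
            fraction=frac,
            numerator=int(numerator),
            denominator=int(denominator),
            low_count_flag=bool(numerator < cfg.min_reportable_events),
        )


@dataclass
class GateLabels:
    """Per-event compartment assignment plus the thresholds that made it.

    ``compartment`` is a length-``n_events`` array over
    :data:`COMPARTMENT_NAMES`; the labels are mutually exclusive and
    exhaustive.  Index arrays for the lymphocyte and blast gates and the
    antigen thresholds used are kept for traceability.
    """

    compartment: np.ndarray
    lymphocytes: np.ndarray
    blasts: np.ndarray
    thresholds: Dict[str, float] = field(default_factory=dict)

    def indices(self, name: str) -> np.ndarray:
        """Event indices of one compartment."""
        if name not in COMPARTMENT_NAMES:
            raise KeyError(f"unknown compartment {name!r}")
        return np.flatnonzero(self.compartment == name)

    def counts(self) -> Dict[str, int]:
        return {c: int((self.compartment == c).sum()) for c in COMPARTMENT_NAMES}


def gate_lymphocytes(events: EventTable, cfg: ClassifierConfig) -> np.ndarray:
    """Index set of the lymphocyte gate: CD45-bright AND SSC-low.

    Thresholds are whole-sample quantiles (CD45 above the
    ``lymph_cd45_quantile``, SSC below the ``lymph_ssc_quantile``).
    Raises :class:`ReferencePopulationError` when the gate is empty, since
    every downstream normalisation depends on it.
    """
    if events.n_events == 0:
        raise ReferencePopulationError("no events to gate lymphocytes from")
    cd45 = events.column("CD45")
    ssc = events.column("SSC")
    cd45_thr = empirical_quantile(cd45, cfg.lymph_cd45_quantile)
    ssc_thr = empirical_quantile(ssc, cfg.lymph_ssc_quantile)
    mask = (cd45 > cd45_thr) & (ssc < ssc_thr)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ReferencePopulationError(
            "lymphocyte gate is empty; cannot establish the internal reference"
        )
    return idx


def gate_blasts(
    events: EventTable, lymphocytes: np.ndarray, cfg: ClassifierConfig
) -> np.ndarray:
    """Index set of the CD45dim blast gate.

    Events whose CD45 lies within ``cd45dim_band`` times the lymphocyte
    CD45 median and that are not in the lymphocyte gate.  May be empty.
    """
    if lymphocytes.size == 0:
        raise ReferencePopulationError("blast gating requires a lymphocyte gate")
    cd45 = events.column("CD45")
    med = float(np.median(cd45[lymphocytes]))
    lo, hi = cfg.cd45dim_band
    mask = (cd45 >= lo * med) & (cd45 <= hi * med)
    mask[lymphocytes] = False
    return np.flatnonzero(mask)


def antigen_threshold(
    events: EventTable, reference: np.ndarray, role: str, cfg: ClassifierConfig
) -> float:
    """Positivity threshold for an antigen from the negative reference.

    The ``antigen_threshold_quantile`` of a log-normal fitted to the
    reference intensities by median and MAD.  The robust fit matters: the
    automated lymphocyte gate can carry a few percent of antigen-positive
    contaminants, which would dominate a raw 99.5th-percentile threshold
    but leave median/MAD untouched.
    """
    if reference.size == 0:
        raise ReferencePopulationError(f"empty reference for {role} threshold")
    vals = events.column(role)[reference]
    logs = np.log(np.maximum(vals, np.finfo(float).tiny))
    med = float(np.median(logs))
    sigma = 1.4826 * float(np.median(np.abs(logs - med)))
    z = norm.ppf(cfg.antigen_threshold_quantile)
    return float(np.exp(med + z * sigma))


def partition_stem_compartments(
    events: EventTable,
    blasts: np.ndarray,
    lymphocytes: np.ndarray,
    cfg: ClassifierConfig,
) -> GateLabels:
    """Partition all events into the five compartments.

    Within the blast gate, CD34 and (within CD34+) CD38 positivity are
    decided against lymphocyte-referenced thresholds.  Events in neither
    the lymphocyte nor the blast gate are labelled ``other``.
    """
    n = events.n_events
    compartment = np.full(n, "other", dtype=object)
    compartment[lymphocytes] = "lymphocyte"
    cd34_thr = antigen_threshold(events, lymphocytes, "CD34", cfg)
    cd38_thr = antigen_threshold(events, lymphocytes, "CD38", cfg)
    cd34 = events.column("CD34")[blasts]
    cd38 = events.column("CD38")[blasts]
    lab = np.where(
        cd34 > cd34_thr,
        np.where(cd38 > cd38_thr, "blast_CD34pos_CD38pos", "blast_CD34pos_CD38neg"),
        "blast_CD34neg",
    )
    compartment[blasts] = lab
    return GateLabels(
        compartment=compartment.astype(str),
        lymphocytes=np.asarray(lymphocytes),
        blasts=np.asarray(blasts),
        thresholds={"CD34": cd34_thr, "CD38": cd38_thr},
    )


def gate_sample(events: EventTable, cfg: ClassifierConfig) -> GateLabels:
    """Run the full gating chain (lymphocytes -> blasts -> compartments)."""
    lymphocytes = gate_lymphocytes(events, cfg)
    blasts = gate_blasts(events, lymphocytes, cfg)
    return partition_stem_compartments(events, blasts, lymphocytes, cfg)


def marker_positive_fraction(
    events: EventTable,
    subset: np.ndarray,
    threshold: float,
    cfg: ClassifierConfig,
) -> FractionReport:
    """Fraction of ``subset`` events with MARKER intensity strictly above
    ``threshold`` (typically from :func:`antigen_threshold` on lymphocytes).

    An empty subset yields an undefined fraction (``fraction=None``).
    """
    subset = np.asarray(subset)
    marker = events.column("MARKER")[subset]
    return FractionReport.from_counts(int((marker > threshold).sum()), subset.size, cfg)
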