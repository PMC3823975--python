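"""Per-sample summaries and cohort tables with median rows.

A :class:`SampleSummary` is one row of the cohort view: compartment
frequencies (CD34+CD38- cells as a percentage of the ALDH-bright and
ALDH-low compartments), marker-positive percentages within those subsets,
lymphocyte-standardized ALDH MFIs and their HSC/LSC fold, the sample-level
ALDH-positive percentage, and the categorical classifications.

Cohort medians follow the convention that reproduces published cohort
tables: missing entries are excluded (never treated as zero), low-count
values enter at face value with the count carried as a flag, and the
median of an even count is the midpoint of the two central values.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClassifierConfig
from .gating import FractionReport, GateLabels

#: Numeric SampleSummary columns that enter the cohort median row.
NUMERIC_COLUMNS = (
    "pct_cd34cd38neg_in_aldh_bright",
    "pct_cd34cd38neg_in_aldh_low",
    "marker_pos_pct_bright",
    "marker_pos_pct_low",
    "hsc_std_mfi",
    "lsc_std_mfi",
    "fold",
    "aldh_pos_pct_total",
)


@dataclass
class SampleSummary:
    """One analysed sample condensed to a cohort-table row."""

    sample_id: str
    marker_name: str
    cd34_status: str
    pct_cd34cd38neg_in_aldh_bright: Optional[float]
    pct_cd34cd38neg_in_aldh_low: Optional[float]
    marker_pos_pct_bright: Optional[float]
    marker_pos_pct_low: Optional[float]
    hsc_std_mfi: Optional[float]
    lsc_std_mfi: Optional[float]
    fold: Optional[float]
    aldh_pos_pct_total: Optional[float]
    cheung_class: str
    pearce_pattern: str
    low_count_flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in NUMERIC_COLUMNS:
            v = getattr(self, name)
            if v is None:
                continue
            if name.startswith(("pct_", "marker_", "aldh_")) and not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if (self.fold is None) != (
            self.hsc_std_mfi is None or self.lsc_std_mfi is None
        ):
            raise ValueError("fold must be present iff both MFIs are defined")


def column_median(values: Sequence[Optional[float]]) -> Optional[float]:
    """Median over non-missing values; ``None`` when all are missing.

    Missing means ``None`` or NaN.  Even counts take the midpoint of the
    two central values.
    """
    clean = [float(v) for v in values
             if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not clean:
        return None
    return float(np.median(clean))


@dataclass
class CohortTable:
    """Stacked sample summaries plus a per-column median row."""

    rows: List[SampleSummary]
    medians: Dict[str, Optional[float]]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            d = asdict(r)
            d["low_count_flags"] = ";".join(k for k, v in r.low_count_flags.items() if v)
            recs.append(d)
        frame = pd.DataFrame(recs)
        med = {c: self.medians.get(c) for c in frame.columns}
        med["sample_id"] = "Median"
        frame = pd.concat([frame, pd.DataFrame([med])], ignore_index=True)
        return frame


def build_cohort_table(rows: Sequence[SampleSummary]) -> CohortTable:
    """Stack summaries (input order preserved) and append column medians."""
    rows = list(rows)
    if not rows:
        raise ValueError("cohort table needs at least one sample")
    medians = {
        col: column_median([getattr(r, col) for r in rows]) for col in NUMERIC_COLUMNS
    }
    return CohortTable(rows=rows, medians=medians)


# ---------------------------------------------------------------------------
# Assembling a summary from pipeline stage outputs
# ---------------------------------------------------------------------------

def summarize_sample(
    *,
    sample_id: str,
    marker_name: str,
    cd34_status: str,
    labels: GateLabels,
    bright: np.ndarray,
    marker_positive: np.ndarray,
    hsc_std_mfi: Optional[float],
    lsc_std_mfi: Optional[float],
    aldh_pos_total: FractionReport,
    cheung_class: str,
    pearce_pattern: str,
    cfg: ClassifierConfig,
) -> SampleSummary:
    """Condense stage outputs into a :class:`SampleSummary`.

    Compartment percentages use the ALDH compartment (bright or low, over
    the blast gate) as the denominator; marker percentages are taken
    within the CD34+CD38- slice of each ALDH compartment.  Undefined
    fractions (empty denominators) become missing, and every fraction's
    low-count status lands in ``low_count_flags``.
    """
    for name, value in (("gating", labels), ("aldh_split", bright),
                        ("marker", marker_positive)):
        if value is None:
            raise ValueError(f"missing stage output: {name}")
    bright = np.asarray(bright, dtype=bool)
    marker_positive = np.asarray(marker_positive, dtype=bool)

    in_blast = np.isin(
        labels.compartment,
        ("blast_CD34pos_CD38neg", "blast_CD34pos_CD38pos", "blast_CD34neg"),
    )
    stem = labels.compartment == "blast_CD34pos_CD38neg"
    flags: Dict[str, bool] = {}

    def frac(numer_mask: np.ndarray, denom_mask: np.ndarray, key: str):
        rep = FractionReport.from_counts(
            int((numer_mask & denom_mask).sum()), int(denom_mask.sum()), cfg
        )
        flags[key] = rep.low_count_flag
        return rep.fraction

    pct_bright = frac(stem, in_blast & bright, "pct_cd34cd38neg_in_aldh_bright")
    pct_low = frac(stem, in_blast & ~bright, "pct_cd34cd38neg_in_aldh_low")
    mk_bright = frac(marker_positive, stem & bright, "marker_pos_pct_bright")
    mk_low = frac(marker_positive, stem & ~bright, "marker_pos_pct_low")
    flags["aldh_pos_pct_total"] = aldh_pos_total.low_count_flag

    fold = None
    if hsc_std_mfi is not None and lsc_std_mfi is not None and lsc_std_mfi > 0:
        fold = hsc_std_mfi / lsc_std_mfi
    return SampleSummary(
        sample_id=sample_id,
        marker_name=marker_name,
        cd34_status=cd34_status,
        pct_cd34cd38neg_in_aldh_bright=pct_bright,
        pct_cd34cd38neg_in_aldh_low=pct_low,
        marker_pos_pct_bright=mk_bright,
        marker_pos_pct_low=mk_low,
        hsc_std_mfi=hsc_std_mfi,
        lsc_std_mfi=lsc_std_mfi,
        fold=fold,
        aldh_pos_pct_total=aldh_pos_total.fraction,
        cheung_class=cheung_class,
        pearce_pattern=pearce_pattern,
        low_count_flags=flags,
    )


# ---------------------------------------------------------------------------
# Serialization (JSON per sample, TSV per cohort)
# ---------------------------------------------------------------------------

def write_sample_summary(summary: SampleSummary, path: str | Path) -> None:
    """Write a summary as structured JSON text; missing fields are null."""
    doc = asdict(summary)
    for key in NUMERIC_COLUMNS:
        if doc[key] is not None:
            doc[key] = float(f"{doc[key]:.6g}")
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sample_summary(path: str | Path) -> SampleSummary:
    with open(path) as fh:
        doc = json.load(fh)
    return SampleSummary(**doc)


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Published reference cohorts (transcribed cohort tables shipped as fixtures)
# ---------------------------------------------------------------------------

def load_reference_cohort(which: str) -> pd.DataFrame:
    """Load the transcribed published cohort table for ``"cd34pos"`` or
    ``"cd34neg"`` AML.

    Columns: ``sample_id``, ``marker``, then per ALDH compartment the
    CD34+CD38- percentage, its event count where under the reporting floor
    (else missing), the marker-positive percentage and its low count.
    Missing entries are NaN.
    """
    if which not in ("cd34pos", "cd34neg"):
        raise ValueError("which must be 'cd34pos' or 'cd34neg'")
    ref = resources.files("aldhgate.data").joinpath(f"{which}_cohort.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
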