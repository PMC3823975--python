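"""Sample-level and per-event classification rules.

* CD34-positive vs CD34-negative AML: a sample is CD34-negative when its
  CD34+ cells are (strictly) under 1% of the blast compartment.
* Per-event HSC/LSC calls on stem-cell candidates: ALDH has priority;
  aberrant-marker and scatter evidence is recorded but never silently
  overrides it — conflicting evidence (ALDH-bright yet marker-positive)
  yields ``ambiguous`` so QC problems surface instead of being resolved.
* Cheung sample-level ALDH positivity: more than 5% DEAB-defined ALDH+
  cells in the total sample.
* Pearce rare/numerous/negative pattern: an operational rendering of a
  visual classification — the negative floor (0.1%), rare ceiling (5%)
  and SSC-confinement fraction (80%) are this package's own knobs, all
  config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .aldh import AldhThreshold
from .config import ClassifierConfig
from .gating import GateLabels
from .io_flow import EventTable

CD34_POSITIVE = "CD34_positive"
CD34_NEGATIVE = "CD34_negative"

STEM_CALLS = ("HSC", "LSC", "ambiguous", "not_stem")


class ClassificationError(ValueError):
    pass


def classify_cd34_status(labels: GateLabels, cfg: ClassifierConfig) -> str:
    """CD34-negative iff CD34+ cells are under ``cd34_pos_cutoff`` percent
    of the blast compartment (strict ``<``; exactly at the cutoff is
    CD34-positive)."""
    counts = labels.counts()
    n_blasts = sum(counts[c] for c in
                   ("blast_CD34pos_CD38neg", "blast_CD34pos_CD38pos", "blast_CD34neg"))
    if n_blasts == 0:
        raise ClassificationError("blast compartment is empty; no CD34 status")
    n_cd34pos = counts["blast_CD34pos_CD38neg"] + counts["blast_CD34pos_CD38pos"]
    pct = 100.0 * n_cd34pos / n_blasts
    return CD34_NEGATIVE if pct < cfg.cd34_pos_cutoff else CD34_POSITIVE


@dataclass
class StemCellCall:
    """Per-event HSC/LSC calls with the evidence behind them.

    ``call`` covers all events (``not_stem`` outside the stem-candidate
    gates).  ``evidence`` holds per-event boolean arrays ``aldh_bright``
    and ``marker_positive`` (meaningful on candidates) and optionally the
    population-level scatter class per compartment.
    """

    call: np.ndarray
    evidence: Dict[str, np.ndarray]
    scatter_class: Dict[str, str]

    def indices(self, name: str) -> np.ndarray:
        if name not in STEM_CALLS:
            raise KeyError(f"unknown call {name!r}")
        return np.flatnonzero(self.call == name)


def call_stem_cells(
    labels: GateLabels,
    bright: np.ndarray,
    marker_positive: np.ndarray,
    status: str,
    scatter_class: Optional[Dict[str, str]] = None,
) -> StemCellCall:
    """Call HSC / LSC / ambiguous on stem-candidate events.

    Candidates are the CD34+CD38- gate and, in CD34-negative AML, also the
    CD34- blasts.  Rules (ALDH first):

    * CD34+CD38-: bright & marker- -> HSC; not bright -> LSC;
      bright & marker+ -> ambiguous.
    * CD34- blasts (CD34-negative samples only): not bright -> LSC;
      bright -> ambiguous (normal progenitor vs LSC is undecidable
      without molecular data).

    ``bright`` and ``marker_positive`` are full-length boolean arrays.
    """
    bright = np.asarray(bright, dtype=bool)
    marker_positive = np.asarray(marker_positive, dtype=bool)
    n = labels.compartment.size
    if bright.size != n or marker_positive.size != n:
        raise ClassificationError(
            "bright/marker arrays must cover all events (missing ALDH split?)"
        )
    call = np.full(n, "not_stem", dtype=object)

    stem = labels.compartment == "blast_CD34pos_CD38neg"
    call[stem & ~bright] = "LSC"
    call[stem & bright & ~marker_positive] = "HSC"
    call[stem & bright & marker_positive] = "ambiguous"

    if status == CD34_NEGATIVE:
        cd34neg = labels.compartment == "blast_CD34neg"
        call[cd34neg & ~bright] = "LSC"
        call[cd34neg & bright] = "ambiguous"

    return StemCellCall(
        call=call.astype(str),
        evidence={"aldh_bright": bright, "marker_positive": marker_positive},
        scatter_class=dict(scatter_class or {}),
    )


def cheung_classification(aldh_pos_pct: float, cfg: ClassifierConfig) -> str:
    """Sample-level ALDH class: positive iff the DEAB-defined ALDH+ share of
    the total sample strictly exceeds ``aldh_pos_sample_cutoff`` percent."""
    return "positive" if aldh_pos_pct > cfg.aldh_pos_sample_cutoff else "negative"


def pearce_pattern(
    native: EventTable,
    thr: AldhThreshold,
    lymphocytes: np.ndarray,
    cfg: ClassifierConfig,
) -> str:
    """Rare / numerous / negative pattern of the ALDH+ compartment.

    negative: ALDH+ share of the sample under ``pearce_negative_max_pct``;
    rare: share under ``pearce_rare_max_pct`` AND at least
    ``pearce_ssc_confinement`` of ALDH+ events SSC-confined (SSC at most
    ``ssc_ratio_max`` times the lymphocyte SSC median); numerous otherwise.
    """
    lymphocytes = np.asarray(lymphocytes)
    if lymphocytes.size == 0:
        raise ClassificationError("Pearce pattern needs a lymphocyte reference")
    aldh = native.column("ALDH")
    pos = aldh > thr.value
    pct = 100.0 * pos.sum() / native.n_events if native.n_events else 0.0
    if pct < cfg.pearce_negative_max_pct:
        return "negative"
    if pct < cfg.pearce_rare_max_pct:
        ssc = native.column("SSC")
        bound = cfg.ssc_ratio_max * float(np.median(ssc[lymphocytes]))
        confined = float((ssc[pos] <= bound).mean())
        if confined >= cfg.pearce_ssc_confinement:
            return "rare"
    return "numerous"
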