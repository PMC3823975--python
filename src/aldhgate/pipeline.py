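"""End-to-end analysis of one native/DEAB sample pair.

Stage order: gate (lymphocytes -> CD45dim blasts -> CD34/CD38
compartments, on each aliquot independently) -> DEAB-derived ALDH
threshold -> bright/low split -> scatter profile -> per-event HSC/LSC
calls -> sample classifications -> summary.  Every reported fraction is
traceable to a numerator/denominator recorded in the run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .aldh import (
    AldhThreshold,
    aldh_positive_fraction,
    deab_threshold,
    split_aldh_compartments,
    standardized_mfi,
)
from .classify import (
    StemCellCall,
    call_stem_cells,
    cheung_classification,
    classify_cd34_status,
    pearce_pattern,
)
from .config import ClassifierConfig, load_config
from .gating import GateLabels, antigen_threshold, gate_sample
from .io_flow import SamplePair, read_panel_config, read_sample_pair
from .scatter import UndefinedRatioError, classify_scatter, scatter_ratios
from .summary import SampleSummary, summarize_sample, write_sample_summary


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class SampleResult:
    """Everything the pipeline derives from one sample pair."""

    summary: SampleSummary
    labels: GateLabels
    calls: StemCellCall
    bright: np.ndarray
    marker_positive: np.ndarray
    threshold: AldhThreshold
    manifest: Dict = field(default_factory=dict)

    def event_frame(self) -> pd.DataFrame:
        """Per-event label table (compartment, ALDH class, call, evidence)."""
        aldh_class = np.where(self.bright, "bright", "low")
        return pd.DataFrame(
            {
                "compartment": self.labels.compartment,
                "aldh_class": aldh_class,
                "marker_positive": self.marker_positive,
                "stem_call": self.calls.call,
            }
        )


def analyze_sample_pair(
    pair: SamplePair,
    cfg: Optional[ClassifierConfig] = None,
    marker_name: str = "marker",
) -> SampleResult:
    """Run the full discrimination scheme on a sample pair."""
    cfg = cfg or ClassifierConfig()

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(stage, exc) from exc

    native, deab = pair.native, pair.deab
    labels = run("gate_native", gate_sample, native, cfg)
    deab_labels = run("gate_deab", gate_sample, deab, cfg)

    # DEAB threshold scoped to the compartment being split, whole-sample
    # fallback when the gate is below the reporting floor
    deab_stem = deab_labels.indices("blast_CD34pos_CD38neg")
    scope = deab_stem if deab_stem.size >= cfg.min_reportable_events else np.arange(deab.n_events)
    thr = run("deab_threshold", deab_threshold, deab, scope, cfg)

    all_idx = np.arange(native.n_events)
    bright = run("aldh_split", split_aldh_compartments, native, all_idx, thr)

    marker_thr = run(
        "marker_threshold", antigen_threshold, native, labels.lymphocytes, "MARKER", cfg
    )
    marker_positive = native.column("MARKER") > marker_thr

    status = run("cd34_status", classify_cd34_status, labels, cfg)

    # population-level scatter evidence per stem-candidate compartment
    scatter_class: Dict[str, str] = {}
    for comp in ("blast_CD34pos_CD38neg", "blast_CD34neg"):
        idx = labels.indices(comp)
        if idx.size:
            try:
                r = scatter_ratios(native, idx, labels.lymphocytes)
                scatter_class[comp] = classify_scatter(r, cfg)
            except UndefinedRatioError:
                pass

    calls = run(
        "stem_calls", call_stem_cells, labels, bright, marker_positive, status, scatter_class
    )

    aldh_pos_total = run(
        "aldh_positive_fraction", aldh_positive_fraction, native, all_idx, thr, cfg
    )
    cheung = cheung_classification(aldh_pos_total.fraction or 0.0, cfg)
    pearce = run("pearce_pattern", pearce_pattern, native, thr, labels.lymphocytes, cfg)

    # MFIs only for call sets at or above the reporting floor: a handful of
    # stray events below the ALDH threshold is not an LSC compartment
    hsc_idx = calls.indices("HSC")
    lsc_idx = calls.indices("LSC")
    hsc_mfi = lsc_mfi = None
    if hsc_idx.size >= cfg.min_reportable_events:
        hsc_mfi = standardized_mfi(
            native, hsc_idx, labels.lymphocytes, cfg.mfi_statistic
        ).ratio
    if lsc_idx.size >= cfg.min_reportable_events:
        lsc_mfi = standardized_mfi(
            native, lsc_idx, labels.lymphocytes, cfg.mfi_statistic
        ).ratio

    summary = run(
        "summarize",
        summarize_sample,
        sample_id=pair.source_id,
        marker_name=marker_name,
        cd34_status=status,
        labels=labels,
        bright=bright,
        marker_positive=marker_positive,
        hsc_std_mfi=hsc_mfi,
        lsc_std_mfi=lsc_mfi,
        aldh_pos_total=aldh_pos_total,
        cheung_class=cheung,
        pearce_pattern=pearce,
        cfg=cfg,
    )

    n_ambig = int((calls.call == "ambiguous").sum())
    n_candidates = int((calls.call != "not_stem").sum())
    manifest = {
        "software_version": _version,
        "sample_id": pair.source_id,
        "config": cfg.to_dict(),
        "event_counts": {
            "native_raw": native.n_events + native.n_dropped,
            "native_dropped": native.n_dropped,
            "native_retained": native.n_events,
            "deab_raw": deab.n_events + deab.n_dropped,
            "deab_dropped": deab.n_dropped,
            "deab_retained": deab.n_events,
            "lymphocytes": int(labels.lymphocytes.size),
            "blasts": int(labels.blasts.size),
            **labels.counts(),
        },
        "thresholds": {
            "aldh": thr.value,
            "aldh_quantile": thr.quantile_used,
            "aldh_reference_events": thr.n_reference_events,
            "marker": marker_thr,
            **labels.thresholds,
        },
        "scatter_class": scatter_class,
        "warnings": {
            "low_count_flags": {k: bool(v) for k, v in summary.low_count_flags.items()},
            "ambiguous_call_fraction": (n_ambig / n_candidates) if n_candidates else 0.0,
        },
    }
    return SampleResult(
        summary=summary,
        labels=labels,
        calls=calls,
        bright=np.asarray(bright),
        marker_positive=marker_positive,
        threshold=thr,
        manifest=manifest,
    )


def orchestrate_run(
    native_path: str | Path,
    deab_path: str | Path,
    panel_path: str | Path,
    config_path: Optional[str | Path],
    out_dir: str | Path,
) -> SampleResult:
    """File-level entry point: read inputs, analyse, write outputs.

    Writes ``summary.json``, ``manifest.json`` and ``events.csv`` into
    ``out_dir``.  On any stage failure the partially written outputs are
    removed and a :class:`StageError` naming the stage propagates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "summary.json", out_dir / "manifest.json", out_dir / "events.csv"]
    try:
        try:
            panel = read_panel_config(panel_path)
            cfg = load_config(config_path) if config_path else ClassifierConfig()
            pair = read_sample_pair(native_path, deab_path, panel)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("read_inputs", exc) from exc
        result = analyze_sample_pair(pair, cfg, marker_name=panel.marker_name)
        result.manifest["inputs"] = {
            "native": str(native_path),
            "deab": str(deab_path),
            "panel": str(panel_path),
            "config": str(config_path) if config_path else None,
        }
        write_sample_summary(result.summary, outputs[0])
        with open(outputs[1], "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result.event_frame().to_csv(outputs[2], index=False)
        return result
    except Exception:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise
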