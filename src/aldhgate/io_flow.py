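"""Reading and writing of event-level cytometry data and panel configuration.

Two on-disk event formats are supported: FCS 3.0/3.1 (the de-facto
cytometry standard; list-mode, datatypes F/D/I) and plain delimited text
with a header row of channel names.  The FCS reader is deliberately
minimal: it honours the TEXT segment, ``$PnE`` logarithmic amplification
and both byte orders, but does not implement spillover compensation,
FCS 2.0, or the ANALYSIS segment.

The seven channel *roles* the pipeline understands are fixed:
``FSC, SSC, CD45, CD34, CD38, MARKER, ALDH``.  A :class:`PanelConfig` maps
each role to an instrument channel name; every :class:`EventTable` column
is ordered by role, so downstream code never touches instrument names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

#: Canonical role order; EventTable columns follow this order.
ROLES: Tuple[str, ...] = ("FSC", "SSC", "CD45", "CD34", "CD38", "MARKER", "ALDH")

ROLE_INDEX: Dict[str, int] = {r: i for i, r in enumerate(ROLES)}

_TRANSFORMS = ("linear", "log10-like")


class PanelConfigError(ValueError):
    """Raised for an invalid or incomplete panel configuration."""


class ChannelError(KeyError):
    """Raised when a mapped channel is absent from an event file."""


class FormatError(ValueError):
    """Raised for an unrecognised or malformed event file."""


@dataclass(frozen=True)
class PanelConfig:
    """Mapping from the seven pipeline roles to instrument channel names.

    Parameters
    ----------
    channel_roles:
        Role -> channel name.  Every role in :data:`ROLES` must be mapped
        and no channel may serve two roles.
    marker_name:
        Free-text name of the aberrant marker (e.g. ``"CLL-1"``).
    transform:
        Per-role scale declaration for *delimited-text* input: ``"linear"``
        (default) or ``"log10-like"`` (stored values are log10 of linear
        intensity and are back-transformed on read).  FCS input uses the
        file's own ``$PnE`` amplification instead.
    """

    channel_roles: Dict[str, str]
    marker_name: str = "marker"
    transform: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.channel_roles]
        if missing:
            raise PanelConfigError(f"role {missing[0]} unmapped")
        extra = set(self.channel_roles) - set(ROLES)
        if extra:
            raise PanelConfigError(f"unknown roles: {sorted(extra)}")
        names = list(self.channel_roles.values())
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelConfigError(
                f"channel mapped to more than one role: {sorted(dupes)}"
            )
        for role, t in self.transform.items():
            if role not in ROLES:
                raise PanelConfigError(f"transform for unknown role {role}")
            if t not in _TRANSFORMS:
                raise PanelConfigError(
                    f"transform for {role} must be one of {_TRANSFORMS}, got {t!r}"
                )

    @property
    def channel_names(self) -> Tuple[str, ...]:
        """Instrument channel names in role order."""
        return tuple(self.channel_roles[r] for r in ROLES)


@dataclass
class EventTable:
    """Per-cell measurement matrix with role-ordered columns.

    ``values`` is an ``(n_events, 7)`` float array of nonnegative, finite
    linear-scale intensities; column ``i`` corresponds to ``ROLES[i]``.
    ``n_dropped`` records events removed on read because a mapped channel
    held a negative or non-finite value.
    """

    values: np.ndarray
    source_id: str = ""
    treatment: str = "native"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(ROLES):
            raise ValueError(
                f"values must be (n_events, {len(ROLES)}), got {self.values.shape}"
            )
        if self.treatment not in ("native", "DEAB"):
            raise ValueError("treatment must be 'native' or 'DEAB'")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError("event values must be finite and >= 0")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, role: str) -> np.ndarray:
        """The intensity column for one role."""
        return self.values[:, ROLE_INDEX[role]]

    def to_frame(self, panel: Optional[PanelConfig] = None) -> pd.DataFrame:
        cols = panel.channel_names if panel is not None else ROLES
        return pd.DataFrame(self.values, columns=list(cols))


@dataclass
class SamplePair:
    """A native aliquot and its DEAB-treated companion from one specimen."""

    native: EventTable
    deab: EventTable

    def __post_init__(self) -> None:
        if self.native.treatment != "native":
            raise ValueError("native table must have treatment='native'")
        if self.deab.treatment != "DEAB":
            raise ValueError("deab table must have treatment='DEAB'")
        if self.native.source_id != self.deab.source_id:
            raise ValueError("native and DEAB tables must share source_id")

    @property
    def source_id(self) -> str:
        return self.native.source_id


# ---------------------------------------------------------------------------
# Panel configuration files
# ---------------------------------------------------------------------------

def read_panel_config(path: str | Path) -> PanelConfig:
    """Read a panel configuration from a YAML (or ``role: channel``) file.

    Accepted layouts::

        channels: {FSC: FSC-A, SSC: SSC-A, ...}
        marker_name: CLL-1
        transform: {ALDH: linear}

    or a flat mapping ``FSC: FSC-A`` etc. with optional ``marker_name``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PanelConfigError(f"panel file {path} must contain a mapping")
    if "channels" in raw:
        channels = raw["channels"]
        marker_name = raw.get("marker_name", "marker")
        transform = raw.get("transform", {}) or {}
    else:
        channels = {k: v for k, v in raw.items() if k in ROLES}
        marker_name = raw.get("marker_name", "marker")
        transform = raw.get("transform", {}) or {}
    return PanelConfig(
        channel_roles=dict(channels),
        marker_name=str(marker_name),
        transform=dict(transform),
    )


def write_panel_config(panel: PanelConfig, path: str | Path) -> None:
    doc = {
        "channels": dict(panel.channel_roles),
        "marker_name": panel.marker_name,
    }
    if panel.transform:
        doc["transform"] = dict(panel.transform)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Event data: delimited text
# ---------------------------------------------------------------------------

def _from_frame(
    frame: pd.DataFrame,
    panel: PanelConfig,
    source_id: str,
    treatment: str,
    apply_transform: bool,
) -> EventTable:
    cols = []
    for role in ROLES:
        name = panel.channel_roles[role]
        if name not in frame.columns:
            raise ChannelError(f"channel {name!r} (role {role}) absent from file")
        col = frame[name].to_numpy(dtype=float)
        if apply_transform and panel.transform.get(role) == "log10-like":
            col = np.power(10.0, col)
        cols.append(col)
    values = np.column_stack(cols) if cols[0].size else np.empty((0, len(ROLES)))
    keep = np.all(np.isfinite(values), axis=1) & np.all(values >= 0, axis=1)
    dropped = int(values.shape[0] - keep.sum())
    return EventTable(
        values=values[keep],
        source_id=source_id,
        treatment=treatment,
        n_dropped=dropped,
    )


def write_events_csv(
    events: EventTable, path: str | Path, panel: Optional[PanelConfig] = None
) -> None:
    """Write an event table as CSV with a header row of channel names."""
    events.to_frame(panel).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Event data: FCS 3.0 / 3.1
# ---------------------------------------------------------------------------

def _parse_fcs_text(segment: bytes) -> Dict[str, str]:
    if not segment:
        raise FormatError("empty FCS TEXT segment")
    delim = segment[0:1]
    body = segment[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2:
        parts = parts[:-1]
    out: Dict[str, str] = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("utf-8", "replace").strip().upper()
        out[key] = parts[i + 1].decode("utf-8", "replace").strip()
    return out


def _read_fcs(path: Path) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Parse an FCS 3.0/3.1 file into a linear-scale DataFrame.

    Returns the event frame (columns = ``$PnN`` names, amplification
    already undone per ``$PnE``) and the raw TEXT keywords.
    """
    data = path.read_bytes()
    if len(data) < 58 or not data[:3] == b"FCS":
        raise FormatError(f"{path} is not an FCS file")
    version = data[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        return int(data[lo:hi].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_fcs_text(data[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text["$DATATYPE"].upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    raw = data[data_start : data_end + 1]
    if dtype_code == "F":
        arr = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=f"{order}f4")
        mat = arr.reshape(n_tot, n_par).astype(float)
    elif dtype_code == "D":
        arr = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=f"{order}f8")
        mat = arr.reshape(n_tot, n_par).astype(float)
    elif dtype_code == "I":
        widths = [int(text[f"$P{i}B"]) // 8 for i in range(1, n_par + 1)]
        if len(set(widths)) != 1 or widths[0] not in (2, 4):
            raise FormatError("only uniform 16/32-bit integer FCS data supported")
        code = "u2" if widths[0] == 2 else "u4"
        arr = np.frombuffer(raw[: widths[0] * n_par * n_tot], dtype=f"{order}{code}")
        mat = arr.reshape(n_tot, n_par).astype(float)
    else:
        raise FormatError(f"unsupported $DATATYPE {dtype_code!r}")

    names = []
    for i in range(1, n_par + 1):
        names.append(text.get(f"$P{i}N", f"P{i}"))
        pne = text.get(f"$P{i}E", "0,0")
        try:
            decades, f2 = (float(x) for x in pne.split(","))
        except ValueError:
            decades, f2 = 0.0, 0.0
        if decades > 0:
            # log-amplified channel: stored value x in [0, PnR) maps to
            # f2 * 10^(decades * x / PnR) on the linear scale
            pnr = float(text.get(f"$P{i}R", 1024))
            if f2 <= 0:  # files commonly write "4,0"; 0 means 1 by convention
                f2 = 1.0
            mat[:, i - 1] = f2 * np.power(10.0, decades * mat[:, i - 1] / pnr)
    return pd.DataFrame(mat, columns=names), text


def write_fcs(
    events: EventTable,
    path: str | Path,
    panel: Optional[PanelConfig] = None,
) -> None:
    """Write an event table as a minimal FCS 3.0 file (float32, linear).

    Intended for round-trip testing and interchange with cytometry
    software; all channels are written unamplified (``$PnE/0,0``).
    """
    names = panel.channel_names if panel is not None else ROLES
    mat = events.values.astype("<f4")
    n_tot, n_par = mat.shape
    delim = "/"
    kv = {
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$MODE": "L",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(float(mat[:, i - 1].max(initial=0.0)), 1)) + 1)

    # two-pass: sizes of BEGINDATA/ENDDATA change the TEXT length
    def render(begin: int, end: int) -> bytes:
        items = dict(kv)
        items["$BEGINDATA"] = str(begin)
        items["$ENDDATA"] = str(end)
        body = delim + delim.join(f"{k}{delim}{v}" for k, v in items.items()) + delim
        return body.encode("ascii")

    text = render(0, 0)
    header_len = 58
    for _ in range(4):
        text_start = header_len
        text_end = text_start + len(text) - 1
        data_start = text_end + 1
        data_end = data_start + mat.nbytes - 1
        new_text = render(data_start, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(mat.tobytes())


# ---------------------------------------------------------------------------
# Unified reader
# ---------------------------------------------------------------------------

def read_events(
    path: str | Path,
    panel: PanelConfig,
    treatment: str = "native",
    source_id: Optional[str] = None,
) -> EventTable:
    """Read events from an FCS 3.0/3.1 or delimited-text file.

    Columns are selected and reordered per the panel; text-input channels
    declared ``log10-like`` are back-transformed to linear scale; events
    with a negative or non-finite value in any mapped channel are dropped
    and counted in ``EventTable.n_dropped``.
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    with open(path, "rb") as fh:
        head = fh.read(1024)
    if head[:3] == b"FCS":
        frame, _ = _read_fcs(path)
        return _from_frame(frame, panel, source_id, treatment, apply_transform=False)
    if b"\x00" in head:
        raise FormatError(f"{path}: binary data that is not an FCS file")
    # delimited text: sniff comma vs tab from the header line
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
        frame = pd.read_csv(path, sep=sep)
    except (UnicodeDecodeError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not FCS and not readable as delimited text") from exc
    if frame.columns.dtype != object:
        raise FormatError(f"{path}: delimited text requires a header row")
    return _from_frame(frame, panel, source_id, treatment, apply_transform=True)


def read_sample_pair(
    native_path: str | Path,
    deab_path: str | Path,
    panel: PanelConfig,
    source_id: Optional[str] = None,
) -> SamplePair:
    """Read a native/DEAB file pair into a :class:`SamplePair`."""
    if source_id is None:
        source_id = Path(native_path).stem
    native = read_events(native_path, panel, treatment="native", source_id=source_id)
    deab = read_events(deab_path, panel, treatment="DEAB", source_id=source_id)
    return SamplePair(native=native, deab=deab)
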