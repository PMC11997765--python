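"""Readers and writers for the pipeline's interchange formats.

Signals travel as EDF (European Data Format); channel metadata, event
annotations and cohort tables are comma-separated UTF-8 with a
mandatory header. Reading EDF goes through :mod:`mne`; writing uses a
small 16-bit EDF encoder so synthetic recordings can round-trip
through the same path as clinical exports.
"""

from __future__ import annotations

import datetime as _dt
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ChannelInfo,
    ElectrodeKind,
    Event,
    EventType,
    FormatError,
    Lobe,
    Recording,
    UnsupportedLayoutError,
    ValidationError,
)

_EVENT_COLUMNS = ["channel_id", "onset", "offset", "event_type"]
_CHANNEL_COLUMNS = ["channel_id", "lobe", "is_soz", "is_resected", "electrode_kind"]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    if len(b) > width:
        raise ValidationError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a Recording as 16-bit EDF (one signal per channel, microvolts).

    Data records are 1 s long when the sample count divides evenly by the
    sampling rate, otherwise a single record spanning the whole segment.
    """
    path = Path(path)
    sig = recording.signal
    n_ch, n_samp = sig.shape
    fs = recording.sampling_rate
    if n_ch == 0:
        raise ValidationError("cannot write an EDF with zero channels")

    spr = int(round(fs))  # samples per record at 1 s
    if abs(spr - fs) < 1e-9 and n_samp % spr == 0:
        n_records = n_samp // spr
        record_dur = 1.0
    else:
        n_records = 1
        spr = n_samp
        record_dur = n_samp / fs

    pmin = sig.min(axis=1)
    pmax = sig.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),  # patient id (anonymous)
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(f"{record_dur:g}"[:8], 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        (16, [c[:16] for c in recording.channel_ids]),
        (80, ["" for _ in range(n_ch)]),  # transducer
        (8, ["uV"] * n_ch),
        (8, [f"{v:.8g}"[:8] for v in pmin]),
        (8, [f"{v:.8g}"[:8] for v in pmax]),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, ["" for _ in range(n_ch)]),  # prefiltering
        (8, [str(spr)] * n_ch),
        (32, ["" for _ in range(n_ch)]),
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for width, values in fields
    )

    # physical -> digital
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((sig - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            sl = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(sl.tobytes())


def _edf_header_layout(path: Path) -> tuple[int, list[int]]:
    """Return (n_channels, samples-per-record per channel) from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: invalid EDF header") from exc
        sig_head = fh.read(256 * n_ch)
        if n_ch > 0 and len(sig_head) < 256 * n_ch:
            raise FormatError(f"{path}: truncated EDF signal header")
        off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_ch
        spr = [
            int(sig_head[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
            for i in range(n_ch)
        ]
    return n_ch, spr


def read_recording(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts).

    Raises UnsupportedLayoutError for zero-channel files or files whose
    channels do not share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        n_ch, spr = _edf_header_layout(path)
    except struct.error as exc:  # pragma: no cover - defensive
        raise FormatError(f"{path}: unreadable EDF") from exc
    if n_ch == 0:
        raise UnsupportedLayoutError(f"{path}: EDF contains no channels")
    if len(set(spr)) > 1:
        raise UnsupportedLayoutError(
            f"{path}: channels have mixed sampling rates {sorted(set(spr))}"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _parse_flag(value) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true"):
        return True
    if s in ("0", "false"):
        return False
    raise ValidationError(f"cannot parse boolean flag from {value!r}")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing columns {missing}")


def read_channel_table(path: str | Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _CHANNEL_COLUMNS, "channel table")
    if df["channel_id"].duplicated().any():
        dup = df["channel_id"][df["channel_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate channel_id {dup!r} in channel table")
    out = []
    for _, row in df.iterrows():
        out.append(
            ChannelInfo(
                channel_id=row["channel_id"],
                lobe=Lobe(row["lobe"].strip().lower()),
                is_soz=_parse_flag(row["is_soz"]),
                is_resected=_parse_flag(row["is_resected"]),
                electrode_kind=ElectrodeKind(row["electrode_kind"].strip().lower()),
            )
        )
    return out


def write_channel_table(channels: list[ChannelInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "channel_id": c.channel_id,
                "lobe": c.lobe.value,
                "is_soz": int(c.is_soz),
                "is_resected": int(c.is_resected),
                "electrode_kind": c.electrode_kind.value,
            }
            for c in channels
        ],
        columns=_CHANNEL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_event_table(path: str | Path) -> list[Event]:
    df = pd.read_csv(path)
    _require_columns(df, _EVENT_COLUMNS, "event table")
    events = []
    for _, row in df.iterrows():
        try:
            etype = EventType(str(row["event_type"]).strip().lower())
        except ValueError as exc:
            raise ValidationError(
                f"unknown event_type {row['event_type']!r}"
            ) from exc
        peak = row.get("peak_time")
        peak_f = row.get("peak_frequency")
        n_osc = row.get("n_oscillations")
        events.append(
            Event(
                channel_id=str(row["channel_id"]),
                onset=float(row["onset"]),
                offset=float(row["offset"]),
                event_type=etype,
                peak_time=float(peak) if peak is not None and pd.notna(peak) else None,
                peak_frequency=(
                    float(peak_f) if peak_f is not None and pd.notna(peak_f) else None
                ),
                n_oscillations=(
                    int(n_osc) if n_osc is not None and pd.notna(n_osc) else None
                ),
            )
        )
    return events


def write_event_table(events: list[Event], path: str | Path) -> None:
    """Write events as CSV, ordered by (channel_id, onset) for stable diffs."""
    rows = [
        {
            "channel_id": ev.channel_id,
            "onset": ev.onset,
            "offset": ev.offset,
            "event_type": ev.event_type.value,
            "peak_time": ev.peak_time,
            "peak_frequency": ev.peak_frequency,
            "n_oscillations": ev.n_oscillations,
            "qc_status": ev.qc_status.value,
        }
        for ev in sorted(events, key=lambda e: (e.channel_id, e.onset))
    ]
    df = pd.DataFrame(
        rows,
        columns=_EVENT_COLUMNS
        + ["peak_time", "peak_frequency", "n_oscillations", "qc_status"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "duration_min", "engel"], "cohort table")
    return df


def write_cohort_table(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
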