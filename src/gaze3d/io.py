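"""Reading, writing and timestamp validation of gaze recording files.

The on-disk format is a CSV with one gaze sample per row and the
canonical column header, plus a JSON metadata sidecar (participant,
recording name, start/stop time, logged info events).  CSV dialect:
comma separator, ``.`` decimal, UTF-8, LF line endings; booleans are
written ``True``/``False`` and parsed case-insensitively; absent values
are empty cells.  ``eyeDataRelativeTimestamp`` is written with four
decimals (the 100 ns resolution of the device clock), all other floats
with full shortest-repr precision, so write -> load is the identity.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .model import (
    GazeRecording,
    RecordingMetadata,
    RowParseError,
    SchemaError,
    TimestampReport,
    UnsortedTimestampsError,
    empty_frame,
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "": False}

#: Expected sampling interval of the device (ms).
EXPECTED_DELTA_MS = 1000.0 / 30.0


def _parse_bool_column(raw: pd.Series, col: str) -> pd.Series:
    lowered = raw.str.strip().str.lower()
    bad = ~lowered.isin(_BOOL_MAP)
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowParseError(idx, col, str(raw.iloc[idx]))
    return lowered.map(_BOOL_MAP).astype(bool)


def _parse_float_column(raw: pd.Series, col: str) -> pd.Series:
    stripped = raw.str.strip()
    try:
        # numpy's parser is correctly rounded, so shortest-repr values
        # written by write_recording read back bit-identically
        values = stripped.replace("", "nan").to_numpy(dtype=str).astype(np.float64)
    except ValueError:
        for idx, cell in enumerate(stripped):
            if cell == "":
                continue
            try:
                float(cell)
            except ValueError:
                raise RowParseError(idx, col, str(raw.iloc[idx])) from None
        raise
    return pd.Series(values, index=raw.index)


def _parse_int_column(raw: pd.Series, col: str) -> pd.Series:
    values = _parse_float_column(raw, col)
    if values.isna().any():
        idx = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise RowParseError(idx, col, "")
    return values.astype(np.int64)


def load_recording(csv_path, json_path=None) -> GazeRecording:
    """Load a gaze CSV (and optional JSON sidecar) into a recording.

    Unknown extra columns are tolerated and carried along untouched;
    missing optional columns are filled as absent.  Rows are returned in
    file order.
    """
    raw = pd.read_csv(csv_path, dtype=str, keep_default_na=False, skipinitialspace=False)
    missing = [c for c in schema.MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"CSV is missing mandatory columns: {missing}")

    frame = empty_frame(len(raw))
    for col in schema.TABLE_COLUMNS:
        if col not in raw.columns:
            continue
        if col in schema.BOOL_COLUMNS:
            frame[col] = _parse_bool_column(raw[col], col)
        elif col in schema.INT_COLUMNS:
            frame[col] = _parse_int_column(raw[col], col)
        elif col in schema.TEXT_COLUMNS:
            frame[col] = raw[col].astype(object)
        else:
            frame[col] = _parse_float_column(raw[col], col)

    known = set(schema.TABLE_COLUMNS)
    for col in raw.columns:
        if col in known:
            continue
        if col == schema.GAP_FILLED_COLUMN:
            frame[col] = _parse_bool_column(raw[col], col)
        elif col.startswith(schema.GAME_OBJECT_PREFIX):
            frame[col] = _parse_float_column(raw[col], col)
        else:
            frame[col] = raw[col].astype(object)

    metadata = RecordingMetadata()
    if json_path is not None:
        metadata = _load_metadata(json_path)
    elif len(frame):
        metadata = RecordingMetadata(
            start_time=int(frame["eyeDataTimestamp"].iloc[0]),
            stop_time=int(frame["eyeDataTimestamp"].iloc[-1]),
        )
    return GazeRecording(frame, metadata)


def _load_metadata(json_path) -> RecordingMetadata:
    with open(json_path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return RecordingMetadata(
        participant=doc.get("participant", "unknown"),
        recording_name=doc.get("recording", "recording"),
        start_time=int(doc.get("startTime", 0)),
        stop_time=int(doc.get("stopTime", 0)),
        info_events=[(int(t), str(s)) for t, s in doc.get("infoEvents", [])],
    )


def write_recording(recording: GazeRecording, csv_path, json_path=None) -> None:
    """Write a recording as CSV (+ JSON metadata sidecar).

    The header lists the canonical columns in order, dynamic
    ``gameObject_*`` columns before ``info``, and any other extra columns
    at the end.  Absent values become empty cells.
    """
    df = recording.data
    game_cols = [c for c in df.columns if c.startswith(schema.GAME_OBJECT_PREFIX)]
    known = set(schema.TABLE_COLUMNS) | set(game_cols)
    extra = [c for c in df.columns if c not in known]
    fixed = schema.TABLE_COLUMNS[:-1] + game_cols + ["info"] + extra

    out = {}
    for col in fixed:
        series = df[col]
        if col == "eyeDataRelativeTimestamp":
            out[col] = series.map(lambda v: "" if _isnan(v) else f"{v:.4f}")
        elif col in schema.BOOL_COLUMNS or col == schema.GAP_FILLED_COLUMN:
            out[col] = series.map(lambda v: "True" if bool(v) else "False")
        elif col in schema.INT_COLUMNS:
            out[col] = series.map(lambda v: str(int(v)))
        elif col in schema.TEXT_COLUMNS or series.dtype == object:
            out[col] = series.map(lambda v: "" if v is None or _isnan(v) else str(v))
        else:
            out[col] = series.map(lambda v: "" if _isnan(v) else repr(float(v)))
    pd.DataFrame(out, columns=fixed).to_csv(
        csv_path, index=False, lineterminator="\n", encoding="utf-8"
    )

    if json_path is not None:
        meta = recording.metadata
        doc = {
            "participant": meta.participant,
            "recording": meta.recording_name,
            "startTime": meta.start_time,
            "stopTime": meta.stop_time,
            "infoEvents": [[t, s] for t, s in meta.info_events],
        }
        Path(json_path).write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _isnan(v) -> bool:
    return isinstance(v, float) and math.isnan(v)


def validate_timestamps(
    recording: GazeRecording,
    expected_delta_ms: float = EXPECTED_DELTA_MS,
    lower: float = 32.0,
    upper: float = 34.0,
    drop_gap_samples: bool = False,
) -> tuple[GazeRecording, TimestampReport]:
    """Remove duplicate-timestamp samples and flag dropped-frame gaps.

    Samples whose relative timestamp equals the previous kept sample's
    (delta 0) are removed, keeping the first of each duplicate run.
    Deltas above ``upper`` ms indicate frames dropped by the device; they
    are counted (and, with ``drop_gap_samples=True``, the samples ending
    them removed) but retained by default, since the data they carry is
    valid.  The report's mean/SD cover the regular deltas only, so a
    fault-free 30 Hz stream reports a mean of ``expected_delta_ms``.
    Deltas below ``lower`` but above zero would indicate clock anomalies
    never observed on the device and are left untouched.
    ``expected_delta_ms`` is the nominal sampling interval; each gap is
    reported also as its nearest frame-count multiple of it.
    """
    if len(recording) < 2:
        raise ValueError("timestamp validation requires at least 2 samples")
    ts = recording.relative_timestamps
    if np.any(np.diff(ts) < 0):
        raise UnsortedTimestampsError(
            "relative timestamps decrease; sort the recording first"
        )

    removed: list[int] = []
    kept: list[int] = [0]
    last_ts = ts[0]
    for i in range(1, len(ts)):
        if abs(ts[i] - last_ts) < 1e-7:
            removed.append(i)
        else:
            kept.append(i)
            last_ts = ts[i]

    kept_ts = ts[kept]
    deltas = np.diff(kept_ts)
    gap_mask = deltas > upper
    gap_positions = np.flatnonzero(gap_mask) + 1  # position within kept order
    gap_indices = [int(kept[p]) for p in gap_positions]
    gap_deltas = [float(deltas[p - 1]) for p in gap_positions]

    if drop_gap_samples:
        drop = set(gap_indices)
        kept = [i for i in kept if i not in drop]
        removed = sorted(removed + gap_indices)

    regular = deltas[~gap_mask]
    mean_delta = float(regular.mean()) if regular.size else float("nan")
    sd_delta = float(regular.std(ddof=1)) if regular.size > 1 else 0.0

    frame = recording.data.iloc[kept].reset_index(drop=True)
    report = TimestampReport(
        n_samples=len(ts),
        mean_delta=mean_delta,
        sd_delta=sd_delta,
        n_duplicates=len([i for i in removed if i not in gap_indices]),
        n_dropped_frame_gaps=int(gap_mask.sum()),
        removed_indices=removed,
        gap_indices=gap_indices,
        gap_deltas=gap_deltas,
        gap_multiples=[int(round(d / expected_delta_ms)) for d in gap_deltas],
    )
    return GazeRecording(frame, recording.metadata), report
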