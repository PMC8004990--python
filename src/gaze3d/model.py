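"""In-memory containers for gaze recordings.

A recording is held as a :class:`pandas.DataFrame` with one gaze sample
per row and the canonical column schema (see :mod:`gaze3d.schema`),
wrapped together with the recording metadata.  Vector accessors return
``(n, 3)`` float arrays in the world frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema


class SchemaError(ValueError):
    """The CSV is missing mandatory columns or is structurally unreadable."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the zero-based data row index."""

    def __init__(self, row_index: int, column: str, value: str):
        self.row_index = row_index
        self.column = column
        self.value = value
        super().__init__(
            f"row {row_index}: cannot parse {column}={value!r} as a number"
        )


class UnsortedTimestampsError(ValueError):
    """Relative timestamps decrease; the caller must sort before validating."""


@dataclass
class RecordingMetadata:
    """Sidecar metadata: who was recorded, when, and the logged events."""

    participant: str = "unknown"
    recording_name: str = "recording"
    start_time: int = 0
    stop_time: int = 0
    info_events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.stop_time < self.start_time:
            raise ValueError("stop_time must be >= start_time")
        self.info_events = [(int(t), str(s)) for t, s in self.info_events]


def empty_frame(n: int = 0) -> pd.DataFrame:
    """A schema-complete frame of ``n`` blank samples."""
    data: dict = {}
    for col in schema.TABLE_COLUMNS:
        if col in schema.BOOL_COLUMNS:
            data[col] = np.zeros(n, dtype=bool)
        elif col in schema.INT_COLUMNS:
            data[col] = np.zeros(n, dtype=np.int64)
        elif col in schema.TEXT_COLUMNS:
            data[col] = np.full(n, "", dtype=object)
        else:
            data[col] = np.full(n, np.nan)
    return pd.DataFrame(data)


@dataclass
class GazeRecording:
    """An ordered gaze-sample table plus its metadata.

    Samples are ordered by ``eyeDataRelativeTimestamp``; loading preserves
    file order and timestamp validation checks (rather than enforces)
    monotonicity.
    """

    data: pd.DataFrame
    metadata: RecordingMetadata = field(default_factory=RecordingMetadata)

    def __post_init__(self):
        missing = [c for c in schema.TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"recording frame is missing columns: {missing[:5]}...")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "GazeRecording":
        return GazeRecording(
            self.data.copy(), dataclasses.replace(self.metadata)
        )

    # -- array accessors ----------------------------------------------------

    @property
    def relative_timestamps(self) -> np.ndarray:
        return self.data["eyeDataRelativeTimestamp"].to_numpy(dtype=float)

    @property
    def valid(self) -> np.ndarray:
        return self.data["gazeHasValue"].to_numpy(dtype=bool)

    @property
    def origins(self) -> np.ndarray:
        return self.data[schema.vec("gazeOrigin")].to_numpy(dtype=float)

    @property
    def directions(self) -> np.ndarray:
        return self.data[schema.vec("gazeDirection")].to_numpy(dtype=float)

    @property
    def points(self) -> np.ndarray:
        return self.data[schema.vec("gazePoint")].to_numpy(dtype=float)

    @property
    def point_hit(self) -> np.ndarray:
        return self.data["gazePointHit"].to_numpy(dtype=bool)

    @property
    def aoi_names(self) -> np.ndarray:
        return self.data["gazePointAOI_target_name"].fillna("").to_numpy(dtype=object)


@dataclass
class TimestampReport:
    """Outcome of timestamp-integrity validation of one recording.

    ``mean_delta``/``sd_delta`` describe the regular inter-sample intervals
    after duplicate removal, excluding the flagged dropped-frame gaps
    (which are counted and listed separately).
    """

    n_samples: int
    mean_delta: float
    sd_delta: float
    n_duplicates: int
    n_dropped_frame_gaps: int
    removed_indices: list[int] = field(default_factory=list)
    gap_indices: list[int] = field(default_factory=list)
    gap_deltas: list[float] = field(default_factory=list)
    gap_multiples: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nSamples": self.n_samples,
            "meanDelta": self.mean_delta,
            "sdDelta": self.sd_delta,
            "nDuplicates": self.n_duplicates,
            "nDroppedFrameGaps": self.n_dropped_frame_gaps,
            "removedIndices": list(self.removed_indices),
            "gapIndices": list(self.gap_indices),
            "gapDeltas": list(self.gap_deltas),
            "gapMultiples": list(self.gap_multiples),
        }
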