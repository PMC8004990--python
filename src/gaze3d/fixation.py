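"""Offline fixation detection on world-referenced 3D gaze.

Three classic event-detection families operate directly on the 3D gaze
points (seen from the recorded gaze origins), so no projection to a 2D
screen is needed:

* I-VT - velocity threshold: an angular velocity is computed for every
  sample over a centered time window and compared against a deg/s
  threshold.
* I-DT - dispersion threshold: a duration window slides over the data;
  while the angular dispersion (maximum pairwise visual angle among the
  window's gaze points, viewed from the window's mean gaze origin) stays
  below the threshold, the window is extended, and the covered samples
  (excluding the sample that broke the threshold) form a fixation.
* I-AOI - area-of-interest: maximal runs of samples mapped to the same
  AOI become fixation candidates; runs shorter than a minimum duration
  are discarded.

Two post-processing passes are provided: merging adjacent fixations
separated by a short gap, and discarding short fixations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .geometry import angular_distance
from .model import GazeRecording, UnsortedTimestampsError

LABEL_FIXATION = "fixation"
LABEL_SACCADE = "saccade"
LABEL_GAP = "gap"
LABEL_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class IVTParams:
    velocity_threshold: float = 30.0  # deg/s
    velocity_window: float = 20.0  # ms


@dataclass(frozen=True)
class IDTParams:
    dispersion_threshold: float = 1.0  # deg
    window_duration: float = 250.0  # ms


@dataclass(frozen=True)
class IAOIParams:
    min_duration: float = 100.0  # ms


@dataclass(frozen=True)
class MergeParams:
    max_gap_duration: float = 75.0  # ms
    max_angle: float = 0.5  # deg, I-VT condition
    max_dispersion: float = 1.0  # deg, I-DT condition


@dataclass(frozen=True)
class DiscardParams:
    min_duration: float = 60.0  # ms


@dataclass
class FixationEvent:
    """A detected fixation: time span, centroid and sample bookkeeping."""

    start_timestamp: float
    end_timestamp: float
    centroid: np.ndarray
    mean_gaze_origin: np.ndarray
    dispersion: float
    sample_indices: list[int]
    aoi_name: str | None = None

    @property
    def duration(self) -> float:
        return self.end_timestamp - self.start_timestamp

    @property
    def n_samples(self) -> int:
        return len(self.sample_indices)


def dispersion_of(points: np.ndarray, origins: np.ndarray) -> float:
    """Max pairwise visual angle among gaze points, from the mean origin."""
    if len(points) < 2:
        return 0.0
    rays = points - origins.mean(axis=0)
    norms = np.linalg.norm(rays, axis=1)
    unit = rays / norms[:, np.newaxis]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)).max())


def _make_event(recording: GazeRecording, indices: list[int], aoi: str | None = None,
                points: np.ndarray | None = None) -> FixationEvent:
    ts = recording.relative_timestamps
    pts = recording.points[indices] if points is None else points
    origins = recording.origins[indices]
    return FixationEvent(
        start_timestamp=float(ts[indices[0]]),
        end_timestamp=float(ts[indices[-1]]),
        centroid=pts.mean(axis=0),
        mean_gaze_origin=origins.mean(axis=0),
        dispersion=dispersion_of(pts, origins),
        sample_indices=list(indices),
        aoi_name=aoi,
    )


def _usable(recording: GazeRecording) -> np.ndarray:
    """Samples that carry a gaze point usable for 3D event detection."""
    return (
        recording.valid
        & recording.point_hit
        & ~np.isnan(recording.points).any(axis=1)
    )


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, stop) index pairs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _check_window(recording: GazeRecording, window_ms: float) -> np.ndarray:
    ts = recording.relative_timestamps
    if np.any(np.diff(ts) <= 0):
        raise UnsortedTimestampsError("timestamps must be strictly increasing")
    if len(ts) and window_ms > ts[-1] - ts[0]:
        raise ValueError(
            f"window of {window_ms} ms exceeds the recording span "
            f"of {ts[-1] - ts[0]:.1f} ms"
        )
    return ts


# ---------------------------------------------------------------------------
# I-VT


def ivt(
    recording: GazeRecording, params: IVTParams = IVTParams()
) -> tuple[pd.DataFrame, list[FixationEvent]]:
    """Velocity-threshold fixation detection.

    Per sample, the angular velocity is the visual angle between the gaze
    points of the first and last sample inside a centered window of
    ``velocity_window`` ms (seen from the window's mean gaze origin),
    divided by their time difference.  When the window holds only the
    sample itself - unavoidable when the window is shorter than the
    sampling interval - the immediate neighbours are used instead.
    Samples at or below ``velocity_threshold`` deg/s are fixation
    samples; consecutive fixation samples form events.  Invalid samples
    are labeled ``gap`` and split candidate fixations.

    Returns a per-sample label frame (``label``, ``velocity``) and the
    list of fixation events.
    """
    ts = _check_window(recording, params.velocity_window)
    usable = _usable(recording)
    points = recording.points
    origins = recording.origins
    n = len(recording)

    labels = np.full(n, LABEL_GAP, dtype=object)
    labels[recording.valid & ~usable] = LABEL_UNCLASSIFIED
    velocity = np.full(n, np.nan)

    half = params.velocity_window / 2.0
    for start, stop in _runs(usable):
        run_ts = ts[start:stop]
        for i in range(start, stop):
            lo = int(np.searchsorted(run_ts, ts[i] - half, side="left")) + start
            hi = int(np.searchsorted(run_ts, ts[i] + half, side="right")) - 1 + start
            if lo == hi:  # window holds only the sample: neighbour fallback
                lo, hi = max(start, i - 1), min(stop - 1, i + 1)
            if lo == hi:
                labels[i] = LABEL_UNCLASSIFIED
                continue
            mean_origin = origins[lo : hi + 1].mean(axis=0)
            ang = angular_distance(points[lo] - mean_origin, points[hi] - mean_origin)
            dt_s = (ts[hi] - ts[lo]) / 1000.0
            velocity[i] = ang / dt_s
            labels[i] = (
                LABEL_FIXATION
                if velocity[i] <= params.velocity_threshold
                else LABEL_SACCADE
            )

    events = [
        _make_event(recording, list(range(s, e)))
        for s, e in _runs(labels == LABEL_FIXATION)
    ]
    frame = pd.DataFrame({"label": labels, "velocity": velocity})
    return frame, events


# ---------------------------------------------------------------------------
# I-DT


def idt(
    recording: GazeRecording, params: IDTParams = IDTParams()
) -> list[FixationEvent]:
    """Dispersion-threshold fixation detection (duration-based window).

    A window spanning at least ``window_duration`` ms is initialized at
    the current sample; if its dispersion exceeds the threshold it is
    moved forward one sample at a time.  Otherwise it is extended to the
    right until the threshold is exceeded; all window samples except the
    last form a fixation, and the next window starts at that last
    sample.  If the data end before the threshold is exceeded, the open
    window becomes a final fixation.  Stretches too short to span the
    window duration (including whole recordings) yield no fixation.
    Invalid samples split the stream.
    """
    ts = _check_window(recording, 0.0)
    usable = _usable(recording)
    points = recording.points
    origins = recording.origins
    events: list[FixationEvent] = []

    for start, stop in _runs(usable):
        i = start
        while i < stop:
            # initial window: minimal sample span covering window_duration
            j = int(
                np.searchsorted(ts[start:stop], ts[i] + params.window_duration, "left")
            ) + start
            if j >= stop:
                break  # remaining samples cannot span the window
            disp = dispersion_of(points[i : j + 1], origins[i : j + 1])
            if disp > params.dispersion_threshold:
                i += 1
                continue
            j += 1
            while j < stop:
                disp = dispersion_of(points[i : j + 1], origins[i : j + 1])
                if disp > params.dispersion_threshold:
                    break
                j += 1
            if j < stop:
                events.append(_make_event(recording, list(range(i, j))))
                i = j  # next window starts at the sample that broke the threshold
            else:
                events.append(_make_event(recording, list(range(i, stop))))
                i = stop
    return events


# ---------------------------------------------------------------------------
# I-AOI


def iaoi(
    recording: GazeRecording,
    params: IAOIParams = IAOIParams(),
    aoi_labels=None,
) -> list[FixationEvent]:
    """AOI-based fixation detection.

    Samples inside an AOI (non-empty AOI name) are fixation samples;
    maximal runs sharing one AOI name become candidate events, and runs
    shorter than ``min_duration`` ms are discarded.  AOI names default to
    the recorded real-time gaze-to-AOI mapping column.
    """
    ts = recording.relative_timestamps
    if np.any(np.diff(ts) <= 0):
        raise UnsortedTimestampsError("timestamps must be strictly increasing")
    if aoi_labels is None:
        aoi_labels = recording.aoi_names
    aoi_labels = np.asarray(
        ["" if lbl is None or (isinstance(lbl, float) and np.isnan(lbl)) else str(lbl)
         for lbl in aoi_labels],
        dtype=object,
    )
    valid = recording.valid
    aoi_points = recording.data[schema.vec("gazePointAOI")].to_numpy(dtype=float)
    have_aoi_pt = ~np.isnan(aoi_points).any(axis=1)

    events: list[FixationEvent] = []
    n = len(recording)
    i = 0
    while i < n:
        name = aoi_labels[i]
        if not valid[i] or name == "":
            i += 1
            continue
        j = i
        while j < n and valid[j] and aoi_labels[j] == name:
            j += 1
        if ts[j - 1] - ts[i] >= params.min_duration:
            indices = list(range(i, j))
            pts = np.where(
                have_aoi_pt[indices, np.newaxis],
                aoi_points[indices],
                recording.points[indices],
            )
            events.append(_make_event(recording, indices, aoi=name, points=pts))
        i = j
    return events


# ---------------------------------------------------------------------------
# Post-processing


def merge_adjacent_fixations(
    events: list[FixationEvent],
    params: MergeParams,
    mode: str,
    recording: GazeRecording,
) -> list[FixationEvent]:
    """Merge subsequent fixations separated by a short gap.

    A pair merges when the gap is shorter than ``max_gap_duration`` ms
    and the mode-specific condition holds: centroid angle at most
    ``max_angle`` (I-VT, measured from the mean of the two events' mean
    gaze origins), combined dispersion at most ``max_dispersion`` (I-DT),
    or identical AOI (I-AOI).  Merging recomputes centroid, origin and
    dispersion from the union of samples and repeats left-to-right until
    no pair merges.
    """
    if mode not in ("ivt", "idt", "iaoi"):
        raise ValueError("mode must be one of 'ivt', 'idt', 'iaoi'")
    evs = sorted(events, key=lambda e: e.start_timestamp)
    for a, b in zip(evs, evs[1:]):
        if b.start_timestamp < a.end_timestamp:
            raise ValueError("fixation events overlap; cannot merge")

    def can_merge(a: FixationEvent, b: FixationEvent) -> bool:
        if b.start_timestamp - a.end_timestamp >= params.max_gap_duration:
            return False
        if mode == "ivt":
            origin = (a.mean_gaze_origin + b.mean_gaze_origin) / 2.0
            return (
                angular_distance(a.centroid - origin, b.centroid - origin)
                <= params.max_angle
            )
        if mode == "idt":
            indices = a.sample_indices + b.sample_indices
            return (
                dispersion_of(recording.points[indices], recording.origins[indices])
                <= params.max_dispersion
            )
        return a.aoi_name is not None and a.aoi_name == b.aoi_name

    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(evs) - 1:
            a, b = evs[i], evs[i + 1]
            if can_merge(a, b):
                merged = _make_event(
                    recording, a.sample_indices + b.sample_indices, aoi=a.aoi_name
                )
                evs[i : i + 2] = [merged]
                changed = True
            else:
                i += 1
    return evs


def discard_short_fixations(
    events: list[FixationEvent], params: DiscardParams
) -> list[FixationEvent]:
    """Drop fixations shorter than ``min_duration`` ms (boundary kept)."""
    return [e for e in events if e.duration >= params.min_duration]


def events_to_frame(events: list[FixationEvent]) -> pd.DataFrame:
    """Tabulate events for CSV export."""
    return pd.DataFrame(
        {
            "start_ms": [e.start_timestamp for e in events],
            "end_ms": [e.end_timestamp for e in events],
            "duration_ms": [e.duration for e in events],
            "centroid_x": [e.centroid[0] for e in events],
            "centroid_y": [e.centroid[1] for e in events],
            "centroid_z": [e.centroid[2] for e in events],
            "dispersion_deg": [e.dispersion for e in events],
            "n_samples": [e.n_samples for e in events],
            "aoi": [e.aoi_name or "" for e in events],
        }
    )
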