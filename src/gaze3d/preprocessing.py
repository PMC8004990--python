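"""Pre-processing of raw gaze streams: gap filling and noise reduction.

Tracking losses shorter than a configurable duration are bridged by
linear interpolation between the valid anchor samples; measurement
noise is attenuated with a windowed mean or median filter computed over
the valid samples in a centered window.  Both operations preserve the
number and order of samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import schema
from .model import GazeRecording, UnsortedTimestampsError


@dataclass(frozen=True)
class GapFillParams:
    """Maximum anchor-to-anchor time difference (ms) that is interpolated."""

    max_gap_duration: float = 75.0

    def __post_init__(self):
        if self.max_gap_duration <= 0:
            raise ValueError("max_gap_duration must be > 0")


@dataclass(frozen=True)
class NoiseReductionParams:
    method: str = "median"
    window: int = 3

    def __post_init__(self):
        if self.method not in ("mean", "median"):
            raise ValueError("method must be 'mean' or 'median'")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")


def _check_sorted(ts: np.ndarray) -> None:
    if np.any(np.diff(ts) <= 0):
        raise UnsortedTimestampsError("timestamps must be strictly increasing")


def gap_fill(recording: GazeRecording, params: GapFillParams) -> GazeRecording:
    """Linearly interpolate gaze across short tracking losses.

    A maximal run of invalid samples bounded on both sides by valid
    samples is filled when the bounding valid samples are at most
    ``max_gap_duration`` ms apart.  Filled samples get interpolated
    origin/direction (direction re-normalized) and, when both anchors
    carry a gaze point, an interpolated gaze point; they are marked valid
    and flagged in the ``gapFilled`` provenance column so downstream
    event detection can exclude them.  Edge runs and longer gaps are left
    untouched; valid samples are never modified.
    """
    ts = recording.relative_timestamps
    _check_sorted(ts)
    valid = recording.valid
    frame = recording.data.copy()
    if schema.GAP_FILLED_COLUMN not in frame.columns:
        frame[schema.GAP_FILLED_COLUMN] = np.zeros(len(frame), dtype=bool)

    origin_cols = schema.vec("gazeOrigin")
    dir_cols = schema.vec("gazeDirection")
    point_cols = schema.vec("gazePoint")
    origins = recording.origins
    directions = recording.directions
    points = recording.points
    hits = recording.point_hit

    i = 0
    n = len(frame)
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        left, right = i - 1, j
        if left >= 0 and right < n and (ts[right] - ts[left]) <= params.max_gap_duration:
            frac = (ts[i:right] - ts[left]) / (ts[right] - ts[left])
            frac = frac[:, np.newaxis]
            frame.loc[i : right - 1, origin_cols] = (
                origins[left] * (1 - frac) + origins[right] * frac
            )
            d = directions[left] * (1 - frac) + directions[right] * frac
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            frame.loc[i : right - 1, dir_cols] = d / norms
            if hits[left] and hits[right]:
                frame.loc[i : right - 1, point_cols] = (
                    points[left] * (1 - frac) + points[right] * frac
                )
                frame.loc[i : right - 1, "gazePointHit"] = True
            frame.loc[i : right - 1, "gazeHasValue"] = True
            frame.loc[i : right - 1, schema.GAP_FILLED_COLUMN] = True
        i = j
    return GazeRecording(frame, recording.metadata)


def _windowed_mean(values: np.ndarray, member: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average over rows flagged as members (shrinks at edges)."""
    window = 2 * half + 1
    kernel = np.ones(window)
    filled = np.where(member[:, np.newaxis], values, 0.0)
    out = np.empty_like(values)
    counts = np.convolve(member.astype(float), kernel, mode="same")
    for k in range(values.shape[1]):
        sums = np.convolve(filled[:, k], kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, k] = sums / counts
    return out


def _lower_median(sorted_vals: np.ndarray) -> float:
    # deterministic "lower median" for even counts
    return float(sorted_vals[(len(sorted_vals) - 1) // 2])


def _windowed_median(values: np.ndarray, member: np.ndarray, half: int) -> np.ndarray:
    n = len(values)
    out = np.full_like(values, np.nan)
    idx_members = np.flatnonzero(member)
    member_set = member
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sel = np.flatnonzero(member_set[lo:hi]) + lo
        if sel.size == 0:
            continue
        for k in range(values.shape[1]):
            out[i, k] = _lower_median(np.sort(values[sel, k]))
    return out


def noise_reduction(
    recording: GazeRecording, params: NoiseReductionParams
) -> GazeRecording:
    """Windowed mean/median filter of gaze point and direction.

    Each valid sample's gaze point and direction are replaced by the
    component-wise mean (or lower median) over the valid samples inside a
    centered window of ``params.window`` samples; the window shrinks at
    the recording edges so output length equals input length.  Directions
    are re-normalized after filtering.  Invalid samples pass through
    unchanged and never contribute to a window.  The gaze origin (head
    position) is left unfiltered.
    """
    ts = recording.relative_timestamps
    _check_sorted(ts)
    half = params.window // 2
    valid = recording.valid
    frame = recording.data.copy()

    filt = _windowed_mean if params.method == "mean" else _windowed_median

    directions = recording.directions
    dir_member = valid & ~np.isnan(directions).any(axis=1)
    new_dirs = filt(directions, dir_member, half)
    norms = np.linalg.norm(new_dirs, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        new_dirs = np.where(norms > 0, new_dirs / np.where(norms == 0, 1, norms), new_dirs)
    apply_dir = dir_member & ~np.isnan(new_dirs).any(axis=1)
    dir_cols = schema.vec("gazeDirection")
    frame.loc[apply_dir, dir_cols] = new_dirs[apply_dir]

    points = recording.points
    pt_member = valid & recording.point_hit & ~np.isnan(points).any(axis=1)
    new_pts = filt(points, pt_member, half)
    apply_pt = pt_member & ~np.isnan(new_pts).any(axis=1)
    point_cols = schema.vec("gazePoint")
    frame.loc[apply_pt, point_cols] = new_pts[apply_pt]

    return GazeRecording(frame, recording.metadata)
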