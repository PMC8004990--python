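"""Builders shared by the test modules."""

import numpy as np

from gaze3d import GazeRecording
from gaze3d import model, schema

DT_MS = 1000.0 / 30.0


def make_recording(
    points,
    ts=None,
    valid=None,
    origins=None,
    aoi_names=None,
    aoi_points=None,
) -> GazeRecording:
    """A minimal recording with the given gaze points (world frame).

    Directions are derived from origin->point; invalid samples get blank
    gaze fields.  Timestamps default to a 30 Hz grid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    ts = np.arange(n) * DT_MS if ts is None else np.asarray(ts, dtype=float)
    origins = np.zeros((n, 3)) if origins is None else np.asarray(origins, dtype=float)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)

    frame = model.empty_frame(n)
    frame["eyeDataRelativeTimestamp"] = ts
    frame["eyeDataTimestamp"] = (1_600_000_000_000 + np.round(ts)).astype(np.int64)
    frame["frameTimestamp"] = frame["eyeDataTimestamp"]
    frame["isCalibrationValid"] = True
    frame["gazeHasValue"] = valid
    frame.loc[valid, schema.vec("gazeOrigin")] = origins[valid]
    d = points - origins
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    frame.loc[valid, schema.vec("gazeDirection")] = (d / norms)[valid]
    frame.loc[valid, "gazePointHit"] = True
    frame.loc[valid, schema.vec("gazePoint")] = points[valid]
    if aoi_names is not None:
        names = np.asarray(aoi_names, dtype=object)
        frame["gazePointAOI_target_name"] = names
        has = valid & (names != "")
        frame.loc[has, "gazePointAOIHit"] = True
        pts = points if aoi_points is None else np.asarray(aoi_points, dtype=float)
        frame.loc[has, schema.vec("gazePointAOI")] = pts[has]
    return GazeRecording(frame)


def cluster_stream(cluster_dirs, samples_per_cluster, distance=2.0, jitter_deg=0.0,
                   rng=None, saccade_samples=0):
    """Gaze points for consecutive fixation clusters with linear saccades."""
    pts = []
    truth = []
    prev = None
    for ci, (az, el) in enumerate(cluster_dirs):
        center = _dir_from_angles(az, el) * distance
        if prev is not None and saccade_samples:
            for k in range(1, saccade_samples + 1):
                frac = k / (saccade_samples + 1)
                pts.append(prev * (1 - frac) + center * frac)
                truth.append(-1)
        for _ in range(samples_per_cluster):
            p = center.copy()
            if jitter_deg and rng is not None:
                p += rng.normal(0, distance * np.tan(np.radians(jitter_deg)), 3)
            pts.append(p)
            truth.append(ci)
        prev = center
    return np.asarray(pts), np.asarray(truth)


def _dir_from_angles(azimuth_deg, elevation_deg):
    az, el = np.radians(azimuth_deg), np.radians(elevation_deg)
    return np.array([np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)])
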