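"""Extending gaze samples with scene hits, AOI hits and 2D projections.

This reproduces what the recording tool does at acquisition time: for
every valid gaze sample a ray is cast from the gaze origin along the
gaze direction against the scene colliders (nearest hit wins) and,
separately, against the AOI collider layer; hits fill the gaze-point,
object-name, local-coordinate and object-pose columns, and the 3D gaze
point is projected onto the head-mounted camera image.  Display
(per-eye screen) projections are not modeled.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema
from .geometry import (
    CameraModel,
    Pose,
    SceneCollider,
    cast_ray,
    cast_rays,
    project_camera_frame,
    world_to_camera_matrix,
)
from .model import GazeRecording


def _pose_columns(prefix: str, pose: Pose) -> dict[str, float]:
    cols = {}
    for part, values in (
        ("pos", pose.position),
        ("rot", pose.rotation),
        ("scale", pose.scale),
    ):
        for axis, v in zip("xyz", values):
            cols[f"{prefix}_{part}_{axis}"] = float(v)
    return cols


def enrich_sample(
    sample: pd.Series,
    colliders: Sequence[SceneCollider],
    camera: CameraModel | None = None,
    head_pose: Pose | None = None,
    tracked: Mapping[str, Pose] | None = None,
) -> pd.Series:
    """Fill the scene/AOI/projection columns of one gaze sample row.

    The sample must carry a valid gaze (origin and direction); rows
    without one are returned unchanged apart from cleared hit flags.
    """
    row = sample.copy()
    row["gazePointHit"] = False
    row["gazePointAOIHit"] = False
    if not bool(row["gazeHasValue"]):
        return row
    origin = np.array([row[c] for c in schema.vec("gazeOrigin")], dtype=float)
    direction = np.array([row[c] for c in schema.vec("gazeDirection")], dtype=float)

    scene = [c for c in colliders if not c.is_aoi]
    hit = cast_ray(origin, direction, scene)
    if hit.hit:
        row["gazePointHit"] = True
        for axis, v in zip("xyz", hit.point):
            row[f"gazePoint_{axis}"] = float(v)
        row["gazePoint_target_name"] = hit.object_name
        for axis, v in zip("xyz", hit.local_point):
            row[f"gazePoint_target_{axis}"] = float(v)
        for col, v in _pose_columns("gazePoint_target", hit.collider.pose).items():
            row[col] = v

    aoi_hit = cast_ray(origin, direction, colliders, aoi_only=True)
    if aoi_hit.hit:
        row["gazePointAOIHit"] = True
        for axis, v in zip("xyz", aoi_hit.point):
            row[f"gazePointAOI_{axis}"] = float(v)
        row["gazePointAOI_target_name"] = aoi_hit.object_name
        for axis, v in zip("xyz", aoi_hit.local_point):
            row[f"gazePointAOI_target_{axis}"] = float(v)
        for col, v in _pose_columns("gazePointAOI_target", aoi_hit.collider.pose).items():
            row[col] = v

    if camera is not None:
        m = world_to_camera_matrix(camera, head_pose or Pose())
        for prefix, ok, point in (
            ("gazePointWebcam", hit.hit, hit.point),
            ("gazePointAOIWebcam", aoi_hit.hit, aoi_hit.point),
        ):
            if not ok:
                continue
            p_cam = m[:3, :3] @ point + m[:3, 3]
            if p_cam[2] <= 0:
                continue
            uv = project_camera_frame(p_cam[np.newaxis], camera)[0]
            row[f"{prefix}_x"] = float(uv[0])
            row[f"{prefix}_y"] = float(uv[1])
            row[f"{prefix}_z"] = float(p_cam[2])

    if tracked:
        for name, pose in tracked.items():
            for col, v in _pose_columns(f"{schema.GAME_OBJECT_PREFIX}{name}", pose).items():
                row[col] = v
    return row


def _fill_block(
    frame: pd.DataFrame,
    sel: np.ndarray,
    prefix: str,
    points: np.ndarray,
    local: np.ndarray,
    idx: np.ndarray,
    eligible: list[SceneCollider],
) -> None:
    hit_col = "gazePointAOIHit" if "AOI" in prefix else "gazePointHit"
    rows = np.flatnonzero(sel)
    frame.loc[rows, hit_col] = True
    frame.loc[rows, schema.vec(prefix)] = points[sel]
    frame.loc[rows, schema.vec(f"{prefix}_target")] = local[sel]
    for k, coll in enumerate(eligible):
        rows_k = np.flatnonzero(sel & (idx == k))
        if rows_k.size == 0:
            continue
        frame.loc[rows_k, f"{prefix}_target_name"] = coll.name
        for col, v in _pose_columns(f"{prefix}_target", coll.pose).items():
            frame.loc[rows_k, col] = v


def enrich_recording(
    recording: GazeRecording,
    colliders: Sequence[SceneCollider],
    camera: CameraModel | None = None,
    head_pose: Pose | Sequence[Pose] | None = None,
    tracked: Mapping[str, Pose] | None = None,
) -> GazeRecording:
    """Vectorized :func:`enrich_sample` over a whole recording.

    ``head_pose`` may be a single pose (static head, fully vectorized
    projection) or one pose per sample (moving head).  Colliders are
    static in the world frame for the duration of the recording.
    """
    frame = recording.data.copy()
    valid = recording.valid
    frame["gazePointHit"] = False
    frame["gazePointAOIHit"] = False
    if not valid.any():
        return GazeRecording(frame, recording.metadata)

    origins = recording.origins[valid]
    directions = recording.directions[valid]

    scene = [c for c in colliders if not c.is_aoi]
    n = len(frame)
    out = {}
    for prefix, layer, aoi_only in (
        ("gazePoint", scene, False),
        ("gazePointAOI", colliders, True),
    ):
        hit = np.zeros(n, dtype=bool)
        points = np.full((n, 3), np.nan)
        local = np.full((n, 3), np.nan)
        idx = np.full(n, -1, dtype=int)
        if layer:
            h, _, pts, loc, ix, eligible = cast_rays(
                origins, directions, layer, aoi_only=aoi_only
            )
            hit[valid] = h
            points[valid] = pts
            local[valid] = loc
            idx[valid] = ix
            _fill_block(frame, hit, prefix, points, local, idx, eligible)
        out[prefix] = (hit, points)

    if camera is not None:
        for prefix in ("gazePoint", "gazePointAOI"):
            hit, points = out[prefix]
            cam_pts = _to_camera_frame(points, hit, camera, head_pose)
            uv = np.full((n, 2), np.nan)
            front = hit & (cam_pts[:, 2] > 0)
            uv[front] = project_camera_frame(cam_pts[front], camera)
            web = "gazePointWebcam" if prefix == "gazePoint" else "gazePointAOIWebcam"
            rows = np.flatnonzero(front)
            frame.loc[rows, f"{web}_x"] = uv[front, 0]
            frame.loc[rows, f"{web}_y"] = uv[front, 1]
            frame.loc[rows, f"{web}_z"] = cam_pts[front, 2]

    if tracked:
        for name, pose in tracked.items():
            for col, v in _pose_columns(f"{schema.GAME_OBJECT_PREFIX}{name}", pose).items():
                frame[col] = v

    return GazeRecording(frame, recording.metadata)


def _to_camera_frame(points, hit, camera, head_pose) -> np.ndarray:
    n = len(points)
    cam_pts = np.full((n, 3), np.nan)
    if isinstance(head_pose, Pose) or head_pose is None:
        m = world_to_camera_matrix(camera, head_pose or Pose())
        cam_pts[hit] = points[hit] @ m[:3, :3].T + m[:3, 3]
    else:
        for i in np.flatnonzero(hit):
            m = world_to_camera_matrix(camera, head_pose[i])
            cam_pts[i] = m[:3, :3] @ points[i] + m[:3, 3]
    return cam_pts
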