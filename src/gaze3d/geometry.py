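"""Recording-side 3D geometry: poses, colliders, ray casting, projection.

Coordinate convention
---------------------
All world coordinates are in the frame the recordings were made in: a
*left-handed* system with +y up and +z forward, distances in metres.
Euler rotations are degrees applied in Z, then X, then Y order about the
world axes (the game-engine convention of the recording tool).  Most
scientific Python stacks assume right-handed frames; everything in this
module stays consistently inside the left-handed frame, so recordings
round-trip without any axis flipping.

Angles between rays are reported in degrees of visual angle, the
device-independent unit for gaze error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

_EPS = 1e-9


def _as_vec3(value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Pose


def rotation_matrix(rotation_deg: np.ndarray) -> np.ndarray:
    """3x3 rotation for Euler angles (deg) applied in Z-X-Y order.

    Matches the recording engine: yaw (+y) turns +z toward +x, pitch (+x)
    turns +z toward -y, roll (+z) turns +x toward +y.
    """
    rx, ry, rz = np.radians(np.asarray(rotation_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return my @ mx @ mz


@dataclass(frozen=True)
class Pose:
    """Position (m), Euler rotation (deg, Z-X-Y order) and scale of an object."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        object.__setattr__(self, "rotation", _as_vec3(self.rotation))
        object.__setattr__(self, "scale", _as_vec3(self.scale))
        if np.any(self.scale <= 0):
            raise ValueError("pose scale components must be > 0")

    @cached_property
    def rotation_matrix(self) -> np.ndarray:
        return rotation_matrix(self.rotation)

    @cached_property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform local -> world (scale, rotate, translate)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix * self.scale[np.newaxis, :]
        m[:3, 3] = self.position
        return m

    @cached_property
    def inverse_matrix(self) -> np.ndarray:
        inv = np.eye(4)
        rs_inv = (self.rotation_matrix / self.scale[np.newaxis, :]).T
        inv[:3, :3] = rs_inv
        inv[:3, 3] = -rs_inv @ self.position
        return inv

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.position

    def inverse_transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.position) @ self.inverse_matrix[:3, :3].T

    def transform_directions(self, dirs: np.ndarray) -> np.ndarray:
        return np.asarray(dirs, dtype=float) @ self.matrix[:3, :3].T

    def inverse_transform_directions(self, dirs: np.ndarray) -> np.ndarray:
        return np.asarray(dirs, dtype=float) @ self.inverse_matrix[:3, :3].T


# ---------------------------------------------------------------------------
# Angular distance


def angular_distance(u, v) -> Union[float, np.ndarray]:
    """Angle in degrees between vectors ``u`` and ``v`` (broadcast over rows).

    Computed from normalized vectors with the inner product clamped to
    [-1, 1]; raises for (near-)zero vectors.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < _EPS) or np.any(nv < _EPS):
        raise ValueError("angular_distance requires nonzero vectors")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


# ---------------------------------------------------------------------------
# Colliders


@dataclass(frozen=True)
class Sphere:
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")


@dataclass(frozen=True)
class Box:
    half_extents: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "half_extents", _as_vec3(self.half_extents))
        if np.any(self.half_extents <= 0):
            raise ValueError("box half-extents must be > 0")


@dataclass(frozen=True)
class Quad:
    """Rectangle in the local x-y plane (normal +z), hit from either side."""

    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("quad dimensions must be > 0")


Shape = Union[Sphere, Box, Quad]


@dataclass(frozen=True)
class SceneCollider:
    name: str
    shape: Shape
    pose: Pose = field(default_factory=Pose)
    is_aoi: bool = False


@dataclass(frozen=True)
class RayHit:
    hit: bool
    point: np.ndarray | None = None
    distance: float | None = None
    object_name: str | None = None
    local_point: np.ndarray | None = None
    collider: SceneCollider | None = None


def _intersect_local(shape: Shape, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Smallest positive ray parameter per ray in the collider local frame.

    ``o``/``d`` are (n,3) local-frame origins and (unnormalized) directions;
    because the local direction is the inverse-transformed *world unit*
    direction, the returned parameter equals the metric world distance.
    Misses are +inf.
    """
    n = o.shape[0]
    t = np.full(n, np.inf)
    if isinstance(shape, Sphere):
        a = np.sum(d * d, axis=1)
        b = 2.0 * np.sum(o * d, axis=1)
        c = np.sum(o * o, axis=1) - shape.radius**2
        disc = b * b - 4 * a * c
        ok = disc >= 0
        sq = np.sqrt(np.where(ok, disc, 0.0))
        t1 = (-b - sq) / (2 * a)
        t2 = (-b + sq) / (2 * a)
        cand = np.where(t1 > _EPS, t1, np.where(t2 > _EPS, t2, np.inf))
        t = np.where(ok, cand, np.inf)
    elif isinstance(shape, Box):
        h = shape.half_extents
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lo = (-h - o) / d
            t_hi = (h - o) / d
        near = np.minimum(t_lo, t_hi)
        far = np.maximum(t_lo, t_hi)
        # rays parallel to a slab: inside -> (-inf, inf), outside -> miss
        parallel = np.abs(d) < _EPS
        inside = np.abs(o) <= h
        near = np.where(parallel, np.where(inside, -np.inf, np.inf), near)
        far = np.where(parallel, np.where(inside, np.inf, -np.inf), far)
        tmin = near.max(axis=1)
        tmax = far.min(axis=1)
        # entry from outside only; origins inside the box do not register hits
        ok = (tmin > _EPS) & (tmin <= tmax)
        t = np.where(ok, tmin, np.inf)
    elif isinstance(shape, Quad):
        dz = d[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            tq = -o[:, 2] / dz
        x = o[:, 0] + tq * d[:, 0]
        y = o[:, 1] + tq * d[:, 1]
        ok = (
            (np.abs(dz) > _EPS)
            & (tq > _EPS)
            & (np.abs(x) <= shape.width / 2)
            & (np.abs(y) <= shape.height / 2)
        )
        t = np.where(ok, tq, np.inf)
    else:  # pragma: no cover
        raise TypeError(f"unknown shape {shape!r}")
    return t


def cast_rays(
    origins: np.ndarray,
    directions: np.ndarray,
    colliders: Sequence[SceneCollider],
    aoi_only: bool = False,
):
    """Vectorized nearest-hit ray cast of many rays against a static scene.

    Returns ``(hit, distance, point, local_point, collider_index)`` arrays.
    Directions are normalized internally so distances are metric.  Ties at
    identical distances resolve to the lowest collider index.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < _EPS):
        raise ValueError("ray direction must be nonzero")
    directions = directions / norms[:, np.newaxis]
    n = origins.shape[0]

    eligible = [c for c in colliders if c.is_aoi] if aoi_only else list(colliders)

    best_t = np.full(n, np.inf)
    best_idx = np.full(n, -1, dtype=int)
    for idx, coll in enumerate(eligible):
        o_l = coll.pose.inverse_transform_points(origins)
        d_l = coll.pose.inverse_transform_directions(directions)
        t = _intersect_local(coll.shape, o_l, d_l)
        better = t < best_t  # strict: earlier collider wins ties
        best_t = np.where(better, t, best_t)
        best_idx = np.where(better, idx, best_idx)

    hit = np.isfinite(best_t)
    points = np.full((n, 3), np.nan)
    local_points = np.full((n, 3), np.nan)
    if hit.any():
        pts = origins[hit] + best_t[hit, np.newaxis] * directions[hit]
        points[hit] = pts
        for idx, coll in enumerate(eligible):
            sel = hit & (best_idx == idx)
            if sel.any():
                local_points[sel] = coll.pose.inverse_transform_points(points[sel])
    best_t = np.where(hit, best_t, np.nan)
    return hit, best_t, points, local_points, best_idx, eligible


def cast_ray(
    origin,
    direction,
    colliders: Sequence[SceneCollider],
    aoi_only: bool = False,
) -> RayHit:
    """Nearest intersection of one gaze ray with the scene (or AOI layer)."""
    hit, t, pts, local, idx, eligible = cast_rays(
        _as_vec3(origin)[np.newaxis], _as_vec3(direction)[np.newaxis],
        colliders, aoi_only=aoi_only,
    )
    if not hit[0]:
        return RayHit(hit=False)
    coll = eligible[idx[0]]
    return RayHit(
        hit=True,
        point=pts[0],
        distance=float(t[0]),
        object_name=coll.name,
        local_point=local[0],
        collider=coll,
    )


# ---------------------------------------------------------------------------
# Camera projection


@dataclass(frozen=True)
class CameraModel:
    """Pinhole model of the headset's front-facing camera.

    The pose is head-relative.  The default intrinsics (1920x1080,
    fx=fy=1460, centered principal point) are a documented placeholder:
    the real device intrinsics are not published and should be supplied
    per use case.
    """

    pose: Pose = field(default_factory=Pose)
    resolution: tuple[int, int] = (1920, 1080)
    focal: tuple[float, float] = (1460.0, 1460.0)
    principal: tuple[float, float] = (960.0, 540.0)

    def __post_init__(self):
        if min(self.resolution) <= 0 or min(self.focal) <= 0:
            raise ValueError("camera resolution and focal length must be > 0")


@dataclass(frozen=True)
class ImagePoint:
    u: float
    v: float
    in_bounds: bool


def world_to_camera_matrix(camera: CameraModel, head_pose: Pose) -> np.ndarray:
    """4x4 world -> camera-frame transform for a head-mounted camera."""
    cam_world = head_pose.matrix @ camera.pose.matrix
    return np.linalg.inv(cam_world)


def project_camera_frame(points_cam: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Pinhole projection of (n,3) camera-frame points to (n,2) pixels.

    Points at or behind the camera plane project to NaN.  Image v runs
    downward, so +y (up) in the camera frame decreases v.
    """
    pts = np.atleast_2d(np.asarray(points_cam, dtype=float))
    z = pts[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = camera.principal[0] + camera.focal[0] * pts[:, 0] / z
        v = camera.principal[1] - camera.focal[1] * pts[:, 1] / z
    uv = np.stack([u, v], axis=1)
    uv[z <= _EPS] = np.nan
    return uv


def project_to_image(
    point, camera: CameraModel, head_pose: Pose | None = None
) -> ImagePoint | None:
    """Project a world point onto the camera image.

    Returns ``None`` for points behind the camera; out-of-frame pixels are
    returned with ``in_bounds=False``.  A point at the camera center is an
    error (the projection is undefined there).
    """
    head_pose = head_pose or Pose()
    m = world_to_camera_matrix(camera, head_pose)
    p = _as_vec3(point)
    p_cam = m[:3, :3] @ p + m[:3, 3]
    if np.linalg.norm(p_cam) < _EPS:
        raise ValueError("point coincides with the camera center")
    if p_cam[2] <= _EPS:
        return None
    uv = project_camera_frame(p_cam[np.newaxis], camera)[0]
    w, h = camera.resolution
    in_bounds = bool(0 <= uv[0] < w and 0 <= uv[1] < h)
    return ImagePoint(float(uv[0]), float(uv[1]), in_bounds)


# ---------------------------------------------------------------------------
# Scene description files


def _pose_from_dict(d: dict) -> Pose:
    return Pose(
        position=d.get("position", (0, 0, 0)),
        rotation=d.get("rotation", (0, 0, 0)),
        scale=d.get("scale", (1, 1, 1)),
    )


def _shape_from_dict(d: dict) -> Shape:
    kind = d["shape"]
    if kind == "sphere":
        return Sphere(radius=float(d["radius"]))
    if kind == "box":
        return Box(half_extents=d["half_extents"])
    if kind == "quad":
        return Quad(width=float(d["width"]), height=float(d["height"]))
    raise ValueError(f"unknown collider shape {kind!r}")


def load_scene(path) -> list[SceneCollider]:
    """Read a YAML/JSON scene description into a collider list.

    The file holds a top-level ``colliders`` list; each entry gives a name,
    a shape (``sphere``/``box``/``quad`` with its dimensions), an optional
    pose and an ``is_aoi`` flag.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    colliders = []
    for entry in doc["colliders"]:
        colliders.append(
            SceneCollider(
                name=str(entry["name"]),
                shape=_shape_from_dict(entry),
                pose=_pose_from_dict(entry.get("pose", {})),
                is_aoi=bool(entry.get("is_aoi", False)),
            )
        )
    return colliders


def save_scene(colliders: Sequence[SceneCollider], path) -> None:
    entries = []
    for c in colliders:
        d: dict = {"name": c.name, "is_aoi": c.is_aoi}
        if isinstance(c.shape, Sphere):
            d.update(shape="sphere", radius=c.shape.radius)
        elif isinstance(c.shape, Box):
            d.update(shape="box", half_extents=c.shape.half_extents.tolist())
        else:
            d.update(shape="quad", width=c.shape.width, height=c.shape.height)
        d["pose"] = {
            "position": c.pose.position.tolist(),
            "rotation": c.pose.rotation.tolist(),
            "scale": c.pose.scale.tolist(),
        }
        entries.append(d)
    Path(path).write_text(yaml.safe_dump({"colliders": entries}, sort_keys=False))
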