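"""Synthetic 30 Hz gaze streams with known ground truth.

The simulator emulates the three evaluation settings used to
characterize a head-mounted eye tracker:

* ``resting_grid`` - the wearer is still; a planar 3x3 grid of fixation
  targets is centered in front of the head, orthogonal to the forward
  direction, with edge targets at 12.13 deg and corner targets at
  18.25 deg of visual angle from the center; the wearer fixates each
  target in reading order for a fixed duration at each configured grid
  distance.
* ``walking_grid`` - identical geometry, but the head translates
  forward/backward sinusoidally and the grid moves rigidly with it.
* ``stationary_target`` - a world-fixed 1 cm sphere 15 cm above a 75 cm
  table; the head yaws left/right while the eyes counter-rotate to hold
  the fixation (vestibulo-ocular reflex).

The measured gaze direction is the true direction perturbed by one
session-constant offset rotation (calibration error, magnitude
``offset_deg`` at a random azimuth) plus per-sample isotropic angular
noise (magnitude ``|N(0, noise_sd_deg)|`` at a uniform azimuth).
Samples are ray-cast against the scene so every recorded column is
populated, and tracking dropouts, duplicated timestamps and dropped
frames can be injected.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import schema
from .enrich import enrich_recording
from .geometry import CameraModel, Pose, Quad, SceneCollider, Sphere
from .model import GazeRecording, RecordingMetadata, empty_frame
from .quality import AccuracyPrecisionResult, TargetSpec, accuracy_precision

GRID_SETTINGS = ("resting_grid", "walking_grid")
SETTINGS = GRID_SETTINGS + ("stationary_target",)

#: Reading-order target ids of the 3x3 grid.
GRID_TARGET_IDS = (
    "upper_left", "upper_center", "upper_right",
    "middle_left", "center", "middle_right",
    "lower_left", "lower_center", "lower_right",
)

_BASE_EPOCH_MS = 1_600_000_000_000
_TABLE_HEIGHT_M = 0.75
_SPHERE_ABOVE_TABLE_M = 0.15
_SPHERE_DIAMETER_M = 0.01


@dataclass(frozen=True)
class HeadMotionParams:
    """Head movement amplitudes/frequencies (documented guesses, not
    measured study values)."""

    walk_amplitude_m: float = 0.2
    walk_frequency_hz: float = 0.25
    yaw_amplitude_deg: float = 30.0
    yaw_frequency_hz: float = 0.25


@dataclass(frozen=True)
class SimulationConfig:
    setting: str = "resting_grid"
    distances: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    edge_angle_deg: float = 12.13
    corner_angle_deg: float = 18.25
    sampling_rate_hz: float = 30.0
    fixation_duration_s: float = 3.0
    saccade_duration_ms: float = 66.67
    offset_deg: float = 0.0
    noise_sd_deg: float = 0.0
    dropout_rate: float = 0.0
    duplicate_count: int = 0
    drop_frame_count: int = 0
    head_motion: HeadMotionParams = field(default_factory=HeadMotionParams)
    session_length_s: float = 60.0
    target_distance_m: float = 0.5
    aoi_radius_deg: float = 2.0
    eye_height_m: float = 1.2
    seed: int = 42
    participant: str = "sim"
    recording_name: str = ""

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not self.distances and self.setting in GRID_SETTINGS:
            raise ValueError("grid settings need at least one distance")
        for name in ("fixation_duration_s", "saccade_duration_ms", "offset_deg",
                     "noise_sd_deg", "session_length_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.setting in GRID_SETTINGS and self.target_distance_m <= 0:
            raise ValueError("target_distance_m must be > 0")


@dataclass
class GroundTruth:
    """Per-sample generative truth plus the session-level parameters.

    ``per_sample`` has one row per recorded sample: true target id,
    true fixation/saccade label, true (unperturbed) world gaze
    direction, target position relative to the gaze origin, head yaw
    and the grid distance of the block.
    """

    per_sample: pd.DataFrame
    session: dict

    def __len__(self) -> int:
        return len(self.per_sample)


def make_target_grid(
    distance: float, edge_angle_deg: float = 12.13, corner_angle_deg: float = 18.25
) -> list[TargetSpec]:
    """The 3x3 fixation-target grid on the plane z=distance (head frame).

    Eccentricities are imposed exactly: edge targets sit on the
    horizontal/vertical axes at ``edge_angle_deg`` of visual angle from
    the center, corner targets on the +-45 deg diagonals at
    ``corner_angle_deg``.  (A uniform rectangular lattice cannot satisfy
    both stated angles at once, so the grid is constructed from the
    angles, not from a lattice spacing.)
    """
    for name, ang in (("edge", edge_angle_deg), ("corner", corner_angle_deg)):
        if not 0 < ang < 80:
            raise ValueError(f"{name} angle must be in (0, 80) degrees")
    r_edge = distance * math.tan(math.radians(edge_angle_deg))
    r_corner = distance * math.tan(math.radians(corner_angle_deg)) / math.sqrt(2)
    offsets = {
        "upper_left": (-r_corner, r_corner),
        "upper_center": (0.0, r_edge),
        "upper_right": (r_corner, r_corner),
        "middle_left": (-r_edge, 0.0),
        "center": (0.0, 0.0),
        "middle_right": (r_edge, 0.0),
        "lower_left": (-r_corner, -r_corner),
        "lower_center": (0.0, -r_edge),
        "lower_right": (r_corner, -r_corner),
    }
    return [
        TargetSpec(id=tid, position=(offsets[tid][0], offsets[tid][1], distance),
                   nominal_distance=distance)
        for tid in GRID_TARGET_IDS
    ]


# ---------------------------------------------------------------------------
# direction perturbation


def _tilt(dirs: np.ndarray, angles_deg: np.ndarray, azimuths_deg: np.ndarray) -> np.ndarray:
    """Rotate each unit direction away from itself by an angle at an azimuth."""
    up = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(np.broadcast_to(up, dirs.shape), dirs)
    n1 = np.linalg.norm(e1, axis=1, keepdims=True)
    # gaze along +-y never occurs in these settings, but guard anyway
    fallback = np.array([1.0, 0.0, 0.0])
    e1 = np.where(n1 > 1e-12, e1 / np.where(n1 == 0, 1, n1), fallback)
    e2 = np.cross(dirs, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    a = np.radians(angles_deg)[:, np.newaxis]
    phi = np.radians(azimuths_deg)[:, np.newaxis]
    out = np.cos(a) * dirs + np.sin(a) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _perturb(
    dirs: np.ndarray,
    rng: np.random.Generator,
    offset_deg: float,
    offset_azimuth_deg: float,
    noise_sd_deg: float,
) -> np.ndarray:
    n = len(dirs)
    out = dirs
    if offset_deg > 0:
        out = _tilt(out, np.full(n, offset_deg), np.full(n, offset_azimuth_deg))
    if noise_sd_deg > 0:
        mags = np.abs(rng.normal(0.0, noise_sd_deg, size=n))
        azis = rng.uniform(0.0, 360.0, size=n)
        out = _tilt(out, mags, azis)
    return out


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _slerp(d0: np.ndarray, d1: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical interpolation between two unit vectors."""
    cos = float(np.clip(np.dot(d0, d1), -1.0, 1.0))
    omega = math.acos(cos)
    if omega < 1e-9:
        return np.broadcast_to(d0, (len(frac), 3)).copy()
    s = np.sin((1 - frac) * omega)[:, np.newaxis] * d0 + np.sin(frac * omega)[
        :, np.newaxis
    ] * d1
    return s / np.linalg.norm(s, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# session assembly


def _base_frame(n: int, rel_ts: np.ndarray) -> pd.DataFrame:
    frame = empty_frame(n)
    frame["eyeDataRelativeTimestamp"] = np.round(rel_ts, 4)  # 100 ns clock
    frame["eyeDataTimestamp"] = _BASE_EPOCH_MS + np.round(rel_ts).astype(np.int64)
    frame["frameTimestamp"] = frame["eyeDataTimestamp"] + 11
    frame["isCalibrationValid"] = True
    return frame


def _apply_dropout(frame: pd.DataFrame, gt: pd.DataFrame, rate: float,
                   rng: np.random.Generator) -> None:
    n = len(frame)
    k = int(math.floor(rate * n))
    if k == 0:
        return
    drop = rng.choice(n, size=k, replace=False)
    frame.loc[drop, "gazeHasValue"] = False
    frame.loc[drop, "gazePointHit"] = False
    frame.loc[drop, "gazePointAOIHit"] = False
    float_cols = [c for c in schema.FLOAT_COLUMNS if c not in schema.TIME_COLUMNS]
    frame.loc[drop, float_cols] = np.nan
    frame.loc[drop, ["gazePoint_target_name", "gazePointAOI_target_name"]] = ""
    gt.loc[drop, "dropout"] = True


def _apply_timestamp_faults(
    frame: pd.DataFrame, gt: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    n = len(frame)
    faults: dict = {"dropped_frame_indices": [], "duplicate_indices": []}
    keep = np.arange(n)
    if config.drop_frame_count > 0:
        interior = np.arange(1, n - 1)
        dropped = np.sort(rng.choice(interior, size=config.drop_frame_count, replace=False))
        faults["dropped_frame_indices"] = dropped.tolist()
        keep = np.setdiff1d(keep, dropped)
    order = list(keep)
    if config.duplicate_count > 0:
        m = len(order)
        pos = np.sort(rng.choice(np.arange(1, m), size=config.duplicate_count, replace=False))
        for shift, p in enumerate(pos):
            order.insert(int(p) + shift, order[int(p) + shift])
        faults["duplicate_indices"] = [int(p) for p in pos]
    frame = frame.iloc[order].reset_index(drop=True)
    gt = gt.iloc[order].reset_index(drop=True)
    return frame, gt, faults


def _finalize(
    frame: pd.DataFrame,
    gt_frame: pd.DataFrame,
    session: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GazeRecording, GroundTruth]:
    gt_frame = gt_frame.copy()
    gt_frame["dropout"] = False
    _apply_dropout(frame, gt_frame, config.dropout_rate, rng)
    frame, gt_frame, faults = _apply_timestamp_faults(frame, gt_frame, config, rng)
    session = dict(session, **faults)
    metadata = RecordingMetadata(
        participant=config.participant,
        recording_name=config.recording_name or config.setting,
        start_time=int(frame["eyeDataTimestamp"].iloc[0]) if len(frame) else 0,
        stop_time=int(frame["eyeDataTimestamp"].iloc[-1]) if len(frame) else 0,
    )
    return GazeRecording(frame, metadata), GroundTruth(gt_frame, session)


def simulate_recording(config: SimulationConfig) -> tuple[GazeRecording, GroundTruth]:
    """Generate a full synthetic session for the configured setting.

    Deterministic given ``config.seed``.  Grid settings produce one
    block per configured distance (fixating the nine targets in reading
    order, joined by minimum-jerk saccades); the stationary-target
    setting delegates to :func:`simulate_vor_session`.
    """
    if config.setting == "stationary_target":
        return simulate_vor_session(config)
    return _simulate_grid(config)


def _simulate_grid(config: SimulationConfig) -> tuple[GazeRecording, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    offset_azimuth = float(rng.uniform(0.0, 360.0))
    dt_ms = 1000.0 / config.sampling_rate_hz
    n_fix = max(1, round(config.fixation_duration_s * config.sampling_rate_hz))
    n_sac = int(round(config.saccade_duration_ms / dt_ms))

    head = np.array([0.0, config.eye_height_m, 0.0])

    # head-frame truth for the whole session
    dirs: list[np.ndarray] = []
    labels: list[str] = []
    target_ids: list[str] = []
    target_pos: list[np.ndarray] = []
    distances: list[float] = []

    prev_dir: np.ndarray | None = None
    block_slices = []
    colliders_per_block = []
    for d in config.distances:
        targets = make_target_grid(d, config.edge_angle_deg, config.corner_angle_deg)
        aoi_radius = d * math.tan(math.radians(config.aoi_radius_deg))
        half_w = d * math.tan(math.radians(config.corner_angle_deg)) + 0.5
        block_colliders = [
            SceneCollider(
                name=f"grid_plane_{d:g}m",
                shape=Quad(width=2 * half_w, height=2 * half_w),
                pose=Pose(position=(0.0, 0.0, d)),
            )
        ] + [
            SceneCollider(
                name=f"aoi_{t.id}",
                shape=Sphere(radius=aoi_radius),
                pose=Pose(position=t.position),
                is_aoi=True,
            )
            for t in targets
        ]
        start_idx = len(dirs)
        for t in targets:
            t_dir = t.position / np.linalg.norm(t.position)
            if prev_dir is not None and n_sac > 0:
                tau = (np.arange(n_sac) + 1.0) / (n_sac + 1.0)
                for sdir in _slerp(prev_dir, t_dir, _minimum_jerk(tau)):
                    dirs.append(sdir)
                    labels.append("saccade")
                    target_ids.append("")
                    target_pos.append(np.full(3, np.nan))
                    distances.append(d)
            for _ in range(n_fix):
                dirs.append(t_dir)
                labels.append("fixation")
                target_ids.append(t.id)
                target_pos.append(t.position)
                distances.append(d)
            prev_dir = t_dir
        block_slices.append((start_idx, len(dirs)))
        colliders_per_block.append(block_colliders)

    n = len(dirs)
    true_dirs = np.asarray(dirs)
    measured = _perturb(true_dirs, rng, config.offset_deg, offset_azimuth,
                        config.noise_sd_deg)
    rel_ts = np.arange(n) * dt_ms
    frame = _base_frame(n, rel_ts)
    frame["gazeHasValue"] = True
    # cast in the head frame (grid rigid with the head): origin at zero
    frame[schema.vec("gazeOrigin")] = 0.0
    frame[schema.vec("gazeDirection")] = measured

    camera = CameraModel()
    rec = GazeRecording(frame, RecordingMetadata())
    pieces = []
    for (lo, hi), block_colliders in zip(block_slices, colliders_per_block):
        sub = GazeRecording(rec.data.iloc[lo:hi].reset_index(drop=True))
        pieces.append(enrich_recording(sub, block_colliders, camera=camera).data)
    frame = pd.concat(pieces, ignore_index=True)

    # translate the head frame to the world frame
    t_s = rel_ts / 1000.0
    if config.setting == "walking_grid":
        hm = config.head_motion
        walk = hm.walk_amplitude_m * np.sin(2 * np.pi * hm.walk_frequency_hz * t_s)
        head_pos = head[np.newaxis, :] + np.stack(
            [np.zeros(n), np.zeros(n), walk], axis=1
        )
    else:
        head_pos = np.broadcast_to(head, (n, 3)).copy()
    for prefix in ("gazeOrigin", "gazePoint", "gazePointAOI",
                   "gazePoint_target_pos", "gazePointAOI_target_pos"):
        cols = schema.vec(prefix)
        vals = frame[cols].to_numpy(dtype=float)
        present = ~np.isnan(vals).any(axis=1)
        vals[present] += head_pos[present]
        frame[cols] = vals

    gt_frame = pd.DataFrame(
        {
            "true_target_id": target_ids,
            "true_label": labels,
            "true_dir_x": true_dirs[:, 0],
            "true_dir_y": true_dirs[:, 1],
            "true_dir_z": true_dirs[:, 2],
            "true_target_x": [p[0] for p in target_pos],
            "true_target_y": [p[1] for p in target_pos],
            "true_target_z": [p[2] for p in target_pos],
            "head_yaw_deg": 0.0,
            "distance_m": distances,
        }
    )
    session = {
        "setting": config.setting,
        "offset_deg": config.offset_deg,
        "offset_azimuth_deg": offset_azimuth,
        "noise_sd_deg": config.noise_sd_deg,
        "distances": list(config.distances),
        "sampling_rate_hz": config.sampling_rate_hz,
    }
    return _finalize(frame, gt_frame, session, config, rng)


def simulate_vor_session(config: SimulationConfig) -> tuple[GazeRecording, GroundTruth]:
    """Stationary-target session with vestibulo-ocular head yaw.

    A 1 cm sphere sits 15 cm above a 75 cm table, world-fixed; the head
    yaws sinusoidally about the target bearing while the eyes hold the
    fixation, so the recorded world gaze direction stays on the sphere.
    The configured head-to-sphere distance is reproduced exactly (the
    head rotates in place).  Scene colliders: the AOI sphere itself plus
    a large backing plane through the sphere center facing the wearer,
    which catches the noisy gaze rays like the tabletop scene does.
    """
    if config.setting != "stationary_target":
        raise ValueError("simulate_vor_session requires setting='stationary_target'")
    rng = np.random.default_rng(config.seed)
    offset_azimuth = float(rng.uniform(0.0, 360.0))
    dt_ms = 1000.0 / config.sampling_rate_hz
    n = max(2, round(config.session_length_s * config.sampling_rate_hz))

    head = np.array([0.0, config.eye_height_m, 0.0])
    sphere_y = _TABLE_HEIGHT_M + _SPHERE_ABOVE_TABLE_M
    dy = config.eye_height_m - sphere_y
    if config.target_distance_m <= abs(dy):
        raise ValueError("target_distance_m too small for the table geometry")
    z0 = math.sqrt(config.target_distance_m**2 - dy**2)
    center = np.array([0.0, sphere_y, z0])

    bearing = center - head
    bearing_dir = bearing / np.linalg.norm(bearing)
    pitch_deg = math.degrees(math.asin(-bearing_dir[1]))
    yaw0_deg = math.degrees(math.atan2(bearing_dir[0], bearing_dir[2]))

    t_s = np.arange(n) * dt_ms / 1000.0
    hm = config.head_motion
    yaw = yaw0_deg + hm.yaw_amplitude_deg * np.sin(2 * np.pi * hm.yaw_frequency_hz * t_s)

    true_dirs = np.broadcast_to(bearing_dir, (n, 3)).copy()
    measured = _perturb(true_dirs, rng, config.offset_deg, offset_azimuth,
                        config.noise_sd_deg)

    colliders = [
        SceneCollider(
            name="backing_plane",
            shape=Quad(width=2.0, height=2.0),
            pose=Pose(position=center, rotation=(pitch_deg, yaw0_deg, 0.0)),
        ),
        SceneCollider(
            name="stationary_target",
            shape=Sphere(radius=_SPHERE_DIAMETER_M / 2),
            pose=Pose(position=center),
            is_aoi=True,
        ),
    ]

    frame = _base_frame(n, np.arange(n) * dt_ms)
    frame["gazeHasValue"] = True
    frame[schema.vec("gazeOrigin")] = np.broadcast_to(head, (n, 3))
    frame[schema.vec("gazeDirection")] = measured
    head_poses = [Pose(position=head, rotation=(0.0, y, 0.0)) for y in yaw]
    rec = enrich_recording(
        GazeRecording(frame, RecordingMetadata()),
        colliders,
        camera=CameraModel(),
        head_pose=head_poses,
    )
    frame = rec.data

    gt_frame = pd.DataFrame(
        {
            "true_target_id": "stationary_target",
            "true_label": "fixation",
            "true_dir_x": true_dirs[:, 0],
            "true_dir_y": true_dirs[:, 1],
            "true_dir_z": true_dirs[:, 2],
            "true_target_x": center[0] - head[0],
            "true_target_y": center[1] - head[1],
            "true_target_z": center[2] - head[2],
            "head_yaw_deg": yaw - yaw0_deg,
            "distance_m": config.target_distance_m,
        }
    )
    session = {
        "setting": config.setting,
        "offset_deg": config.offset_deg,
        "offset_azimuth_deg": offset_azimuth,
        "noise_sd_deg": config.noise_sd_deg,
        "target_distance_m": config.target_distance_m,
        "sphere_center": center.tolist(),
        "sampling_rate_hz": config.sampling_rate_hz,
    }
    return _finalize(frame, gt_frame, session, config, rng)


# ---------------------------------------------------------------------------
# evaluation against ground truth


def evaluate_against_ground_truth(
    recording: GazeRecording,
    ground_truth: GroundTruth,
    angle_mode: str = "per_sample",
    precision_mode: str = "sd",
) -> list[AccuracyPrecisionResult]:
    """Per-target accuracy/precision using the simulator's true labels.

    Saccade-labeled, dropout and invalid samples are excluded (the
    simulation stand-in for manual saccade annotation).  Metrics are
    computed in the head frame - gaze points relative to the per-sample
    gaze origin - so that grid targets, which move rigidly with the
    head, have a fixed position.  One result per (distance, target).
    """
    gt = ground_truth.per_sample
    if len(gt) != len(recording):
        raise ValueError("ground truth and recording lengths differ")
    usable = (
        recording.valid
        & recording.point_hit
        & (gt["true_label"] == "fixation").to_numpy()
        & ~gt["dropout"].to_numpy(dtype=bool)
    )
    points_h = recording.points - recording.origins
    results = []
    for (dist, tid), grp in gt[usable].groupby(["distance_m", "true_target_id"], sort=True):
        idx = grp.index.to_numpy()
        target = TargetSpec(
            id=str(tid),
            position=grp[["true_target_x", "true_target_y", "true_target_z"]].iloc[0],
            nominal_distance=float(dist),
        )
        results.append(
            accuracy_precision(
                points_h[idx],
                np.zeros((len(idx), 3)),
                target,
                angle_mode=angle_mode,
                precision_mode=precision_mode,
            )
        )
    return results


def write_ground_truth(ground_truth: GroundTruth, path) -> None:
    ground_truth.per_sample.to_csv(path, index=False, lineterminator="\n")


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["distances"] = list(config.distances)
    return d
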