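"""Gaze data-quality metrics: spatial accuracy and precision.

Per fixation target, spatial accuracy is the systematic error of the
gaze estimate and spatial precision the dispersion of the individual
samples.  Both are reported in centimetres (3D distances in the world
frame) and in degrees of visual angle (angles at the gaze origin):

* accuracy (cm), offset ``O``: Euclidean distance between the mean gaze
  point and the target position;
* accuracy (deg): mean over samples of the visual angle between the ray
  origin->gaze point and the ray origin->target (a centroid variant -
  the angle of the mean gaze point - is available for sensitivity
  checks and converges to the pure systematic offset as n grows);
* precision (cm), ``sigma``: standard deviation of the per-sample
  distances to the mean gaze point (RMS optional);
* precision (deg): the same statistic on the per-sample visual angles
  to the mean gaze point.

For sessions where the head-to-target distance varies, the small-angle
conversion ``theta = atan(O / d)`` with the mean gaze distance ``d``
approximates the angular error from the cm values.

The minimum target size such that ~95% of gaze samples land on the
target follows the 2D-Gaussian rule ``S = 2 (O + 2 sigma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up
from .geometry import angular_distance

M_TO_CM = 100.0


@dataclass(frozen=True)
class TargetSpec:
    """A fixation target in the world frame (position in metres)."""

    id: str
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    nominal_distance: float | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass
class AccuracyPrecisionResult:
    """Per-target accuracy/precision in cm and degrees of visual angle."""

    target_id: str = ""
    n_samples: int = 0
    accuracy_cm: float = 0.0
    accuracy_deg: float = 0.0
    precision_cm: float = 0.0
    precision_deg: float = 0.0
    mean_distance_cm: float = 0.0
    approx_accuracy_deg: float = 0.0
    approx_precision_deg: float = 0.0


@dataclass(frozen=True)
class TargetSizeRecommendation:
    minimum_size_cm: float
    accuracy_cm: float
    precision_cm: float


def accuracy_precision(
    points: np.ndarray,
    origins: np.ndarray,
    target: TargetSpec,
    angle_mode: str = "per_sample",
    precision_mode: str = "sd",
) -> AccuracyPrecisionResult:
    """Accuracy and precision of gaze samples against one target.

    ``points``/``origins`` are (n, 3) world-frame gaze points and gaze
    origins (metres) of the samples attributed to the target, with
    saccade samples already removed.  ``angle_mode`` selects the angular
    accuracy convention (``per_sample`` mean of per-ray angles, or
    ``centroid`` angle of the mean gaze point); ``precision_mode``
    selects SD (default) or RMS dispersion.  Requires n >= 2.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    if len(points) < 2:
        raise ValueError("accuracy/precision require at least 2 samples")
    if angle_mode not in ("per_sample", "centroid"):
        raise ValueError("angle_mode must be 'per_sample' or 'centroid'")
    if precision_mode not in ("sd", "rms"):
        raise ValueError("precision_mode must be 'sd' or 'rms'")

    mean_point = points.mean(axis=0)
    mean_origin = origins.mean(axis=0)
    accuracy_cm = float(np.linalg.norm(mean_point - target.position)) * M_TO_CM

    if angle_mode == "per_sample":
        angles = angular_distance(points - origins, target.position - origins)
        accuracy_deg = float(np.mean(angles))
    else:
        accuracy_deg = float(
            angular_distance(mean_point - mean_origin, target.position - mean_origin)
        )

    dists_cm = np.linalg.norm(points - mean_point, axis=1) * M_TO_CM
    ang_disp = angular_distance(points - origins, mean_point - origins)
    if precision_mode == "sd":
        precision_cm = float(np.std(dists_cm, ddof=1))
        precision_deg = float(np.std(ang_disp, ddof=1))
    else:
        precision_cm = float(np.sqrt(np.mean(dists_cm**2)))
        precision_deg = float(np.sqrt(np.mean(ang_disp**2)))

    mean_distance_cm = float(
        np.mean(np.linalg.norm(points - mean_origin, axis=1)) * M_TO_CM
    )
    return AccuracyPrecisionResult(
        target_id=target.id,
        n_samples=len(points),
        accuracy_cm=accuracy_cm,
        accuracy_deg=accuracy_deg,
        precision_cm=precision_cm,
        precision_deg=precision_deg,
        mean_distance_cm=mean_distance_cm,
        approx_accuracy_deg=small_angle_accuracy(accuracy_cm, mean_distance_cm),
        approx_precision_deg=small_angle_accuracy(precision_cm, mean_distance_cm),
    )


def small_angle_accuracy(value_cm: float, mean_distance_cm: float) -> float:
    """Angular error (deg) from a cm offset at mean viewing distance d.

    ``theta = atan(O / d)``; the same conversion applies to precision by
    passing the cm precision as the offset.
    """
    if mean_distance_cm <= 0:
        raise ValueError("mean distance must be > 0")
    if value_cm < 0:
        raise ValueError("offset must be >= 0")
    return math.degrees(math.atan(value_cm / mean_distance_cm))


def minimum_target_size(accuracy_cm: float, precision_cm: float) -> float:
    """Minimum target size (cm) so ~95% of gaze samples hit the target.

    ``S = 2 (O + 2 sigma)`` with accuracy offset ``O`` and precision
    ``sigma``, both in cm (2D-Gaussian 95% coverage rule).
    """
    if accuracy_cm < 0 or precision_cm < 0:
        raise ValueError("accuracy and precision must be >= 0")
    return 2.0 * (accuracy_cm + 2.0 * precision_cm)


def recommend_target_size(
    accuracy_cm: float, precision_cm: float
) -> TargetSizeRecommendation:
    return TargetSizeRecommendation(
        minimum_size_cm=minimum_target_size(accuracy_cm, precision_cm),
        accuracy_cm=accuracy_cm,
        precision_cm=precision_cm,
    )


def summarize_over_distances(
    results: list[AccuracyPrecisionResult],
) -> tuple[float, float]:
    """Unweighted mean angular accuracy/precision over per-distance results.

    Values are rounded half-up to two decimals, the report-table
    convention.
    """
    if not results:
        raise ValueError("cannot summarize an empty result list")
    acc = [r.accuracy_deg for r in results]
    prec = [r.precision_deg for r in results]
    return (
        round_half_up(float(np.mean(acc)), 2),
        round_half_up(float(np.mean(prec)), 2),
    )
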