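"""Column registry for the gaze-sample CSV schema.

One gaze sample per row.  Vector-valued quantities are stored as three
columns suffixed ``_x``/``_y``/``_z``; poses as ``_pos``/``_rot``/``_scale``
triples of those.  Dynamic per-object columns follow the
``gameObject_<name>_(pos|rot|scale)_(x|y|z)`` pattern and are appended
between the AOI block and ``info``.
"""

from __future__ import annotations


def vec(prefix: str) -> list[str]:
    return [f"{prefix}_{axis}" for axis in "xyz"]


def pose_cols(prefix: str) -> list[str]:
    return [c for part in ("pos", "rot", "scale") for c in vec(f"{prefix}_{part}")]


TIME_COLUMNS = [
    "eyeDataTimestamp",
    "eyeDataRelativeTimestamp",
    "frameTimestamp",
]

GAZE_COLUMNS = (
    ["isCalibrationValid", "gazeHasValue"]
    + vec("gazeOrigin")
    + vec("gazeDirection")
    + ["gazePointHit"]
    + vec("gazePoint")
    + ["gazePoint_target_name"]
    + vec("gazePoint_target")
    + pose_cols("gazePoint_target")
    + vec("gazePointLeftScreen")
    + vec("gazePointRightScreen")
    + vec("gazePointMonoScreen")
    + vec("gazePointWebcam")
)

AOI_COLUMNS = (
    ["gazePointAOIHit"]
    + vec("gazePointAOI")
    + ["gazePointAOI_target_name"]
    + vec("gazePointAOI_target")
    + pose_cols("gazePointAOI_target")
    + vec("gazePointAOIWebcam")
)

#: Fixed columns in canonical file order (dynamic gameObject_* columns are
#: inserted before ``info`` when written).
TABLE_COLUMNS = TIME_COLUMNS + GAZE_COLUMNS + AOI_COLUMNS + ["info"]

BOOL_COLUMNS = ["isCalibrationValid", "gazeHasValue", "gazePointHit", "gazePointAOIHit"]
TEXT_COLUMNS = ["gazePoint_target_name", "gazePointAOI_target_name", "info"]
INT_COLUMNS = ["eyeDataTimestamp", "frameTimestamp"]
FLOAT_COLUMNS = [
    c
    for c in TABLE_COLUMNS
    if c not in BOOL_COLUMNS + TEXT_COLUMNS + INT_COLUMNS
]

#: Columns a file must contain to be loadable at all.
MANDATORY_COLUMNS = TIME_COLUMNS + ["gazeHasValue"]

#: Provenance flag added by preprocessing (not part of the recorded schema).
GAP_FILLED_COLUMN = "gapFilled"

GAME_OBJECT_PREFIX = "gameObject_"
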