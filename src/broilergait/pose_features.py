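"""The seven leg pose features.

Six features are measured on double-support poses and one (relative step
height) on maximum-leg-lift poses.  Lengths and the step height are
expressed relative to a per-frame normalization factor N — the vertical
pixel distance between the highest knee and the lowest foot — which makes
every feature invariant to translation and to uniform scaling of the
image, so features are comparable across ages and camera distances.

Features
--------
hock_joint_angle        interior knee-hock-foot angle, degrees (per side)
shank_floor_angle       medial angle of the shank (foot->hock) with the
                        horizontal toward the body midline, degrees (per side)
tibiotarsus_rel_length  |knee-hock| / N (per side)
shank_rel_length        |hock-foot| / N (per side)
hock_knee_ratio         horizontal hock spacing / horizontal knee spacing
hock_feet_ratio         horizontal hock spacing / horizontal feet spacing
step_height_rel         100 x (y_grounded_foot - y_lifted_foot) / N, percent
"""

from __future__ import annotations

import math
import warnings
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import DegeneratePoseError
from .keypoint_io import BodyPart
from .pose_extraction import Pose, PoseSet


class Feature(str, Enum):
    HOCK_JOINT_ANGLE = "hock_joint_angle"
    SHANK_FLOOR_ANGLE = "shank_floor_angle"
    TIBIOTARSUS_REL_LENGTH = "tibiotarsus_rel_length"
    SHANK_REL_LENGTH = "shank_rel_length"
    HOCK_KNEE_RATIO = "hock_knee_ratio"
    HOCK_FEET_RATIO = "hock_feet_ratio"
    STEP_HEIGHT_REL = "step_height_rel"


#: features carrying a left/right side
SIDED_FEATURES = (
    Feature.HOCK_JOINT_ANGLE,
    Feature.SHANK_FLOOR_ANGLE,
    Feature.TIBIOTARSUS_REL_LENGTH,
    Feature.SHANK_REL_LENGTH,
    Feature.STEP_HEIGHT_REL,
)
UNSIDED_FEATURES = (Feature.HOCK_KNEE_RATIO, Feature.HOCK_FEET_RATIO)

_SIDE_PARTS = {
    "left": (BodyPart.KNEE_LEFT, BodyPart.HOCK_LEFT, BodyPart.FOOT_LEFT),
    "right": (BodyPart.KNEE_RIGHT, BodyPart.HOCK_RIGHT, BodyPart.FOOT_RIGHT),
}


def normalization_factor(pose: Pose) -> float:
    """Vertical px distance between the highest knee and the lowest foot.

    y grows downward, so this is max(foot y) - min(knee y); a
    non-positive value means knees at or below feet and is rejected.
    """
    feet_y = [pose.point(BodyPart.FOOT_LEFT)[1], pose.point(BodyPart.FOOT_RIGHT)[1]]
    knee_y = [pose.point(BodyPart.KNEE_LEFT)[1], pose.point(BodyPart.KNEE_RIGHT)[1]]
    n = max(feet_y) - min(knee_y)
    if not n > 0:
        raise DegeneratePoseError(
            f"frame {pose.frame_index}: normalization factor {n:.3f} px <= 0"
        )
    return float(n)


def hock_joint_angle(pose: Pose, side: str) -> float:
    """Interior angle at the hock between hock->knee and hock->foot, degrees."""
    knee, hock, foot = (pose.point(p) for p in _SIDE_PARTS[side])
    v1 = knee - hock
    v2 = foot - hock
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegeneratePoseError(
            f"frame {pose.frame_index}: zero-length leg segment on {side}"
        )
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def shank_floor_angle(pose: Pose, side: str) -> float:
    """Medial angle between the shank (foot->hock) and the horizontal, degrees.

    The horizontal reference points from the foot toward the body midline
    (the mean x of the two feet), so a vertical shank reads 90 deg and a
    hock medial of its foot reads < 90 deg.
    """
    _, hock, foot = (pose.point(p) for p in _SIDE_PARTS[side])
    x_l = pose.point(BodyPart.FOOT_LEFT)[0]
    x_r = pose.point(BodyPart.FOOT_RIGHT)[0]
    if math.isclose(x_l, x_r, abs_tol=1e-9):
        raise DegeneratePoseError(
            f"frame {pose.frame_index}: feet coincide in x, midline undefined"
        )
    midline_x = 0.5 * (x_l + x_r)
    toward_mid = np.array([math.copysign(1.0, midline_x - foot[0]), 0.0])
    shank = hock - foot
    norm = np.linalg.norm(shank)
    if norm == 0:
        raise DegeneratePoseError(
            f"frame {pose.frame_index}: zero-length shank on {side}"
        )
    cosang = float(np.clip(np.dot(shank, toward_mid) / norm, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def relative_segment_lengths(pose: Pose, side: str) -> tuple[float, float]:
    """(tibiotarsus, shank) lengths relative to the normalization factor."""
    n = normalization_factor(pose)
    knee, hock, foot = (pose.point(p) for p in _SIDE_PARTS[side])
    tib = float(np.linalg.norm(knee - hock)) / n
    shank = float(np.linalg.norm(hock - foot)) / n
    return tib, shank


def _x_spread(pose: Pose, left: BodyPart, right: BodyPart) -> float:
    return abs(pose.point(left)[0] - pose.point(right)[0])


def hock_knee_ratio(pose: Pose) -> float:
    """Horizontal hock spacing over horizontal knee spacing (HKDR)."""
    knees = _x_spread(pose, BodyPart.KNEE_LEFT, BodyPart.KNEE_RIGHT)
    if knees == 0:
        raise DegeneratePoseError(f"frame {pose.frame_index}: knees coincide in x")
    return _x_spread(pose, BodyPart.HOCK_LEFT, BodyPart.HOCK_RIGHT) / knees


def hock_feet_ratio(pose: Pose) -> float:
    """Horizontal hock spacing over horizontal feet spacing (HFDR)."""
    feet = _x_spread(pose, BodyPart.FOOT_LEFT, BodyPart.FOOT_RIGHT)
    if feet == 0:
        raise DegeneratePoseError(f"frame {pose.frame_index}: feet coincide in x")
    return _x_spread(pose, BodyPart.HOCK_LEFT, BodyPart.HOCK_RIGHT) / feet


def step_height(pose: Pose) -> float:
    """Normalized step height in percent, on a maximum-leg-lift pose.

    The lifted foot is the pose's step side; the value is
    100 x (y_grounded - y_lifted) / N with N from the same frame.  A
    negative value (lifted foot below the grounded one) indicates a
    mis-selected candidate and is returned with a warning.
    """
    if pose.kind not in ("step_left", "step_right"):
        raise DegeneratePoseError(
            f"step_height needs a step pose, got kind {pose.kind!r}"
        )
    lifted_side = pose.kind.removeprefix("step_")
    lifted = pose.point(_SIDE_PARTS[lifted_side][2])
    grounded_side = "right" if lifted_side == "left" else "left"
    grounded = pose.point(_SIDE_PARTS[grounded_side][2])
    n = normalization_factor(pose)
    value = 100.0 * (grounded[1] - lifted[1]) / n
    if value < 0:
        warnings.warn(
            f"frame {pose.frame_index}: lifted foot below grounded foot "
            f"({value:.2f}%); candidate may be mis-selected",
            stacklevel=2,
        )
    return float(value)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _pose_values(pose: Pose) -> list[tuple[Feature, str, float]]:
    vals: list[tuple[Feature, str, float]] = []
    if pose.kind == "double_support":
        for side in ("left", "right"):
            vals.append((Feature.HOCK_JOINT_ANGLE, side, hock_joint_angle(pose, side)))
            vals.append((Feature.SHANK_FLOOR_ANGLE, side, shank_floor_angle(pose, side)))
            tib, shank = relative_segment_lengths(pose, side)
            vals.append((Feature.TIBIOTARSUS_REL_LENGTH, side, tib))
            vals.append((Feature.SHANK_REL_LENGTH, side, shank))
        vals.append((Feature.HOCK_KNEE_RATIO, "none", hock_knee_ratio(pose)))
        vals.append((Feature.HOCK_FEET_RATIO, "none", hock_feet_ratio(pose)))
    else:
        side = pose.kind.removeprefix("step_")
        vals.append((Feature.STEP_HEIGHT_REL, side, step_height(pose)))
    return vals


def aggregate_features(poseset: PoseSet) -> pd.DataFrame:
    """Average each feature over the selected frames of one bird-age.

    Returns the analysis-unit records with columns bird_id, age_days,
    feature, side, value, n_frames_used.  A pose whose geometry is
    degenerate for some feature contributes nothing to that feature; pose
    kinds with no selected frames yield no records at all.
    """
    acc: dict[tuple[str, str], list[float]] = {}
    for pose in poseset.all_poses():
        try:
            values = _pose_values(pose)
        except DegeneratePoseError:
            warnings.warn(
                f"bird {poseset.bird_id} frame {pose.frame_index}: degenerate "
                f"{pose.kind} pose skipped",
                stacklevel=2,
            )
            continue
        for feature, side, value in values:
            acc.setdefault((feature.value, side), []).append(value)

    rows = [
        {
            "bird_id": poseset.bird_id,
            "age_days": poseset.age_days,
            "feature": feature,
            "side": side,
            "value": float(np.mean(vals)),
            "n_frames_used": len(vals),
        }
        for (feature, side), vals in acc.items()
    ]
    return pd.DataFrame(
        rows,
        columns=["bird_id", "age_days", "feature", "side", "value", "n_frames_used"],
    )
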