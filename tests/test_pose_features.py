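"""Feature geometry against independent trigonometric/arithmetic oracles,
plus the invariances every feature must satisfy (translation, scale,
left-right mirror)."""

import math

import numpy as np
import pytest

from broilergait import (
    BodyPart,
    DegeneratePoseError,
    Pose,
    PoseSet,
    aggregate_features,
    hock_feet_ratio,
    hock_joint_angle,
    hock_knee_ratio,
    normalization_factor,
    relative_segment_lengths,
    shank_floor_angle,
    step_height,
)

L = BodyPart


def make_pose(knee_l, knee_r, hock_l, hock_r, foot_l, foot_r,
              kind="double_support", frame=0):
    return Pose(frame_index=frame, kind=kind, coords={
        L.KNEE_LEFT: knee_l, L.KNEE_RIGHT: knee_r,
        L.HOCK_LEFT: hock_l, L.HOCK_RIGHT: hock_r,
        L.FOOT_LEFT: foot_l, L.FOOT_RIGHT: foot_r,
    })


def random_pose(rng, kind="double_support"):
    """A physically plausible rear-view pose with randomised geometry."""
    mid = rng.uniform(300, 900)
    ground = rng.uniform(400, 650)
    spread = rng.uniform(60, 160)
    coords = {}
    for sign, side in ((-1, "l"), (1, "r")):
        foot = (mid + sign * spread / 2 + rng.normal(0, 3), ground + rng.normal(0, 3))
        hock = (foot[0] - sign * rng.uniform(2, 20), foot[1] - rng.uniform(40, 80))
        knee = (hock[0] + sign * rng.uniform(5, 35), hock[1] - rng.uniform(45, 85))
        coords[side] = (knee, hock, foot)
    return make_pose(coords["l"][0], coords["r"][0], coords["l"][1],
                     coords["r"][1], coords["l"][2], coords["r"][2], kind=kind)


def oracle_angle(a, vertex, b):
    """Interior angle via atan2 of the two rays (independent of arccos path)."""
    a1 = math.atan2(a[1] - vertex[1], a[0] - vertex[0])
    a2 = math.atan2(b[1] - vertex[1], b[0] - vertex[0])
    d = abs(a1 - a2) % (2 * math.pi)
    return math.degrees(min(d, 2 * math.pi - d))


class TestNormalizationFactor:
    def test_worked_example(self):
        pose = make_pose((100, 200), (160, 205), (110, 260), (150, 262),
                         (105, 330), (155, 330))
        assert normalization_factor(pose) == pytest.approx(130.0)

    def test_inverted_pose_rejected(self):
        pose = make_pose((100, 400), (160, 400), (110, 350), (150, 350),
                         (105, 300), (155, 300))
        with pytest.raises(DegeneratePoseError):
            normalization_factor(pose)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            pose = random_pose(rng)
            ys_feet = [pose.coords[L.FOOT_LEFT][1], pose.coords[L.FOOT_RIGHT][1]]
            ys_knee = [pose.coords[L.KNEE_LEFT][1], pose.coords[L.KNEE_RIGHT][1]]
            assert normalization_factor(pose) == pytest.approx(
                max(ys_feet) - min(ys_knee))


class TestHockJointAngle:
    def test_collinear_is_straight(self):
        pose = make_pose((100, 200), (200, 200), (100, 260), (200, 260),
                         (100, 330), (200, 330))
        assert hock_joint_angle(pose, "left") == pytest.approx(180.0)

    def test_worked_example(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 330), (215, 330))
        expected = oracle_angle((100, 200), (110, 260), (105, 330))
        assert hock_joint_angle(pose, "left") == pytest.approx(expected)
        assert expected == pytest.approx(166.4, abs=0.1)

    def test_matches_atan2_oracle(self, rng):
        for _ in range(25):
            pose = random_pose(rng)
            for side, (k, h, f) in (("left", (L.KNEE_LEFT, L.HOCK_LEFT, L.FOOT_LEFT)),
                                    ("right", (L.KNEE_RIGHT, L.HOCK_RIGHT,
                                               L.FOOT_RIGHT))):
                expected = oracle_angle(pose.coords[k], pose.coords[h],
                                        pose.coords[f])
                assert hock_joint_angle(pose, side) == pytest.approx(expected)

    def test_zero_segment_degenerate(self):
        pose = make_pose((110, 260), (220, 200), (110, 260), (210, 260),
                         (105, 330), (215, 330))
        with pytest.raises(DegeneratePoseError):
            hock_joint_angle(pose, "left")


class TestShankFloorAngle:
    def test_vertical_shank_is_90(self):
        pose = make_pose((120, 200), (190, 200), (130, 260), (190, 260),
                         (130, 330), (190, 330))
        assert shank_floor_angle(pose, "left") == pytest.approx(90.0)

    def test_worked_example_right(self):
        # feet x 130/190; right hock 10 px medial, 70 px up -> 81.87 deg
        pose = make_pose((120, 200), (185, 190), (140, 262), (180, 260),
                         (130, 330), (190, 330))
        expected = math.degrees(math.atan2(70, 10))
        assert shank_floor_angle(pose, "right") == pytest.approx(expected)
        assert expected == pytest.approx(81.87, abs=0.01)

    def test_hock_medial_below_90_lateral_above(self):
        medial = make_pose((120, 200), (185, 200), (140, 262), (180, 260),
                           (130, 330), (190, 330))
        assert shank_floor_angle(medial, "left") < 90
        lateral = make_pose((120, 200), (185, 200), (120, 262), (180, 260),
                            (130, 330), (190, 330))
        assert shank_floor_angle(lateral, "left") > 90

    def test_coincident_feet_degenerate(self):
        pose = make_pose((120, 200), (185, 200), (140, 262), (180, 260),
                         (150, 330), (150, 330))
        with pytest.raises(DegeneratePoseError):
            shank_floor_angle(pose, "left")


class TestSegmentLengths:
    def test_straight_vertical_leg_sums_to_one(self):
        pose = make_pose((130, 200), (190, 200), (130, 260), (190, 260),
                         (130, 330), (190, 330))
        tib, shank = relative_segment_lengths(pose, "left")
        assert tib + shank == pytest.approx(1.0)

    def test_worked_example(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 330), (215, 330))
        tib, shank = relative_segment_lengths(pose, "left")
        assert tib == pytest.approx(math.hypot(10, 60) / 130, abs=1e-9)
        assert tib == pytest.approx(0.468, abs=0.001)
        assert shank == pytest.approx(math.hypot(5, 70) / 130, abs=1e-9)


class TestDistanceRatios:
    def test_hkdr_worked_example(self):
        pose = make_pose((130, 200), (195, 200), (140, 260), (180, 260),
                         (135, 330), (190, 330))
        assert hock_knee_ratio(pose) == pytest.approx(40 / 65)

    def test_hfdr_worked_example(self):
        pose = make_pose((90, 200), (195, 200), (100, 260), (180, 260),
                         (90, 330), (190, 330))
        assert hock_feet_ratio(pose) == pytest.approx(0.8)

    def test_zero_denominator_degenerate(self):
        pose = make_pose((150, 200), (150, 200), (140, 260), (180, 260),
                         (135, 330), (190, 330))
        with pytest.raises(DegeneratePoseError):
            hock_knee_ratio(pose)


class TestStepHeight:
    def test_worked_example(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 283), (215, 330), kind="step_left")
        assert step_height(pose) == pytest.approx(100 * 47 / 130)

    def test_level_feet_zero(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 330), (215, 330), kind="step_right")
        assert step_height(pose) == pytest.approx(0.0)

    def test_negative_lift_warns(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 340), (215, 330), kind="step_left")
        with pytest.warns(UserWarning, match="mis-selected"):
            value = step_height(pose)
        assert value < 0

    def test_requires_step_pose(self):
        pose = make_pose((100, 200), (220, 200), (110, 260), (210, 260),
                         (105, 330), (215, 330))
        with pytest.raises(DegeneratePoseError):
            step_height(pose)


def _translate(pose, dx, dy):
    return Pose(pose.frame_index, pose.kind,
                {p: (x + dx, y + dy) for p, (x, y) in pose.coords.items()})


def _scale(pose, s):
    return Pose(pose.frame_index, pose.kind,
                {p: (x * s, y * s) for p, (x, y) in pose.coords.items()})


def _mirror(pose, width=1280.0):
    swap = {L.KNEE_LEFT: L.KNEE_RIGHT, L.KNEE_RIGHT: L.KNEE_LEFT,
            L.HOCK_LEFT: L.HOCK_RIGHT, L.HOCK_RIGHT: L.HOCK_LEFT,
            L.FOOT_LEFT: L.FOOT_RIGHT, L.FOOT_RIGHT: L.FOOT_LEFT}
    kind = pose.kind
    if kind == "step_left":
        kind = "step_right"
    elif kind == "step_right":
        kind = "step_left"
    return Pose(pose.frame_index, kind,
                {swap[p]: (width - x, y) for p, (x, y) in pose.coords.items()})


def _all_values(pose):
    out = {}
    for side in ("left", "right"):
        out[f"hock_{side}"] = hock_joint_angle(pose, side)
        out[f"shank_{side}"] = shank_floor_angle(pose, side)
        tib, shank = relative_segment_lengths(pose, side)
        out[f"tib_{side}"] = tib
        out[f"shankrel_{side}"] = shank
    out["hkdr"] = hock_knee_ratio(pose)
    out["hfdr"] = hock_feet_ratio(pose)
    return out


class TestInvariances:
    @pytest.mark.parametrize("dx,dy", [(37.5, -12.25), (-200.0, 55.0)])
    def test_translation_invariance(self, rng, dx, dy):
        for _ in range(10):
            pose = random_pose(rng)
            a, b = _all_values(pose), _all_values(_translate(pose, dx, dy))
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-9)

    @pytest.mark.parametrize("s", [0.25, 3.5])
    def test_scale_invariance(self, rng, s):
        for _ in range(10):
            pose = random_pose(rng)
            a, b = _all_values(pose), _all_values(_scale(pose, s))
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_mirror_maps_left_to_right(self, rng):
        for _ in range(10):
            pose = random_pose(rng)
            a, b = _all_values(pose), _all_values(_mirror(pose))
            for key in ("hock", "shank", "tib", "shankrel"):
                assert a[f"{key}_left"] == pytest.approx(b[f"{key}_right"], rel=1e-9)
                assert a[f"{key}_right"] == pytest.approx(b[f"{key}_left"], rel=1e-9)
            assert a["hkdr"] == pytest.approx(b["hkdr"], rel=1e-9)
            assert a["hfdr"] == pytest.approx(b["hfdr"], rel=1e-9)

    def test_mirror_preserves_step_height(self, rng):
        pose = random_pose(rng, kind="step_left")
        assert step_height(pose) == pytest.approx(step_height(_mirror(pose)),
                                                  rel=1e-9)


class TestAggregate:
    def _poseset_with_steps(self, heights):
        """step_left poses with prescribed lift (ground 330, N = 130)."""
        poses = []
        for i, h in enumerate(heights):
            lifted_y = 330 - h / 100 * 130
            poses.append(make_pose((100, 200), (220, 200), (110, 260),
                                   (210, 260), (105, lifted_y), (215, 330),
                                   kind="step_left", frame=i * 10))
        ps = PoseSet(bird_id="b", age_days=33)
        ps.step_left = poses
        return ps

    def test_mean_of_three(self):
        records = aggregate_features(self._poseset_with_steps([10, 12, 14]))
        row = records[(records.feature == "step_height_rel")]
        assert row["value"].iloc[0] == pytest.approx(12.0)
        assert row["n_frames_used"].iloc[0] == 3
        assert row["side"].iloc[0] == "left"

    def test_single_frame_allowed(self):
        records = aggregate_features(self._poseset_with_steps([21.5]))
        assert records["value"].iloc[0] == pytest.approx(21.5)
        assert records["n_frames_used"].iloc[0] == 1

    def test_matches_bruteforce_mean(self, rng):
        ps = PoseSet(bird_id="b", age_days=33)
        ps.double_support = [random_pose(rng) for _ in range(3)]
        records = aggregate_features(ps).set_index(["feature", "side"])["value"]
        expected = np.mean([hock_joint_angle(p, "left")
                            for p in ps.double_support])
        assert records[("hock_joint_angle", "left")] == pytest.approx(expected)
        expected_hfdr = np.mean([hock_feet_ratio(p) for p in ps.double_support])
        assert records[("hock_feet_ratio", "none")] == pytest.approx(expected_hfdr)

    def test_missing_kind_yields_no_records(self):
        ps = PoseSet(bird_id="b", age_days=33)
        ps.step_left = self._poseset_with_steps([10]).step_left
        records = aggregate_features(ps)
        assert set(records["feature"]) == {"step_height_rel"}
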