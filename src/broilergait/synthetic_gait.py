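"""Kinematic simulator of rear-view keypoint trajectories of walking broilers.

The generator stands in for video data: it emits DeepLabCut-style keypoint
tables of birds walking a 3 m x 0.4 m corridor filmed from behind at
12 fps, 1280 x 720 px, together with per-bird body weights and 0-5 gait
scores from four simulated raters.

Generative model
----------------
A bird is a planar rear-view skeleton.  Its stance (double-support)
geometry is solved from a small set of primitive truths per side: the
hock joint angle, the medial shank-vs-floor angle, the relative
tibiotarsus length, the hock-feet distance ratio, and a pixel scale (the
normalization factor N).  The shank length, foot spread, knee positions,
relative shank length and hock-knee distance ratio all follow from
closing the kinematic chain, so in the noiseless limit every pose feature
computed downstream equals the generating truth.

Walking is a fixed-period stride cycle: each foot is planted (constant
ground y) for a stance fraction of the cycle and swings with a half-sine
lift otherwise; the two feet are phase-shifted so both are never airborne
and a double-support window exists every half stride.  During a swing the
foot (and, half as much, its hock) rises while the knees hold their
stance height, which keeps the per-frame normalization factor equal to
its stance value at the lift apex — the condition under which the
extracted relative step height equals the generating truth.

Population structure: bird-level truths are drawn around age-specific
good-gait means; a per-bird latent *crouch* factor loads on both leg
angles (and the hock-feet ratio), reproducing the strong observed
correlation between the two angle features; birds labelled suboptimal
receive additive class effects.  On top sit per-side asymmetries,
per-stride jitter and torso pitch, Gaussian pixel noise, and likelihood
dropout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InfeasibleGeometryError
from .keypoint_io import ALL_PARTS, BodyPart, CohortMeta, TrackedTrial, _empty_frame

RATERS = ("A", "B", "C", "D")
DEFAULT_AGES = (14, 21, 33)

#: reference mixing proportion of the suboptimal class (36 of 84 birds);
#: age-level cohort means are recovered when cohorts are simulated at the
#: same proportions.
REF_SUBOPTIMAL_SHARE = 36 / 84


@dataclass(frozen=True)
class ClassEffects:
    """Additive shifts applied to suboptimal-gait birds (suboptimal - good)."""

    hock_angle_deg: float = -2.2
    shank_angle_deg: float = -1.3
    tibiotarsus_rel: float = 0.01
    hock_feet_ratio: float = -0.03
    step_height_pp: float = -4.5
    body_weight_g: dict = field(
        default_factory=lambda: {14: 9.7, 21: 26.4, 33: 64.3}
    )


@dataclass(frozen=True)
class AgeMeans:
    """Cohort-level feature means at one age (good and suboptimal pooled at
    the reference 48:36 mixture), plus pixel scale and body weight."""

    hock_angle_deg: float
    shank_angle_deg: float
    tibiotarsus_rel: float
    hock_feet_ratio: float
    step_height_pct: float
    body_weight_g: float
    norm_px: float


#: age-specific cohort means; feature columns follow the descriptive
#: statistics of the study population, body weights are typical for
#: fast-growing male broilers, and norm_px grows with bird size.
DEFAULT_AGE_MEANS: dict[int, AgeMeans] = {
    14: AgeMeans(154.2, 83.9, 0.59, 0.86, 37.9, 470.0, 90.0),
    21: AgeMeans(155.6, 84.9, 0.55, 0.88, 37.5, 950.0, 110.0),
    33: AgeMeans(151.9, 82.4, 0.55, 0.85, 35.9, 1975.0, 130.0),
}

DEFAULT_WEIGHT_BIRD_SD = {14: 60.0, 21: 110.0, 33: 150.0}
DEFAULT_WEIGHT_RESID_SD = {14: 20.0, 21: 40.0, 33: 90.0}


@dataclass
class GaitParams:
    """Simulator parameters; defaults define the study conditions.

    Dispersion parameters are layered: bird-level truth SDs (crouch
    loadings plus residuals), persistent left/right asymmetry SDs,
    per-stride jitter SDs and pixel measurement noise together make up the
    record-level dispersion of each feature.
    """

    # --- gait timing (12 fps; 15-frame stride, 9 frames stance) ---
    fps: float = 12.0
    stride_period_s: float = 1.25
    stance_fraction: float = 0.6
    #: phase shift of the right foot in stride fractions; 7/15 keeps both
    #: double-support windows and both swing apexes on the frame grid
    phase_offset_fraction: float = 7.0 / 15.0
    trial_duration_s: float = 8.0

    # --- scene ---
    frame_size: tuple[int, int] = (1280, 720)
    ground_y_px: float = 600.0
    center_x_px: float = 640.0
    lateral_sway_px: float = 12.0
    sway_period_s: float = 2.6
    walk_speed_px_per_s: float = 0.0  # scale drift off by default

    # --- population (bird-level truth dispersion) ---
    age_means: dict = field(default_factory=lambda: dict(DEFAULT_AGE_MEANS))
    crouch_hock_deg: float = 3.65      # loading of the crouch latent on hock angle
    crouch_shank_deg: float = 3.35
    crouch_hfdr: float = 0.042
    hock_resid_sd: float = 0.6
    shank_resid_sd: float = 1.75
    hfdr_resid_sd: float = 0.022
    tibiotarsus_rel_sd: float = 0.005
    step_height_sd: float = 5.0
    norm_rel_sd: float = 0.08
    #: mean extraction bias (extracted minus truth) of the default
    #: measurement layer at the reference scale norm_px = 130; the
    #: population truth means are shifted by -bias * (130 / norm_px) so
    #: that *extracted* cohort means, not latent truths, match the
    #: age_means table.  Dominant mechanisms: order-statistic inflation
    #: of the per-frame normalization factor (tibiotarsus), arccos
    #: curvature under coordinate noise (angles), and best-of-candidates
    #: selection optimism (step height).
    extraction_bias: dict = field(default_factory=lambda: {
        "hock_angle_deg": -0.32,
        "shank_angle_deg": -0.12,
        "tibiotarsus_rel": -0.0105,
        "step_height_pct": 1.06,
        "hock_feet_ratio": 0.0,
    })

    # --- within-bird structure ---
    hock_asym_sd: float = 1.8         # persistent left/right asymmetry, deg
    shank_asym_sd: float = 1.6
    step_asym_sd: float = 4.0         # percentage points
    hock_jitter_sd: float = 3.0       # per-stride angle jitter, deg
    shank_jitter_sd: float = 2.5
    step_jitter_sd: float = 6.0       # per-swing step-height jitter, pp
    pitch_jitter_px: float = 4.5      # per-stride torso pitch on the knees

    # --- measurement layer ---
    noise_sd_px: float = 2.5
    dropout_prob: float = 0.05        # leg keypoints, per frame and keypoint
    dropout_head: float = 0.10
    dropout_neck: dict = field(default_factory=lambda: {14: 0.10, 21: 0.20, 33: 0.30})
    likelihood_threshold: float = 0.6

    # --- class structure ---
    class_effects: ClassEffects = field(default_factory=ClassEffects)
    weight_bird_sd: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHT_BIRD_SD))
    weight_resid_sd: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHT_RESID_SD))

    # --- simulated raters ---
    rater_biases: tuple = (-0.2, -0.07, 0.07, 0.2)
    rater_sd: float = 0.5            # between-rater score noise (Fleiss kappa knob)
    intra_sd: float = 0.25            # within-rater repeat noise (weighted kappa knob)
    good_latent: tuple = (1.2, 0.55)  # mean, sd of the good-class lameness latent
    suboptimal_latent: tuple = (2.9, 0.65)
    score_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ConfigError("stance_fraction must be in (0, 1)")
        if self.stance_fraction <= 0.5:
            raise ConfigError(
                "stance_fraction must exceed 0.5 so double support exists"
            )
        if self.noise_sd_px < 0 or self.dropout_prob < 0 or self.dropout_prob >= 1:
            raise ConfigError("noise_sd_px >= 0 and dropout_prob in [0, 1) required")
        n_strides = self.trial_duration_s / self.stride_period_s
        if n_strides < 4:
            raise ConfigError("trial must contain at least 4 full strides")

    def good_base(self, age: int) -> AgeMeans:
        """Good-class means at ``age``: cohort means un-mixed at the
        reference suboptimal share, so simulated cohorts at 48:36
        reproduce the cohort-level means exactly."""
        m: AgeMeans = self.age_means[age]
        e = self.class_effects
        p = REF_SUBOPTIMAL_SHARE
        scale = 130.0 / m.norm_px
        b = {k: v * scale for k, v in self.extraction_bias.items()}
        return AgeMeans(
            hock_angle_deg=m.hock_angle_deg - p * e.hock_angle_deg - b["hock_angle_deg"],
            shank_angle_deg=m.shank_angle_deg - p * e.shank_angle_deg
            - b["shank_angle_deg"],
            tibiotarsus_rel=m.tibiotarsus_rel - p * e.tibiotarsus_rel
            - b["tibiotarsus_rel"],
            hock_feet_ratio=m.hock_feet_ratio - p * e.hock_feet_ratio
            - b["hock_feet_ratio"],
            step_height_pct=m.step_height_pct - p * e.step_height_pp
            - b["step_height_pct"],
            body_weight_g=m.body_weight_g - p * e.body_weight_g[age],
            norm_px=m.norm_px,
        )


# ---------------------------------------------------------------------------
# skeleton geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Skeleton:
    """Stance-pose keypoint offsets relative to (mid x, ground y)."""

    foot: dict    # side -> (x, y)
    hock: dict
    knee: dict
    tib_len: float
    shank_len: float
    norm_px: float

    def true_features(self, theta_h: dict, theta_s: dict, hfdr: float) -> dict:
        """Analytic feature values implied by this skeleton."""
        hock_spread = self.hock["right"][0] - self.hock["left"][0]
        knee_spread = self.knee["right"][0] - self.knee["left"][0]
        feet_spread = self.foot["right"][0] - self.foot["left"][0]
        return {
            "hock_joint_angle": dict(theta_h),
            "shank_floor_angle": dict(theta_s),
            "tibiotarsus_rel_length": self.tib_len / self.norm_px,
            "shank_rel_length": self.shank_len / self.norm_px,
            "hock_knee_ratio": hock_spread / knee_spread,
            "hock_feet_ratio": hock_spread / feet_spread,
        }


def solve_skeleton(theta_s: dict, theta_h: dict, tib_rel: float, hfdr: float,
                   norm_px: float) -> Skeleton:
    """Close the planar leg chain from primitive truths.

    ``theta_s``/``theta_h`` map side -> degrees.  The shank length is
    chosen so the taller leg's knee-to-foot vertical extent equals
    ``norm_px`` exactly; the foot spread is chosen so the hock-feet
    distance ratio equals ``hfdr`` exactly.
    """
    if not 0 < hfdr < 1:
        raise InfeasibleGeometryError(f"hock-feet ratio {hfdr} outside (0, 1)")
    if not 0 < tib_rel < 1:
        raise InfeasibleGeometryError(f"tibiotarsus_rel {tib_rel} outside (0, 1)")
    tib_len = tib_rel * norm_px
    v_lat, v_up, extent_coef = {}, {}, {}
    for side in ("left", "right"):
        ts, th = theta_s[side], theta_h[side]
        if not 5.0 < ts <= 90.0:
            raise InfeasibleGeometryError(f"shank angle {ts} deg outside (5, 90]")
        if not 0.0 < th <= 180.0:
            raise InfeasibleGeometryError(f"hock angle {th} deg outside (0, 180]")
        psi = math.radians(th + 90.0 - ts)
        v_lat[side] = math.sin(psi)
        v_up[side] = -math.cos(psi)
        if v_up[side] <= 0.05:
            raise InfeasibleGeometryError(
                f"hock angle {th} deg with shank angle {ts} deg folds the "
                "tibiotarsus below the hock"
            )
    shank_len = min(
        (norm_px - tib_len * v_up[s]) / math.sin(math.radians(theta_s[s]))
        for s in ("left", "right")
    )
    if shank_len <= 0:
        raise InfeasibleGeometryError(
            "tibiotarsus takes the whole vertical extent; shank length <= 0"
        )
    medial = {s: shank_len * math.cos(math.radians(theta_s[s])) for s in ("left", "right")}
    foot_spread = (medial["left"] + medial["right"]) / (1.0 - hfdr)
    if foot_spread <= 0:
        raise InfeasibleGeometryError("non-positive foot spread")

    foot = {"left": (-foot_spread / 2.0, 0.0), "right": (foot_spread / 2.0, 0.0)}
    hock, knee = {}, {}
    for side, lat in (("left", -1.0), ("right", 1.0)):
        fx, fy = foot[side]
        hx = fx - lat * medial[side]          # hock sits medial of the foot
        hy = fy - shank_len * math.sin(math.radians(theta_s[side]))
        hock[side] = (hx, hy)
        knee[side] = (hx + lat * tib_len * v_lat[side], hy - tib_len * v_up[side])
    return Skeleton(foot=foot, hock=hock, knee=knee, tib_len=tib_len,
                    shank_len=shank_len, norm_px=norm_px)


# ---------------------------------------------------------------------------
# birds
# ---------------------------------------------------------------------------

@dataclass
class AgeTruth:
    """Ground-truth pose parameters of one bird at one age."""

    theta_h: dict          # side -> deg
    theta_s: dict
    tib_rel: float
    hfdr: float
    step_height: dict      # side -> percent of N
    norm_px: float
    body_weight_g: float
    skeleton: Skeleton
    true_features: dict    # feature name -> value or side dict


@dataclass
class SimulatedBird:
    bird_id: str
    class_label: str               # "good" | "suboptimal"
    crouch: float
    walks: bool = True
    truths: dict = field(default_factory=dict)   # age -> AgeTruth
    rater_scores: dict = field(default_factory=dict)   # rater -> int
    repeat_scores: dict | None = None

    @property
    def mean_score(self) -> float:
        return float(np.mean(list(self.rater_scores.values())))


def _draw_age_truth(rng: np.random.Generator, params: GaitParams, age: int,
                    class_label: str, crouch: float, weight_latent: float
                    ) -> AgeTruth:
    base = params.good_base(age)
    eff = params.class_effects if class_label == "suboptimal" else None

    hock_mid = base.hock_angle_deg - params.crouch_hock_deg * crouch \
        + rng.normal(0.0, params.hock_resid_sd)
    shank_mid = base.shank_angle_deg - params.crouch_shank_deg * crouch \
        + rng.normal(0.0, params.shank_resid_sd)
    tib = base.tibiotarsus_rel + rng.normal(0.0, params.tibiotarsus_rel_sd)
    hfdr = base.hock_feet_ratio - params.crouch_hfdr * crouch \
        + rng.normal(0.0, params.hfdr_resid_sd)
    step_mid = base.step_height_pct + rng.normal(0.0, params.step_height_sd)
    if eff is not None:
        hock_mid += eff.hock_angle_deg
        shank_mid += eff.shank_angle_deg
        tib += eff.tibiotarsus_rel
        hfdr += eff.hock_feet_ratio
        step_mid += eff.step_height_pp

    half_h = rng.normal(0.0, params.hock_asym_sd)
    half_s = rng.normal(0.0, params.shank_asym_sd)
    half_step = rng.normal(0.0, params.step_asym_sd)
    theta_h = {"left": hock_mid + half_h, "right": hock_mid - half_h}
    theta_s = {"left": shank_mid + half_s, "right": shank_mid - half_s}
    step = {"left": step_mid + half_step, "right": step_mid - half_step}

    # keep draws physical
    for d, lo, hi in ((theta_h, 95.0, 178.0), (theta_s, 55.0, 89.5)):
        for side in d:
            d[side] = float(np.clip(d[side], lo, hi))
    tib = float(np.clip(tib, 0.30, 0.75))
    hfdr = float(np.clip(hfdr, 0.55, 0.97))
    for side in step:
        step[side] = float(np.clip(step[side], 5.0, 80.0))

    norm_px = base.norm_px * float(np.clip(1.0 + rng.normal(0.0, params.norm_rel_sd),
                                           0.6, 1.4))
    weight = base.body_weight_g \
        + (params.class_effects.body_weight_g[age] if eff is not None else 0.0) \
        + weight_latent * params.weight_bird_sd[age] \
        + rng.normal(0.0, params.weight_resid_sd[age])
    weight = max(weight, 50.0)

    skel = solve_skeleton(theta_s, theta_h, tib, hfdr, norm_px)
    feats = skel.true_features(theta_h, theta_s, hfdr)
    feats["step_height_rel"] = dict(step)
    return AgeTruth(theta_h=theta_h, theta_s=theta_s, tib_rel=tib, hfdr=hfdr,
                    step_height=step, norm_px=norm_px, body_weight_g=float(weight),
                    skeleton=skel, true_features=feats)


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

def simulate_trial(params: GaitParams, bird: SimulatedBird, age_days: int,
                   seed: int) -> TrackedTrial:
    """Render one walking trial of ``bird`` at ``age_days`` as keypoints.

    Deterministic given (params, bird, seed).  Foot y series alternate
    planted stance and half-sine swing; hocks and knees follow the bird's
    stance skeleton, per-stride jitter, torso pitch, Gaussian pixel noise
    and likelihood dropout as configured.
    """
    rng = np.random.default_rng(seed)
    truth = bird.truths[age_days]
    fps = params.fps
    n_frames = int(round(params.trial_duration_s * fps))
    period = params.stride_period_s * fps
    stance = params.stance_fraction * period
    offset = params.phase_offset_fraction * period
    n_cycles = int(math.ceil(n_frames / period)) + 2

    # per-stride draws (index by cycle; +1 pad for the shifted right foot)
    jit_h = rng.normal(0.0, params.hock_jitter_sd, size=(n_cycles + 1, 2))
    jit_s = rng.normal(0.0, params.shank_jitter_sd, size=(n_cycles + 1, 2))
    pitch = rng.normal(0.0, params.pitch_jitter_px, size=n_cycles + 1)
    step_jit = rng.normal(0.0, params.step_jitter_sd, size=(n_cycles + 1, 2))
    sway_phase = rng.uniform(0.0, 2.0 * math.pi)
    bob_phase = rng.uniform(0.0, 2.0 * math.pi)

    ground = params.ground_y_px
    cx = params.center_x_px
    sides = ("left", "right")

    xs = np.zeros((n_frames, len(ALL_PARTS)))
    ys = np.zeros((n_frames, len(ALL_PARTS)))
    col = {part: i for i, part in enumerate(ALL_PARTS)}

    for f in range(n_frames):
        cyc = int(f // period)
        phase = {"left": f - cyc * period, "right": (f - offset) % period}
        cyc_r = int(math.floor((f - offset) / period))

        if params.hock_jitter_sd or params.shank_jitter_sd:
            th = {s: float(np.clip(truth.theta_h[s] + jit_h[cyc, i], 95.0, 178.0))
                  for i, s in enumerate(sides)}
            ts = {s: float(np.clip(truth.theta_s[s] + jit_s[cyc, i], 55.0, 89.5))
                  for i, s in enumerate(sides)}
            skel = _jittered_skeleton(truth.skeleton, th, ts)
        else:
            skel = truth.skeleton

        dx = cx + params.lateral_sway_px * math.sin(
            2.0 * math.pi * f / (params.sway_period_s * fps) + sway_phase
        )
        dpitch = pitch[cyc]

        lift = {"left": 0.0, "right": 0.0}
        if bird.walks:
            for i, s in enumerate(sides):
                ph = phase[s]
                if ph >= stance:
                    u = (ph - stance) / (period - stance)
                    ev = cyc if s == "left" else cyc_r
                    h_pct = truth.step_height[s] + step_jit[ev, i] \
                        * (1.0 if params.step_jitter_sd else 0.0)
                    h_px = max(h_pct, 0.0) / 100.0 * truth.norm_px
                    lift[s] = h_px * math.sin(math.pi * u)

        for s in sides:
            fx, fy = skel.foot[s]
            hx, hy = skel.hock[s]
            kx, ky = skel.knee[s]
            part_f = BodyPart.FOOT_LEFT if s == "left" else BodyPart.FOOT_RIGHT
            part_h = BodyPart.HOCK_LEFT if s == "left" else BodyPart.HOCK_RIGHT
            part_k = BodyPart.KNEE_LEFT if s == "left" else BodyPart.KNEE_RIGHT
            xs[f, col[part_f]] = dx + fx
            ys[f, col[part_f]] = ground + fy - lift[s]
            xs[f, col[part_h]] = dx + hx
            ys[f, col[part_h]] = ground + hy - 0.5 * lift[s] + 0.5 * dpitch
            xs[f, col[part_k]] = dx + kx
            ys[f, col[part_k]] = ground + ky + dpitch

        bob = 0.03 * truth.norm_px * math.sin(2.0 * math.pi * f / period + bob_phase)
        xs[f, col[BodyPart.HEAD]] = dx
        ys[f, col[BodyPart.HEAD]] = ground - 2.1 * truth.norm_px + bob
        xs[f, col[BodyPart.NECK]] = dx
        ys[f, col[BodyPart.NECK]] = ground - 1.7 * truth.norm_px + 0.6 * bob

    if params.noise_sd_px > 0:
        xs += rng.normal(0.0, params.noise_sd_px, xs.shape)
        ys += rng.normal(0.0, params.noise_sd_px, ys.shape)

    tau = params.likelihood_threshold
    lik = np.empty((n_frames, len(ALL_PARTS)))
    for part in ALL_PARTS:
        if part is BodyPart.HEAD:
            p_drop = params.dropout_head
        elif part is BodyPart.NECK:
            p_drop = params.dropout_neck.get(age_days, params.dropout_head)
        else:
            p_drop = params.dropout_prob
        dropped = rng.random(n_frames) < p_drop
        values = rng.uniform(tau, 1.0, n_frames)
        values[dropped] = rng.uniform(0.0, tau * 0.999, int(dropped.sum()))
        lik[:, col[part]] = values

    data = _empty_frame(n_frames)
    for part in ALL_PARTS:
        data[(part.value, "x")] = xs[:, col[part]]
        data[(part.value, "y")] = ys[:, col[part]]
        data[(part.value, "likelihood")] = lik[:, col[part]]

    return TrackedTrial(
        bird_id=bird.bird_id,
        age_days=age_days,
        data=data,
        fps=fps,
        frame_size=params.frame_size,
        start_frame=0,
        end_frame=n_frames - 1,
        scorer="synthetic",
    )


def _jittered_skeleton(base: Skeleton, theta_h: dict, theta_s: dict) -> Skeleton:
    """Re-pose a fixed-anatomy skeleton at jittered angles (feet stay planted)."""
    hock, knee = {}, {}
    for side, lat in (("left", -1.0), ("right", 1.0)):
        ts, th = theta_s[side], theta_h[side]
        psi = math.radians(th + 90.0 - ts)
        fx, fy = base.foot[side]
        hx = fx - lat * base.shank_len * math.cos(math.radians(ts))
        hy = fy - base.shank_len * math.sin(math.radians(ts))
        hock[side] = (hx, hy)
        knee[side] = (
            hx + lat * base.tib_len * math.sin(psi),
            hy + base.tib_len * math.cos(psi),
        )
    return Skeleton(foot=base.foot, hock=hock, knee=knee, tib_len=base.tib_len,
                    shank_len=base.shank_len, norm_px=base.norm_px)


# ---------------------------------------------------------------------------
# raters
# ---------------------------------------------------------------------------

def _draw_scores(rng: np.random.Generator, latent: float, params: GaitParams,
                 lo: float | None, hi: float | None, sd: float) -> dict:
    """Integer 0-5 scores from 4 raters around a lameness latent; redraw
    until the mean lands inside the (lo, hi] class bounds."""
    for _ in range(400):
        scores = {
            r: int(np.clip(round(latent + b + rng.normal(0.0, sd)), 0, 5))
            for r, b in zip(RATERS, params.rater_biases)
        }
        mean = float(np.mean(list(scores.values())))
        if (lo is None or mean > lo) and (hi is None or mean <= hi):
            return scores
    fallback = int(np.clip(round(latent), 0, 5))
    return {r: fallback for r in RATERS}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    birds: list
    trials: dict                    # (bird_id, age) -> TrackedTrial
    meta: CohortMeta
    score_table: pd.DataFrame       # index bird_id, columns raters
    repeat_table: pd.DataFrame      # second scoring pass, subset of birds
    params: GaitParams
    ages: tuple

    def bird(self, bird_id: str) -> SimulatedBird:
        return next(b for b in self.birds if b.bird_id == bird_id)


def simulate_cohort(params: GaitParams | None = None, n_good: int = 48,
                    n_suboptimal: int = 36, ages=DEFAULT_AGES, seed: int = 0,
                    n_nonwalkers: int = 0, n_repeat: int = 15) -> SimulatedCohort:
    """Simulate a full cohort: birds, trials per age, weights and scores.

    Non-walkers are additional suboptimal birds that stand still during
    the trial (their poses cannot be extracted) and carry the worst gait
    scores, mirroring the exclusion of non-walking birds from a live test.
    Reproducible given (params, seed).
    """
    params = params or GaitParams()
    if n_good < 0 or n_suboptimal < 0 or n_nonwalkers < 0:
        raise ConfigError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)

    labels = (["good"] * n_good + ["suboptimal"] * n_suboptimal
              + ["suboptimal"] * n_nonwalkers)
    walks = [True] * (n_good + n_suboptimal) + [False] * n_nonwalkers

    birds: list[SimulatedBird] = []
    for i, (label, walking) in enumerate(zip(labels, walks)):
        bird = SimulatedBird(
            bird_id=f"B{i + 1:03d}",
            class_label=label,
            crouch=float(rng.normal()),
            walks=walking,
        )
        weight_latent = float(rng.normal())
        for age in ages:
            bird.truths[age] = _draw_age_truth(
                rng, params, age, label, bird.crouch, weight_latent
            )
        if not walking:
            latent = float(rng.uniform(4.4, 5.0))
            bird.rater_scores = _draw_scores(rng, latent, params, 4.25, None,
                                             params.rater_sd)
        elif label == "good":
            mu, sd = params.good_latent
            latent = float(np.clip(rng.normal(mu, sd), 0.3, 1.9))
            bird.rater_scores = _draw_scores(rng, latent, params, None,
                                             params.score_cutoff, params.rater_sd)
        else:
            mu, sd = params.suboptimal_latent
            latent = float(np.clip(rng.normal(mu, sd), 2.15, 3.9))
            bird.rater_scores = _draw_scores(rng, latent, params,
                                             params.score_cutoff, None,
                                             params.rater_sd)
        birds.append(bird)

    # repeat-scoring arm: same birds re-scored by every rater with
    # within-rater noise, keeping each rater's first-pass score as anchor
    repeat_ids = []
    if birds and n_repeat > 0:
        take = min(n_repeat, len(birds))
        repeat_ids = [birds[i].bird_id
                      for i in rng.choice(len(birds), size=take, replace=False)]
        for bird in birds:
            if bird.bird_id in repeat_ids:
                bird.repeat_scores = {
                    r: int(np.clip(round(s + rng.normal(0.0, params.intra_sd)), 0, 5))
                    for r, s in bird.rater_scores.items()
                }

    trials = {}
    for bird in birds:
        for age in ages:
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials[(bird.bird_id, age)] = simulate_trial(params, bird, age,
                                                         trial_seed)

    meta_rows = [
        {"bird_id": b.bird_id, "age_days": age,
         "body_weight_g": b.truths[age].body_weight_g, "group": "pen1"}
        for b in birds for age in ages
    ]
    meta = CohortMeta(pd.DataFrame(
        meta_rows, columns=["bird_id", "age_days", "body_weight_g", "group"]
    ))

    score_table = pd.DataFrame(
        {r: [b.rater_scores[r] for b in birds] for r in RATERS},
        index=pd.Index([b.bird_id for b in birds], name="bird_id"),
        dtype=int,
    )
    repeat_rows = {
        b.bird_id: b.repeat_scores for b in birds if b.repeat_scores is not None
    }
    repeat_table = pd.DataFrame.from_dict(repeat_rows, orient="index").reindex(
        columns=list(RATERS)
    )
    repeat_table.index.name = "bird_id"

    return SimulatedCohort(birds=birds, trials=trials, meta=meta,
                           score_table=score_table, repeat_table=repeat_table,
                           params=params, ages=tuple(ages))


def noiseless(params: GaitParams | None = None) -> GaitParams:
    """A copy of ``params`` with every stochastic layer switched off.

    In this limit extracted features equal the generating truths exactly;
    used by inverse-consistency checks.
    """
    params = params or GaitParams()
    return replace(
        params,
        noise_sd_px=0.0,
        dropout_prob=0.0,
        dropout_head=0.0,
        dropout_neck={k: 0.0 for k in params.dropout_neck},
        hock_jitter_sd=0.0,
        shank_jitter_sd=0.0,
        step_jitter_sd=0.0,
        pitch_jitter_px=0.0,
        hock_asym_sd=0.0,
        shank_asym_sd=0.0,
        step_asym_sd=0.0,
    )
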