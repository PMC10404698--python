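"""Trajectory cleaning ahead of pose extraction.

Three rules are applied to each clipped walking trial:

1. the first and last 10% of frames are discarded (entry/exit of the
   corridor is unreliable for keypoint tracking);
2. a frame is *pose-eligible* only if all six leg keypoints reach the
   detection-likelihood threshold (0.6 by default);
3. optionally, each coordinate series is denoised with a cubic smoothing
   spline fitted over eligible frames.

The module also provides the per-age, per-body-part summary of the
percentage of frames above the likelihood threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .exceptions import ConfigError, TooShortTrialError
from .keypoint_io import ALL_PARTS, LEG_PARTS, BodyPart, TrackedTrial

logger = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Parameters of the cleaning stage.

    trim_fraction         fraction of frames dropped at each end (default 0.10)
    likelihood_threshold  minimum keypoint likelihood tau (default 0.6)
    smoothing             "spline" (default, mirroring the spline filter
                          applied to the keypoint estimates) or "none"
    smoothing_cap_px      a smoothed point never moves further than this
    min_spline_frames     parts with fewer eligible frames are left alone
    """

    trim_fraction: float = 0.10
    likelihood_threshold: float = 0.6
    smoothing: str = "spline"
    smoothing_cap_px: float = 10.0
    min_spline_frames: int = 4
    #: estimated noise below this (sub-quantization) leaves a series as-is
    noise_floor_px: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ConfigError("clean.trim_fraction must be in [0, 0.5)")
        if not 0 < self.likelihood_threshold < 1:
            raise ConfigError("clean.likelihood_threshold must be in (0, 1)")
        if self.smoothing not in ("none", "spline"):
            raise ConfigError("clean.smoothing must be 'none' or 'spline'")


def trim_edges(trial: TrackedTrial, config: CleaningConfig | None = None) -> TrackedTrial:
    """Drop floor(trim_fraction * n) frames from each end of the trial."""
    config = config or CleaningConfig()
    n = trial.n_frames
    if config.trim_fraction == 0:
        return trial
    if n < 10:
        raise TooShortTrialError(
            f"bird {trial.bird_id}: {n} frames is too short to trim"
        )
    cut = math.floor(config.trim_fraction * n)
    data = trial.data.iloc[cut : n - cut].reset_index(drop=True)
    out = trial.with_data(data, start_frame=None, end_frame=None)
    if trial.eligible is not None:
        out.eligible = np.asarray(trial.eligible, bool)[cut : n - cut].copy()
    return out


def mask_low_likelihood(trial: TrackedTrial, config: CleaningConfig | None = None
                        ) -> TrackedTrial:
    """Mark frames pose-eligible iff all six leg keypoints reach tau.

    Coordinates are untouched; non-leg parts do not affect eligibility.
    """
    config = config or CleaningConfig()
    out = trial.with_data(trial.data.copy())
    out.eligible = np.all(
        trial.leg_likelihoods() >= config.likelihood_threshold, axis=1
    )
    return out


def _part_mask(trial: TrackedTrial, part: BodyPart, tau: float) -> np.ndarray:
    ok = trial.likelihood(part) >= tau
    xy = trial.xy(part)
    return ok & np.isfinite(xy).all(axis=1)


def smooth_trajectories(trial: TrackedTrial, config: CleaningConfig | None = None
                        ) -> TrackedTrial:
    """Cubic smoothing spline per coordinate series, fitted on eligible frames.

    The smoothing strength is set from a robust noise estimate (median
    absolute frame-to-frame difference scaled to a Gaussian sigma), giving
    an interpolating spline for noiseless input.  Smoothing never moves a
    point further than ``smoothing_cap_px``; parts with fewer than
    ``min_spline_frames`` usable frames are left unsmoothed.
    """
    config = config or CleaningConfig()
    if config.smoothing == "none":
        return trial
    data = trial.data.copy()
    tau = config.likelihood_threshold
    for part in ALL_PARTS:
        mask = _part_mask(trial, part, tau)
        frames = np.flatnonzero(mask)
        if frames.size < config.min_spline_frames:
            logger.warning(
                "bird %s: part %s has %d usable frames, left unsmoothed",
                trial.bird_id, part.value, frames.size,
            )
            continue
        for coord in ("x", "y"):
            y = data[(part.value, coord)].to_numpy(float)[frames]
            # noise scale from second differences: insensitive to smooth
            # motion (locally linear trends cancel), so a noiseless series
            # yields s = 0 and an interpolating spline
            dd = np.abs(np.diff(y, n=2))
            sigma = np.median(dd) / (0.6745 * math.sqrt(6.0))
            if sigma < config.noise_floor_px:
                continue
            s = frames.size * sigma**2
            try:
                spline = UnivariateSpline(frames, y, k=3, s=s)
            except Exception:  # singular fits on degenerate series
                continue
            smoothed = spline(frames)
            delta = np.clip(smoothed - y, -config.smoothing_cap_px,
                            config.smoothing_cap_px)
            col = data[(part.value, coord)].to_numpy(float)
            col[frames] = y + delta
            data[(part.value, coord)] = col
    out = trial.with_data(data)
    out.eligible = None if trial.eligible is None else trial.eligible.copy()
    return out


def clean_trial(trial: TrackedTrial, config: CleaningConfig | None = None
                ) -> TrackedTrial:
    """trim -> mask -> (optional) smooth, the standard cleaning sequence."""
    config = config or CleaningConfig()
    out = trim_edges(trial, config)
    out = mask_low_likelihood(out, config)
    return smooth_trajectories(out, config)


def likelihood_summary(trials, config: CleaningConfig | None = None) -> pd.DataFrame:
    """Percentage of frames with likelihood >= tau, by age and body part.

    Per trial the percentage is computed over its frames; trials of the
    same age are then averaged (each bird weighted equally).  Columns:
    age_days, body_part, pct_above_threshold.
    """
    config = config or CleaningConfig()
    trials = list(trials)
    if not trials:
        raise ValueError("likelihood_summary needs at least one trial")
    rows = []
    for trial in trials:
        for part in ALL_PARTS:
            lik = trial.likelihood(part)
            pct = 100.0 * float(
                (lik >= config.likelihood_threshold).sum()) / len(lik)
            rows.append({"age_days": trial.age_days, "body_part": part.value,
                         "pct": pct})
    per_trial = pd.DataFrame(rows)
    out = (
        per_trial.groupby(["age_days", "body_part"], sort=True)["pct"]
        .mean()
        .reset_index()
        .rename(columns={"pct": "pct_above_threshold"})
    )
    return out
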