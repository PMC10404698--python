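"""Gait-phase detection and pose-frame selection.

Walking is segmented from the vertical (y) trajectories of the two feet:
in image coordinates the ground is *down* (large y), so ground contacts
show up as local maxima of a foot's y series and maximum leg lifts as
local minima.  Two poses are harvested per bird and age:

* **double support** — both feet on the ground; frames are ranked by the
  vertical difference between the feet (smaller is better);
* **step (left/right)** — one foot at the apex of its swing while the
  other is grounded; frames are ranked by the vertical difference
  (larger is better).

Up to ``k`` frames per pose kind are kept, pairwise separated by at least
``min_separation`` frames so they come from distinct gait cycles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import ConfigError, NoPoseError, NoWalkError
from .keypoint_io import BodyPart, LEG_PARTS, TrackedTrial


@dataclass(frozen=True)
class Pose:
    """One selected frame: the six leg-keypoint coordinates plus pose kind."""

    frame_index: int
    kind: str  # "double_support" | "step_left" | "step_right"
    coords: dict  # BodyPart -> (x, y) in px

    def point(self, part: BodyPart) -> np.ndarray:
        return np.asarray(self.coords[part], float)


@dataclass
class PoseSet:
    """Up to k poses per kind for one bird at one age."""

    bird_id: str
    age_days: int
    double_support: list[Pose] = field(default_factory=list)
    step_left: list[Pose] = field(default_factory=list)
    step_right: list[Pose] = field(default_factory=list)

    def all_poses(self) -> list[Pose]:
        return [*self.double_support, *self.step_left, *self.step_right]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pose in self.all_poses():
            row = {
                "bird_id": self.bird_id,
                "age_days": self.age_days,
                "kind": pose.kind,
                "frame_index": pose.frame_index,
            }
            for part in LEG_PARTS:
                x, y = pose.coords[part]
                row[f"{part.value}_x"] = x
                row[f"{part.value}_y"] = y
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class PoseConfig:
    """Selection parameters.

    min_separation defaults to half the expected stride period in frames
    (7 frames at 12 fps for a ~1.25 s stride) so that the k frames of one
    pose kind come from distinct gait cycles.  ``prominence=None`` uses a
    scale-free default of 3x the noise level, estimated from the median
    absolute frame-to-frame difference of the series.  Ground contact is
    recognised within ``contact_tolerance`` x (normalization-factor
    estimate) of a foot's own contact level, keeping the rule free of
    absolute pixel thresholds.
    """

    k: int = 3
    min_separation: int = 7
    prominence: float | None = None
    #: lower bound on the automatic prominence, as a fraction of the
    #: normalization-factor estimate; keeps detector noise on a standing
    #: bird from masquerading as strides (a real leg lift is ~30-50% of N)
    prominence_floor: float = 0.08
    contact_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("poses.k must be >= 1")
        if self.min_separation < 1:
            raise ConfigError("poses.min_separation must be >= 1")
        if not 0 < self.contact_tolerance < 1:
            raise ConfigError("poses.contact_tolerance must be in (0, 1)")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _eligible_index(trial: TrackedTrial) -> np.ndarray:
    if trial.eligible is not None:
        idx = np.flatnonzero(np.asarray(trial.eligible, bool))
    else:
        idx = np.arange(trial.n_frames)
    return idx


def _noise_estimate(y: np.ndarray) -> float:
    """Robust per-frame noise scale: median absolute first difference."""
    if len(y) < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(y))))


def _normalization_scale(trial: TrackedTrial, idx: np.ndarray) -> float:
    """Median per-frame (lowest foot y - highest knee y) over eligible frames."""
    feet_y = np.column_stack(
        [trial.xy(BodyPart.FOOT_LEFT)[idx, 1], trial.xy(BodyPart.FOOT_RIGHT)[idx, 1]]
    )
    knee_y = np.column_stack(
        [trial.xy(BodyPart.KNEE_LEFT)[idx, 1], trial.xy(BodyPart.KNEE_RIGHT)[idx, 1]]
    )
    per_frame = feet_y.max(axis=1) - knee_y.min(axis=1)
    scale = float(np.nanmedian(per_frame))
    return scale if scale > 0 else 1.0


def find_foot_extrema(trial: TrackedTrial, config: PoseConfig | None = None) -> dict:
    """Local extrema of each foot's y series over eligible frames.

    Returns ``{"left"|"right": {"maxima": idx, "minima": idx,
    "contact_level": float}}`` with indices in original frame numbering.
    Maxima (ground contacts) are detected with plateau support because a
    planted foot holds a constant level for several frames.
    """
    config = config or PoseConfig()
    idx = _eligible_index(trial)
    if idx.size == 0:
        raise NoWalkError(f"bird {trial.bird_id}: no eligible frames")

    scale = _normalization_scale(trial, idx)
    out = {}
    for side, part in (("left", BodyPart.FOOT_LEFT), ("right", BodyPart.FOOT_RIGHT)):
        y = trial.xy(part)[idx, 1]
        prom = config.prominence
        if prom is None:
            prom = max(3.0 * _noise_estimate(y),
                       config.prominence_floor * scale, 1e-9)
        maxima, _ = find_peaks(y, prominence=prom, plateau_size=(1, None))
        minima, _ = find_peaks(-y, prominence=prom, plateau_size=(1, None))
        contact = float(np.median(y[maxima])) if maxima.size else math.nan
        out[side] = {
            "maxima": idx[maxima],
            "minima": idx[minima],
            "contact_level": contact,
        }
    return out


def _contact_mask(trial: TrackedTrial, idx: np.ndarray, extrema: dict, side: str,
                  tol: float) -> np.ndarray:
    """Boolean mask over ``idx``: foot of ``side`` within tol of its contact level."""
    part = BodyPart.FOOT_LEFT if side == "left" else BodyPart.FOOT_RIGHT
    level = extrema[side]["contact_level"]
    if math.isnan(level):
        return np.zeros(idx.size, dtype=bool)
    y = trial.xy(part)[idx, 1]
    return np.abs(y - level) <= tol


def _pose_at(trial: TrackedTrial, frame: int, kind: str) -> Pose:
    coords = {part: tuple(trial.xy(part)[frame]) for part in LEG_PARTS}
    return Pose(frame_index=int(frame), kind=kind, coords=coords)


def _select_separated(candidates: np.ndarray, values: np.ndarray, k: int,
                      min_sep: int, maximize: bool) -> list[int]:
    """Optimal subset of candidate frames under the pairwise-separation rule.

    Among subsets of the maximal feasible size (capped at k), minimise
    (or maximise) the summed value; ties break toward the lexicographically
    smallest frame-index tuple.  Candidate counts are small (a handful per
    gait cycle), so exhaustive search over combinations is exact and cheap.
    """
    order = np.argsort(candidates)
    cand = candidates[order]
    vals = values[order]

    # maximal feasible subset size by greedy scan (interval scheduling)
    m, last = 0, None
    for f in cand:
        if last is None or f - last >= min_sep:
            m += 1
            last = f
    m = min(m, k)
    if m == 0:
        return []

    if cand.size > 80:  # keep the exhaustive scan bounded; never hit in practice
        best_by_value = np.argsort(vals if not maximize else -vals)[:80]
        keep = np.sort(best_by_value)
        cand, vals = cand[keep], vals[keep]

    sign = -1.0 if maximize else 1.0
    cand_l = [int(c) for c in cand]
    vals_l = [sign * float(v) for v in vals]
    best_key, best_combo = None, None
    for combo in itertools.combinations(range(len(cand_l)), m):
        frames = tuple(cand_l[i] for i in combo)
        if any(b - a < min_sep for a, b in zip(frames, frames[1:])):
            continue
        key = (sum(vals_l[i] for i in combo), frames)
        if best_key is None or key < best_key:
            best_key, best_combo = key, frames
    if best_combo is None:
        return []
    return list(best_combo)


# ---------------------------------------------------------------------------
# selection operations
# ---------------------------------------------------------------------------

def select_double_support(trial: TrackedTrial, extrema: dict,
                          config: PoseConfig | None = None) -> list[Pose]:
    """Up to k double-support poses minimising |y_foot_left - y_foot_right|."""
    config = config or PoseConfig()
    idx = _eligible_index(trial)
    tol = config.contact_tolerance * _normalization_scale(trial, idx)
    both = _contact_mask(trial, idx, extrema, "left", tol) & _contact_mask(
        trial, idx, extrema, "right", tol
    )
    candidates = idx[both]
    if candidates.size == 0:
        raise NoPoseError(f"bird {trial.bird_id}: no double-support candidates")
    y_l = trial.xy(BodyPart.FOOT_LEFT)[candidates, 1]
    y_r = trial.xy(BodyPart.FOOT_RIGHT)[candidates, 1]
    values = np.abs(y_l - y_r)
    frames = _select_separated(candidates, values, config.k,
                               config.min_separation, maximize=False)
    return [_pose_at(trial, f, "double_support") for f in frames]


def select_steps(trial: TrackedTrial, extrema: dict, side: str,
                 config: PoseConfig | None = None) -> list[Pose]:
    """Up to k maximum-leg-lift poses for ``side``.

    Candidates are lift minima of the ``side`` foot at frames where the
    other foot is grounded; frames maximise y_other - y_side.
    """
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")
    config = config or PoseConfig()
    idx = _eligible_index(trial)
    other = "right" if side == "left" else "left"
    tol = config.contact_tolerance * _normalization_scale(trial, idx)

    minima = extrema[side]["minima"]
    eligible_set = set(int(i) for i in idx)
    minima = np.array([f for f in minima if int(f) in eligible_set], dtype=int)
    if minima.size:
        pos = np.searchsorted(idx, minima)
        grounded = _contact_mask(trial, idx, extrema, other, tol)[pos]
        candidates = minima[grounded]
    else:
        candidates = minima
    if candidates.size == 0:
        raise NoPoseError(f"bird {trial.bird_id}: no {side}-step candidates")

    part_side = BodyPart.FOOT_LEFT if side == "left" else BodyPart.FOOT_RIGHT
    part_other = BodyPart.FOOT_RIGHT if side == "left" else BodyPart.FOOT_LEFT
    values = trial.xy(part_other)[candidates, 1] - trial.xy(part_side)[candidates, 1]
    frames = _select_separated(candidates, values, config.k,
                               config.min_separation, maximize=True)
    return [_pose_at(trial, f, f"step_{side}") for f in frames]


def extract_poses(trial: TrackedTrial, config: PoseConfig | None = None) -> PoseSet:
    """Bundle double-support and left/right step selections for one trial.

    A pose kind with no candidates is simply absent from the result; if no
    pose of *any* kind is found the bird did not walk and a
    :class:`NoWalkError` is raised so the caller can exclude it.
    """
    config = config or PoseConfig()
    poseset = PoseSet(bird_id=trial.bird_id, age_days=trial.age_days)
    try:
        extrema = find_foot_extrema(trial, config)
    except NoWalkError:
        raise
    failures = []
    try:
        poseset.double_support = select_double_support(trial, extrema, config)
    except NoPoseError as exc:
        failures.append(str(exc))
    for side in ("left", "right"):
        try:
            poses = select_steps(trial, extrema, side, config)
        except NoPoseError as exc:
            failures.append(str(exc))
            poses = []
        setattr(poseset, f"step_{side}", poses)
    if not poseset.all_poses():
        raise NoWalkError(
            f"bird {trial.bird_id} at {trial.age_days} d: no pose of any kind "
            f"({'; '.join(failures)})"
        )
    return poseset
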