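"""Reading and writing DeepLabCut-dialect keypoint tables.

The pipeline's raw input is the per-frame table a pose-estimation network
exports for one walking trial: for each of 8 body parts (head, neck, left
and right knees, hocks and feet) an ``x``/``y`` pixel coordinate and a
detection likelihood in [0, 1].  The CSV dialect has three header rows
(``scorer`` / ``bodyparts`` / ``coords``) and an integer frame-index first
column.

Conventions
-----------
* Image coordinates: origin top-left, y grows downward.  "Lower on the
  ground" therefore means *larger* y throughout the package.
* Frame indices are 0-based; clip bounds are inclusive on both ends.
* Missing detections are stored as ``(NaN, NaN, likelihood 0)`` so that all
  series stay frame-aligned; rows are never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import BoundsNotSetError, FormatError, InsufficientDataError


class BodyPart(str, Enum):
    """The 8 tracked keypoints of a rear-view broiler skeleton."""

    HEAD = "head"
    NECK = "neck"
    KNEE_LEFT = "knee_left"
    KNEE_RIGHT = "knee_right"
    HOCK_LEFT = "hock_left"
    HOCK_RIGHT = "hock_right"
    FOOT_LEFT = "foot_left"
    FOOT_RIGHT = "foot_right"


ALL_PARTS: tuple[BodyPart, ...] = tuple(BodyPart)
#: The six leg keypoints; every pose feature is computed from these alone.
LEG_PARTS: tuple[BodyPart, ...] = (
    BodyPart.KNEE_LEFT,
    BodyPart.KNEE_RIGHT,
    BodyPart.HOCK_LEFT,
    BodyPart.HOCK_RIGHT,
    BodyPart.FOOT_LEFT,
    BodyPart.FOOT_RIGHT,
)
COORDS = ("x", "y", "likelihood")

_PART_NAMES = tuple(p.value for p in ALL_PARTS)


def _empty_frame(n: int) -> pd.DataFrame:
    cols = pd.MultiIndex.from_product(
        [_PART_NAMES, COORDS], names=["bodyparts", "coords"]
    )
    return pd.DataFrame(np.nan, index=pd.RangeIndex(n), columns=cols)


@dataclass
class TrackedTrial:
    """Per-frame keypoint series of one bird in one walking trial.

    ``data`` is a frame-indexed DataFrame with a (bodypart, coord) column
    MultiIndex; ``eligible`` (set by the preprocessing stage) marks frames
    in which all six leg keypoints pass the likelihood threshold.
    """

    bird_id: str
    age_days: int
    data: pd.DataFrame
    fps: float = 12.0
    frame_size: tuple[int, int] = (1280, 720)
    start_frame: int | None = None
    end_frame: int | None = None
    scorer: str = "model"
    eligible: np.ndarray | None = field(default=None, repr=False)
    _xy_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        filled = np.nan_to_num(lik, nan=0.0)
        if (filled < 0).any() or (filled > 1).any():
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, part: BodyPart | str) -> np.ndarray:
        """(n_frames, 2) float array of x, y for one body part (cached)."""
        part = BodyPart(part).value
        if part not in self._xy_cache:
            self._xy_cache[part] = self.data[part][["x", "y"]].to_numpy(float)
        return self._xy_cache[part]

    def likelihood(self, part: BodyPart | str) -> np.ndarray:
        part = BodyPart(part).value
        return np.nan_to_num(self.data[(part, "likelihood")].to_numpy(float), nan=0.0)

    def leg_likelihoods(self) -> np.ndarray:
        """(n_frames, 6) likelihoods of the leg keypoints, in LEG_PARTS order."""
        return np.column_stack([self.likelihood(p) for p in LEG_PARTS])

    def with_data(self, data: pd.DataFrame, **changes) -> "TrackedTrial":
        return replace(self, data=data, eligible=None, _xy_cache={}, **changes)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_keypoint_table(
    path: str | Path,
    *,
    bird_id: str | None = None,
    age_days: int = 0,
    fps: float = 12.0,
    frame_size: tuple[int, int] = (1280, 720),
    start_frame: int | None = None,
    end_frame: int | None = None,
) -> TrackedTrial:
    """Read one DeepLabCut-dialect keypoint CSV into a :class:`TrackedTrial`.

    The file must carry the three header rows ``scorer`` / ``bodyparts`` /
    ``coords`` and, per body part, the columns x, y, likelihood in that
    order.  Missing cells become (NaN, likelihood 0).  Trial metadata is not
    part of the dialect and is supplied by the caller; ``bird_id`` defaults
    to the file stem.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                          float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: not a 3-header-row keypoint CSV ({exc})") from exc

    labels = [str(name) for name in raw.columns.names]
    expected = ["scorer", "bodyparts", "coords"]
    for row_no, (got, want) in enumerate(zip(labels, expected)):
        if got != want:
            raise FormatError(
                f"{path}: header row {row_no} should be labelled {want!r}, got {got!r}"
            )

    scorer = str(raw.columns.get_level_values(0)[0])
    parts_in_file = list(dict.fromkeys(raw.columns.get_level_values(1)))
    unknown = [p for p in parts_in_file if p not in _PART_NAMES]
    if unknown:
        raise FormatError(
            f"{path}: unknown body part(s) {unknown}; expected {list(_PART_NAMES)}"
        )

    n = len(raw)
    data = _empty_frame(n)
    data.index = raw.index.astype(int)
    for part in parts_in_file:
        sub = raw[scorer][part]
        got_coords = tuple(sub.columns)
        if got_coords != COORDS:
            raise FormatError(
                f"{path}: part {part!r} has coords columns {got_coords}, "
                f"expected {COORDS} in that order"
            )
        for c in COORDS:
            data[(part, c)] = pd.to_numeric(sub[c], errors="coerce").to_numpy(float)

    # missing detections: likelihood 0, coordinates NaN (out-of-frame marker)
    for part in _PART_NAMES:
        lik = data[(part, "likelihood")]
        data[(part, "likelihood")] = lik.fillna(0.0)

    data.index = pd.RangeIndex(n)
    return TrackedTrial(
        bird_id=bird_id if bird_id is not None else path.stem,
        age_days=age_days,
        data=data,
        fps=fps,
        frame_size=frame_size,
        start_frame=start_frame,
        end_frame=end_frame,
        scorer=scorer,
    )


def write_keypoint_table(trial: TrackedTrial, path: str | Path) -> None:
    """Write ``trial`` in the same dialect read by :func:`read_keypoint_table`.

    ``read(write(trial))`` reproduces the trial's coordinate series up to
    float text precision (17 significant digits, i.e. exactly).
    """
    path = Path(path)
    out = trial.data.copy()
    out.columns = pd.MultiIndex.from_tuples(
        [(trial.scorer, part, coord) for part, coord in trial.data.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    out.to_csv(path, float_format="%.17g")


def clip_trial(trial: TrackedTrial) -> TrackedTrial:
    """Restrict a trial to its manually recorded start/end bounds (inclusive)."""
    if trial.start_frame is None or trial.end_frame is None:
        raise BoundsNotSetError(
            f"bird {trial.bird_id}: set start_frame and end_frame before clipping"
        )
    s, e = int(trial.start_frame), int(trial.end_frame)
    if not (0 <= s <= e < trial.n_frames):
        raise BoundsNotSetError(
            f"bird {trial.bird_id}: bounds [{s}, {e}] outside 0..{trial.n_frames - 1}"
        )
    data = trial.data.iloc[s : e + 1].reset_index(drop=True)
    return trial.with_data(data, start_frame=0, end_frame=e - s)


# ---------------------------------------------------------------------------
# Keypoint-error metric
# ---------------------------------------------------------------------------

def pixel_error(
    predicted: np.ndarray,
    annotated: np.ndarray,
    likelihoods: np.ndarray | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Euclidean pixel error between predicted and annotated keypoints.

    Parameters
    ----------
    predicted, annotated : (n, 2) arrays of matched keypoint coordinates.
    likelihoods, threshold : optional per-pair likelihood filter; pairs with
        likelihood < threshold are excluded from both outputs.

    Returns
    -------
    (per-pair distances in px, mean distance in px)
    """
    predicted = np.asarray(predicted, float)
    annotated = np.asarray(annotated, float)
    if predicted.shape != annotated.shape or predicted.ndim != 2:
        raise ValueError("predicted and annotated must be matched (n, 2) arrays")
    dists = np.hypot(*(predicted - annotated).T)
    if likelihoods is not None and threshold is not None:
        dists = dists[np.asarray(likelihoods, float) >= threshold]
    if dists.size == 0:
        raise InsufficientDataError("no keypoint pairs left; mean error undefined")
    return dists, float(dists.mean())


# ---------------------------------------------------------------------------
# Cohort metadata
# ---------------------------------------------------------------------------

@dataclass
class CohortMeta:
    """Per bird-age body weights and group labels.

    ``table`` columns: bird_id, age_days, body_weight_g, group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"bird_id", "age_days", "body_weight_g", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        if (self.table["body_weight_g"] <= 0).any():
            raise ValueError("body weights must be positive")
        if self.table.duplicated(["bird_id", "age_days"]).any():
            raise ValueError("one weight per bird-age expected")

    def weight(self, bird_id: str, age_days: int) -> float:
        rows = self.table[
            (self.table["bird_id"] == bird_id) & (self.table["age_days"] == age_days)
        ]
        if rows.empty:
            raise KeyError(f"no weight for bird {bird_id} at {age_days} d")
        return float(rows["body_weight_g"].iloc[0])


def read_cohort_meta(path: str | Path) -> CohortMeta:
    return CohortMeta(pd.read_csv(path))


def write_cohort_meta(meta: CohortMeta, path: str | Path) -> None:
    meta.table.to_csv(path, index=False)
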