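"""Multi-rater gait scores: means, binary classes and rater agreement.

Gait is scored 0-5 (0 = walks normally, 5 = incapable of sustained
walking) by several raters per bird; each bird carries the mean of its
rater scores and is classed *good* (mean <= cutoff, default 2) or
*suboptimal*.  Interobserver agreement is Fleiss' kappa over the six
score categories; intraobserver reliability is Cohen's weighted kappa
between two scoring passes of the same rater.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .exceptions import ConfigError, InsufficientDataError

SCORE_CATEGORIES = tuple(range(6))

#: agreement-strength bands for kappa; each printed upper bound is
#: inclusive (0.20 -> slight, 0.205 -> fair, 0.40 -> fair, ...)
_BANDS = (
    (0.00, "poor"),       # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "excellent"),
)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    band: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)


def agreement_band(kappa: float) -> str:
    if math.isnan(kappa):
        return "undefined"
    if not -1.0 <= kappa <= 1.0 + 1e-12:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0.0:
        return "poor"
    for upper, label in _BANDS[1:]:
        if kappa <= upper + 1e-12:
            return label
    return "excellent"


def _validate_scores(values: np.ndarray) -> None:
    if not np.isin(values, SCORE_CATEGORIES).all():
        raise ConfigError("gait scores must be integers in 0..5")


def mean_gait_score(table: pd.DataFrame, bird_id: str) -> float:
    """Mean of one bird's rater scores (rows = birds, columns = raters)."""
    if bird_id not in table.index:
        raise InsufficientDataError(f"no scores for bird {bird_id}")
    scores = table.loc[bird_id].dropna().to_numpy(float)
    if scores.size == 0:
        raise InsufficientDataError(f"no scores for bird {bird_id}")
    _validate_scores(scores)
    return float(scores.mean())


def classify_gait(mean_score: float, cutoff: float = 2.0) -> str:
    """good iff mean score <= cutoff (robustness cutoffs 2.5 and 3 allowed)."""
    return "good" if mean_score <= cutoff else "suboptimal"


def class_table(table: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Per-bird mean score and binary class for a full score table."""
    rows = []
    for bird_id in table.index:
        mean = mean_gait_score(table, bird_id)
        rows.append({"bird_id": bird_id, "mean_score": mean,
                     "gait_class": classify_gait(mean, cutoff)})
    return pd.DataFrame(rows).set_index("bird_id")


def fleiss_kappa(table: pd.DataFrame) -> KappaResult:
    """Fleiss' kappa over score categories 0-5 for a complete birds x raters
    table.  Returns an undefined marker (NaN kappa) when expected agreement
    is 1 (all raters used a single category)."""
    values = table.to_numpy()
    if np.isnan(values.astype(float)).any():
        raise InsufficientDataError("Fleiss' kappa needs a complete table")
    _validate_scores(values)
    if values.shape[1] < 2:
        raise InsufficientDataError("Fleiss' kappa needs >= 2 raters")
    counts = np.zeros((values.shape[0], len(SCORE_CATEGORIES)), dtype=float)
    for j, cat in enumerate(SCORE_CATEGORIES):
        counts[:, j] = (values == cat).sum(axis=1)
    marginals = counts.sum(axis=0) / counts.sum()
    if np.max(marginals) >= 1.0:      # single category used: P_e = 1
        return KappaResult(kappa=float("nan"), band="undefined")
    kappa = float(_sm_fleiss(counts, method="fleiss"))
    return KappaResult(kappa=kappa, band=agreement_band(kappa))


def cohen_weighted_kappa(pass1, pass2, weighting: str = "linear") -> KappaResult:
    """Cohen's weighted kappa between two scoring passes on the same birds.

    Weights w_ij = 1 - (|i-j|/5)^p with p = 1 (linear) or 2 (quadratic).
    """
    if weighting not in ("linear", "quadratic"):
        raise ConfigError("weighting must be 'linear' or 'quadratic'")
    a = np.asarray(pass1)
    b = np.asarray(pass2)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientDataError("passes must be 1-d arrays of equal length")
    if a.size < 2:
        raise InsufficientDataError("weighted kappa needs >= 2 birds")
    _validate_scores(a)
    _validate_scores(b)
    if np.array_equal(a, b) and np.unique(a).size > 1:
        return KappaResult(kappa=1.0, band=agreement_band(1.0))
    kappa = cohen_kappa_score(a, b, labels=list(SCORE_CATEGORIES),
                              weights=weighting)
    if math.isnan(kappa):
        return KappaResult(kappa=float("nan"), band="undefined")
    return KappaResult(kappa=float(kappa), band=agreement_band(float(kappa)))


def kappa_report(score_table: pd.DataFrame, repeat_table: pd.DataFrame | None = None,
                 weighting: str = "linear") -> pd.DataFrame:
    """Fleiss' kappa of the panel plus per-rater intraobserver weighted kappa."""
    rows = []
    fk = fleiss_kappa(score_table)
    rows.append({"statistic": "fleiss_kappa", "rater": "all",
                 "kappa": fk.kappa, "band": fk.band})
    if repeat_table is not None and len(repeat_table):
        birds = repeat_table.index
        for rater in repeat_table.columns:
            ck = cohen_weighted_kappa(
                score_table.loc[birds, rater].to_numpy(int),
                repeat_table[rater].to_numpy(int),
                weighting=weighting,
            )
            rows.append({"statistic": f"cohen_weighted_kappa_{weighting}",
                         "rater": str(rater), "kappa": ck.kappa, "band": ck.band})
    return pd.DataFrame(rows)
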