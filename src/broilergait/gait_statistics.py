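"""Statistical comparison of pose features between gait classes.

The analysis layer mirrors a conventional livestock-phenotyping workflow:

* outliers removed per age x feature with a 2 x IQR fence around the
  quartiles (quartiles by linear interpolation);
* features with left/right sides compared between gait classes by OLS
  with gait class, body weight, side and the class x side interaction
  (the interaction is dropped and the model refitted when not
  significant); unsided ratios use class + body weight only;
* each class difference is also expressed as a percentage of the
  adjusted good-class mean, with a delta-method CI;
* feature-feature association at the oldest age by Pearson correlation
  on per-bird side-averaged values;
* the repeated body-weight measurements are compared between classes per
  age with a GEE marginal model (exchangeable working correlation on the
  bird, robust standard errors).

No multiple-testing correction is applied; P <= 0.05 is reported as
significant and 0.05 < P <= 0.10 as a tendency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .exceptions import ConfigError, InsufficientDataError


@dataclass
class AnalysisConfig:
    iqr_multiplier: float = 2.0
    alpha: float = 0.05
    tendency_upper: float = 0.10
    cutoff: float = 2.0
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0:
            raise ConfigError("analysis.iqr_multiplier must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("analysis.alpha must be in (0, 1)")


@dataclass
class EffectEstimate:
    """One fitted class contrast (a results-table row).

    ``diff`` is suboptimal minus good; ``value_at_good`` is the
    model-implied good-class mean at covariate means; ``pct_diff`` is
    100 * diff / value_at_good from unrounded quantities.
    """

    feature: str
    value_at_good: float
    diff: float
    ci95: tuple
    p_value: float
    pct_diff: float
    pct_ci95: tuple
    n_records: int
    interaction_dropped: bool | None = None


def significance_label(p: float, config: AnalysisConfig | None = None) -> str:
    config = config or AnalysisConfig()
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= config.alpha:
        return "significant"
    if p <= config.tendency_upper:
        return "tendency"
    return "ns"


# ---------------------------------------------------------------------------
# outliers
# ---------------------------------------------------------------------------

def remove_outliers(values, config: AnalysisConfig | None = None) -> np.ndarray:
    """Keep mask under the quartile +- multiplier x IQR fence.

    With fewer than 4 values the quartiles are too unstable; nothing is
    removed and a warning is emitted.
    """
    config = config or AnalysisConfig()
    values = np.asarray(values, float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; outlier rule skipped", stacklevel=2)
        return np.ones(values.shape, dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=config.quartile_method)
    iqr = q3 - q1
    lo = q1 - config.iqr_multiplier * iqr
    hi = q3 + config.iqr_multiplier * iqr
    return (values >= lo) & (values <= hi)


def apply_outlier_rule(records: pd.DataFrame, config: AnalysisConfig | None = None
                       ) -> pd.DataFrame:
    """Apply the fence within each age x feature, pooling sides."""
    config = config or AnalysisConfig()
    keep = np.ones(len(records), dtype=bool)
    for _, idx in records.groupby(["age_days", "feature"]).groups.items():
        pos = records.index.get_indexer(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep[pos] = remove_outliers(records["value"].iloc[pos], config)
    return records.loc[keep]


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def descriptive_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and record count per feature and age (sides pooled)."""
    out = (
        records.groupby(["feature", "age_days"])["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# class-difference models
# ---------------------------------------------------------------------------

def _merge_analysis_frame(records: pd.DataFrame, weights: pd.DataFrame,
                          classes: pd.DataFrame) -> pd.DataFrame:
    df = records.merge(
        weights[["bird_id", "age_days", "body_weight_g"]],
        on=["bird_id", "age_days"], how="left",
    )
    df = df.merge(classes.reset_index()[["bird_id", "gait_class"]],
                  on="bird_id", how="left")
    return df.dropna(subset=["value", "body_weight_g", "gait_class"])


def _effect_from_fit(result, feature: str, term: str,
                     interaction_dropped: bool | None) -> EffectEstimate:
    """Pull the class contrast and the adjusted good-class mean out of a fit."""
    diff = float(result.params[term])
    ci = result.conf_int().loc[term]
    p = float(result.pvalues[term])

    exog = np.asarray(result.model.exog, float)
    names = list(result.model.exog_names)
    x0 = exog.mean(axis=0)
    class_cols = [i for i, n in enumerate(names)
                  if "gait_class" in n]       # class dummy + any interactions
    x0[class_cols] = 0.0                      # -> good class at covariate means
    beta = np.asarray(result.params, float)
    mu_good = float(x0 @ beta)

    # delta-method CI for 100 * beta_c / mu_good
    if mu_good == 0:
        raise InsufficientDataError(f"{feature}: zero good-class baseline")
    c_idx = names.index(term)
    grad = -100.0 * diff / mu_good**2 * x0
    grad[c_idx] += 100.0 / mu_good
    cov = np.asarray(result.cov_params(), float)
    pct_se = float(np.sqrt(grad @ cov @ grad))
    pct = 100.0 * diff / mu_good
    tcrit = scipy.stats.t.ppf(0.975, result.df_resid)
    return EffectEstimate(
        feature=feature,
        value_at_good=mu_good,
        diff=diff,
        ci95=(float(ci[0]), float(ci[1])),
        p_value=p,
        pct_diff=pct,
        pct_ci95=(pct - tcrit * pct_se, pct + tcrit * pct_se),
        n_records=int(result.nobs),
        interaction_dropped=interaction_dropped,
    )


def feature_class_model(records: pd.DataFrame, weights: pd.DataFrame,
                        classes: pd.DataFrame, feature: str,
                        config: AnalysisConfig | None = None) -> EffectEstimate:
    """Class contrast for a sided feature by OLS.

    Model: value ~ gait class + body weight + side + class x side; the
    interaction is removed and the model refitted when its P > alpha.
    ``records`` are the post-outlier-removal rows of one age.
    """
    config = config or AnalysisConfig()
    df = _merge_analysis_frame(records[records["feature"] == feature], weights,
                               classes)
    if df.empty or df["gait_class"].nunique() < 2:
        raise InsufficientDataError(
            f"{feature}: need both gait classes to estimate a contrast"
        )
    if set(df["side"]) - {"left", "right"}:
        raise ConfigError(f"{feature}: expected sided records")

    full = smf.ols(
        "value ~ C(gait_class) + body_weight_g + C(side) "
        "+ C(gait_class):C(side)",
        data=df,
    ).fit()
    inter_terms = [n for n in full.params.index
                   if ":" in n and "gait_class" in n]
    inter_p = min(float(full.pvalues[t]) for t in inter_terms)
    term = "C(gait_class)[T.suboptimal]"
    if inter_p > config.alpha:
        refit = smf.ols("value ~ C(gait_class) + body_weight_g + C(side)",
                        data=df).fit()
        return _effect_from_fit(refit, feature, term, interaction_dropped=True)
    return _effect_from_fit(full, feature, term, interaction_dropped=False)


def ratio_class_model(records: pd.DataFrame, weights: pd.DataFrame,
                      classes: pd.DataFrame, feature: str,
                      config: AnalysisConfig | None = None) -> EffectEstimate:
    """Class contrast for an unsided ratio: value ~ gait class + body weight."""
    config = config or AnalysisConfig()
    df = _merge_analysis_frame(records[records["feature"] == feature], weights,
                               classes)
    if df.empty or df["gait_class"].nunique() < 2:
        raise InsufficientDataError(
            f"{feature}: need both gait classes to estimate a contrast"
        )
    fit = smf.ols("value ~ C(gait_class) + body_weight_g", data=df).fit()
    return _effect_from_fit(fit, feature, "C(gait_class)[T.suboptimal]",
                            interaction_dropped=None)


def percent_difference(diff: float, value_at_good: float) -> float:
    """100 x diff / value_at_good, computed from unrounded quantities."""
    if value_at_good == 0:
        raise InsufficientDataError("zero baseline; percent difference undefined")
    return 100.0 * diff / value_at_good


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def feature_correlations(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over birds (sides averaged first).

    Returns (r matrix, two-sided P matrix); features with zero variance
    get NaN against every partner.
    """
    wide = (
        records.groupby(["bird_id", "feature"])["value"].mean().unstack("feature")
    )
    if len(wide) < 3:
        raise InsufficientDataError("Pearson correlation needs >= 3 birds")
    feats = list(wide.columns)
    r = pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats)
    p = pd.DataFrame(np.zeros((len(feats), len(feats))), index=feats, columns=feats)
    for i, fa in enumerate(feats):
        for j, fb in enumerate(feats):
            if j <= i:
                continue
            pair = wide[[fa, fb]].dropna()
            if len(pair) < 3 or pair[fa].std() == 0 or pair[fb].std() == 0:
                r.loc[fa, fb] = r.loc[fb, fa] = np.nan
                p.loc[fa, fb] = p.loc[fb, fa] = np.nan
                continue
            res = scipy.stats.pearsonr(pair[fa], pair[fb])
            r.loc[fa, fb] = r.loc[fb, fa] = res.statistic
            p.loc[fa, fb] = p.loc[fb, fa] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# body weight (repeated measures)
# ---------------------------------------------------------------------------

def bodyweight_class_contrast(weights: pd.DataFrame, classes: pd.DataFrame
                              ) -> pd.DataFrame:
    """Per-age class contrast in body weight from a GEE marginal model.

    Model: weight ~ age * class with exchangeable working correlation on
    the bird and robust (sandwich) standard errors.  Returns one row per
    age: diff (suboptimal - good, g), 95% CI and P.
    """
    df = weights.merge(classes.reset_index()[["bird_id", "gait_class"]],
                       on="bird_id", how="inner").dropna(
        subset=["body_weight_g", "gait_class"])
    counts = df.groupby(["age_days", "gait_class"])["bird_id"].nunique()
    if (counts < 2).any() or df["gait_class"].nunique() < 2:
        raise InsufficientDataError("need >= 2 birds per class at every age")

    model = smf.gee(
        "body_weight_g ~ C(age_days) * C(gait_class)",
        groups="bird_id",
        data=df,
        cov_struct=sm.cov_struct.Exchangeable(),
        family=sm.families.Gaussian(),
    )
    result = model.fit()
    ages = sorted(df["age_days"].unique())
    ref = ages[0]
    rows = []
    for age in ages:
        contrast = "C(gait_class)[T.suboptimal]"
        if age != ref:
            contrast += f" + C(age_days)[T.{age}]:C(gait_class)[T.suboptimal]"
        test = result.t_test(contrast)
        ci = test.conf_int()[0]
        rows.append({
            "age_days": age,
            "diff_g": float(np.atleast_1d(test.effect)[0]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "p_value": float(np.atleast_1d(test.pvalue).ravel()[0]),
        })
    return pd.DataFrame(rows)
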