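"""End-to-end pipeline: simulate -> clean -> extract -> features -> score
-> analyze, with YAML configuration and reproducible file outputs.

Every stochastic stage draws from one seeded generator, so a fixed seed
reproduces the full report bundle byte for byte.  Birds whose trials
yield no pose of any kind (non-walkers) are excluded and accounted for in
the run log rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import BroilerGaitError, ConfigError, NoWalkError
from .gait_scoring import class_table, kappa_report
from .gait_statistics import (
    AnalysisConfig,
    EffectEstimate,
    apply_outlier_rule,
    bodyweight_class_contrast,
    descriptive_summary,
    feature_class_model,
    feature_correlations,
    ratio_class_model,
    significance_label,
)
from .keypoint_io import TrackedTrial, clip_trial, write_keypoint_table
from .pose_extraction import PoseConfig, PoseSet, extract_poses
from .pose_features import Feature, SIDED_FEATURES, UNSIDED_FEATURES, aggregate_features
from .preprocessing import CleaningConfig, clean_trial, likelihood_summary
from .synthetic_gait import GaitParams, SimulatedCohort, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    n_good: int = 48
    n_suboptimal: int = 36
    n_nonwalkers: int = 0
    n_repeat: int = 15
    ages: tuple = (14, 21, 33)
    params: GaitParams = field(default_factory=GaitParams)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clean: CleaningConfig = field(default_factory=CleaningConfig)
    poses: PoseConfig = field(default_factory=PoseConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    kappa_weighting: str = "linear"


_BLOCKS = {"simulate", "clean", "poses", "analysis"}


def _apply_block(obj, block: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in block.items():
        if key not in fields:
            hint = difflib.get_close_matches(key, fields, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {context}.{key}{suggestion}")
        if dataclasses.is_dataclass(getattr(obj, key)) and isinstance(value, dict):
            _apply_block(getattr(obj, key), value, f"{context}.{key}")
        else:
            setattr(obj, key, value)
    # re-run invariant checks
    if hasattr(obj, "__post_init__"):
        obj.__post_init__()
    return obj


def validate_config(raw: dict | None) -> PipelineConfig:
    """Turn a raw mapping (parsed YAML) into a validated PipelineConfig.

    Unknown keys are rejected with a closest-match suggestion; range
    violations surface as :class:`ConfigError` naming the field.
    """
    config = PipelineConfig()
    if not raw:
        return config
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    for key, value in raw.items():
        if key in ("seed", "outdir", "kappa_weighting"):
            setattr(config, key, value)
        elif key in _BLOCKS:
            _apply_block(getattr(config, key), value or {}, key)
        else:
            hint = difflib.get_close_matches(key, _BLOCKS | {"seed", "outdir"}, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suggestion}")
    if not isinstance(config.seed, int) or config.seed < 0:
        raise ConfigError("seed must be a non-negative integer")
    if config.kappa_weighting not in ("linear", "quadratic"):
        raise ConfigError("kappa_weighting must be 'linear' or 'quadratic'")
    return config


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# per-trial processing
# ---------------------------------------------------------------------------

def process_trial(trial: TrackedTrial, clean_cfg: CleaningConfig,
                  pose_cfg: PoseConfig) -> tuple[pd.DataFrame, PoseSet]:
    """clip -> trim -> mask -> smooth -> extract poses -> per-bird features."""
    if trial.start_frame is not None and trial.end_frame is not None:
        trial = clip_trial(trial)
    cleaned = clean_trial(trial, clean_cfg)
    poseset = extract_poses(cleaned, pose_cfg)
    return aggregate_features(poseset), poseset


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SimulatedCohort
    features: pd.DataFrame            # post-outlier-removal records
    features_raw: pd.DataFrame
    classes: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    correlations_r: pd.DataFrame
    correlations_p: pd.DataFrame
    weight_contrasts: pd.DataFrame
    kappa: pd.DataFrame
    likelihoods: pd.DataFrame
    exclusions: pd.DataFrame
    log_lines: list


def _fit_table2(records: pd.DataFrame, weights: pd.DataFrame,
                classes: pd.DataFrame, age: int, cfg: AnalysisConfig
                ) -> pd.DataFrame:
    sub = records[records["age_days"] == age]
    rows = []
    for feature in Feature:
        try:
            if feature in UNSIDED_FEATURES:
                est = ratio_class_model(sub, weights, classes, feature.value, cfg)
            else:
                est = feature_class_model(sub, weights, classes, feature.value, cfg)
        except BroilerGaitError as exc:
            logger.warning("model for %s failed: %s", feature.value, exc)
            continue
        rows.append({
            "feature": est.feature,
            "value_at_good": est.value_at_good,
            "diff": est.diff,
            "ci_low": est.ci95[0],
            "ci_high": est.ci95[1],
            "p_value": est.p_value,
            "label": significance_label(est.p_value, cfg),
            "pct_diff": est.pct_diff,
            "pct_ci_low": est.pct_ci95[0],
            "pct_ci_high": est.pct_ci95[1],
            "n_records": est.n_records,
            "interaction_dropped": est.interaction_dropped,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the report bundle."""
    config = config or PipelineConfig()
    sim = config.simulate
    log: list[str] = [f"broilergait {__version__} | seed {config.seed}"]

    cohort = simulate_cohort(
        params=sim.params, n_good=sim.n_good, n_suboptimal=sim.n_suboptimal,
        ages=sim.ages, seed=config.seed, n_nonwalkers=sim.n_nonwalkers,
        n_repeat=sim.n_repeat,
    )
    n_birds = len(cohort.birds)
    log.append(f"simulated {n_birds} birds x ages {list(sim.ages)}")

    records, exclusions = [], []
    for (bird_id, age), trial in cohort.trials.items():
        try:
            feats, _ = process_trial(trial, config.clean, config.poses)
            records.append(feats)
        except NoWalkError as exc:
            exclusions.append({"bird_id": bird_id, "age_days": age,
                               "stage": "pose_extraction", "reason": str(exc)})
        except BroilerGaitError as exc:
            exclusions.append({"bird_id": bird_id, "age_days": age,
                               "stage": "cleaning", "reason": str(exc)})
    features_raw = (pd.concat(records, ignore_index=True) if records
                    else pd.DataFrame())
    exclusions = pd.DataFrame(
        exclusions, columns=["bird_id", "age_days", "stage", "reason"]
    )
    analyzed = features_raw["bird_id"].nunique() if len(features_raw) else 0
    log.append(
        f"pose extraction: {analyzed} birds analyzed, "
        f"{len(exclusions)} bird-ages excluded"
    )
    for _, row in exclusions.iterrows():
        log.append(f"  excluded {row.bird_id} at d{row.age_days}: {row.reason}")

    features = apply_outlier_rule(features_raw, config.analysis) \
        if len(features_raw) else features_raw
    n_out = len(features_raw) - len(features)
    log.append(f"outlier rule (2 x IQR): removed {n_out} of "
               f"{len(features_raw)} records")

    classes = class_table(cohort.score_table, cutoff=config.analysis.cutoff)
    share = classes["gait_class"].value_counts(normalize=True) * 100
    log.append(
        "gait classes: "
        + ", ".join(f"{k} {v:.1f}%" for k, v in share.items())
    )

    # birds excluded at the scoring age are excluded from the analysis ages
    top_age = max(sim.ages)
    excluded_top = set(
        exclusions.loc[exclusions["age_days"] == top_age, "bird_id"]
    )
    analysis_features = features[~features["bird_id"].isin(excluded_top)]

    table1 = descriptive_summary(analysis_features)
    table2 = _fit_table2(analysis_features, cohort.meta.table, classes,
                         top_age, config.analysis)
    corr_records = analysis_features[analysis_features["age_days"] == top_age]
    corr_r, corr_p = feature_correlations(corr_records)
    weight_contrasts = bodyweight_class_contrast(
        cohort.meta.table[~cohort.meta.table["bird_id"].isin(excluded_top)],
        classes,
    )
    kappa = kappa_report(cohort.score_table, cohort.repeat_table,
                         weighting=config.kappa_weighting)
    lik = likelihood_summary(cohort.trials.values(), config.clean)

    result = PipelineResult(
        config=config, cohort=cohort, features=features,
        features_raw=features_raw, classes=classes, table1=table1,
        table2=table2, correlations_r=corr_r, correlations_p=corr_p,
        weight_contrasts=weight_contrasts, kappa=kappa, likelihoods=lik,
        exclusions=exclusions, log_lines=log,
    )
    if outdir is not None:
        write_report(result, outdir)
    return result


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(outdir / "features.csv", index=False)
    result.classes.to_csv(outdir / "gait_classes.csv")
    result.table1.to_csv(outdir / "table1_descriptives.csv", index=False)
    result.table2.to_csv(outdir / "table2_class_effects.csv", index=False)
    result.correlations_r.to_csv(outdir / "correlations_r.csv")
    result.correlations_p.to_csv(outdir / "correlations_p.csv")
    result.weight_contrasts.to_csv(outdir / "bodyweight_contrasts.csv", index=False)
    result.kappa.to_csv(outdir / "kappa.csv", index=False)
    result.likelihoods.to_csv(outdir / "likelihood_summary.csv", index=False)
    result.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    versions = (f"numpy {np.__version__}, pandas {pd.__version__}")
    (outdir / "run_log.txt").write_text(
        "\n".join([*result.log_lines, versions]) + "\n"
    )


def export_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write a simulated cohort as DLC-style keypoint CSVs plus metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (bird_id, age), trial in cohort.trials.items():
        write_keypoint_table(trial, outdir / f"{bird_id}_d{age}.csv")
    cohort.meta.table.to_csv(outdir / "cohort_meta.csv", index=False)
    cohort.score_table.to_csv(outdir / "gait_scores.csv")
    cohort.repeat_table.to_csv(outdir / "gait_scores_repeat.csv")
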