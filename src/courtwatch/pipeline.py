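"""End-to-end pipeline: generate (or load) raw data, extract weekly features,
assemble and filter athlete-weeks, fit/project the PCA, build MDC thresholds
and flags, and screen component-psychology associations.

Every tunable named in the module design decisions lives in
:class:`PipelineConfig`; outputs carry the config hash and seed so reruns are
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import cmj, io as cw_io, oncourt, pca, reliability, weekly
from .association import association_screen
from .synthetic import (PSYCH_SCALES, ConfigurationError, SyntheticConfig,
                        SyntheticDataset, generate_dataset)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration with every design-decision tunable."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    out_dir: str = "courtwatch_out"
    # feature extraction
    asymmetry_method: str = "mean"        # or "max"
    asymmetry_basis: str = "magnitude"    # or "count" (on-court bins)
    # PCA
    pca_train_split: str = "first_season"  # or "pooled"
    pca_retention_threshold: float = 0.90
    # MDC / flags
    baseline_weeks: int = 5
    sem_method: str = "baseline_sd"        # or "ms_err"
    yellow_margin: float = 0.2
    baseline_pain_threshold: float = 4.0
    # association
    association_lag: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.synthetic.n_weeks < self.baseline_weeks + 1:
            raise ConfigurationError(
                f"n_weeks={self.synthetic.n_weeks} must exceed "
                f"baseline_weeks={self.baseline_weeks}")
        if self.pca_train_split not in ("first_season", "pooled"):
            raise ConfigurationError(
                f"unknown pca_train_split {self.pca_train_split!r}")
        self.synthetic = dataclasses.replace(self.synthetic,
                                             baseline_weeks=self.baseline_weeks)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "PipelineConfig":
        payload = dict(payload)
        syn = payload.pop("synthetic", {})
        if not isinstance(syn, SyntheticConfig):
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **payload)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)
                        if f.name != "out_dir"}  # paths don't alter results
            if isinstance(obj, Mapping):
                return {str(k): clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if hasattr(obj, "isoformat"):
                return obj.isoformat()
            return obj

        return clean(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# feature stages
# ---------------------------------------------------------------------------

def cmj_weekly_from_trials(trials, asymmetry_method: str = "mean"
                           ) -> pd.DataFrame:
    """Per-trial metric extraction + weekly averaging.

    ``trials``: records with athlete_id, season, week and a ``trace``.
    Returns one tidy row per athlete-week with the 10 CMJ variables plus a
    trial count.  Trials whose extraction fails are dropped with a log entry.
    """
    per_trial = {}
    for rec in trials:
        key = (rec["athlete_id"], rec["season"], rec["week"])
        try:
            metrics = cmj.extract_metrics(rec["trace"],
                                          asymmetry_method=asymmetry_method)
        except cmj.CMJError as exc:
            logger.warning("trial %s/%s/w%s#%s dropped: %s", *key,
                           rec.get("trial", "?"), exc)
            continue
        per_trial.setdefault(key, []).append(metrics)
    rows = []
    for (athlete, season, week), metrics_list in sorted(per_trial.items()):
        avg = cmj.average_trials(metrics_list)
        rows.append({"athlete_id": athlete, "season": season, "week": week,
                     **avg.as_dict(), "n_trials": len(metrics_list)})
    return pd.DataFrame(rows)


def oncourt_weekly_from_events(events: pd.DataFrame,
                               asymmetry_method: str = "mean",
                               asymmetry_basis: str = "magnitude"
                               ) -> pd.DataFrame:
    """Session-level reduction then weekly averaging of impact events.

    ``events`` must carry athlete_id, season, week, session_id, foot,
    magnitude_g.  Metrics are computed per session and averaged per week
    (unweighted), so weeks with different session counts stay comparable.
    """
    rows = []
    if len(events) == 0:
        return pd.DataFrame(columns=["athlete_id", "season", "week",
                                     *oncourt.OnCourtMetrics.FIELD_NAMES])
    for (athlete, season, week), group in events.groupby(
            ["athlete_id", "season", "week"], sort=True):
        sessions = [oncourt.session_metrics(sdf,
                                            asymmetry_method=asymmetry_method,
                                            asymmetry_basis=asymmetry_basis)
                    for _, sdf in group.groupby("session_id", sort=True)]
        wk = oncourt.weekly_oncourt(sessions)
        if wk is None:
            continue
        rows.append({"athlete_id": athlete, "season": season, "week": week,
                     **wk.as_dict(),
                     "n_sessions": sum(s is not None for s in sessions)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _baseline_week_range(config: PipelineConfig) -> list:
    off, _pre, _reg = config.synthetic.resolved_phase_weeks()
    return list(range(off + 1, off + 1 + config.baseline_weeks))


def run_pipeline(config: PipelineConfig,
                 dataset: Optional[SyntheticDataset] = None) -> dict:
    """Execute the full monitoring pipeline and write the report bundle.

    Stages: synthetic generation -> feature extraction -> athlete-week
    assembly -> complete-case filter -> PCA fit (training split) and
    projection -> preseason MDC thresholds and in-season flags -> rmcorr
    association screen.  Returns a report dict with the run log and the main
    tables; writes CSV/YAML outputs under ``config.out_dir``.
    """
    meta = {"config_hash": config.config_hash(), "seed": config.seed}
    out = config.out_dir
    log: dict = {"counts": {}, "meta": dict(meta)}

    if dataset is None:
        dataset = generate_dataset(config.synthetic, seed=config.seed)
    season_order = [s.season_label for s in dataset.schedules]
    log["counts"]["possible_weekly_observations_per_season"] = \
        weekly.possible_observations(config.synthetic.n_athletes,
                                     config.synthetic.n_weeks)
    log["counts"]["possible_weekly_observations_total"] = \
        weekly.possible_observations(config.synthetic.n_athletes,
                                     config.synthetic.n_weeks) * len(season_order)
    log["counts"]["cmj_trials"] = len(dataset.cmj_trials)
    log["counts"]["oncourt_sessions"] = int(
        dataset.impact_events["session_id"].nunique()) if len(dataset.impact_events) else 0
    log["counts"]["questionnaires_observed"] = int(
        dataset.psych[list(PSYCH_SCALES)].notna().any(axis=1).sum())

    # feature extraction
    cmj_weekly = cmj_weekly_from_trials(dataset.cmj_trials,
                                        config.asymmetry_method)
    oncourt_weekly = oncourt_weekly_from_events(dataset.impact_events,
                                                config.asymmetry_method,
                                                config.asymmetry_basis)
    observations = weekly.assemble_weeks(cmj_weekly, oncourt_weekly,
                                         dataset.psych)
    log["counts"]["weekly_observations_any_source"] = len(observations)
    matrix = weekly.complete_case_filter(observations)
    log["counts"]["complete_case_rows"] = len(matrix)

    # PCA: fit on the training split, project every complete week
    if config.pca_train_split == "first_season":
        train = matrix.loc[matrix.index.get_level_values("season")
                           == season_order[0]]
    else:
        train = matrix
    if len(train) == 0:
        raise weekly.PipelineError("PCA training split is empty")
    model = pca.fit_pca(train, config.pca_retention_threshold)
    scores = pca.project(model, matrix).reset_index()
    log["counts"]["pca_train_rows"] = len(train)
    log["pca"] = {
        "n_retained": model.n_retained,
        "cumulative_evr": float(np.cumsum(
            model.explained_variance_ratio)[model.n_retained - 1]),
        "diagnostics": pca.retention_diagnostics(model),
    }

    # MDC thresholds from the final season's preseason baseline window
    final_season = season_order[-1]
    baseline_weeks = _baseline_week_range(config)
    in_final = scores["season"] == final_season
    score_metrics = model.component_names
    psych_final = dataset.psych[dataset.psych["season"] == final_season]

    flag_frames = []
    thresholds_log = {}
    baseline_scores = scores[in_final & scores["week"].isin(baseline_weeks)]
    pain_base = psych_final[psych_final["week"].isin(baseline_weeks)]
    confounded = reliability.baseline_pain_warning(
        pain_base[["athlete_id", "pain"]], config.baseline_pain_threshold)
    log["baseline_pain_confounded_athletes"] = confounded

    metric_tables = {m: baseline_scores.pivot(index="athlete_id",
                                              columns="week", values=m)
                     for m in score_metrics}
    metric_tables.update({
        s: psych_final[psych_final["week"].isin(baseline_weeks)]
        .pivot(index="athlete_id", columns="week", values=s)
        for s in PSYCH_SCALES})

    weekly_tables = {m: scores[in_final][["athlete_id", "week", m]]
                     for m in score_metrics}
    weekly_tables.update({s: psych_final[["athlete_id", "week", s]]
                          for s in PSYCH_SCALES})

    for metric, table in metric_tables.items():
        try:
            window = reliability.BaselineWindow.from_frame(metric, table)
            thr = reliability.build_thresholds(window, config.sem_method)
        except reliability.ReliabilityError as exc:
            logger.info("thresholds[%s] skipped: %s", metric, exc)
            continue
        thresholds_log[metric] = {"icc": thr.icc, "sem": thr.sem,
                                  "mdc95": thr.mdc95,
                                  "n_subjects": window.n_subjects}
        flags = reliability.flag_cohort(weekly_tables[metric], thr,
                                        config.yellow_margin)
        flag_frames.append(flags)
    flags = (pd.concat(flag_frames, ignore_index=True) if flag_frames
             else pd.DataFrame())
    log["thresholds"] = thresholds_log
    if len(flags):
        log["counts"]["flags_by_status"] = (
            flags["status"].value_counts().to_dict())

    # associations over the applied (final) season
    associations = association_screen(
        scores[in_final], psych_final, lag=config.association_lag)
    log["counts"]["association_pairs"] = len(associations)
    if len(associations):
        sig = associations[associations["p_value"] < config.alpha]
        log["significant_associations"] = sig[
            ["x", "y", "r_rm", "p_value"]].to_dict("records")

    # report bundle
    cw_io.write_table(observations, os.path.join(out, "observations.csv"), meta)
    cw_io.write_table(matrix.reset_index(),
                      os.path.join(out, "analysis_matrix.csv"), meta)
    cw_io.save_model(model, os.path.join(out, "pca_model.yaml"), meta)
    cw_io.write_table(pca.loading_table(model).reset_index(names="variable"),
                      os.path.join(out, "loading_table.csv"), meta)
    cw_io.write_table(scores, os.path.join(out, "pc_scores.csv"), meta)
    cw_io.write_table(flags, os.path.join(out, "flags.csv"), meta)
    cw_io.write_table(associations, os.path.join(out, "associations.csv"), meta)
    if dataset.perturbations:
        pert = pd.DataFrame([{
            "athlete_id": p.athlete_id, "season": p.season,
            "onset_week": p.onset_week, "duration_weeks": p.duration_weeks,
            "pain_shift": p.pain_shift, "load_reduction": p.load_reduction,
            **{f"shift_{k}": v for k, v in p.asym_shift.items()},
        } for p in dataset.perturbations])
        cw_io.write_table(pert, os.path.join(out, "planted_perturbations.csv"),
                          meta)
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)

    return {"log": log, "observations": observations, "matrix": matrix,
            "model": model, "scores": scores, "flags": flags,
            "associations": associations, "dataset": dataset}
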