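"""End-to-end orchestration: simulate -> clean -> detect -> feature ->
label -> train -> score -> evaluate -> alert.

The pipeline is a pure function of its configuration and seed: every
random draw (cohort generation, pseudo-onsets, fold shuffling, forest
training, random-hour evaluation) derives from one master seed, so two
runs with the same inputs produce bit-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alerting, evaluation, labeling, trajectories
from .events import (
    EventDefinition,
    assignments_to_frame,
    classify_subjects,
    detect_hypotension_events,
    time_to_first_event_stats,
)
from .features import FeatureConfig, build_feature_matrix, feature_names
from .model import ModelSpec, cross_validate, oof_score_minutes, score_minutes
from .preprocess import DEFAULT_BOUNDS, ImputationConfig, VitalSeries, impute_missing, remove_artifacts
from .synthetic import SimConfig, SubjectTruth, generate_cohort, interventions_frame


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    event_defn: EventDefinition = field(default_factory=EventDefinition)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    labels: labeling.LabelConfig = field(default_factory=labeling.LabelConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    stacked_model: ModelSpec = field(default_factory=ModelSpec)
    policy: alerting.AlertPolicy = field(default_factory=alerting.AlertPolicy)
    cv_folds: int = 10
    lead_grid: tuple[int, ...] = tuple(range(0, 125, 5))
    trajectory_grid: tuple[int, ...] = tuple(range(0, 245, 5))
    true_positive_horizon_min: int | None = None
    sweep_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))


@dataclass
class PipelineResult:
    config: PipelineConfig
    seed: int
    truths: list[SubjectTruth]
    assignments: pd.DataFrame  # subject_id, group, first_onset_min, exclusion_reason, admission
    train_subjects: list[str]
    val_subjects: list[str]
    time_to_first_event: dict[str, float]
    mean_onset_train: float
    labeled: pd.DataFrame  # features + subject_id, split, label, lead_time_min
    cv_first: object
    val_scores: pd.DataFrame  # stay_id, minute, score (first stage, validation)
    train_oof_scores: pd.DataFrame
    group_by_stay: dict[str, str]
    onset_by_stay: dict[str, int | None]
    pseudo_onset_by_stay: dict[str, int]
    lead_curves: pd.DataFrame
    calibration: object
    trajectory_summary: pd.DataFrame
    patient_auprc: dict[str, float]
    stacked_cv: object
    val_stacked_scores: pd.DataFrame
    alert_metrics: dict[str, alerting.OperationalMetrics]
    alerts_per_hour_full_stay: dict[str, float]
    threshold_sweep: pd.DataFrame


def preprocess_stay(
    series: VitalSeries, imputation: ImputationConfig = ImputationConfig()
) -> VitalSeries:
    """Plausibility cleaning followed by causal gap filling for one stay."""
    clean, _ = remove_artifacts(series, DEFAULT_BOUNDS)
    return impute_missing(clean, imputation)


def _scores_series(scores: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        str(stay): grp.set_index("minute")["score"].sort_index()
        for stay, grp in scores.groupby("stay_id")
    }


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0) -> PipelineResult:
    """Run the whole analysis on a freshly simulated cohort."""
    config = config or PipelineConfig()
    master = np.random.SeedSequence(seed)
    sim_seed, label_seed, model_seed, eval_seed = (
        int(s) for s in master.generate_state(4, dtype=np.uint32) >> 1
    )
    sim = dataclasses.replace(config.sim, seed=sim_seed)
    model_spec = dataclasses.replace(config.model, seed=model_seed)
    stacked_spec = dataclasses.replace(config.stacked_model, seed=model_seed + 1)

    # --- simulate and preprocess -----------------------------------------
    raw_series, truths = generate_cohort(sim)
    clean = [preprocess_stay(s, config.imputation) for s in raw_series]
    stay_of_subject = {t.subject_id: t.stay_id for t in truths}
    subject_of_stay = {t.stay_id: t.subject_id for t in truths}
    admission = {t.subject_id: t.admission_datetime for t in truths}

    # --- events and cohort assignment ------------------------------------
    events = [ev for s in clean for ev in detect_hypotension_events(s, config.event_defn)]
    stays_df = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "stay_id": [t.stay_id for t in truths],
            "admission_datetime": [t.admission_datetime for t in truths],
        }
    )
    assignments = classify_subjects(stays_df, events, interventions_frame(truths))
    ttfe = time_to_first_event_stats(assignments)
    adf = assignments_to_frame(assignments)
    adf["admission_datetime"] = adf["subject_id"].map(admission)
    included = adf[adf["group"] != "excluded"].reset_index(drop=True)

    train_subjects, val_subjects = labeling.chronological_split(included)
    split_of = {s: "train" for s in train_subjects} | {s: "val" for s in val_subjects}

    group_by_subject = dict(zip(included["subject_id"], included["group"]))
    onset_by_subject = {
        row.subject_id: (None if np.isnan(row.first_onset_min) else int(row.first_onset_min))
        for row in included.itertuples()
    }
    group_by_stay = {stay_of_subject[s]: g for s, g in group_by_subject.items()}
    onset_by_stay = {stay_of_subject[s]: o for s, o in onset_by_subject.items()}

    mean_onset_train = float(
        np.mean(
            [
                onset_by_subject[s]
                for s in train_subjects
                if group_by_subject[s] == "hypotension"
            ]
        )
    )

    # --- features and labels (single pass over stays) ---------------------
    clean_by_stay = {s.stay_id: s for s in clean}
    included_subjects = sorted(split_of)
    names = feature_names(config.features)
    features_by_stay: dict[str, pd.DataFrame] = {}
    labeled_parts: list[pd.DataFrame] = []
    label_ss = np.random.SeedSequence(label_seed).spawn(len(included_subjects))
    for i, subj in enumerate(included_subjects):
        stay_id = stay_of_subject[subj]
        feats = build_feature_matrix(clean_by_stay[stay_id], config.features)
        # float32 storage keeps the 200-stay cohort comfortably in memory
        feats[names] = feats[names].astype(np.float32)
        features_by_stay[stay_id] = feats
        if group_by_subject[subj] == "hypotension":
            lab = labeling.label_hypotension_stay(feats, onset_by_subject[subj], config.labels)
        else:
            rng = np.random.default_rng(label_ss[i])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lab, pseudo = labeling.label_nonhypotension_stay(
                    feats, mean_onset_train, config.labels, rng
                )
            features_by_stay[stay_id].attrs["pseudo_onset"] = pseudo
        if len(lab):
            lab = lab.copy()
            lab["subject_id"] = subj
            lab["split"] = split_of[subj]
            labeled_parts.append(lab)
    pseudo_onset_by_stay = {
        stay: df.attrs["pseudo_onset"]
        for stay, df in features_by_stay.items()
        if df.attrs.get("pseudo_onset") is not None
    }
    labeled = pd.concat(labeled_parts, ignore_index=True)

    # --- first-stage model -------------------------------------------------
    train_rows = labeled[labeled["split"] == "train"].reset_index(drop=True)
    y_train = (train_rows["label"] == "positive").to_numpy(dtype=int)
    cv_first = cross_validate(
        train_rows[names],
        y_train,
        train_rows["subject_id"].to_numpy(),
        spec=model_spec,
        k=config.cv_folds,
    )

    # --- per-minute scores -------------------------------------------------
    val_parts, oof_parts = [], []
    for subj in included_subjects:
        stay_id = stay_of_subject[subj]
        feats = features_by_stay[stay_id]
        if split_of[subj] == "val":
            val_parts.append(score_minutes(cv_first.final_model, feats, names))
        else:
            oof_parts.append(
                oof_score_minutes(cv_first, feats, np.repeat(subj, len(feats)))
            )
    val_scores = pd.concat(val_parts, ignore_index=True)
    train_oof_scores = pd.concat(oof_parts, ignore_index=True)
    val_by_stay = _scores_series(val_scores)

    # --- evaluation --------------------------------------------------------
    def origin(stay: str) -> int | None:
        o = onset_by_stay.get(stay)
        return o if o is not None else pseudo_onset_by_stay.get(stay)

    aligned_val = {
        stay: trajectories.align_trajectory(s, origin(stay))
        for stay, s in val_by_stay.items()
        if origin(stay) is not None
    }
    lead_curves = evaluation.lead_time_curves(
        aligned_val, group_by_stay, list(config.lead_grid)
    )
    val_rows = labeled[labeled["split"] == "val"]
    val_rows = val_rows.merge(
        val_scores,
        left_on=["stay_id", "end_minute"],
        right_on=["stay_id", "minute"],
        how="inner",
    )
    calib = evaluation.calibration(
        val_rows["score"].to_numpy(), (val_rows["label"] == "positive").to_numpy(dtype=int)
    )
    traj_summary = trajectories.group_summary(
        aligned_val, {s: g for s, g in group_by_stay.items() if s in aligned_val},
        list(config.trajectory_grid),
    )
    patient_auprc = {
        mode: evaluation.patient_level_auprc(
            val_by_stay,
            group_by_stay,
            mode=mode,
            onset_by_stay={s: o for s, o in onset_by_stay.items() if o is not None},
            seed=eval_seed,
        )
        for mode in ("whole-stay", "random-hour")
    }

    # --- stacked model and alerting ---------------------------------------
    stacked_train = alerting.build_stacked_features(train_oof_scores)
    st = stacked_train.merge(
        train_rows[["stay_id", "end_minute", "label", "subject_id"]],
        left_on=["stay_id", "minute"],
        right_on=["stay_id", "end_minute"],
        how="inner",
    )
    stacked_cv = alerting.train_stacked(
        st,
        (st["label"] == "positive").to_numpy(dtype=int),
        st["subject_id"].to_numpy(),
        spec=stacked_spec,
        k=config.cv_folds,
    )
    stacked_val_feats = alerting.build_stacked_features(val_scores)
    sv_scores = stacked_cv.final_model.predict_proba(
        stacked_val_feats[alerting.stacked_feature_names()].to_numpy(dtype=float)
    )[:, 1]
    val_stacked_scores = pd.DataFrame(
        {
            "stay_id": stacked_val_feats["stay_id"].to_numpy(),
            "minute": stacked_val_feats["minute"].to_numpy(),
            "score": sv_scores,
        }
    )
    stacked_by_stay = _scores_series(val_stacked_scores)

    onsets_val = {s: onset_by_stay.get(s) for s in val_by_stay}
    monitored = {
        s: int((scores.index < onsets_val[s]).sum()) if onsets_val[s] is not None else len(scores)
        for s, scores in val_by_stay.items()
    }
    full_minutes = {s: len(scores) for s, scores in val_by_stay.items()}
    thr, lock = config.policy.threshold, config.policy.lockout_min
    variants = {
        "single_no_lockout": (val_by_stay, 0),
        "single_lockout": (val_by_stay, lock),
        "stacked_no_lockout": (stacked_by_stay, 0),
        "stacked_lockout": (stacked_by_stay, lock),
    }
    alert_metrics: dict[str, alerting.OperationalMetrics] = {}
    alerts_full: dict[str, float] = {}
    for name, (streams, lockout) in variants.items():
        alerts = alerting.generate_alerts(
            streams,
            alerting.AlertPolicy(threshold=thr, lockout_min=lockout),
            {s: o for s, o in onsets_val.items() if o is not None},
        )
        alert_metrics[name] = alerting.adjudicate_and_summarize(
            alerts, onsets_val, monitored, config.true_positive_horizon_min
        )
        alerts_full[name] = len(alerts) / (sum(full_minutes.values()) / 60.0)
    sweep = alerting.threshold_sweep(
        stacked_by_stay, onsets_val, monitored, np.asarray(config.sweep_thresholds), lock
    )

    return PipelineResult(
        config=config,
        seed=seed,
        truths=truths,
        assignments=adf,
        train_subjects=train_subjects,
        val_subjects=val_subjects,
        time_to_first_event=ttfe,
        mean_onset_train=mean_onset_train,
        labeled=labeled,
        cv_first=cv_first,
        val_scores=val_scores,
        train_oof_scores=train_oof_scores,
        group_by_stay=group_by_stay,
        onset_by_stay=onset_by_stay,
        pseudo_onset_by_stay=pseudo_onset_by_stay,
        lead_curves=lead_curves,
        calibration=calib,
        trajectory_summary=traj_summary,
        patient_auprc=patient_auprc,
        stacked_cv=stacked_cv,
        val_stacked_scores=val_stacked_scores,
        alert_metrics=alert_metrics,
        alerts_per_hour_full_stay=alerts_full,
        threshold_sweep=sweep,
    )


def lead_value(curves: pd.DataFrame, lead: int, metric: str = "auroc") -> float:
    """Convenience lookup of a lead-time curve value."""
    row = curves[curves["lead_min"] == lead]
    if not len(row):
        raise KeyError(f"lead time {lead} not on the grid")
    return float(row[metric].iloc[0])


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the run's tabular artifacts (CSV/JSON) and trajectory figure."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.assignments.to_csv(outdir / "assignments.csv", index=False)
    result.labeled.to_csv(outdir / "labeled.csv", index=False)
    result.val_scores.to_csv(outdir / "scores.csv", index=False)
    result.val_stacked_scores.to_csv(outdir / "stacked_scores.csv", index=False)
    result.lead_curves.to_csv(outdir / "lead_curves.csv", index=False)
    result.trajectory_summary.to_csv(outdir / "trajectory_summary.csv", index=False)
    result.threshold_sweep.to_csv(outdir / "threshold_sweep.csv", index=False)
    metrics = {
        "time_to_first_event": result.time_to_first_event,
        "cv_mean_auroc": result.cv_first.mean_auroc,
        "cv_mean_auprc": result.cv_first.mean_auprc,
        "cv_mean_brier": result.cv_first.mean_brier,
        "validation_brier": result.calibration.brier,
        "patient_auprc": result.patient_auprc,
        "alerts": {
            name: dataclasses.asdict(m) for name, m in result.alert_metrics.items()
        },
        "alerts_per_hour_full_stay": result.alerts_per_hour_full_stay,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    labeled_hash = hashlib.sha256(
        result.labeled.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "seed": result.seed,
        "n_subjects": result.config.sim.n_subjects,
        "model_family": result.config.model.family,
        "feature_names": result.cv_first.feature_names,
        "training_set_sha256": labeled_hash,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    try:
        trajectories.plot_group_summary(result.trajectory_summary, outdir / "trajectories.png")
    except Exception:  # plotting is best-effort; headless backends can differ
        pass
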