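"""End-to-end orchestration: simulate -> segment -> extract -> statistics -> models.

Failures in a single participant-task-trial are logged and skipped, never
fatal; every stage logs its input/output row counts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import features, io, mlpipe, reliability, segment, synth
from .errors import SegmentationError

__all__ = ["RunConfig", "run_all", "segment_cohort", "extract_cohort", "summarize_icc_vs_rc"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "tuglab_run"
    groups: list[str] = field(default_factory=lambda: ["control", "mild", "moderate", "severe"])
    n_per_group: int = 10
    seed: int = 0
    tasks: list[str] = field(default_factory=lambda: list(synth.TASKS))
    n_trees: int = 500
    rank_trees: int = 200
    aic_trees: int = 200
    max_candidates: int = 15
    feature_sets: list[str] = field(default_factory=lambda: list(mlpipe.FEATURE_SETS))
    profiles_path: str | None = None
    sd_mode: str = "pooled"
    rc_flag_threshold: float = 0.10
    write_recordings: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def segment_cohort(
    recordings: list[synth.SensorRecording],
    config: segment.SegmentationConfig | None = None,
) -> list[segment.SegmentedTask]:
    """Segment every recording, splitting 32-foot walks into two 16-foot trials."""
    out: list[segment.SegmentedTask] = []
    n_failed = 0
    for rec in recordings:
        try:
            if rec.task == "walk32ft":
                out.extend(segment.split_32ft(rec, config))
            else:
                out.append(segment.segment_tug(rec, config))
        except SegmentationError as exc:
            n_failed += 1
            log.warning("skipping %s %s trial %s: %s", rec.participant_id, rec.task, rec.trial_index, exc)
    log.info("segmented %d recordings -> %d trials (%d failed)", len(recordings), len(out), n_failed)
    return out


def extract_cohort(
    segmented: list[segment.SegmentedTask],
    config: features.FeatureConfig | None = None,
) -> pd.DataFrame:
    frames = [features.extract_all(st, config) for st in segmented]
    measures = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=features.MEASURE_COLUMNS)
    log.info("extracted %d measure rows from %d trials", len(measures), len(segmented))
    return measures


def summarize_icc_vs_rc(
    rel: pd.DataFrame,
    measures: pd.DataFrame,
    good_icc: float = 0.75,
    rc_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per group x task: total-duration ICC, median RC, between-subject variance,
    and a flag for groups that are simultaneously 'good' by ICC and unstable by RC."""
    total = rel[rel["measure"] == "total_duration"]
    rows = []
    for r in total.itertuples():
        sub = measures[
            (measures["group"] == r.group)
            & (measures["task"] == r.task)
            & (measures["measure"] == "total_duration")
        ]
        participant_means = sub.groupby("participant_id")["value"].mean()
        between_var = float(participant_means.var(ddof=1)) if len(participant_means) > 1 else float("nan")
        flagged = bool(r.icc >= good_icc and abs(r.median_abs_rc) >= rc_threshold)
        rows.append(
            {
                "group": r.group,
                "task": r.task,
                "icc": r.icc,
                "median_rc": r.median_rc,
                "median_abs_rc": r.median_abs_rc,
                "between_subject_variance": between_var,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict[str, str]:
    """Execute the full pipeline and write every summary artifact.

    Returns a mapping from artifact name to path.
    """
    profiles = synth.load_group_profiles(config.profiles_path)
    unknown = [g for g in config.groups if g not in profiles]
    if unknown:
        raise ValueError(f"unknown group profiles: {unknown}")
    if not config.groups or config.n_per_group < 1:
        raise ValueError("empty cohort configuration")
    os.makedirs(config.out_dir, exist_ok=True)
    artifacts: dict[str, str] = {}

    specs = [(profiles[g], config.n_per_group) for g in config.groups]
    recordings = synth.simulate_cohort(specs, seed=config.seed, tasks=tuple(config.tasks))
    log.info("simulated %d recordings", len(recordings))
    if config.write_recordings:
        manifest = io.write_cohort(recordings, config.out_dir)
    else:
        manifest = pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "group": r.group,
                    "task": r.task,
                    "trial": r.trial_index or 0,
                    "path": "",
                }
                for r in recordings
            ],
            columns=io.MANIFEST_COLUMNS,
        )
        manifest.to_csv(os.path.join(config.out_dir, "manifest.csv"), index=False)
    artifacts["manifest"] = os.path.join(config.out_dir, "manifest.csv")

    segmented = segment_cohort(recordings)
    seg_frame = pd.concat([io.segments_to_frame(st) for st in segmented], ignore_index=True)
    artifacts["segments"] = os.path.join(config.out_dir, "segments.csv")
    seg_frame.to_csv(artifacts["segments"], index=False)

    measures = extract_cohort(segmented)
    artifacts["measures"] = os.path.join(config.out_dir, "measures.csv")
    measures.to_csv(artifacts["measures"], index=False)

    rel = reliability.reliability_table(measures, sd_mode=config.sd_mode)
    artifacts["reliability"] = os.path.join(config.out_dir, "reliability.csv")
    rel.to_csv(artifacts["reliability"], index=False)

    paradox = summarize_icc_vs_rc(rel, measures, rc_threshold=config.rc_flag_threshold)
    artifacts["paradox"] = os.path.join(config.out_dir, "paradox.csv")
    paradox.to_csv(artifacts["paradox"], index=False)

    # trial-wise diagnostic models: each PD-like group vs control
    eval_dir = os.path.join(config.out_dir, "eval")
    os.makedirs(eval_dir, exist_ok=True)
    ml_config = mlpipe.MLConfig(
        n_trees=config.n_trees,
        rank_trees=config.rank_trees,
        aic_trees=config.aic_trees,
        max_candidates=config.max_candidates,
    )
    ml_tasks = [t for t in ("TUG", "cogTUG") if t in config.tasks]
    if "walk32ft" in config.tasks:
        ml_tasks.append("walk16ft")
    case_groups = [g for g in config.groups if g != "control"]
    acc_rows = []
    for task in ml_tasks:
        for group in case_groups:
            for fset in config.feature_sets:
                try:
                    if fset == "duration_only":
                        fm = mlpipe.build_feature_matrix(measures, manifest, task, group, "duration_only")
                        ev = mlpipe.duration_only_model(
                            fm.X["mean_total_duration"], fm.y, seed=config.seed, config=ml_config
                        )
                        ev.task, ev.group = task, group
                    else:
                        fm = mlpipe.build_feature_matrix(measures, manifest, task, group, fset)
                        ev = mlpipe.evaluate(fm, seed=config.seed, config=ml_config)
                except ValueError as exc:
                    log.warning("skipping model %s/%s/%s: %s", task, group, fset, exc)
                    continue
                path = os.path.join(eval_dir, f"{task}_{group}_{fset}.json")
                with open(path, "w") as fh:
                    json.dump(
                        {
                            "task": task,
                            "group": group,
                            "feature_set": fset,
                            "accuracy": ev.accuracy,
                            "votes": ev.votes.reset_index().to_dict(orient="records"),
                        },
                        fh,
                        indent=1,
                    )
                acc_rows.append(
                    {"task": task, "group": group, "feature_set": fset, "accuracy": ev.accuracy}
                )
    artifacts["eval_dir"] = eval_dir
    if acc_rows:
        acc = pd.DataFrame(acc_rows)
        try:
            cells, summary = mlpipe.compare_trial_models(acc)
            artifacts["comparison"] = os.path.join(config.out_dir, "comparison.csv")
            cells.to_csv(artifacts["comparison"], index=False)
            artifacts["comparison_summary"] = os.path.join(config.out_dir, "comparison_summary.csv")
            summary.to_csv(artifacts["comparison_summary"], index=False)
        except ValueError as exc:
            log.warning("comparison table skipped: %s", exc)
    return artifacts
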