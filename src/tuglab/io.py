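"""Plain-CSV persistence for recordings, manifests and segment annotations."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .segment import Segment, SegmentedTask
from .synth import SensorRecording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_cohort",
    "segments_to_frame",
    "frame_to_segmented_task",
]

RECORDING_COLUMNS = ["time_s", "acc_v", "acc_ml", "acc_ap", "gyr_yaw", "gyr_pitch", "gyr_roll"]
MANIFEST_COLUMNS = ["participant_id", "group", "task", "trial", "path"]
SEGMENT_COLUMNS = ["participant_id", "task", "trial", "label", "start_s", "end_s"]


def write_recording_csv(rec: SensorRecording, path: str) -> None:
    n = rec.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.fs,
            "acc_v": rec.acc_v,
            "acc_ml": rec.acc_ml,
            "acc_ap": rec.acc_ap,
            "gyr_yaw": rec.gyr_yaw,
            "gyr_pitch": rec.gyr_pitch,
            "gyr_roll": rec.gyr_roll,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(
    path: str, task: str, trial_index: int | None, participant_id: str, group: str = ""
) -> SensorRecording:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dt = np.diff(df["time_s"].to_numpy())
    fs = 1.0 / float(np.median(dt))
    return SensorRecording(
        fs=round(fs, 6),
        acc_v=df["acc_v"].to_numpy(),
        acc_ml=df["acc_ml"].to_numpy(),
        acc_ap=df["acc_ap"].to_numpy(),
        gyr_yaw=df["gyr_yaw"].to_numpy(),
        gyr_pitch=df["gyr_pitch"].to_numpy(),
        gyr_roll=df["gyr_roll"].to_numpy(),
        task=task,
        trial_index=trial_index,
        participant_id=participant_id,
        group=group,
    )


def write_cohort(recordings: list[SensorRecording], out_dir: str) -> pd.DataFrame:
    """Write one CSV per recording plus a manifest; returns the manifest frame."""
    rec_dir = os.path.join(out_dir, "recordings")
    os.makedirs(rec_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        trial = rec.trial_index if rec.trial_index is not None else 0
        fname = f"{rec.participant_id}_{rec.task}_t{trial}.csv"
        path = os.path.join(rec_dir, fname)
        write_recording_csv(rec, path)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "task": rec.task,
                "trial": trial,
                "path": os.path.relpath(path, out_dir),
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def segments_to_frame(seg_task: SegmentedTask) -> pd.DataFrame:
    fs = seg_task.fs
    return pd.DataFrame(
        {
            "participant_id": seg_task.recording.participant_id,
            "task": seg_task.task,
            "trial": seg_task.trial_index,
            "label": [s.label for s in seg_task.segments],
            "start_s": [s.start_idx / fs for s in seg_task.segments],
            "end_s": [s.end_idx / fs for s in seg_task.segments],
        }
    )[SEGMENT_COLUMNS]


def frame_to_segmented_task(
    rows: pd.DataFrame, rec: SensorRecording, task: str, trial: int | None
) -> SegmentedTask:
    fs = rec.fs
    segs = [
        Segment(r.label, int(round(r.start_s * fs)), int(round(r.end_s * fs)))
        for r in rows.sort_values("start_s").itertuples()
    ]
    return SegmentedTask(rec, segs, task, trial)
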