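"""Subtask segmentation of mobility-task recordings.

Turns are located on the angular position obtained by trapezoidal
integration of the yaw angular velocity; chair transitions and walking
bouts are delimited from the turns and from a gait-band envelope criterion
on the vertical acceleration.  All intervals are 0-based, half-open
``[start, end)`` sample index pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .errors import SegmentationError
from .synth import SensorRecording

__all__ = [
    "Segment",
    "SegmentedTask",
    "SegmentationConfig",
    "angular_position",
    "detect_turns",
    "segment_tug",
    "split_32ft",
]

TUG_LABELS = ("sit_to_stand", "walk1", "turn1", "walk2", "turn2", "stand_to_sit")


@dataclass(frozen=True)
class Segment:
    label: str
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_idx < self.end_idx):
            raise ValueError(f"invalid segment bounds [{self.start_idx}, {self.end_idx})")

    def duration_s(self, fs: float) -> float:
        return (self.end_idx - self.start_idx) / fs


@dataclass
class SegmentedTask:
    """Ordered, non-overlapping subtask intervals over one recording."""

    recording: SensorRecording
    segments: list[Segment]
    task: str
    trial_index: int | None = None

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_idx < a.end_idx:
                raise ValueError("segments overlap or are out of order")
        n = self.recording.n_samples
        if self.segments and self.segments[-1].end_idx > n:
            raise ValueError("segment extends past the recording")

    @property
    def fs(self) -> float:
        return self.recording.fs

    def __getitem__(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def total_span_s(self) -> float:
        return sum(s.duration_s(self.fs) for s in self.segments)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds; defaults documented rather than inherited from any source."""

    min_angle_deg: float = 90.0
    angle_smooth_s: float = 0.25
    #: minimum smoothed yaw velocity (deg/s) to seed a candidate turn
    turn_seed_velocity: float = 15.0
    #: quantile trimming of a turn's net angular change before zero-crossing extension
    trim_quantiles: tuple[float, float] = (0.05, 0.95)
    #: velocity magnitude (deg/s) treated as zero during boundary extension
    zero_velocity_eps: float = 2.0
    #: gait band for the walk-onset envelope (Hz)
    gait_band: tuple[float, float] = (1.5, 6.0)
    envelope_window_s: float = 0.25
    baseline_window_s: float = 0.4
    onset_factor: float = 3.0
    #: absolute envelope floor (g); keeps the criterion meaningful on noiseless input
    onset_floor_g: float = 0.04
    onset_sustain_s: float = 0.5


DEFAULT_CONFIG = SegmentationConfig()


def angular_position(gyr_yaw: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integral of yaw velocity -> angle in degrees."""
    gyr_yaw = np.asarray(gyr_yaw, dtype=float)
    if gyr_yaw.ndim != 1 or len(gyr_yaw) < 2:
        raise ValueError("need a 1-D series of length >= 2")
    if fs <= 0:
        raise ValueError("fs must be > 0")
    return cumulative_trapezoid(gyr_yaw, dx=1.0 / fs, initial=0.0)


def _smooth(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    win = max(1, int(round(window_s * fs)))
    return uniform_filter1d(x, size=win, mode="nearest")


def detect_turns(
    angle: np.ndarray,
    fs: float,
    min_angle_deg: float = 90.0,
    config: SegmentationConfig | None = None,
) -> list[tuple[int, int]]:
    """Maximal monotone sweeps of the smoothed angle covering >= ``min_angle_deg``.

    Candidate intervals are seeded where the smoothed angular velocity
    exceeds a small threshold, extended to the surrounding velocity zero
    crossings, trimmed to the 5%/95% quantiles of the net angular change and
    re-extended to the nearest zero crossing.  Sign of rotation is ignored.
    """
    cfg = config or DEFAULT_CONFIG
    angle = np.asarray(angle, dtype=float)
    n = len(angle)
    if n < 3:
        return []
    sm = _smooth(angle, fs, cfg.angle_smooth_s)
    vel = np.gradient(sm) * fs

    turns: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if abs(vel[i]) < cfg.turn_seed_velocity:
            i += 1
            continue
        sign = np.sign(vel[i])
        # extend to zero crossings of the (smoothed) velocity on both sides
        eps = cfg.zero_velocity_eps
        start = i
        while start > 0 and sign * vel[start - 1] > eps:
            start -= 1
        end = i
        while end < n - 1 and sign * vel[end + 1] > eps:
            end += 1
        end += 1  # half-open
        i = end
        net = sm[end - 1] - sm[start]
        if abs(net) < min_angle_deg:
            continue
        frac = (sm[start:end] - sm[start]) / net
        lo, hi = cfg.trim_quantiles
        above = np.nonzero(frac >= lo)[0]
        below = np.nonzero(frac <= hi)[0]
        t_start = start + int(above[0]) if len(above) else start
        t_end = start + int(below[-1]) + 1 if len(below) else end
        # re-extend outward to the nearest velocity zero crossing
        while t_start > start and sign * vel[t_start - 1] > eps:
            t_start -= 1
        while t_end < end and sign * vel[t_end] > eps:
            t_end += 1
        if turns and t_start < turns[-1][1]:
            t_start = turns[-1][1]
        if t_end - t_start >= 2:
            turns.append((t_start, t_end))
    return turns


def _walk_onset(rec: SensorRecording, cfg: SegmentationConfig, search_end: int) -> int:
    """First sample where the gait-band vertical-acceleration envelope stays
    above ``onset_factor`` x seated-baseline SD for ``onset_sustain_s``."""
    fs = rec.fs
    acc = np.asarray(rec.acc_v, dtype=float)
    acc = acc - acc.mean()
    lo, hi = cfg.gait_band
    sos = butter(4, [lo / (fs / 2), min(hi / (fs / 2), 0.99)], btype="band", output="sos")
    band = sosfiltfilt(sos, acc)
    env = np.sqrt(_smooth(band**2, fs, cfg.envelope_window_s))
    n_base = max(2, int(round(cfg.baseline_window_s * fs)))
    thresh = max(cfg.onset_factor * float(np.std(band[:n_base])), cfg.onset_floor_g)
    sustain = max(1, int(round(cfg.onset_sustain_s * fs)))
    above = env[:search_end] > thresh
    # first index opening a run of >= sustain consecutive True values
    run = 0
    for idx in range(len(above)):
        run = run + 1 if above[idx] else 0
        if run >= sustain:
            return idx - sustain + 1
    raise SegmentationError("no walking onset found before the first turn")


def segment_tug(rec: SensorRecording, config: SegmentationConfig | None = None) -> SegmentedTask:
    """Six ordered subtasks: sit_to_stand, walk1, turn1, walk2, turn2, stand_to_sit."""
    cfg = config or DEFAULT_CONFIG
    if rec.task not in ("TUG", "cogTUG"):
        raise ValueError(f"segment_tug expects a TUG/cogTUG recording, got {rec.task!r}")
    angle = angular_position(rec.gyr_yaw, rec.fs)
    turns = detect_turns(angle, rec.fs, cfg.min_angle_deg, cfg)
    if len(turns) != 2:
        raise SegmentationError(f"expected 2 turns in {rec.task}, found {len(turns)}")
    (t1s, t1e), (t2s, t2e) = turns
    onset = _walk_onset(rec, cfg, search_end=t1s)
    if onset <= 0:
        onset = 1
    n = rec.n_samples
    segments = [
        Segment("sit_to_stand", 0, onset),
        Segment("walk1", onset, t1s),
        Segment("turn1", t1s, t1e),
        Segment("walk2", t1e, t2s),
        Segment("turn2", t2s, t2e),
        Segment("stand_to_sit", t2e, n),
    ]
    return SegmentedTask(rec, segments, rec.task, rec.trial_index)


def split_32ft(
    rec: SensorRecording, config: SegmentationConfig | None = None
) -> tuple[SegmentedTask, SegmentedTask]:
    """Split the 32-foot walk into two 16-foot walk/turn/walk trials.

    The middle (second) turn is omitted: trial A ends at its onset and trial
    B starts at its end.
    """
    cfg = config or DEFAULT_CONFIG
    if rec.task != "walk32ft":
        raise ValueError(f"split_32ft expects a walk32ft recording, got {rec.task!r}")
    angle = angular_position(rec.gyr_yaw, rec.fs)
    turns = detect_turns(angle, rec.fs, cfg.min_angle_deg, cfg)
    if len(turns) != 3:
        raise SegmentationError(f"expected 3 turns in walk32ft, found {len(turns)}")
    (a1s, a1e), (mid_s, mid_e), (b1s, b1e) = turns
    n = rec.n_samples
    trial_a = SegmentedTask(
        rec,
        [Segment("walk", 0, a1s), Segment("turn", a1s, a1e), Segment("walk", a1e, mid_s)],
        "walk16ft",
        trial_index=1,
    )
    trial_b = SegmentedTask(
        rec,
        [Segment("walk", mid_e, b1s), Segment("turn", b1s, b1e), Segment("walk", b1e, n)],
        "walk16ft",
        trial_index=2,
    )
    return trial_a, trial_b
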