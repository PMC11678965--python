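"""Synthetic IMU recordings and two-trial measure tables.

Generates 6-axis sensor recordings with the structure of the three mobility
tasks (TUG, cogTUG, 32-foot walk with three turns) plus long-format
participant x trial measure tables drawn from an additive two-way model
``Y_ij = mu + p_i + t_j + e_ij``.  Every recording carries a ``truth``
dictionary (segment boundaries, step peak times, turn angles) so that the
segmentation and feature stages can be tested against ground truth.

Units: acceleration in g, angular velocity in degrees/s, sampling in Hz.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroupParams",
    "VarianceComponents",
    "SensorRecording",
    "gait_waveform",
    "simulate_recording",
    "simulate_cohort",
    "simulate_measure_table",
    "load_group_profiles",
]

TASKS = ("TUG", "cogTUG", "walk32ft")

#: nominal seconds to cover one 8-foot walk bout at unit speed scale
NOMINAL_WALK_S = 3.5
#: extra slowing applied to every segment under the dual (counting) task
DUAL_TASK_FACTOR = 1.12
#: quiet sitting lead-in / tail included in the chair-transition segments
QUIET_S = 0.5
#: relative jitter on turn/transition durations (residual trial-to-trial noise)
SEGMENT_JITTER_CV = 0.03

_TRANSITION_AMP_AP = 0.35  # g
_TRANSITION_AMP_V = 0.25  # g
_GAIT_AMP_V = 0.25  # g
_GAIT_AMP_AP = 0.15  # g
_TURN_GAIT_SCALE = 0.5
_GYRO_NOISE_PER_G = 100.0  # deg/s of yaw noise per 1 g of accelerometer noise


@dataclass(frozen=True)
class GroupParams:
    """Simulation knobs for one participant group."""

    group_label: str
    step_frequency_hz: float = 1.0  # stride rate = cadence / 2
    step_frequency_cv: float = 0.03
    walk_speed_scale: float = 1.0
    turn_duration_s: float = 2.0
    transition_duration_s: float = 1.5
    noise_sd_g: float = 0.02
    between_subject_sd: float = 0.08
    trial2_multiplier: float = 1.0
    asymmetry_ratio: float = 1.0  # alternate-step amplitude ratio, 1 = symmetric

    def __post_init__(self) -> None:
        if not (0.5 < self.step_frequency_hz < 3.0):
            raise ValueError("step_frequency_hz must be in (0.5, 3)")
        for name in ("walk_speed_scale", "turn_duration_s", "transition_duration_s", "trial2_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("step_frequency_cv", "noise_sd_g", "between_subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.asymmetry_ratio <= 0:
            raise ValueError("asymmetry_ratio must be > 0")


@dataclass(frozen=True)
class VarianceComponents:
    """Generative counterparts of the ANOVA mean squares (participants/trials/error)."""

    mu: float
    sigma_p: float
    sigma_t: float
    sigma_e: float

    def __post_init__(self) -> None:
        if min(self.sigma_p, self.sigma_t, self.sigma_e) < 0:
            raise ValueError("variance component SDs must be >= 0")


@dataclass
class SensorRecording:
    """One task trial's synchronized 6-axis time series."""

    fs: float
    acc_v: np.ndarray
    acc_ml: np.ndarray
    acc_ap: np.ndarray
    gyr_yaw: np.ndarray
    gyr_pitch: np.ndarray
    gyr_roll: np.ndarray
    task: str
    trial_index: int | None
    participant_id: str
    group: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        n = len(self.acc_v)
        for ch in self.channels():
            if len(ch) != n:
                raise ValueError("all channels must have equal length")
        if n < self.fs:
            raise ValueError("recording must be at least 1 s long")

    def channels(self) -> tuple[np.ndarray, ...]:
        return (self.acc_v, self.acc_ml, self.acc_ap, self.gyr_yaw, self.gyr_pitch, self.gyr_roll)

    @property
    def n_samples(self) -> int:
        return len(self.acc_v)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def gait_waveform(
    n_steps: int,
    step_period_s: float,
    fs: float,
    rng: np.random.Generator,
    amplitude: float = _GAIT_AMP_V,
    cv: float = 0.0,
    asymmetry: float = 1.0,
    harmonic: float = 0.35,
    amp_jitter: float = 0.05,
    normalize_total: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One full oscillation cycle per step, amplitude-jittered, with one harmonic.

    Returns ``(signal, peak_indices)`` where ``peak_indices`` are the
    ground-truth step peak sample positions.  Alternate steps are scaled by
    ``asymmetry`` so step symmetry is controllable.  With
    ``normalize_total`` the jittered step intervals are rescaled so their
    sum is exactly ``n_steps * step_period_s``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    intervals = step_period_s * np.clip(1.0 + cv * rng.standard_normal(n_steps), 0.5, 1.5)
    if normalize_total:
        intervals *= (n_steps * step_period_s) / intervals.sum()
    # sample counts from cumulative step boundaries so timing does not drift
    # with the sampling rate
    edges = np.round(np.concatenate([[0.0], np.cumsum(intervals)]) * fs).astype(int)
    pieces: list[np.ndarray] = []
    peaks: list[int] = []
    offset = 0
    for k in range(n_steps):
        n = max(2, int(edges[k + 1] - edges[k]))
        x = np.arange(n) / n
        a = amplitude * (1.0 if k % 2 == 0 else asymmetry)
        a *= 1.0 + amp_jitter * rng.standard_normal()
        seg = a * (np.sin(2 * np.pi * x) + harmonic * np.sin(4 * np.pi * x))
        peaks.append(offset + int(np.argmax(seg)))
        pieces.append(seg)
        offset += n
    return np.concatenate(pieces), np.asarray(peaks, dtype=int)


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth unit-peak hump on n samples, zero at both ends."""
    x = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2 * np.pi * x))


def _zeros_block(n: int) -> dict[str, np.ndarray]:
    return {ch: np.zeros(n) for ch in ("acc_v", "acc_ml", "acc_ap", "gyr_yaw", "gyr_pitch", "gyr_roll")}


class _Assembler:
    """Accumulates labeled channel blocks and the truth bookkeeping."""

    def __init__(self, fs: float) -> None:
        self.fs = fs
        self.blocks: list[dict[str, np.ndarray]] = []
        self.segments: list[tuple[str, int, int]] = []
        self.step_peaks: dict[str, np.ndarray] = {}
        self.turn_angles: dict[str, float] = {}
        self._cursor = 0

    def add(self, label: str, block: dict[str, np.ndarray], peaks: np.ndarray | None = None) -> None:
        n = len(block["acc_v"])
        self.blocks.append(block)
        self.segments.append((label, self._cursor, self._cursor + n))
        if peaks is not None:
            self.step_peaks[label] = peaks + self._cursor
        self._cursor += n

    def concat(self) -> dict[str, np.ndarray]:
        return {
            ch: np.concatenate([b[ch] for b in self.blocks])
            for ch in ("acc_v", "acc_ml", "acc_ap", "gyr_yaw", "gyr_pitch", "gyr_roll")
        }


def _build_walk(
    params: GroupParams,
    fs: float,
    duration_s: float,
    rng: np.random.Generator,
    amp_scale: float = 1.0,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    step_rate = 2.0 * params.step_frequency_hz
    n_steps = max(4, int(round(duration_s * step_rate)))
    step_period = duration_s / n_steps
    sig_v, peaks = gait_waveform(
        n_steps,
        step_period,
        fs,
        rng,
        amplitude=_GAIT_AMP_V * amp_scale,
        cv=params.step_frequency_cv,
        asymmetry=params.asymmetry_ratio,
        normalize_total=True,
    )
    # AP channel mirrors the step structure at reduced amplitude
    sig_ap, _ = gait_waveform(
        n_steps,
        step_period,
        fs,
        rng,
        amplitude=_GAIT_AMP_AP * amp_scale,
        cv=params.step_frequency_cv,
        asymmetry=params.asymmetry_ratio,
        normalize_total=True,
    )
    n = len(sig_v)
    if len(sig_ap) >= n:
        sig_ap = sig_ap[:n]
    else:
        sig_ap = np.pad(sig_ap, (0, n - len(sig_ap)))
    block = _zeros_block(n)
    block["acc_v"] = sig_v
    block["acc_ap"] = sig_ap
    return block, peaks


def _build_turn(
    params: GroupParams,
    fs: float,
    duration_s: float,
    sign: float,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray, float]:
    """Raised-cosine yaw pulse integrating to ``sign * 180`` degrees, with in-turn steps."""
    block, peaks = _build_walk(params, fs, duration_s, rng, amp_scale=_TURN_GAIT_SCALE)
    n = len(block["acc_v"])
    actual_dur = n / fs
    omega_max = sign * 360.0 / actual_dur  # integral of the hump = omega_max * T / 2
    block["gyr_yaw"] = omega_max * _raised_cosine(n)
    return block, peaks, sign * 180.0


def _build_transition(
    fs: float, duration_s: float, sign: float, lead_s: float, tail_s: float
) -> dict[str, np.ndarray]:
    """Band-limited chair-transition pulse in AP and vertical, padded with quiet sitting."""
    n_pulse = max(2, int(round(duration_s * fs)))
    hump = _raised_cosine(n_pulse)
    n_lead = int(round(lead_s * fs))
    n_tail = int(round(tail_s * fs))
    block = _zeros_block(n_lead + n_pulse + n_tail)
    sl = slice(n_lead, n_lead + n_pulse)
    block["acc_ap"][sl] = sign * _TRANSITION_AMP_AP * hump
    block["acc_v"][sl] = _TRANSITION_AMP_V * hump
    return block


def _jitter(rng: np.random.Generator, cv: float = SEGMENT_JITTER_CV) -> float:
    return float(np.clip(1.0 + cv * rng.standard_normal(), 0.7, 1.3))


def simulate_recording(
    params: GroupParams,
    task: str,
    trial_index: int = 1,
    seed: int = 0,
    *,
    fs: float = 100.0,
    participant_id: str = "p0",
    speed_offset: float = 1.0,
) -> SensorRecording:
    """Simulate one trial of a mobility task.

    ``speed_offset`` is the per-participant random speed multiplier; cohorts
    draw it once per participant and share it across trials.  All segment
    durations of trial 2 are scaled by ``params.trial2_multiplier``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if trial_index not in (1, 2):
        raise ValueError("trial_index must be 1 or 2")
    # separate streams so segment-duration jitter draws are identical across
    # trials of the same seed: trial-2 durations then scale structurally
    rng_jit = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    scale = speed_offset
    if task == "cogTUG":
        scale *= DUAL_TASK_FACTOR
    trial_mult = params.trial2_multiplier if trial_index == 2 else 1.0

    asm = _Assembler(fs)
    if task in ("TUG", "cogTUG"):
        walk_s = NOMINAL_WALK_S * params.walk_speed_scale * scale * trial_mult
        turn_s = params.turn_duration_s * scale * trial_mult
        trans_s = params.transition_duration_s * scale * trial_mult
        asm.add("sit_to_stand", _build_transition(fs, trans_s * _jitter(rng_jit), +1.0, QUIET_S, 0.0))
        block, peaks = _build_walk(params, fs, walk_s * _jitter(rng_jit), rng)
        asm.add("walk1", block, peaks)
        block, peaks, angle = _build_turn(params, fs, turn_s * _jitter(rng_jit), +1.0, rng)
        asm.add("turn1", block, peaks)
        asm.turn_angles["turn1"] = angle
        block, peaks = _build_walk(params, fs, walk_s * _jitter(rng_jit), rng)
        asm.add("walk2", block, peaks)
        block, peaks, angle = _build_turn(params, fs, turn_s * _jitter(rng_jit), -1.0, rng)
        asm.add("turn2", block, peaks)
        asm.turn_angles["turn2"] = angle
        asm.add("stand_to_sit", _build_transition(fs, trans_s * _jitter(rng_jit), -1.0, 0.0, QUIET_S))
        rec_trial: int | None = trial_index
    else:  # walk32ft: four 8-foot bouts, three alternating ~180 degree turns
        walk_s = NOMINAL_WALK_S * params.walk_speed_scale * scale
        turn_s = params.turn_duration_s * scale
        sign = +1.0
        for i in range(1, 5):
            seg_mult = trial_mult if i >= 3 else 1.0  # second 16-ft trial scaled
            block, peaks = _build_walk(params, fs, walk_s * seg_mult * _jitter(rng_jit), rng)
            asm.add(f"walk{i}", block, peaks)
            if i < 4:
                seg_mult = trial_mult if i >= 2 else 1.0
                block, peaks, angle = _build_turn(params, fs, turn_s * seg_mult * _jitter(rng_jit), sign, rng)
                asm.add(f"turn{i}", block, peaks)
                asm.turn_angles[f"turn{i}"] = angle
                sign = -sign
        rec_trial = None

    data = asm.concat()
    n = len(data["acc_v"])
    for ch in ("acc_v", "acc_ml", "acc_ap"):
        data[ch] = data[ch] + params.noise_sd_g * rng_noise.standard_normal(n)
    gyr_noise = params.noise_sd_g * _GYRO_NOISE_PER_G
    for ch in ("gyr_yaw", "gyr_pitch", "gyr_roll"):
        data[ch] = data[ch] + gyr_noise * rng_noise.standard_normal(n)

    truth = {
        "segments": asm.segments,
        "step_peaks": asm.step_peaks,
        "turn_angles": asm.turn_angles,
        "transition_amp_ap": _TRANSITION_AMP_AP,
    }
    return SensorRecording(
        fs=fs,
        task=task,
        trial_index=rec_trial,
        participant_id=participant_id,
        group=params.group_label,
        truth=truth,
        **data,
    )


def simulate_cohort(
    group_specs: list[tuple[GroupParams, int]],
    seed: int = 0,
    tasks: tuple[str, ...] = TASKS,
    fs: float = 100.0,
) -> list[SensorRecording]:
    """Two trials per participant for TUG/cogTUG plus one 32-foot recording.

    The per-participant speed offset is drawn once and shared across trials
    and tasks, which is what induces between-subject variance (and hence a
    nonzero ICC) downstream.
    """
    if not group_specs:
        raise ValueError("group_specs must not be empty")
    for params, n_participants in group_specs:
        if n_participants < 1:
            raise ValueError("n_participants must be >= 1 per group")
    recordings: list[SensorRecording] = []
    for gi, (params, n_participants) in enumerate(group_specs):
        offset_rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        offsets = np.clip(1.0 + params.between_subject_sd * offset_rng.standard_normal(n_participants), 0.3, None)
        for pi in range(n_participants):
            pid = f"{params.group_label}-{gi}{pi:03d}"
            for task in tasks:
                trials = (1,) if task == "walk32ft" else (1, 2)
                for trial in trials:
                    rec_seed = int(
                        np.random.SeedSequence([seed, gi, pi, TASKS.index(task), trial]).generate_state(1)[0]
                    )
                    recordings.append(
                        simulate_recording(
                            params,
                            task,
                            trial,
                            rec_seed,
                            fs=fs,
                            participant_id=pid,
                            speed_offset=float(offsets[pi]),
                        )
                    )
    return recordings


def simulate_measure_table(
    vc: VarianceComponents, n: int, k: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Long-format two-trial table from ``Y_ij = mu + p_i + t_j + e_ij``.

    ``p_i ~ N(0, sigma_p^2)``, ``e_ij ~ N(0, sigma_e^2)``; the trial effects
    ``t_j`` are fixed, centered offsets whose population SD equals
    ``sigma_t``.
    """
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 participants and k >= 2 trials (ICC undefined otherwise)")
    rng = np.random.default_rng(seed)
    j = np.arange(k, dtype=float)
    c = j - j.mean()
    sd = float(np.sqrt(np.mean(c**2)))
    t = vc.sigma_t * (c / sd) if vc.sigma_t > 0 else np.zeros(k)
    p = vc.sigma_p * rng.standard_normal(n)
    e = vc.sigma_e * rng.standard_normal((n, k))
    y = vc.mu + p[:, None] + t[None, :] + e
    return pd.DataFrame(
        {
            "participant": np.repeat([f"p{i:04d}" for i in range(n)], k),
            "trial": np.tile(np.arange(1, k + 1), n),
            "value": y.ravel(),
        }
    )


def load_group_profiles(path: str | None = None) -> dict[str, GroupParams]:
    """Load the four named group profiles (control/mild/moderate/severe)."""
    if path is None:
        ref = importlib.resources.files("tuglab").joinpath("data/group_profiles.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: GroupParams(group_label=name, **cfg) for name, cfg in raw["groups"].items()}
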