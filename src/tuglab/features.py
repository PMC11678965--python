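"""Sensor-derived quantitative measures per segmented trial.

Measure families: durations (total and per subtask), walking measures
(step counts and timing, step/stride regularity from the unbiased
acceleration autocorrelation, step symmetry, Welch-PSD peak amplitude /
width / slope), chair-transition measures (range, jerk, SD, median) and
turn measures (step count, net yaw amplitude, dominant frequency).
Walking measures are computed independently for the vertical and
anteroposterior axes.

All measures are computed on mean-removed signals and are therefore
invariant to a constant offset, with the single documented exception of the
transition ``median``, which is reported on the raw samples.

Undefined measures (e.g. too few detected steps) are emitted as explicit
missing values (NaN), never silently as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, welch

from .segment import Segment, SegmentedTask, angular_position

__all__ = [
    "FeatureConfig",
    "total_duration",
    "count_steps",
    "step_stride_timing",
    "regularity",
    "step_symmetry",
    "dominant_frequency",
    "psd_peak_measures",
    "transition_measures",
    "turn_measures",
    "extract_all",
]

log = logging.getLogger(__name__)

MEASURE_COLUMNS = ["participant_id", "group", "task", "trial", "measure", "value"]


@dataclass(frozen=True)
class FeatureConfig:
    peak_distance_s: float = 0.3
    peak_prominence_factor: float = 0.5
    ac_lag_range_s: tuple[float, float] = (0.2, 2.5)
    #: autocorrelation peaks below this fraction of the in-range maximum are
    #: not considered dominant (suppresses harmonic side peaks)
    ac_dominance: float = 0.5
    #: Welch segment length in seconds (256 samples at the native 100 Hz);
    #: time-based so PSD measures are invariant to the sampling rate
    welch_seg_s: float = 2.56
    psd_band_hz: tuple[float, float] = (0.5, 5.0)


DEFAULT_CONFIG = FeatureConfig()


def total_duration(seg: SegmentedTask) -> float:
    """Sum of segment durations in seconds."""
    return seg.total_span_s()


def _step_peaks(acc: np.ndarray, fs: float, cfg: FeatureConfig) -> np.ndarray:
    x = np.asarray(acc, dtype=float)
    x = x - x.mean()
    sd = float(x.std())
    if sd == 0:
        return np.asarray([], dtype=int)
    peaks, _ = find_peaks(
        x,
        distance=max(1, int(round(cfg.peak_distance_s * fs))),
        prominence=cfg.peak_prominence_factor * sd,
    )
    return peaks


def count_steps(acc: np.ndarray, fs: float, config: FeatureConfig | None = None) -> int:
    """Number of gait peaks in one acceleration channel."""
    return int(len(_step_peaks(acc, fs, config or DEFAULT_CONFIG)))


def step_stride_timing(
    acc: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> tuple[float, float]:
    """Mean inter-peak (step) and alternate-peak (stride) intervals, seconds.

    Returns ``(nan, nan)`` when fewer than 3 peaks are detected.
    """
    peaks = _step_peaks(acc, fs, config or DEFAULT_CONFIG)
    if len(peaks) < 3:
        log.debug("step_stride_timing undefined: %d peaks", len(peaks))
        return (math.nan, math.nan)
    t = peaks / fs
    step = float(np.mean(np.diff(t)))
    stride = float(np.mean(t[2:] - t[:-2]))
    return step, stride


def _unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    n = len(x)
    c = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    lags = np.arange(max_lag + 1)
    c = c / (n - lags)  # unbiased estimator
    if c[0] <= 0:
        return np.zeros(max_lag + 1)
    return c / c[0]


def regularity(
    acc: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> tuple[float, float]:
    """Step and stride regularity from the normalized unbiased autocorrelation.

    Step regularity is the autocorrelation value at the first dominant
    positive-lag peak, stride regularity the value at the second.  Values
    are clipped to [-1, 1]; missing peaks yield NaN.
    """
    cfg = config or DEFAULT_CONFIG
    x = np.asarray(acc, dtype=float)
    x = x - x.mean()
    n = len(x)
    lo = max(1, int(round(cfg.ac_lag_range_s[0] * fs)))
    hi = min(n - 1, int(round(cfg.ac_lag_range_s[1] * fs)))
    if hi <= lo or x.std() == 0:
        return (math.nan, math.nan)
    ac = _unbiased_autocorr(x, hi)
    window = ac[lo : hi + 1]
    peaks, _ = find_peaks(window)
    if len(peaks) == 0:
        return (math.nan, math.nan)
    heights = window[peaks]
    dominant = peaks[heights >= cfg.ac_dominance * heights.max()]
    vals = np.clip(window[dominant], -1.0, 1.0)
    step_reg = float(vals[0]) if len(vals) >= 1 else math.nan
    stride_reg = float(vals[1]) if len(vals) >= 2 else math.nan
    return step_reg, stride_reg


def step_symmetry(step_regularity: float, stride_regularity: float) -> float:
    """Proximity of the step/stride regularity ratio to 1, as ``min(r, 1/r)``.

    Bounded in (0, 1]; 1 means perfectly symmetric gait.  NaN when either
    regularity is missing or the stride regularity is not positive.
    """
    if not (np.isfinite(step_regularity) and np.isfinite(stride_regularity)):
        return math.nan
    if stride_regularity <= 0 or step_regularity <= 0:
        log.debug("step_symmetry undefined for nonpositive regularity")
        return math.nan
    r = step_regularity / stride_regularity
    return float(min(r, 1.0 / r))


def dominant_frequency(signal: np.ndarray, fs: float) -> float:
    """Frequency of the largest-amplitude DFT bin (mean removed, DC excluded)."""
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    if len(x) < 2:
        return math.nan
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    if len(spec) < 2:
        return math.nan
    return float(freqs[1:][np.argmax(spec[1:])])


def psd_peak_measures(
    signal: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> tuple[float, float, float]:
    """Welch-PSD peak amplitude, full width at half maximum, and decay slope.

    The slope is the least-squares slope of PSD vs frequency from the peak to
    the first higher-frequency point at or below half the peak.
    """
    cfg = config or DEFAULT_CONFIG
    x = np.asarray(signal, dtype=float)
    x = x - x.mean()
    n = len(x)
    if n < 8 or x.std() == 0:
        return (math.nan, math.nan, math.nan)
    nperseg = min(n, int(round(cfg.welch_seg_s * fs)))
    # 4x zero padding: finer, sampling-rate-independent frequency grid for
    # the interpolated width and slope
    freqs, psd = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2, nfft=4 * nperseg)
    band = (freqs >= cfg.psd_band_hz[0]) & (freqs <= cfg.psd_band_hz[1])
    if not band.any():
        return (math.nan, math.nan, math.nan)
    band_idx = np.nonzero(band)[0]
    ipk = band_idx[np.argmax(psd[band_idx])]
    amp = float(psd[ipk])
    half = amp / 2.0

    def _cross(direction: int) -> float:
        j = ipk
        while 0 < j < len(psd) - 1:
            j += direction
            if psd[j] <= half:
                # linear interpolation between j-direction and j
                f0, f1 = freqs[j - direction], freqs[j]
                p0, p1 = psd[j - direction], psd[j]
                if p0 == p1:
                    return float(f1)
                return float(f0 + (half - p0) * (f1 - f0) / (p1 - p0))
        return float(freqs[j])

    width = _cross(+1) - _cross(-1)

    j = ipk
    while j < len(psd) - 1 and psd[j] > half:
        j += 1
    j = max(j, ipk + 1)
    fit_f, fit_p = freqs[ipk : j + 1], psd[ipk : j + 1]
    slope = float(np.polyfit(fit_f, fit_p, 1)[0]) if len(fit_f) >= 2 else math.nan
    return amp, float(width), slope


def transition_measures(acc: np.ndarray, fs: float) -> dict[str, float]:
    """Range, RMS jerk (g/s), SD and median of one transition-segment channel.

    All but ``median`` are computed after mean removal (offset-invariant);
    the median is intentionally reported on the raw samples.
    """
    x = np.asarray(acc, dtype=float)
    if len(x) < 2:
        return {k: math.nan for k in ("duration_s", "range", "jerk", "sd", "median")}
    xc = x - x.mean()
    jerk = float(np.sqrt(np.mean(np.diff(xc) ** 2)) * fs)
    return {
        "duration_s": len(x) / fs,
        "range": float(xc.max() - xc.min()),
        "jerk": jerk,
        "sd": float(xc.std()),
        "median": float(np.median(x)),
    }


def turn_measures(
    rec, seg: Segment, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Duration, in-turn step count, net yaw amplitude (deg) and dominant frequency."""
    cfg = config or DEFAULT_CONFIG
    fs = rec.fs
    sl = slice(seg.start_idx, seg.end_idx)
    yaw = np.asarray(rec.gyr_yaw[sl], dtype=float)
    angle = angular_position(yaw, fs) if len(yaw) >= 2 else np.zeros(2)
    return {
        "duration_s": seg.duration_s(fs),
        "step_count": float(count_steps(rec.acc_v[sl], fs, cfg)),
        "amplitude_yaw_deg": float(abs(angle[-1] - angle[0])),
        "dominant_frequency_hz": dominant_frequency(yaw, fs),
    }


def _walk_rows(rec, seg: Segment, prefix: str, cfg: FeatureConfig) -> dict[str, float]:
    fs = rec.fs
    sl = slice(seg.start_idx, seg.end_idx)
    rows: dict[str, float] = {}
    for axis, channel in (("v", rec.acc_v), ("ap", rec.acc_ap)):
        x = np.asarray(channel[sl], dtype=float)
        rows[f"{prefix}_{axis}_step_count"] = float(count_steps(x, fs, cfg))
        step, stride = step_stride_timing(x, fs, cfg)
        rows[f"{prefix}_{axis}_step_duration"] = step
        rows[f"{prefix}_{axis}_stride_duration"] = stride
        sreg, streg = regularity(x, fs, cfg)
        rows[f"{prefix}_{axis}_step_regularity"] = sreg
        rows[f"{prefix}_{axis}_stride_regularity"] = streg
        rows[f"{prefix}_{axis}_step_symmetry"] = step_symmetry(sreg, streg)
        amp, width, slope = psd_peak_measures(x, fs, cfg)
        rows[f"{prefix}_{axis}_psd_amplitude"] = amp
        rows[f"{prefix}_{axis}_psd_width"] = width
        rows[f"{prefix}_{axis}_psd_slope"] = slope
    return rows


def extract_all(
    seg_task: SegmentedTask,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """All declared measures for one segmented trial, in long format."""
    cfg = config or DEFAULT_CONFIG
    rec = seg_task.recording
    fs = rec.fs
    values: dict[str, float] = {"total_duration": total_duration(seg_task)}

    if seg_task.task in ("TUG", "cogTUG"):
        for seg in seg_task.segments:
            values[f"{seg.label}_duration"] = seg.duration_s(fs)
        for label in ("walk1", "walk2"):
            values.update(_walk_rows(rec, seg_task[label], label, cfg))
        for label in ("sit_to_stand", "stand_to_sit"):
            seg = seg_task[label]
            sl = slice(seg.start_idx, seg.end_idx)
            for axis, channel in (("v", rec.acc_v), ("ap", rec.acc_ap)):
                tm = transition_measures(np.asarray(channel[sl]), fs)
                for key in ("range", "jerk", "sd", "median"):
                    values[f"{label}_{axis}_{key}"] = tm[key]
        for label in ("turn1", "turn2"):
            tm = turn_measures(rec, seg_task[label], cfg)
            values[f"{label}_step_count"] = tm["step_count"]
            values[f"{label}_amplitude_yaw"] = tm["amplitude_yaw_deg"]
            values[f"{label}_dominant_frequency"] = tm["dominant_frequency_hz"]
    elif seg_task.task == "walk16ft":
        walk_a, turn, walk_b = seg_task.segments
        values["walk1_duration"] = walk_a.duration_s(fs)
        values["turn_duration"] = turn.duration_s(fs)
        values["walk2_duration"] = walk_b.duration_s(fs)
        values.update(_walk_rows(rec, walk_a, "walk1", cfg))
        values.update(_walk_rows(rec, walk_b, "walk2", cfg))
        tm = turn_measures(rec, turn, cfg)
        values["turn_step_count"] = tm["step_count"]
        values["turn_amplitude_yaw"] = tm["amplitude_yaw_deg"]
        values["turn_dominant_frequency"] = tm["dominant_frequency_hz"]
    else:
        raise ValueError(f"unsupported segmented task {seg_task.task!r}")

    n_undef = sum(1 for v in values.values() if not np.isfinite(v))
    if n_undef:
        log.warning(
            "%s %s trial %s: %d undefined measures",
            rec.participant_id,
            seg_task.task,
            seg_task.trial_index,
            n_undef,
        )
    return pd.DataFrame(
        {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "task": seg_task.task,
            "trial": seg_task.trial_index,
            "measure": list(values.keys()),
            "value": list(values.values()),
        }
    )[MEASURE_COLUMNS]
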