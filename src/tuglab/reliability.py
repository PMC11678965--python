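"""Test-retest reliability statistics.

Implements the single-measure two-way absolute-agreement intraclass
correlation coefficient from the ANOVA mean squares,

    ICC = (MSP - MSE) / (MSP + (k - 1) MSE + (k / n)(MST - MSE)),

with an F-distribution confidence interval (McGraw-Wong A,1), plus
SEM = SD * sqrt(1 - ICC), MDC = SEM * 1.96 * sqrt(2), signed relative
change between trials, Bland-Altman limits of agreement with exact-t
confidence intervals, and the qualitative ICC labels
(poor / moderate / good / excellent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError

__all__ = [
    "TrialMatrix",
    "ReliabilityResult",
    "BlandAltmanSummary",
    "icc_agreement",
    "sem",
    "mdc",
    "relative_change",
    "group_rc_summary",
    "bland_altman",
    "classify_icc",
    "analyze_matrix",
    "reliability_table",
]

MDC_FACTOR = 1.96 * math.sqrt(2.0)


@dataclass(frozen=True)
class TrialMatrix:
    """n participants x k trials of one measure for one group."""

    values: np.ndarray
    measure_name: str = ""
    group_label: str = ""
    n_dropped: int = 0  # participants excluded for missing trials

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("values must be an (n >= 2) x (k >= 2) matrix")
        if np.isnan(v).any():
            raise ValueError("values must be complete after pairwise exclusion")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BlandAltmanSummary:
    bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    loa_ci_halfwidth: float
    n_outliers: int
    n: int


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    ci95: tuple[float, float]
    sem: float
    mdc: float
    label: str
    median_rc: float
    median_abs_rc: float
    bland_altman: BlandAltmanSummary | None
    n_used: int


def _mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (participants, trials, error)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ssp = k * float(((row_means - grand) ** 2).sum())
    sst = n * float(((col_means - grand) ** 2).sum())
    resid = values - row_means[:, None] - col_means[None, :] + grand
    sse = float((resid**2).sum())
    msp = ssp / (n - 1)
    mst = sst / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msp, mst, mse


def icc_agreement(m: TrialMatrix, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Two-way absolute-agreement single-measure ICC with a 95% CI.

    May be negative.  Raises :class:`DegenerateDataError` when the matrix
    carries no variance at all.
    """
    values = m.values
    n, k = values.shape
    msp, mst, mse = _mean_squares(values)
    denom = msp + (k - 1) * mse + (k / n) * (mst - mse)
    if math.isclose(denom, 0.0, abs_tol=1e-300) or values.std() == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    icc = (msp - mse) / denom
    ci = _icc_ci(icc, msp, mst, mse, n, k, alpha)
    return float(icc), ci


def _icc_ci(
    icc: float, msp: float, mst: float, mse: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    """McGraw-Wong F-based interval for the (A,1) coefficient."""
    if mse == 0:
        # no residual error: the coefficient is determined exactly
        return (icc, icc)
    fj = mst / mse
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    num = (k * icc * fj + n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2
    den = ((n - 1.0) * k**2 * icc**2 * fj**2 + (n * (1.0 + (k - 1.0) * icc) - k * icc) ** 2)
    v = (k - 1.0) * (n - 1.0) * num / den if den > 0 else (n - 1.0) * (k - 1.0)
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msp - f_l * mse) / (f_l * (k * mst + (k * n - k - n) * mse) + n * msp)
    upper = n * (f_u * msp - mse) / (k * mst + (k * n - k - n) * mse + n * f_u * msp)
    return (float(min(lower, icc)), float(max(upper, icc)))


def sem(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, ``SD * sqrt(1 - ICC)``."""
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if sd_pooled < 0:
        raise ValueError("SD must be >= 0")
    return float(sd_pooled * math.sqrt(1.0 - icc))


def mdc(sem_value: float) -> float:
    """Minimal detectable change, ``SEM * 1.96 * sqrt(2)``."""
    if sem_value < 0:
        raise ValueError("SEM must be >= 0")
    return float(sem_value * MDC_FACTOR)


def relative_change(t1: float, t2: float) -> float:
    """Signed relative change ``(t2 - t1) / t1``; requires ``t1 > 0``."""
    if t1 <= 0:
        raise ValueError("relative change requires a positive first-trial value")
    return float((t2 - t1) / t1)


def group_rc_summary(rc_values: np.ndarray | list[float]) -> dict[str, float]:
    """Median signed RC and median absolute RC across participants."""
    rc = np.asarray(rc_values, dtype=float)
    rc = rc[np.isfinite(rc)]
    if len(rc) == 0:
        return {"median_rc": math.nan, "median_abs_rc": math.nan, "n": 0}
    return {
        "median_rc": float(np.median(rc)),
        "median_abs_rc": float(np.median(np.abs(rc))),
        "n": int(len(rc)),
    }


def bland_altman(m: TrialMatrix, alpha: float = 0.05) -> BlandAltmanSummary:
    """Bias, 95% limits of agreement and their exact-t confidence intervals.

    Uses the classic variance approximation ``Var(LoA) ~= 3 s^2 / n`` for the
    limit CIs; the outlier count is the number of paired differences outside
    the outer CI bounds of the limits.
    """
    if m.k != 2:
        raise ValueError("Bland-Altman requires exactly 2 trials")
    if m.n < 3:
        raise ValueError("Bland-Altman CI requires n >= 3")
    diffs = m.values[:, 1] - m.values[:, 0]
    n = len(diffs)
    bias = float(diffs.mean())
    sd_d = float(diffs.std(ddof=1))
    loa_low = bias - 1.96 * sd_d
    loa_high = bias + 1.96 * sd_d
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    bias_half = t_crit * sd_d / math.sqrt(n)
    loa_half = t_crit * sd_d * math.sqrt(3.0 / n)
    n_out = int(np.sum((diffs > loa_high + loa_half) | (diffs < loa_low - loa_half)))
    return BlandAltmanSummary(
        bias=bias,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        bias_ci=(bias - bias_half, bias + bias_half),
        loa_ci_halfwidth=float(loa_half),
        n_outliers=n_out,
        n=n,
    )


def classify_icc(icc: float) -> str:
    """Qualitative reliability label with left-closed boundaries.

    < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.90] good, > 0.90 excellent.
    """
    if icc > 1.0:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def analyze_matrix(m: TrialMatrix, sd_mode: str = "pooled") -> ReliabilityResult:
    """Full per-measure reliability summary from an n x k trial matrix.

    ``sd_mode`` selects the SD entering the SEM: ``"pooled"`` over all n*k
    observations (default) or ``"trial1"`` for the baseline-only convention.
    """
    icc, ci = icc_agreement(m)
    if sd_mode == "pooled":
        sd = float(m.values.std(ddof=1))
    elif sd_mode == "trial1":
        sd = float(m.values[:, 0].std(ddof=1))
    else:
        raise ValueError("sd_mode must be 'pooled' or 'trial1'")
    sem_value = sem(sd, min(icc, 1.0)) if icc <= 1.0 else 0.0
    rc = np.array(
        [
            relative_change(v1, v2) if v1 > 0 else math.nan
            for v1, v2 in zip(m.values[:, 0], m.values[:, 1])
        ]
    ) if m.k == 2 else np.array([])
    rc_summary = group_rc_summary(rc)
    ba = bland_altman(m) if (m.k == 2 and m.n >= 3) else None
    return ReliabilityResult(
        icc=icc,
        ci95=ci,
        sem=sem_value,
        mdc=mdc(sem_value),
        label=classify_icc(min(icc, 1.0)),
        median_rc=rc_summary["median_rc"],
        median_abs_rc=rc_summary["median_abs_rc"],
        bland_altman=ba,
        n_used=m.n,
    )


def reliability_table(
    measures: pd.DataFrame, sd_mode: str = "pooled"
) -> pd.DataFrame:
    """Per (group, task, measure) reliability statistics from a long measure table.

    Participants missing either trial of a measure are dropped pairwise for
    that measure, with the drop count reported in ``n_dropped``.
    """
    rows = []
    for (group, task, measure), sub in measures.groupby(["group", "task", "measure"]):
        wide = sub.pivot_table(index="participant_id", columns="trial", values="value")
        if wide.shape[1] < 2:
            continue
        wide = wide.iloc[:, :2]
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if len(complete) < 3:
            continue
        try:
            m = TrialMatrix(complete.to_numpy(), measure, group, n_dropped)
            res = analyze_matrix(m, sd_mode=sd_mode)
        except (DegenerateDataError, ValueError):
            continue
        ba = res.bland_altman
        rows.append(
            {
                "group": group,
                "task": task,
                "measure": measure,
                "icc": res.icc,
                "ci_low": res.ci95[0],
                "ci_high": res.ci95[1],
                "label": res.label,
                "sem": res.sem,
                "mdc": res.mdc,
                "median_rc": res.median_rc,
                "median_abs_rc": res.median_abs_rc,
                "ba_bias": ba.bias if ba else math.nan,
                "ba_loa_low": ba.loa_low if ba else math.nan,
                "ba_loa_high": ba.loa_high if ba else math.nan,
                "n_used": res.n_used,
                "n_dropped": n_dropped,
            }
        )
    return pd.DataFrame(rows)
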