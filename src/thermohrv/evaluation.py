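"""Agreement between measured (PPG-derived) and predicted (IRT-derived) HRV.

Spearman rank correlation, least-squares regression of predicted on
measured, Bland-Altman bias/limits of agreement, and the paired t-test.
The sign convention is fixed everywhere as ``predicted - measured``, so a
positive bias means the thermal model overestimates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import BootstrapResult
from .signals import DegenerateInputError

__all__ = [
    "AgreementStats",
    "spearman",
    "bland_altman",
    "paired_ttest",
    "regression_line",
    "agreement_stats",
    "full_report",
]

#: Limits-of-agreement multiplier (standard 95% Bland-Altman).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Agreement summary between one metric's measured and predicted values."""

    spearman_r: float
    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_lower: float
    loa_upper: float
    t_stat: float
    df: int
    p_value: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _pair(measured, predicted, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise ValueError("measured and predicted must be 1-d and equal length")
    if m.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return m, p


def spearman(measured, predicted) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    m, p = _pair(measured, predicted, 3)
    if np.std(m) == 0 or np.std(p) == 0:
        raise DegenerateInputError("Spearman undefined for a constant vector")
    return float(stats.spearmanr(m, p).statistic)


def bland_altman(measured, predicted) -> tuple[float, float, float]:
    """(bias, loa_lower, loa_upper) of the differences predicted - measured.

    bias = mean(d), LoA = bias +/- 1.96 * sd(d) with sample SD (ddof=1).
    """
    m, p = _pair(measured, predicted, 2)
    d = p - m
    bias = float(np.mean(d))
    half = LOA_MULTIPLIER * float(np.std(d, ddof=1))
    return bias, bias - half, bias + half


def paired_ttest(measured, predicted) -> tuple[float, int, float]:
    """Two-sided paired t-test on predicted - measured: (t, df, p)."""
    m, p = _pair(measured, predicted, 2)
    d = p - m
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateInputError("paired t-test undefined for zero-variance differences")
    res = stats.ttest_rel(p, m)
    return float(res.statistic), int(res.df), float(res.pvalue)


def regression_line(measured, predicted) -> tuple[float, float, float]:
    """Least-squares line of predicted on measured: (slope, intercept, r^2)."""
    m, p = _pair(measured, predicted, 3)
    if np.std(m) == 0.0:
        raise DegenerateInputError("regression undefined for a constant measured vector")
    res = stats.linregress(m, p)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def agreement_stats(measured, predicted) -> AgreementStats:
    """All agreement statistics for one metric."""
    r = spearman(measured, predicted)
    slope, intercept, r2 = regression_line(measured, predicted)
    bias, lo, hi = bland_altman(measured, predicted)
    t, df, p = paired_ttest(measured, predicted)
    return AgreementStats(
        spearman_r=r,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        t_stat=t,
        df=df,
        p_value=p,
    )


def full_report(
    measured: pd.DataFrame,
    predicted: pd.DataFrame,
    bootstrap: dict[str, BootstrapResult],
) -> dict[str, dict]:
    """Per-metric report bundle: stability, agreement, model weights.

    For every metric column present in both tables, returns a dict with
    ``r_mean``/``r_sd`` from the fold bootstrap, the r histogram data, the
    agreement statistics, and the representative model's named weights.
    """
    report: dict[str, dict] = {}
    for metric in measured.columns:
        if metric not in predicted.columns:
            continue
        stats_ = agreement_stats(
            measured[metric].to_numpy(), predicted[metric].to_numpy()
        )
        entry: dict = dict(stats_.as_dict())
        boot = bootstrap.get(metric)
        if boot is not None:
            counts, edges = np.histogram(boot.r_per_iteration, bins=20, range=(-1, 1))
            model = boot.representative_model
            entry.update(
                r_mean=boot.r_mean,
                r_sd=boot.r_sd,
                r_histogram={
                    "bin_edges": edges.tolist(),
                    "counts": counts.tolist(),
                },
                selected_features=list(model.selected_features),
                weights=[float(w) for w in model.weights],
            )
        report[metric] = entry
    return report
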