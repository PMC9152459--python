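"""Thermal ROI features: distribution moments, delta, SampEn, percentile, band PSD.

Ten features are computed from each 10-Hz facial ROI temperature trace
(glabella G, nose tip NT, nostrils N), giving the 30 candidate predictors
for the regression stage:

``mean, sd, kurtosis, skewness, delta, sampen, p75, psd_myo, psd_breath,
psd_cardiac``

Band-limited PSD means cover the myogenic (0.04-0.15 Hz), respiratory
(0.15-0.5 Hz) and cardiac (0.5-1 Hz) bands of skin-temperature
oscillation; all three sit below the 5 Hz Nyquist limit of the camera.
Kurtosis is reported in the non-excess convention (Gaussian -> 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.spatial.distance import cdist

from .signals import ROI_NAMES, DegenerateInputError, ThermalROISeries

__all__ = [
    "FEATURE_NAMES",
    "BANDS",
    "ThermalFeatureVector",
    "moments",
    "delta_first_last",
    "sample_entropy",
    "percentile75",
    "band_psd_means",
    "feature_vector",
    "reduce_frames",
]

#: Per-ROI feature ordering; column names follow the ``{roi}_{feature}`` pattern.
FEATURE_NAMES = (
    "mean",
    "sd",
    "kurtosis",
    "skewness",
    "delta",
    "sampen",
    "p75",
    "psd_myo",
    "psd_breath",
    "psd_cardiac",
)

#: Half-open frequency bands [lo, hi) in Hz for the band-mean PSD features.
BANDS = {
    "psd_myo": (0.04, 0.15),
    "psd_breath": (0.15, 0.5),
    "psd_cardiac": (0.5, 1.0),
}


@dataclass(frozen=True)
class ThermalFeatureVector:
    """The 30 candidate predictors (10 features x 3 ROIs) for one subject."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def moments(series: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sample SD, non-excess kurtosis, skewness) of a series.

    Raises :class:`DegenerateInputError` for constant input, where the
    standardized moments are undefined.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise DegenerateInputError("moments need at least four samples")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("kurtosis/skewness undefined for a constant series")
    return (
        float(np.mean(x)),
        sd,
        float(stats.kurtosis(x, fisher=False, bias=True)),
        float(stats.skew(x, bias=True)),
    )


def delta_first_last(series: np.ndarray, fs: float = 10.0, window: float = 5.0) -> float:
    """Temperature change: mean of the last ``window`` s minus the first.

    Positive values mean the ROI warmed over the acquisition.
    """
    x = np.asarray(series, dtype=float)
    w = int(round(window * fs))
    if x.size < 2 * w:
        raise DegenerateInputError(
            f"need at least {2 * window:.0f} s of data for the delta feature"
        )
    return float(np.mean(x[-w:]) - np.mean(x[:w]))


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    The negative natural log of the conditional probability that length-m
    subseries matching pointwise within tolerance ``r`` also match at the
    (m+1)-th point.  Self-matches are excluded; ``r`` defaults to 0.2 times
    the sample SD.  A constant series returns 0.0 (every template matches
    trivially at any tolerance).

    Raises
    ------
    DegenerateInputError
        If the series is too short, or no template pair matches at length
        m or m+1 (entropy undefined).
    """
    x = np.asarray(series, dtype=float)
    if x.size < m + 2:
        raise DegenerateInputError(f"sample entropy needs at least {m + 2} samples")
    sd = float(np.std(x, ddof=1))
    if r is None:
        r = 0.2 * sd
    if sd == 0.0:
        return 0.0
    n_templates = x.size - m  # same template count at both lengths
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    db = cdist(tm, tm, metric="chebyshev")
    da = cdist(tm1, tm1, metric="chebyshev")
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(db[iu] <= r))
    a = int(np.count_nonzero(da[iu] <= r))
    if b == 0 or a == 0:
        raise DegenerateInputError("no matching templates; sample entropy undefined")
    return float(-np.log(a / b))


def percentile75(series: np.ndarray) -> float:
    """75th percentile with linear interpolation between order statistics."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("percentile of an empty series")
    return float(np.percentile(x, 75, method="linear"))


def band_psd_means(
    series: np.ndarray, fs: float = 10.0, segment_s: float = 30.0
) -> tuple[float, float, float]:
    """Mean PSD (degC^2/Hz) over the myogenic, respiratory and cardiac bands.

    A mean-detrended Welch estimate with Hann-tapered ``segment_s``-second
    segments and 50% overlap; each band mean averages the PSD ordinates at
    frequencies inside the half-open band ``[lo, hi)``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 25 * fs:
        raise DegenerateInputError("band PSD needs at least 25 s of data")
    nperseg = min(x.size, int(round(segment_s * fs)))
    freqs, psd = sps.welch(
        x, fs=fs, nperseg=nperseg, window="hann", detrend="constant"
    )
    out = []
    for lo, hi in BANDS.values():
        mask = (freqs >= lo) & (freqs < hi)
        out.append(float(np.mean(psd[mask])))
    return tuple(out)


def _roi_features(
    series: ThermalROISeries, sampen_m: int = 2, sampen_r_factor: float = 0.2
) -> dict[str, float]:
    x = series.samples
    feats: dict[str, float] = {}
    try:
        feats["mean"], feats["sd"], feats["kurtosis"], feats["skewness"] = moments(x)
    except DegenerateInputError:
        # constant trace: central moments exist, standardized ones do not
        feats["mean"] = float(np.mean(x))
        feats["sd"] = float(np.std(x, ddof=1))
        feats["kurtosis"] = float("nan")
        feats["skewness"] = float("nan")
        warnings.warn(
            f"ROI {series.roi}: kurtosis/skewness flagged missing (constant trace)",
            stacklevel=3,
        )
    feats["delta"] = delta_first_last(x, fs=series.fs)
    try:
        sd = float(np.std(x, ddof=1))
        feats["sampen"] = sample_entropy(x, m=sampen_m, r=sampen_r_factor * sd)
    except DegenerateInputError:
        feats["sampen"] = float("nan")
        warnings.warn(
            f"ROI {series.roi}: sample entropy flagged missing", stacklevel=3
        )
    feats["p75"] = percentile75(x)
    feats["psd_myo"], feats["psd_breath"], feats["psd_cardiac"] = band_psd_means(
        x, fs=series.fs
    )
    return feats


def feature_vector(
    g: ThermalROISeries,
    nt: ThermalROISeries,
    n: ThermalROISeries,
    sampen_m: int = 2,
    sampen_r_factor: float = 0.2,
) -> ThermalFeatureVector:
    """The 30-entry predictor vector for one subject.

    Order is ROI-major (G, NT, N), feature-minor per :data:`FEATURE_NAMES`;
    names follow ``{roi}_{feature}``.  Hard failures are re-raised naming
    the offending ROI.
    """
    by_roi = {"G": g, "NT": nt, "N": n}
    values: list[float] = []
    names: list[str] = []
    for roi in ROI_NAMES:
        series = by_roi[roi]
        if series.roi != roi:
            raise ValueError(f"expected ROI {roi!r}, got {series.roi!r}")
        try:
            feats = _roi_features(series, sampen_m, sampen_r_factor)
        except DegenerateInputError as exc:
            raise DegenerateInputError(f"ROI {roi}: {exc}") from exc
        for feature in FEATURE_NAMES:
            values.append(feats[feature])
            names.append(f"{roi}_{feature}")
    return ThermalFeatureVector(np.asarray(values), tuple(names))


def reduce_frames(frames: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Mean temperature inside a fixed pixel box, per frame.

    Convenience reducer for synthetic frame stacks only; real-imagery ROI
    tracking is out of scope.  ``box`` is 0-based half-open
    ``(row_lo, row_hi, col_lo, col_hi)``.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frames must be a (time, rows, cols) stack")
    r0, r1, c0, c1 = box
    if not (0 <= r0 < r1 <= stack.shape[1] and 0 <= c0 < c1 <= stack.shape[2]):
        raise ValueError(f"box {box} outside frame of shape {stack.shape[1:]}")
    return stack[:, r0:r1, c0:c1].mean(axis=(1, 2))
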