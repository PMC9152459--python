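"""Time- and frequency-domain heart-rate-variability metrics.

Seven indices are computed from an :class:`~thermohrv.signals.RRSeries`:
mean HR (bpm), mean RR (ms), SDNN (ms), RMSSD (ms), pNN50 (%), TINN (ms)
and the LF/HF spectral power ratio.  Conventions the literature leaves
loose are pinned down here and documented:

* mean HR is the mean of instantaneous rates ``60000/rr`` (an
  ``"overall"`` mode computing ``60000/mean(rr)`` is available);
* SDNN uses the sample (n-1) standard deviation;
* pNN50 divides the NN50 count by the *total number of RR intervals*,
  ``len(rr)``, not by the number of successive pairs;
* TINN uses a 1/128 s histogram bin and an exhaustive triangular fit whose
  base endpoints are confined to the occupied histogram range, with error
  ties resolved toward the widest base;
* LF/HF integrates a Welch periodogram of the cubic-spline-resampled
  (4 Hz), mean-detrended tachogram over 0.03-0.15 Hz and 0.15-0.35 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .signals import DegenerateInputError, RRSeries

__all__ = [
    "SpectralConfig",
    "HRVMetrics",
    "METRIC_NAMES",
    "TINN_BIN_MS",
    "mean_hr",
    "mean_rr",
    "sdnn",
    "rmssd",
    "pnn50",
    "tinn",
    "lf_hf_ratio",
    "compute_all",
]

#: Histogram bin width for TINN: 1/128 s expressed in ms.
TINN_BIN_MS = 1000.0 / 128.0

#: Canonical ordering of the seven HRV target variables.
METRIC_NAMES = ("hr", "rr_mean", "sdnn", "rmssd", "pnn50", "tinn", "lf_hf")


@dataclass(frozen=True)
class SpectralConfig:
    """Frequency bands and resampling rate for the LF/HF ratio.

    LF is 0.03-0.15 Hz, HF is 0.15-0.35 Hz; the tachogram is resampled at
    ``resample_rate`` Hz (must exceed twice the HF upper edge).
    """

    lf_band: tuple[float, float] = (0.03, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.35)
    resample_rate: float = 4.0

    def __post_init__(self) -> None:
        if not (self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1]):
            raise ValueError("bands must be ordered and non-overlapping")
        if self.resample_rate <= 2 * self.hf_band[1]:
            raise ValueError("resample_rate must exceed twice the HF upper edge")


@dataclass(frozen=True)
class HRVMetrics:
    """The seven HRV target variables for one subject."""

    hr: float
    rr_mean: float
    sdnn: float
    rmssd: float
    pnn50: float
    tinn: float
    lf_hf: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _rr_array(rr: RRSeries | np.ndarray) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.rr
    return np.asarray(rr, dtype=float)


def mean_hr(rr: RRSeries | np.ndarray, method: str = "instantaneous") -> float:
    """Mean heart rate in bpm.

    ``"instantaneous"`` (default) averages the beat-wise rates 60000/rr;
    ``"overall"`` returns 60000/mean(rr).  The two differ whenever the RR
    series is non-constant (Jensen's inequality).
    """
    x = _rr_array(rr)
    if x.size < 1:
        raise DegenerateInputError("mean_hr needs at least one interval")
    if method == "instantaneous":
        return float(np.mean(60000.0 / x))
    if method == "overall":
        return float(60000.0 / np.mean(x))
    raise ValueError(f"unknown method {method!r}")


def mean_rr(rr: RRSeries | np.ndarray) -> float:
    """Mean RR interval in ms."""
    x = _rr_array(rr)
    if x.size < 1:
        raise DegenerateInputError("mean_rr needs at least one interval")
    return float(np.mean(x))


def sdnn(rr: RRSeries | np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of the RR intervals, ms."""
    x = _rr_array(rr)
    if x.size < 2:
        raise DegenerateInputError("sdnn needs at least two intervals")
    return float(np.std(x, ddof=1))


def rmssd(rr: RRSeries | np.ndarray) -> float:
    """Root mean square of successive RR differences, ms."""
    x = _rr_array(rr)
    if x.size < 3:
        raise DegenerateInputError("rmssd needs at least two successive differences")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def pnn50(rr: RRSeries | np.ndarray, threshold_ms: float = 50.0) -> float:
    """NN50 count divided by the total number of RR intervals, as a percentage.

    The denominator is ``len(rr)`` (total intervals), not the number of
    successive pairs, so the value is bounded by ``100*(n-1)/n``.
    """
    x = _rr_array(rr)
    if x.size < 3:
        raise DegenerateInputError("pnn50 needs at least two successive differences")
    nn50 = int(np.sum(np.abs(np.diff(x)) > threshold_ms))
    return 100.0 * nn50 / x.size


def _triangle(centers: np.ndarray, n: float, apex: float, m: float, height: float) -> np.ndarray:
    q = np.zeros_like(centers)
    left = (centers >= n) & (centers <= apex)
    right = (centers > apex) & (centers <= m)
    if apex > n:
        q[left] = height * (centers[left] - n) / (apex - n)
    else:
        q[left] = height
    if m > apex:
        q[right] = height * (m - centers[right]) / (m - apex)
    return q


def tinn(rr: RRSeries | np.ndarray, bin_ms: float = TINN_BIN_MS) -> float:
    """Baseline width of the triangular fit to the RR histogram, in ms.

    The RR histogram uses bins of ``bin_ms`` (default 1/128 s) aligned to
    the bin grid.  A triangle with apex at the modal bin's height and base
    endpoints N <= mode <= M on the bin-center grid is fit by exhaustive
    search minimizing the squared error against the bin counts; N and M are
    confined to the occupied range of the histogram and error ties are
    broken toward the widest base.  A single-occupied-bin histogram returns
    0 (degenerate triangle).
    """
    x = _rr_array(rr)
    if x.size < 2:
        raise DegenerateInputError("tinn needs at least two intervals")
    lo = np.floor(x.min() / bin_ms) * bin_ms
    nbins = int(np.floor((x.max() - lo) / bin_ms)) + 1
    edges = lo + bin_ms * np.arange(nbins + 1)
    counts, _ = np.histogram(x, bins=edges)
    centers = edges[:-1] + bin_ms / 2.0
    nz = np.nonzero(counts)[0]
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        return 0.0
    counts = counts[first : last + 1].astype(float)
    centers = centers[first : last + 1]
    apex_idx = int(np.argmax(counts))
    apex, height = centers[apex_idx], counts[apex_idx]
    best = None  # (error, -(m - n), n) lexicographic
    for n in centers[: apex_idx + 1]:
        for m in centers[apex_idx:]:
            q = _triangle(centers, n, apex, m, height)
            err = float(np.sum((counts - q) ** 2))
            key = (err, -(m - n), n)
            if best is None or key < best[0]:
                best = (key, m - n)
    return float(best[1])


def lf_hf_ratio(rr: RRSeries, cfg: SpectralConfig | None = None) -> float:
    """LF/HF power ratio of the RR tachogram.

    The tachogram (RR value at each interval's ending beat time) is
    cubic-spline interpolated to a uniform grid at ``cfg.resample_rate``,
    mean-detrended, and a Welch periodogram is integrated over the LF and
    HF bands (half-open ``[lo, hi)``).

    Raises
    ------
    DegenerateInputError
        If the record spans under 30 s or the HF power is numerically zero.
    """
    cfg = cfg or SpectralConfig()
    if rr.duration < 30.0:
        raise DegenerateInputError("LF/HF needs a recording spanning at least 30 s")
    n_lf_cycles = rr.duration * cfg.lf_band[0]
    if n_lf_cycles < 2:
        warnings.warn(
            f"record spans {n_lf_cycles:.2f} cycles of the {cfg.lf_band[0]} Hz LF "
            "lower edge (<2); LF power is poorly resolved",
            stacklevel=2,
        )
    t = rr.beat_times[1:]
    spline = CubicSpline(t, rr.rr)
    fs = cfg.resample_rate
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    tach = spline(grid)
    tach = tach - tach.mean()
    nperseg = min(tach.size, 256)
    freqs, psd = sps.welch(tach, fs=fs, nperseg=nperseg, window="hann", detrend=False)
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= cfg.lf_band[0]) & (freqs < cfg.lf_band[1])
    hf_mask = (freqs >= cfg.hf_band[0]) & (freqs < cfg.hf_band[1])
    lf_power = float(np.sum(psd[lf_mask]) * df)
    hf_power = float(np.sum(psd[hf_mask]) * df)
    if hf_power <= 0.0:
        raise DegenerateInputError("HF power is numerically zero; LF/HF undefined")
    return lf_power / hf_power


def compute_all(rr: RRSeries, cfg: SpectralConfig | None = None) -> HRVMetrics:
    """All seven HRV metrics for one subject.

    A degenerate spectrum (e.g., a perfectly constant RR series) yields
    ``lf_hf = nan`` with a warning rather than an exception, so the other
    six time-domain metrics remain usable.
    """
    try:
        ratio = lf_hf_ratio(rr, cfg)
    except DegenerateInputError as exc:
        warnings.warn(f"LF/HF flagged as missing: {exc}", stacklevel=2)
        ratio = float("nan")
    return HRVMetrics(
        hr=mean_hr(rr),
        rr_mean=mean_rr(rr),
        sdnn=sdnn(rr),
        rmssd=rmssd(rr),
        pnn50=pnn50(rr),
        tinn=tinn(rr),
        lf_hf=ratio,
    )
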