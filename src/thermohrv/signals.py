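"""Domain containers for pulse and thermal time series.

The pipeline moves three kinds of data around: a raw photoplethysmogram
(:class:`PulseSignal`), the beat-to-beat interval series derived from it
(:class:`RRSeries`), and per-ROI facial temperature traces
(:class:`ThermalROISeries`).  All are thin, validated wrappers over numpy
arrays; heavy lifting lives in the processing modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseSignal",
    "RRSeries",
    "ThermalROISeries",
    "ROI_NAMES",
    "DegenerateInputError",
    "InsufficientBeatsError",
]

#: Canonical region-of-interest labels: glabella, nose tip, nostrils.
ROI_NAMES = ("G", "NT", "N")


class DegenerateInputError(ValueError):
    """Raised when an input is constant/too short for the requested statistic."""


class InsufficientBeatsError(ValueError):
    """Raised when a pulse waveform yields fewer than three detectable beats."""


@dataclass(frozen=True)
class PulseSignal:
    """A photoplethysmography waveform.

    Parameters
    ----------
    samples : array of float
        Amplitude in arbitrary units.
    fs : float
        Sampling frequency in Hz (370 Hz for study-conform recordings).
    """

    samples: np.ndarray
    fs: float = 370.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Beat times (s) and the inter-beat (RR) intervals (ms) between them.

    ``rr[i] = 1000 * (beat_times[i+1] - beat_times[i])``.  No ectopic-beat
    correction is applied, so NN and RR coincide here; intervals outside the
    physiological 300-2000 ms band are warned about but kept.
    """

    beat_times: np.ndarray
    rr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.ndim != 1 or bt.size < 2:
            raise ValueError("need at least two beat times")
        if np.any(np.diff(bt) <= 0):
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr", 1000.0 * np.diff(bt))
        outside = (self.rr < 300.0) | (self.rr > 2000.0)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} RR interval(s) outside [300, 2000] ms "
                "(kept; no ectopic correction applied)",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.rr.size)

    @property
    def duration(self) -> float:
        """Span from first to last beat, in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class ThermalROISeries:
    """Mean skin temperature of one facial ROI over time, in deg C at 10 Hz."""

    roi: str
    samples: np.ndarray
    fs: float = 10.0

    def __post_init__(self) -> None:
        if self.roi not in ROI_NAMES:
            raise ValueError(f"roi must be one of {ROI_NAMES}, got {self.roi!r}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size < 10 * self.fs:
            raise ValueError("need at least 10 s of thermal data")
        out = (self.samples < 20.0) | (self.samples > 45.0)
        if out.any():
            warnings.warn(
                f"ROI {self.roi}: {int(out.sum())} sample(s) outside the "
                "[20, 45] degC sanity band",
                stacklevel=2,
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs
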