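"""Synthetic cohorts of coupled PPG + facial-thermal recordings with known HRV.

Real paired PPG/thermography data are not publicly deposited, so every
stage of the pipeline is exercised against cohorts generated here.  Each
subject's heart rhythm is a deterministic two-tone RR modulation (an
integral-pulse-frequency-modulation flavoured construction):

``rr(t) = mean_rr + lf_amp * sin(2*pi*0.1*t) + hf_amp * sin(2*pi*breath_freq*t)``

which makes the ground-truth LF/HF content analytically controllable.  The
pulse waveform places one smooth raised-cosine lobe per beat; the three
thermal ROI traces are a 34 degC-ish baseline plus slow drift plus tones in
the respiratory, cardiac and myogenic bands whose amplitudes are linear in
the subject's true HRV metrics (the coupling the regression stage must
recover), plus white noise.

Cohort defaults emulate the study conditions: 32 subjects, 60-s recordings,
PPG at 370 Hz, thermography at 10 Hz, breathing frequency varying across
subjects within the high-frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hrv, thermal
from .signals import ROI_NAMES, PulseSignal, RRSeries, ThermalROISeries

__all__ = [
    "SubjectParams",
    "CouplingParams",
    "SyntheticSubject",
    "CohortDataset",
    "generate_rr_series",
    "synthesize_ppg",
    "synthesize_thermal",
    "make_subject",
    "generate_cohort",
    "DEFAULT_PPG_NOISE_SD",
    "F_LF",
    "F_MYO",
    "PULSE_WIDTH_S",
]

#: Fixed low-frequency RR modulation tone (band centre of 0.03-0.15 Hz).
F_LF = 0.1
#: Thermal myogenic tone frequency, inside the 0.04-0.15 Hz myogenic band.
F_MYO = 0.095
#: Raised-cosine pulse lobe width (s); narrower than any plausible RR interval.
PULSE_WIDTH_S = 0.3
#: Moderate additive PPG noise (a.u., against unit lobe amplitude).
DEFAULT_PPG_NOISE_SD = 0.1

#: Per-ROI thermal baselines (degC): glabella warmest, nostrils coolest.
_ROI_BASELINE = {"G": 34.5, "NT": 33.8, "N": 33.2}
#: Reference mean RR (ms) around which the baseline-coupling term is centred.
_RR_REF = 1200.0


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth rhythm parameters of one synthetic subject.

    mean_rr : ms, in [500, 1500]
    lf_amp, hf_amp : ms, amplitudes of the 0.1 Hz and breathing-frequency
        RR modulation tones; must leave every generated RR positive.
    breath_freq : Hz, within the 0.15-0.35 Hz high-frequency band.
    duration : s (default 60, the study's recording length).
    seed : integer, drives the subject's noise streams.
    """

    mean_rr: float = 1000.0
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    breath_freq: float = 0.25
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 500.0 <= self.mean_rr <= 1500.0:
            raise ValueError(f"mean_rr must be in [500, 1500] ms, got {self.mean_rr}")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise ValueError("modulation amplitudes must be non-negative")
        if not 0.15 <= self.breath_freq <= 0.35:
            raise ValueError(
                f"breath_freq must lie in [0.15, 0.35] Hz, got {self.breath_freq}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mean_rr - self.lf_amp - self.hf_amp <= 0:
            raise ValueError("modulation amplitudes too large: RR would go negative")


@dataclass(frozen=True)
class CouplingParams:
    """Linear coefficients tying thermal signal components to true HRV.

    resp_amp : per-ROI amplitude (degC) of the respiratory tone at the
        subject's breathing frequency; largest at the nostrils, where
        inhaled/exhaled air dominates the temperature time course.
    cardiac_gain : degC per bpm; cardiac-band tone amplitude =
        ``cardiac_gain * mean HR``, at the subject's mean heart frequency.
    myo_gain : degC per ms; myogenic tone amplitude = ``myo_gain * RMSSD``.
    mean_gain : degC per ms; baseline shift = ``mean_gain * (mean_rr - 1200)``.
    noise_sd : degC, white measurement noise.
    drift_amp : degC, half-period cosine drift over the recording.
    """

    resp_amp: dict[str, float] = field(
        default_factory=lambda: {"G": 0.01, "NT": 0.05, "N": 0.08}
    )
    cardiac_gain: float = 0.002
    myo_gain: float = 0.002
    mean_gain: float = 0.001
    noise_sd: float = 0.01
    drift_amp: float = 0.1

    def __post_init__(self) -> None:
        vals = [*self.resp_amp.values(), self.cardiac_gain, self.myo_gain,
                self.mean_gain, self.drift_amp]
        if not all(np.isfinite(vals)):
            raise ValueError("coupling coefficients must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def strong(cls) -> "CouplingParams":
        """The default, clearly-recoverable coupling regime."""
        return cls()

    @classmethod
    def null(cls) -> "CouplingParams":
        """No thermal-HRV coupling: traces carry drift and noise only."""
        return cls(
            resp_amp={"G": 0.0, "NT": 0.0, "N": 0.0},
            cardiac_gain=0.0,
            myo_gain=0.0,
            mean_gain=0.0,
        )


@dataclass(frozen=True)
class SyntheticSubject:
    """One subject's ground truth plus simulated sensor outputs."""

    params: SubjectParams
    true_rr: RRSeries
    true_metrics: hrv.HRVMetrics
    ppg: PulseSignal
    thermal: dict[str, ThermalROISeries]


@dataclass(frozen=True)
class CohortDataset:
    """Cohort-level predictor matrix, truth targets, and raw subjects.

    ``features`` holds the raw (not yet z-scored) 30-column thermal
    predictor matrix; normalization happens inside the regression stage,
    within training folds, to avoid leakage.
    """

    subjects: tuple[SyntheticSubject, ...]
    features: pd.DataFrame
    targets: pd.DataFrame


def _instantaneous_rr_ms(params: SubjectParams, t: np.ndarray | float) -> np.ndarray:
    return (
        params.mean_rr
        + params.lf_amp * np.sin(2 * np.pi * F_LF * np.asarray(t))
        + params.hf_amp * np.sin(2 * np.pi * params.breath_freq * np.asarray(t))
    )


def generate_rr_series(params: SubjectParams, margin: float | None = None) -> RRSeries:
    """Emit beat times over [0, duration) from the two-tone RR modulation.

    Beats are placed iteratively: the next beat follows the current one by
    the instantaneous RR evaluated at the current beat time.  Deterministic
    (the rhythm itself carries no noise).  ``margin`` (default 0.25 s)
    keeps the first and last beats far enough from the record boundaries
    for their pulse waveforms to fit inside the recording with room for
    the band-pass filter to settle; a beat whose lobe is cut by the
    record boundary is unrecoverable by any detector.
    """
    if margin is None:
        margin = 0.25
    beats = [margin]
    while True:
        rr_ms = float(_instantaneous_rr_ms(params, beats[-1]))
        if rr_ms <= 0:
            raise ValueError("generated RR interval <= 0; reduce modulation amplitudes")
        t_next = beats[-1] + rr_ms / 1000.0
        if t_next >= params.duration - margin:
            break
        beats.append(t_next)
    return RRSeries(beat_times=np.asarray(beats))


def synthesize_ppg(
    rr: RRSeries,
    fs: float = 370.0,
    noise_sd: float = 0.0,
    duration: float | None = None,
    seed: int = 0,
) -> PulseSignal:
    """Pulse waveform with one raised-cosine lobe per beat plus white noise.

    Each beat contributes ``0.5 * (1 + cos(2*pi*(t - t_beat)/w))`` over a
    window of width ``w = 0.3 s`` centred on the beat, so the single
    dominant local maximum sits at the beat time to within one sample.
    """
    if duration is None:
        duration = float(rr.beat_times[-1]) + rr.rr[-1] / 1000.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    half = PULSE_WIDTH_S / 2.0
    for tb in rr.beat_times:
        i0 = max(0, int(np.ceil((tb - half) * fs)))
        i1 = min(n, int(np.floor((tb + half) * fs)) + 1)
        if i0 >= i1:
            continue
        tt = t[i0:i1] - tb
        x[i0:i1] += 0.5 * (1.0 + np.cos(2 * np.pi * tt / PULSE_WIDTH_S))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return PulseSignal(x, fs)


def synthesize_thermal(
    params: SubjectParams,
    metrics: hrv.HRVMetrics,
    coupling: CouplingParams,
    fs: float = 10.0,
    seed: int | None = None,
) -> dict[str, ThermalROISeries]:
    """Three ROI temperature traces whose band content encodes the true HRV.

    Components per ROI: baseline (+ mean-RR-coupled offset), half-period
    cosine drift, respiratory tone at the breathing frequency, cardiac-band
    tone at the mean heart frequency with amplitude linear in mean HR,
    myogenic tone with amplitude linear in RMSSD, and white noise.
    """
    if seed is None:
        seed = params.seed
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    f_cardiac = 1000.0 / params.mean_rr  # mean heart frequency, Hz
    amp_cardiac = coupling.cardiac_gain * metrics.hr
    amp_myo = coupling.myo_gain * metrics.rmssd
    offset = coupling.mean_gain * (params.mean_rr - _RR_REF)
    drift = coupling.drift_amp * np.cos(np.pi * t / params.duration)
    rng = np.random.default_rng(seed)
    out: dict[str, ThermalROISeries] = {}
    for roi in ROI_NAMES:
        x = (
            _ROI_BASELINE[roi]
            + offset
            + drift
            + coupling.resp_amp[roi] * np.sin(2 * np.pi * params.breath_freq * t)
            + amp_cardiac * np.sin(2 * np.pi * f_cardiac * t)
            + amp_myo * np.sin(2 * np.pi * F_MYO * t)
        )
        if coupling.noise_sd > 0:
            x = x + rng.normal(0.0, coupling.noise_sd, size=n)
        out[roi] = ThermalROISeries(roi=roi, samples=x, fs=fs)
    return out


def make_subject(
    params: SubjectParams,
    coupling: CouplingParams | None = None,
    ppg_noise_sd: float = DEFAULT_PPG_NOISE_SD,
    spectral_cfg: hrv.SpectralConfig | None = None,
) -> SyntheticSubject:
    """Ground truth plus simulated PPG and thermal recordings for one subject."""
    coupling = coupling or CouplingParams.strong()
    true_rr = generate_rr_series(params)
    true_metrics = hrv.compute_all(true_rr, spectral_cfg)
    ss = np.random.SeedSequence(params.seed)
    ppg_seed, thermal_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    ppg = synthesize_ppg(
        true_rr, noise_sd=ppg_noise_sd, duration=params.duration, seed=ppg_seed
    )
    thermal_series = synthesize_thermal(params, true_metrics, coupling, seed=thermal_seed)
    return SyntheticSubject(
        params=params,
        true_rr=true_rr,
        true_metrics=true_metrics,
        ppg=ppg,
        thermal=thermal_series,
    )


def draw_subject_params(rng: np.random.Generator, duration: float = 60.0) -> SubjectParams:
    """One subject's rhythm parameters from the cohort's uniform ranges.

    mean_rr ~ U[1050, 1400] ms keeps the mean heart frequency inside the
    0.5-1 Hz cardiac band of the thermal spectrum; lf_amp, hf_amp ~
    U[10, 60] ms; breath_freq ~ U[0.2, 0.33] Hz so high-frequency content
    varies across the cohort.
    """
    return SubjectParams(
        mean_rr=float(rng.uniform(1050.0, 1400.0)),
        lf_amp=float(rng.uniform(10.0, 60.0)),
        hf_amp=float(rng.uniform(10.0, 60.0)),
        breath_freq=float(rng.uniform(0.20, 0.33)),
        duration=duration,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int = 32,
    coupling: CouplingParams | None = None,
    master_seed: int = 0,
    ppg_noise_sd: float = DEFAULT_PPG_NOISE_SD,
    duration: float = 60.0,
    k_folds: int = 5,
) -> CohortDataset:
    """A reproducible cohort with thermal features and ground-truth targets.

    The predictor matrix is n x 30 (3 ROIs x 10 features); targets are the
    seven true HRV metrics computed from each subject's true RR series.
    Fully reproducible from ``master_seed``.
    """
    if n < 2 * k_folds:
        raise ValueError(f"n={n} too small for {k_folds}-fold cross-validation")
    coupling = coupling or CouplingParams.strong()
    rng = np.random.default_rng(master_seed)
    subjects = []
    rows = []
    target_rows = []
    ids = []
    for i in range(n):
        params = draw_subject_params(rng, duration=duration)
        subject = make_subject(params, coupling, ppg_noise_sd=ppg_noise_sd)
        subjects.append(subject)
        fv = thermal.feature_vector(
            subject.thermal["G"], subject.thermal["NT"], subject.thermal["N"]
        )
        rows.append(fv.to_series())
        target_rows.append(pd.Series(subject.true_metrics.as_dict()))
        ids.append(f"s{i + 1:02d}")
    features = pd.DataFrame(rows, index=ids)
    targets = pd.DataFrame(target_rows, index=ids)
    return CohortDataset(subjects=tuple(subjects), features=features, targets=targets)
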