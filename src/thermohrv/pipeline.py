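"""End-to-end orchestration: simulate -> extract -> train -> report.

Every stage reads and writes documented plain-text artifacts so it can be
run (and audited) in isolation:

* per-subject signal files: two-column CSV ``time_s,value`` with a JSON
  sidecar ``{fs_hz, units, roi, subject_id}``;
* feature table: ``subject_id`` + 30 ``{roi}_{feature}`` columns;
* HRV table: ``subject_id`` + the seven metric columns;
* summary: one JSON object per metric with stability, agreement, and the
  representative model's named weights.

A :class:`RunConfig` (YAML-serializable) plus the written manifest fully
determine a run; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, hrv, ppg, regression, synthetic, thermal
from .signals import ROI_NAMES, PulseSignal, ThermalROISeries

__all__ = ["RunConfig", "run_simulate", "run_extract", "run_train_eval", "run_all"]

logger = logging.getLogger("thermohrv.pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    n_subjects: int = 32
    master_seed: int = 0
    duration: float = 60.0
    ppg_noise_sd: float = synthetic.DEFAULT_PPG_NOISE_SD
    coupling: synthetic.CouplingParams = field(
        default_factory=synthetic.CouplingParams.strong
    )
    spectral: hrv.SpectralConfig = field(default_factory=hrv.SpectralConfig)
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    model: regression.ModelConfig = field(default_factory=regression.ModelConfig)
    metrics: tuple[str, ...] = hrv.METRIC_NAMES
    out_dir: str = "runs/default"

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["spectral"]["lf_band"] = list(self.spectral.lf_band)
        payload["spectral"]["hf_band"] = list(self.spectral.hf_band)
        payload["metrics"] = list(self.metrics)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if "coupling" in payload:
            payload["coupling"] = synthetic.CouplingParams(**payload["coupling"])
        if "spectral" in payload:
            sp = dict(payload["spectral"])
            sp["lf_band"] = tuple(sp["lf_band"])
            sp["hf_band"] = tuple(sp["hf_band"])
            payload["spectral"] = hrv.SpectralConfig(**sp)
        if "model" in payload:
            payload["model"] = regression.ModelConfig(**payload["model"])
        if "metrics" in payload:
            payload["metrics"] = tuple(payload["metrics"])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_signal(path: Path, times: np.ndarray, values: np.ndarray, sidecar: dict) -> None:
    frame = pd.DataFrame({"time_s": times, "value": values})
    frame.to_csv(path, index=False, float_format="%.10g")
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def _read_signal(path: Path) -> tuple[pd.DataFrame, dict]:
    sidecar_path = path.with_suffix(".json")
    if not path.exists() or not sidecar_path.exists():
        raise FileNotFoundError(f"missing signal file or sidecar for {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - defensive
        raise ValueError(f"malformed signal file {path}: {exc}") from exc
    if list(frame.columns) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected columns time_s,value, got {list(frame.columns)}")
    return frame, json.loads(sidecar_path.read_text())


def run_simulate(cfg: RunConfig) -> Path:
    """Generate the cohort and write all signal files, truth table, manifest."""
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = Path(cfg.out_dir)
    signals_dir = out / "signals"
    signals_dir.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(
        n=cfg.n_subjects,
        coupling=cfg.coupling,
        master_seed=cfg.master_seed,
        ppg_noise_sd=cfg.ppg_noise_sd,
        duration=cfg.duration,
        k_folds=cfg.model.k_folds,
    )
    for sid, subject in zip(cohort.features.index, cohort.subjects):
        _write_signal(
            signals_dir / f"{sid}_ppg.csv",
            subject.ppg.times,
            subject.ppg.samples,
            {"fs_hz": subject.ppg.fs, "units": "a.u.", "roi": None, "subject_id": sid},
        )
        for roi in ROI_NAMES:
            series = subject.thermal[roi]
            _write_signal(
                signals_dir / f"{sid}_{roi}.csv",
                series.times,
                series.samples,
                {"fs_hz": series.fs, "units": "degC", "roi": roi, "subject_id": sid},
            )
    truth = cohort.targets.copy()
    truth.index.name = "subject_id"
    truth.to_csv(out / "truth.csv", float_format="%.10g")
    manifest = {
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "config_hash": cfg.config_hash(),
        "subject_ids": list(cohort.features.index),
        "subject_seeds": [s.params.seed for s in cohort.subjects],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    logger.info("simulated %d subjects into %s (config %s)",
                cfg.n_subjects, out, cfg.config_hash())
    return out


def run_extract(cfg: RunConfig, cohort_dir: str | Path | None = None) -> tuple[Path, Path]:
    """Compute the feature and measured-HRV tables from the signal files."""
    out = Path(cohort_dir) if cohort_dir is not None else Path(cfg.out_dir)
    signals_dir = out / "signals"
    manifest = json.loads((out / "manifest.json").read_text())
    feature_rows, hrv_rows = [], []
    for sid in manifest["subject_ids"]:
        frame, meta = _read_signal(signals_dir / f"{sid}_ppg.csv")
        pulse = PulseSignal(frame["value"].to_numpy(), fs=float(meta["fs_hz"]))
        rr = ppg.preprocess(pulse)
        metrics = hrv.compute_all(rr, cfg.spectral)
        hrv_rows.append(pd.Series(metrics.as_dict(), name=sid))
        rois = {}
        for roi in ROI_NAMES:
            path = signals_dir / f"{sid}_{roi}.csv"
            if not path.exists():
                raise FileNotFoundError(f"subject {sid}: missing ROI {roi} file {path}")
            frame, meta = _read_signal(path)
            rois[roi] = ThermalROISeries(
                roi=roi, samples=frame["value"].to_numpy(), fs=float(meta["fs_hz"])
            )
        fv = thermal.feature_vector(
            rois["G"], rois["NT"], rois["N"],
            sampen_m=cfg.sampen_m, sampen_r_factor=cfg.sampen_r_factor,
        )
        feature_rows.append(fv.to_series().rename(sid))
    features = pd.DataFrame(feature_rows)
    features.index.name = "subject_id"
    measured = pd.DataFrame(hrv_rows)
    measured.index.name = "subject_id"
    features_path = out / "features.csv"
    hrv_path = out / "hrv_measured.csv"
    features.to_csv(features_path, float_format="%.10g")
    measured.to_csv(hrv_path, float_format="%.10g")
    logger.info("extracted %d x %d features into %s", *features.shape, features_path)
    return features_path, hrv_path


def run_train_eval(
    cfg: RunConfig,
    features_path: str | Path | None = None,
    hrv_path: str | Path | None = None,
) -> Path:
    """Per-metric bootstrap SVR training plus agreement evaluation.

    Writes ``summary.json`` (machine-readable, one entry per metric) and
    ``predictions.csv`` (measured and representative predicted values).
    """
    out = Path(cfg.out_dir)
    features = pd.read_csv(features_path or out / "features.csv", index_col="subject_id")
    measured = pd.read_csv(hrv_path or out / "hrv_measured.csv", index_col="subject_id")
    boot_results: dict[str, regression.BootstrapResult] = {}
    predicted = {}
    for metric in cfg.metrics:
        y = measured[metric].to_numpy()
        if not np.all(np.isfinite(y)):
            logger.warning("metric %s has non-finite measured values; skipped", metric)
            continue
        boot = regression.bootstrap_cv(features, y, cfg.model)
        boot_results[metric] = boot
        predicted[metric] = boot.representative_predictions
        logger.info("metric %s: r = %.3f +/- %.3f over %d fold draws",
                    metric, boot.r_mean, boot.r_sd, cfg.model.n_bootstrap)
    predicted = pd.DataFrame(predicted, index=measured.index)
    report = evaluation.full_report(measured[list(predicted.columns)], predicted, boot_results)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(report, sort_keys=True, indent=1))
    both = pd.concat(
        {"measured": measured[list(predicted.columns)], "predicted": predicted}, axis=1
    )
    both.columns = [f"{a}_{b}" for a, b in both.columns]
    both.to_csv(out / "predictions.csv", float_format="%.10g")
    return summary_path


def run_all(cfg: RunConfig) -> Path:
    """simulate -> extract -> train/eval; returns the summary path."""
    run_simulate(cfg)
    run_extract(cfg)
    return run_train_eval(cfg)
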