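"""End-to-end orchestration: read -> epochs -> OBS -> ICA -> select -> remove
-> metrics -> report, plus the 2 (ICA intervals) x 4 (selection criteria)
method-comparison sweep."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .events import (
    EEGRecording,
    PA_WINDOW,
    RPeakSeries,
    VALIDATION_WINDOW,
    detect_r_peaks,
    extract_epochs,
    partition_channels,
)
from .ica import fit_ica
from .metrics import (
    BandDefinition,
    QualityReport,
    bfc_metrics,
    compare_methods,
    cwt_epoch_mean,
    cwt_off,
    mean_time_derivative,
    ptp_ratio,
)
from .obs import correct_obs
from .selection import (
    apply_selection,
    build_pa_templates,
    score_corr,
    score_pacf,
    score_pvaf,
    score_wave,
)

__all__ = ["PipelineConfig", "run_pipeline", "run_sweep", "compare_runs"]

logger = logging.getLogger("pacorrect")

METHODS = ("pvaf", "corr", "pacf", "wave")
INTERVAL_MODES = ("whole", "pa_epochs")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    eeg_path: str
    out_dir: str
    events_path: str | None = None
    ecg_label: str | None = None
    method: str = "pvaf"
    interval_mode: str = "whole"
    seed: int = 0
    obs_n_pc: int = 3
    ica_max_iter: int = 500
    ica_tol: float = 1e-6
    ica_max_fit_samples: int | None = None
    pvaf_threshold_pct: float = 2.5
    corr_rel_threshold: float = 0.40
    pacf_block_size: int = 4
    pacf_rel_threshold: float = 1.0 / 3.0
    wave_threshold: float = 3.0
    compute_tfc: bool = True
    bands: BandDefinition = field(default_factory=BandDefinition)

    def __post_init__(self) -> None:
        if (self.events_path is None) == (self.ecg_label is None):
            raise PipelineConfigError(
                "exactly one of events_path / ecg_label must be given"
            )
        if self.method not in METHODS:
            raise PipelineConfigError(f"method must be one of {METHODS}")
        if self.interval_mode not in INTERVAL_MODES:
            raise PipelineConfigError(f"interval_mode must be one of {INTERVAL_MODES}")
        if not Path(self.eeg_path).exists():
            raise PipelineConfigError(f"EEG file not found: {self.eeg_path}")
        if self.events_path is not None and not Path(self.events_path).exists():
            raise PipelineConfigError(f"events file not found: {self.events_path}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        bands = payload.pop("bands", None)
        cfg = cls(**payload)
        if bands is not None:
            cfg.bands = BandDefinition(**{k: tuple(v) for k, v in bands.items()})
        return cfg


def _load_inputs(config: PipelineConfig) -> tuple[EEGRecording, RPeakSeries]:
    rec, marker_peaks = pio.read_recording(config.eeg_path)
    if config.ecg_label is not None:
        if config.ecg_label not in rec.labels:
            raise PipelineConfigError(
                f"ECG channel {config.ecg_label!r} not found in recording"
            )
        ecg = rec.data[rec.labels.index(config.ecg_label)]
        eeg_labels = [l for l in rec.labels if l != config.ecg_label]
        rec = rec.pick(eeg_labels)
        # bootstrap template from the strongest deflection (presumed QRS)
        fs = rec.fs
        center = int(np.argmax(np.abs(ecg)))
        half = int(round(0.06 * fs))
        lo, hi = max(center - half, 0), min(center + half, ecg.size)
        rpeaks = detect_r_peaks(ecg, fs, ecg[lo:hi])
        if not isinstance(rpeaks, RPeakSeries):
            raise ValueError("R-peak detection failed on the ECG channel")
    else:
        rpeaks = pio.read_events(config.events_path, fs=rec.fs)
    del marker_peaks
    # drop auxiliary channels (ECG, EOG, ...) that are not 10-20 scalp sites
    from .events import _parse_label

    scalp = [l for l in rec.labels if _parse_label(l) is not None]
    if len(scalp) != rec.n_channels:
        dropped = [l for l in rec.labels if l not in scalp]
        logger.info("dropping non-scalp channel(s): %s", dropped)
        rec = rec.pick(scalp)
    return rec, rpeaks


def _select(config, method, dec, raw, post_obs, rpeaks, part):
    if method == "pvaf":
        return score_pvaf(
            dec, post_obs, rpeaks, threshold_pct=config.pvaf_threshold_pct
        )
    if method == "corr":
        templates = build_pa_templates(raw, rpeaks, part)
        return score_corr(dec, templates, rpeaks, rel_threshold=config.corr_rel_threshold)
    if method == "pacf":
        return score_pacf(
            dec,
            rpeaks,
            block_size=config.pacf_block_size,
            rel_threshold=config.pacf_rel_threshold,
        )
    if method == "wave":
        return score_wave(dec, rpeaks, threshold=config.wave_threshold)
    raise PipelineConfigError(f"unknown method {method!r}")


def _evaluate(
    config: PipelineConfig,
    raw: EEGRecording,
    post_obs: EEGRecording,
    post_ica: EEGRecording,
    rpeaks: RPeakSeries,
    part,
    method: str,
    interval_mode: str,
    n_removed: int,
) -> QualityReport:
    report = QualityReport(method=method, interval_mode=interval_mode, n_removed=n_removed)
    pre_eps = extract_epochs(post_obs, rpeaks, VALIDATION_WINDOW)
    post_eps = extract_epochs(post_ica, rpeaks, VALIDATION_WINDOW)
    report.ptp_ratio_channels, report.ptp_ratio_mean = ptp_ratio(pre_eps, post_eps)
    occ = part.occipital or list(post_obs.labels)
    bfc = bfc_metrics(post_obs, post_ica, rpeaks, occ, bands=config.bands)
    report.delta_ratio = bfc["delta_ratio"]
    report.theta_ratio = bfc["theta_ratio"]
    report.alpha_ratio = bfc["alpha_ratio"]
    report.delta_theta_ratio = bfc["delta_theta_ratio"]
    report.qc = bfc["qc"]
    if config.compute_tfc:
        pre_all = cwt_epoch_mean(post_obs, rpeaks)
        post_all = cwt_epoch_mean(post_ica, rpeaks)
        report.cwt_md_all = mean_time_derivative(cwt_off(pre_all, post_all), post_obs.fs)
        pre_occ = cwt_epoch_mean(post_obs, rpeaks, channels=occ)
        post_occ = cwt_epoch_mean(post_ica, rpeaks, channels=occ)
        report.cwt_md_occ = mean_time_derivative(cwt_off(pre_occ, post_occ), post_obs.fs)
    return report


def _write_outputs(out_dir: Path, tag: str, rec, result, report) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pio.write_brainvision(out_dir / f"corrected_{tag}.vhdr", rec)
    pd.DataFrame(
        {
            "component": np.arange(result.scores.size),
            "score": result.scores,
            "removed": result.mask.astype(int),
        }
    ).to_csv(out_dir / f"scores_{tag}.tsv", sep="\t", index=False)
    (out_dir / f"report_{tag}.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    rows = [
        {"metric": k, "value": v}
        for k, v in report.metric_values().items()
        if k not in ("method", "interval_mode")
    ]
    pd.DataFrame(rows).to_csv(out_dir / f"report_{tag}.tsv", sep="\t", index=False)


def run_pipeline(config: PipelineConfig, write: bool = True) -> QualityReport:
    """Execute the full correction chain for one method/interval combination."""
    raw, rpeaks = _load_inputs(config)
    part = partition_channels(raw.labels)
    logger.info(
        "pipeline start: %d channels, %.1f s, %d R peaks, method=%s interval=%s seed=%d",
        raw.n_channels, raw.duration, len(rpeaks), config.method,
        config.interval_mode, config.seed,
    )
    post_obs, _ = correct_obs(raw, rpeaks, window=PA_WINDOW, n_pc=config.obs_n_pc)
    dec = fit_ica(
        post_obs,
        rpeaks,
        interval_mode=config.interval_mode,
        seed=config.seed,
        max_iter=config.ica_max_iter,
        tol=config.ica_tol,
        max_fit_samples=config.ica_max_fit_samples,
    )
    result = _select(config, config.method, dec, raw, post_obs, rpeaks, part)
    logger.info("%s: removing %d / %d components", config.method, result.n_removed,
                dec.n_components)
    post_ica = apply_selection(post_obs, dec, result)
    report = _evaluate(
        config, raw, post_obs, post_ica, rpeaks, part,
        config.method, config.interval_mode, result.n_removed,
    )
    if write:
        tag = f"{config.method}_{config.interval_mode}"
        _write_outputs(Path(config.out_dir), tag, post_ica, result, report)
        _write_log(Path(config.out_dir), config, tag)
    return report


def _write_log(out_dir: Path, config: PipelineConfig, tag: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {k: (v if not isinstance(v, BandDefinition) else vars(v))
               for k, v in vars(config).items()}
    (out_dir / f"run_{tag}.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_sweep(config: PipelineConfig, write: bool = True) -> dict[str, QualityReport]:
    """All 8 variants (2 ICA intervals x 4 selection criteria), sharing the
    OBS-corrected input and one ICA fit per interval mode."""
    raw, rpeaks = _load_inputs(config)
    part = partition_channels(raw.labels)
    post_obs, _ = correct_obs(raw, rpeaks, window=PA_WINDOW, n_pc=config.obs_n_pc)
    reports: dict[str, QualityReport] = {}
    for mode in INTERVAL_MODES:
        dec = fit_ica(
            post_obs,
            rpeaks,
            interval_mode=mode,
            seed=config.seed,
            max_iter=config.ica_max_iter,
            tol=config.ica_tol,
            max_fit_samples=config.ica_max_fit_samples,
        )
        for method in METHODS:
            result = _select(config, method, dec, raw, post_obs, rpeaks, part)
            post_ica = apply_selection(post_obs, dec, result)
            report = _evaluate(
                config, raw, post_obs, post_ica, rpeaks, part, method, mode,
                result.n_removed,
            )
            tag = f"{method}_{mode}"
            reports[tag] = report
            if write:
                _write_outputs(Path(config.out_dir), tag, post_ica, result, report)
    if write:
        _write_log(Path(config.out_dir), config, "sweep")
    return reports


def compare_runs(
    reports_by_method: dict[str, list],
    metric: str,
    alpha: float = 0.05,
):
    """Tabulate a metric across methods and run the nonparametric comparison.

    ``reports_by_method`` maps a method tag to a list of
    :class:`QualityReport` (or plain numbers), one per subject/dataset.
    Returns ``(table, comparison)`` where ``table`` is a subjects x methods
    DataFrame.
    """
    if len(reports_by_method) < 2:
        raise ValueError("need at least 2 method groups to compare")
    columns = {}
    for name, reports in reports_by_method.items():
        vals = []
        for r in reports:
            if isinstance(r, QualityReport):
                v = r.metric_values().get(metric, None)
                if v is None:
                    raise ValueError(f"metric {metric!r} absent from a report of {name}")
                vals.append(float(v))
            else:
                vals.append(float(r))
        columns[name] = vals
    table = pd.DataFrame(columns)
    comparison = compare_methods({k: np.asarray(v) for k, v in columns.items()}, alpha=alpha)
    return table, comparison
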