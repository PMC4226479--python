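"""Ground-truthed synthetic EEG-in-MR data.

Two generators:

* :func:`generate_dataset` — a full recording: 1/f background with occipital
  alpha, an R-locked pulse artifact whose amplitude drifts over the recording
  and whose polarity flips between hemispheres, and a matching noisy ECG
  trace.  ``mixed = clean + artifact`` holds sample-wise.
* :func:`generate_component_dataset` — a source-model dataset (R-locked
  artifact sources + neural sources mixed by a known matrix) with ground-truth
  component labels, for testing component-selection criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import truncnorm

from .events import EEGRecording, PA_WINDOW, RPeakSeries, extract_epochs
from .ica import ICADecomposition

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "ComponentDataset",
    "default_montage",
    "generate_rr",
    "generate_artifact",
    "generate_background",
    "generate_ecg",
    "generate_dataset",
    "generate_component_dataset",
]

# 64-channel 10-10 montage, ordered so that truncations keep a usable core
# (the first 16 labels already cover frontal/central/parietal/occipital sites,
# occipital trio included); left/right labels come in symmetric pairs.
_MONTAGE_64 = [
    "Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4",
    "O1", "Oz", "O2", "T7", "T8",
    "F7", "F8", "FC5", "FC1", "FC2", "FC6", "CP5", "CP1", "CP2", "CP6",
    "P7", "P8", "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6", "FT7", "FC3", "FCz", "FC4", "FT8", "C5", "C1",
    "C2", "C6", "TP7", "CP3", "CPz",
    "CP4", "TP8", "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4",
    "PO8", "FT9", "FT10", "TP9", "TP10", "AFz",
]


def default_montage(n_channels: int = 64) -> list[str]:
    if not 1 <= n_channels <= len(_MONTAGE_64):
        raise ValueError(f"n_channels must be in [1, {len(_MONTAGE_64)}]")
    return list(_MONTAGE_64[:n_channels])


@dataclass
class SyntheticConfig:
    n_channels: int = 64
    fs: float = 250.0
    duration: float = 360.0
    rr_mean: float = 1.0
    rr_sd: float = 0.05
    artifact_gain: float = 1.0
    artifact_drift: float = 0.3
    alpha_freq: float = 10.0
    alpha_channels: tuple[str, ...] = ("O1", "Oz", "O2", "PO3", "POz", "PO4")
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rr_mean <= 0 or self.rr_sd < 0:
            raise ValueError("rr_mean must be positive, rr_sd non-negative")
        if self.rr_sd >= self.rr_mean / 3.0:
            raise ValueError("rr_sd must be below rr_mean / 3")
        if self.artifact_gain < 0 or not 0 <= self.artifact_drift < 1:
            raise ValueError("invalid artifact gain/drift")
        montage = set(default_montage(self.n_channels))
        missing = [c for c in self.alpha_channels if c not in montage]
        if missing:
            raise ValueError(f"alpha_channels not in montage: {missing}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_channels"] = list(self.alpha_channels)
        return d


@dataclass
class SyntheticDataset:
    mixed: EEGRecording
    clean: EEGRecording
    artifact: EEGRecording
    ecg: np.ndarray
    ecg_template: np.ndarray
    rpeaks: RPeakSeries
    config: SyntheticConfig
    artifact_source_ids: list[int] = field(default_factory=list)


def generate_rr(config: SyntheticConfig) -> RPeakSeries:
    """R-peak grid with truncated-normal R-R intervals, deterministic by seed."""
    rng = np.random.default_rng(config.seed)
    t0 = 0.5
    horizon = config.duration - 0.1
    if horizon - t0 < config.rr_mean:
        raise ValueError("duration too short for 2 R peaks")
    n_draw = int(np.ceil((horizon - t0) / config.rr_mean * 2)) + 10
    if config.rr_sd == 0:
        intervals = np.full(n_draw, config.rr_mean)
    else:
        a = (-3.0, 3.0)  # truncate at +/- 3 sd
        intervals = truncnorm.rvs(
            a[0], a[1], loc=config.rr_mean, scale=config.rr_sd,
            size=n_draw, random_state=rng,
        )
    times = t0 + np.concatenate([[0.0], np.cumsum(intervals)])
    times = times[times < horizon]
    if times.size < 2:
        raise ValueError("duration too short for 2 R peaks")
    return RPeakSeries(indices=np.round(times * config.fs).astype(np.int64), fs=config.fs)


def _topography(labels: list[str]) -> np.ndarray:
    """Smooth left-positive / right-negative weights; midline channels zero.

    Symmetric electrode pairs (C3/C4, FT9/FT10, ...) get equal magnitude and
    opposite sign, so the left and right epoch-averaged artifact mirror each
    other exactly.
    """
    from .events import _LABEL_RE

    w = np.zeros(len(labels))
    for i, lab in enumerate(labels):
        m = _LABEL_RE.match(lab)
        if m is None:
            raise ValueError(f"unknown montage label: {lab}")
        suffix = m.group(2)
        if suffix in ("z", "Z"):
            continue
        num = int(suffix)
        # pair key: letters + ring index; drives a smooth magnitude profile
        ring = (num + 1) // 2
        key = sum(ord(ch) for ch in m.group(1).lower()) + 7 * ring
        mag = 0.55 + 0.45 * np.sin(0.9 * key)
        w[i] = mag if num % 2 == 1 else -mag
    return w


def _pa_kernel(fs: float) -> np.ndarray:
    """Pulse-artifact waveform over 0-700 ms: damped low-frequency oscillation,
    a slow lobe, and a smaller alpha-range lobe."""
    t = np.arange(int(round(0.7 * fs))) / fs
    osc = np.sin(2 * np.pi * 4.5 * t) * np.exp(-t / 0.12)
    lobe = 0.8 * np.exp(-((t - 0.25) ** 2) / (2 * 0.08**2))
    alpha_lobe = 0.35 * np.sin(2 * np.pi * 10.5 * t) * np.exp(
        -((t - 0.15) ** 2) / (2 * 0.05**2)
    )
    return osc + lobe + alpha_lobe


def _drift(times: np.ndarray, duration: float, depth: float) -> np.ndarray:
    """Monotone half-sine amplitude modulation from 1-depth to 1+depth."""
    return 1.0 - depth * np.cos(np.pi * times / duration)


def generate_artifact(
    rpeaks: RPeakSeries, config: SyntheticConfig, labels: list[str] | None = None
) -> EEGRecording:
    """R-locked artifact: per-beat kernel x hemispheric topography x drift."""
    labels = labels or default_montage(config.n_channels)
    rng = np.random.default_rng(config.seed + 1)
    n = int(round(config.duration * config.fs))
    kernel = _pa_kernel(config.fs)
    topo = _topography(labels)
    train = np.zeros(n)
    beat_times = rpeaks.indices / config.fs
    gains = _drift(beat_times, config.duration, config.artifact_drift)
    jitter = np.round(rng.uniform(-0.02, 0.02, size=len(rpeaks)) * config.fs).astype(int)
    for idx, g, j in zip(rpeaks.indices, gains, jitter):
        start = int(idx) + int(j)
        if start < 0 or start + kernel.size > n:
            continue
        train[start : start + kernel.size] += g * kernel
    data = config.artifact_gain * np.outer(topo, train)
    return EEGRecording(data=data, fs=config.fs, labels=labels, stage="raw")


def generate_background(
    config: SyntheticConfig, labels: list[str] | None = None
) -> EEGRecording:
    """1/f background with neighbor-channel correlation + occipital alpha."""
    labels = labels or default_montage(config.n_channels)
    rng = np.random.default_rng(config.seed + 2)
    n = int(round(config.duration * config.fs))
    n_ch = len(labels)
    # shaped noise: white Gaussian spectrally scaled by f^(-exponent/2)
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1) * shaping[None, :]
    noise = np.fft.irfft(spec, n=n, axis=1)
    # neighbor smoothing across channel index gives mild spatial correlation
    noise = 0.2 * np.roll(noise, 1, axis=0) + 0.6 * noise + 0.2 * np.roll(noise, -1, axis=0)
    noise *= 10.0 / np.std(noise, axis=1, keepdims=True)  # ~10 uV RMS

    t = np.arange(n) / config.fs
    phase = rng.uniform(0, 2 * np.pi)
    env = 1.0 + 0.5 * np.sin(2 * np.pi * t / 7.0 + rng.uniform(0, 2 * np.pi))
    alpha = 8.0 * env * np.sin(2 * np.pi * config.alpha_freq * t + phase)
    data = noise
    for lab in config.alpha_channels:
        if lab in labels:
            c = labels.index(lab)
            data[c] += (0.8 + 0.2 * rng.uniform()) * alpha
    return EEGRecording(data=data, fs=config.fs, labels=labels, stage="raw")


def _qrs_kernel(fs: float) -> np.ndarray:
    """Q-R-S complex plus T wave, ~1 mV R spike, in microvolts; R at index argmax."""
    t = np.arange(int(round(-0.1 * fs)), int(round(0.45 * fs))) / fs
    q = -150.0 * np.exp(-((t + 0.040) ** 2) / (2 * 0.012**2))
    r = 1000.0 * np.exp(-(t**2) / (2 * 0.011**2))
    s = -250.0 * np.exp(-((t - 0.035) ** 2) / (2 * 0.014**2))
    tw = 280.0 * np.exp(-((t - 0.30) ** 2) / (2 * 0.060**2))
    return q + r + s + tw


def generate_ecg(
    rpeaks: RPeakSeries, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy ECG trace with QRS-T complexes at the R peaks + the clean template."""
    rng = np.random.default_rng(config.seed + 3)
    n = int(round(config.duration * config.fs))
    kernel = _qrs_kernel(config.fs)
    r_off = int(np.argmax(kernel))
    ecg = rng.standard_normal(n) * 25.0
    for idx in rpeaks.indices:
        start = int(idx) - r_off
        lo, hi = max(start, 0), min(start + kernel.size, n)
        ecg[lo:hi] += kernel[lo - start : hi - start]
    template = kernel[max(r_off - int(0.06 * config.fs), 0) : r_off + int(0.06 * config.fs)]
    return ecg, template


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Assemble clean + artifact + ECG; ``mixed = clean + artifact`` exactly.

    The artifact is rescaled so its RMS over the cardiac-locked 0-700 ms
    epochs equals ``artifact_gain`` times the clean signal's RMS over the same
    samples (epoch signal-to-background ratio).
    """
    labels = default_montage(config.n_channels)
    rpeaks = generate_rr(config)
    clean = generate_background(config, labels)
    artifact = generate_artifact(rpeaks, config, labels)
    if config.artifact_gain > 0:
        art_eps = extract_epochs(artifact, rpeaks, PA_WINDOW)
        cln_eps = extract_epochs(clean, rpeaks, PA_WINDOW)
        rms_art = float(np.sqrt(np.mean(art_eps.epochs**2)))
        rms_cln = float(np.sqrt(np.mean(cln_eps.epochs**2)))
        if rms_art > 0:
            artifact.data *= config.artifact_gain * rms_cln / rms_art
    mixed = clean.copy(data=clean.data + artifact.data)
    ecg, template = generate_ecg(rpeaks, config)
    return SyntheticDataset(
        mixed=mixed,
        clean=clean,
        artifact=artifact,
        ecg=ecg,
        ecg_template=template,
        rpeaks=rpeaks,
        config=config,
        artifact_source_ids=[0],
    )


@dataclass
class ComponentDataset:
    """Known-mixing source-model dataset for selection-criterion tests."""

    rec: EEGRecording
    sources: np.ndarray  # (n_sources, n_samples)
    mixing: np.ndarray  # (n_channels, n_sources)
    is_artifact: np.ndarray  # bool per source
    rpeaks: RPeakSeries
    config: SyntheticConfig

    def as_decomposition(self) -> ICADecomposition:
        """Oracle decomposition built from the generating model."""
        return ICADecomposition(
            unmixing=np.linalg.pinv(self.mixing),
            mixing=self.mixing.copy(),
            sources=self.sources.copy(),
            interval_mode="whole",
            rank=self.mixing.shape[1],
            seed=self.config.seed,
            fs=self.config.fs,
            labels=list(self.rec.labels),
        )


def generate_component_dataset(
    config: SyntheticConfig,
    n_artifact: int = 5,
    n_neural: int = 5,
) -> ComponentDataset:
    """Mix R-locked artifact sources and neural sources by a known matrix.

    Artifact sources are per-beat damped oscillations with distinct
    frequencies (4-9 Hz), onsets and decay times, with latency jitter and
    the configured amplitude drift.  Neural sources are a continuous
    enveloped alpha rhythm and 1/f noise processes.
    """
    labels = default_montage(config.n_channels)
    rng = np.random.default_rng(config.seed + 10)
    rpeaks = generate_rr(config)
    n = int(round(config.duration * config.fs))
    t_axis = np.arange(n) / config.fs
    sources = []
    is_art = []
    beat_times = rpeaks.indices / config.fs
    gains = _drift(beat_times, config.duration, config.artifact_drift)
    for a in range(n_artifact):
        f_osc = 4.0 + 5.0 * a / max(n_artifact - 1, 1)
        onset = 0.05 + 0.25 * rng.uniform()
        decay = 0.05 + 0.05 * rng.uniform()
        kt = np.arange(int(round(0.45 * config.fs))) / config.fs
        kernel = np.sin(2 * np.pi * f_osc * kt) * np.exp(-kt / decay)
        src = np.zeros(n)
        jit = np.round(rng.uniform(-0.02, 0.02, len(rpeaks)) * config.fs).astype(int)
        for idx, g, j in zip(rpeaks.indices, gains, jit):
            start = int(idx) + int(round(onset * config.fs)) + int(j)
            if start < 0 or start + kernel.size > n:
                continue
            src[start : start + kernel.size] += g * kernel
        sources.append(src)
        is_art.append(True)
    for b in range(n_neural):
        if b == 0:  # continuous alpha, random phase w.r.t. R peaks
            env = 1.0 + 0.5 * np.sin(2 * np.pi * t_axis / 6.0 + rng.uniform(0, 2 * np.pi))
            src = env * np.sin(2 * np.pi * config.alpha_freq * t_axis + rng.uniform(0, 2 * np.pi))
        else:  # 1/f noise
            freqs = np.fft.rfftfreq(n, 1.0 / config.fs)
            shaping = np.zeros_like(freqs)
            shaping[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
            src = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * shaping, n=n)
        sources.append(src)
        is_art.append(False)
    sources = np.asarray(sources)
    sources /= np.std(sources, axis=1, keepdims=True)  # unit-variance sources
    n_src = sources.shape[0]
    mixing = rng.standard_normal((len(labels), n_src))
    rec = EEGRecording(
        data=mixing @ sources, fs=config.fs, labels=labels, stage="raw"
    )
    return ComponentDataset(
        rec=rec,
        sources=sources,
        mixing=mixing,
        is_artifact=np.asarray(is_art, dtype=bool),
        rpeaks=rpeaks,
        config=config,
    )
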