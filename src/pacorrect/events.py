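"""Cardiac event handling: R-peak detection, R-locked epoching, montage partitioning.

Everything downstream of the raw recording is anchored to the R-peak grid:
artifact templates are built from epochs locked to the cardiac cycle, and the
validation metrics compare epochs extracted before and after correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EEGRecording",
    "RPeakSeries",
    "EpochWindow",
    "EpochSet",
    "HemispherePartition",
    "UndetectableECGError",
    "EmptyEpochSetError",
    "detect_r_peaks",
    "extract_epochs",
    "partition_channels",
]

#: Minimum separation between detected R peaks, in seconds.  Corresponds to a
#: heart rate of 200 bpm, a physiological upper bound at rest.
REFRACTORY_S = 0.3

OCCIPITAL_LABELS = ("O1", "O2", "Oz")


class UndetectableECGError(ValueError):
    """ECG channel carries no usable signal (flat / zero variance)."""


class EmptyEpochSetError(ValueError):
    """No R-peak window fits inside the recording."""


@dataclass
class EEGRecording:
    """Multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Per-channel 10-20 electrode names; unique, one per row.
    stage : {"raw", "post_obs", "post_ica"}
        Provenance tag advanced by each correction stage.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self, *, data: np.ndarray | None = None, stage: str | None = None) -> "EEGRecording":
        return replace(
            self,
            data=self.data.copy() if data is None else np.asarray(data, dtype=np.float64),
            labels=list(self.labels),
            stage=self.stage if stage is None else stage,
            meta=dict(self.meta),
        )

    def pick(self, labels: list[str]) -> "EEGRecording":
        """Return a sub-recording restricted to ``labels`` (kept in given order)."""
        idx = [self.labels.index(l) for l in labels]
        return replace(self, data=self.data[idx].copy(), labels=list(labels), meta=dict(self.meta))


@dataclass
class RPeakSeries:
    """Ordered R-peak sample indices defining the cardiac cycle grid."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.indices.size < 1:
            raise ValueError("need at least 1 R peak")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")
        if np.any(self.indices < 0):
            raise ValueError("R-peak indices must be non-negative")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def mean_rr(self) -> float:
        """Mean R-R interval in seconds.  Requires at least 2 peaks."""
        if self.indices.size < 2:
            raise ValueError("need at least 2 R peaks to form an R-R interval")
        return float(np.mean(np.diff(self.indices))) / self.fs


@dataclass(frozen=True)
class EpochWindow:
    """Epoch limits relative to each R peak, in milliseconds."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("end_ms must exceed start_ms")

    def n_samples(self, fs: float) -> int:
        return int(round((self.end_ms - self.start_ms) / 1000.0 * fs))

    def start_offset(self, fs: float) -> int:
        return int(round(self.start_ms / 1000.0 * fs))


#: The pulse-artifact interval: 0-700 ms after each R peak.
PA_WINDOW = EpochWindow(0.0, 700.0)
#: The validation interval: -200 ms to 1 s around each R peak.
VALIDATION_WINDOW = EpochWindow(-200.0, 1000.0)


@dataclass
class EpochSet:
    """R-locked epochs cut from a recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples).  ``kept`` holds the
    indices (into ``source_rpeaks``) of peaks whose full window fit in bounds;
    out-of-bounds peaks are dropped, never zero-padded.
    """

    epochs: np.ndarray
    window: EpochWindow
    source_rpeaks: RPeakSeries
    kept: np.ndarray
    labels: list[str]
    fs: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def starts(self) -> np.ndarray:
        """Absolute sample index of the first sample of each kept epoch."""
        off = self.window.start_offset(self.fs)
        return self.source_rpeaks.indices[self.kept] + off

    def slices(self) -> list[slice]:
        n = self.n_samples
        return [slice(int(s), int(s) + n) for s in self.starts()]


@dataclass
class HemispherePartition:
    """10-20 labels split by hemisphere.

    ``mesial`` (z-suffixed midline channels) belongs to neither hemisphere but
    is merged into both groups when building per-hemisphere artifact templates.
    """

    left: list[str]
    right: list[str]
    mesial: list[str]
    occipital: list[str]


_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+|z|Z)$")

#: Electrode site prefixes of the extended 10-20 (10-10) system.
_SITE_PREFIXES = frozenset(
    p.lower()
    for p in (
        "Fp", "AF", "F", "FT", "FC", "T", "C", "TP", "CP", "P", "PO", "O",
        "I", "A", "M", "N", "AFp", "FFC", "FCC", "CCP", "CPP", "PPO", "POO", "OI",
    )
)


def _parse_label(label: str) -> tuple[str, str] | None:
    m = _LABEL_RE.match(label)
    if m is None or m.group(1).lower() not in _SITE_PREFIXES:
        return None
    return m.group(1), m.group(2)


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    template: np.ndarray,
    threshold: float = 0.6,
    refractory_s: float = REFRACTORY_S,
) -> RPeakSeries:
    """Detect R peaks by normalized matched filtering against a QRS template.

    The normalized cross-correlation between the (z-scored) template and every
    same-length segment of ``ecg`` is computed; local maxima above ``threshold``
    separated by at least ``refractory_s`` are taken as beats.  The reported
    index of each beat is the position of the template's own maximum within the
    matched segment, so a beat aligned with the template is located at its R
    peak, not at the window start.

    Raises
    ------
    UndetectableECGError
        If the ECG (or the template) has zero variance.
    """
    ecg = np.asarray(ecg, dtype=np.float64).ravel()
    template = np.asarray(template, dtype=np.float64).ravel()
    if not np.all(np.isfinite(ecg)):
        raise ValueError("ECG contains non-finite samples")
    if template.size >= ecg.size:
        raise ValueError("template must be shorter than the ECG")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if np.ptp(ecg) == 0.0:
        raise UndetectableECGError("ECG is flat: R peaks undetectable")
    t_sd = np.std(template)
    if t_sd == 0.0:
        raise UndetectableECGError("template is flat: R peaks undetectable")

    m = template.size
    tz = (template - template.mean()) / (t_sd * np.sqrt(m))

    # Sliding mean/std of the ECG via cumulative sums.
    c1 = np.concatenate([[0.0], np.cumsum(ecg)])
    c2 = np.concatenate([[0.0], np.cumsum(ecg * ecg)])
    win_sum = c1[m:] - c1[:-m]
    win_sq = c2[m:] - c2[:-m]
    win_var = np.maximum(win_sq - win_sum**2 / m, 0.0)
    win_sd = np.sqrt(win_var / m)

    num = np.correlate(ecg, tz, mode="valid") / np.sqrt(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(win_sd > 0, num / win_sd, 0.0)

    distance = max(1, int(round(refractory_s * fs)))
    starts, _ = find_peaks(ncc, height=threshold, distance=distance)
    # An exact match at the very start/end of the ECG is not an interior local
    # maximum of ncc; rescue boundary hits above threshold.
    for edge in (0, ncc.size - 1):
        if ncc[edge] >= threshold and not np.any(np.abs(starts - edge) < distance):
            starts = np.sort(np.append(starts, edge))
    peaks = starts + int(np.argmax(template))
    peaks = peaks[peaks < ecg.size]
    if peaks.size < 2:
        import warnings

        warnings.warn(
            f"matched filter found only {peaks.size} beat(s) above threshold "
            f"{threshold}",
            stacklevel=2,
        )
        if peaks.size == 0:
            return np.asarray([], dtype=np.int64)  # type: ignore[return-value]
    return RPeakSeries(indices=peaks, fs=fs)


def extract_epochs(rec: EEGRecording, rpeaks: RPeakSeries, window: EpochWindow) -> EpochSet:
    """Cut one epoch per R peak whose window fits fully inside the recording.

    Windows are half-open ``[start, start + n)`` in samples, with the start
    offset rounded to the nearest sample, so epoch length depends only on the
    window and the sampling rate.
    """
    if abs(rpeaks.fs - rec.fs) > 1e-9:
        raise ValueError(f"R-peak fs {rpeaks.fs} differs from recording fs {rec.fs}")
    off = window.start_offset(rec.fs)
    n = window.n_samples(rec.fs)
    starts = rpeaks.indices + off
    ok = (starts >= 0) & (starts + n <= rec.n_samples)
    kept = np.nonzero(ok)[0]
    if kept.size == 0:
        raise EmptyEpochSetError("no R-peak window fits inside the recording")
    idx = starts[kept][:, None] + np.arange(n)[None, :]
    epochs = rec.data[:, idx].transpose(1, 0, 2).copy()
    return EpochSet(
        epochs=epochs,
        window=window,
        source_rpeaks=rpeaks,
        kept=kept,
        labels=list(rec.labels),
        fs=rec.fs,
    )


def partition_channels(labels: list[str]) -> HemispherePartition:
    """Split 10-20 labels into left (odd), right (even) and mesial (z) groups.

    Raises
    ------
    ValueError
        Listing every label that does not parse as a 10-20 name.
    """
    if not labels:
        raise ValueError("labels must be non-empty")
    left: list[str] = []
    right: list[str] = []
    mesial: list[str] = []
    bad: list[str] = []
    for lab in labels:
        parsed = _parse_label(lab)
        if parsed is None:
            bad.append(lab)
            continue
        _, suffix = parsed
        if suffix in ("z", "Z"):
            mesial.append(lab)
        elif int(suffix) % 2 == 1:
            left.append(lab)
        else:
            right.append(lab)
    if bad:
        raise ValueError(f"unknown montage label(s): {bad}")
    occipital = [l for l in labels if l in OCCIPITAL_LABELS]
    return HemispherePartition(left=left, right=right, mesial=mesial, occipital=occipital)
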