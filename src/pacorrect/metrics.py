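"""Validation metrics for pulse-artifact correction.

Three families:

* **PTP** — ratio of mean epoch peak-to-peak amplitude after vs before
  correction, per channel and averaged.
* **BFC** — batch frequency content: autoregressive (Burg) PSD of the
  occipital channels averaged over epochs, band-power ratios (delta, theta,
  alpha, delta+theta) and the quality coefficient QC = alpha ratio / mean of
  delta and theta ratios.
* **TFC** — time-varying frequency content: epoch-averaged Morlet CWT
  magnitude maps before/after correction, their difference (the removed
  content) and its mean absolute time derivative MD.

Plus a nonparametric comparison of per-subject metric values across methods
(Kruskal-Wallis omnibus + Tukey-style rank posthoc).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.regression.linear_model import burg as sm_burg

from .events import (
    EEGRecording,
    EpochSet,
    RPeakSeries,
    VALIDATION_WINDOW,
    extract_epochs,
)
from .wavelets import TFC_WAVE, WaveParams, coi_samples, cwt_magnitude

__all__ = [
    "BandDefinition",
    "QualityReport",
    "ptp_ratio",
    "ar_psd",
    "band_power",
    "band_ratios",
    "quality_coefficient",
    "bfc_metrics",
    "cwt_epoch_mean",
    "cwt_off",
    "mean_time_derivative",
    "compare_methods",
]

AR_ORDER = 16


@dataclass(frozen=True)
class BandDefinition:
    """Frequency bands in Hz: ascending, non-overlapping [low, high] pairs."""

    delta: tuple[float, float] = (1.0, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name in ("delta", "theta", "alpha"):
            lo, hi = getattr(self, name)
            if hi <= lo:
                raise ValueError(f"{name} band must have high > low")
            if lo < prev_hi:
                raise ValueError("bands must be ascending and non-overlapping")
            prev_hi = hi


@dataclass
class QualityReport:
    """Container for the validation metrics of one corrected recording."""

    method: str = ""
    interval_mode: str = ""
    n_removed: int = 0
    ptp_ratio_channels: dict = field(default_factory=dict)
    ptp_ratio_mean: float = float("nan")
    delta_ratio: float | None = None
    theta_ratio: float | None = None
    alpha_ratio: float | None = None
    delta_theta_ratio: float | None = None
    qc: float | None = None
    cwt_md_all: float | None = None
    cwt_md_occ: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "interval_mode": self.interval_mode,
            "n_removed": self.n_removed,
            "ptp_ratio_mean": self.ptp_ratio_mean,
            "ptp_ratio_channels": self.ptp_ratio_channels,
            "delta_ratio": self.delta_ratio,
            "theta_ratio": self.theta_ratio,
            "alpha_ratio": self.alpha_ratio,
            "delta_theta_ratio": self.delta_theta_ratio,
            "qc": self.qc,
            "cwt_md_all": self.cwt_md_all,
            "cwt_md_occ": self.cwt_md_occ,
        }

    def metric_values(self) -> dict:
        """Flat scalar metrics, for tabulation across runs."""
        d = self.to_dict()
        d.pop("ptp_ratio_channels")
        return d


def ptp_ratio(pre: EpochSet, post: EpochSet) -> tuple[dict, float]:
    """Mean epoch peak-to-peak amplitude, after/before, per channel + mean.

    Channels whose pre-correction peak-to-peak is zero are excluded with a
    warning.
    """
    if pre.epochs.shape != post.epochs.shape:
        raise ValueError("pre/post epoch sets must have identical shape")
    if pre.labels != post.labels:
        raise ValueError("pre/post channel labels differ")
    ptp_pre = np.ptp(pre.epochs, axis=2).mean(axis=0)  # (ch,)
    ptp_post = np.ptp(post.epochs, axis=2).mean(axis=0)
    ratios: dict[str, float] = {}
    for c, lab in enumerate(pre.labels):
        if ptp_pre[c] == 0.0:
            warnings.warn(
                f"channel {lab}: zero pre peak-to-peak, excluded from PTP ratio",
                stacklevel=2,
            )
            continue
        ratios[lab] = float(ptp_post[c] / ptp_pre[c])
    if not ratios:
        raise ValueError("no channel with non-zero pre peak-to-peak")
    return ratios, float(np.mean(list(ratios.values())))


def ar_psd(
    x: np.ndarray, fs: float, freqs: np.ndarray, order: int = AR_ORDER
) -> np.ndarray:
    """One-sided autoregressive (Burg) power spectral density on ``freqs``."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if order >= x.size:
        raise ValueError(f"AR order {order} >= signal length {x.size}")
    if np.std(x) == 0.0:
        raise ValueError("degenerate signal: zero variance")
    rho, sigma2 = sm_burg(x, order=order, demean=True)
    freqs = np.asarray(freqs, dtype=np.float64)
    w = np.exp(-2j * np.pi * np.outer(freqs / fs, np.arange(1, order + 1)))
    denom = np.abs(1.0 - w @ rho) ** 2
    return 2.0 * sigma2 / (fs * denom)


def band_power(psd: np.ndarray, freqs: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over grid points within ``band``."""
    freqs = np.asarray(freqs, dtype=np.float64)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError(f"fewer than 2 grid points inside band {band}")
    return float(np.trapezoid(np.asarray(psd)[sel], freqs[sel]))


def band_ratios(
    psd_pre: np.ndarray,
    psd_post: np.ndarray,
    freqs: np.ndarray,
    bands: BandDefinition = BandDefinition(),
) -> dict:
    """Post/pre band-power ratios for delta, theta, alpha, and delta+theta."""
    psd_pre = np.asarray(psd_pre)
    psd_post = np.asarray(psd_post)
    if psd_pre.shape != psd_post.shape:
        raise ValueError("pre/post PSDs must share the frequency grid")
    out: dict[str, float | None] = {}
    for name in ("delta", "theta", "alpha"):
        b = getattr(bands, name)
        p_pre = band_power(psd_pre, freqs, b)
        p_post = band_power(psd_post, freqs, b)
        out[f"{name}_ratio"] = p_post / p_pre if p_pre > 0 else None
    dt = (bands.delta[0], bands.theta[1])
    p_pre = band_power(psd_pre, freqs, dt)
    out["delta_theta_ratio"] = (
        band_power(psd_post, freqs, dt) / p_pre if p_pre > 0 else None
    )
    return out


def quality_coefficient(ratios: dict) -> float:
    """QC = alpha ratio / mean(delta ratio, theta ratio)."""
    for key in ("delta_ratio", "theta_ratio", "alpha_ratio"):
        if ratios.get(key) is None:
            raise ValueError(f"missing {key}")
    denom = (ratios["delta_ratio"] + ratios["theta_ratio"]) / 2.0
    if denom == 0.0:
        raise ValueError("degenerate QC: zero delta/theta ratio mean")
    return float(ratios["alpha_ratio"] / denom)


def _mean_epoch_psd(
    rec: EEGRecording,
    rpeaks: RPeakSeries,
    channels: list[str],
    freqs: np.ndarray,
    order: int,
) -> np.ndarray:
    eps = extract_epochs(rec.pick(channels), rpeaks, VALIDATION_WINDOW)
    psds = []
    for e in range(eps.n_epochs):
        for c in range(eps.n_channels):
            x = eps.epochs[e, c]
            if np.std(x) == 0.0:
                continue
            psds.append(ar_psd(x, rec.fs, freqs, order=order))
    if not psds:
        raise ValueError("degenerate signal: all epochs flat")
    return np.mean(psds, axis=0)


def bfc_metrics(
    pre: EEGRecording,
    post: EEGRecording,
    rpeaks: RPeakSeries,
    channels: list[str],
    bands: BandDefinition = BandDefinition(),
    order: int = AR_ORDER,
    freqs: np.ndarray | None = None,
) -> dict:
    """Band-power ratios + QC from epoch-mean AR PSDs of the given channels."""
    if freqs is None:
        freqs = np.linspace(0.5, 30.0, 241)
    psd_pre = _mean_epoch_psd(pre, rpeaks, channels, freqs, order)
    psd_post = _mean_epoch_psd(post, rpeaks, channels, freqs, order)
    ratios = band_ratios(psd_pre, psd_post, freqs, bands)
    try:
        ratios["qc"] = quality_coefficient(ratios)
    except ValueError:
        ratios["qc"] = None
    return ratios


def cwt_epoch_mean(
    rec: EEGRecording,
    rpeaks: RPeakSeries,
    params: WaveParams = TFC_WAVE,
    channels: list[str] | None = None,
    window=VALIDATION_WINDOW,
) -> np.ndarray:
    """Epoch-averaged |CWT| map, averaged over the channel subset.

    The transform runs over the continuous signal and the magnitude is then
    segmented, so epoch boundaries add no edge artifacts.  Returns an array of
    shape (n_freqs, n_window_samples).
    """
    channels = rec.labels if channels is None else channels
    if not channels:
        raise ValueError("empty channel subset")
    sub = rec.pick(channels)
    off = window.start_offset(rec.fs)
    n = window.n_samples(rec.fs)
    starts = rpeaks.indices + off
    starts = starts[(starts >= 0) & (starts + n <= rec.n_samples)]
    if starts.size == 0:
        raise ValueError("no validation epoch fits inside the recording")
    idx = starts[:, None] + np.arange(n)[None, :]
    acc = np.zeros((len(params.freqs), n))
    for c in range(sub.n_channels):
        mag = cwt_magnitude(sub.data[c], rec.fs, params)
        acc += mag[:, idx].mean(axis=1)
    return acc / sub.n_channels


def cwt_off(cwt_pre: np.ndarray, cwt_post: np.ndarray) -> np.ndarray:
    """Removed time-frequency content: pre map minus post map (signed)."""
    cwt_pre = np.asarray(cwt_pre)
    cwt_post = np.asarray(cwt_post)
    if cwt_pre.shape != cwt_post.shape:
        raise ValueError("CWT maps must share the time-frequency grid")
    return cwt_pre - cwt_post


def mean_time_derivative(
    cwt_map: np.ndarray,
    fs: float,
    params: WaveParams = TFC_WAVE,
    exclude_coi: bool = True,
) -> float:
    """Mean |time derivative| of a time-frequency map, in magnitude per second.

    Per frequency row, the absolute first difference along time is averaged
    (excluding each row's cone-of-influence edges when ``exclude_coi``), then
    rows are averaged.  Zero iff the map is time-constant per row.
    """
    cwt_map = np.asarray(cwt_map, dtype=np.float64)
    if cwt_map.ndim != 2:
        raise ValueError("map must be 2-D (freqs x time)")
    n_f, n_t = cwt_map.shape
    d = np.abs(np.diff(cwt_map, axis=1)) * fs
    if not exclude_coi:
        return float(d.mean())
    coi = coi_samples(params, fs)
    vals = []
    for r in range(n_f):
        c = int(min(coi[r], (n_t - 2) // 2))
        row = d[r, c : d.shape[1] - c] if c > 0 else d[r]
        if row.size:
            vals.append(row.mean())
    return float(np.mean(vals))


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    group_names: list[str]
    mean_ranks: np.ndarray
    pairwise: list[dict]  # {"pair": (a, b), "p": float, "significant": bool}

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [tuple(p["pair"]) for p in self.pairwise if p["significant"]]


def compare_methods(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test with Tukey-style rank posthoc.

    Pairwise comparisons (run only when the omnibus test rejects) use the
    tie-corrected mean-rank statistic referred to the studentized range
    distribution (Nemenyi procedure).
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        data = [np.asarray(groups[n], dtype=np.float64) for n in names]
    else:
        data = [np.asarray(g, dtype=np.float64) for g in groups]
        names = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in data):
        raise ValueError("each group needs at least 2 values")

    pooled = np.concatenate(data)
    try:
        stat, p = stats.kruskal(*data)
    except ValueError:
        # all values identical: no evidence of any difference
        stat, p = 0.0, 1.0

    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in data]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = np.array(
        [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(data))]
    )
    n_total = pooled.size
    k = len(data)
    # tie correction for the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n_total**3 - n_total) if n_total > 1 else 0
    var = n_total * (n_total + 1) / 12.0 * (1.0 - tie_term)

    pairwise = []
    if p < alpha and var > 0:
        for i, j in itertools.combinations(range(k), 2):
            se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p_ij = float(stats.studentized_range.sf(z * np.sqrt(2.0), k, np.inf))
            pairwise.append(
                {
                    "pair": (names[i], names[j]),
                    "p": p_ij,
                    "significant": p_ij < alpha,
                }
            )
    return ComparisonResult(
        statistic=float(stat),
        p_value=float(p),
        group_names=names,
        mean_ranks=mean_ranks,
        pairwise=pairwise,
    )
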