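"""Marking pulse-artifact ICA components: pvaf, corr, pacf and wave criteria.

Each criterion produces a :class:`SelectionResult` holding per-component
scores, the textual threshold rule applied, and the boolean removal mask.
All four scores are invariant to component sign flips and permute with the
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm
from statsmodels.tsa.stattools import pacf as sm_pacf

from .events import (
    EEGRecording,
    EpochWindow,
    HemispherePartition,
    PA_WINDOW,
    RPeakSeries,
    extract_epochs,
)
from .ica import ICADecomposition, remove_components
from .wavelets import SELECTION_WAVE, WaveParams, cwt_magnitude

__all__ = [
    "PATemplatePair",
    "SelectionResult",
    "score_pvaf",
    "build_pa_templates",
    "score_corr",
    "score_pacf",
    "score_wave",
    "apply_selection",
]

PVAF_THRESHOLD_PCT = 2.5
CORR_REL_THRESHOLD = 0.40
PACF_BLOCK_SIZE = 4
PACF_REL_THRESHOLD = 1.0 / 3.0
WAVE_THRESHOLD = 3.0
WAVE_BAND_HZ = (1.0, 13.0)


@dataclass
class PATemplatePair:
    """Per-hemisphere mean pulse-artifact waveforms from the uncorrected EEG."""

    left: np.ndarray
    right: np.ndarray
    fs: float
    window: EpochWindow
    built_from: str = "raw"


@dataclass
class SelectionResult:
    method: str
    scores: np.ndarray
    threshold_rule: str
    mask: np.ndarray
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask must have equal length")

    @property
    def n_removed(self) -> int:
        return int(self.mask.sum())


def _source_epochs(
    dec: ICADecomposition, rpeaks: RPeakSeries, window: EpochWindow
) -> np.ndarray:
    """Cardiac-locked epochs of the source activations: (epochs, comps, samples)."""
    rec = EEGRecording(
        data=dec.sources,
        fs=dec.fs,
        labels=[f"IC{k:03d}" for k in range(dec.n_components)],
        stage="raw",
    )
    return extract_epochs(rec, rpeaks, window).epochs


def score_pvaf(
    dec: ICADecomposition,
    reference: EEGRecording,
    rpeaks: RPeakSeries,
    window: EpochWindow = PA_WINDOW,
    threshold_pct: float = PVAF_THRESHOLD_PCT,
) -> SelectionResult:
    """Percent variance each component accounts for within the PA intervals.

    The score of component ``k`` is 100 x the variance of its back-projection
    (all channels, concatenated PA intervals) divided by the variance of
    ``reference`` over the same samples.  Components above ``threshold_pct``
    are marked for removal.
    """
    ref_eps = extract_epochs(reference, rpeaks, window)
    ref = ref_eps.epochs.transpose(1, 0, 2).reshape(reference.n_channels, -1)
    var_ref = float(np.var(ref))
    if var_ref == 0.0:
        raise ValueError("degenerate reference: zero variance in PA intervals")
    src_eps = _source_epochs(dec, rpeaks, window)
    s = src_eps.transpose(1, 0, 2).reshape(dec.n_components, -1)  # (k, t)
    m = dec.mixing  # (c, k)
    # back-projection of component k is outer(m[:, k], s[k]); its variance over
    # the flattened channels-x-time block factorizes into channel and time moments
    em, em2 = m.mean(axis=0), (m**2).mean(axis=0)
    es, es2 = s.mean(axis=1), (s**2).mean(axis=1)
    scores = 100.0 * (em2 * es2 - (em * es) ** 2) / var_ref
    mask = scores > threshold_pct
    return SelectionResult(
        method="pvaf",
        scores=scores,
        threshold_rule=f"score > {threshold_pct}% of PA-interval variance",
        mask=mask,
    )


def build_pa_templates(
    rec_raw: EEGRecording,
    rpeaks: RPeakSeries,
    part: HemispherePartition,
    window: EpochWindow = PA_WINDOW,
) -> PATemplatePair:
    """Per-hemisphere PA templates from the *uncorrected* recording.

    Each template is the mean over PA epochs and over the hemisphere's
    channels, with the mesial (midline) channels included in both groups.
    """
    if rec_raw.stage != "raw":
        raise ValueError(
            f"templates must use uncorrected signal (stage 'raw', got "
            f"'{rec_raw.stage}')"
        )
    eps = extract_epochs(rec_raw, rpeaks, window)
    mean_by_channel = eps.epochs.mean(axis=0)  # (ch, s)
    idx = {lab: i for i, lab in enumerate(eps.labels)}

    def group_mean(labels: list[str]) -> np.ndarray:
        rows = [idx[l] for l in labels if l in idx]
        if not rows:
            raise ValueError("hemisphere group has no channels in the recording")
        return mean_by_channel[rows].mean(axis=0)

    return PATemplatePair(
        left=group_mean(part.left + part.mesial),
        right=group_mean(part.right + part.mesial),
        fs=rec_raw.fs,
        window=window,
    )


def score_corr(
    dec: ICADecomposition,
    templates: PATemplatePair,
    rpeaks: RPeakSeries,
    rel_threshold: float = CORR_REL_THRESHOLD,
) -> SelectionResult:
    """Correlation of each epoch-averaged component with the PA templates.

    The score is the larger absolute zero-lag Pearson correlation against the
    left/right template; components scoring at least ``rel_threshold`` times
    the best score are marked.
    """
    src_eps = _source_epochs(dec, rpeaks, templates.window)
    avg = src_eps.mean(axis=0)  # (k, s)
    scores = np.zeros(dec.n_components)
    for k in range(dec.n_components):
        a = avg[k]
        if np.std(a) == 0.0:
            warnings.warn(
                f"component {k}: zero-variance epoch average, corr score set to 0",
                stacklevel=2,
            )
            continue
        rs = []
        for tpl in (templates.left, templates.right):
            if np.std(tpl) == 0.0:
                rs.append(0.0)
            else:
                rs.append(abs(np.corrcoef(a, tpl)[0, 1]))
        scores[k] = max(rs)
    ref = scores.max()
    mask = scores >= rel_threshold * ref if ref > 0 else np.zeros_like(scores, bool)
    return SelectionResult(
        method="corr",
        scores=scores,
        threshold_rule=f"score >= {rel_threshold:g} x max score ({ref:.3f})",
        mask=mask,
    )


def score_pacf(
    dec: ICADecomposition,
    rpeaks: RPeakSeries,
    block_size: int = PACF_BLOCK_SIZE,
    rel_threshold: float = PACF_REL_THRESHOLD,
    lag_tol: float = 0.10,
) -> SelectionResult:
    """Partial-autocorrelation peak at the R-R lag.

    Blocks spanning ``block_size`` consecutive cardiac cycles are cut from
    each component's continuous activation (one block per ``block_size`` R
    peaks, so the R-R periodicity is preserved inside each block), the blocks
    are averaged sample-wise, and the PACF of the averaged block is scanned
    for a local maximum within ``lag_tol`` of the mean R-R lag.  Peaks must
    clear a Bonferroni-corrected white-noise significance bound; the
    best-scoring component sets the reference and components above
    ``rel_threshold`` x reference are marked.
    """
    rr_lag = int(round(rpeaks.mean_rr * dec.fs))
    block_len = block_size * rr_lag
    if rr_lag >= block_len:
        raise ValueError(
            f"block too short for R-R lag: lag {rr_lag} >= block {block_len}"
        )
    n_total = dec.sources.shape[1]
    starts = rpeaks.indices[::block_size]
    starts = starts[(starts >= 0) & (starts + block_len <= n_total)]
    if starts.size < 2:
        raise ValueError(
            f"need >= 2 blocks of {block_size} cardiac cycles "
            f"(have {starts.size})"
        )
    lo = max(1, int(np.floor(rr_lag * (1.0 - lag_tol))))
    hi = int(np.ceil(rr_lag * (1.0 + lag_tol)))
    nlags = min(hi + 2, block_len // 2 - 1)
    if nlags < hi:
        raise ValueError("block too short for R-R lag tolerance window")
    # white-noise significance floor, Bonferroni over the lags examined
    n_lags_examined = hi - lo + 1
    floor = norm.ppf(1.0 - 0.025 / max(n_lags_examined, 1)) / np.sqrt(block_len)

    idx = starts[:, None] + np.arange(block_len)[None, :]
    scores = np.zeros(dec.n_components)
    for k in range(dec.n_components):
        avg = dec.sources[k][idx].mean(axis=0)
        if np.std(avg) == 0.0:
            continue
        p = sm_pacf(avg, nlags=nlags, method="burg")
        peaks, props = find_peaks(p[1:], height=floor)  # lags 1..nlags
        lags = peaks + 1
        in_win = (lags >= lo) & (lags <= hi)
        if np.any(in_win):
            scores[k] = float(props["peak_heights"][in_win].max())
    ref = scores.max()
    mask = (scores > 0) & (scores > rel_threshold * ref)
    return SelectionResult(
        method="pacf",
        scores=scores,
        threshold_rule=(
            f"R-R-lag PACF peak > {rel_threshold:g} x max peak ({ref:.3f}); "
            f"lag window [{lo}, {hi}] samples, noise floor {floor:.3f}"
        ),
        mask=mask,
        extras={"rr_lag": rr_lag, "floor": floor},
    )


def score_wave(
    dec: ICADecomposition,
    rpeaks: RPeakSeries,
    params: WaveParams = SELECTION_WAVE,
    threshold: float = WAVE_THRESHOLD,
    band_hz: tuple[float, float] = WAVE_BAND_HZ,
    window: EpochWindow = PA_WINDOW,
) -> SelectionResult:
    """Time-locking ratio of the epoch-averaged Morlet CWT magnitude.

    For each component the |CWT| is computed over the continuous activation,
    segmented into PA epochs and averaged.  The score is the peak of the
    averaged map within ``band_hz`` divided by the temporal median of the
    peak's frequency row; a time-locked burst stands far above its row median
    while stationary rhythms and noise stay near 1.  This automated score
    stands in for visual inspection of the component time-frequency maps.
    """
    freqs = params.freq_array()
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(band):
        raise ValueError("no analysis frequency falls inside the band")
    off = window.start_offset(dec.fs)
    n = window.n_samples(dec.fs)
    starts = rpeaks.indices + off
    starts = starts[(starts >= 0) & (starts + n <= dec.sources.shape[1])]
    if starts.size == 0:
        raise ValueError("no PA epoch fits inside the recording")
    scores = np.zeros(dec.n_components)
    for k in range(dec.n_components):
        x = dec.sources[k]
        if np.all(x == x[0]):
            continue  # flat source: score 0
        mag = cwt_magnitude(x, dec.fs, params)[band]
        idx = starts[:, None] + np.arange(n)[None, :]
        avg = mag[:, idx].mean(axis=1)  # (band rows, n)
        r, t = np.unravel_index(int(np.argmax(avg)), avg.shape)
        peak = avg[r, t]
        med = float(np.median(avg[r]))
        scores[k] = peak / med if med > 0 else 0.0
    mask = scores >= threshold
    return SelectionResult(
        method="wave",
        scores=scores,
        threshold_rule=(
            f"CWT time-locking ratio >= {threshold:g} within "
            f"{band_hz[0]:g}-{band_hz[1]:g} Hz"
        ),
        mask=mask,
    )


def apply_selection(
    rec: EEGRecording, dec: ICADecomposition, result: SelectionResult
) -> EEGRecording:
    """Remove the components marked by ``result`` from ``rec``."""
    if result.mask.size != dec.n_components:
        raise ValueError(
            f"mask length {result.mask.size} != {dec.n_components} components"
        )
    out = remove_components(rec, dec, result.mask, method=result.method)
    out.meta["selection_scores"] = result.scores.tolist()
    out.meta["selection_rule"] = result.threshold_rule
    return out
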