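"""Complex Morlet continuous wavelet transform.

The mother wavelet is a Gaussian-windowed complex exponential

    psi(t) = exp(2*pi*i*fc*t) * exp(-t**2 / (2*sigma_t**2)),

where ``fc`` is the centre frequency at scale 1 and ``sigma_t`` is fixed by
the spectral bandwidth ``bw`` (the Gaussian standard deviation in Hz at scale
1): ``sigma_t = 1 / (2*pi*bw)``.  A row at analysis frequency ``f`` uses the
daughter at scale ``a = fc / f``, i.e. a wavelet of ``fc / bw`` effective
cycles at every frequency.

Row magnitudes are normalized so that a unit-amplitude stationary sinusoid at
the row's frequency yields magnitude 1 (instantaneous-amplitude convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["WaveParams", "cwt_magnitude", "SELECTION_WAVE", "TFC_WAVE"]


def _log_freqs(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class WaveParams:
    """Morlet CWT parameterization: mother wavelet + analysis frequency grid."""

    center_freq: float
    bandwidth: float
    freqs: tuple[float, ...]
    trunc_sigmas: float = 4.0

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be positive")
        if len(self.freqs) == 0 or any(f <= 0 for f in self.freqs):
            raise ValueError("analysis frequencies must be positive")

    @property
    def sigma_t(self) -> float:
        """Time-domain Gaussian std of the mother wavelet, in seconds."""
        return 1.0 / (2.0 * np.pi * self.bandwidth)

    def row_sigma_t(self, f: float) -> float:
        """Time std of the daughter wavelet analysing frequency ``f``."""
        return self.sigma_t * self.center_freq / f

    def freq_array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=np.float64)


#: Wavelet used for component selection: centre 14.591 Hz, bandwidth 5.836 Hz,
#: 20 log-spaced analysis frequencies from 1 to 20 Hz.
SELECTION_WAVE = WaveParams(
    center_freq=14.591,
    bandwidth=5.836,
    freqs=tuple(_log_freqs(1.0, 20.0, 20)),
)

#: Wavelet used for the time-frequency validation maps: the classic Morlet
#: whose centre frequency at scale 1 is 0.8125 Hz (unit time std), on a denser
#: 1-20 Hz grid.
TFC_WAVE = WaveParams(
    center_freq=0.8125,
    bandwidth=1.0 / (2.0 * np.pi),
    freqs=tuple(_log_freqs(1.0, 20.0, 40)),
)


def _kernel(f: float, fs: float, params: WaveParams, max_half: int) -> np.ndarray:
    sig = params.row_sigma_t(f)
    half = int(np.ceil(params.trunc_sigmas * sig * fs))
    half = int(min(max(half, 1), max_half))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2.0 * sig**2))
    kern = env * np.exp(2j * np.pi * f * t)
    # unit-sinusoid gain: |sum(env)| / 2  ->  normalize to instantaneous amp
    return kern * (2.0 / env.sum())


def coi_samples(params: WaveParams, fs: float, n_sigmas: float = 2.0) -> np.ndarray:
    """Per-row cone-of-influence half-width in samples."""
    return np.array(
        [int(np.ceil(n_sigmas * params.row_sigma_t(f) * fs)) for f in params.freqs]
    )


def cwt_magnitude(x: np.ndarray, fs: float, params: WaveParams) -> np.ndarray:
    """|CWT| of a 1-D signal: shape (n_freqs, n_samples).

    Rows are scaled so a unit-amplitude sinusoid at the row frequency maps to
    magnitude 1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("signal too short for CWT")
    out = np.empty((len(params.freqs), x.size))
    max_half = x.size  # kernels longer than the signal bring nothing
    for i, f in enumerate(params.freqs):
        kern = _kernel(float(f), fs, params, max_half)
        out[i] = np.abs(fftconvolve(x, kern, mode="same"))
    return out
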