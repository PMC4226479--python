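"""Extended-infomax ICA: decomposition, back-projection, component removal.

The unmixing matrix can be estimated either on the whole recording
(``interval_mode="whole"``) or on the concatenated cardiac-locked 0-700 ms
epochs (``interval_mode="pa_epochs"``); in both cases source activations are
computed over the full recording so that components can be removed from the
continuous signal.

The optimizer is the natural-gradient infomax rule extended with a per-source
sign switch so both super- and sub-Gaussian sources can be separated: with
whitened data x, activations u = Wx and y = tanh(u),

    dW  ∝  (I - K y uᵀ - u uᵀ) W,      K = diag(±1),

where K is re-estimated from the sign of E[sech²(u)]E[u²] - E[u tanh(u)].
Learning-rate annealing on oscillation of the update direction follows the
standard runica schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EEGRecording, PA_WINDOW, RPeakSeries, extract_epochs

__all__ = [
    "ICADecomposition",
    "ICAConvergenceError",
    "fit_ica",
    "backproject",
    "remove_components",
    "save_decomposition",
    "load_decomposition",
]


class ICAConvergenceError(RuntimeError):
    pass


@dataclass
class ICADecomposition:
    """Result of an ICA fit.

    ``unmixing`` (components x channels) maps channel data to source
    activations; ``mixing`` (channels x components) is its pseudo-inverse.
    ``sources`` are activations over the *full* recording regardless of the
    interval the unmixing was estimated on.  Components are ordered by
    descending back-projected variance, with signs fixed so each component's
    largest-magnitude mixing weight is positive.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    sources: np.ndarray
    interval_mode: str
    rank: int
    seed: int
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def _whiten(x: np.ndarray, rel_eig_tol: float = 1e-10) -> tuple[np.ndarray, int]:
    """PCA whitening matrix for centered data; drops near-null eigenvalues."""
    cov = np.cov(x)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > rel_eig_tol * evals[0]
    evals, evecs = evals[keep], evecs[:, keep]
    sphere = (evecs / np.sqrt(evals)).T  # (rank, channels)
    return sphere, int(evals.size)


def _infomax_extended(
    xw: np.ndarray,
    seed: int,
    max_iter: int,
    tol: float,
    l_rate: float | None,
    block: int | None,
    verbose: bool = False,
) -> np.ndarray:
    """Run extended infomax on whitened data ``xw`` (rank x samples)."""
    rng = np.random.default_rng(seed)
    n_comp, n_samp = xw.shape
    if block is None:
        block = int(min(max(int(np.sqrt(n_samp / 3.0)), 256), n_samp))
    if l_rate is None:
        l_rate = 0.08 / np.log(max(n_comp, 2) ** 2.0)
    anneal = 0.98
    angle_thresh_cos = np.cos(np.deg2rad(60.0))
    blowup_limit = 1e8
    n_sub_probe = min(n_samp, 6000)
    w = np.eye(n_comp)
    signs = np.ones(n_comp)  # +1 super-Gaussian, -1 sub-Gaussian
    old_w = w.copy()
    old_delta = None
    old_wchange = np.inf
    eye_b = None
    for it in range(max_iter):
        perm = rng.permutation(n_samp)
        blowup = False
        for start in range(0, n_samp - block + 1, block):
            xb = xw[:, perm[start : start + block]]
            u = w @ xb
            y = np.tanh(u)
            if eye_b is None or eye_b.shape[0] != n_comp:
                eye_b = np.eye(n_comp)
            grad = block * eye_b - (signs[:, None] * y) @ u.T - u @ u.T
            w = w + (l_rate / block) * (grad @ w)
            if np.max(np.abs(w)) > blowup_limit:
                blowup = True
                break
        if blowup:
            # restart colder
            l_rate *= 0.5
            w = np.eye(n_comp)
            old_w = w.copy()
            old_delta = None
            if l_rate < 1e-10:
                raise ICAConvergenceError(
                    "extended infomax diverged: learning rate annealed below 1e-10"
                )
            continue
        # re-estimate source sign (sub/super-Gaussian) on a fixed-size probe
        probe = rng.choice(n_samp, size=n_sub_probe, replace=False)
        up = w @ xw[:, probe]
        tu = np.tanh(up)
        kurt_sign = np.mean(1.0 - tu**2, axis=1) * np.mean(up**2, axis=1) - np.mean(
            tu * up, axis=1
        )
        signs = np.where(kurt_sign >= 0, 1.0, -1.0)

        delta = w - old_w
        wchange = float(np.sum(delta**2) / np.sum(w**2))
        if old_delta is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(old_delta)
            cos_angle = float(np.sum(delta * old_delta) / denom) if denom > 0 else 1.0
            if cos_angle < angle_thresh_cos:  # oscillating: anneal
                l_rate *= anneal
        if wchange > old_wchange:  # stochastic noise floor reached: anneal
            l_rate *= anneal
        old_wchange = wchange
        old_delta = delta
        old_w = w.copy()
        if verbose and it % 20 == 0:
            print(f"  infomax pass {it}: wchange={wchange:.3e} lrate={l_rate:.3e}")
        if wchange < tol:
            return w
    raise ICAConvergenceError(
        f"extended infomax did not converge within {max_iter} iterations "
        f"at tolerance {tol}"
    )


def fit_ica(
    rec: EEGRecording,
    rpeaks: RPeakSeries | None = None,
    interval_mode: str = "whole",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    l_rate: float | None = None,
    block: int | None = None,
    max_fit_samples: int | None = None,
    allow_raw: bool = False,
    rel_eig_tol: float = 1e-10,
    verbose: bool = False,
) -> ICADecomposition:
    """Fit extended-infomax ICA on a recording.

    Parameters
    ----------
    interval_mode : {"whole", "pa_epochs"}
        Estimate the unmixing on the full recording or on concatenated
        0-700 ms cardiac-locked epochs.  Sources are always computed over the
        full recording.
    max_fit_samples : int, optional
        Cap on the number of time points used for estimating the unmixing
        (deterministic subsampling).  Sources are unaffected.
    allow_raw : bool
        Fitting is normally restricted to OBS-corrected input; set True to
        override the stage check.

    Raises
    ------
    ICAConvergenceError
        If the optimizer does not reach ``tol`` within ``max_iter`` passes.
    """
    if rec.stage != "post_obs" and not allow_raw:
        raise ValueError(
            f"ICA expects an OBS-corrected recording (stage 'post_obs', got "
            f"'{rec.stage}'); pass allow_raw=True to override"
        )
    if interval_mode not in ("whole", "pa_epochs"):
        raise ValueError("interval_mode must be 'whole' or 'pa_epochs'")
    if interval_mode == "pa_epochs":
        if rpeaks is None:
            raise ValueError("interval_mode='pa_epochs' requires R peaks")
        eps = extract_epochs(rec, rpeaks, PA_WINDOW)
        fit_data = eps.epochs.transpose(1, 0, 2).reshape(rec.n_channels, -1)
    else:
        fit_data = rec.data
    if fit_data.shape[1] < 20 * rec.n_channels:
        raise ValueError(
            f"too few samples to fit ICA: {fit_data.shape[1]} < 20 x "
            f"{rec.n_channels} channels"
        )
    if max_fit_samples is not None and fit_data.shape[1] > max_fit_samples:
        step = fit_data.shape[1] / max_fit_samples
        idx = (np.arange(max_fit_samples) * step).astype(np.int64)
        fit_data = fit_data[:, idx]

    centered = fit_data - fit_data.mean(axis=1, keepdims=True)
    sphere, rank = _whiten(centered, rel_eig_tol=rel_eig_tol)
    xw = sphere @ centered
    w = _infomax_extended(
        xw, seed=seed, max_iter=max_iter, tol=tol, l_rate=l_rate, block=block,
        verbose=verbose,
    )
    unmixing = w @ sphere  # (rank, channels)
    mixing = np.linalg.pinv(unmixing)  # (channels, rank)
    sources = unmixing @ rec.data

    # Order by descending back-projected variance, fix signs.
    bp_var = np.einsum("ck->k", mixing**2) * sources.var(axis=1)
    order = np.argsort(bp_var)[::-1]
    unmixing, mixing, sources = unmixing[order], mixing[:, order], sources[order]
    flip = np.where(
        mixing[np.argmax(np.abs(mixing), axis=0), np.arange(rank)] < 0, -1.0, 1.0
    )
    unmixing *= flip[:, None]
    mixing *= flip[None, :]
    sources *= flip[:, None]

    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        sources=sources,
        interval_mode=interval_mode,
        rank=rank,
        seed=seed,
        fs=rec.fs,
        labels=list(rec.labels),
        meta={"max_iter": max_iter, "tol": tol},
    )


def save_decomposition(dec: ICADecomposition, directory) -> None:
    """Serialize a decomposition: ``ica.npz`` matrices + ``ica.json`` sidecar."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "ica.npz",
        unmixing=dec.unmixing,
        mixing=dec.mixing,
        sources=dec.sources,
    )
    sidecar = {
        "interval_mode": dec.interval_mode,
        "rank": dec.rank,
        "seed": dec.seed,
        "fs": dec.fs,
        "labels": dec.labels,
        "shapes": {
            "unmixing": list(dec.unmixing.shape),
            "mixing": list(dec.mixing.shape),
            "sources": list(dec.sources.shape),
        },
    }
    (directory / "ica.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_decomposition(directory) -> ICADecomposition:
    """Load a decomposition written by :func:`save_decomposition`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    sidecar = json.loads((directory / "ica.json").read_text())
    with np.load(directory / "ica.npz") as npz:
        return ICADecomposition(
            unmixing=npz["unmixing"],
            mixing=npz["mixing"],
            sources=npz["sources"],
            interval_mode=sidecar["interval_mode"],
            rank=int(sidecar["rank"]),
            seed=int(sidecar["seed"]),
            fs=float(sidecar["fs"]),
            labels=list(sidecar["labels"]),
        )


def _check_mask(dec: ICADecomposition, mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.size != dec.n_components:
            raise ValueError(
                f"boolean mask length {mask.size} != {dec.n_components} components"
            )
        idx = np.nonzero(mask)[0]
    else:
        idx = mask.astype(np.int64).ravel()
        if idx.size and (idx.min() < 0 or idx.max() >= dec.n_components):
            raise ValueError("component index out of range")
    return idx


def backproject(dec: ICADecomposition, mask) -> np.ndarray:
    """Channel-space signal carried by the components in ``mask``.

    An empty mask yields an all-zero signal.
    """
    idx = _check_mask(dec, mask)
    if idx.size == 0:
        return np.zeros((dec.mixing.shape[0], dec.sources.shape[1]))
    return dec.mixing[:, idx] @ dec.sources[idx]


def remove_components(
    rec: EEGRecording, dec: ICADecomposition, mask, method: str | None = None
) -> EEGRecording:
    """Subtract the back-projection of the masked components from ``rec``."""
    idx = _check_mask(dec, mask)
    out = rec.copy(data=rec.data - backproject(dec, idx), stage="post_ica")
    out.meta["ica_removed"] = idx.tolist()
    if method is not None:
        out.meta["selection_method"] = method
    return out
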