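"""Optimal basis set (OBS) correction of the pulse artifact.

For each channel, the artifact template over the cardiac-locked window is
modelled as the epoch mean plus the first ``n_pc`` principal components of the
mean-removed epoch stack.  The least-squares fit of that basis to each observed
epoch is subtracted in place; samples outside every window are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EEGRecording, EpochSet, EpochWindow, RPeakSeries, extract_epochs

__all__ = ["OBSModel", "fit_obs", "apply_obs", "correct_obs"]

DEFAULT_N_PC = 3


class InsufficientEpochsError(ValueError):
    """Fewer epochs than needed to estimate the requested basis."""


@dataclass
class OBSModel:
    """Per-channel artifact basis over the cardiac-locked window.

    ``mean`` has shape (n_channels, n_samples); ``basis`` has shape
    (n_channels, n_pc, n_samples) with orthonormal rows per channel, ordered by
    explained variance.
    """

    mean: np.ndarray
    basis: np.ndarray
    window: EpochWindow
    fs: float
    labels: list[str]
    explained_variance: np.ndarray  # (n_channels, n_pc)

    @property
    def n_pc(self) -> int:
        return self.basis.shape[1]


def _stack_pca(stack: np.ndarray, n_pc: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-``n_pc`` principal components of an (observations x samples) stack."""
    n_obs, n_s = stack.shape
    basis = np.zeros((n_pc, n_s))
    expvar = np.zeros(n_pc)
    _, s, vt = np.linalg.svd(stack, full_matrices=False)
    k = min(n_pc, s.size)
    basis[:k] = vt[:k]
    expvar[:k] = s[:k] ** 2 / max(n_obs - 1, 1)
    return basis, expvar


def fit_obs(
    epochs: EpochSet, n_pc: int = DEFAULT_N_PC, block_size: int | None = None
) -> OBSModel:
    """Estimate the per-channel mean + principal-component artifact basis.

    With ``block_size`` set, the PCA runs on block-averaged epochs
    (consecutive groups of ``block_size`` epochs averaged before
    decomposition): cardiac-locked variability survives the averaging while
    non-locked background is suppressed by sqrt(block_size), biasing the basis
    toward genuine artifact modes.  Default is the plain mean-removed epoch
    stack.

    Raises
    ------
    InsufficientEpochsError
        If fewer than ``n_pc + 1`` epochs (or 2 blocks) are available.
    """
    if n_pc < 0:
        raise ValueError("n_pc must be >= 0")
    if epochs.n_epochs < n_pc + 1:
        raise InsufficientEpochsError(
            f"insufficient epochs for basis: {epochs.n_epochs} < {n_pc + 1}"
        )
    n_ch, n_s = epochs.n_channels, epochs.n_samples
    mean = epochs.epochs.mean(axis=0)  # (ch, s)
    basis = np.zeros((n_ch, n_pc, n_s))
    expvar = np.zeros((n_ch, n_pc))
    if n_pc > 0:
        if block_size is not None and block_size > 1:
            nb = epochs.n_epochs // block_size
            if nb < max(2, n_pc + 1):
                raise InsufficientEpochsError(
                    f"insufficient epochs for {n_pc}-PC basis from blocks of "
                    f"{block_size}: {epochs.n_epochs} epochs give {nb} blocks"
                )
            stack = epochs.epochs[: nb * block_size].reshape(
                nb, block_size, n_ch, n_s
            ).mean(axis=1)
        else:
            stack = epochs.epochs
        centered = stack - mean[None, :, :]
        for c in range(n_ch):
            basis[c], expvar[c] = _stack_pca(centered[:, c, :], n_pc)
    return OBSModel(
        mean=mean,
        basis=basis,
        window=epochs.window,
        fs=epochs.fs,
        labels=list(epochs.labels),
        explained_variance=expvar,
    )


def apply_obs(rec: EEGRecording, model: OBSModel, rpeaks: RPeakSeries) -> EEGRecording:
    """Subtract the fitted OBS template inside every cardiac-locked window.

    Each in-bounds epoch is projected onto ``[mean, pc_1..pc_n]`` by ordinary
    least squares and the fit subtracted.  When consecutive windows overlap
    (short R-R intervals) the later epoch's fit is applied only to the samples
    not already corrected, so no stretch of signal is corrected twice.
    """
    if abs(model.fs - rec.fs) > 1e-9:
        raise ValueError("model/recording mismatch: sampling rates differ")
    if model.mean.shape[0] != rec.n_channels:
        raise ValueError("model/recording mismatch: channel counts differ")
    epochs = extract_epochs(rec, rpeaks, model.window)
    n_s = epochs.n_samples
    out = rec.data.copy()
    n_pc = model.n_pc
    # The design matrix [mean, pc_1..pc_n] is fixed per channel, so the
    # least-squares fit of every epoch is a single projection: precompute
    # P_c = D_c (D_c^+) once per channel.
    proj = np.zeros((rec.n_channels, n_s, n_s))
    for c in range(rec.n_channels):
        design = np.empty((n_s, 1 + n_pc))
        design[:, 0] = model.mean[c]
        if n_pc:
            design[:, 1:] = model.basis[c].T
        proj[c] = design @ np.linalg.pinv(design, rcond=1e-12)
    last_end = -1
    for start in epochs.starts():
        start = int(start)
        seg = rec.data[:, start : start + n_s]  # fit on the uncorrected signal
        fit = np.einsum("cst,ct->cs", proj, seg)
        lo = max(start, last_end)  # skip samples already corrected
        out[:, lo : start + n_s] -= fit[:, lo - start :]
        last_end = start + n_s
    res = rec.copy(data=out, stage="post_obs")
    res.meta["obs_n_pc"] = n_pc
    return res


def guard_obs_model(
    model: OBSModel,
    rec: EEGRecording,
    rpeaks: RPeakSeries,
    gate_factor: float = 2.0,
    block_size: int | None = None,
) -> OBSModel:
    """Suppress template parts that are not genuinely cardiac-locked.

    The template is re-estimated on a *null* epoch grid (every window shifted
    by half the mean R-R interval, which destroys cardiac locking but keeps
    the background statistics).  Per channel:

    * the mean template is zeroed unless its energy exceeds ``gate_factor``
      times the null mean's energy (no detectable locked artifact -> the
      channel is left untouched);
    * each principal component is zeroed unless its explained variance
      exceeds ``gate_factor`` times the *largest* null eigenvalue.

    Without this guard, channels dominated by rhythmic background (e.g. a
    continuous alpha rhythm) hand the basis their own top variance directions
    and the subtraction strips genuine signal.
    """
    shift = int(round(rpeaks.mean_rr * rec.fs / 2.0))
    null_idx = rpeaks.indices + shift
    null_idx = null_idx[null_idx + model.window.n_samples(rec.fs) <= rec.n_samples]
    if null_idx.size < 2:
        return model  # cannot form a null grid; leave the model as is
    null_rpeaks = RPeakSeries(indices=null_idx, fs=rec.fs)
    null_eps = extract_epochs(rec, null_rpeaks, model.window)
    bs = block_size
    while bs is not None and bs > 1 and null_eps.n_epochs // bs < max(2, model.n_pc + 1):
        bs //= 2
    null_model = fit_obs(null_eps, n_pc=model.n_pc, block_size=bs if bs and bs > 1 else None)

    mean = model.mean.copy()
    basis = model.basis.copy()
    gates_mean = np.zeros(mean.shape[0], dtype=bool)
    gates_pc = np.zeros(basis.shape[:2], dtype=bool)
    for c in range(mean.shape[0]):
        e_true = float(np.sum(model.mean[c] ** 2))
        e_null = float(np.sum(null_model.mean[c] ** 2))
        gates_mean[c] = e_true > gate_factor * e_null
        if not gates_mean[c]:
            mean[c] = 0.0
        null_top = null_model.explained_variance[c].max() if model.n_pc else 0.0
        for k in range(model.n_pc):
            gates_pc[c, k] = model.explained_variance[c, k] > gate_factor * null_top
            if not gates_pc[c, k]:
                basis[c, k] = 0.0
    return OBSModel(
        mean=mean,
        basis=basis,
        window=model.window,
        fs=model.fs,
        labels=list(model.labels),
        explained_variance=model.explained_variance.copy(),
    )


def correct_obs(
    rec: EEGRecording,
    rpeaks: RPeakSeries,
    window: EpochWindow | None = None,
    n_pc: int = DEFAULT_N_PC,
    guard: bool = True,
    guard_block_size: int = 20,
    gate_factor: float = 2.0,
) -> tuple[EEGRecording, OBSModel]:
    """Fit and apply OBS in one step over the pulse-artifact window.

    By default the template is estimated on block-averaged epochs and gated
    against a non-cardiac-locked null grid (see :func:`guard_obs_model`), so
    that channels and components without real locked artifact content are not
    touched.  Set ``guard=False`` for the plain unguarded fit.
    """
    from .events import PA_WINDOW

    window = window or PA_WINDOW
    epochs = extract_epochs(rec, rpeaks, window)
    if guard:
        bs = guard_block_size
        while bs > 1 and epochs.n_epochs // bs < max(2, n_pc + 1):
            bs //= 2
        block_size = bs if bs > 1 else None
        model = fit_obs(epochs, n_pc=n_pc, block_size=block_size)
        model = guard_obs_model(
            model, rec, rpeaks, gate_factor=gate_factor, block_size=block_size
        )
    else:
        model = fit_obs(epochs, n_pc=n_pc)
    return apply_obs(rec, model, rpeaks), model
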