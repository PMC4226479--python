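import numpy as np
import pytest

from pacorrect.events import (
    EEGRecording,
    PA_WINDOW,
    RPeakSeries,
    extract_epochs,
    partition_channels,
)
from pacorrect.ica import ICADecomposition
from pacorrect.selection import (
    SelectionResult,
    apply_selection,
    build_pa_templates,
    score_corr,
    score_pacf,
    score_pvaf,
    score_wave,
)

from conftest import make_recording, periodic_rpeaks


def make_decomposition(sources, mixing=None, fs=250.0, seed=0):
    sources = np.asarray(sources, dtype=float)
    k = sources.shape[0]
    if mixing is None:
        mixing = np.eye(k)
    mixing = np.asarray(mixing, dtype=float)
    return ICADecomposition(
        unmixing=np.linalg.pinv(mixing),
        mixing=mixing,
        sources=sources,
        interval_mode="whole",
        rank=k,
        seed=seed,
        fs=fs,
        labels=[f"C{2 * i + 1}" for i in range(mixing.shape[0])],
    )


def brute_force_pvaf(dec, reference, rpeaks, window=PA_WINDOW):
    """Oracle: explicit back-projection, variance over concatenated epochs."""
    eps_ref = extract_epochs(reference, rpeaks, window)
    ref = eps_ref.epochs.transpose(1, 0, 2).reshape(reference.n_channels, -1)
    out = []
    for k in range(dec.n_components):
        bp = np.outer(dec.mixing[:, k], dec.sources[k])
        rec_bp = EEGRecording(bp, reference.fs, reference.labels, "post_obs")
        eps_bp = extract_epochs(rec_bp, rpeaks, window)
        flat = eps_bp.epochs.transpose(1, 0, 2).reshape(reference.n_channels, -1)
        out.append(100.0 * np.var(flat) / np.var(ref))
    return np.asarray(out)


class TestPvaf:
    def test_threshold_rule(self, rng):
        # engineered scores around the 2.5% threshold
        n = 20000
        rp = periodic_rpeaks(n)
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        sources = np.vstack([s1 * np.sqrt(3.0), s2 * np.sqrt(2.4),
                             rng.standard_normal((2, n)) * np.sqrt(47.3)])
        dec = make_decomposition(sources, np.eye(4))
        ref = EEGRecording(sources.sum(axis=0, keepdims=True) * 0 + sources,
                          250.0, dec.labels, "post_obs")
        res = score_pvaf(dec, ref, rp)
        order = np.argsort(res.scores)[::-1]
        assert res.mask[order[0]] and res.mask[order[1]]  # the two big ones
        # approximate percent levels
        assert res.scores[0] == pytest.approx(3.0, rel=0.2)
        assert res.scores[1] == pytest.approx(2.4, rel=0.2)

    def test_zero_component_not_selected(self, rng):
        n = 20000
        rp = periodic_rpeaks(n)
        sources = np.vstack([rng.standard_normal(n), np.zeros(n)])
        dec = make_decomposition(sources)
        ref = EEGRecording(sources.copy(), 250.0, dec.labels, "post_obs")
        res = score_pvaf(dec, ref, rp)
        assert res.scores[1] == 0.0
        assert not res.mask[1]

    def test_matches_brute_force_oracle(self, rng):
        n = 30000
        rp = periodic_rpeaks(n)
        sources = rng.standard_normal((3, n)) * np.array([[3.0], [1.0], [0.3]])
        mixing = rng.standard_normal((3, 3))
        dec = make_decomposition(sources, mixing)
        ref = EEGRecording(mixing @ sources, 250.0, dec.labels, "post_obs")
        res = score_pvaf(dec, ref, rp)
        oracle = brute_force_pvaf(dec, ref, rp)
        np.testing.assert_allclose(res.scores, oracle, rtol=0, atol=1e-10)

    def test_degenerate_reference(self, rng):
        n = 20000
        rp = periodic_rpeaks(n)
        dec = make_decomposition(rng.standard_normal((2, n)))
        ref = EEGRecording(np.zeros((2, n)), 250.0, dec.labels, "post_obs")
        with pytest.raises(ValueError, match="degenerate reference"):
            score_pvaf(dec, ref, rp)


class TestTemplates:
    def test_constant_case(self):
        fs, n = 250.0, 20000
        rp = periodic_rpeaks(n, fs=fs)
        w = np.sin(np.linspace(0, 6 * np.pi, 175))
        data = np.zeros((3, n))
        for i in rp.indices:
            if i + 175 <= n:
                data[:, i : i + 175] = w
        rec = EEGRecording(data, fs, ["C3", "C4", "Cz"], "raw")
        part = partition_channels(rec.labels)
        tpl = build_pa_templates(rec, rp, part)
        np.testing.assert_allclose(tpl.left, w, atol=1e-12)
        np.testing.assert_allclose(tpl.right, w, atol=1e-12)

    def test_weighted_hemisphere_means(self):
        # left carries +w, right -w, mesial 0
        fs, n = 250.0, 20000
        rp = periodic_rpeaks(n, fs=fs)
        w = np.cos(np.linspace(0, 4 * np.pi, 175))
        labels = ["C3", "P3", "C4", "Cz"]  # nL=2, nR=1, nM=1
        signs = {"C3": 1.0, "P3": 1.0, "C4": -1.0, "Cz": 0.0}
        data = np.zeros((4, n))
        for c, lab in enumerate(labels):
            for i in rp.indices:
                if i + 175 <= n:
                    data[c, i : i + 175] = signs[lab] * w
        rec = EEGRecording(data, fs, labels, "raw")
        tpl = build_pa_templates(rec, rp, partition_channels(labels))
        np.testing.assert_allclose(tpl.left, w * 2.0 / 3.0, atol=1e-12)
        np.testing.assert_allclose(tpl.right, -w * 1.0 / 2.0, atol=1e-12)

    def test_post_obs_input_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 8000)), stage="post_obs")
        rp = periodic_rpeaks(8000)
        with pytest.raises(ValueError, match="uncorrected"):
            build_pa_templates(rec, rp, partition_channels(rec.labels))


class TestCorr:
    def _setup(self, rng, n=40000):
        fs = 250.0
        rp = periodic_rpeaks(n, fs=fs)
        w = np.sin(np.linspace(0, 8 * np.pi, 175)) * np.hanning(175)
        data = np.zeros((2, n))
        for i in rp.indices:
            if i + 175 <= n:
                data[0, i : i + 175] = w
                data[1, i : i + 175] = -w
        rec = EEGRecording(data + rng.standard_normal((2, n)) * 0.01,
                          fs, ["C3", "C4"], "raw")
        tpl = build_pa_templates(rec, rp, partition_channels(rec.labels))
        return fs, rp, w, tpl

    def test_identity_component_scores_max(self, rng):
        fs, rp, w, tpl = self._setup(rng)
        n = 40000
        locked = np.zeros(n)
        for i in rp.indices:
            if i + 175 <= n:
                locked[i : i + 175] = w
        sources = np.vstack([locked, rng.standard_normal(n)])
        dec = make_decomposition(sources, fs=fs)
        res = score_corr(dec, tpl, rp)
        assert res.scores[0] > 0.99
        assert res.mask[0]

    def test_relative_threshold(self):
        # scores {0.80, 0.33, 0.31}: threshold 0.32 -> {True, True, False}
        scores = np.array([0.80, 0.33, 0.31])
        mask = scores >= 0.40 * scores.max()
        assert list(mask) == [True, True, False]

    def test_orthogonal_component_scores_low(self, rng):
        fs, rp, w, tpl = self._setup(rng)
        n = 40000
        # build an epoch-locked source whose epoch average is orthogonal to
        # both templates by Gram-Schmidt
        g = rng.standard_normal(175)
        for t in (tpl.left, tpl.right):
            tt = t - t.mean()
            gg = g - g.mean()
            g = gg - (gg @ tt) / (tt @ tt) * tt
        locked = np.zeros(n)
        for i in rp.indices:
            if i + 175 <= n:
                locked[i : i + 175] = g
        dec = make_decomposition(locked[None, :], fs=fs)
        res = score_corr(dec, tpl, rp)
        assert res.scores[0] < 0.05


class TestPacf:
    def test_periodic_source_flagged_noise_not(self, rng):
        fs, n = 250.0, int(250 * 120)
        rp = periodic_rpeaks(n, fs=fs)
        wf = rng.standard_normal(250)  # broadband waveform, period = R-R
        periodic = np.tile(wf, n // 250 + 1)[:n]
        periodic = periodic / periodic.std() + rng.standard_normal(n) * np.sqrt(0.1)
        noise = rng.standard_normal(n)
        dec = make_decomposition(np.vstack([periodic, noise]), fs=fs)
        res = score_pacf(dec, rp)
        assert res.mask[0]
        assert not res.mask[1]
        assert res.scores[1] < res.scores[0] / 3

    def test_oracle_yule_walker_peak_location(self, rng):
        # brute-force PACF via Yule-Walker on the same averaged block
        from scipy.linalg import solve_toeplitz

        fs, n = 250.0, int(250 * 120)
        rp = periodic_rpeaks(n, fs=fs)
        wf = rng.standard_normal(250)
        x = np.tile(wf, n // 250 + 1)[:n]
        x = x / x.std() + rng.standard_normal(n) * np.sqrt(0.1)
        rr_lag = int(round(rp.mean_rr * fs))
        block_len = 4 * rr_lag
        starts = rp.indices[::4]
        starts = starts[starts + block_len <= n]
        avg = np.mean([x[s : s + block_len] for s in starts], axis=0)
        avg = avg - avg.mean()
        acov = np.correlate(avg, avg, "full")[len(avg) - 1 :] / len(avg)
        pacf_or = []
        for m in range(rr_lag - 5, rr_lag + 6):
            phi = solve_toeplitz(acov[:m], acov[1 : m + 1])
            pacf_or.append(phi[-1])
        peak_lag = int(np.argmax(pacf_or)) + rr_lag - 5
        assert abs(peak_lag - rr_lag) <= 2
        assert max(pacf_or) > 0.3

    def test_relative_threshold_rule(self):
        scores = np.array([0.9, 0.31, 0.29])
        mask = (scores > 0) & (scores > scores.max() / 3.0)
        assert list(mask) == [True, True, False]

    def test_too_few_blocks(self, rng):
        fs = 250.0
        rp = RPeakSeries(indices=[100, 350, 600], fs=fs)
        dec = make_decomposition(rng.standard_normal((1, 1500)), fs=fs)
        with pytest.raises(ValueError, match="blocks"):
            score_pacf(dec, rp)


class TestWave:
    def test_r_locked_burst_selected(self, rng):
        fs, n = 250.0, int(250 * 90)
        rp = periodic_rpeaks(n, fs=fs)
        # pink background
        fr = np.fft.rfftfreq(n, 1 / fs)
        sh = np.zeros_like(fr)
        sh[1:] = fr[1:] ** -0.5
        bg = np.fft.irfft(np.fft.rfft(rng.standard_normal(n)) * sh, n=n)
        bg /= bg.std()
        t = np.arange(int(0.15 * fs)) / fs
        burst = np.sin(2 * np.pi * 6 * t) * np.hanning(t.size)
        src = bg.copy()
        for i in rp.indices:
            s = i + int(0.25 * fs)
            if s + burst.size <= n:
                src[s : s + burst.size] += 5.0 * burst / burst.std()
        dec = make_decomposition(src[None, :], fs=fs)
        res = score_wave(dec, rp)
        assert res.scores[0] > 3.0
        assert res.mask[0]

    def test_random_phase_sinusoid_not_selected(self, rng):
        fs, n = 250.0, int(250 * 90)
        rp = periodic_rpeaks(n, fs=fs, rr_s=1.013)  # incommensurate with 10 Hz
        t = np.arange(n) / fs
        src = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        dec = make_decomposition(src[None, :], fs=fs)
        res = score_wave(dec, rp)
        assert res.scores[0] < 1.5
        assert not res.mask[0]

    def test_zero_source_scores_zero(self):
        n = int(250 * 30)
        rp = periodic_rpeaks(n)
        dec = make_decomposition(np.zeros((1, n)))
        res = score_wave(dec, rp)
        assert res.scores[0] == 0.0

    def test_direct_convolution_oracle(self, rng):
        # fft-based CWT equals a plain time-domain convolution
        from pacorrect.wavelets import SELECTION_WAVE, _kernel, cwt_magnitude

        fs = 250.0
        x = rng.standard_normal(2000)
        mag = cwt_magnitude(x, fs, SELECTION_WAVE)
        f = SELECTION_WAVE.freqs[10]
        kern = _kernel(float(f), fs, SELECTION_WAVE, x.size)
        direct = np.abs(np.convolve(x, kern, mode="same"))
        np.testing.assert_allclose(mag[10], direct, atol=1e-8)


class TestInvariances:
    def _dataset(self, rng):
        fs, n = 250.0, int(250 * 60)
        rp = periodic_rpeaks(n, fs=fs)
        t = np.arange(int(0.2 * fs)) / fs
        kern = np.sin(2 * np.pi * 5 * t) * np.exp(-t / 0.06)
        art = np.zeros(n)
        for i in rp.indices:
            if i + kern.size <= n:
                art[i : i + kern.size] += kern
        sources = np.vstack([art / art.std(), rng.standard_normal(n)])
        mixing = rng.standard_normal((3, 2))
        return rp, sources, mixing

    def test_sign_and_permutation_invariance(self, rng):
        rp, sources, mixing = self._dataset(rng)
        ref = EEGRecording(mixing @ sources, 250.0,
                          ["C3", "C4", "Cz"], "post_obs")
        dec = make_decomposition(sources, mixing)
        flipped = make_decomposition(
            sources[::-1] * np.array([[-1.0], [1.0]]),
            mixing[:, ::-1] * np.array([-1.0, 1.0]),
        )
        r1 = score_pvaf(dec, ref, rp)
        r2 = score_pvaf(flipped, ref, rp)
        np.testing.assert_allclose(r1.scores, r2.scores[::-1], atol=1e-10)
        assert list(r1.mask) == list(r2.mask[::-1])
        w1 = score_wave(dec, rp)
        w2 = score_wave(flipped, rp)
        np.testing.assert_allclose(w1.scores, w2.scores[::-1], atol=1e-8)


class TestApplySelection:
    def test_empty_mask_identity(self, rng):
        n = 20000
        rp = periodic_rpeaks(n)
        sources = rng.standard_normal((2, n))
        dec = make_decomposition(sources)
        rec = EEGRecording(sources.copy(), 250.0, dec.labels, "post_obs")
        res = SelectionResult("pvaf", np.zeros(2), "none", np.zeros(2, bool))
        out = apply_selection(rec, dec, res)
        np.testing.assert_array_equal(out.data, rec.data)
        assert out.meta["selection_method"] == "pvaf"

    def test_mask_length_mismatch(self, rng):
        n = 20000
        dec = make_decomposition(rng.standard_normal((2, n)))
        rec = EEGRecording(rng.standard_normal((2, n)), 250.0, dec.labels,
                          "post_obs")
        res = SelectionResult("pvaf", np.zeros(3), "none", np.zeros(3, bool))
        with pytest.raises(ValueError, match="mask length"):
            apply_selection(rec, dec, res)
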