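import numpy as np
import pytest

from pacorrect.events import EEGRecording, VALIDATION_WINDOW, extract_epochs
from pacorrect.metrics import (
    BandDefinition,
    ar_psd,
    band_power,
    band_ratios,
    compare_methods,
    cwt_epoch_mean,
    cwt_off,
    mean_time_derivative,
    ptp_ratio,
    quality_coefficient,
)
from pacorrect.wavelets import TFC_WAVE

from conftest import make_recording, periodic_rpeaks


def _epoch_sets(rng, scale_post=1.0, n=40000):
    rec = make_recording(rng.standard_normal((3, n)))
    rp = periodic_rpeaks(n)
    pre = extract_epochs(rec, rp, VALIDATION_WINDOW)
    post_rec = rec.copy(data=rec.data * scale_post)
    post = extract_epochs(post_rec, rp, VALIDATION_WINDOW)
    return pre, post


class TestPtp:
    def test_identity(self, rng):
        pre, post = _epoch_sets(rng, 1.0)
        ratios, mean = ptp_ratio(pre, post)
        assert mean == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in ratios.values())

    def test_half_scaling(self, rng):
        pre, post = _epoch_sets(rng, 0.5)
        _, mean = ptp_ratio(pre, post)
        assert mean == pytest.approx(0.5)

    def test_known_artifact_ratio(self, small_dataset):
        ds = small_dataset
        pre = extract_epochs(ds.mixed, ds.rpeaks, VALIDATION_WINDOW)
        post = extract_epochs(ds.clean, ds.rpeaks, VALIDATION_WINDOW)
        _, mean = ptp_ratio(pre, post)
        # oracle from the generator's own components
        ptp_pre = np.ptp(pre.epochs, axis=2).mean(axis=0)
        ptp_post = np.ptp(post.epochs, axis=2).mean(axis=0)
        oracle = float(np.mean(ptp_post / ptp_pre))
        assert mean == pytest.approx(oracle, rel=1e-12)
        assert mean < 1.0  # removing the artifact shrinks the peak-to-peak

    def test_zero_pre_channel_excluded(self, rng):
        pre, post = _epoch_sets(rng, 1.0)
        pre.epochs[:, 1, :] = 0.0
        with pytest.warns(UserWarning, match="excluded"):
            ratios, _ = ptp_ratio(pre, post)
        assert len(ratios) == 2


class TestArPsd:
    def test_sinusoid_peak_location(self, rng):
        fs = 250.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t) + 0.05 * rng.standard_normal(t.size)
        freqs = np.linspace(1.0, 30.0, 291)
        psd = ar_psd(x, fs, freqs, order=16)
        assert abs(freqs[np.argmax(psd)] - 10.0) <= 0.5
        assert np.all(psd >= 0)

    def test_white_noise_flatter_than_sinusoid(self, rng):
        fs = 250.0
        freqs = np.linspace(1.0, 20.0, 191)
        t = np.arange(int(4 * fs)) / fs
        x_sin = np.sin(2 * np.pi * 10.0 * t) + 0.05 * rng.standard_normal(t.size)
        x_wn = rng.standard_normal(t.size)
        dyn_sin = np.ptp(np.log(ar_psd(x_sin, fs, freqs, order=16)))
        dyn_wn = np.ptp(np.log(ar_psd(x_wn, fs, freqs, order=16)))
        assert np.exp(dyn_sin) / np.exp(dyn_wn) >= 10.0

    def test_zero_signal_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            ar_psd(np.zeros(500), 250.0, np.linspace(1, 20, 20))

    def test_order_too_large(self, rng):
        with pytest.raises(ValueError, match="order"):
            ar_psd(rng.standard_normal(10), 250.0, np.linspace(1, 20, 20), order=16)


class TestBandRatios:
    bands = BandDefinition()

    def test_identity(self, rng):
        freqs = np.linspace(0.5, 30.0, 241)
        psd = np.abs(rng.standard_normal(freqs.size)) + 0.1
        out = band_ratios(psd, psd, freqs, self.bands)
        for v in out.values():
            assert v == pytest.approx(1.0)

    def test_alpha_zeroed(self, rng):
        freqs = np.linspace(0.5, 30.0, 2401)
        psd = np.ones(freqs.size)
        post = psd.copy()
        post[(freqs >= 8.0) & (freqs <= 13.0)] = 0.0
        out = band_ratios(psd, post, freqs, self.bands)
        assert out["alpha_ratio"] == pytest.approx(0.0, abs=1e-3)
        assert out["delta_ratio"] == pytest.approx(1.0)
        assert out["theta_ratio"] == pytest.approx(1.0)

    def test_boxcar_closed_form(self):
        # trapezoidal integration of a boxcar equals its analytic area when
        # the boxcar edges sit on grid points
        freqs = np.linspace(0.0, 20.0, 201)  # step 0.1
        psd = np.where((freqs >= 4.0) & (freqs <= 8.0), 2.0, 0.0)
        assert band_power(psd, freqs, (4.0, 8.0)) == pytest.approx(8.0)

    def test_scale_equivariance(self, rng):
        freqs = np.linspace(0.5, 30.0, 241)
        psd = np.abs(rng.standard_normal(freqs.size)) + 0.1
        out = band_ratios(psd, 4.0 * psd, freqs, self.bands)  # c^2 with c=2
        for v in out.values():
            assert v == pytest.approx(4.0)

    def test_band_validation(self):
        with pytest.raises(ValueError):
            BandDefinition(delta=(4.0, 1.0))
        with pytest.raises(ValueError):
            BandDefinition(delta=(1.0, 5.0), theta=(4.0, 8.0))


class TestQC:
    def test_definition_arithmetic(self):
        qc = quality_coefficient(
            {"alpha_ratio": 0.6, "delta_ratio": 0.5, "theta_ratio": 0.4}
        )
        assert qc == pytest.approx(1.3333, abs=1e-4)

    def test_equal_ratios_give_one(self):
        qc = quality_coefficient(
            {"alpha_ratio": 0.7, "delta_ratio": 0.7, "theta_ratio": 0.7}
        )
        assert qc == pytest.approx(1.0)

    def test_preserved_alpha_half_low_freq(self):
        qc = quality_coefficient(
            {"alpha_ratio": 1.0, "delta_ratio": 0.5, "theta_ratio": 0.5}
        )
        assert qc == pytest.approx(2.0)

    def test_missing_ratio(self):
        with pytest.raises(ValueError, match="missing"):
            quality_coefficient({"alpha_ratio": 1.0, "delta_ratio": 0.5,
                                 "theta_ratio": None})


class TestCwtMaps:
    def test_sinusoid_row_time_constant(self):
        fs, n = 250.0, int(250 * 60)
        t = np.arange(n) / fs
        rec = make_recording(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=fs)
        rp = periodic_rpeaks(n, fs=fs, rr_s=1.013)
        m = cwt_epoch_mean(rec, rp)
        freqs = TFC_WAVE.freq_array()
        row = m[int(np.argmin(np.abs(freqs - 10.0)))]
        interior = row[30:-30]
        assert np.ptp(interior) / np.mean(interior) < 0.05

    def test_r_locked_burst_peaks_at_latency(self, rng):
        fs, n = 250.0, int(250 * 60)
        rp = periodic_rpeaks(n, fs=fs)
        t = np.arange(int(0.15 * fs)) / fs
        burst = np.sin(2 * np.pi * 6.0 * t) * np.hanning(t.size)
        x = rng.standard_normal(n) * 0.1
        for i in rp.indices:
            s = i + int(0.3 * fs)
            if s + burst.size <= n:
                x[s : s + burst.size] += burst
        rec = make_recording(x[None, :], fs=fs)
        m = cwt_epoch_mean(rec, rp)
        freqs = TFC_WAVE.freq_array()
        row = m[int(np.argmin(np.abs(freqs - 6.0)))]
        # window starts at -200 ms; burst center at +375 ms
        peak_idx = int(np.argmax(row))
        expected = int((0.2 + 0.3 + 0.075) * fs)
        assert abs(peak_idx - expected) < int(0.08 * fs)
        assert row.max() > 2.0 * np.median(row)

    def test_zero_signal_zero_map(self):
        n = int(250 * 30)
        rec = make_recording(np.zeros((2, n)))
        rp = periodic_rpeaks(n)
        m = cwt_epoch_mean(rec, rp)
        assert np.all(m == 0.0)

    def test_empty_channel_subset(self, rng):
        rec = make_recording(rng.standard_normal((2, 10000)))
        with pytest.raises(ValueError, match="empty"):
            cwt_epoch_mean(rec, periodic_rpeaks(10000), channels=[])


class TestMD:
    def test_identical_maps_md_zero(self, rng):
        m = np.abs(rng.standard_normal((len(TFC_WAVE.freqs), 300)))
        off = cwt_off(m, m)
        assert mean_time_derivative(off, 250.0) == 0.0

    def test_time_constant_map_md_zero(self):
        off = np.outer(np.arange(len(TFC_WAVE.freqs), dtype=float), np.ones(300))
        assert mean_time_derivative(off, 250.0) == 0.0

    def test_grid_mismatch(self, rng):
        a = np.zeros((40, 300))
        b = np.zeros((40, 200))
        with pytest.raises(ValueError, match="grid"):
            cwt_off(a, b)

    def test_nonnegative(self, rng):
        off = rng.standard_normal((len(TFC_WAVE.freqs), 300))
        assert mean_time_derivative(off, 250.0) >= 0.0


class TestCompareMethods:
    def test_identical_groups_p_one(self):
        res = compare_methods([np.array([1.0, 2, 3, 4, 5]),
                               np.array([1.0, 2, 3, 4, 5])])
        assert res.p_value > 0.9
        assert res.pairwise == []

    def test_shifted_group_detected(self):
        g = np.array([1.0, 2, 3, 4, 5])
        res = compare_methods({"a": g, "b": g + 10.0, "c": g})
        assert res.p_value < 0.05
        flagged = res.significant_pairs()
        assert ("a", "b") in flagged and ("b", "c") in flagged
        assert ("a", "c") not in flagged

    def test_brute_force_h_statistic(self, rng):
        # tie-free case: H computed from first principles
        groups = [rng.permutation(30)[:8] + 0.5 * i for i in range(3)]
        groups = [g.astype(float) + rng.uniform(0, 1e-6, g.size) for g in groups]
        res = compare_methods(groups)
        pooled = np.concatenate(groups)
        order = pooled.argsort().argsort() + 1.0
        n_total = pooled.size
        bounds = np.cumsum([0] + [g.size for g in groups])
        h = 12.0 / (n_total * (n_total + 1)) * sum(
            order[bounds[i] : bounds[i + 1]].sum() ** 2 / groups[i].size
            for i in range(3)
        ) - 3 * (n_total + 1)
        assert res.statistic == pytest.approx(h, rel=1e-10)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_methods([np.array([1.0, 2.0])])

    def test_small_groups_raise(self):
        with pytest.raises(ValueError, match="at least 2 values"):
            compare_methods([np.array([1.0]), np.array([2.0, 3.0])])

    def test_null_calibration_quick(self):
        # a light version of the full calibration (acceptance runs 2000)
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.standard_normal(12) for _ in range(4)]
            rejections += compare_methods(groups).p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.08
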