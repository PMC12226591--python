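"""Conditioning chain: filtering, epoching, detrending, rejection, resampling."""

import numpy as np
import pytest
from scipy import signal as sps

from cfctacs.preprocess import (
    PreprocessConfig,
    bandpass,
    detrend_epoch,
    extract_epochs,
    reject_artifacts,
    resample_to_model_rate,
    select_band,
    select_roi,
)

FS = 500.0


def sinusoid(freq, fs=FS, seconds=2.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def filtfilt_gain(freq, low, high, fs, order=4):
    """Analytic two-pass magnitude response of the designed filter."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2  # forward-backward squares the magnitude


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,bound,kind",
        [(2.0, 0.10, "stop"), (20.0, 0.05, "pass")],
    )
    def test_attenuation_matches_analytic_response(self, freq, bound, kind):
        x = sinusoid(freq, seconds=4.0)
        y = bandpass(x, 4.0, 50.0, FS)
        # compare the central portion to avoid transients
        sl = slice(500, -500)
        ratio = np.sqrt((y[sl] ** 2).mean() / (x[sl] ** 2).mean())
        expected = filtfilt_gain(freq, 4.0, 50.0, FS)
        assert ratio == pytest.approx(expected, abs=0.02)
        if kind == "stop":
            assert ratio < bound
        else:
            assert abs(ratio - 1.0) < bound

    def test_zero_in_zero_out(self):
        y = bandpass(np.zeros(1000), 4.0, 50.0, FS)
        np.testing.assert_array_equal(y, 0.0)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.ones(100), 50.0, 4.0, FS)
        with pytest.raises(ValueError):
            bandpass(np.ones(100), 4.0, 300.0, FS)


class TestExtractEpochs:
    def test_printed_window_arithmetic(self):
        timeline = np.arange(6000.0)[None, :]  # 1 channel, sample index value
        pre, post = extract_epochs(timeline, 1000, FS)
        assert pre.shape == (1, 250) and post.shape == (1, 250)
        assert pre[0, 0] == 1000 and pre[0, -1] == 1249
        assert post[0, 0] == 5250 and post[0, -1] == 5499

    def test_out_of_range_onset_errors(self):
        timeline = np.zeros((2, 1000))
        with pytest.raises(ValueError, match="outside"):
            extract_epochs(timeline, 900, FS)


class TestDetrend:
    def test_constant_channel_zeroed(self):
        seg = np.full((3, 250), 7.0)
        np.testing.assert_allclose(detrend_epoch(seg), 0.0, atol=1e-9)

    def test_ramp_removed(self):
        seg = np.linspace(0, 10, 250)[None, :]
        assert np.abs(detrend_epoch(seg)).max() < 1e-9

    def test_sinusoid_amplitude_preserved(self):
        # the projection of whole sinusoid cycles on a linear basis is ~0,
        # so the least-squares amplitude survives detrending within 1%
        x = sinusoid(16.0, seconds=0.5)[None, :]
        y = detrend_epoch(x)
        t = np.arange(250) / FS
        basis = np.vstack(
            [np.sin(2 * np.pi * 16 * t), np.cos(2 * np.pi * 16 * t)]
        ).T
        coef, *_ = np.linalg.lstsq(basis, y[0], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, rel=0.01)


class TestRejectArtifacts:
    def test_peak_rule(self):
        epoch = np.zeros((1, 2, 250))
        epoch[0, 1, 100] = 101.0
        keep, log = reject_artifacts(epoch, FS)
        assert not keep[0]
        assert log[0]["violations"][0]["rule"] == "peak"

    def test_slope_rule(self):
        # 120 uV jump across one 2-ms sample interval = 60 uV/ms while the
        # peak stays at 60 uV, so only the slope rule can fire
        epoch = np.full((1, 1, 250), -60.0)
        epoch[0, 0, 100:] = 60.0
        keep, log = reject_artifacts(epoch, FS)
        assert not keep[0]
        assert [v["rule"] for v in log[0]["violations"]] == ["slope"]
        assert log[0]["violations"][0]["value_uV_per_ms"] == pytest.approx(60.0)

    def test_compliant_epoch_kept(self):
        # bounded by +-50 uV, jumps of 30 uV per 2 ms = 15 uV/ms
        epoch = np.zeros((1, 1, 250))
        epoch[0, 0, ::2] = 20.0
        epoch[0, 0, 1::2] = 50.0
        keep, log = reject_artifacts(epoch, FS)
        assert keep[0] and not log

    def test_ground_truth_fixture_exact(self):
        """On a constructed set with known violations the rejected set
        equals the ground truth exactly."""
        rng = np.random.default_rng(0)
        n = 60
        epochs = 10.0 * rng.standard_normal((n, 3, 250)).clip(-4, 4)
        bad_peak = rng.choice(n, 8, replace=False)
        remaining = np.setdiff1d(np.arange(n), bad_peak)
        bad_slope = rng.choice(remaining, 7, replace=False)
        for i in bad_peak:
            epochs[i, 0, 50] = 130.0
        for i in bad_slope:
            epochs[i, 1, 60] = 40.0
            epochs[i, 1, 61] = -80.0  # 120 uV in 2 ms = 60 uV/ms
        truth = np.ones(n, dtype=bool)
        truth[bad_peak] = False
        truth[bad_slope] = False
        keep, log = reject_artifacts(epochs, FS)
        np.testing.assert_array_equal(keep, truth)
        assert len(log) == 15


class TestResample:
    def test_250_samples_become_64(self):
        seg = np.zeros((9, 250))
        out = resample_to_model_rate(seg, FS, 128.0)
        assert out.shape == (9, 64)

    def test_constant_preserved(self):
        seg = np.full((1, 250), 3.3)
        out = resample_to_model_rate(seg, FS, 128.0)
        np.testing.assert_allclose(out, 3.3, rtol=1e-3)

    def test_inband_sinusoid_amplitude_within_2pct(self):
        x = sinusoid(20.0, seconds=2.0)[None, :]
        y = resample_to_model_rate(x, FS, 128.0)
        t = np.arange(y.shape[1]) / 128.0
        # least-squares amplitude at 20 Hz on the resampled grid
        basis = np.vstack([np.sin(2 * np.pi * 20 * t), np.cos(2 * np.pi * 20 * t)])
        sl = slice(20, -20)
        coef, *_ = np.linalg.lstsq(basis.T[sl], y[0][sl], rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, rel=0.02)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_to_model_rate(np.zeros((1, 250)), FS, 600.0)


class TestBandRoiSelection:
    CHANNELS = ("Fz", "F1", "F2", "Pz", "P1", "P2", "Oz", "O1", "O2")

    def test_parietal_subset_order(self):
        seg = np.arange(9)[:, None] * np.ones((9, 10))
        sub, names = select_roi(seg, "parietal", self.CHANNELS)
        assert names == ("Pz", "P1", "P2")
        np.testing.assert_array_equal(sub[:, 0], [3, 4, 5])

    def test_roi_all_identity(self):
        seg = np.random.default_rng(0).standard_normal((9, 20))
        sub, names = select_roi(seg, "all", self.CHANNELS)
        np.testing.assert_array_equal(sub, seg)
        assert names == self.CHANNELS

    def test_unknown_labels_error(self):
        seg = np.zeros((9, 10))
        with pytest.raises(KeyError):
            select_roi(seg, "temporal", self.CHANNELS)
        with pytest.raises(KeyError):
            select_band(seg, "delta", FS)

    def test_out_of_band_sinusoid_suppressed(self):
        x = sinusoid(40.0, seconds=2.0)[None, :]
        y = select_band(x, "beta", FS)  # 13-30 Hz
        sl = slice(200, -200)
        assert np.sqrt((y[0][sl] ** 2).mean()) < 0.1 * np.sqrt(
            (x[0][sl] ** 2).mean()
        )

    def test_band_selection_near_idempotent(self):
        # a second pass only nibbles at the transition bands: interior
        # (17-24 Hz) power of the 13-30 Hz selection changes by < 1%
        from cfctacs.models import band_power

        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 4000))
        once = select_band(x, "beta", FS)
        twice = select_band(once, "beta", FS)
        sl = (slice(None), slice(300, -300))
        p1 = band_power(once[sl], FS, (17, 24), nperseg=512).mean()
        p2 = band_power(twice[sl], FS, (17, 24), nperseg=512).mean()
        assert p2 / p1 == pytest.approx(1.0, abs=0.01)


class TestConfig:
    def test_windows_must_avoid_stimulation_interval(self):
        with pytest.raises(ValueError, match="stimulation interval"):
            PreprocessConfig(epoch_windows=((1.0, 2.0), (8.5, 9.0)))

    def test_defaults_valid(self):
        cfg = PreprocessConfig()
        assert cfg.bands["lower_beta"] == (13.0, 20.0)
        assert cfg.rois["parietal"] == ("Pz", "P1", "P2")

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            PreprocessConfig(peak_thresh=-1.0)
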