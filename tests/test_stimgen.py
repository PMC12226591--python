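"""Stimulus synthesis: waveform formula, return currents, phase lags, caps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from cfctacs.stimgen import (
    CONDITIONS,
    MontageSpec,
    StimConfig,
    StimulationConfigError,
    build_condition_waveforms,
    default_montage,
    derive_return_currents,
    estimate_phase_lag,
    export_waveform_set,
    synthesize_stimulus,
)


def xcorr_lag_deg(a, b, f_p, fs):
    """Independent phase-lag estimate: isolate the slow component with an
    FFT brick-wall mask, then maximise cross-correlation over integer-sample
    shifts of the reference within one slow period."""

    def isolate(x):
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(len(x), d=1 / fs)
        spec[(freqs < f_p / 1.5) | (freqs > f_p * 1.5)] = 0.0
        return np.fft.irfft(spec, n=len(x))

    ai, bi = isolate(a), isolate(b)
    period = int(round(fs / f_p))
    shifts = np.arange(period)
    score = [np.dot(ai, np.roll(bi, -s)) for s in shifts]
    best = shifts[int(np.argmax(score))]
    return (best / period * 360.0) % 360.0


class TestSynthesizeStimulus:
    def test_matches_closed_form(self, stim_config):
        t = stim_config.times()
        phi = np.deg2rad(45.0)
        expected = (
            stim_config.a_fa
            / 2
            * (np.sin(2 * np.pi * 6 * t + phi) + 1)
            * np.sin(2 * np.pi * 40 * t)
            + stim_config.a_fp * np.sin(2 * np.pi * 6 * t + phi)
        )
        np.testing.assert_allclose(
            synthesize_stimulus(stim_config, 45.0), expected, rtol=1e-12
        )

    def test_degenerate_envelope_is_pure_slow_sinusoid(self):
        cfg = StimConfig(a_fa=0.0, a_fp=0.8, f_p=6.0)
        s = synthesize_stimulus(cfg)
        t = cfg.times()
        np.testing.assert_allclose(
            s, 0.8 * np.sin(2 * np.pi * 6 * t), atol=1e-12
        )
        freqs, psd = signal.periodogram(s, fs=cfg.fs)
        peak_bin = np.argmax(psd)
        assert abs(freqs[peak_bin] - 6.0) < 0.2
        # spectral power concentrated in that single component
        assert psd[peak_bin] / psd.sum() > 0.95

    def test_phase_offset_periodicity(self, stim_config):
        np.testing.assert_allclose(
            synthesize_stimulus(stim_config, 0.0),
            synthesize_stimulus(stim_config, 360.0),
            atol=1e-12,
        )

    def test_peak_amplitude_matches_oversampled_oracle(self):
        # 2:8 intensity split; brute-force maximum on a 10x finer grid
        cfg = StimConfig(a_fa=0.2, a_fp=0.8, f_p=6, f_a=40, fs=500, duration=6)
        dense = StimConfig(
            a_fa=0.2, a_fp=0.8, f_p=6, f_a=40, fs=5000, duration=6
        )
        peak = np.abs(synthesize_stimulus(cfg)).max()
        oracle = np.abs(synthesize_stimulus(dense)).max()
        assert peak == pytest.approx(oracle, rel=0.01)

    def test_aliasing_rejected(self):
        with pytest.raises(StimulationConfigError, match="alias"):
            StimConfig(f_a=40.0, fs=80.0)

    @given(k=st.floats(0.1, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_intensity(self, k):
        base = StimConfig(duration=1.0)
        scaled = StimConfig(a_fa=base.a_fa * k, a_fp=base.a_fp * k, duration=1.0)
        np.testing.assert_allclose(
            synthesize_stimulus(scaled, 30.0),
            k * synthesize_stimulus(base, 30.0),
            rtol=1e-9,
            atol=1e-12,
        )


class TestReturnCurrents:
    def test_single_return_is_negated_stimulus(self):
        s = synthesize_stimulus(StimConfig(duration=1.0))
        r = derive_return_currents(s, 1)
        np.testing.assert_array_equal(r[0], -s)

    def test_four_returns_quarter_amplitude(self):
        s = np.array([1.0, -0.5, 0.25])
        r = derive_return_currents(s, 4)
        assert r.shape == (4, 3)
        np.testing.assert_allclose(np.abs(r).max(), 0.25)
        assert (np.sign(r[0]) == -np.sign(s)).all()

    @given(n=st.integers(1, 8), amp=st.floats(0.01, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_conservation(self, n, amp):
        s = amp * synthesize_stimulus(StimConfig(duration=0.5))
        r = derive_return_currents(s, n)
        np.testing.assert_array_less(
            np.abs(s + r.sum(axis=0)).max(), 1e-10
        )

    def test_zero_returns_rejected(self):
        with pytest.raises(StimulationConfigError):
            derive_return_currents(np.ones(10), 0)


class TestPhaseLag:
    def test_identical_series_zero_lag(self, stim_config):
        s = synthesize_stimulus(stim_config)
        lag = estimate_phase_lag(s, s, 6.0, 500.0)
        assert min(lag, 360 - lag) < 1e-6

    def test_analytic_sinusoids_90_degrees(self):
        t = np.arange(3000) / 500.0
        a = np.sin(2 * np.pi * 6 * t + np.pi / 2)
        b = np.sin(2 * np.pi * 6 * t)
        assert estimate_phase_lag(a, b, 6.0, 500.0) == pytest.approx(90.0, abs=0.5)

    @pytest.mark.parametrize("lag", [0.0, 45.0, 90.0, 180.0, 270.0])
    def test_roundtrip_on_full_waveforms(self, stim_config, lag):
        ref = synthesize_stimulus(stim_config, 0.0)
        shifted = synthesize_stimulus(stim_config, lag)
        est = estimate_phase_lag(shifted, ref, 6.0, 500.0)
        err = min(abs(est - lag), 360 - abs(est - lag))
        assert err < 1.0

    def test_agrees_with_crosscorrelation_oracle(self, stim_config):
        ref = synthesize_stimulus(stim_config, 0.0)
        shifted = synthesize_stimulus(stim_config, 45.0)
        est = estimate_phase_lag(shifted, ref, 6.0, 500.0)
        oracle = xcorr_lag_deg(shifted, ref, 6.0, 500.0)
        err = min(abs(est - oracle), 360 - abs(est - oracle))
        assert err < 3.0

    def test_too_short_series_rejected(self):
        t = np.arange(100) / 500.0  # 0.2 s < 3 cycles of 6 Hz
        s = np.sin(2 * np.pi * 6 * t)
        with pytest.raises(ValueError, match="3 cycles"):
            estimate_phase_lag(s, s, 6.0, 500.0)


class TestConditionWaveforms:
    @pytest.mark.parametrize("condition", CONDITIONS)
    def test_configured_lag_realised(self, stim_config, condition):
        ws = build_condition_waveforms(default_montage(), stim_config, condition)
        dmn = ws.electrode("Fpz")
        cen = ws.electrode("F3")
        est = estimate_phase_lag(dmn, cen, stim_config.f_p, stim_config.fs)
        err = min(abs(est - condition), 360 - abs(est - condition))
        assert err < 1.0

    def test_antiphase_components_anticorrelated(self, stim_config):
        from cfctacs.preprocess import bandpass

        ws = build_condition_waveforms(default_montage(), stim_config, 180)
        dmn = bandpass(ws.electrode("Fpz"), 4.0, 9.0, stim_config.fs)
        cen = bandpass(ws.electrode("F3"), 4.0, 9.0, stim_config.fs)
        r = np.corrcoef(dmn, cen)[0, 1]
        assert r == pytest.approx(-1.0, abs=0.01)

    def test_current_conservation_at_every_sample(self, stim_config):
        for condition in CONDITIONS:
            ws = build_condition_waveforms(
                default_montage(), stim_config, condition
            )
            assert np.abs(ws.net_current()).max() < 1e-10

    def test_cap_enforced_when_binding(self, stim_config):
        montage = default_montage(total_current_cap=0.2)
        ws = build_condition_waveforms(montage, stim_config, 45)
        assert ws.source_current().max() <= 0.2 + 1e-12
        assert ws.scale < 1.0

    def test_waveforms_unchanged_when_cap_not_binding(self, stim_config):
        loose = build_condition_waveforms(
            default_montage(total_current_cap=100.0), stim_config, 45
        )
        assert loose.scale == 1.0
        # equal split of a 1.0 mA-peak stimulus over 6 targets
        direct = synthesize_stimulus(stim_config, 0.0) / 6.0
        np.testing.assert_allclose(loose.electrode("F3"), direct, rtol=1e-12)

    def test_default_cap_1p5_not_exceeded(self, stim_config):
        ws = build_condition_waveforms(default_montage(1.5), stim_config, 45)
        assert ws.source_current().max() <= 1.5 + 1e-12

    def test_invalid_condition_rejected(self, stim_config):
        with pytest.raises(StimulationConfigError):
            build_condition_waveforms(default_montage(), stim_config, 90)


def test_export_roundtrip(tmp_path, stim_config):
    ws = build_condition_waveforms(default_montage(), stim_config, 45)
    path = export_waveform_set(ws, tmp_path / "wave.tsv")
    loaded = np.loadtxt(path, delimiter="\t", skiprows=1)
    np.testing.assert_allclose(loaded, ws.currents.T, rtol=1e-5, atol=1e-9)
    header = path.read_text().splitlines()[0].split("\t")
    assert header == ws.electrodes
    assert (path.parent / "wave.tsv.json").exists()
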