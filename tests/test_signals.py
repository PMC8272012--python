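"""Wavelets, the hybrid splice, filters, and bandwidth measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from usctfwi.signals import (Wavelet, add_noise, bandpass_window,
                             bandwidth_limit_db, highpass_filter,
                             hybrid_broadband, ideal_pulse, lowpass_filter,
                             narrowband_wavelet)

DT_FULL = 1.0 / 20e6  # full-scale sampling for the probe-band defaults


class TestNarrowbandWavelet:
    def test_default_minus40db_low_limit_near_half_megahertz(self):
        w = narrowband_wavelet()  # fc=2 MHz surrogate of a P4-1 pulse
        f, found = bandwidth_limit_db(w, -40, "low")
        assert found
        assert 0.40e6 <= f <= 0.65e6

    def test_spectrum_peaks_at_center_frequency(self):
        w = narrowband_wavelet(fc=2.0e6, dt=DT_FULL, n=512)
        freqs, spec = w.spectrum(8192)
        assert abs(freqs[np.argmax(np.abs(spec))] - 2.0e6) <= freqs[1]

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=10, deadline=None)
    def test_amplitude_scale_leaves_db_limits_unchanged(self, scale):
        w = narrowband_wavelet()
        ws = Wavelet(w.samples * scale, w.dt)
        assert bandwidth_limit_db(ws)[0] == pytest.approx(
            bandwidth_limit_db(w)[0], rel=1e-9
        )

    def test_fc_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            narrowband_wavelet(fc=11e6, dt=DT_FULL)


class TestIdealPulse:
    def test_zero_mean(self):
        w = ideal_pulse()
        assert abs(w.samples.mean()) < 1e-10 * np.abs(w.samples).max()

    def test_duration_about_n_cycles_over_fc(self):
        fc, n_cycles = 0.5e6, 3
        w = ideal_pulse(fc=fc, n_cycles=n_cycles, dt=DT_FULL, n=512)
        env = np.abs(w.samples) > 1e-3 * np.abs(w.samples).max()
        duration = (np.nonzero(env)[0][-1] - np.nonzero(env)[0][0]) * w.dt
        assert abs(duration - n_cycles / fc) <= 1.0 / fc

    def test_low_limit_below_200khz_at_half_mhz_center(self):
        w = ideal_pulse(fc=0.5e6, dt=DT_FULL, n=512)
        f, _ = bandwidth_limit_db(w, -40, "low")
        assert f < 0.2e6


class TestHybridBroadband:
    def test_identity_splice(self):
        w = narrowband_wavelet()
        h = hybrid_broadband(w, w)
        ref = np.abs(w.samples).max()
        assert np.abs(h.samples[:len(w)] - w.samples).max() < 1e-9 * ref

    def test_lowers_minus40db_low_limit(self):
        narrow = narrowband_wavelet()
        hybrid = hybrid_broadband(narrow, ideal_pulse())
        f_n, _ = bandwidth_limit_db(narrow)
        f_h, _ = bandwidth_limit_db(hybrid)
        assert f_h < f_n
        assert f_h < 0.1e6  # deep low-frequency extension

    def test_limit_bounded_below_by_ideal_ingredient(self):
        narrow = narrowband_wavelet()
        ideal = ideal_pulse(fc=0.5e6, dt=DT_FULL, n=512)
        hybrid = hybrid_broadband(narrow, ideal)
        f_i, _ = bandwidth_limit_db(ideal)
        f_h, _ = bandwidth_limit_db(hybrid)
        assert f_h == pytest.approx(f_i, rel=0.05)

    @pytest.mark.parametrize("fc,splice", [(1.5e6, 0.8e6), (2.0e6, 1.0e6),
                                           (2.5e6, 1.2e6)])
    def test_never_raises_low_limit(self, fc, splice):
        narrow = narrowband_wavelet(fc=fc, dt=DT_FULL, n=512)
        ideal = ideal_pulse(fc=0.4e6, dt=DT_FULL, n=512)
        hybrid = hybrid_broadband(narrow, ideal, splice_f=splice)
        assert bandwidth_limit_db(hybrid)[0] <= bandwidth_limit_db(narrow)[0] + 1.0

    def test_high_band_preserved_within_one_percent(self):
        narrow = narrowband_wavelet()
        ideal = ideal_pulse(fc=0.5e6, dt=DT_FULL, n=512)
        hybrid = hybrid_broadband(narrow, ideal, splice_f=1.0e6)
        # compare on the splice's native frequency grid (the contract is
        # exact equality of the sampled spectrum above splice + taper)
        n = max(len(narrow), len(ideal))
        f, spec_n = narrow.spectrum(n)
        _, spec_h = hybrid.spectrum(n)
        k = np.argmin(np.abs(f - 1.5e6))
        assert np.abs(spec_h[k]) == pytest.approx(np.abs(spec_n[k]), rel=0.01)

    def test_dt_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dt mismatch"):
            hybrid_broadband(narrowband_wavelet(dt=DT_FULL),
                             ideal_pulse(dt=2 * DT_FULL))

    def test_output_is_real_valued(self):
        h = hybrid_broadband(narrowband_wavelet(),
                             ideal_pulse(fc=0.5e6, dt=DT_FULL, n=512))
        assert np.isrealobj(h.samples)


class TestBandwidthLimit:
    def test_pure_sinusoid_limits_bracket_frequency(self):
        dt = DT_FULL
        t = dt * np.arange(1024)
        w = Wavelet(np.sin(2 * np.pi * 1.0e6 * t) * np.hanning(1024), dt)
        f_lo, _ = bandwidth_limit_db(w, -40, "low")
        f_hi, _ = bandwidth_limit_db(w, -40, "high")
        assert f_lo < 1.0e6 < f_hi

    def test_matches_dense_fft_bruteforce_scan(self):
        w = narrowband_wavelet()
        n_dense = 1 << 16
        f, spec = w.spectrum(n_dense)
        db = 20 * np.log10(np.abs(spec) / np.abs(spec).max() + 1e-300)
        k_peak = np.argmax(db)
        below = np.nonzero(db[:k_peak] < -40)[0]
        brute = f[below[-1] + 1]
        measured, _ = bandwidth_limit_db(w, -40, "low", n_fft=n_dense)
        assert abs(measured - brute) <= 2 * f[1]

    def test_unreachable_threshold_flags_and_returns_edges(self):
        dt = DT_FULL
        w = Wavelet(np.ones(64), dt)  # DC: low side never drops below peak
        f, found = bandwidth_limit_db(w, -200, "low")
        assert not found and f == 0.0
        f_hi, found_hi = bandwidth_limit_db(w, -400, "high")
        assert f_hi == pytest.approx(0.5 / dt) if not found_hi else f_hi > 0


class TestFilters:
    dt = 1.0 / 12.5e6

    def test_highpass_kills_dc(self):
        traces = np.ones((4, 2000))
        out = highpass_filter(traces, self.dt, cutoff=0.55e6, order=40)
        assert np.abs(out).max() < 1e-6

    def test_highpass_sinusoid_probes(self):
        t = self.dt * np.arange(4000)
        lo = np.sin(2 * np.pi * 0.2e6 * t)
        hi = np.sin(2 * np.pi * 1.0e6 * t)
        out_lo = highpass_filter(lo, self.dt)
        out_hi = highpass_filter(hi, self.dt)
        mid = slice(1000, 3000)  # avoid edge transients
        att_lo = 20 * np.log10(np.abs(out_lo[mid]).max())
        att_hi = 20 * np.log10(np.abs(out_hi[mid]).max())
        assert att_lo <= -40
        assert abs(att_hi) <= 1.0

    def test_highpass_nearly_idempotent_on_passband(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        once = highpass_filter(x, self.dt)
        twice = highpass_filter(once, self.dt)
        passband = np.fft.rfftfreq(4000, self.dt) > 0.8e6
        F1 = np.fft.rfft(once)[passband]
        F2 = np.fft.rfft(twice)[passband]
        assert np.abs(F2 - F1).max() < 0.1 * np.abs(F1).max()

    def test_highpass_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            highpass_filter(np.zeros(50), self.dt, order=40)

    def test_bandpass_in_band_passes_out_of_band_blocked(self):
        t = self.dt * np.arange(6000)
        mid = slice(2000, 4000)
        inband = np.sin(2 * np.pi * 1.0e6 * t)
        out = bandpass_window(inband, self.dt, center_f=1.0e6, width=50e3,
                              order=512)
        assert abs(20 * np.log10(np.abs(out[mid]).max())) <= 1.0
        faroff = np.sin(2 * np.pi * 1.2e6 * t)  # 4 widths away
        out2 = bandpass_window(faroff, self.dt, center_f=1.0e6, width=50e3,
                               order=512)
        assert 20 * np.log10(np.abs(out2[mid]).max()) <= -40

    def test_bandpass_linearity(self, rng):
        a = rng.standard_normal(3000)
        b = rng.standard_normal(3000)
        fa = bandpass_window(a, self.dt, 1.0e6)
        fb = bandpass_window(b, self.dt, 1.0e6)
        fab = bandpass_window(a + b, self.dt, 1.0e6)
        assert np.allclose(fab, fa + fb, atol=1e-12 * np.abs(fa).max())

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass_window(np.zeros(3000), self.dt, center_f=6.3e6, width=50e3)

    def test_zero_phase_preserves_arrival_time(self):
        # band limiting must not shift first arrivals (zero-phase contract)
        from usctfwi.wavesim import first_arrival_pick

        w = narrowband_wavelet(fc=1.5e6, dt=self.dt, n=3000)
        delayed = np.roll(w.samples, 700)
        t0 = first_arrival_pick(delayed, self.dt)
        t1 = first_arrival_pick(highpass_filter(delayed, self.dt, 0.55e6), self.dt)
        t2 = first_arrival_pick(lowpass_filter(delayed, self.dt, 3.0e6), self.dt)
        assert abs(t1 - t0) <= 2 * self.dt
        assert abs(t2 - t0) <= 2 * self.dt


class TestAddNoise:
    dt = 1e-6

    def test_zero_level_is_identity(self, rng):
        x = rng.standard_normal((8, 300))
        assert np.array_equal(add_noise(x, self.dt, 0.0, seed=1), x)

    def test_snr_matches_request_within_five_percent(self, rng):
        x = np.sin(2 * np.pi * 100e3 * self.dt * np.arange(3000))[None, :] * np.ones((4, 1))
        ratios = []
        for seed in range(10):
            noisy = add_noise(x, self.dt, 0.1, seed=seed)
            noise = noisy - x
            ratios.append(np.sqrt(np.mean(noise**2) / np.mean(x**2)))
        assert np.mean(ratios) == pytest.approx(0.1, rel=0.05)

    def test_noise_confined_to_band(self):
        x = np.zeros((2, 4096))
        x[:, 100] = 1.0  # reference energy for scaling
        noisy = add_noise(x, self.dt, 1.0, band=(100e3, 200e3), seed=3)
        noise = noisy - x
        f = np.fft.rfftfreq(4096, self.dt)
        spec = np.abs(np.fft.rfft(noise, axis=1)).mean(axis=0)
        inband = spec[(f > 110e3) & (f < 190e3)].mean()
        outband = spec[(f > 320e3)].mean()
        assert outband < 0.05 * inband

    def test_deterministic_per_seed(self, rng):
        x = rng.standard_normal((4, 200))
        assert np.array_equal(add_noise(x, self.dt, 0.2, seed=9),
                              add_noise(x, self.dt, 0.2, seed=9))


def test_wavelet_csv_roundtrip(tmp_path):
    w = narrowband_wavelet()
    path = tmp_path / "w.csv"
    w.to_csv(path)
    back = Wavelet.from_csv(path)
    assert back.dt == pytest.approx(w.dt, rel=1e-9)
    assert np.allclose(back.samples, w.samples, atol=1e-12)
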