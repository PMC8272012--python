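"""Probe localization and wavelet estimation."""

import numpy as np
import pytest

from usctfwi.calib import (TOFTable, estimate_wavelet,
                           fractional_delay, geometry_from_poses,
                           localize_probes, nmo_correct, nominal_poses,
                           point_source_guard, predict_tof)
from usctfwi.geometry import ring_geometry
from usctfwi.signals import add_noise, narrowband_wavelet
from usctfwi.wavesim import ShotGather, first_arrival_pick

GEOM = ring_geometry(8, 8, 0.104, 1.2e-3)
C = 1484.0


def delayed_water_gather(geometry, source_id, receiver_probe, wavelet,
                         n_t=240, dt=1e-6, amp_decay=True):
    """Straight-ray water gather: the wavelet delayed by distance / c per
    receiver, with 1/sqrt(r) cylindrical amplitude decay. This is exactly
    the propagation model the calibration assumes, so it serves as the
    recovery oracle."""
    sp, se = source_id
    src = geometry.element_coords[sp, se]
    rec = geometry.element_coords[receiver_probe]
    dist = np.linalg.norm(rec - src[None, :], axis=1)
    base = np.zeros((n_t, len(rec)))
    base[:len(wavelet.samples)] = wavelet.samples[:, None]
    shifted = fractional_delay(base, dist / C / dt)
    if amp_decay:
        shifted = shifted / np.sqrt(dist[None, :])
    return ShotGather(
        traces=shifted.astype(np.float32), dt=dt, source_id=source_id,
        receiver_probe=receiver_probe,
        receiver_ids=[(receiver_probe, e) for e in range(len(rec))],
    )


def normalized_peak_correlation(a, b):
    from scipy.signal import correlate

    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return correlate(a, b).max()


class TestPredictTOF:
    def test_closed_form_pair(self):
        geom = ring_geometry(6, 1, 0.1484, 1e-3)
        table = predict_tof(geom, C, pairs=[(0, 0, 3, 0)])
        # opposite points on a 148.4 mm ring at 1484 m/s: exactly 100 us
        assert table.entries[(0, 0, 3, 0)] == pytest.approx(1.0e-4, rel=1e-12)

    def test_symmetric_in_source_and_receiver(self):
        table = predict_tof(GEOM, C, pairs=[(0, 2, 4, 5), (4, 5, 0, 2)])
        assert table.entries[(0, 2, 4, 5)] == table.entries[(4, 5, 0, 2)]

    def test_matches_bruteforce_distances(self):
        table = predict_tof(GEOM, C)
        for (sp, se, rp, re), t in list(table.entries.items())[::37]:
            d = np.linalg.norm(GEOM.element_coords[rp, re]
                               - GEOM.element_coords[sp, se])
            assert abs(t - d / C) < 1e-12

    def test_invalid_water_speed_rejected(self):
        with pytest.raises(ValueError, match="c_water"):
            TOFTable({(0, 0, 1, 0): 1e-4}, c_water=1300.0)


class TestLocalizeProbes:
    def test_exact_measurements_give_zero_update(self):
        tof = predict_tof(GEOM, C)
        res = localize_probes(tof, GEOM)
        assert res.residual_rms < 1e-15
        nominal = nominal_poses(GEOM)
        for a, b in zip(res.poses, nominal):
            assert np.linalg.norm(a.center - b.center) < 1e-12

    def test_perturbation_recovery_within_tolerances(self):
        rng = np.random.default_rng(3)
        poses_true = nominal_poses(GEOM)
        for p in poses_true[1:]:
            p.center = p.center + rng.uniform(-2e-3, 2e-3, 2)
            p.angle += rng.uniform(-np.radians(2), np.radians(2))
        geom_true = geometry_from_poses(poses_true, GEOM)
        tof = predict_tof(geom_true, C)
        res = localize_probes(tof, GEOM, max_iter=10)
        assert res.iterations <= 10
        for est, true in zip(res.poses, poses_true):
            assert np.linalg.norm(est.center - true.center) < 0.05e-3
            assert abs(est.angle - true.angle) < np.radians(0.05)

    def test_residual_history_nonincreasing(self):
        rng = np.random.default_rng(4)
        poses_true = nominal_poses(GEOM)
        for p in poses_true[1:]:
            p.center = p.center + rng.uniform(-1e-3, 1e-3, 2)
        tof = predict_tof(geometry_from_poses(poses_true, GEOM), C)
        res = localize_probes(tof, GEOM)
        assert np.all(np.diff(res.residual_history) <= 1e-15)

    def test_pose_error_scales_linearly_with_pick_noise(self):
        # Monte-Carlo regression over a decade of noise levels
        rng = np.random.default_rng(5)
        tof_clean = predict_tof(GEOM, C)
        sigmas = np.array([2e-9, 20e-9])
        errors = []
        for sigma in sigmas:
            errs = []
            for trial in range(3):
                noisy = TOFTable(
                    {k: t + sigma * rng.standard_normal()
                     for k, t in tof_clean.entries.items()}, C
                )
                res = localize_probes(noisy, GEOM)
                nominal = nominal_poses(GEOM)
                errs.append(np.mean([np.linalg.norm(a.center - b.center)
                                     for a, b in zip(res.poses, nominal)]))
            errors.append(np.mean(errs))
        ratio = errors[1] / errors[0]
        assert 10 / 2 < ratio < 10 * 2  # ~linear over the decade

    def test_underdetermined_system_rejected(self):
        tof = predict_tof(GEOM, C, pairs=[(0, 0, 3, 0), (0, 0, 4, 0)])
        with pytest.raises(ValueError, match="constrain"):
            localize_probes(tof, GEOM)

    def test_report_serialization(self, tmp_path):
        res = localize_probes(predict_tof(GEOM, C), GEOM)
        res.to_json(tmp_path / "calib.json")
        import json

        data = json.loads((tmp_path / "calib.json").read_text())
        assert len(data["poses"]) == GEOM.n_probe_positions


class TestNMOCorrect:
    wavelet = narrowband_wavelet(fc=185e3, fractional_bandwidth=0.5,
                                 dt=1e-6, n=80)

    def test_alignment_within_two_samples(self):
        g = delayed_water_gather(GEOM, (0, 3), 4, self.wavelet)
        corrected = nmo_correct(g, GEOM, C)
        picks = [first_arrival_pick(np.asarray(corrected.traces[:, k], float), 1e-6)
                 for k in range(corrected.traces.shape[1])]
        assert np.ptp(picks) <= 2e-6

    def test_roundtrip_shift_restores_trace(self):
        rng = np.random.default_rng(0)
        from usctfwi.signals import lowpass_filter

        # band-limited trace with energy away from the record edges
        tr = np.zeros((256, 3))
        seg = lowpass_filter(rng.standard_normal((3, 128)), 1e-6, 300e3).T
        tr[60:188] = seg * np.hanning(128)[:, None]  # no sharp cut edges
        shifts = np.array([3.3, -7.7, 12.1])
        back = fractional_delay(fractional_delay(tr, shifts), -shifts)
        rel = np.linalg.norm(back - tr) / np.linalg.norm(tr)
        assert rel < 1e-3

    def test_zero_distance_receiver_unshifted(self):
        tr = np.zeros((64, 1))
        tr[10] = 1.0
        out = fractional_delay(tr, np.array([0.0]))
        assert np.allclose(out, tr, atol=1e-12)

    def test_overlong_shift_warns(self):
        short = narrowband_wavelet(fc=185e3, fractional_bandwidth=0.5,
                                   dt=1e-6, n=30)
        g = delayed_water_gather(GEOM, (0, 3), 4, short, n_t=40)
        with pytest.warns(UserWarning, match="beyond"):
            nmo_correct(g, GEOM, C)


class TestEstimateWavelet:
    wavelet = narrowband_wavelet(fc=185e3, fractional_bandwidth=0.5,
                                 dt=1e-6, n=80)
    # 16-position ring: 11 receiving probes x 12 elements > 100 traces
    geom = ring_geometry(16, 12, 0.2, 1.2e-3)

    def water_gathers(self, n_probes=3, noise=0.0, seed=0):
        gathers = []
        for k, rp in enumerate(self.geom.receive_map[0][:n_probes]):
            g = delayed_water_gather(self.geom, (0, 3), rp, self.wavelet)
            if noise > 0:
                from dataclasses import replace

                tr = add_noise(np.asarray(g.traces, float).T, g.dt, noise,
                               seed=seed + k).T
                g = replace(g, traces=tr.astype(np.float32))
            gathers.append(g)
        return gathers

    def test_noise_free_recovery_correlation(self):
        est = estimate_wavelet(self.water_gathers(), self.geom, C,
                               correct_2d_response=False)
        assert normalized_peak_correlation(est.samples, self.wavelet.samples) > 0.99

    def test_snr10_recovery_with_hundred_traces(self):
        gathers = self.water_gathers(n_probes=11, noise=0.1, seed=42)
        n_traces = sum(g.traces.shape[1] for g in gathers)
        assert n_traces >= 100
        est = estimate_wavelet(gathers, self.geom, C, correct_2d_response=False)
        assert normalized_peak_correlation(est.samples, self.wavelet.samples) > 0.95

    def test_stacking_gain_scales_inverse_sqrt_n(self):
        # estimate residual noise vs trace count on noisy water shots
        resid = []
        for n_probes in (1, 4):
            gathers = self.water_gathers(n_probes=n_probes, noise=0.3, seed=1)
            est = estimate_wavelet(gathers, self.geom, C,
                                   correct_2d_response=False)
            clean = estimate_wavelet(self.water_gathers(n_probes=n_probes),
                                     self.geom, C, correct_2d_response=False)
            n = min(len(est.samples), len(clean.samples))
            resid.append(np.std(est.samples[:n] - clean.samples[:n]))
        ratio = resid[0] / resid[1]
        assert 1.3 < ratio < 3.2  # sqrt(4) = 2 expected

    def test_single_trace_is_that_trace(self):
        g = delayed_water_gather(self.geom, (0, 3), 4, self.wavelet)
        from dataclasses import replace

        single = replace(g, traces=g.traces[:, :1],
                         receiver_ids=g.receiver_ids[:1])
        est = estimate_wavelet([single], self.geom, C,
                               correct_2d_response=False)
        assert normalized_peak_correlation(est.samples, self.wavelet.samples) > 0.99
        assert np.abs(est.samples).max() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no gathers"):
            estimate_wavelet([], GEOM, C)

    def test_half_derivative_undoes_half_integration(self):
        # half-integrate the wavelet spectrally, then check the 2D-response
        # correction restores it
        from usctfwi.calib import half_derivative

        w = self.wavelet.samples
        n_fft = 512
        f = np.fft.rfftfreq(n_fft, 1e-6)
        spec = np.fft.rfft(w, n_fft)
        with np.errstate(divide="ignore", invalid="ignore"):
            half_int = np.where(f > 0, spec / np.sqrt(2j * np.pi * f), 0.0)
        received = np.fft.irfft(half_int, n_fft)[:len(w) + 50]
        restored = half_derivative(received, 1e-6)[:len(w)]
        assert normalized_peak_correlation(restored, w) > 0.99


def test_point_source_guard():
    assert point_source_guard(0.245e-3, 1484.0, 1.6e6)  # width < lambda_min
    with pytest.warns(UserWarning, match="point-source"):
        assert not point_source_guard(1.0e-3, 1484.0, 1.6e6)


def test_tof_table_csv_roundtrip(tmp_path):
    table = predict_tof(GEOM, C)
    table.to_csv(tmp_path / "tof.csv")
    back = TOFTable.from_csv(tmp_path / "tof.csv")
    assert back.entries == table.entries
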