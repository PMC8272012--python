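"""Window sampling, augmentation arithmetic, architectures, training."""

import numpy as np
import pytest

from usctfwi.bandext import (BandextModel, CNN1dConfig, SamplePair, UNetConfig,
                             augmentation_count, build_cnn1d, build_unet,
                             extrapolate, make_pairs, train)
from usctfwi.geometry import ring_geometry
from usctfwi.signals import Wavelet
from usctfwi.wavesim import ShotGather, USCTDataset


def synthetic_dataset(n_t=200, n_x=16, seed=0, label="bandlimited", scale=1.0):
    """Small dataset with deterministic pseudo-random traces."""
    rng = np.random.default_rng(seed)
    geom = ring_geometry(8, n_x, 0.104, 1.2e-3)
    gathers = {}
    for sp in (0, 1):
        for se in (0, 5):
            for rp in geom.receive_map[sp][:2]:
                gathers[(sp, se, rp)] = ShotGather(
                    traces=(scale * rng.standard_normal((n_t, n_x))).astype(np.float32),
                    dt=1e-6, source_id=(sp, se), receiver_probe=rp,
                    receiver_ids=[(rp, e) for e in range(n_x)],
                )
    wavelet = Wavelet(np.sin(np.linspace(0, 6, 50)), 1e-6)
    return USCTDataset(gathers, geom, wavelet, label=label)


class TestAugmentationArithmetic:
    def test_printed_training_pool_size(self):
        # 4 datasets x 3072 gathers x 288 shifts x 2 flips
        assert augmentation_count(4, 3072, 288, 2) == 7_077_888

    def test_shift_range_is_half_open(self):
        # +/-144 steps means 288 distinct integer shifts
        assert augmentation_count(1, 1, 2 * 144, 1) == 288

    def test_sampled_augmentations_enumerable(self):
        bl = synthetic_dataset(seed=1)
        bb = synthetic_dataset(seed=2, label="broadband")
        pairs = make_pairs(bl, bb, 400, seed=3, window_t=96, window_x=16,
                           shift=16)
        combos = {(p.provenance[1], p.offset, p.flip) for p in pairs}
        n_gathers = len(bl.gathers)
        assert len(combos) <= n_gathers * 32 * 2
        shifts = {p.offset for p in pairs}
        assert min(shifts) >= -16 and max(shifts) <= 15


class TestMakePairs:
    def test_zero_shift_no_flip_is_central_crop(self):
        bl = synthetic_dataset(seed=1)
        bb = synthetic_dataset(seed=2, label="broadband")
        pairs = make_pairs(bl, bb, 400, seed=0, window_t=96, window_x=16, shift=16)
        for p in pairs:
            if p.offset == 0 and not p.flip:
                key = p.provenance[1]
                base = (200 - 96) // 2
                expected = np.asarray(bl.gathers[key].traces[base:base + 96],
                                      np.float64)
                assert np.array_equal(p.input_window, expected)
                break
        else:
            pytest.skip("no zero-shift unflipped sample drawn")

    def test_flip_twice_is_identity(self):
        bl = synthetic_dataset(seed=1)
        bb = synthetic_dataset(seed=2, label="broadband")
        pairs = make_pairs(bl, bb, 30, seed=0, window_t=96, window_x=16, shift=16)
        flipped = next(p for p in pairs if p.flip)
        assert np.array_equal(flipped.input_window[:, ::-1][:, ::-1],
                              flipped.input_window)

    def test_flip_applied_identically_to_input_and_target(self):
        bl = synthetic_dataset(seed=1)
        bb = synthetic_dataset(seed=2, label="broadband")
        pairs = make_pairs(bl, bb, 60, seed=0, window_t=96, window_x=16, shift=16)
        p = next(p for p in pairs if p.flip)
        key = p.provenance[1]
        base = (200 - 96) // 2 + p.offset
        raw_in = np.asarray(bl.gathers[key].traces[base:base + 96], np.float64)
        raw_tg = np.asarray(bb.gathers[key].traces[base:base + 96], np.float64)
        assert np.array_equal(p.input_window, raw_in[:, ::-1])
        assert np.array_equal(p.target_window, raw_tg[:, ::-1])

    def test_too_short_trace_reports_required_length(self):
        bl = synthetic_dataset(n_t=100, seed=1)
        bb = synthetic_dataset(n_t=100, seed=2, label="broadband")
        with pytest.raises(ValueError, match="at least 128"):
            make_pairs(bl, bb, 5, window_t=96, window_x=16, shift=16)

    def test_deterministic_per_seed(self):
        bl = synthetic_dataset(seed=1)
        bb = synthetic_dataset(seed=2, label="broadband")
        a = make_pairs(bl, bb, 20, seed=5, window_t=96, window_x=16, shift=16)
        b = make_pairs(bl, bb, 20, seed=5, window_t=96, window_x=16, shift=16)
        assert all(np.array_equal(x.input_window, y.input_window)
                   for x, y in zip(a, b))


class TestArchitectures:
    def test_unet_forward_shape_and_finiteness(self):
        model = build_unet(UNetConfig(depth=3, base_channels=4))
        out = model.net.forward(np.zeros((1, 1, 96, 16)), train=False)
        assert out.shape == (1, 1, 96, 16)
        assert np.all(np.isfinite(out))

    def test_unet_parameter_count_grows_with_width(self):
        counts = [build_unet(UNetConfig(depth=2, base_channels=c)).n_parameters()
                  for c in (4, 8, 16)]
        assert counts[0] < counts[1] < counts[2]

    def test_unet_skip_shapes_match_decoder_partners(self):
        model = build_unet(UNetConfig(depth=3, base_channels=4))
        for enc_shape, dec_shape in model.net.encoder_feature_shapes(96, 16):
            assert enc_shape == dec_shape

    def test_unet_incompatible_depth_rejected(self):
        model = build_unet(UNetConfig(depth=5, base_channels=2))
        with pytest.raises(ValueError, match="divisible"):
            model.net.forward(np.zeros((1, 1, 96, 16)))

    def test_cnn1d_has_five_conv_stages(self):
        model = build_cnn1d(CNN1dConfig())
        assert model.net.conv_stages() == 5

    def test_cnn1d_forward_per_trace_equals_stacked(self):
        model = build_cnn1d(CNN1dConfig(channels=(4, 4, 4, 4), kernel=7))
        rng = np.random.default_rng(0)
        window = rng.standard_normal((64, 8))
        full = model.predict_window(window)
        # column-wise application with the shared window normalization
        scale = np.abs(window).max()
        per_trace = np.stack([
            model.net.forward((window[:, k] / scale)[None, None, :],
                              train=False)[0, 0] * scale
            for k in range(8)
        ], axis=1)
        assert np.allclose(full, per_trace, rtol=1e-5, atol=1e-7)

    def test_checkpoint_roundtrip(self, tmp_path):
        model = build_unet(UNetConfig(depth=2, base_channels=3, seed=4))
        model.save(tmp_path / "ckpt")
        back = BandextModel.load(tmp_path / "ckpt")
        x = np.random.default_rng(0).standard_normal((48, 8))
        assert np.allclose(model.predict_window(x), back.predict_window(x))


class TestTraining:
    def make_identity_pairs(self, n=24, shape=(32, 8), seed=0):
        rng = np.random.default_rng(seed)
        return [SamplePair(w, w.copy(), 0, False)
                for w in rng.standard_normal((n,) + shape)]

    def test_identity_task_loss_drops_tenfold(self):
        pairs = self.make_identity_pairs()
        model = build_unet(UNetConfig(depth=2, base_channels=4, seed=0))
        train(model, pairs, epochs=50, lr=2e-3, batch=4, seed=0)
        assert model.history["train"][-1] < 0.1 * model.history["train"][0]

    def test_validation_loss_tracked_and_improves(self):
        pairs = self.make_identity_pairs(n=40)
        model = build_unet(UNetConfig(depth=2, base_channels=4, seed=0))
        train(model, pairs, epochs=30, lr=2e-3, batch=4, seed=0)
        assert len(model.history["val"]) == 30
        assert model.history["val"][-1] < model.history["val"][0]

    def test_fixed_seed_reproduces_loss_curve(self):
        pairs = self.make_identity_pairs()
        h = []
        for _ in range(2):
            model = build_unet(UNetConfig(depth=2, base_channels=4, seed=0))
            train(model, pairs, epochs=5, lr=1e-3, batch=4, seed=7)
            h.append(model.history["train"])
        assert h[0] == h[1]

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="no training pairs"):
            train(build_unet(UNetConfig(depth=2, base_channels=2)), [])


class TestExtrapolate:
    def test_identity_trained_model_roundtrips_dataset(self):
        pairs = [SamplePair(w, w.copy(), 0, False)
                 for w in np.random.default_rng(0).standard_normal((32, 96, 16))]
        model = build_unet(UNetConfig(depth=3, base_channels=6, seed=0))
        train(model, pairs, epochs=60, lr=2e-3, batch=4, seed=0)
        ds = synthetic_dataset(seed=5)
        out = extrapolate(model, ds, window_t=96)
        for key in ds.gathers:
            a = np.asarray(ds.gathers[key].traces, np.float64)
            b = np.asarray(out.gathers[key].traces, np.float64)
            rel = np.linalg.norm(a - b) / np.linalg.norm(a)
            assert rel < 0.35  # identity learned to within training error

    def test_output_label_and_wavelet(self):
        model = build_unet(UNetConfig(depth=2, base_channels=2))
        ds = synthetic_dataset(seed=5)
        new_wavelet = Wavelet(np.ones(10), 1e-6)
        out = extrapolate(model, ds, window_t=96, wavelet=new_wavelet)
        assert out.label == "extrapolated"
        assert np.array_equal(out.wavelet.samples, new_wavelet.samples)

    def test_window_longer_than_trace_rejected(self):
        model = build_unet(UNetConfig(depth=2, base_channels=2))
        ds = synthetic_dataset(n_t=64, seed=5)
        with pytest.raises(ValueError, match="shorter"):
            extrapolate(model, ds, window_t=96)
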