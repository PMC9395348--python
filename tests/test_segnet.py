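from dataclasses import replace

import numpy as np
import pytest

from glottikit.protocols import clips_to_arrays, make_clips
from glottikit.segnet import (SegNetSpec, TrainConfig, build_segnet,
                              decode_latent, extract_latent, filters_at_depth,
                              load_segnet, predict_mask, predict_soft, relu6,
                              train_segnet)
from glottikit.synthetic import ClipSpec

TINY = SegNetSpec(f_base=2, depth=2, latent_channels=1, skips=False,
                  input_height=16, input_width=8)


class TestFiltersAtDepth:
    def test_reference_256(self):
        assert filters_at_depth(16, 4) == 256

    def test_full_unet_1024(self):
        assert filters_at_depth(64, 4) == 1024

    def test_depth_zero(self):
        assert filters_at_depth(16, 0) == 16

    def test_negative_depth_errors(self):
        with pytest.raises(ValueError):
            filters_at_depth(16, -1)

    def test_zero_base_errors(self):
        with pytest.raises(ValueError):
            filters_at_depth(0, 2)


class TestReLU6:
    @pytest.mark.parametrize("x,y", [(7, 6), (-1, 0), (3, 3), (6, 6), (0, 0)])
    def test_scalar(self, x, y):
        assert relu6(x) == y


class TestSpecValidation:
    def test_indivisible_dims_error(self):
        with pytest.raises(ValueError):
            SegNetSpec(depth=4, input_height=100, input_width=64)

    def test_latent_shape_schedule(self):
        spec = SegNetSpec(f_base=16, depth=4, input_height=512,
                          input_width=256)
        assert spec.latent_shape == (32, 16, 256)

    def test_latent_shape_override(self):
        spec = SegNetSpec(f_base=16, depth=4, latent_channels=1,
                          input_height=512, input_width=256)
        assert spec.latent_shape == (32, 16, 1)


class TestBuild:
    def test_depth0_latent_spatial_equals_input(self):
        spec = SegNetSpec(f_base=2, depth=0, latent_channels=1,
                          input_height=8, input_width=8)
        model = build_segnet(spec)
        lat = extract_latent(model, np.zeros((8, 8), np.float32))
        assert lat.shape == (8, 8)

    @pytest.mark.parametrize("f_base", [1, 8, 16])
    @pytest.mark.parametrize("depth", [0, 1, 2, 3, 4])
    def test_channel_schedule_introspection(self, f_base, depth):
        spec = SegNetSpec(f_base=f_base, depth=depth, latent_channels=1,
                          input_height=32, input_width=16)
        model = build_segnet(spec)
        for i in range(depth):
            for block in ("a", "b"):
                node = model.net._by_name[f"enc{i}_{block}_conv"]
                assert node.op.c_out == filters_at_depth(f_base, i)
        bott = model.net._by_name["bott_a_conv"]
        assert bott.op.c_out == filters_at_depth(f_base, depth)

    def test_latent_spatial_division(self):
        model = build_segnet(TINY)
        lat = extract_latent(model, np.zeros((16, 8), np.float32))
        assert lat.shape == (4, 2)

    def test_latent_channels_override(self):
        spec = replace(TINY, latent_channels=3)
        model = build_segnet(spec)
        tape = model.forward(np.zeros((16, 8), np.float32))
        assert tape["latent"].shape == (1, 3, 4, 2)


class TestInference:
    @pytest.mark.parametrize("skips", [False, True])
    def test_decode_extract_identity(self, skips, rng):
        model = build_segnet(replace(TINY, skips=skips), seed=2)
        for _ in range(10):
            f = rng.normal(size=(16, 8)).astype(np.float32)
            full = predict_soft(model, f)
            lat = extract_latent(model, f)
            dec = decode_latent(model, lat, frame=f if skips else None)
            assert np.allclose(dec, full, atol=1e-5)

    def test_decode_skips_without_frame_errors(self, rng):
        model = build_segnet(replace(TINY, skips=True))
        lat = extract_latent(model, rng.normal(size=(16, 8)).astype(np.float32))
        with pytest.raises(ValueError):
            decode_latent(model, lat)

    def test_latent_in_relu6_range(self, rng):
        model = build_segnet(TINY, seed=1)
        lat = extract_latent(model, rng.normal(
            size=(5, 16, 8)).astype(np.float32))
        assert lat.min() >= 0.0 and lat.max() <= 6.0

    def test_decode_wrong_shape_errors(self):
        model = build_segnet(TINY)
        with pytest.raises(ValueError):
            decode_latent(model, np.zeros((3, 3), np.float32))

    def test_predict_mask_binary(self, rng):
        model = build_segnet(TINY)
        m = predict_mask(model, rng.normal(size=(16, 8)).astype(np.float32))
        assert set(np.unique(m)) <= {0, 1}


def _tiny_training_setup(n_clips=3, seed=0):
    tmpl = ClipSpec(height=32, width=16, n_frames=10, flicker=0.0, seed=0)
    clips = make_clips(n_clips, seed, tmpl)
    x, y = clips_to_arrays(clips)
    spec = SegNetSpec(f_base=2, depth=2, latent_channels=1, skips=False,
                      input_height=32, input_width=16)
    return x, y, spec


class TestTraining:
    def test_history_length(self):
        x, y, spec = _tiny_training_setup()
        model = build_segnet(spec, seed=0)
        hist = train_segnet(model, (x, y),
                            TrainConfig(epochs=3, batch_size=8, seed=0))
        assert len(hist) == 3

    def test_determinism(self):
        x, y, spec = _tiny_training_setup()
        finals = []
        for _ in range(2):
            model = build_segnet(spec, seed=0)
            hist = train_segnet(model, (x, y),
                                TrainConfig(epochs=2, batch_size=8, seed=0))
            finals.append(hist["val_iou"].tolist())
        assert finals[0] == finals[1]

    def test_empty_dataset_errors(self):
        _, _, spec = _tiny_training_setup()
        model = build_segnet(spec)
        with pytest.raises(ValueError):
            train_segnet(model, (np.zeros((0, 32, 16)), np.zeros((0, 32, 16))),
                         TrainConfig(epochs=1, seed=0))

    def test_loss_decreases(self):
        x, y, spec = _tiny_training_setup(n_clips=5)
        model = build_segnet(spec, seed=0)
        hist = train_segnet(model, (x, y),
                            TrainConfig(epochs=5, learning_rate=1e-3,
                                        batch_size=8, seed=0))
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_pairs_dataset_accepted(self):
        x, y, spec = _tiny_training_setup()
        model = build_segnet(spec, seed=0)
        pairs = list(zip(x[:20], y[:20]))
        hist = train_segnet(model, pairs, TrainConfig(epochs=1, seed=0))
        assert len(hist) == 1

    def test_skips_do_not_hurt_materially(self):
        # equal budget, tiny scale: best val IoU with skips within 0.05
        # of (or better than) the no-skip run
        tmpl = ClipSpec(height=64, width=32, flicker=0.0, seed=0)
        clips = make_clips(8, 3, tmpl)
        x, y = clips_to_arrays(clips)
        cfg = TrainConfig(epochs=12, learning_rate=1e-3, batch_size=8, seed=0)
        best = {}
        for skips in (False, True):
            spec = SegNetSpec(f_base=4, depth=3, latent_channels=1,
                              skips=skips, input_height=64, input_width=32)
            model = build_segnet(spec, seed=0)
            hist = train_segnet(model, (x, y), cfg)
            best[skips] = hist["val_iou"].max()
        assert best[True] >= best[False] - 0.05


class TestTrainConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"epochs": 0}, {"validation_fraction": 0.0},
        {"validation_fraction": 1.0}, {"optimizer": "sgd"},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)


class TestSerialization:
    def test_save_load_same_predictions(self, tmp_path, rng):
        model = build_segnet(TINY, seed=4)
        f = rng.normal(size=(16, 8)).astype(np.float32)
        before = predict_soft(model, f)
        model.save(tmp_path / "m.npz")
        loaded = load_segnet(tmp_path / "m.npz")
        assert loaded.spec == model.spec
        assert np.allclose(predict_soft(loaded, f), before)


class TestTrainedBehaviour:
    def test_background_frame_mostly_empty(self, desk_net_fl1):
        model, _ = desk_net_fl1
        clip_spec = ClipSpec(height=128, width=64, n_frames=1,
                             max_area_fraction=0.0, flicker=0.0, seed=11)
        from glottikit.synthetic import generate_clip
        frame = generate_clip(clip_spec).frames[0]
        mask = predict_mask(model, frame)
        assert mask.mean() < 0.05
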