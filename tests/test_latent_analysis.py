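import numpy as np
import pytest

from glottikit.latent_analysis import (ALPHA, BETA, GAMMA, classify_subtypes,
                                       latent_stats, make_artificial_latent,
                                       perpixel_gaw_correlation,
                                       perturbation_sweep, subtype_threshold)
from glottikit.metrics import pearson


def percentile_oracle(values, q):
    """Linear interpolation on the sorted array, written independently."""
    s = sorted(values)
    pos = (len(s) - 1) * q / 100.0
    lo = int(pos)
    frac = pos - lo
    if lo + 1 >= len(s):
        return s[-1]
    return s[lo] * (1 - frac) + s[lo + 1] * frac


class TestLatentStats:
    def test_constant_image(self):
        stats = latent_stats([np.full((4, 4), 1.2)])
        assert stats.mean == pytest.approx(1.2)
        assert stats.median == pytest.approx(1.2)
        assert stats.mode == pytest.approx(1.2, abs=1.2 / 256)
        assert stats.max == pytest.approx(1.2)

    def test_pooled_max(self):
        a = np.full((2, 2), 0.9)
        b = np.full((2, 2), 1.45)
        assert latent_stats([a, b]).max == pytest.approx(1.45)

    def test_percentile_interpolation(self):
        stats = latent_stats([np.arange(1.0, 101.0).reshape(10, 10)])
        assert stats.percentile(95) == pytest.approx(95.05)
        assert stats.percentile(95) == pytest.approx(
            percentile_oracle(np.arange(1.0, 101.0), 95))

    def test_counts_sum_to_pixels(self, rng):
        lats = [rng.uniform(0, 2, size=(5, 5)) for _ in range(3)]
        stats = latent_stats(lats)
        assert stats.counts.sum() == 75

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            latent_stats([])


class TestSubtypeThreshold:
    def test_symmetric_distribution(self, rng):
        vals = rng.uniform(0, 1, size=(100, 100))
        t_lo, t_hi = subtype_threshold(latent_stats([vals]))
        assert t_lo + t_hi == pytest.approx(1.0, abs=0.05)

    def test_upper_100_is_max(self):
        stats = latent_stats([np.arange(1.0, 101.0).reshape(10, 10)])
        _, t_hi = subtype_threshold(stats, upper_pct=100)
        assert t_hi == pytest.approx(stats.max)

    def test_values_1_to_100(self):
        stats = latent_stats([np.arange(1.0, 101.0).reshape(10, 10)])
        t_lo, t_hi = subtype_threshold(stats, 95, 5)
        assert (t_lo, t_hi) == (pytest.approx(5.95), pytest.approx(95.05))

    def test_inverted_percentiles_error(self):
        stats = latent_stats([np.ones((2, 2))])
        with pytest.raises(ValueError):
            subtype_threshold(stats, upper_pct=5, lower_pct=95)


class TestClassifySubtypes:
    def test_rule_application(self):
        img = np.array([[0.8, 1.2, 0.1]])
        smap = classify_subtypes(img, 0.5, 0.9)
        assert list(smap.labels[0]) == [BETA, GAMMA, ALPHA]

    def test_uniform_inside_band_all_beta(self):
        smap = classify_subtypes(np.full((3, 3), 0.7), 0.5, 0.9)
        assert np.all(smap.labels == BETA)

    def test_partition_complete(self, rng):
        img = rng.uniform(0, 2, size=(8, 8))
        smap = classify_subtypes(img, 0.5, 1.5)
        assert (smap.count(ALPHA) + smap.count(BETA)
                + smap.count(GAMMA)) == 64

    def test_idempotent(self, rng):
        img = rng.uniform(0, 2, size=(8, 8))
        a = classify_subtypes(img, 0.5, 1.5)
        b = classify_subtypes(img, 0.5, 1.5)
        assert np.array_equal(a.labels, b.labels)

    def test_invalid_thresholds_error(self):
        with pytest.raises(ValueError):
            classify_subtypes(np.ones((2, 2)), 1.0, 0.5)

    def test_palette_rendering(self):
        img = np.array([[0.8, 1.2, 0.1]])
        out = classify_subtypes(img, 0.5, 0.9).to_uint8()
        assert list(out[0]) == [128, 255, 64]


class TestArtificialLatent:
    def test_plain_canvas(self):
        lat = make_artificial_latent(4, 6, 0.8)
        assert lat.shape == (4, 6)
        assert np.all(lat == np.float32(0.8))

    def test_radius_zero_single_pixel(self):
        lat = make_artificial_latent(5, 5, 0.0, blobs=[(2, 3, 0, 1.5)])
        assert lat[3, 2] == np.float32(1.5)
        assert (lat > 0).sum() == 1

    def test_disk_matches_bruteforce(self):
        lat = make_artificial_latent(16, 12, 0.5, blobs=[(8, 4, 2, 2.0)])
        changed = {tuple(p) for p in np.argwhere(lat != np.float32(0.5))}
        expect = {(y, x) for y in range(16) for x in range(12)
                  if (y - 4) ** 2 + (x - 8) ** 2 <= 4}
        assert changed == expect

    def test_ring_between_radii(self):
        lat = make_artificial_latent(16, 16, 0.8,
                                     rings=[(8, 8, 2, 4, 0.2)])
        low = {tuple(p) for p in np.argwhere(lat == np.float32(0.2))}
        expect = {(y, x) for y in range(16) for x in range(16)
                  if 4 < (y - 8) ** 2 + (x - 8) ** 2 <= 16}
        assert low == expect

    def test_later_entries_overwrite(self):
        lat = make_artificial_latent(8, 8, 0.0,
                                     blobs=[(4, 4, 2, 1.0), (4, 4, 1, 2.0)])
        assert lat[4, 4] == np.float32(2.0)

    @pytest.mark.parametrize("kw", [
        {"blobs": [(2, 2, -1, 1.0)]},
        {"blobs": [(2, 2, 1, 7.0)]},
        {"blobs": [(20, 2, 1, 1.0)]},
        {"rings": [(2, 2, 3, 1, 0.5)]},
    ])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            make_artificial_latent(8, 8, 0.5, **kw)


class TestPerturbationSweep:
    def test_row_count(self):
        dec = lambda l: (l > 0.5).astype(float)
        tab = perturbation_sweep(dec, 8, 8,
                                 grid={"x": [2, 4], "radius": [1, 2, 3]})
        assert len(tab) == 6

    def test_unknown_parameter_errors(self):
        with pytest.raises(ValueError):
            perturbation_sweep(lambda l: l, 8, 8, grid={"bogus": [1]})

    def test_centroid_monotone_on_trained_decoder(self, desk_net_fl1):
        from glottikit.segnet import decode_latent
        model, _ = desk_net_fl1
        tab = perturbation_sweep(
            lambda l: decode_latent(model, l), 8, 4,
            grid={"y": [1, 2, 3, 4, 5, 6]},
            base={"beta_value": 0.0, "gamma_value": 4.0, "alpha_value": 0.0,
                  "radius": 1.0, "x": 2})
        cys = tab["centroid_y"].to_numpy()
        assert np.all(np.isfinite(cys))
        assert np.all(np.diff(cys) > 0)

    def test_no_contrast_decodes_empty(self, desk_net_fl1):
        from glottikit.segnet import decode_latent
        model, _ = desk_net_fl1
        tab = perturbation_sweep(
            lambda l: decode_latent(model, l), 8, 4,
            grid={"gamma_value": [0.0]},
            base={"beta_value": 0.0, "alpha_value": 0.0, "radius": 1.0})
        assert tab["area"].iloc[0] <= 0.01 * 128 * 64


class TestPerPixelCorrelation:
    def test_pixel_equal_to_gaw(self, rng):
        g = rng.uniform(0, 10, size=20)
        stack = rng.normal(size=(20, 3, 3))
        stack[:, 1, 1] = g
        cmap = perpixel_gaw_correlation(stack, g)
        assert cmap[1, 1] == pytest.approx(1.0)

    def test_constant_pixel_zero(self, rng):
        g = rng.uniform(0, 10, size=20)
        stack = rng.normal(size=(20, 2, 2))
        stack[:, 0, 0] = 3.14
        assert perpixel_gaw_correlation(stack, g)[0, 0] == 0.0

    def test_matches_loop_oracle(self, rng):
        stack = rng.normal(size=(20, 3, 3))
        g = rng.uniform(0, 5, size=20)
        cmap = perpixel_gaw_correlation(stack, g)
        for i in range(3):
            for j in range(3):
                assert cmap[i, j] == pytest.approx(
                    pearson(stack[:, i, j], g), abs=1e-10)

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError):
            perpixel_gaw_correlation(rng.normal(size=(5, 2, 2)),
                                     np.arange(4))


class TestTrainedLatentProperties:
    def test_modal_bin_dominates(self, desk_net_fl1, desk_test_clips):
        from glottikit.segnet import extract_latent
        model, _ = desk_net_fl1
        lats = [extract_latent(model, c.frames) for c in desk_test_clips]
        stats = latent_stats(lats)
        assert stats.counts.max() / stats.counts.sum() > 0.5

    def test_gamma_pixels_overlap_prediction(self, desk_net_fl1,
                                             desk_test_clips):
        from glottikit.segnet import extract_latent, predict_mask
        model, _ = desk_net_fl1
        lats = [extract_latent(model, c.frames) for c in desk_test_clips]
        stats = latent_stats(lats)
        t_lo, t_hi = subtype_threshold(stats)
        diag = np.hypot(128, 64)
        step = 2 ** model.spec.depth
        checked = ok = 0
        for clip, lat_seq in zip(desk_test_clips, lats):
            for frame, lat in zip(clip.frames, lat_seq):
                if clip.masks.sum() == 0:
                    continue
                gam = classify_subtypes(lat, t_lo, t_hi).labels == GAMMA
                pred = predict_mask(model, frame)
                if gam.sum() == 0 or pred.sum() == 0:
                    continue
                gy, gx = np.argwhere(gam).mean(axis=0) * step
                py, px = np.argwhere(pred == 1).mean(axis=0)
                checked += 1
                ok += np.hypot(gy - py, gx - px) < 0.2 * diag
        assert checked >= 20
        assert ok / checked > 0.9
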