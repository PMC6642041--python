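import numpy as np
import pytest
from hypothesis import given, strategies as st

from histonet.inference import (
    MeanVarMaps,
    TileBox,
    argmax_labels,
    blend_weights,
    foreground_mask,
    merge_tiles,
    predict_image,
    predict_stochastic,
    render_maps,
    tile_grid,
)
from histonet.palette import BLC, MST, NEC, TUM, make_palette


class TestForegroundMask:
    def test_all_white_image_gives_empty_mask(self):
        assert not foreground_mask(np.ones((32, 32, 3))).any()

    def test_dark_disc_on_white_recovered(self):
        img = np.ones((64, 64, 3))
        yy, xx = np.mgrid[:64, :64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        img[disc] = 0.3
        mask = foreground_mask(img)
        iou = (mask & disc).sum() / (mask | disc).sum()
        assert iou >= 0.95

    def test_small_specks_removed(self):
        img = np.ones((32, 32, 3))
        img[4, 4] = 0.0  # single dark pixel, below the object-size floor
        assert not foreground_mask(img).any()


class TestTileGrid:
    def test_100px_image_40px_patch_quarter_overlap(self):
        boxes = tile_grid(100, 100, 40, 0.25)
        row_starts = sorted({b.row0 for b in boxes})
        col_starts = sorted({b.col0 for b in boxes})
        assert row_starts == [0, 30, 60]
        assert col_starts == [0, 30, 60]
        assert len(boxes) == 9

    def test_zero_overlap_exact_tiling(self):
        boxes = tile_grid(80, 80, 40, 0.0)
        assert len(boxes) == 4
        covered = np.zeros((80, 80), dtype=int)
        for b in boxes:
            covered[b.slices] += 1
        assert (covered == 1).all()

    def test_final_box_clamped_to_border(self):
        boxes = tile_grid(90, 90, 40, 0.25)
        assert max(b.row0 + b.height for b in boxes) == 90
        assert max(b.col0 + b.width for b in boxes) == 90

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            tile_grid(30, 30, 40)

    @given(
        st.integers(20, 90),
        st.integers(20, 90),
        st.integers(8, 20),
        st.floats(0.0, 0.75),
    )
    def test_every_pixel_covered(self, h, w, patch, overlap):
        if patch > min(h, w):
            patch = min(h, w)
        boxes = tile_grid(h, w, patch, overlap)
        covered = np.zeros((h, w), dtype=bool)
        for b in boxes:
            covered[b.slices] = True
        assert covered.all()


class TestPredictStochastic:
    def test_single_sample_has_zero_variance(self, tiny_model, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        maps = predict_stochastic(tiny_model, x, n_samples=1, seed=0)
        assert (maps.var == 0).all()

    def test_dropout_free_model_has_zero_variance(self, tiny_model_nodrop, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        maps = predict_stochastic(tiny_model_nodrop, x, n_samples=4, seed=0)
        assert (maps.var == 0).all()

    def test_mean_and_var_match_stored_sample_recomputation(self, tiny_model, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        n = 4
        seed = 5
        samples = [
            tiny_model.forward(x, stochastic=True, rng=seed + k)[0][0] for k in range(n)
        ]
        stack = np.stack([s.astype(np.float64) for s in samples])
        maps = predict_stochastic(tiny_model, x, n_samples=n, seed=seed)
        assert np.abs(maps.mean - stack.mean(axis=0)).max() < 1e-6
        assert np.abs(maps.var - stack.var(axis=0)).max() < 1e-6

    def test_invalid_sample_count_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            predict_stochastic(tiny_model, rng.random((32, 32, 3)), n_samples=0)


class TestMergeTiles:
    def test_constant_tiles_merge_to_constant(self):
        boxes = tile_grid(50, 50, 20, 0.25)
        value = np.zeros((8, 20, 20))
        value[2] = 0.7
        value[0] = 0.3
        tiles = [MeanVarMaps(mean=value.copy(), var=np.zeros_like(value)) for _ in boxes]
        merged = merge_tiles(tiles, boxes, (50, 50))
        assert np.allclose(merged.mean[2], 0.7, atol=1e-9)
        assert np.allclose(merged.mean[0], 0.3, atol=1e-9)

    def test_single_full_tile_is_identity(self, rng):
        boxes = [TileBox(0, 0, 16, 16)]
        raw = rng.random((8, 16, 16))
        mean = raw / raw.sum(axis=0)
        tiles = [MeanVarMaps(mean=mean, var=rng.random((8, 16, 16)))]
        merged = merge_tiles(tiles, boxes, (16, 16))
        assert np.allclose(merged.mean, mean)
        assert np.allclose(merged.var, tiles[0].var)

    @given(st.integers(30, 70), st.integers(10, 25), st.floats(0.0, 0.6))
    def test_weights_form_partition_of_unity(self, size, patch, overlap):
        patch = min(patch, size)
        boxes = tile_grid(size, size, patch, overlap)
        weights = blend_weights(boxes, (size, size))
        assert np.abs(weights.sum(axis=0) - 1.0).max() < 1e-6

    def test_merged_mean_stays_on_simplex(self, rng):
        boxes = tile_grid(40, 40, 16, 0.25)
        tiles = []
        for _ in boxes:
            raw = rng.random((8, 16, 16))
            tiles.append(MeanVarMaps(mean=raw / raw.sum(axis=0), var=np.zeros((8, 16, 16))))
        merged = merge_tiles(tiles, boxes, (40, 40))
        assert np.abs(merged.mean.sum(axis=0) - 1.0).max() < 1e-9

    def test_uncovered_pixel_raises(self):
        boxes = [TileBox(0, 0, 10, 10)]
        tiles = [MeanVarMaps(mean=np.zeros((8, 10, 10)), var=np.zeros((8, 10, 10)))]
        with pytest.raises(ValueError):
            merge_tiles(tiles, boxes, (20, 20))


class TestArgmaxLabels:
    def test_one_hot_map_recovers_class(self):
        mean = np.zeros((8, 4, 4))
        mean[5] = 1.0
        assert (argmax_labels(mean) == 5).all()

    def test_exact_tie_breaks_to_lowest_id(self):
        mean = np.zeros((8, 1, 1))
        mean[TUM] = 0.5
        mean[NEC] = 0.5
        assert argmax_labels(mean)[0, 0] == TUM

    def test_matches_naive_per_pixel_loop(self, rng):
        raw = rng.random((8, 6, 6))
        mean = raw / raw.sum(axis=0)
        labels = argmax_labels(mean)
        for r in range(6):
            for c in range(6):
                assert labels[r, c] == int(np.argmax(mean[:, r, c]))


class TestRenderMaps:
    def _maps_with_var(self, var):
        mean = np.zeros_like(var)
        mean[0] = 1.0
        return MeanVarMaps(mean=mean, var=var)

    def test_equal_blc_nec_variance_renders_light_green(self):
        var = np.zeros((8, 4, 4))
        var[BLC] = 0.2
        var[NEC] = 0.2
        _, vimg = render_maps(self._maps_with_var(var), make_palette())
        assert np.allclose(vimg.vr / vimg.vg, 0.5)
        assert (vimg.vb == 0).all()

    def test_zero_variance_renders_black(self):
        _, vimg = render_maps(self._maps_with_var(np.zeros((8, 4, 4))))
        assert (vimg.rgb == 0).all()

    def test_mst_only_variance_has_no_red(self):
        var = np.zeros((8, 4, 4))
        var[MST] = 0.3
        _, vimg = render_maps(self._maps_with_var(var))
        assert (vimg.vr == 0).all()
        assert vimg.vb.max() == 1.0

    def test_channel_ratios_invariant_to_variance_scale(self, rng):
        var = rng.random((8, 5, 5))
        _, v1 = render_maps(self._maps_with_var(var))
        _, v2 = render_maps(self._maps_with_var(7.3 * var))
        assert np.allclose(v1.rgb, v2.rgb)

    def test_tissue_rgb_uses_palette_colors(self):
        mean = np.zeros((8, 2, 2))
        mean[TUM, 0] = 1.0
        mean[MST, 1] = 1.0
        tissue, _ = render_maps(MeanVarMaps(mean=mean, var=np.zeros_like(mean)))
        assert (tissue[0] == (1.0, 0.0, 0.0)).all()
        assert (tissue[1] == (0.0, 0.0, 1.0)).all()


class TestEndToEnd:
    def test_tiled_stochastic_prediction_preserves_simplex(self, tiny_model, rng):
        image = rng.random((72, 72, 3)).astype(np.float32)
        maps = predict_image(tiny_model, image, patch_size=32, n_samples=2, seed=0)
        assert maps.mean.shape == (8, 72, 72)
        assert np.abs(maps.mean.sum(axis=0) - 1.0).max() < 1e-6
        assert (maps.var >= 0).all()
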