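import numpy as np
import pytest
from hypothesis import given, strategies as st

from histonet.network import (
    HistoNet,
    LossBreakdown,
    NetConfig,
    TrainConfig,
    build_model,
    loss_total,
    train,
    true_distribution,
    save_model,
    load_model,
)
from histonet.palette import N_CLASSES
from histonet.synthetic_data import Rect, SyntheticLayout, synth_tissue_sample


def _small_cfg(**kw):
    base = dict(
        levels=2,
        base_width=8,
        bottleneck_factor=2,
        blocks_per_level=1,
        compression_widths=(4, 6),
        dropout_rate=0.1,
        seed=0,
    )
    base.update(kw)
    return NetConfig(**base)


class TestBuildAndForward:
    def test_output_shapes(self, tiny_model, rng):
        x = rng.random((64, 64, 3)).astype(np.float32)
        probs, dist = tiny_model.forward(x)
        assert probs.shape == (1, N_CLASSES, 64, 64)
        assert dist.shape == (1, N_CLASSES)

    def test_doubling_base_width_increases_parameters(self):
        small = build_model(_small_cfg(base_width=8))
        big = build_model(_small_cfg(base_width=16))
        assert big.n_parameters() > small.n_parameters()

    def test_identical_config_and_seed_give_identical_weights(self):
        m1, m2 = build_model(_small_cfg(seed=5)), build_model(_small_cfg(seed=5))
        for (w1, _), (w2, _) in zip(m1.parameters(), m2.parameters()):
            assert (w1 == w2).all()

    def test_deterministic_forward_is_reproducible(self, tiny_model, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        p1, d1 = tiny_model.forward(x, stochastic=False)
        p2, d2 = tiny_model.forward(x, stochastic=False)
        assert (p1 == p2).all() and (d1 == d2).all()

    def test_pixel_probabilities_on_simplex(self, tiny_model, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        probs, dist = tiny_model.forward(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(dist.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0

    def test_stochastic_passes_differ_across_seeds(self, tiny_model, rng):
        x = rng.random((32, 32, 3)).astype(np.float32)
        p1, _ = tiny_model.forward(x, stochastic=True, rng=0)
        p2, _ = tiny_model.forward(x, stochastic=True, rng=1)
        assert (p1 != p2).any()

    def test_indivisible_spatial_dims_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(rng.random((30, 30, 3)))

    def test_non_rgb_input_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError):
            tiny_model.forward(rng.random((32, 32, 5)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetConfig(levels=3, compression_widths=(4, 6))
        with pytest.raises(ValueError):
            NetConfig(dropout_rate=1.0)


class TestTrueDistribution:
    def test_four_pixel_map(self):
        ann = np.array([[0, 0], [2, 7]])
        dist = true_distribution(ann)
        assert np.allclose(dist, (0.5, 0, 0.25, 0, 0, 0, 0, 0.25))

    def test_constant_map_is_one_hot(self):
        dist = true_distribution(np.full((5, 5), 3))
        expected = np.zeros(8)
        expected[3] = 1.0
        assert np.allclose(dist, expected)

    def test_matches_nested_loop_histogram(self, rng):
        ann = rng.integers(0, 8, (32, 32))
        counts = np.zeros(8)
        for r in range(32):
            for c in range(32):
                counts[ann[r, c]] += 1
        assert np.allclose(true_distribution(ann), counts / counts.sum())

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            true_distribution(np.zeros((0,), dtype=int))
        with pytest.raises(ValueError):
            true_distribution(np.array([[9]]))


def _one_hot_map(ann, eps=0.0):
    c = N_CLASSES
    probs = np.full((c,) + ann.shape, eps / (c - 1) if c > 1 else 0.0)
    for i in range(c):
        probs[i][ann == i] = 1.0 - eps
    return probs


class TestLoss:
    def test_perfect_prediction_has_zero_loss(self):
        ann = np.array([[0, 1], [2, 3]])
        probs = _one_hot_map(ann)
        lb = loss_total(probs, true_distribution(ann), ann)
        assert lb.cce < 1e-6 and lb.ddl < 1e-5 and lb.mse < 1e-12
        assert abs(lb.total - (lb.cce + lb.ddl + lb.mse)) < 1e-12

    def test_uniform_prediction_cce_is_log8(self, rng):
        ann = rng.integers(0, 8, (8, 8))
        probs = np.full((8, 8, 8), 1.0 / 8.0)
        lb = loss_total(probs, np.full(8, 1.0 / 8.0), ann)
        assert abs(lb.cce - np.log(8)) < 1e-9

    def test_terms_match_naive_loop_oracle(self, rng):
        h = w = 6
        ann = rng.integers(0, 8, (h, w))
        raw = rng.random((8, h, w))
        probs = raw / raw.sum(axis=0)
        draw = rng.random(8)
        dist = draw / draw.sum()
        lb = loss_total(probs, dist, ann)
        # CCE loop
        cce = 0.0
        for r in range(h):
            for c in range(w):
                cce -= np.log(max(probs[ann[r, c], r, c], 1e-7))
        cce /= h * w
        # dice loop over present classes
        eps = 1e-6
        dices = []
        for i in np.unique(ann):
            inter = s_p = s_t = 0.0
            for r in range(h):
                for c in range(w):
                    t = 1.0 if ann[r, c] == i else 0.0
                    inter += probs[i, r, c] * t
                    s_p += probs[i, r, c]
                    s_t += t
            dices.append((2 * inter + eps) / (s_p + s_t + eps))
        ddl = 1.0 - np.mean(dices)
        # distribution MSE loop
        td = true_distribution(ann)
        mse = np.mean([(dist[i] - td[i]) ** 2 for i in range(8)])
        assert abs(lb.cce - cce) < 1e-6
        assert abs(lb.ddl - ddl) < 1e-6
        assert abs(lb.mse - mse) < 1e-6

    def test_zero_probability_at_true_class_is_clamped(self):
        ann = np.array([[0]])
        probs = np.zeros((8, 1, 1))
        probs[1] = 1.0
        lb = loss_total(probs, true_distribution(ann), ann)
        assert np.isfinite(lb.cce)

    def test_ddl_is_one_for_disjoint_one_hots(self):
        ann = np.zeros((4, 4), dtype=int)
        probs = _one_hot_map(np.ones((4, 4), dtype=int))  # predicts class 1
        lb = loss_total(probs, true_distribution(ann), ann)
        assert lb.ddl == pytest.approx(1.0, abs=1e-4)

    @given(st.integers(0, 10_000))
    def test_total_additivity_property(self, seed):
        rng = np.random.default_rng(seed)
        ann = rng.integers(0, 8, (4, 4))
        raw = rng.random((8, 4, 4))
        probs = raw / raw.sum(axis=0)
        draw = rng.random(8)
        lb = loss_total(probs, draw / draw.sum(), ann)
        assert lb.total == pytest.approx(lb.cce + lb.ddl + lb.mse, abs=1e-12)
        assert 0.0 <= lb.ddl <= 1.0

    def test_permutation_equivariance(self, rng):
        ann = rng.integers(0, 8, (6, 6))
        raw = rng.random((8, 6, 6))
        probs = raw / raw.sum(axis=0)
        draw = rng.random(8)
        dist = draw / draw.sum()
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        lb1 = loss_total(probs, dist, ann)
        lb2 = loss_total(probs[inv], dist[inv], perm[ann])
        assert lb1.cce == pytest.approx(lb2.cce, abs=1e-12)
        assert lb1.ddl == pytest.approx(lb2.ddl, abs=1e-12)
        assert lb1.mse == pytest.approx(lb2.mse, abs=1e-12)


def _texture_dataset(n=6, size=32, seed=0):
    sets = []
    for i in range(n):
        layout = SyntheticLayout(
            (size, size),
            (
                ((i % 8), Rect(0, 0, size, size)),
                (((i + 3) % 8), Rect(0, size // 2, size, size // 2)),
            ),
        )
        sets.append(synth_tissue_sample(layout, seed=seed + i))
    return sets


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        model = build_model(_small_cfg())
        before = [w.copy() for w, _ in model.parameters()]
        data = _texture_dataset(n=1)
        cfg = TrainConfig(learning_rate=0.0, epochs=1, batch_size=1, seed=0)
        model, _ = train(model, data, cfg)
        for b, (w, _) in zip(before, model.parameters()):
            assert (b == w).all()

    def test_loss_decreases_over_first_five_epochs(self):
        model = build_model(_small_cfg(seed=2))
        data = _texture_dataset(n=6, seed=2)
        cfg = TrainConfig(epochs=5, batch_size=2, seed=2)
        model, history = train(model, data, cfg)
        totals = history["total"].to_numpy()
        assert (np.diff(totals) < 0).all()

    def test_history_has_loss_terms_and_macro_f1(self):
        model = build_model(_small_cfg(seed=3))
        data = _texture_dataset(n=2, seed=3)
        cfg = TrainConfig(epochs=2, batch_size=2, seed=3)
        _, history = train(model, data, cfg)
        assert list(history.columns) == ["epoch", "cce", "ddl", "mse", "total", "macro_f1"]
        assert len(history) == 2
        assert ((history["macro_f1"] >= 0) & (history["macro_f1"] <= 1)).all()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(_small_cfg()), [], TrainConfig())


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(_small_cfg(seed=9))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = rng.random((32, 32, 3)).astype(np.float32)
        p1, d1 = model.forward(x)
        p2, d2 = loaded.forward(x)
        assert np.allclose(p1, p2) and np.allclose(d1, d2)
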