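import numpy as np
import pytest

from aftgnet.model import (
    AttnMLP,
    AttnMLPConfig,
    _backward,
    _forward,
    _init_params,
    cosine_lr,
    cross_entropy,
    tokenize,
    train,
)

TINY = AttnMLPConfig(
    n_tokens=2, token_dim=8, n_heads=2, hidden_dims=(8, 4),
    dropout_rate=0.0, noise_std=0.0, seed=3,
)


def _separable_data(rng, n=200, dim=16, shift=2.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, dim))
    X[y == 1, : dim // 2] += shift
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestTokenize:
    def test_default_geometry(self, rng):
        tokens = tokenize(rng.random(2560))
        assert tokens.shape == (8, 320)

    def test_reshape_roundtrip(self, rng):
        v = rng.random(2560)
        assert np.array_equal(tokenize(v).ravel(), v)

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError):
            tokenize(rng.random(2564))


class TestForward:
    def test_probability_rows_sum_to_one(self, rng):
        params = _init_params(TINY, rng)
        X = rng.normal(size=(7, 2, 8))
        probs, _ = _forward(params, X, TINY, training=False)
        assert probs.shape == (7, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_inference_is_deterministic(self, rng):
        cfg = AttnMLPConfig(**{**TINY.__dict__, "dropout_rate": 0.4, "noise_std": 0.1})
        params = _init_params(cfg, rng)
        X = rng.normal(size=(5, 2, 8))
        p1, _ = _forward(params, X, cfg, training=False)
        p2, _ = _forward(params, X, cfg, training=False)
        assert np.array_equal(p1, p2)

    def test_training_noise_changes_outputs(self, rng):
        cfg = AttnMLPConfig(**{**TINY.__dict__, "noise_std": 0.1})
        params = _init_params(cfg, rng)
        X = rng.normal(size=(5, 2, 8))
        p1, _ = _forward(params, X, cfg, training=True, rng=np.random.default_rng(1))
        p2, _ = _forward(params, X, cfg, training=True, rng=np.random.default_rng(2))
        assert not np.array_equal(p1, p2)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        params = _init_params(TINY, rng)
        X = rng.normal(size=(5, 2, 8))
        y = np.array([0, 1, 1, 0, 1])
        _, cache = _forward(params, X, TINY, training=False)
        grads = _backward(params, cache, y, TINY)
        eps = 1e-6
        for k in params:
            flat_idx = rng.integers(0, params[k].size, size=min(6, params[k].size))
            for fi in np.unique(flat_idx):
                idx = np.unravel_index(fi, params[k].shape)
                orig = params[k][idx]
                params[k][idx] = orig + eps
                lp = cross_entropy(_forward(params, X, TINY, training=False)[0], y)
                params[k][idx] = orig - eps
                lm = cross_entropy(_forward(params, X, TINY, training=False)[0], y)
                params[k][idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), k


class TestSchedule:
    def test_cosine_annealing_endpoints(self):
        assert cosine_lr(1e-3, 0, 100) == pytest.approx(1e-3)
        assert cosine_lr(1e-3, 50, 100) == pytest.approx(5e-4)
        assert cosine_lr(1e-3, 100, 100) == pytest.approx(0.0, abs=1e-18)


class TestTrain:
    def test_learns_linearly_separable_data(self, rng):
        X, y = _separable_data(rng)
        tr, te = np.arange(150), np.arange(150, 200)
        cfg = AttnMLPConfig(
            n_tokens=2, token_dim=8, n_heads=2, hidden_dims=(32, 16),
            dropout_rate=0.1, lr=1e-3, epochs=60, seed=11,
        )
        model, hist = train(X[tr], y[tr], X[te], y[te], cfg)
        acc = float((model.predict(X[te]) == y[te]).mean())
        assert acc >= 0.95
        # independent linear oracle achieves ~1.0 on the same data
        from sklearn.linear_model import LogisticRegression

        lin = LogisticRegression(max_iter=2000).fit(X[tr], y[tr])
        assert lin.score(X[te], y[te]) >= 0.95

    def test_checkpoint_is_best_validation_snapshot(self, rng):
        X, y = _separable_data(rng, n=80)
        tr, te = np.arange(60), np.arange(60, 80)
        cfg = AttnMLPConfig(
            n_tokens=2, token_dim=8, n_heads=2, hidden_dims=(16, 8),
            lr=1e-3, epochs=20, seed=5,
        )
        model, hist = train(X[tr], y[tr], X[te], y[te], cfg)
        reported = float((model.predict(X[te]) == y[te]).mean())
        assert reported == pytest.approx(hist.best_val_acc)
        assert hist.best_val_acc == max(hist.val_acc)

    def test_same_seed_reproduces_training(self, rng):
        X, y = _separable_data(rng, n=60)
        tr, te = np.arange(40), np.arange(40, 60)
        cfg = AttnMLPConfig(
            n_tokens=2, token_dim=8, n_heads=2, hidden_dims=(16, 8),
            lr=1e-3, epochs=10, seed=21,
        )
        m1, h1 = train(X[tr], y[tr], X[te], y[te], cfg)
        m2, h2 = train(X[tr], y[tr], X[te], y[te], cfg)
        assert h1.val_acc == h2.val_acc
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_split_rejected(self, rng):
        X = rng.normal(size=(10, 16))
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError, match="class"):
            train(X, y, X, y, TINY)


class TestSaveLoad:
    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = AttnMLP.initialize(TINY, rng)
        X = rng.normal(size=(3, 16))
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        loaded = AttnMLP.load(path)
        assert np.array_equal(model.predict_proba(X), loaded.predict_proba(X))
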