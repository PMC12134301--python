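"""Conditional GAN: network contracts, objective closed forms, training."""

import numpy as np
import pytest

import kvtrack as kt
from kvtrack.cgan import (
    CGANSegmenter,
    ModelArtifact,
    NetworkConfig,
    TrainConfig,
    _train_arrays,
    build_networks,
    cgan_objective,
)
from kvtrack.nn import Tensor, autodiff as ad

SMALL = dict(image_size=64, base_channels=8, generator_depth=3)


def toy_pairs(n=16, size=64, seed=0):
    """Synthetic pairs: a soft blob whose location determines the mask."""
    rng = np.random.default_rng(seed)
    x = np.zeros((n, size, size))
    y = np.zeros((n, size, size))
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    for i in range(n):
        r0, c0 = rng.integers(size // 4, 3 * size // 4, 2)
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        x[i] = np.exp(-d2 / 50.0) + 0.05 * rng.normal(size=(size, size))
        y[i] = d2 < 36.0
    return np.clip(x, 0, 1), y.astype(float)


class TestBuildNetworks:
    @pytest.mark.parametrize("size", [64, 128])
    def test_generator_preserves_shape_with_bounded_output(self, size):
        cfg = NetworkConfig(image_size=size, base_channels=4, generator_depth=3)
        g, _ = build_networks(cfg, seed=0)
        out = g(Tensor(np.random.default_rng(0).random((2, 1, size, size))))
        assert out.shape == (2, 1, size, size)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_discriminator_patch_grid_is_smaller_than_input(self):
        cfg = NetworkConfig(**SMALL)
        _, d = build_networks(cfg, seed=0)
        scores = d(Tensor(np.zeros((1, 1, 64, 64))), Tensor(np.zeros((1, 1, 64, 64))))
        assert scores.shape[2] < 64 and scores.shape[3] < 64
        assert np.all((scores.data > 0) & (scores.data < 1))

    def test_same_seed_gives_identical_parameters(self):
        cfg = NetworkConfig(**SMALL)
        g1, d1 = build_networks(cfg, seed=42)
        g2, d2 = build_networks(cfg, seed=42)
        for a, b in zip(g1.state_arrays() + d1.state_arrays(), g2.state_arrays() + d2.state_arrays()):
            assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs", [{"image_size": 4, "generator_depth": 4}, {"image_size": 63},
                   {"lambda_l1": -1.0}]
    )
    def test_invalid_configs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**{**SMALL, **kwargs})


class TestObjective:
    def test_closed_form_at_uninformative_discriminator(self):
        """D = 0.5 everywhere with a perfect generator: loss_D = 2 ln 2 and
        the generator loss reduces to its adversarial term ln 2."""
        half = Tensor(np.full((2, 1, 5, 5), 0.5))
        y = Tensor(np.random.default_rng(0).random((2, 1, 8, 8)))
        loss_d, loss_g = cgan_objective(half, half, y, y, lam=100.0)
        assert loss_d.item() == pytest.approx(2 * np.log(2), rel=1e-12)
        assert loss_g.item() == pytest.approx(np.log(2), rel=1e-12)

    def test_l1_term_vanishes_for_perfect_generator(self):
        y = Tensor(np.random.default_rng(1).random((1, 1, 4, 4)))
        d = Tensor(np.full((1, 1, 2, 2), 0.9))
        _, loss_g = cgan_objective(d, d, y, y, lam=100.0)
        assert loss_g.item() == pytest.approx(-np.log(0.9))

    def test_default_l1_weight_is_100(self):
        assert NetworkConfig().lambda_l1 == 100.0

    def test_saturated_scores_are_clamped_to_finite_loss(self):
        zero = Tensor(np.zeros((1, 1, 2, 2)))
        one = Tensor(np.ones((1, 1, 2, 2)))
        y = Tensor(np.zeros((1, 1, 4, 4)))
        loss_d, loss_g = cgan_objective(zero, one, y, y, lam=100.0)
        assert np.isfinite(loss_d.item()) and np.isfinite(loss_g.item())

    def test_loss_terms_are_nonnegative(self, rng):
        d_real = Tensor(rng.uniform(0.1, 0.9, (1, 1, 3, 3)))
        d_fake = Tensor(rng.uniform(0.1, 0.9, (1, 1, 3, 3)))
        y = Tensor(rng.random((1, 1, 6, 6)))
        gx = Tensor(rng.random((1, 1, 6, 6)))
        loss_d, _ = cgan_objective(d_real, d_fake, y, gx, lam=100.0)
        assert loss_d.item() >= 0.0

    def test_dominant_l1_weight_reduces_to_regression_direction(self):
        """With lambda -> infinity the generator gradient aligns with the
        pure-L1 regression gradient (cosine similarity > 0.99)."""
        cfg = NetworkConfig(image_size=16, base_channels=4, generator_depth=2)
        x = Tensor(np.random.default_rng(0).random((2, 1, 16, 16)))
        y = Tensor((np.random.default_rng(1).random((2, 1, 16, 16)) > 0.7).astype(float))

        def grad_vector(lam):
            g, d = build_networks(cfg, seed=5)
            gx = g(x)
            if lam is None:
                loss = ad.mean(ad.abs_(ad.sub(y, gx)))
            else:
                _, loss = cgan_objective(d(x, y), d(x, gx), y, gx, lam)
            g.zero_grad()
            loss.backward()
            vec = np.concatenate([p.grad.ravel() for p in g.parameters()])
            return vec / (lam or 1.0)

        adv = grad_vector(1e6)
        pure = grad_vector(None)
        cos = adv @ pure / (np.linalg.norm(adv) * np.linalg.norm(pure))
        assert cos > 0.99


class TestTraining:
    def test_reconstruction_error_decreases_on_toy_problem(self):
        x, y = toy_pairs(n=16)
        art = _train_arrays(
            x, y, NetworkConfig(**SMALL), TrainConfig(epochs=5, batch_size=4, seed=0)
        )
        assert len(art.history) == 5
        assert art.history[-1]["l1"] < art.history[0]["l1"]

    def test_training_is_deterministic_under_fixed_seed(self):
        x, y = toy_pairs(n=8)
        runs = [
            _train_arrays(
                x, y, NetworkConfig(**SMALL), TrainConfig(epochs=2, batch_size=4, seed=3)
            )
            for _ in range(2)
        ]
        assert runs[0].history == runs[1].history
        for a, b in zip(runs[0].generator.state_arrays(), runs[1].generator.state_arrays()):
            assert np.array_equal(a, b)

    def test_zero_epochs_is_an_invalid_config(self):
        with pytest.raises(ValueError, match="epochs"):
            TrainConfig(epochs=0)

    def test_empty_training_set_is_rejected(self):
        with pytest.raises(ValueError):
            _train_arrays(
                np.zeros((0, 64, 64)), np.zeros((0, 64, 64)),
                NetworkConfig(**SMALL), TrainConfig(epochs=1),
            )

    def test_size_mismatch_is_rejected(self):
        with pytest.raises(ValueError, match="image_size"):
            _train_arrays(
                np.zeros((4, 32, 32)), np.zeros((4, 32, 32)),
                NetworkConfig(**SMALL), TrainConfig(epochs=1),
            )


class TestModelArtifact:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        x, y = toy_pairs(n=8)
        art = _train_arrays(
            x, y, NetworkConfig(**SMALL), TrainConfig(epochs=1, batch_size=4, seed=0)
        )
        art.save(tmp_path / "model.npz")
        loaded = ModelArtifact.load(tmp_path / "model.npz")
        probe = Tensor(x[:2][:, None])
        assert np.allclose(art.generator(probe).data, loaded.generator(probe).data)
        assert loaded.history == art.history


class TestCGANSegmenter:
    def test_sklearn_param_interface_roundtrip(self):
        est = CGANSegmenter(epochs=2, seed=9)
        params = est.get_params()
        assert params["epochs"] == 2 and params["lambda_l1"] == 100.0
        est.set_params(threshold=0.2)
        assert est.threshold == 0.2

    def test_fit_predict_shapes_and_binary_output(self):
        x, y = toy_pairs(n=8)
        est = CGANSegmenter(epochs=1, batch_size=4, seed=0).fit(x, y)
        assert hasattr(est, "generator_")
        pred = est.predict(x[:3])
        assert pred.shape == (3, 64, 64) and pred.dtype == bool
        proba = est.predict_proba(x[:3])
        assert proba.min() >= 0.0 and proba.max() <= 1.0

    def test_predict_before_fit_raises(self):
        with pytest.raises(AttributeError):
            CGANSegmenter().predict(np.zeros((1, 64, 64)))
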