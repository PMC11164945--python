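import numpy as np
import pytest

from fedliver._nn import Dense, ReLU
from fedliver.model import (
    Adam,
    Network,
    PreprocessSpec,
    TrainConfig,
    WeightVector,
    _focal_grad_logit,
    augment,
    build_model,
    focal_loss,
    load_weights,
    local_train,
    preprocess,
    save_weights,
)


class TestWeightVector:
    def test_algebra_and_conformability(self):
        a = WeightVector({"w": np.array([1.0, 2.0]), "b": np.array([3.0])})
        b = WeightVector({"w": np.array([0.5, 0.5]), "b": np.array([1.0])})
        s = a + b.scale(2.0)
        assert np.allclose(s["w"], [2.0, 3.0]) and np.allclose(s["b"], [5.0])
        c = WeightVector({"w": np.array([1.0, 2.0, 3.0]), "b": np.array([3.0])})
        with pytest.raises(ValueError):
            a + c

    def test_save_load_round_trip(self, tmp_path):
        net = build_model("tiny", init_seed=5, input_size=(16, 16))
        w = net.get_weights()
        save_weights(w, str(tmp_path / "ckpt"))
        w2 = load_weights(str(tmp_path / "ckpt"))
        assert w.equal(w2)
        assert list(w.keys()) == list(w2.keys())


class TestPreprocess:
    def test_rectangular_input_padded_then_resized(self):
        img = np.full((434, 636), 128, dtype=np.uint8)
        out = preprocess(img, PreprocessSpec(target_size=(128, 128)))
        assert out.shape == (128, 128, 3)
        assert out.dtype == np.float32
        # zero padding shows up as dark bands at top and bottom after resize
        assert out[0, 64, 0] == 0.0
        assert out[64, 64, 0] == pytest.approx(128 / 255, abs=1e-6)

    def test_constant_255_square_maps_to_ones(self):
        img = np.full((128, 128), 255, dtype=np.uint8)
        out = preprocess(img, PreprocessSpec(target_size=(128, 128)))
        assert np.allclose(out, 1.0)

    def test_square_target_size_input_passes_through(self):
        rngl = np.random.default_rng(0)
        img = rngl.integers(0, 256, (32, 32)).astype(np.uint8)
        out = preprocess(img, PreprocessSpec(target_size=(32, 32)))
        assert np.allclose(out[:, :, 0], img / 255.0, atol=1e-6)
        # geometric part is idempotent: re-applying to the (rescaled) output
        # channel changes nothing
        again = preprocess(out[:, :, 0] * 255.0, PreprocessSpec(target_size=(32, 32)))
        assert np.allclose(again, out, atol=1e-6)

    def test_center_crop(self):
        img = np.zeros((40, 40), dtype=np.uint8)
        img[10:30, 10:30] = 200
        out = preprocess(img, PreprocessSpec(crop_fraction=0.5, target_size=(20, 20)))
        assert np.allclose(out[:, :, 0], 200 / 255, atol=1e-6)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((4, 4, 3)))


class TestAugment:
    def test_rotation_zero_flip_forced_is_involution(self):
        rngl = np.random.default_rng(1)
        t = rngl.random((16, 16, 3)).astype(np.float32)
        flipped = augment(t, np.random.default_rng(0), flip_prob=1.0, rotation_deg=0.0)
        back = augment(flipped, np.random.default_rng(0), flip_prob=1.0, rotation_deg=0.0)
        assert np.allclose(back, t)

    def test_no_flip_no_rotation_is_identity(self):
        t = np.random.default_rng(2).random((16, 16, 3)).astype(np.float32)
        out = augment(t, np.random.default_rng(0), flip_prob=0.0, rotation_deg=0.0)
        assert np.array_equal(out, t)

    def test_deterministic_per_seed(self):
        t = np.random.default_rng(3).random((16, 16, 3)).astype(np.float32)
        a = augment(t, np.random.default_rng(42))
        b = augment(t, np.random.default_rng(42))
        assert np.array_equal(a, b)


class TestBuildModel:
    def test_same_seed_gives_identical_weights(self):
        a = build_model("tiny", init_seed=3, input_size=(32, 32)).get_weights()
        b = build_model("tiny", init_seed=3, input_size=(32, 32)).get_weights()
        assert a.equal(b)
        c = build_model("tiny", init_seed=4, input_size=(32, 32)).get_weights()
        assert not a.allclose(c)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            build_model("resnet", init_seed=0)

    def test_tiny_forward_is_finite_sigmoid(self):
        net = build_model("tiny", init_seed=0, input_size=(32, 32))
        p = net.predict_proba(np.zeros((2, 32, 32, 3), dtype=np.float32))
        assert np.all(np.isfinite(p)) and np.all((p > 0) & (p < 1))

    def test_vgg16_like_forward_in_unit_interval(self):
        net = build_model("vgg16_like", init_seed=0, input_size=(128, 128))
        x = np.random.default_rng(0).random((1, 128, 128, 3), dtype=np.float32)
        p = net.predict_proba(x)
        assert 0 < p[0] < 1


class TestFocalLoss:
    def test_gamma_zero_reduces_to_scaled_bce(self):
        rngl = np.random.default_rng(4)
        p = rngl.uniform(0.05, 0.95, 50)
        y = rngl.integers(0, 2, 50)
        fl = focal_loss(p, y, gamma=0.0, alpha_weight=0.5)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert fl == pytest.approx(0.5 * bce, rel=1e-12)

    def test_hand_worked_example(self):
        # y=1, p=0.9, gamma=2, alpha=0.25: 0.25 * 0.01 * (-ln 0.9)
        expected = 0.25 * 0.1**2 * -np.log(0.9)
        assert focal_loss(0.9, 1, gamma=2.0, alpha_weight=0.25) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(2.634e-4, abs=2e-7)

    def test_loss_vanishes_monotonically_as_p_to_1_for_positive(self):
        ps = [0.5, 0.8, 0.95, 0.999]
        losses = [focal_loss(p, 1) for p in ps]
        assert all(b < a for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-6

    def test_out_of_range_probabilities_clipped_not_fatal(self):
        val = focal_loss(np.array([0.0, 1.0]), np.array([0, 1]))
        assert np.isfinite(val) and val >= 0


class TestGradients:
    def test_backprop_matches_finite_differences_on_toy_network(self):
        """Finite-difference check of focal loss (+ proximal term) gradients."""
        rngl = np.random.default_rng(7)
        net = Network([Dense("d1", 2, 3), ReLU(), Dense("d2", 3, 1)])
        net.init_weights(11)
        X = rngl.random((6, 2)).astype(np.float64)
        y = rngl.integers(0, 2, 6)
        # float64 throughout so the central-difference perturbation is exact
        w0 = net.get_weights().map(lambda v: v.astype(np.float64))
        anchor = w0.map(lambda v: v + 0.05)
        mu, gamma, alpha = 0.7, 2.0, 0.25

        def objective(w: WeightVector) -> float:
            net.set_weights(w)
            z = net.forward_logits(X)
            p = 1 / (1 + np.exp(-z))
            prox = 0.5 * mu * sum(
                float(np.sum((w[k].astype(np.float64) - anchor[k]) ** 2)) for k in w
            )
            return focal_loss(p, y, gamma, alpha) + prox

        net.set_weights(w0)
        z = net.forward_logits(X)
        _, dz = _focal_grad_logit(z, y, gamma, alpha)
        grads = net.backward(dz)
        for k in w0:
            grads[k] = grads[k] + mu * (w0[k] - anchor[k])

        eps = 1e-5
        for name in w0:
            flat = w0[name].ravel()
            for idx in range(min(flat.size, 4)):
                w_plus, w_minus = w0.copy(), w0.copy()
                w_plus[name].ravel()[idx] += eps
                w_minus[name].ravel()[idx] -= eps
                fd = (objective(w_plus) - objective(w_minus)) / (2 * eps)
                an = grads[name].ravel()[idx]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-7), name


@pytest.fixture(scope="module")
def toy():
    rngl = np.random.default_rng(8)
    X = rngl.random((24, 16, 16, 3), dtype=np.float32)
    y = (X.mean(axis=(1, 2, 3)) > X.mean()).astype(int)
    return X, y


class TestLocalTrain:

    def test_zero_learning_rate_is_noop(self, toy):
        cfg = TrainConfig(arch="tiny", input_size=(16, 16), learning_rate=0.0, augment=False)
        net = build_model("tiny", 0, (16, 16))
        w0 = net.get_weights()
        w1 = local_train(w0, toy, cfg, seed=1, network=net)
        assert w0.equal(w1)

    def test_mu_zero_equals_plain_training(self, toy):
        net = build_model("tiny", 0, (16, 16))
        w0 = net.get_weights()
        cfg = TrainConfig(arch="tiny", input_size=(16, 16), learning_rate=1e-3, augment=False)
        a = local_train(w0, toy, cfg, global_anchor=w0, seed=3, network=net)
        b = local_train(w0, toy, cfg.with_(prox_mu=0.0), global_anchor=w0.scale(2.0), seed=3, network=net)
        assert a.equal(b)

    def test_large_mu_keeps_weights_near_anchor(self, toy):
        """The proximal term dominates as mu grows: the distance to the anchor
        shrinks by orders of magnitude, saturating at the adaptive optimizer's
        per-step size for extreme mu."""
        net = build_model("tiny", 0, (16, 16))
        w0 = net.get_weights()
        cfg = TrainConfig(
            arch="tiny",
            input_size=(16, 16),
            learning_rate=1e-3,
            augment=False,
            batch_size=6,
            local_epochs=3,
        )
        dists = []
        for mu in (1.0, 1e2, 1e6):
            w = local_train(w0, toy, cfg.with_(prox_mu=mu), global_anchor=w0, seed=3, network=net)
            dists.append((w - w0).norm())
        assert dists[1] < 0.5 * dists[0]
        assert dists[2] < 0.5 * dists[0]
        assert dists[2] <= 1.05 * dists[1]

    def test_optimization_learns_separable_toy_problem(self):
        """A dense head on a linearly separable 2-feature set reaches
        training AUC > 0.95 within 50 epochs."""
        from fedliver.evalstats import ScoreSet, roc_auc

        rngl = np.random.default_rng(9)
        n = 60
        X2 = np.vstack(
            [rngl.normal(-1.0, 0.5, (n // 2, 2)), rngl.normal(1.0, 0.5, (n // 2, 2))]
        ).astype(np.float32)
        y = np.repeat([0, 1], n // 2)
        net = Network([Dense("d1", 2, 8), ReLU(), Dense("d2", 8, 1)])
        net.init_weights(21)
        w = net.get_weights()
        cfg = TrainConfig(
            arch="tiny", batch_size=16, learning_rate=0.01, local_epochs=50, augment=False
        )
        w = local_train(w, (X2, y), cfg, seed=2, network=net)
        net.set_weights(w)
        p = net.predict_proba(X2)
        assert roc_auc(ScoreSet(p, y)) > 0.95

    def test_empty_site_rejected(self):
        cfg = TrainConfig(arch="tiny", input_size=(16, 16))
        net = build_model("tiny", 0, (16, 16))
        with pytest.raises(ValueError, match="empty|no images"):
            local_train(
                net.get_weights(),
                (np.empty((0, 16, 16, 3), dtype=np.float32), np.empty(0, int)),
                cfg,
                network=net,
            )


def test_adam_moves_against_gradient_direction():
    w = WeightVector({"x": np.array([1.0, -1.0], dtype=np.float32)})
    opt = Adam(lr=0.1)
    g = {"x": np.array([1.0, -1.0], dtype=np.float32)}
    w2 = opt.step(w, g)
    assert w2["x"][0] < 1.0 and w2["x"][1] > -1.0
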