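import numpy as np
import pytest

from fedliver.fedsim import (
    ServerHParams,
    ServerState,
    derive_seed,
    fedavg_aggregate,
    fedavgm_update,
    fedyogi_update,
    run_centralized,
    run_federated,
    run_single_site,
)
from fedliver.model import TrainConfig, WeightVector, build_model

from conftest import make_pool


def wv(x: float) -> WeightVector:
    return WeightVector({"w": np.array([x], dtype=np.float64)})


@pytest.fixture(scope="module")
def small_sites():
    """Two tiny sites with mean-intensity-separable 12x12 images."""
    rngl = np.random.default_rng(31)

    def make_site(n):
        y = rngl.integers(0, 2, n)
        X = rngl.random((n, 16, 16, 3), dtype=np.float32) * 0.4 + y[:, None, None, None] * 0.3
        return X.astype(np.float32), y

    return [make_site(12), make_site(18)]


@pytest.fixture(scope="module")
def tiny_train_config():
    return TrainConfig(
        arch="tiny", input_size=(16, 16), learning_rate=1e-3, augment=False, batch_size=8
    )


class TestFedAvgAggregate:
    def test_identical_weights_are_a_fixed_point(self):
        w = WeightVector({"a": np.array([1.5, -2.0]), "b": np.array([0.25])})
        agg = fedavg_aggregate([w, w.copy(), w.copy()], [5, 17, 3])
        assert agg.allclose(w, atol=1e-12)

    def test_scalar_hand_example_with_study_counts(self):
        # sites of 42 and 146 patients holding scalar weights 1.0 and 0.0
        agg = fedavg_aggregate([wv(1.0), wv(0.0)], [42, 146])
        assert agg["w"][0] == pytest.approx(42 / 188, abs=1e-12)

    def test_single_site_unchanged(self):
        w = wv(0.123456789)
        assert fedavg_aggregate([w], [99]).allclose(w, atol=0)

    def test_envelope_property(self):
        rngl = np.random.default_rng(5)
        ws = [WeightVector({"x": rngl.normal(size=7)}) for _ in range(4)]
        sizes = [3, 1, 4, 2]
        agg = fedavg_aggregate(ws, sizes)
        stack = np.stack([w["x"] for w in ws])
        assert np.all(agg["x"] >= stack.min(axis=0) - 1e-12)
        assert np.all(agg["x"] <= stack.max(axis=0) + 1e-12)

    def test_permutation_invariance(self):
        rngl = np.random.default_rng(6)
        ws = [WeightVector({"x": rngl.normal(size=5)}) for _ in range(3)]
        sizes = [2, 7, 5]
        a = fedavg_aggregate(ws, sizes)
        b = fedavg_aggregate([ws[2], ws[0], ws[1]], [5, 2, 7])
        assert a.allclose(b, atol=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([], [])
        with pytest.raises(ValueError):
            fedavg_aggregate([wv(1.0)], [1, 2])
        with pytest.raises(ValueError):
            fedavg_aggregate([wv(1.0)], [0])


class TestFedAvgM:
    def test_scalar_hand_example(self):
        # w=1.0, w_fedavg=0.6, v=0.2, beta=0.9, eta=1:
        # delta=0.4, v'=0.58, w'=0.42
        state = ServerState(
            "fedavgm",
            wv(1.0),
            ServerHParams(server_momentum=0.9, server_lr=1.0),
            momentum_buffer=wv(0.2),
        )
        new = fedavgm_update(state, wv(0.6))
        assert new.momentum_buffer["w"][0] == pytest.approx(0.58, abs=1e-12)
        assert new.global_weights["w"][0] == pytest.approx(0.42, abs=1e-12)
        assert new.round_index == 1

    def test_zero_momentum_unit_lr_reduces_to_fedavg(self):
        state = ServerState(
            "fedavgm", wv(0.731), ServerHParams(server_momentum=0.0, server_lr=1.0)
        )
        new = fedavgm_update(state, wv(0.299))
        assert new.global_weights["w"][0] == 0.299

    def test_stationary_point(self):
        state = ServerState("fedavgm", wv(0.5))
        new = fedavgm_update(state, wv(0.5))
        assert new.global_weights["w"][0] == pytest.approx(0.5, abs=0)


class TestFedYogi:
    def test_scalar_hand_example(self):
        # w=1.0, w_fedavg=1.5, m=0, v=0.1, b1=0.9, b2=0.99, eta=0.1, tau=1e-3
        state = ServerState(
            "fedyogi",
            wv(1.0),
            ServerHParams(yogi_beta1=0.9, yogi_beta2=0.99, yogi_lr=0.1, yogi_tau=1e-3),
            first_moment=wv(0.0),
            second_moment=wv(0.1),
        )
        new = fedyogi_update(state, wv(1.5))
        assert new.first_moment["w"][0] == pytest.approx(0.05, abs=1e-12)
        assert new.second_moment["w"][0] == pytest.approx(0.1025, abs=1e-12)
        expected = 1.0 + 0.1 * 0.05 / (np.sqrt(0.1025) + 1e-3)
        assert new.global_weights["w"][0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0156, abs=5e-5)

    def test_stationary_when_delta_and_momentum_zero(self):
        state = ServerState("fedyogi", wv(2.0), first_moment=wv(0.0), second_moment=wv(0.04))
        new = fedyogi_update(state, wv(2.0))
        assert new.global_weights["w"][0] == pytest.approx(2.0, abs=0)

    def test_second_moment_fixed_point_with_sign_zero(self):
        # v == delta^2 everywhere: sign(0) = 0 leaves v unchanged
        state = ServerState("fedyogi", wv(0.0), first_moment=wv(0.0), second_moment=wv(0.25))
        new = fedyogi_update(state, wv(0.5))  # delta = 0.5, delta^2 = 0.25
        assert new.second_moment["w"][0] == pytest.approx(0.25, abs=0)

    def test_default_initialization_is_tau_squared(self):
        state = ServerState("fedyogi", wv(1.0))
        assert state.second_moment["w"][0] == pytest.approx(1e-6, abs=0)


class TestReductions:
    def test_fedavgm_beta0_eta1_equals_fedavg_bitwise(self, small_sites, tiny_train_config):
        """FedAvgM with beta=0 and eta=1 reproduces FedAvg exactly over rounds."""
        hp = ServerHParams(server_momentum=0.0, server_lr=1.0)
        w_a, _ = run_federated(small_sites, "fedavg", 3, tiny_train_config, hp, trial_seed=5)
        w_m, _ = run_federated(small_sites, "fedavgm", 3, tiny_train_config, hp, trial_seed=5)
        assert w_a.equal(w_m)

    def test_fedprox_mu0_equals_fedavg_bitwise(self, small_sites, tiny_train_config):
        hp = ServerHParams(prox_mu=0.0)
        w_a, _ = run_federated(small_sites, "fedavg", 3, tiny_train_config, hp, trial_seed=5)
        w_p, _ = run_federated(small_sites, "fedprox", 3, tiny_train_config, hp, trial_seed=5)
        assert w_a.equal(w_p)

    def test_fedprox_with_positive_mu_differs_from_fedavg(self, small_sites, tiny_train_config):
        hp = ServerHParams(prox_mu=0.5)
        w_a, _ = run_federated(small_sites, "fedavg", 2, tiny_train_config, hp, trial_seed=5)
        w_p, _ = run_federated(small_sites, "fedprox", 2, tiny_train_config, hp, trial_seed=5)
        assert not w_a.equal(w_p)


class TestRoundLoop:
    def test_identical_sites_synchronized_seeds_aggregate_to_local_result(
        self, small_sites, tiny_train_config
    ):
        from fedliver.model import local_train

        X, y = small_sites[0]
        net = build_model("tiny", 0, (16, 16))
        w0 = net.get_weights()
        w_local = local_train(w0, (X, y), tiny_train_config, seed=77, network=net)
        w_twin = local_train(w0, (X, y), tiny_train_config, seed=77, network=net)
        agg = fedavg_aggregate([w_local, w_twin], [len(X), len(X)])
        assert agg.allclose(w_local, atol=1e-7)

    def test_centralized_equals_one_site_federated(self, small_sites, tiny_train_config):
        pooled = (
            np.concatenate([small_sites[0][0], small_sites[1][0]]),
            np.concatenate([small_sites[0][1], small_sites[1][1]]),
        )
        w_c, logs_c = run_centralized(pooled, 2, tiny_train_config, trial_seed=9)
        w_f, logs_f = run_federated([pooled], "fedavg", 2, tiny_train_config, trial_seed=9)
        assert w_c.equal(w_f)
        assert [l.n for l in logs_c] == [l.n for l in logs_f]

    def test_deterministic_given_trial_seed(self, small_sites, tiny_train_config):
        w1, _ = run_federated(small_sites, "fedavg", 2, tiny_train_config, trial_seed=4)
        w2, _ = run_federated(small_sites, "fedavg", 2, tiny_train_config, trial_seed=4)
        assert w1.equal(w2)
        w3, _ = run_federated(small_sites, "fedavg", 2, tiny_train_config, trial_seed=5)
        assert not w1.equal(w3)

    def test_empty_sites_skipped_and_all_empty_rejected(self, small_sites, tiny_train_config):
        empty = (np.empty((0, 16, 16, 3), dtype=np.float32), np.empty(0, int))
        w_with, _ = run_federated(
            [small_sites[0], empty], "fedavg", 1, tiny_train_config, trial_seed=2
        )
        w_alone, _ = run_federated([small_sites[0]], "fedavg", 1, tiny_train_config, trial_seed=2)
        assert w_with.equal(w_alone)
        with pytest.raises(ValueError):
            run_federated([empty], "fedavg", 1, tiny_train_config)

    def test_eval_logging(self, small_sites, tiny_train_config):
        X = np.concatenate([small_sites[0][0], small_sites[1][0]])
        y = np.concatenate([small_sites[0][1], small_sites[1][1]])
        _, logs = run_federated(
            small_sites, "fedavg", 2, tiny_train_config, eval_data=(X, y), trial_seed=1
        )
        assert len(logs) == 2
        assert logs[0].n == 30 and logs[0].site_sizes == [12, 18]
        assert 0 <= logs[-1].accuracy <= 1 and 0 <= logs[-1].auc <= 1


class TestSingleSite:
    def test_filters_private_like_patients(self, default_split, tiny_train_config):
        pool = default_split.train_patients
        seen = {}

        def materialize(patients):
            seen["n"] = len(patients)
            rngl = np.random.default_rng(0)
            X = rngl.random((len(patients), 16, 16, 3), dtype=np.float32)
            y = np.array([p.label for p in patients])
            return X, y

        run_single_site(pool, materialize, 1, tiny_train_config, trial_seed=1)
        # 153 private-like patients minus 10 in the test split
        assert seen["n"] == 143

    def test_no_matching_patients_rejected(self, tiny_train_config):
        pool = make_pool(3, 3, site="public_like")
        with pytest.raises(ValueError, match="private_like"):
            run_single_site(pool, lambda p: None, 1, tiny_train_config)


def test_derive_seed_stable_distinct_and_in_range():
    s = derive_seed(3, 7, 1)
    assert s == derive_seed(3, 7, 1)
    assert len({derive_seed(3, r, i) for r in range(5) for i in range(4)}) == 20
    assert 0 <= s < 2**31
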