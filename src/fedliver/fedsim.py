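"""In-process federated learning simulation: one server, N sites.

Server aggregation rules implemented on plain named-tensor weight vectors:

* FedAvg — sample-size weighted average of the site weights.
* FedAvgM — server momentum on the pseudo-gradient
  Delta_t = w^{t-1} - w_FedAvg; v^t = beta v^{t-1} + Delta_t;
  w^t = w^{t-1} - eta v^t.
* FedYogi — adaptive server optimizer with the opposite sign convention,
  Delta_t = w_FedAvg - w^{t-1}; m^t = beta1 m^{t-1} + (1-beta1) Delta_t;
  v^t = v^{t-1} - (1-beta2) Delta_t^2 sign(v^{t-1} - Delta_t^2);
  w^t = w^{t-1} + eta m^t / (sqrt(v^t) + tau).
* FedProx — server side identical to FedAvg; the proximal term lives in the
  local objective (model.local_train with prox_mu > 0).

The round loop replaces a networked deployment with a deterministic
in-process simulation: broadcast, local training at every nonempty site,
aggregation, server update, evaluation on a fixed test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import evalstats
from .model import Network, TrainConfig, WeightVector, build_model, local_train

ALGORITHMS = ("fedavg", "fedavgm", "fedyogi", "fedprox")


@dataclass(frozen=True)
class ServerHParams:
    """Server-side hyperparameters (defaults follow the originating papers)."""

    server_lr: float = 1.0  # eta (FedAvgM); FedYogi overrides via yogi_lr
    server_momentum: float = 0.9  # beta
    yogi_beta1: float = 0.9
    yogi_beta2: float = 0.99
    yogi_tau: float = 1e-3
    yogi_lr: float = 1e-2
    prox_mu: float = 0.01


@dataclass
class ServerState:
    """Round counter plus the server-side optimizer buffers."""

    algorithm: str
    global_weights: WeightVector
    hparams: ServerHParams = field(default_factory=ServerHParams)
    round_index: int = 0
    momentum_buffer: WeightVector | None = None  # FedAvgM v
    first_moment: WeightVector | None = None  # FedYogi m
    second_moment: WeightVector | None = None  # FedYogi v

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.momentum_buffer is None:
            self.momentum_buffer = self.global_weights.zeros_like()
        if self.first_moment is None:
            self.first_moment = self.global_weights.zeros_like()
        if self.second_moment is None:
            # tau^2 keeps sqrt(v) + tau well conditioned at the first update
            tau = self.hparams.yogi_tau
            self.second_moment = self.global_weights.map(
                lambda v: np.full_like(v, tau * tau, dtype=np.float64)
            )


@dataclass(frozen=True)
class RoundLog:
    round_index: int
    site_sizes: list[int]
    n: int
    accuracy: float
    auc: float


def fedavg_aggregate(
    site_weights: list[WeightVector], site_sizes: list[int]
) -> WeightVector:
    """Sample-size weighted average: w = sum_i (n_i / n) w_i."""
    if not site_weights:
        raise ValueError("no site weights to aggregate")
    if len(site_weights) != len(site_sizes):
        raise ValueError("site_weights and site_sizes length mismatch")
    if any(s <= 0 for s in site_sizes):
        raise ValueError("site sizes must be positive")
    n = float(sum(site_sizes))
    out = site_weights[0].scale(site_sizes[0] / n)
    for w, s in zip(site_weights[1:], site_sizes[1:]):
        out = out + w.scale(s / n)
    return out


def fedavgm_update(state: ServerState, fedavg_result: WeightVector) -> ServerState:
    """Server momentum step on Delta_t = w^{t-1} - w_FedAvg.

    Arithmetic runs in float64 and is cast back to the weight dtype, so the
    beta=0, eta=1 case recovers the FedAvg result exactly.
    """
    hp = state.hparams
    w64 = state.global_weights.map(lambda v: v.astype(np.float64))
    delta = w64.zip_with(fedavg_result, lambda w, f: w - f.astype(np.float64))
    momentum = state.momentum_buffer.zip_with(
        delta, lambda v, d: hp.server_momentum * v.astype(np.float64) + d
    )
    new_weights = state.global_weights.zip_with(
        w64.zip_with(momentum, lambda w, m: w - hp.server_lr * m),
        lambda old, new: new.astype(old.dtype),
    )
    return replace(
        state,
        global_weights=new_weights,
        momentum_buffer=momentum,
        round_index=state.round_index + 1,
    )


def fedyogi_update(state: ServerState, fedavg_result: WeightVector) -> ServerState:
    """Adaptive server step; note the sign of Delta_t is opposite to FedAvgM."""
    hp = state.hparams
    delta = fedavg_result - state.global_weights
    m = state.first_moment.scale(hp.yogi_beta1) + delta.scale(1 - hp.yogi_beta1)
    delta_sq = delta.map(lambda v: v.astype(np.float64) ** 2)
    v = state.second_moment.zip_with(
        delta_sq, lambda vv, d2: vv - (1 - hp.yogi_beta2) * d2 * np.sign(vv - d2)
    )
    if any(np.any(t <= 0) for _, t in v.items()):
        raise FloatingPointError(
            "FedYogi second moment became non-positive; check tau/initialization"
        )
    step = m.zip_with(v, lambda mm, vv: hp.yogi_lr * mm / (np.sqrt(vv) + hp.yogi_tau))
    new_weights = state.global_weights.zip_with(
        step, lambda w, s: (w.astype(np.float64) + s).astype(w.dtype)
    )
    return replace(
        state,
        global_weights=new_weights,
        first_moment=m,
        second_moment=v,
        round_index=state.round_index + 1,
    )


def server_update(state: ServerState, fedavg_result: WeightVector) -> ServerState:
    if state.algorithm in ("fedavg", "fedprox"):
        return replace(
            state, global_weights=fedavg_result, round_index=state.round_index + 1
        )
    if state.algorithm == "fedavgm":
        return fedavgm_update(state, fedavg_result)
    return fedyogi_update(state, fedavg_result)


def derive_seed(trial_seed: int, round_index: int, site_index: int) -> int:
    """Counter-based per-(trial, round, site) seed, stable across runs."""
    ss = np.random.SeedSequence([int(trial_seed), int(round_index), int(site_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (1 << 31))


def evaluate(network: Network, weights: WeightVector, eval_data) -> tuple[float, float]:
    """(accuracy at 0.5, ROC AUC) of the given weights on (X, y)."""
    X, y = eval_data[0], eval_data[1]
    network.set_weights(weights)
    p = network.predict_proba(X)
    acc = float(np.mean((p >= 0.5).astype(int) == y))
    auc = evalstats.roc_auc(evalstats.ScoreSet(p, y))
    return acc, auc


def run_federated(
    site_data: list[tuple[np.ndarray, np.ndarray]],
    algorithm: str,
    rounds: int,
    config: TrainConfig,
    server_hparams: ServerHParams | None = None,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    trial_seed: int = 0,
) -> tuple[WeightVector, list[RoundLog]]:
    """Simulate ``rounds`` federated rounds and return final global weights.

    ``site_data`` holds one (X, y) pair per site (preprocessed tensors).
    Empty sites are skipped in every round. FedProx sets the proximal
    coefficient from ``server_hparams.prox_mu``; its server step is FedAvg.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    nonempty = [i for i, (X, _) in enumerate(site_data) if len(X) > 0]
    if not nonempty:
        raise ValueError("all sites are empty")
    hp = server_hparams or ServerHParams()
    if algorithm == "fedprox":
        config = config.with_(prox_mu=hp.prox_mu)
    network = build_model(config.arch, config.init_seed, config.input_size)
    state = ServerState(
        algorithm=algorithm, global_weights=network.get_weights(), hparams=hp
    )
    logs: list[RoundLog] = []
    for t in range(1, rounds + 1):
        broadcast = state.global_weights
        site_weights, site_sizes = [], []
        for i in nonempty:
            X, y = site_data[i]
            w = local_train(
                broadcast,
                (X, y),
                config,
                global_anchor=broadcast,
                seed=derive_seed(trial_seed, t, i),
                network=network,
            )
            site_weights.append(w)
            site_sizes.append(len(X))
        aggregate = fedavg_aggregate(site_weights, site_sizes)
        state = server_update(state, aggregate)
        if eval_data is not None:
            acc, auc = evaluate(network, state.global_weights, eval_data)
        else:
            acc = auc = float("nan")
        logs.append(
            RoundLog(
                round_index=t,
                site_sizes=list(site_sizes),
                n=int(sum(site_sizes)),
                accuracy=acc,
                auc=auc,
            )
        )
    return state.global_weights, logs


def run_centralized(
    train_data: tuple[np.ndarray, np.ndarray],
    rounds: int,
    config: TrainConfig,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    trial_seed: int = 0,
) -> tuple[WeightVector, list[RoundLog]]:
    """Ordinary pooled training, expressed as a one-site FedAvg run."""
    if len(train_data[0]) == 0:
        raise ValueError("centralized training pool is empty")
    return run_federated(
        [train_data], "fedavg", rounds, config, eval_data=eval_data, trial_seed=trial_seed
    )


def run_single_site(
    pool,
    materialize,
    rounds: int,
    config: TrainConfig,
    eval_data: tuple[np.ndarray, np.ndarray] | None = None,
    trial_seed: int = 0,
    site_of_origin: str = "private_like",
) -> tuple[WeightVector, list[RoundLog]]:
    """Single-center baseline: train only on patients from one origin site.

    ``materialize`` maps a patient list to an (X, y) pair.
    """
    local = [p for p in pool if p.site_of_origin == site_of_origin]
    if not local:
        raise ValueError(f"no patients with site_of_origin={site_of_origin!r}")
    return run_centralized(materialize(local), rounds, config, eval_data, trial_seed)
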