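"""Preprocessing, augmentation, classifier networks, focal loss, local training.

The classifier family consists of a VGG16-style convolutional network (the
configuration used at clinical scale: 128x128x3 input, sigmoid scalar output)
and a tiny three-conv-block variant for desk-scale experiments. Both are
implemented on the in-package layer stack so that model weights are ordinary
named numpy tensors (:class:`WeightVector`) — the unit of exchange between
simulated sites and the server.

Local (per-site) training minimizes the focal loss; with ``prox_mu > 0`` the
FedProx proximal term (mu/2)||w - w_global||^2 is added to the objective,
contributing mu * (w - w_global) to every gradient step.
"""

from __future__ import annotations

import json
import logging
import os
from collections import OrderedDict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from ._nn import Conv2D, Dense, Flatten, Layer, MaxPool2, ReLU

logger = logging.getLogger(__name__)

_EPS = 1e-7


class WeightVector:
    """Ordered set of named numeric tensors with elementwise arithmetic.

    Two WeightVectors are conformable iff they hold the same names with the
    same shapes in the same order; all arithmetic (addition, scaling,
    elementwise ops) preserves names and order.
    """

    def __init__(self, tensors: "OrderedDict[str, np.ndarray] | dict[str, np.ndarray]"):
        self._t = OrderedDict((k, np.asarray(v)) for k, v in tensors.items())

    # -- container protocol -------------------------------------------------
    def __iter__(self):
        return iter(self._t)

    def __len__(self) -> int:
        return len(self._t)

    def __getitem__(self, name: str) -> np.ndarray:
        return self._t[name]

    def items(self):
        return self._t.items()

    def keys(self):
        return self._t.keys()

    # -- algebra ------------------------------------------------------------
    def conformable(self, other: "WeightVector") -> bool:
        return list(self.keys()) == list(other.keys()) and all(
            self[k].shape == other[k].shape for k in self
        )

    def _require_conformable(self, other: "WeightVector") -> None:
        if not isinstance(other, WeightVector) or not self.conformable(other):
            raise ValueError("WeightVectors are not conformable")

    def map(self, fn) -> "WeightVector":
        return WeightVector(OrderedDict((k, fn(v)) for k, v in self.items()))

    def zip_with(self, other: "WeightVector", fn) -> "WeightVector":
        self._require_conformable(other)
        return WeightVector(OrderedDict((k, fn(self[k], other[k])) for k in self))

    def __add__(self, other: "WeightVector") -> "WeightVector":
        return self.zip_with(other, np.add)

    def __sub__(self, other: "WeightVector") -> "WeightVector":
        return self.zip_with(other, np.subtract)

    def scale(self, a: float) -> "WeightVector":
        return self.map(lambda v: a * v)

    def __mul__(self, a: float) -> "WeightVector":
        return self.scale(float(a))

    __rmul__ = __mul__

    def copy(self) -> "WeightVector":
        return self.map(np.copy)

    def norm(self) -> float:
        return float(np.sqrt(sum(float(np.sum(v.astype(np.float64) ** 2)) for v in self._t.values())))

    def allclose(self, other: "WeightVector", **kw) -> bool:
        self._require_conformable(other)
        return all(np.allclose(self[k], other[k], **kw) for k in self)

    def equal(self, other: "WeightVector") -> bool:
        self._require_conformable(other)
        return all(np.array_equal(self[k], other[k]) for k in self)

    def zeros_like(self) -> "WeightVector":
        return self.map(np.zeros_like)

    def is_finite(self) -> bool:
        return all(np.all(np.isfinite(v)) for v in self._t.values())


def save_weights(weights: WeightVector, directory: str) -> str:
    """Persist a WeightVector as one .npy per tensor plus an index manifest."""
    os.makedirs(directory, exist_ok=True)
    index = []
    for i, (name, v) in enumerate(weights.items()):
        fname = f"tensor_{i:03d}.npy"
        np.save(os.path.join(directory, fname), v)
        index.append({"name": name, "file": fname, "shape": list(v.shape), "dtype": str(v.dtype)})
    path = os.path.join(directory, "index.json")
    with open(path, "w") as fh:
        json.dump(index, fh, indent=1)
    return path


def load_weights(directory: str) -> WeightVector:
    with open(os.path.join(directory, "index.json")) as fh:
        index = json.load(fh)
    return WeightVector(
        OrderedDict(
            (e["name"], np.load(os.path.join(directory, e["file"]))) for e in index
        )
    )


# ---------------------------------------------------------------------------
# preprocessing / augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreprocessSpec:
    """Zero-pad to square, resize, scale to [0,1], replicate to 3 channels."""

    crop_fraction: float | None = None
    target_size: tuple[int, int] = (128, 128)
    channels: int = 3


def preprocess(pixels: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Map a 2-D grayscale [0,255] image to a (H, W, C) float32 tensor in [0,1].

    Order of operations: optional center crop; symmetric zero padding of the
    shorter dimension (odd pixel to bottom/right) to a square; bilinear resize
    to the target; division by 255; channel replication.
    """
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got ndim={pixels.ndim}")
    if spec.crop_fraction is not None:
        f = spec.crop_fraction
        if not 0 < f <= 1:
            raise ValueError("crop_fraction must be in (0, 1]")
        h, w = pixels.shape
        ch, cw = max(1, round(h * f)), max(1, round(w * f))
        top, left = (h - ch) // 2, (w - cw) // 2
        pixels = pixels[top : top + ch, left : left + cw]
    h, w = pixels.shape
    side = max(h, w)
    ph, pw = side - h, side - w
    pixels = np.pad(
        pixels, ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    )
    if pixels.shape != tuple(spec.target_size):
        pixels = _sk_resize(
            pixels, spec.target_size, order=1, preserve_range=True, anti_aliasing=False
        ).astype(np.float32)
    pixels = pixels / np.float32(255.0)
    return np.repeat(pixels[:, :, None], spec.channels, axis=2)


def augment(
    tensor: np.ndarray,
    rng: np.random.Generator,
    flip_prob: float = 0.5,
    rotation_deg: float = 15.0,
) -> np.ndarray:
    """Training-time augmentation: horizontal flip (p=0.5) and +-15 deg rotation.

    Rotation uses bilinear interpolation with zero fill and preserves shape.
    Deterministic given the generator state.
    """
    out = tensor
    if rng.random() < flip_prob:
        out = out[:, ::-1, :]
    angle = rng.uniform(-rotation_deg, rotation_deg)
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, axes=(1, 0), reshape=False, order=1, mode="constant", cval=0.0
        )
    return np.ascontiguousarray(out, dtype=np.float32)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class Network:
    """A feed-forward stack producing a scalar logit; sigmoid applied on top."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def init_weights(self, seed: int) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
        for layer in self.layers:
            layer.init(rng)

    def get_weights(self) -> WeightVector:
        t = OrderedDict()
        for layer in self.layers:
            for k, v in layer.params.items():
                t[k] = v.copy()
        return WeightVector(t)

    def set_weights(self, weights: WeightVector) -> None:
        # dtype is preserved: training runs in float32, but float64 weights
        # (e.g. for finite-difference checks) stay float64 end to end
        for layer in self.layers:
            for k in layer.params:
                layer.params[k] = np.array(weights[k])

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            z = self.forward_logits(x[start : start + batch_size])
            out.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(out) if out else np.empty(0)

    def backward(self, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        dy = dlogit[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        grads: dict[str, np.ndarray] = {}
        for layer in self.layers:
            grads.update(layer.grads)
        return grads


def _tiny_layers(input_size: tuple[int, int], channels: int = 3) -> list[Layer]:
    h, w = input_size
    if h % 8 or w % 8:
        raise ValueError("tiny arch needs input dims divisible by 8")
    return [
        Conv2D("conv1", channels, 8),
        ReLU(),
        MaxPool2(),
        Conv2D("conv2", 8, 16),
        ReLU(),
        MaxPool2(),
        Conv2D("conv3", 16, 32),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Dense("fc1", (h // 8) * (w // 8) * 32, 32),
        ReLU(),
        Dense("fc2", 32, 1),
    ]


_VGG_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M", 512, 512, 512, "M"]


def _vgg16_layers(input_size: tuple[int, int], channels: int = 3) -> list[Layer]:
    h, w = input_size
    layers: list[Layer] = []
    in_ch, i = channels, 0
    for item in _VGG_CFG:
        if item == "M":
            layers.append(MaxPool2())
            h, w = h // 2, w // 2
        else:
            i += 1
            layers.append(Conv2D(f"conv{i}", in_ch, int(item)))
            layers.append(ReLU())
            in_ch = int(item)
    layers += [
        Flatten(),
        Dense("fc1", h * w * in_ch, 64),
        ReLU(),
        Dense("fc2", 64, 1),
    ]
    return layers


def build_model(
    arch: str, init_seed: int, input_size: tuple[int, int] = (128, 128)
) -> Network:
    """Construct a classifier with per-layer Glorot-uniform initial weights.

    Two calls with the same seed, arch and input size yield elementwise
    identical weights — every simulated site starts from the same model.
    """
    if arch == "tiny":
        net = Network(_tiny_layers(input_size))
    elif arch == "vgg16_like":
        net = Network(_vgg16_layers(input_size))
    else:
        raise ValueError(f"unknown arch {arch!r}; expected 'tiny' or 'vgg16_like'")
    net.init_weights(init_seed)
    return net


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------


def focal_loss(
    p: np.ndarray,
    y: np.ndarray,
    gamma: float = 2.0,
    alpha_weight: float = 0.25,
) -> float:
    """Mean focal loss over a batch of probabilities.

    For y=1: -alpha * (1-p)^gamma * log(p); for y=0:
    -(1-alpha) * p^gamma * log(1-p). With gamma=0 and alpha=0.5 this is half
    the binary cross-entropy. Probabilities outside (0,1) are clipped to
    [1e-7, 1-1e-7].
    """
    p = np.atleast_1d(np.asarray(p, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if np.any((p <= 0) | (p >= 1)):
        logger.warning("focal_loss: probabilities clipped to (0, 1) open interval")
    p = np.clip(p, _EPS, 1 - _EPS)
    loss = np.where(
        y == 1,
        -alpha_weight * (1 - p) ** gamma * np.log(p),
        -(1 - alpha_weight) * p ** gamma * np.log(1 - p),
    )
    return float(loss.mean())


def _focal_grad_logit(
    z: np.ndarray, y: np.ndarray, gamma: float, alpha_weight: float
) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, d mean-loss / d logit) for a batch of logits."""
    p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
    pc = np.clip(p, _EPS, 1 - _EPS)
    # dL/dp for each branch, then chain through dp/dz = p (1 - p)
    dldp_pos = -alpha_weight * (
        -gamma * (1 - pc) ** (gamma - 1) * np.log(pc) + (1 - pc) ** gamma / pc
    )
    dldp_neg = -(1 - alpha_weight) * (
        gamma * pc ** (gamma - 1) * np.log(1 - pc) - pc ** gamma / (1 - pc)
    )
    dldp = np.where(y == 1, dldp_pos, dldp_neg)
    dz = dldp * pc * (1 - pc) / len(z)
    return p, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer and local training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Local-training hyperparameters shared by all sites."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    local_epochs: int = 1
    prox_mu: float = 0.0
    augment: bool = True
    flip_prob: float = 0.5
    rotation_deg: float = 15.0
    init_seed: int = 0
    arch: str = "tiny"
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.focal_gamma < 0 or self.prox_mu < 0:
            raise ValueError("focal_gamma and prox_mu must be >= 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")

    def with_(self, **kw) -> "TrainConfig":
        return replace(self, **kw)


class Adam:
    """Adam on a WeightVector; one instance per local training session."""

    def __init__(self, lr: float, betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m: dict[str, np.ndarray] | None = None
        self.v: dict[str, np.ndarray] | None = None

    def step(self, weights: WeightVector, grads: dict[str, np.ndarray]) -> WeightVector:
        if self.m is None:
            self.m = {k: np.zeros_like(weights[k], dtype=np.float64) for k in weights}
            self.v = {k: np.zeros_like(weights[k], dtype=np.float64) for k in weights}
        self.t += 1
        new = OrderedDict()
        for k in weights:
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            new[k] = (weights[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )
        return WeightVector(new)


def local_train(
    start_weights: WeightVector,
    data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    global_anchor: WeightVector | None = None,
    seed: int = 0,
    network: Network | None = None,
) -> WeightVector:
    """Train locally for ``config.local_epochs`` epochs; returns new weights.

    ``data`` is (X, y) with X of shape (n, H, W, C) already preprocessed.
    When ``config.prox_mu > 0`` the proximal gradient mu * (w - anchor) is
    added at every step, anchored at ``global_anchor`` (the broadcast global
    weights). The Adam state is fresh for each call, as each round's local
    session is an independent optimization.
    """
    X, y = data
    if len(X) == 0:
        raise ValueError("local_train: site has no images (caller must skip empty sites)")
    if network is None:
        network = build_model(config.arch, config.init_seed, config.input_size)
    network.set_weights(start_weights)
    anchor = global_anchor if global_anchor is not None else start_weights
    rng = np.random.default_rng(seed)
    opt = Adam(config.learning_rate, config.adam_betas)
    weights = start_weights.copy()
    for _ in range(config.local_epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            if config.augment:
                xb = np.stack(
                    [augment(im, rng, config.flip_prob, config.rotation_deg) for im in xb]
                )
            network.set_weights(weights)
            z = network.forward_logits(xb)
            _, dz = _focal_grad_logit(z, y[idx], config.focal_gamma, config.focal_alpha)
            grads = network.backward(dz)
            if config.prox_mu > 0:
                for k in weights:
                    grads[k] = grads[k] + config.prox_mu * (weights[k] - anchor[k])
            weights = opt.step(weights, grads)
    return weights
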