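"""A small configurable encoder-decoder network with swappable heads.

The segmentation backbone is a plain U-Net-style fully convolutional
network: per stage two 3x3 convolutions + leaky ReLU on the way down (2x2 average
pooling between stages), a two-convolution bottleneck, and a mirrored
decoder whose stages upsample (nearest neighbour) and concatenate the
matching encoder feature map via a skip connection.  Output heads are 1x1
convolutions with the activation fitting their target:

* ``binary``      — 1 channel, sigmoid;
* ``categorical`` — 3 channels, softmax (background / edge / core);
* ``bodypart``    — 3 channels, softmax (background / body / head);
* ``embedding``   — D channels, linear (discriminative pixel embedding).

Everything (forward, backward, Adam) is implemented directly on numpy
arrays, NHWC layout.  Two normalized coordinate channels can be appended to
the input (``coord_features``, default on): at desk scale they give the
embedding head a cheap positional cue for separating instances, the same
role the large receptive field of an ImageNet backbone plays at full scale.

Heads are trained with their matching losses (cross-entropies, or the
discriminative loss for the embedding head) and their gradients feed
equally weighted (configurable) into the shared backbone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .losses import (
    DiscriminativeConfig,
    binary_cross_entropy,
    categorical_cross_entropy,
    discriminative_loss_grad,
)

__all__ = [
    "HeadSpec",
    "NetworkConfig",
    "TrainConfig",
    "UNet",
    "build_network",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_HEAD_RULES = {  # name -> (required activation, fixed out_channels or None)
    "binary": ("sigmoid", 1),
    "categorical": ("softmax", 3),
    "bodypart": ("softmax", 3),
    "embedding": ("linear", None),
}


@dataclass(frozen=True)
class HeadSpec:
    name: str
    out_channels: int = 0
    activation: str = ""
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _HEAD_RULES:
            raise ValueError(f"unknown head {self.name!r}; expected one of {sorted(_HEAD_RULES)}")
        act, fixed = _HEAD_RULES[self.name]
        object.__setattr__(self, "activation", self.activation or act)
        if self.activation != act:
            raise ValueError(f"head {self.name!r} requires activation {act!r}")
        channels = self.out_channels or fixed or 8
        if fixed is not None and channels != fixed:
            raise ValueError(f"head {self.name!r} must have {fixed} channel(s)")
        object.__setattr__(self, "out_channels", channels)
        if self.weight < 0:
            raise ValueError("head weight must be >= 0")


@dataclass(frozen=True)
class NetworkConfig:
    input_channels: int = 3
    stages: int = 4
    base_width: int = 16
    heads: tuple[HeadSpec, ...] = (HeadSpec("binary"),)
    coord_features: bool = True

    def __post_init__(self) -> None:
        if self.stages < 2:
            raise ValueError("need at least 2 down/up-sampling stages")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        heads = tuple(h if isinstance(h, HeadSpec) else HeadSpec(**h) for h in self.heads)
        if not heads:
            raise ValueError("at least one head is required")
        if len({h.name for h in heads}) != len(heads):
            raise ValueError("head names must be unique")
        object.__setattr__(self, "heads", heads)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    epochs: int = 1
    batch_size: int = 4
    seed: int = 0
    augment: bool = True
    grayscale_prob: float = 0.25  # augmentation analogue of night-vision imaging
    cosine_decay: bool = True  # anneal the learning rate to lr/10 over the run
    disc: DiscriminativeConfig = field(default_factory=DiscriminativeConfig)


# ---------------------------------------------------------------------------
# array primitives (NHWC)


def _conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution as nine shifted matmuls; returns (y, padded x)."""
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.tile(b, (n, h, wd, 1)).astype(np.float32)
    for i in range(3):
        for j in range(3):
            out += xp[:, i : i + h, j : j + wd, :] @ w[i, j]
    return out, xp


def _conv3_backward(xp: np.ndarray, w: np.ndarray, dy: np.ndarray, need_dx: bool = True):
    n, hp, wp, _ = xp.shape
    h, wd = hp - 2, wp - 2
    dxp = np.zeros_like(xp) if need_dx else None
    dw = np.zeros_like(w)
    dyf = dy.reshape(-1, dy.shape[-1])
    for i in range(3):
        for j in range(3):
            sl = xp[:, i : i + h, j : j + wd, :]
            dw[i, j] = sl.reshape(-1, sl.shape[-1]).T @ dyf
            if need_dx:
                dxp[:, i : i + h, j : j + wd, :] += dy @ w[i, j].T
    db = dyf.sum(axis=0)
    return (dxp[:, 1:-1, 1:-1, :] if need_dx else None), dw, db


_LEAKY = 0.1  # leaky-ReLU slope; dead units starve a small from-scratch net


def _lrelu(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, z, _LEAKY * z)


def _lrelu_grad(z: np.ndarray) -> np.ndarray:
    return np.where(z > 0, np.float32(1.0), np.float32(_LEAKY))


def _pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _pool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class UNet:
    """Encoder-decoder with skip connections; parameters live in ``self.params``."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = cfg.input_channels + (2 if cfg.coord_features else 0)
        widths = [cfg.base_width * 2**i for i in range(cfg.stages + 1)]

        def conv(name, cin, cout, k=3):
            shape = (k, k, cin, cout) if k == 3 else (cin, cout)
            std = math.sqrt(2.0 / (k * k * cin))
            self.params[f"{name}.w"] = rng.normal(0, std, shape).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        c = c_in
        for s in range(cfg.stages):
            conv(f"enc{s}a", c, widths[s])
            conv(f"enc{s}b", widths[s], widths[s])
            c = widths[s]
        conv("mida", c, widths[cfg.stages])
        conv("midb", widths[cfg.stages], widths[cfg.stages])
        c = widths[cfg.stages]
        for s in reversed(range(cfg.stages)):
            conv(f"dec{s}a", c + widths[s], widths[s])
            conv(f"dec{s}b", widths[s], widths[s])
            c = widths[s]
        for head in cfg.heads:
            # heads read the last decoder features plus the input skip
            conv(f"head.{head.name}", c + c_in, head.out_channels, k=1)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _check_size(self, h: int, w: int) -> None:
        d = 2**self.cfg.stages
        if h % d or w % d:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 2^stages = {d}"
            )

    def _with_coords(self, x: np.ndarray) -> np.ndarray:
        if not self.cfg.coord_features:
            return x
        n, h, w, _ = x.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
        coords = np.stack([xx / max(w - 1, 1), yy / max(h - 1, 1)], axis=-1)
        return np.concatenate([x, np.broadcast_to(coords, (n, h, w, 2))], axis=-1)

    def forward(self, images: np.ndarray, cache: dict | None = None) -> dict[str, np.ndarray]:
        """Pre-activation head outputs for a (N, H, W, C) float batch."""
        x = np.ascontiguousarray(images, dtype=np.float32)
        self._check_size(x.shape[1], x.shape[2])
        x = x - 0.5  # images arrive in [0, 1]; center for symmetric activations
        x = x0 = self._with_coords(x)
        p = self.params
        skips = []
        record = cache is not None

        def block(x, name):
            z1, xp1 = _conv3_forward(x, p[f"{name}a.w"], p[f"{name}a.b"])
            a1 = _lrelu(z1)
            z2, xp2 = _conv3_forward(a1, p[f"{name}b.w"], p[f"{name}b.b"])
            a2 = _lrelu(z2)
            if record:
                cache[name] = (xp1, z1, xp2, z2)
            return a2

        for s in range(self.cfg.stages):
            a = block(x, f"enc{s}")
            skips.append(a)
            x = _pool2(a)
        x = block(x, "mid")
        for s in reversed(range(self.cfg.stages)):
            up = _up2(x)
            x = np.concatenate([up, skips[s]], axis=-1)
            x = block(x, f"dec{s}")
        x = np.concatenate([x, x0], axis=-1)  # input skip straight into the heads
        out = {}
        for head in self.cfg.heads:
            out[head.name] = x @ p[f"head.{head.name}.w"] + p[f"head.{head.name}.b"]
        if record:
            cache["trunk"] = x
        return out

    def backward(self, cache: dict, head_grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Parameter gradients from per-head gradients w.r.t. pre-activations."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        trunk = cache["trunk"]
        dx = np.zeros_like(trunk)
        for name, dz in head_grads.items():
            dz = dz.astype(np.float32)
            w = p[f"head.{name}.w"]
            grads[f"head.{name}.w"] = trunk.reshape(-1, trunk.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
            grads[f"head.{name}.b"] = dz.reshape(-1, dz.shape[-1]).sum(axis=0)
            dx += dz @ w.T
        dx = dx[..., : self.cfg.base_width]  # the input-skip slice has no parameters upstream

        def block_backward(name, da2, need_dx=True):
            xp1, z1, xp2, z2 = cache[name]
            dz2 = da2 * _lrelu_grad(z2)
            da1, dw2, db2 = _conv3_backward(xp2, p[f"{name}b.w"], dz2)
            grads[f"{name}b.w"], grads[f"{name}b.b"] = dw2, db2
            dz1 = da1 * _lrelu_grad(z1)
            dxin, dw1, db1 = _conv3_backward(xp1, p[f"{name}a.w"], dz1, need_dx=need_dx)
            grads[f"{name}a.w"], grads[f"{name}a.b"] = dw1, db1
            return dxin

        skip_grads = [None] * self.cfg.stages
        for s in range(self.cfg.stages):
            dxin = block_backward(f"dec{s}", dx)
            w_up = cache[f"dec{s}"][0].shape[-1] - self.cfg.base_width * 2**s
            dup, dskip = dxin[..., :w_up], dxin[..., w_up:]
            skip_grads[s] = dskip
            dx = _up2_backward(dup)
        dx = block_backward("mid", dx)
        for s in reversed(range(self.cfg.stages)):
            da = _pool2_backward(dx) + skip_grads[s]
            # the first block's input is the image; no parameters upstream
            dx = block_backward(f"enc{s}", da, need_dx=s > 0)
        return grads

    def predict(self, image: np.ndarray) -> dict[str, np.ndarray]:
        """Head outputs with activations applied, for one (H, W, C) image."""
        x = np.asarray(image, dtype=np.float32)
        if x.ndim == 2:
            x = x[..., None]
        raw = self.forward(x[None])
        out = {}
        for head in self.cfg.heads:
            z = raw[head.name][0]
            if head.activation == "sigmoid":
                out[head.name] = _sigmoid(z)
            elif head.activation == "softmax":
                out[head.name] = _softmax(z)
            else:
                out[head.name] = z
        return out


def build_network(cfg: NetworkConfig, seed: int = 0) -> UNet:
    return UNet(cfg, seed=seed)


def predict(model: UNet, image: np.ndarray) -> dict[str, np.ndarray]:
    return model.predict(image)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _augment(image, labels, rng, grayscale_prob):
    """Random flip / 90-degree rotation / grayscale, applied jointly."""
    # odd quarter-turns would change the shape of non-square images
    k = int(rng.integers(4)) if image.shape[0] == image.shape[1] else int(rng.integers(2)) * 2
    flip = bool(rng.integers(2))

    def tf(arr):
        if arr is None:
            return None
        a = np.rot90(arr, k, axes=(0, 1))
        return np.flip(a, axis=1) if flip else a

    image = tf(image)
    labels = {name: tf(arr) for name, arr in labels.items()}
    if image.shape[-1] == 3 and rng.random() < grayscale_prob:
        image = np.repeat(image.mean(axis=-1, keepdims=True), 3, axis=-1)
    return np.ascontiguousarray(image), {
        k2: (np.ascontiguousarray(v) if v is not None else None) for k2, v in labels.items()
    }


def _head_loss_and_grad(head: HeadSpec, z: np.ndarray, target, disc: DiscriminativeConfig):
    """Per-image loss and gradient w.r.t. the head's pre-activation."""
    n_px = z.shape[0] * z.shape[1]
    if head.activation == "sigmoid":
        p = _sigmoid(z[..., 0])
        loss = binary_cross_entropy(p, target)
        grad = ((p - target) / n_px)[..., None]
    elif head.activation == "softmax":
        p = _softmax(z)
        onehot = np.eye(z.shape[-1], dtype=np.float64)[target]
        loss = categorical_cross_entropy(p, onehot)
        grad = (p - onehot) / n_px
    else:  # embedding head with the discriminative loss
        loss, grad = discriminative_loss_grad(z, target, disc)
    return loss, grad


def _target_for_head(name: str, maps) -> np.ndarray:
    if name == "binary":
        return maps.binary
    if name == "categorical":
        return maps.categorical
    if name == "bodypart":
        if maps.bodypart is None:
            raise ValueError("dataset lacks body-part labels required by the bodypart head")
        return maps.bodypart
    return maps.instance  # embedding


def train(
    model: UNet,
    images: Sequence[np.ndarray],
    labels: Sequence,
    cfg: TrainConfig,
) -> list[dict[str, float]]:
    """Train in place; returns the per-step loss history.

    ``images`` are (H, W, C) float arrays in [0, 1]; ``labels`` the matching
    :class:`~penseg.labels.LabelMaps`.  Head losses are combined with the
    head weights (equal by default) and optimized with Adam.  Runs are
    reproducible for a fixed seed on a single device.
    """
    if len(images) == 0:
        raise ValueError("dataset is empty")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    for maps in labels:
        for head in model.cfg.heads:
            _target_for_head(head.name, maps)  # fail early on missing labels

    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.params, cfg.learning_rate)
    n_steps = cfg.epochs * math.ceil(len(images) / cfg.batch_size)
    history: list[dict[str, float]] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(images))
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = []
            for i in idx:
                maps = labels[i]
                lab = {h.name: _target_for_head(h.name, maps) for h in model.cfg.heads}
                img = np.asarray(images[i], dtype=np.float32)
                if cfg.augment:
                    img, lab = _augment(img, lab, rng, cfg.grayscale_prob)
                batch.append((img, lab))
            x = np.stack([b[0] for b in batch])
            cache: dict = {}
            raw = model.forward(x, cache=cache)
            step_losses: dict[str, float] = {}
            head_grads: dict[str, np.ndarray] = {}
            for head in model.cfg.heads:
                z = raw[head.name]
                g = np.zeros_like(z, dtype=np.float64)
                total = 0.0
                for bi, (_, lab) in enumerate(batch):
                    zi = z[bi] if head.activation == "linear" else z[bi].astype(np.float64)
                    loss_i, grad_i = _head_loss_and_grad(head, zi, lab[head.name], cfg.disc)
                    total += loss_i
                    g[bi] = grad_i
                step_losses[head.name] = total / len(batch)
                head_grads[head.name] = (head.weight / len(batch)) * g
            grads = model.backward(cache, head_grads)
            if cfg.cosine_decay and n_steps > 1:
                frac = len(history) / (n_steps - 1)
                lr0 = cfg.learning_rate
                opt.lr = lr0 / 10 + (lr0 - lr0 / 10) * 0.5 * (1 + math.cos(math.pi * frac))
            opt.step(model.params, grads)
            step_losses["total"] = float(
                sum(h.weight * step_losses[h.name] for h in model.cfg.heads)
            )
            history.append(step_losses)
    return history


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: UNet, path) -> None:
    meta = asdict(model.cfg)
    np.savez(path, __config__=json.dumps(meta), **model.params)


def load_model(path) -> UNet:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__config__"]))
    meta["heads"] = tuple(HeadSpec(**h) for h in meta["heads"])
    model = UNet(NetworkConfig(**meta))
    for k in model.params:
        model.params[k] = data[k]
    return model
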