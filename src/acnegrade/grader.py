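"""8-level ordinal image grader with interval-weight fusion.

The grader is a compact convolutional network implemented directly in
numpy (im2col convolutions, hand-written backprop, Adam with cosine
learning-rate annealing, cross-entropy loss). Its softmax output is an
8-dim probability vector over severity grades. The count-interval prior
can be fused with that vector in two ways:

* fixed weights — the interval's binary mask multiplies the probabilities
  elementwise at inference (out-of-interval grades get weight 0), then the
  argmax is taken;
* learnable weights — one non-negative 8-vector per distinct interval,
  initialized to the binary mask softened by epsilon and fine-tuned
  jointly with the network on the fused, renormalized probabilities.

Ties at the argmax break toward the lowest grade (the conservative,
less aggressive treatment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image

from .errors import (
    AcnegradeError,
    ConfigError,
    InvalidGradeError,
    InvalidMaskError,
    LeakageError,
)
from .rule import GradingInterval, interval_mask
from .scale import N_GRADES
from .synth import DEFAULT_SKIN_TONE


@dataclass
class GraderConfig:
    """Training/architecture settings.

    The desk-mode defaults are sized for CPU training on 64 px synthetic
    images; ``paper_mode()`` returns the full-scale protocol preset
    (256->224 px, 200 epochs, batch 32, lr 1e-3 -> 1e-4 cosine, Adam,
    weight decay 1e-4).
    """

    backbone: str = "small_cnn"
    resize_side: int = 64
    input_side: int = 56
    flip_prob: float = 0.5
    rotation_deg: float = 20.0
    epochs: int = 30
    batch_size: int = 32
    lr_init: float = 1e-3
    lr_final: float = 1e-4
    weight_decay: float = 1e-4
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    fusion_mode: str = "none"  # none | fixed | learnable
    epsilon: float = 1e-4  # soft floor for masked-out learnable weights
    channels: tuple[int, ...] = (8, 16, 32, 32)
    fill_color: tuple[int, int, int] = DEFAULT_SKIN_TONE
    seed: int = 0

    @classmethod
    def paper_mode(cls, **overrides) -> "GraderConfig":
        base = dict(
            resize_side=256,
            input_side=224,
            epochs=200,
            batch_size=32,
            lr_init=1e-3,
            lr_final=1e-4,
            weight_decay=1e-4,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.backbone != "small_cnn":
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.fusion_mode not in ("none", "fixed", "learnable"):
            raise ConfigError(f"unknown fusion_mode {self.fusion_mode!r}")
        if self.input_side > self.resize_side:
            raise ConfigError("input_side cannot exceed resize_side")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    image: np.ndarray,
    mode: str = "eval",
    config: GraderConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Image -> (3, S, S) float tensor in [0, 1].

    Train mode: resize to ``resize_side``, random crop to ``input_side``,
    horizontal flip with probability ``flip_prob``, rotation uniform in
    +-``rotation_deg`` degrees (empty corners filled with the skin tone).
    Eval mode: resize then center crop; fully deterministic.
    """
    config = config or GraderConfig()
    if mode not in ("train", "eval"):
        raise ConfigError(f"unknown preprocess mode {mode!r}")
    pil = Image.fromarray(np.asarray(image, dtype=np.uint8))
    pil = pil.resize((config.resize_side, config.resize_side), Image.BILINEAR)
    margin = config.resize_side - config.input_side
    if mode == "train":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ox, oy = (int(rng.integers(0, margin + 1)), int(rng.integers(0, margin + 1))) if margin else (0, 0)
        pil = pil.crop((ox, oy, ox + config.input_side, oy + config.input_side))
        if rng.random() < config.flip_prob:
            pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
        angle = float(rng.uniform(-config.rotation_deg, config.rotation_deg))
        pil = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=tuple(config.fill_color))
    else:
        o = margin // 2
        pil = pil.crop((o, o, o + config.input_side, o + config.input_side))
    arr = np.asarray(pil, dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


# ---------------------------------------------------------------------------
# numpy network primitives (3x3 conv, stride 2, pad 1)


def _im2col(x: np.ndarray, k: int = 3, s: int = 2, p: int = 1):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    _, _, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, k: int = 3, s: int = 2, p: int = 1):
    n, c, h, w = x_shape
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += d[:, :, :, :, ki, kj]
    return dxp[:, :, p : p + h, p : p + w]


def _softplus(u: np.ndarray) -> np.ndarray:
    return np.where(u > 30, u, np.log1p(np.exp(np.minimum(u, 30))))


def _softplus_inv(w: float) -> float:
    return float(np.log(np.expm1(w)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _SmallCNN:
    """4 conv blocks (3x3, stride 2) + global average pooling + linear head."""

    def __init__(self, channels: tuple[int, ...], rng: np.random.Generator):
        self.params: dict[str, np.ndarray] = {}
        c_in = 3
        for i, c_out in enumerate(channels):
            fan_in = c_in * 9
            self.params[f"W{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["Wfc"] = rng.normal(0, np.sqrt(2.0 / c_in), (N_GRADES, c_in))
        self.params["bfc"] = np.zeros(N_GRADES)
        self.n_blocks = len(channels)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache = []
        h = x
        for i in range(self.n_blocks):
            cols, (ho, wo) = _im2col(h)
            w = self.params[f"W{i}"]
            z = cols @ w.reshape(w.shape[0], -1).T + self.params[f"b{i}"]
            z = z.reshape(h.shape[0], ho, wo, w.shape[0]).transpose(0, 3, 1, 2)
            a = np.maximum(z, 0.0)
            if want_cache:
                cache.append((h.shape, cols, z > 0))
            h = a
        feat = h.mean(axis=(2, 3))
        logits = feat @ self.params["Wfc"].T + self.params["bfc"]
        if want_cache:
            return logits, (cache, feat, h.shape)
        return logits

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        blocks, feat, h_shape = cache
        grads: dict[str, np.ndarray] = {}
        grads["Wfc"] = dlogits.T @ feat
        grads["bfc"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wfc"]
        n, c, hh, ww = h_shape
        dh = np.broadcast_to(dfeat[:, :, None, None], h_shape) / (hh * ww)
        for i in reversed(range(self.n_blocks)):
            x_shape, cols, relu_mask = blocks[i]
            w = self.params[f"W{i}"]
            dz = dh * relu_mask  # (n, c_out, ho, wo)
            dz2 = dz.transpose(0, 2, 3, 1).reshape(-1, w.shape[0])
            cols2 = cols.reshape(-1, cols.shape[-1])
            grads[f"W{i}"] = (dz2.T @ cols2).reshape(w.shape)
            grads[f"b{i}"] = dz2.sum(axis=0)
            dcols = dz2 @ w.reshape(w.shape[0], -1)
            dh = _col2im(dcols.reshape(cols.shape), x_shape)
        return grads


# ---------------------------------------------------------------------------
# interval weights


@dataclass
class IntervalWeights:
    """Non-negative per-grade weights, one 8-vector per distinct interval."""

    keys: list[str]
    values: np.ndarray  # (n_intervals, 8), already through softplus
    trainable: bool = True

    def weights_for(self, key: str) -> np.ndarray:
        if key not in self.keys:
            raise KeyError(f"unknown interval id {key!r}")
        return self.values[self.keys.index(key)]


def init_interval_logits(intervals: list[GradingInterval], epsilon: float) -> np.ndarray:
    """Pre-softplus parameters whose softplus equals the epsilon-softened mask."""
    u = np.empty((len(intervals), N_GRADES))
    u_in, u_out = _softplus_inv(1.0), _softplus_inv(epsilon)
    for i, iv in enumerate(intervals):
        m = interval_mask(iv)
        u[i] = np.where(m > 0, u_in, u_out)
    return u


# ---------------------------------------------------------------------------
# fusion


def _fuse(probs: np.ndarray, weights: np.ndarray):
    probs = np.asarray(probs, dtype=float)
    if np.all(weights == weights.flat[0]) and weights.flat[0] > 0:
        # uniform weights are a mathematical no-op; skip the division so the
        # identity mask reproduces the input bit-for-bit
        pred = np.argmax(probs, axis=-1) + 1
        return probs, pred
    fused = probs * weights
    total = fused.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise InvalidMaskError("fusion weights leave no admissible grade")
    fused = fused / total
    pred = np.argmax(fused, axis=-1) + 1  # argmax takes the first (lowest) max
    return fused, pred


def fuse_fixed(probs: np.ndarray, mask: np.ndarray):
    """Elementwise product with a binary interval mask, renormalized.

    Returns ``(fused_probs, predicted_grade)``; grades are 1-based and ties
    break toward the lowest grade.
    """
    mask = np.asarray(mask, dtype=float)
    if not (mask > 0).any():
        raise InvalidMaskError("mask has no admissible grade")
    fused, pred = _fuse(probs, mask)
    if np.ndim(probs) == 1:
        return fused, int(pred)
    return fused, pred.astype(int)


def fuse_learnable(probs: np.ndarray, weights: IntervalWeights, interval_id: str):
    """Elementwise product with the learned weights of one interval."""
    fused, pred = _fuse(probs, weights.weights_for(interval_id))
    if np.ndim(probs) == 1:
        return fused, int(pred)
    return fused, pred.astype(int)


# ---------------------------------------------------------------------------
# the grader object


class AcneGrader:
    """A trained ordinal grader (network weights + optional interval weights)."""

    def __init__(self, config: GraderConfig, net: _SmallCNN, interval_logits: np.ndarray | None, interval_keys: list[str]):
        self.config = config
        self.net = net
        self.interval_logits = interval_logits
        self.interval_keys = interval_keys
        self.history: list[float] = []

    # -- inference -------------------------------------------------------

    def predict_probs(self, images) -> np.ndarray:
        """Softmax probability vectors for one image or a list of images."""
        single = isinstance(images, np.ndarray) and images.ndim == 3
        batch = [images] if single else list(images)
        x = np.stack([preprocess(im, "eval", self.config) for im in batch])
        probs = _softmax(self.net.forward(x))
        return probs[0] if single else probs

    def interval_weights(self) -> IntervalWeights:
        if self.interval_logits is None:
            raise AcnegradeError("grader was trained without learnable weights")
        return IntervalWeights(keys=list(self.interval_keys), values=_softplus(self.interval_logits))

    def predict(
        self,
        images,
        intervals: list[GradingInterval] | None = None,
        fusion_mode: str | None = None,
    ) -> np.ndarray:
        """Predicted grades (1..8) under the requested fusion mode."""
        mode = fusion_mode or self.config.fusion_mode
        probs = np.atleast_2d(self.predict_probs(images))
        if mode == "none":
            return (np.argmax(probs, axis=1) + 1).astype(int)
        if intervals is None or len(intervals) != probs.shape[0]:
            raise AcnegradeError("fusion requires one interval per image")
        preds = np.empty(probs.shape[0], dtype=int)
        if mode == "fixed":
            for i, iv in enumerate(intervals):
                _, preds[i] = fuse_fixed(probs[i], interval_mask(iv))
        elif mode == "learnable":
            w = self.interval_weights()
            for i, iv in enumerate(intervals):
                _, preds[i] = fuse_learnable(probs[i], w, iv.key)
        else:
            raise ConfigError(f"unknown fusion mode {mode!r}")
        return preds

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        arrays = {f"net_{k}": v for k, v in self.net.params.items()}
        if self.interval_logits is not None:
            arrays["interval_logits"] = self.interval_logits
        np.savez(
            path,
            config_json=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            interval_keys_json=np.frombuffer(json.dumps(self.interval_keys).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AcneGrader":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            keys = json.loads(bytes(data["interval_keys_json"]).decode())
            cfg["channels"] = tuple(cfg["channels"])
            cfg["fill_color"] = tuple(cfg["fill_color"])
            config = GraderConfig(**cfg)
            net = _SmallCNN(config.channels, np.random.default_rng(0))
            for k in list(net.params):
                net.params[k] = data[f"net_{k}"]
            logits = data["interval_logits"] if "interval_logits" in data else None
        return cls(config, net, logits, keys)


def predict_probs(grader: AcneGrader, image: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`AcneGrader.predict_probs`."""
    return grader.predict_probs(image)


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float, wd: float):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0
        self.lr = lr
        self.wd = wd
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], decay_keys: set[str]):
        self.t += 1
        for k, g in grads.items():
            if k in decay_keys:
                g = g + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _cosine_lr(epoch: int, config: GraderConfig) -> float:
    total = max(config.epochs - 1, 1)
    frac = min(epoch, total) / total
    return config.lr_final + 0.5 * (config.lr_init - config.lr_final) * (1 + np.cos(np.pi * frac))


def train_grader(
    images: list[np.ndarray],
    grades: list[int],
    config: GraderConfig | None = None,
    intervals: list[GradingInterval] | None = None,
    distinct_intervals: list[GradingInterval] | None = None,
) -> AcneGrader:
    """Train the grader with cross-entropy loss.

    In ``none``/``fixed`` fusion modes the loss is taken on the raw softmax
    probabilities (the fixed mask is applied only at inference). In
    ``learnable`` mode per-image intervals are required and the loss is
    taken on the fused, renormalized probabilities, so gradients flow into
    both the network and the interval weights.
    """
    config = config or GraderConfig()
    config.validate()
    if len(images) == 0:
        raise AcnegradeError("empty training set")
    y = np.asarray(grades, dtype=int)
    if len(images) != y.size:
        raise AcnegradeError("images and grades length mismatch")
    if ((y < 1) | (y > N_GRADES)).any():
        raise InvalidGradeError("training grades must be in 1..8")
    learnable = config.fusion_mode == "learnable"
    if learnable:
        if intervals is None or len(intervals) != y.size:
            raise AcnegradeError("learnable fusion requires one interval per image")
        if distinct_intervals is None:
            seen: dict[str, GradingInterval] = {}
            for iv in intervals:
                seen.setdefault(iv.key, iv)
            distinct_intervals = list(seen.values())
        keys = [iv.key for iv in distinct_intervals]
        iid = np.array([keys.index(iv.key) for iv in intervals])
    else:
        keys, iid = [], None

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xACE]))
    net = _SmallCNN(config.channels, rng)
    u = init_interval_logits(distinct_intervals, config.epsilon) if learnable else None

    shapes = {k: v.shape for k, v in net.params.items()}
    if learnable:
        shapes["U"] = u.shape
    opt = _Adam(shapes, config.lr_init, config.weight_decay)
    decay_keys = {k for k in net.params if k.startswith("W")}

    grader = AcneGrader(config, net, u, keys)
    n = y.size
    for epoch in range(config.epochs):
        opt.lr = _cosine_lr(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            aug = np.random.default_rng(np.random.SeedSequence([config.seed, epoch, int(start)]))
            x = np.stack([preprocess(images[i], "train", config, aug) for i in idx])
            yb = y[idx] - 1
            logits, cache = net.forward(x, want_cache=True)
            p = _softmax(logits)
            if learnable:
                w = _softplus(u)[iid[idx]]
                s = p * w
                z = s.sum(axis=1, keepdims=True)
                q = s / z
                loss = -np.log(np.maximum(q[np.arange(len(idx)), yb], 1e-12)).mean()
                # dL/dp and dL/dw of L = -log p_y - log w_y + log Z
                dp = w / z
                dp[np.arange(len(idx)), yb] -= 1.0 / np.maximum(p[np.arange(len(idx)), yb], 1e-12)
                dw = p / z
                dw[np.arange(len(idx)), yb] -= 1.0 / np.maximum(w[np.arange(len(idx)), yb], 1e-12)
                dp /= len(idx)
                dw /= len(idx)
                dlogits = p * (dp - (dp * p).sum(axis=1, keepdims=True))
                du = np.zeros_like(u)
                sig = 1.0 / (1.0 + np.exp(-u))
                np.add.at(du, iid[idx], dw)
                du *= sig
            else:
                loss = -np.log(np.maximum(p[np.arange(len(idx)), yb], 1e-12)).mean()
                dlogits = p.copy()
                dlogits[np.arange(len(idx)), yb] -= 1.0
                dlogits /= len(idx)
                du = None
            grads = net.backward(dlogits, cache)
            if learnable:
                grads["U"] = du
                params = dict(net.params)
                params["U"] = u
                opt.step(params, grads, decay_keys)
                net.params.update({k: v for k, v in params.items() if k != "U"})
                u[...] = params["U"]
            else:
                opt.step(net.params, grads, decay_keys)
            epoch_loss += loss * len(idx)
        grader.history.append(epoch_loss / n)
    return grader


# ---------------------------------------------------------------------------
# evaluation


def evaluate_grader(
    grader: AcneGrader,
    images,
    true_grades,
    subject_ids=None,
    intervals: list[GradingInterval] | None = None,
    fusion_mode: str = "none",
    train_ids=None,
) -> dict:
    """Grading report: predictions, confusion matrix, linear weighted kappa.

    If ``train_ids`` and ``subject_ids`` are given, any overlap raises
    :class:`LeakageError` before evaluation.
    """
    from .agreement import confusion_matrix, linear_weighted_kappa

    if train_ids is not None and subject_ids is not None:
        overlap = set(train_ids) & set(subject_ids)
        if overlap:
            raise LeakageError(f"train/test overlap on subject ids {sorted(overlap)[:5]}")
    truths = np.asarray(true_grades, dtype=int)
    preds = grader.predict(images, intervals=intervals, fusion_mode=fusion_mode)
    kappa = linear_weighted_kappa(preds, truths)
    cm = confusion_matrix(preds, truths)
    report = {
        "fusion_mode": fusion_mode,
        "n": int(truths.size),
        "accuracy": float((preds == truths).mean()),
        "kappa_linear": float(kappa),
        "confusion_matrix": cm.tolist(),
        "predictions": [int(v) for v in preds],
    }
    if subject_ids is not None:
        report["subject_ids"] = [int(s) for s in subject_ids]
    return report
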