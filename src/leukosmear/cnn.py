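"""Desk-scale convolutional network built from first-principles layer operators.

Every operator is implemented directly from its defining equation on numpy
arrays: cross-correlation convolution with zero padding and stride, ReLU,
max/average pooling, inverted dropout, and a numerically stabilized softmax.
A small trainable network (two conv/pool blocks and two dense layers) wires
them together; its penultimate dense activation serves as a deep-feature
vector for the hybrid "CNN features -> max-margin classifier" pipeline mode.

Feature maps are ``(H, W, C)`` arrays; the training path batches them as
``(N, H, W, C)``.  Convolution is cross-correlation (no kernel flip), the
modern CNN convention; the textbook flipped form differs only by a kernel
reflection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConvKernel",
    "MicroCNNSpec",
    "MicroCNN",
    "conv2d",
    "relu",
    "max_pool",
    "avg_pool",
    "dropout",
    "softmax",
    "extract_deep_features",
]


@dataclass(frozen=True)
class ConvKernel:
    """Convolution weights ``(k, k, C_in, C_out)`` with stride and zero padding."""

    weights: np.ndarray
    stride: int = 1
    zero_padding: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 4 or w.shape[0] != w.shape[1]:
            raise ValueError("kernel weights must have shape (k, k, C_in, C_out)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.zero_padding < 0:
            raise ValueError("zero_padding must be >= 0")
        object.__setattr__(self, "weights", w)


def _as_map(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError(f"feature map must be (H, W) or (H, W, C), got shape {x.shape}")
    return x


def _out_size(n: int, k: int, pad: int, stride: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N, H, W, C) -> (N, Ho*Wo, k*k*C) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    N, H, W, C = x.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(N, Ho, Wo, k, k, C),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3), writeable=False)
    return patches.reshape(N, Ho * Wo, k * k * C), Ho, Wo


def conv2d(x, kernel: ConvKernel) -> np.ndarray:
    """Strided, zero-padded cross-correlation of a feature map with a kernel bank.

    Output spatial size is ``floor((H + 2 pad - k) / stride) + 1``; with
    ``pad = (k - 1) / 2`` and stride 1 (odd ``k``) the input size is kept.
    """
    x = _as_map(x)
    k = kernel.weights.shape[0]
    if x.shape[2] != kernel.weights.shape[2]:
        raise ValueError(
            f"input has {x.shape[2]} channels but kernel expects {kernel.weights.shape[2]}")
    if k > x.shape[0] + 2 * kernel.zero_padding or k > x.shape[1] + 2 * kernel.zero_padding:
        raise ValueError("kernel larger than the padded input")
    cols, Ho, Wo = _im2col(x[None], k, kernel.stride, kernel.zero_padding)
    out = cols[0] @ kernel.weights.reshape(k * k * x.shape[2], -1)
    return out.reshape(Ho, Wo, -1)


def relu(x) -> np.ndarray:
    """Elementwise ``max(0, x)``."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def _pool(x, k: int, stride: int, reducer) -> np.ndarray:
    x = _as_map(x)
    if k > x.shape[0] or k > x.shape[1]:
        raise ValueError("pooling window larger than the input")
    cols, Ho, Wo = _im2col(x[None], k, stride, 0)
    C = x.shape[2]
    windows = cols[0].reshape(Ho * Wo, k * k, C)
    return reducer(windows, axis=1).reshape(Ho, Wo, C)


def max_pool(x, k: int = 2, stride: int = 2) -> np.ndarray:
    """Per-window maximum."""
    return _pool(x, k, stride, np.max)


def avg_pool(x, k: int = 2, stride: int = 2) -> np.ndarray:
    """Per-window mean (1/k^2 normalization)."""
    return _pool(x, k, stride, np.mean)


def dropout(x, rate: float, mode: str = "eval", seed: int | None = None) -> np.ndarray:
    """Inverted dropout: train mode zeroes units w.p. ``rate`` and rescales
    survivors by ``1/(1-rate)``; eval mode is the identity."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    x = np.asarray(x, dtype=np.float64)
    if mode == "eval" or rate == 0.0:
        return x.copy()
    rng = np.random.default_rng(seed)
    keep = rng.uniform(size=x.shape) >= rate
    return np.where(keep, x / (1.0 - rate), 0.0)


def softmax(logits) -> np.ndarray:
    """``exp(x_i) / sum_j exp(x_j)`` with max-subtraction for stability."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------------------
# Trainable micro network
# ----------------------------------------------------------------------------

# Two conv/pool blocks, then *global* average pooling before the dense head:
# a head reading the flattened 16x16 map can memorize nucleus positions on
# desk-scale sample counts, while channel-wise averaging is position-invariant
# by construction (a dark-blob detector channel averages to the blob's area
# fraction, exactly the cue that separates blast from normal nuclei).
_DEFAULT_LAYERS = (
    {"type": "conv", "filters": 8, "kernel": 3, "stride": 1, "pad": 1},
    {"type": "relu"},
    {"type": "maxpool", "k": 2, "stride": 2},
    {"type": "conv", "filters": 16, "kernel": 3, "stride": 1, "pad": 1},
    {"type": "relu"},
    {"type": "maxpool", "k": 2, "stride": 2},
    {"type": "avgpool", "k": 16, "stride": 16},  # global average pooling
    {"type": "dense", "units": 32},
    {"type": "relu"},
    {"type": "dense", "units": 2},
    {"type": "softmax"},
)


@dataclass(frozen=True)
class MicroCNNSpec:
    """Ordered layer list plus the feature-tap index.

    ``feature_tap`` names the layer whose (flattened) output is the deep
    feature vector; it must precede the final dense layer.  The final layer
    must be a 2-class softmax.
    """

    input_size: int = 64
    input_channels: int = 1
    layers: tuple = _DEFAULT_LAYERS
    dropout_rate: float = 0.5
    feature_tap: int = 8  # relu after dense(32)

    def __post_init__(self) -> None:
        layers = tuple(dict(l) for l in self.layers)
        object.__setattr__(self, "layers", layers)
        if layers[-1]["type"] != "softmax":
            raise ValueError("final layer must be softmax")
        dense_idx = [i for i, l in enumerate(layers) if l["type"] == "dense"]
        if not dense_idx or layers[dense_idx[-1]]["units"] != 2:
            raise ValueError("the last dense layer must have 2 units (2 classes)")
        if not (0 <= self.feature_tap < dense_idx[-1]):
            raise ValueError("feature_tap must precede the final dense layer")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


class MicroCNN:
    """A tiny sequential CNN trained by mini-batch gradient descent on cross-entropy.

    All randomness (weight init, batch shuffling, dropout masks) flows from the
    seed given at construction.
    """

    def __init__(self, spec: MicroCNNSpec = MicroCNNSpec(), seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.params: dict[str, np.ndarray] = {}
        self._build()

    # -- construction ------------------------------------------------------
    def _build(self) -> None:
        h = w = self.spec.input_size
        c = self.spec.input_channels
        flat = None
        for i, layer in enumerate(self.spec.layers):
            t = layer["type"]
            if t == "conv":
                k, f = layer["kernel"], layer["filters"]
                fan_in = k * k * c
                self.params[f"W{i}"] = self.rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), (k, k, c, f))
                self.params[f"b{i}"] = np.zeros(f)
                h = _out_size(h, k, layer.get("pad", 0), layer.get("stride", 1))
                w = _out_size(w, k, layer.get("pad", 0), layer.get("stride", 1))
                c = f
            elif t in ("maxpool", "avgpool"):
                h = _out_size(h, layer["k"], 0, layer.get("stride", layer["k"]))
                w = _out_size(w, layer["k"], 0, layer.get("stride", layer["k"]))
            elif t == "dense":
                if flat is None:
                    flat = h * w * c
                u = layer["units"]
                self.params[f"W{i}"] = self.rng.normal(0.0, np.sqrt(2.0 / flat), (flat, u))
                self.params[f"b{i}"] = np.zeros(u)
                flat = u
            elif t in ("relu", "softmax", "dropout"):
                pass
            else:
                raise ValueError(f"unknown layer type {t!r} at index {i}")

    # -- forward / backward ------------------------------------------------
    def _forward(self, x: np.ndarray, mode: str, dropout_seed: int | None = None,
                 tap: int | None = None):
        """Run the network; returns (output, cache) or the tap activation."""
        cache = []
        a = x
        for i, layer in enumerate(self.spec.layers):
            t = layer["type"]
            if t == "conv":
                k = layer["kernel"]
                stride, pad = layer.get("stride", 1), layer.get("pad", 0)
                cols, Ho, Wo = _im2col(a, k, stride, pad)
                W = self.params[f"W{i}"]
                out = cols @ W.reshape(-1, W.shape[3]) + self.params[f"b{i}"]
                out = out.reshape(a.shape[0], Ho, Wo, W.shape[3])
                cache.append(("conv", i, a.shape, cols))
                a = out
            elif t == "relu":
                cache.append(("relu", i, a > 0))
                a = np.maximum(a, 0.0)
            elif t in ("maxpool", "avgpool"):
                k, stride = layer["k"], layer.get("stride", layer["k"])
                cols, Ho, Wo = _im2col(a, k, stride, 0)
                N, _, _, C = a.shape
                win = cols.reshape(N, Ho * Wo, k * k, C)
                if t == "maxpool":
                    arg = win.argmax(axis=2)
                    out = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]
                    cache.append(("maxpool", i, a.shape, arg, (k, stride, Ho, Wo)))
                else:
                    out = win.mean(axis=2)
                    cache.append(("avgpool", i, a.shape, None, (k, stride, Ho, Wo)))
                a = out.reshape(N, Ho, Wo, C)
            elif t == "dense":
                flat_in = a.reshape(a.shape[0], -1)
                cache.append(("dense", i, a.shape, flat_in))
                a = flat_in @ self.params[f"W{i}"] + self.params[f"b{i}"]
            elif t == "dropout":
                if mode == "train" and self.spec.dropout_rate > 0:
                    rng = np.random.default_rng(dropout_seed)
                    keep = rng.uniform(size=a.shape) >= self.spec.dropout_rate
                    a = np.where(keep, a / (1.0 - self.spec.dropout_rate), 0.0)
                    cache.append(("dropout", i, keep))
                else:
                    cache.append(("dropout", i, None))
            elif t == "softmax":
                cache.append(("softmax", i, None))
                a = softmax(a)
            if tap is not None and i == tap:
                return a.reshape(a.shape[0], -1), cache
        return a, cache

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache: list) -> dict:
        grads = {}
        delta = (probs - y_onehot) / probs.shape[0]  # dL/dlogits for CE+softmax
        for entry in reversed(cache):
            t, i = entry[0], entry[1]
            layer = self.spec.layers[i]
            if t == "softmax":
                continue  # folded into the cross-entropy delta
            if t == "dense":
                _, _, in_shape, flat_in = entry
                grads[f"W{i}"] = flat_in.T @ delta
                grads[f"b{i}"] = delta.sum(axis=0)
                delta = (delta @ self.params[f"W{i}"].T).reshape(in_shape)
            elif t == "relu":
                delta = delta * entry[2]
            elif t == "dropout":
                keep = entry[2]
                if keep is not None:
                    delta = np.where(keep, delta / (1.0 - self.spec.dropout_rate), 0.0)
            elif t == "maxpool":
                _, _, in_shape, arg, (k, stride, Ho, Wo) = entry
                N, H, W, C = in_shape
                dcols = np.zeros((N, Ho * Wo, k * k, C))
                np.put_along_axis(dcols, arg[:, :, None, :],
                                  delta.reshape(N, Ho * Wo, 1, C), axis=2)
                delta = self._col2im(dcols, in_shape, k, stride)
            elif t == "avgpool":
                _, _, in_shape, _, (k, stride, Ho, Wo) = entry
                N, H, W, C = in_shape
                dcols = np.broadcast_to(
                    delta.reshape(N, Ho * Wo, 1, C) / (k * k), (N, Ho * Wo, k * k, C))
                delta = self._col2im(np.ascontiguousarray(dcols), in_shape, k, stride)
            elif t == "conv":
                _, _, in_shape, cols = entry
                k = layer["kernel"]
                stride, pad = layer.get("stride", 1), layer.get("pad", 0)
                W = self.params[f"W{i}"]
                N, Ho, Wo, F = delta.shape
                dflat = delta.reshape(N, Ho * Wo, F)
                grads[f"W{i}"] = np.einsum("npk,npf->kf", cols, dflat).reshape(W.shape)
                grads[f"b{i}"] = dflat.sum(axis=(0, 1))
                dcols = dflat @ W.reshape(-1, F).T
                C_in = in_shape[3]
                dcols = dcols.reshape(N, Ho * Wo, k * k, C_in)
                padded_shape = (N, in_shape[1] + 2 * pad, in_shape[2] + 2 * pad, C_in)
                dpad = self._col2im(dcols, padded_shape, k, stride)
                delta = dpad[:, pad: pad + in_shape[1], pad: pad + in_shape[2], :] if pad else dpad
        return grads

    @staticmethod
    def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int) -> np.ndarray:
        N, H, W, C = shape
        Ho = (H - k) // stride + 1
        Wo = (W - k) // stride + 1
        out = np.zeros(shape)
        d = dcols.reshape(N, Ho, Wo, k, k, C)
        for a in range(k):
            for b in range(k):
                out[:, a: a + Ho * stride: stride, b: b + Wo * stride: stride, :] += d[:, :, :, a, b, :]
        return out

    # -- training ----------------------------------------------------------
    def fit(self, images: np.ndarray, labels: np.ndarray, epochs: int = 40,
            batch_size: int = 16, learning_rate: float = 0.05,
            momentum: float = 0.9) -> list[float]:
        """Mini-batch SGD on cross-entropy; returns the per-epoch mean loss."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        y = np.asarray(labels, dtype=np.int64)
        n = x.shape[0]
        y_onehot = np.eye(2)[y]
        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        losses = []
        step = 0
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start: start + batch_size]
                probs, cache = self._forward(x[idx], "train",
                                             dropout_seed=self.seed * 7919 + step)
                eps = 1e-12
                epoch_loss += -np.sum(np.log(probs[np.arange(idx.size), y[idx]] + eps))
                grads = self._backward(probs, y_onehot[idx], cache)
                for key, g in grads.items():
                    velocity[key] = momentum * velocity[key] - learning_rate * g
                    self.params[key] += velocity[key]
                step += 1
            losses.append(epoch_loss / n)
            if not np.isfinite(losses[-1]):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss {losses[-1]})")
        return losses

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        probs, _ = self._forward(x, "eval")
        return probs

    def features(self, images: np.ndarray) -> np.ndarray:
        """Deep features: flattened activation at the spec's tap layer (eval mode)."""
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        out, _ = self._forward(x, "eval", tap=self.spec.feature_tap)
        return out

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"version": 1, "seed": self.seed,
                "spec": {"input_size": self.spec.input_size,
                         "input_channels": self.spec.input_channels,
                         "layers": list(self.spec.layers),
                         "dropout_rate": self.spec.dropout_rate,
                         "feature_tap": self.spec.feature_tap}}
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MicroCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = MicroCNNSpec(
            input_size=meta["spec"]["input_size"],
            input_channels=meta["spec"]["input_channels"],
            layers=tuple(meta["spec"]["layers"]),
            dropout_rate=meta["spec"]["dropout_rate"],
            feature_tap=meta["spec"]["feature_tap"])
        model = cls(spec, seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k] for k in data.files}
        return model


def extract_deep_features(model: MicroCNN, image: np.ndarray) -> np.ndarray:
    """Deep-feature vector of one image (see :meth:`MicroCNN.features`)."""
    return model.features(np.asarray(image)[None])[0]
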