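"""Trainable classifiers and their flat weight-vector serialization.

The unit FedAvg operates on is a :class:`WeightVector`: every trainable
parameter of a model flattened into one ordered 1-D array, together with a
layout manifest (parameter names and shapes) that makes two vectors
aggregation-compatible exactly when their layouts match.

Two architectures are implemented natively in numpy so the whole pipeline is
deterministic and dependency-light:

* ``tiny_cnn`` — two 3x3 conv + ReLU + 2x2 max-pool blocks, global average
  pooling, and a linear softmax head.  The desk-scale default.
* ``linear`` — flatten + linear softmax head; its gradient has a short
  closed form, which makes it the fixture for analytic gradient checks.

The seven full-size backbones studied in the field (ResNet50, DenseNet121,
VGG16, MobileNetV2, InceptionV3, ViT-B/16, ViT-B/32) are registered names
that require a deep-learning backend; building one without its backend
raises an informative error.

Local training is plain mini-batch SGD on cross-entropy loss: a seeded
shuffle per epoch, full passes over the data, last batch possibly short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import LabeledImageSet

NATIVE_ARCHITECTURES = ("tiny_cnn", "linear")
BACKBONE_ARCHITECTURES = (
    "resnet50",
    "densenet121",
    "vgg16",
    "mobilenet_v2",
    "inception_v3",
    "vit_b16",
    "vit_b32",
)
ARCHITECTURES = NATIVE_ARCHITECTURES + BACKBONE_ARCHITECTURES


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice plus everything needed to rebuild it exactly."""

    architecture: str = "tiny_cnn"
    n_classes: int = 4
    input_size: tuple[int, int] = (32, 32)
    pretrained: bool = False
    init_seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"known: {', '.join(ARCHITECTURES)}"
            )
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        h, w = self.input_size
        if self.architecture == "tiny_cnn" and (h < 16 or w < 16):
            raise ValueError(
                f"tiny_cnn needs input_size >= 16, got {self.input_size}"
            )


@dataclass(frozen=True)
class WeightVector:
    """Flat, ordered serialization of all trainable parameters."""

    values: np.ndarray
    layout: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        object.__setattr__(self, "values", vals)
        layout = tuple((str(n), tuple(int(d) for d in s)) for n, s in self.layout)
        object.__setattr__(self, "layout", layout)
        expected = sum(int(np.prod(s)) for _, s in layout)
        if expected != len(vals):
            raise ValueError(
                f"layout declares {expected} parameters but values has {len(vals)}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def compatible_with(self, other: "WeightVector") -> bool:
        return self.layout == other.layout

    def unflatten(self) -> dict[str, np.ndarray]:
        out = {}
        start = 0
        for name, shape in self.layout:
            size = int(np.prod(shape))
            out[name] = self.values[start : start + size].reshape(shape).copy()
            start += size
        return out

    @classmethod
    def from_params(cls, params: dict[str, np.ndarray]) -> "WeightVector":
        layout = tuple((name, tuple(p.shape)) for name, p in params.items())
        values = np.concatenate([p.ravel() for p in params.values()])
        return cls(values, layout)


def check_layouts(a: WeightVector, b: WeightVector) -> None:
    """Raise with the first differing parameter name if layouts mismatch."""
    if a.layout == b.layout:
        return
    for (na, sa), (nb, sb) in zip(a.layout, b.layout):
        if na != nb or sa != sb:
            raise ValueError(
                f"weight layout mismatch at parameter {na!r} "
                f"({sa} vs {nb!r} {sb})"
            )
    raise ValueError(
        f"weight layout mismatch: {len(a.layout)} vs {len(b.layout)} parameters"
    )


# ---------------------------------------------------------------------------
# numpy models


class _NumpyModel:
    """Base: ordered parameter dict + flat (de)serialization + SGD step."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params: dict[str, np.ndarray] = {}

    # -- weights ------------------------------------------------------------
    def get_weights(self) -> WeightVector:
        return WeightVector.from_params(self.params)

    def set_weights(self, w: WeightVector) -> None:
        check_layouts(self.get_weights(), w)
        self.params = w.unflatten()

    # -- interface implemented by subclasses --------------------------------
    def logits(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        raise NotImplementedError

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.logits(x), axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class LinearSoftmax(_NumpyModel):
    """Flattened-pixel linear softmax classifier (analytic-gradient fixture)."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        h, w = spec.input_size
        d = h * w * 3
        rng = np.random.default_rng(spec.init_seed)
        self.params = {
            "fc.weight": rng.normal(0.0, 0.01, size=(d, spec.n_classes)),
            "fc.bias": np.zeros(spec.n_classes),
        }

    def logits(self, x: np.ndarray) -> np.ndarray:
        flat = x.reshape(len(x), -1)
        return flat @ self.params["fc.weight"] + self.params["fc.bias"]

    def loss_and_grads(self, x, y):
        flat = x.reshape(len(x), -1)
        probs = _softmax(flat @ self.params["fc.weight"] + self.params["fc.bias"])
        loss = _cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)
        grads = {
            "fc.weight": flat.T @ dlogits,
            "fc.bias": dlogits.sum(axis=0),
        }
        return loss, grads


def _conv3x3_forward(xp: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-convolution on pre-padded input ``xp`` (N, H+2, W+2, Cin)."""
    n, hp, wp, _ = xp.shape
    h, wid = hp - 2, wp - 2
    out = np.tile(b, (n, h, wid, 1)).astype(np.float64)
    for di in range(3):
        for dj in range(3):
            out += xp[:, di : di + h, dj : dj + wid, :] @ w[di, dj]
    return out


def _conv3x3_backward(
    xp: np.ndarray, w: np.ndarray, dz: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dxp, dw, db) of the same-convolution above."""
    n, hp, wp, cin = xp.shape
    h, wid = hp - 2, wp - 2
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    dz2 = dz.reshape(-1, dz.shape[-1])
    for di in range(3):
        for dj in range(3):
            xs = xp[:, di : di + h, dj : dj + wid, :].reshape(-1, cin)
            dw[di, dj] = xs.T @ dz2
            dxp[:, di : di + h, dj : dj + wid, :] += dz @ w[di, dj].T
    db = dz.sum(axis=(0, 1, 2))
    return dxp, dw, db


def _maxpool2_forward(a: np.ndarray):
    n, h, w, c = a.shape
    hp, wp = h // 2, w // 2
    win = a[:, : 2 * hp, : 2 * wp, :].reshape(n, hp, 2, wp, 2, c)
    out = win.max(axis=(2, 4))
    mask = win == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    return out, (mask, counts, a.shape)


def _maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    mask, counts, shape = cache
    n, h, w, c = shape
    hp, wp = mask.shape[1], mask.shape[3]
    da = np.zeros(shape)
    spread = mask * (dout[:, :, None, :, None, :] / counts)
    da[:, : 2 * hp, : 2 * wp, :] = spread.reshape(n, 2 * hp, 2 * wp, c)
    return da


class TinyCNN(_NumpyModel):
    """Two conv blocks + global average pooling + linear softmax head.

    conv(3->8, 3x3) / ReLU / pool2  ->  conv(8->16, 3x3) / ReLU / pool2
    -> global average pool -> linear(16 -> K).  He-initialized from
    ``init_seed``; ~1.5k parameters, CPU-friendly at 32x32.
    """

    F1, F2 = 8, 16

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        rng = np.random.default_rng(spec.init_seed)
        f1, f2, k = self.F1, self.F2, spec.n_classes
        self.params = {
            "conv1.weight": rng.normal(0, np.sqrt(2.0 / (9 * 3)), (3, 3, 3, f1)),
            "conv1.bias": np.zeros(f1),
            "conv2.weight": rng.normal(0, np.sqrt(2.0 / (9 * f1)), (3, 3, f1, f2)),
            "conv2.bias": np.zeros(f2),
            "head.weight": rng.normal(0, np.sqrt(2.0 / f2), (f2, k)),
            "head.bias": np.zeros(k),
        }

    def _forward(self, x: np.ndarray, need_cache: bool):
        p = self.params
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        z1 = _conv3x3_forward(xp, p["conv1.weight"], p["conv1.bias"])
        a1 = np.maximum(z1, 0.0)
        p1, cache1 = _maxpool2_forward(a1)

        p1p = np.pad(p1, ((0, 0), (1, 1), (1, 1), (0, 0)))
        z2 = _conv3x3_forward(p1p, p["conv2.weight"], p["conv2.bias"])
        a2 = np.maximum(z2, 0.0)
        p2, cache2 = _maxpool2_forward(a2)

        feats = p2.mean(axis=(1, 2))
        logits = feats @ p["head.weight"] + p["head.bias"]
        if not need_cache:
            return logits, None
        return logits, (xp, z1, cache1, p1p, z2, cache2, p2.shape, feats)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x, need_cache=False)[0]

    def loss_and_grads(self, x, y):
        p = self.params
        logits, cache = self._forward(x, need_cache=True)
        xp, z1, cache1, p1p, z2, cache2, p2_shape, feats = cache

        probs = _softmax(logits)
        loss = _cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits /= len(y)

        grads = {
            "head.weight": feats.T @ dlogits,
            "head.bias": dlogits.sum(axis=0),
        }
        dfeats = dlogits @ p["head.weight"].T
        n, h2, w2, f2 = p2_shape
        dp2 = np.broadcast_to(
            dfeats[:, None, None, :] / (h2 * w2), p2_shape
        ).copy()

        da2 = _maxpool2_backward(dp2, cache2)
        dz2 = da2 * (z2 > 0)
        dp1p, dw2, db2 = _conv3x3_backward(p1p, p["conv2.weight"], dz2)
        grads["conv2.weight"], grads["conv2.bias"] = dw2, db2

        dp1 = dp1p[:, 1:-1, 1:-1, :]
        da1 = _maxpool2_backward(dp1, cache1)
        dz1 = da1 * (z1 > 0)
        _, dw1, db1 = _conv3x3_backward(xp, p["conv1.weight"], dz1)
        grads["conv1.weight"], grads["conv1.bias"] = dw1, db1
        return loss, grads


def build_model(spec: ModelSpec) -> _NumpyModel:
    """Instantiate the classifier named by ``spec``.

    Native architectures (``tiny_cnn``, ``linear``) are seeded numpy models;
    the named full-size backbones need a deep-learning backend and raise an
    informative error when none is installed.
    """
    spec.validate()
    if spec.architecture in BACKBONE_ARCHITECTURES:
        raise RuntimeError(
            f"architecture {spec.architecture!r} requires a deep-learning "
            "backend (e.g. torch), which is not installed; use 'tiny_cnn' "
            "for the native desk-scale model"
        )
    if spec.pretrained:
        raise ValueError(
            f"no pretrained weights exist for native architecture "
            f"{spec.architecture!r}; set pretrained=False"
        )
    if spec.architecture == "linear":
        return LinearSoftmax(spec)
    return TinyCNN(spec)


def local_train(
    model: _NumpyModel,
    data: LabeledImageSet,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
) -> tuple[WeightVector, list[float]]:
    """Mini-batch SGD with cross-entropy loss, in place on ``model``.

    Each epoch is one full pass in a freshly seeded shuffled order; the last
    batch may be short.  Returns the post-training weights and the mean
    per-sample loss of each epoch (measured on the pre-update batches, i.e.
    the running training loss).  lr = 0 degenerates to a no-op on the
    weights while still reporting losses.
    """
    if len(data) == 0:
        raise ValueError("cannot train on an empty dataset")
    if epochs < 1 or batch_size < 1:
        raise ValueError("epochs and batch_size must be >= 1")
    if lr < 0:
        raise ValueError(f"learning rate must be >= 0, got {lr}")
    rng = np.random.default_rng(seed)
    n = len(data)
    epoch_losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = data.images[idx], data.labels[idx]
            loss, grads = model.loss_and_grads(xb, yb)
            total += loss * len(idx)
            if lr > 0:
                for name, g in grads.items():
                    model.params[name] -= lr * g
        epoch_losses.append(total / n)
    return model.get_weights(), epoch_losses
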