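"""Barcode-image classifiers.

Two architectures behind one interface:

* ``small_cnn`` -- a compact two-conv-layer network implemented directly in
  numpy (im2col convolutions, 2x2 max pooling, softmax cross-entropy,
  Adam).  Runs in seconds on a single CPU core and is fully deterministic
  under a fixed seed, which makes it the default for tests and desk-scale
  experiments.
* ``googlenet_transfer`` -- GoogLeNet with the final layer re-initialized
  to ``n_classes``, via torch/torchvision when those optional dependencies
  are installed.

Both consume the RGB rasters produced by :mod:`topoeeg.images` and support
any number of classes >= 2.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .images import BarcodeImage

__all__ = ["ClassifierConfig", "TrainedModel", "train", "predict", "save_model", "load_model"]


class LabelError(ValueError):
    """Training requires at least two classes."""


class InputSizeError(ValueError):
    """Image size incompatible with the trained architecture."""


@dataclass
class ClassifierConfig:
    architecture: str = "small_cnn"  # or "googlenet_transfer"
    n_classes: int = 2
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    device: str = "cpu"
    input_size: int = 32  # small_cnn internal resolution (images block-averaged down)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.architecture not in ("small_cnn", "googlenet_transfer"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class TrainedModel:
    """Weights plus a manifest sufficient to reproduce training."""

    architecture: str
    params: dict
    class_labels: list[str]
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# image tensor preparation


def _as_pixel_array(images: Sequence) -> np.ndarray:
    arrs = [im.pixels if isinstance(im, BarcodeImage) else np.asarray(im) for im in images]
    return np.stack(arrs)


def _prepare(images: Sequence, input_size: int) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float (N, 1, s, s): grayscale, inverted, block-averaged."""
    x = _as_pixel_array(images).astype(np.float64)
    if x.ndim != 4 or x.shape[3] != 3 or x.shape[1] != x.shape[2]:
        raise InputSizeError("expected square RGB images")
    h = x.shape[1]
    if h % input_size != 0:
        raise InputSizeError(
            f"image size {h} not divisible by network input size {input_size}"
        )
    gray = 1.0 - x.mean(axis=3) / 255.0  # bars bright on zero background
    f = h // input_size
    n = gray.shape[0]
    gray = gray.reshape(n, input_size, f, input_size, f).mean(axis=(2, 4))
    return gray[:, None, :, :]


# ---------------------------------------------------------------------------
# numpy CNN primitives


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di, dj] = x[:, :, di : di + oh, dj : dj + ow]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    n, c, h, w = shape
    oh, ow = h - k + 1, w - k + 1
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    dx = np.zeros(shape, dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dx[:, :, di : di + oh, dj : dj + ow] += dcols[:, :, di, dj]
    return dx


def _conv_forward(x, w, b):
    f, c, k, _ = w.shape
    cols = _im2col(x, k)
    out = np.matmul(w.reshape(f, -1), cols)
    n = x.shape[0]
    oh = x.shape[2] - k + 1
    out = out.reshape(n, f, oh, -1) + b[None, :, None, None]
    return out, cols


def _conv_backward(dout, cols, x_shape, w):
    f, c, k, _ = w.shape
    n = dout.shape[0]
    doutm = dout.reshape(n, f, -1)
    dw = np.einsum("nfl,nkl->fk", doutm, cols).reshape(w.shape)
    db = dout.sum(axis=(0, 2, 3))
    dcols = np.matmul(w.reshape(f, -1).T, doutm)
    dx = _col2im(dcols, x_shape, k)
    return dx, dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _pool_backward(dout, mask):
    return (mask * dout[:, :, :, None, :, None]).reshape(
        mask.shape[0], mask.shape[1], mask.shape[2] * 2, mask.shape[4] * 2
    )


class _SmallCNN:
    """conv(8,3x3)-relu-pool - conv(16,3x3)-relu-pool - dense-softmax."""

    def __init__(self, n_classes: int, input_size: int, rng: np.random.Generator):
        s1 = input_size - 2          # after conv1
        p1 = s1 // 2                 # after pool1
        s2 = p1 - 2                  # after conv2
        self.crop2 = s2 - (s2 % 2)   # even-crop before pool2
        p2 = self.crop2 // 2
        self.flat = 16 * p2 * p2
        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.params = {
            "W1": he((8, 1, 3, 3), 9),
            "b1": np.zeros(8),
            "W2": he((16, 8, 3, 3), 8 * 9),
            "b2": np.zeros(16),
            "W3": he((self.flat, n_classes), self.flat),
            "b3": np.zeros(n_classes),
        }

    def forward(self, x):
        p = self.params
        z1, cols1 = _conv_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        o1, mask1 = _pool_forward(a1)
        z2, cols2 = _conv_forward(o1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)
        a2c = a2[:, :, : self.crop2, : self.crop2]
        o2, mask2 = _pool_forward(a2c)
        flat = o2.reshape(x.shape[0], -1)
        logits = flat @ p["W3"] + p["b3"]
        cache = (x, cols1, z1, o1, cols2, z2, a2.shape, mask1, mask2, flat)
        return logits, cache

    def backward(self, dlogits, cache):
        p = self.params
        x, cols1, z1, o1, cols2, z2, a2_shape, mask1, mask2, flat = cache
        grads = {}
        grads["W3"] = flat.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["W3"].T
        n = x.shape[0]
        do2 = dflat.reshape(n, 16, self.crop2 // 2, self.crop2 // 2)
        da2c = _pool_backward(do2, mask2)
        da2 = np.zeros(a2_shape)
        da2[:, :, : self.crop2, : self.crop2] = da2c
        dz2 = da2 * (z2 > 0)
        do1, grads["W2"], grads["b2"] = _conv_backward(dz2, cols2, o1.shape, p["W2"])
        da1 = _pool_backward(do1, mask1)
        dz1 = da1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(dz1, cols1, x.shape, p["W1"])
        return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _data_hash(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(x.tobytes())
    h.update(y.tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# public interface


def train(
    images: Sequence,
    labels: Sequence[str],
    config: Optional[ClassifierConfig] = None,
) -> TrainedModel:
    """Train a classifier on labeled barcode images.

    Raises :class:`LabelError` when fewer than two classes are present.
    Seeded runs over the same data and config are bit-reproducible for
    ``small_cnn``.
    """
    if config is None:
        config = ClassifierConfig()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise LabelError(f"need >= 2 classes, got {classes}")
    if len(classes) > config.n_classes:
        raise LabelError(
            f"{len(classes)} classes present but n_classes={config.n_classes}"
        )
    if config.architecture == "googlenet_transfer":
        return _train_googlenet(images, labels, classes, config)

    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[lab] for lab in labels], dtype=np.int64)
    x = _prepare(images, config.input_size)
    rng = np.random.default_rng(config.seed)
    net = _SmallCNN(config.n_classes, config.input_size, rng)

    adam_m = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(y)
    onehot = np.eye(config.n_classes)[y]
    for _epoch in range(config.epochs):
        perm = rng.permutation(n)
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            logits, cache = net.forward(x[idx])
            probs = _softmax(logits)
            dlogits = (probs - onehot[idx]) / len(idx)
            grads = net.backward(dlogits, cache)
            step += 1
            lr = config.learning_rate
            for k, g in grads.items():
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                mhat = adam_m[k] / (1 - b1**step)
                vhat = adam_v[k] / (1 - b2**step)
                net.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    manifest = {
        "config": asdict(config),
        "data_hash": _data_hash(x, y),
        "n_train": int(n),
        "class_counts": {c: int((y == i).sum()) for c, i in class_to_idx.items()},
        "image_size": int(_as_pixel_array(images[:1]).shape[1]),
    }
    return TrainedModel(
        architecture="small_cnn",
        params=net.params,
        class_labels=classes,
        manifest=manifest,
    )


def predict(model: TrainedModel, images: Sequence) -> tuple[list[str], np.ndarray]:
    """Labels and class-score vectors (rows sum to 1) for each image."""
    if len(images) == 0:
        return [], np.zeros((0, len(model.class_labels)))
    if model.architecture == "googlenet_transfer":
        return _predict_googlenet(model, images)
    config = model.manifest["config"]
    expected = model.manifest.get("image_size")
    arr = _as_pixel_array(images)
    if expected is not None and arr.shape[1] != expected:
        raise InputSizeError(
            f"model trained on {expected}px images, got {arr.shape[1]}px"
        )
    x = _prepare(images, config["input_size"])
    net = _SmallCNN.__new__(_SmallCNN)
    net.params = model.params
    s1 = config["input_size"] - 2
    s2 = s1 // 2 - 2
    net.crop2 = s2 - (s2 % 2)
    logits, _ = net.forward(x)
    scores = _softmax(logits)
    scores = scores[:, : len(model.class_labels)]
    scores = scores / scores.sum(axis=1, keepdims=True)
    idx = scores.argmax(axis=1)
    return [model.class_labels[i] for i in idx], scores


def save_model(model: TrainedModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        **model.params,
        __meta__=json.dumps(
            {
                "architecture": model.architecture,
                "class_labels": model.class_labels,
                "manifest": model.manifest,
            }
        ),
    )
    return path


def load_model(path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    params = {k: data[k] for k in data.files if k != "__meta__"}
    return TrainedModel(
        architecture=meta["architecture"],
        params=params,
        class_labels=meta["class_labels"],
        manifest=meta["manifest"],
    )


# ---------------------------------------------------------------------------
# GoogLeNet transfer learning (optional torch dependency)


def _require_torch():
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "architecture 'googlenet_transfer' requires the optional "
            "dependencies torch and torchvision (pip install topoeeg[torch])"
        ) from exc
    return torch, torchvision


def _train_googlenet(images, labels, classes, config):  # pragma: no cover
    torch, torchvision = _require_torch()
    torch.manual_seed(config.seed)
    net = torchvision.models.googlenet(weights=None, aux_logits=False, init_weights=True)
    net.fc = torch.nn.Linear(net.fc.in_features, config.n_classes)
    x = _as_pixel_array(images).astype(np.float32) / 255.0
    x = torch.from_numpy(x.transpose(0, 3, 1, 2))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = torch.tensor([class_to_idx[lab] for lab in labels])
    opt = torch.optim.Adam(net.parameters(), lr=config.learning_rate)
    loss_fn = torch.nn.CrossEntropyLoss()
    net.train()
    for _ in range(config.epochs):
        perm = torch.randperm(len(y))
        for lo in range(0, len(y), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            opt.zero_grad()
            loss = loss_fn(net(x[idx]), y[idx])
            loss.backward()
            opt.step()
    params = {k: v.detach().numpy() for k, v in net.state_dict().items()}
    return TrainedModel(
        architecture="googlenet_transfer",
        params=params,
        class_labels=classes,
        manifest={"config": asdict(config), "n_train": len(y)},
    )


def _predict_googlenet(model, images):  # pragma: no cover
    torch, torchvision = _require_torch()
    net = torchvision.models.googlenet(weights=None, aux_logits=False, init_weights=False)
    net.fc = torch.nn.Linear(net.fc.in_features, len(model.class_labels))
    net.load_state_dict({k: torch.from_numpy(v) for k, v in model.params.items()})
    net.eval()
    x = _as_pixel_array(images).astype(np.float32) / 255.0
    x = torch.from_numpy(x.transpose(0, 3, 1, 2))
    with torch.no_grad():
        scores = torch.softmax(net(x), dim=1).numpy()
    idx = scores.argmax(axis=1)
    return [model.class_labels[i] for i in idx], scores
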