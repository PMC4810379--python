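"""Patch classification networks for benthic point annotation.

Three networks share one architecture and differ only in input channels:
``f_ref`` (3-channel reflectance), ``f_flr`` (2-channel fluorescence) and
``f_five`` (the 5-channel stack).  The architecture follows the classic
cifar10 shape for 32 x 32 inputs: three rounds of 5 x 5 convolution,
3 x 3 stride-2 max pooling and rectification, then a linear head emitting one
score per category.  Classification assigns the label with the largest score.

The implementation is pure numpy: convolutions run as im2col matrix products
on BLAS, training uses softmax cross-entropy with SGD + momentum, and every
source of randomness flows from the spec seed, so training is reproducible
bit-for-bit on a given machine.  Scores passed downstream are pre-softmax
logits by default (the fusion stage standardizes them anyway); softmax
probabilities are available via ``score_mode``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .datamodel import LabelSet
from .patching import PatchTensor, stack_pixels


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and training hyper-parameters of a patch network.

    ``filters`` are the three conv-block widths (the reference shape is
    32/32/64); ``lr_decay_at`` are epoch fractions at which the learning rate
    is multiplied by ``lr_decay``.
    """

    in_channels: int
    n_classes: int = 10
    filters: tuple[int, int, int] = (32, 32, 64)
    kernel: int = 5
    epochs: int = 60
    batch_size: int = 128
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay: float = 0.1
    lr_decay_at: tuple[float, ...] = (0.75,)
    seed: int = 0
    score_mode: str = "logit"  # or "softmax"

    def __post_init__(self) -> None:
        if self.in_channels not in (2, 3, 5):
            raise ValueError(f"in_channels must be 2, 3 or 5, got {self.in_channels}")
        if len(self.filters) != 3:
            raise ValueError("exactly three conv blocks are required")
        if self.score_mode not in ("logit", "softmax"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")

    @classmethod
    def reduced(cls, in_channels: int, **kw) -> "NetworkSpec":
        """A slimmed configuration (8/8/16 filters, few epochs) for CPU-scale
        experiments; same depth and layer types as the full network."""
        kw.setdefault("filters", (8, 8, 16))
        kw.setdefault("epochs", 3)
        kw.setdefault("lr", 0.02)
        return cls(in_channels=in_channels, **kw)


# ---------------------------------------------------------------- layer math
#
# Activations flow through the conv stack in channels-first (C, N, H, W)
# layout: the im2col product then lands directly in the next layer's layout
# with no transposes, which matters on a single CPU core.


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(C, N, H, W) -> (C*k*k, N*H*W) patch matrix for stride-1 'same' conv."""
    c, n, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((c, k, k, n, h, w), dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            cols[:, di, dj] = xp[:, :, di : di + h, dj : dj + w]
    return cols.reshape(c * k * k, n * h * w)


class _Conv:
    """5x5 stride-1 'same' convolution via im2col.

    ``input_grad=False`` (first layer) skips the dx computation entirely.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        input_grad: bool = True,
    ):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.pad = k // 2
        self.input_grad = input_grad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, n, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = self.w.reshape(len(self.w), -1) @ cols
        out += self.b[:, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(len(self.w), n, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        c, n, h, w = self._xshape
        f = len(self.w)
        dy_mat = dy.reshape(f, n * h * w)
        self.dw = (dy_mat @ self._cols.T).reshape(self.w.shape)
        self.db = dy_mat.sum(axis=1)
        if not self.input_grad:
            del self._cols
            return None
        dcols = self.w.reshape(f, -1).T @ dy_mat  # (C*k*k, N*H*W)
        dcols = dcols.reshape(c, self.k, self.k, n, h, w)
        p = self.pad
        dxp = np.zeros((c, n, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, di, dj]
        del self._cols
        return dxp[:, :, p : p + h, p : p + w]

    params = property(lambda self: [(self.w, "dw"), (self.b, "db")])


class _MaxPool:
    """3x3 stride-2 max pooling with single-pixel padding (halves H and W)."""

    k, stride, pad = 3, 2, 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, n, h, w = x.shape
        xp = np.full(
            (c, n, h + 2 * self.pad, w + 2 * self.pad), -np.inf, dtype=np.float32
        )
        xp[:, :, self.pad : self.pad + h, self.pad : self.pad + w] = x
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))[
            :, :, :: self.stride, :: self.stride
        ]  # (C, N, oh, ow, k, k)
        flat = win.reshape(*win.shape[:4], -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._xshape = arg, x.shape
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = self._xshape
        oh, ow = dy.shape[2:]
        dxp = np.zeros(
            (c, n, h + 2 * self.pad, w + 2 * self.pad), dtype=np.float32
        )
        for di in range(self.k):
            for dj in range(self.k):
                sel = self._arg == di * self.k + dj
                dxp[:, :, di : di + 2 * oh : 2, dj : dj + 2 * ow : 2] += dy * sel
        return dxp[:, :, self.pad : self.pad + h, self.pad : self.pad + w]

    params = property(lambda self: [])


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    params = property(lambda self: [])


class _Flatten:
    """(C, N, h, w) -> (N, C*h*w) for the linear head."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        c, n, h, w = x.shape
        return np.ascontiguousarray(x.transpose(1, 0, 2, 3).reshape(n, c * h * w))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, n, h, w = self._shape
        return np.ascontiguousarray(
            dy.reshape(n, c, h, w).transpose(1, 0, 2, 3)
        )

    params = property(lambda self: [])


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    params = property(lambda self: [(self.w, "dw"), (self.b, "db")])


def _dihedral_batch(xb: np.ndarray, tags: np.ndarray) -> np.ndarray:
    """Apply per-sample dihedral elements (0-7) to an (B, C, H, W) batch.

    Tag k encodes the same operations as :data:`reeffusion.patching.D4_TAGS`:
    k >= 4 mirrors about the vertical axis, then rotates by (k % 4) right
    angles counter-clockwise.
    """
    out = np.empty_like(xb)
    for k in range(8):
        sel = tags == k
        if not sel.any():
            continue
        part = xb[sel]
        if k >= 4:
            part = part[..., ::-1]
        part = np.rot90(part, k % 4, axes=(2, 3))
        out[sel] = part
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------ network


class PatchNetwork:
    """A trained (or trainable) patch -> score-vector mapping."""

    def __init__(self, spec: NetworkSpec, labelset: LabelSet):
        if spec.n_classes != len(labelset):
            raise ValueError("spec.n_classes must equal the label-set size")
        self.spec = spec
        self.labelset = labelset
        self.channel_means = np.zeros(spec.in_channels, dtype=np.float32)
        self.loss_history: list[float] = []
        rng = np.random.default_rng(spec.seed)
        f1, f2, f3 = spec.filters
        k = spec.kernel
        self.layers = [
            _Conv(spec.in_channels, f1, k, rng, input_grad=False),
            _MaxPool(),
            _ReLU(),
            _Conv(f1, f2, k, rng),
            _MaxPool(),
            _ReLU(),
            _Conv(f2, f3, k, rng),
            _MaxPool(),
            _ReLU(),
            _Flatten(),
            _Linear(f3 * 4 * 4, spec.n_classes, rng),
        ]
        self._rng = rng

    # -- plumbing

    def _check_channels(self, x: np.ndarray) -> None:
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"network expects {self.spec.in_channels} channels, got {x.shape[1]}"
            )

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # -> (C, N, H, W)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def _backward(self, dz: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dz = layer.backward(dz)

    # -- training

    def fit(
        self, x: np.ndarray, y: np.ndarray, orbit_augment: bool = False
    ) -> "PatchNetwork":
        """Train on an (N, C, 32, 32) tensor and integer labels.

        Every class of the label set must be present in ``y``.  With
        ``orbit_augment`` the training set is virtually expanded to the
        8-element dihedral orbit of every patch (rotations by right angles,
        each optionally mirrored), materialized per batch rather than up
        front — the tensors seen by the optimizer are identical to
        pre-augmenting, at an eighth of the memory.
        """
        self._check_channels(x)
        present = np.unique(y)
        missing = sorted(set(range(self.spec.n_classes)) - set(present.tolist()))
        if missing:
            names = [self.labelset.labels[i] for i in missing]
            raise ValueError(f"classes absent from training data: {names}")

        x = np.asarray(x, dtype=np.float32)
        self.channel_means = x.mean(axis=(0, 2, 3)).astype(np.float32)
        x = x - self.channel_means[None, :, None, None]

        spec = self.spec
        n = len(x)
        n_virtual = 8 * n if orbit_augment else n
        velocity = {}
        lr = spec.lr
        decay_epochs = {int(np.floor(f * spec.epochs)) for f in spec.lr_decay_at}
        for epoch in range(spec.epochs):
            if epoch in decay_epochs and epoch > 0:
                lr *= spec.lr_decay
            order = self._rng.permutation(n_virtual)
            epoch_loss = 0.0
            for start in range(0, n_virtual, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                if orbit_augment:
                    xb = _dihedral_batch(x[idx // 8], idx % 8)
                    yb = y[idx // 8]
                else:
                    xb, yb = x[idx], y[idx]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                eps = 1e-12
                epoch_loss += -float(
                    np.log(probs[np.arange(len(yb)), yb] + eps).sum()
                )
                dz = probs
                dz[np.arange(len(yb)), yb] -= 1.0
                dz /= len(yb)
                self._backward(dz.astype(np.float32))
                for li, layer in enumerate(self.layers):
                    for param, gname in layer.params:
                        grad = getattr(layer, gname) + spec.weight_decay * param
                        key = (li, gname)
                        v = velocity.get(key)
                        v = (
                            spec.momentum * v - lr * grad
                            if v is not None
                            else -lr * grad
                        )
                        velocity[key] = v
                        param += v
            self.loss_history.append(epoch_loss / n_virtual)
        return self

    # -- inference

    def predict_scores_array(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Score an (N, C, 32, 32) tensor; returns (N, n_classes) scores."""
        self._check_channels(x)
        x = np.asarray(x, dtype=np.float32) - self.channel_means[None, :, None, None]
        chunks = [
            self._forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        logits = np.concatenate(chunks, axis=0)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite network scores")
        if self.spec.score_mode == "softmax":
            return _softmax(logits)
        return logits


def train_network(
    spec: NetworkSpec,
    patches: Sequence[PatchTensor],
    labelset: LabelSet | None = None,
    orbit_augment: bool = False,
) -> PatchNetwork:
    """Train a patch network on training patches.

    Pass pre-augmented patches, or plain per-annotation patches with
    ``orbit_augment=True`` to expand each to its 8-element dihedral orbit
    batch-by-batch during optimization.
    """
    labelset = labelset or LabelSet()
    net = PatchNetwork(spec, labelset)
    x = stack_pixels(patches)
    y = labelset.to_indices([p.label for p in patches])
    return net.fit(x, y, orbit_augment=orbit_augment)


def predict_scores(net: PatchNetwork, patches: Sequence[PatchTensor]) -> np.ndarray:
    """Score patches; one row of per-class scores per patch (no test-time
    augmentation or averaging)."""
    return net.predict_scores_array(stack_pixels(patches))


def classify(scores: np.ndarray, labelset: LabelSet | None = None) -> list[str]:
    """Argmax labels from score vectors; ties go to the lowest label index."""
    labelset = labelset or LabelSet()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if scores.shape[1] != len(labelset):
        raise ValueError(
            f"expected {len(labelset)} scores per patch, got {scores.shape[1]}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    return [labelset.labels[i] for i in scores.argmax(axis=1)]


# ------------------------------------------------------------- persistence


def save_network(net: PatchNetwork, path: str | Path) -> None:
    """Serialize spec + weights + channel means to an .npz checkpoint."""
    arrays = {"channel_means": net.channel_means}
    for i, layer in enumerate(net.layers):
        if hasattr(layer, "w"):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
    meta = {"spec": asdict(net.spec), "labels": list(net.labelset.labels),
            "coral_subset": list(net.labelset.coral_subset)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_network(path: str | Path) -> PatchNetwork:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        spec_d["filters"] = tuple(spec_d["filters"])
        spec_d["lr_decay_at"] = tuple(spec_d["lr_decay_at"])
        spec = NetworkSpec(**spec_d)
        labelset = LabelSet(tuple(meta["labels"]), tuple(meta["coral_subset"]))
        net = PatchNetwork(spec, labelset)
        net.channel_means = data["channel_means"]
        for i, layer in enumerate(net.layers):
            if hasattr(layer, "w"):
                layer.w = data[f"w{i}"]
                layer.b = data[f"b{i}"]
    return net
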