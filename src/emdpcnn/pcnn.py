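"""Parallel 1-D convolutional network for epoched EEG.

The network consumes a channels x time raster per trial.  A shared stem
(conv -> batch-norm -> ReLU, kernels spanning all input channels and
sliding only along time) feeds two parallel branches that differ in
their pooling operator — one max-pools, one average-pools — so the merge
sees both the sharpest and the smoothest view of the same features.
Branch outputs are concatenated and classified by a dropout-regularised
dense head ending in a K-way softmax.

Everything is implemented directly on NumPy arrays with exact analytic
gradients, which keeps the forward pass a pure function of (weights,
input) at inference and makes finite-difference gradient verification
part of the test surface rather than an afterthought.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = [
    "LayerSpec",
    "ArchConfig",
    "PCNNModel",
    "conv1d_forward",
    "activation",
    "pool",
    "softmax",
    "build_model",
    "predict",
]


# ---------------------------------------------------------------------------
# Stateless reference ops (the documented numerical contracts).
# ---------------------------------------------------------------------------

def activation(x: np.ndarray, name: str) -> np.ndarray:
    """Elementwise tanh, sigmoid or relu."""
    x = np.asarray(x, dtype=float)
    if name == "tanh":
        return np.tanh(x)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-x))
    if name == "relu":
        return np.maximum(0.0, x)
    if name in (None, "identity", "linear"):
        return x
    raise ValueError(f"unknown activation {name!r}")


def _pad_same(x: np.ndarray, Q: int) -> tuple[np.ndarray, int]:
    """Symmetric zero padding along time; extra sample on the right when Q is even."""
    left = (Q - 1) // 2
    right = Q - 1 - left
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(left, right)]), left


def conv1d_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    stride: int = 1,
    padding: str = "valid",
    f: str = "identity",
) -> np.ndarray:
    """Temporal cross-correlation with kernels spanning all channels.

    ``x`` is channels x time (or batch x channels x time); ``w`` is
    filters x channels x Q.  The kernel slides along time only; with
    ``padding="same"`` and stride 1 the output length equals the input
    length.  Output is filters x time' (with the batch axis preserved).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    w = np.asarray(w, dtype=float)
    F, C, Q = w.shape
    if x.shape[1] != C:
        raise ValueError(f"input has {x.shape[1]} channels, kernel expects {C}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if padding == "same":
        x, _ = _pad_same(x, Q)
    elif padding != "valid":
        raise ValueError(f"unknown padding {padding!r}")
    if x.shape[2] < Q:
        raise ValueError("input shorter than kernel")
    win = np.lib.stride_tricks.sliding_window_view(x, Q, axis=2)[:, :, ::stride]
    # win: (B, C, T', Q); w: (F, C, Q) -> (B, F, T')
    y = np.einsum("bctq,fcq->bft", win, w, optimize=True) + np.asarray(b)[None, :, None]
    y = activation(y, f)
    return y[0] if squeeze else y


def pool(x: np.ndarray, size: int, stride: int | None = None, kind: str = "max") -> np.ndarray:
    """Windowed max or mean along the trailing (time) axis.

    Windows are ``[k*stride, k*stride + size)``; a trailing partial
    window is dropped.
    """
    x = np.asarray(x, dtype=float)
    if stride is None:
        stride = size
    if size > x.shape[-1]:
        raise ValueError("pool size exceeds input length")
    win = np.lib.stride_tricks.sliding_window_view(x, size, axis=-1)[..., ::stride, :]
    if kind == "max":
        return win.max(axis=-1)
    if kind == "avg":
        return win.mean(axis=-1)
    raise ValueError(f"unknown pooling kind {kind!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Trainable layers (forward caches what backward needs).
# ---------------------------------------------------------------------------

class _Layer:
    """Base trainable layer; parameter-free layers inherit the no-ops."""

    trainable = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def penalized(self) -> list[bool]:
        """Which params receive the L2 penalty (weights yes, biases no)."""
        return [False] * len(self.params())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def spec(self) -> dict[str, Any]:
        raise NotImplementedError


class Conv1D(_Layer):
    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int = 1, padding: str = "same",
                 rng: np.random.Generator | None = None):
        if kernel < 1:
            raise ValueError("conv kernel must be >= 1")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel
        limit = np.sqrt(6.0 / fan_in)  # variance-scaled uniform, keyed to fan-in
        self.w = rng.uniform(-limit, limit, size=(filters, in_channels, kernel))
        self.b = np.zeros(filters)
        self.stride, self.padding = stride, padding
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def penalized(self):
        return [True, False]

    def forward(self, x, train):
        F, C, Q = self.w.shape
        if self.padding == "same":
            xp, _ = _pad_same(x, Q)
        else:
            xp = x
        self._xp = xp
        win = np.lib.stride_tricks.sliding_window_view(xp, Q, axis=2)[:, :, :: self.stride]
        y = np.einsum("bctq,fcq->bft", win, self.w, optimize=True) + self.b[None, :, None]
        self._t_out = y.shape[2]
        return y

    def backward(self, g):
        F, C, Q = self.w.shape
        xp = self._xp
        Tp = xp.shape[2]
        T_out = self._t_out
        self.db[...] = g.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        if self.stride == 1:
            # windows overlap but each tap q maps to a contiguous slice
            win = np.lib.stride_tricks.sliding_window_view(xp, Q, axis=2)
            self.dw[...] = np.einsum("bft,bctq->fcq", g, win, optimize=True)
            gx = np.einsum("bft,fcq->bctq", g, self.w, optimize=True)
            for q in range(Q):
                dxp[:, :, q : q + T_out] += gx[:, :, :, q]
        else:
            starts = np.arange(T_out) * self.stride
            for q in range(Q):
                cols = xp[:, :, starts + q]  # (B, C, T')
                self.dw[:, :, q] = np.einsum("bft,bct->fc", g, cols, optimize=True)
                np.add.at(dxp, (slice(None), slice(None), starts + q),
                          np.einsum("bft,fc->bct", g, self.w[:, :, q], optimize=True))
        if self.padding == "same":
            left = (Q - 1) // 2
            right = Q - 1 - left
            dxp = dxp[:, :, left : Tp - right]
        return dxp

    def spec(self):
        return {"kind": "conv1d", "filters": self.w.shape[0], "kernel": self.w.shape[2],
                "stride": self.stride, "padding": self.padding}


class BatchNorm(_Layer):
    """Per-feature-map batch normalization over (batch, time).

    Uses batch statistics during training (and accumulates running
    statistics with the given momentum); uses the stored running
    statistics at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        axes = (0, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._train = train
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, g):
        xhat, std = self._xhat, self._std
        self.dgamma[...] = (g * xhat).sum(axis=(0, 2))
        self.dbeta[...] = g.sum(axis=(0, 2))
        if not self._train:
            return g * self.gamma[None, :, None] / std[None, :, None]
        n = g.shape[0] * g.shape[2]
        gx = g * self.gamma[None, :, None]
        return (
            gx
            - gx.mean(axis=(0, 2))[None, :, None]
            - xhat * (gx * xhat).mean(axis=(0, 2))[None, :, None]
        ) / std[None, :, None]

    def spec(self):
        return {"kind": "batchnorm", "features": self.gamma.size}


class Activation(_Layer):
    def __init__(self, name: str):
        if name not in ("tanh", "sigmoid", "relu"):
            raise ValueError(f"unknown activation {name!r}")
        self.name = name

    def forward(self, x, train):
        y = activation(x, self.name)
        self._y = y
        return y

    def backward(self, g):
        y = self._y
        if self.name == "relu":
            return g * (y > 0)
        if self.name == "tanh":
            return g * (1.0 - y**2)
        return g * y * (1.0 - y)  # sigmoid

    def spec(self):
        return {"kind": "activation", "name": self.name}


class Pool(_Layer):
    def __init__(self, size: int, stride: int | None = None, kind: str = "max"):
        if size < 1:
            raise ValueError("pool size must be >= 1")
        if kind not in ("max", "avg"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.size, self.stride, self.kind = size, stride or size, kind

    def forward(self, x, train):
        self._x_shape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=-1)[
            ..., :: self.stride, :
        ]
        if self.kind == "max":
            self._argmax = win.argmax(axis=-1)
            return win.max(axis=-1)
        return win.mean(axis=-1)

    def backward(self, g):
        dx = np.zeros(self._x_shape)
        T_out = g.shape[-1]
        starts = np.arange(T_out) * self.stride
        b_idx = np.arange(self._x_shape[0])[:, None, None]
        f_idx = np.arange(self._x_shape[1])[None, :, None]
        if self.kind == "max":
            t_idx = starts[None, None, :] + self._argmax
            np.add.at(dx, (b_idx, f_idx, t_idx), g)
        else:
            share = g / self.size
            if self.stride >= self.size:  # windows disjoint: direct slice adds
                for o in range(self.size):
                    dx[:, :, starts + o] += share
            else:
                for o in range(self.size):
                    np.add.at(dx, (b_idx, f_idx, (starts + o)[None, None, :]), share)
        return dx

    def spec(self):
        return {"kind": f"{self.kind}pool", "size": self.size, "stride": self.stride}


class Dropout(_Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def spec(self):
        return {"kind": "dropout", "rate": self.rate}


class Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def spec(self):
        return {"kind": "flatten"}


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def penalized(self):
        return [True, False]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.dw[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.w.T

    def spec(self):
        return {"kind": "dense", "units": self.w.shape[1]}


@dataclass(frozen=True)
class LayerSpec:
    """Declarative layer description (used in saved architecture JSON)."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters of the parallel network.

    The defaults follow the reference design: a 32-filter stem with
    kernels of 20 samples and stride 1 under same-padding, batch-norm and
    ReLU; two 32-filter branches (kernel 10) that differ only in max vs
    average pooling; a 64-unit ReLU dense layer behind 0.5 dropout.
    """

    stem_filters: int = 32
    stem_kernel: int = 20
    stem_stride: int = 1
    branch_filters: int = 32
    branch_kernel: int = 10
    pool_size: int = 4
    pool_stride: int = 4
    dense_units: int = 64
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stem_filters", "stem_kernel", "branch_filters",
                     "branch_kernel", "pool_size", "pool_stride", "dense_units"):
            if getattr(self, name) < 1:
                raise ValueError(f"arch config field {name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("arch config field dropout must be in [0, 1)")


class PCNNModel:
    """Stem -> parallel (max-pool | avg-pool) branches -> concat -> dense head."""

    def __init__(self, input_shape: tuple[int, int], n_classes: int,
                 arch: ArchConfig = ArchConfig()):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.arch = arch
        rng = np.random.default_rng(arch.seed)
        C, T = input_shape

        self.stem: list[_Layer] = [
            Conv1D(C, arch.stem_filters, arch.stem_kernel, arch.stem_stride, "same", rng),
            BatchNorm(arch.stem_filters),
            Activation("relu"),
        ]
        t_stem = (T - 1) // arch.stem_stride + 1
        t_pool = (t_stem - arch.pool_size) // arch.pool_stride + 1
        self.branches: list[list[_Layer]] = [
            [
                Conv1D(arch.stem_filters, arch.branch_filters, arch.branch_kernel, 1, "same", rng),
                Activation("relu"),
                Pool(arch.pool_size, arch.pool_stride, kind),
            ]
            for kind in ("max", "avg")
        ]
        merged = 2 * arch.branch_filters * t_pool
        self.head: list[_Layer] = [
            Dropout(arch.dropout, rng),
            Flatten(),
            Dense(merged, arch.dense_units, rng),
            Activation("relu"),
            Dense(arch.dense_units, n_classes, rng),
        ]
        self._frozen: set[int] = set()

    # -- plumbing ----------------------------------------------------------
    def layers(self) -> list[_Layer]:
        out = list(self.stem)
        for br in self.branches:
            out.extend(br)
        out.extend(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def penalized_mask(self) -> list[bool]:
        return [m for layer in self.layers() for m in layer.penalized()]

    def trainable_mask(self) -> list[bool]:
        """Per-parameter trainability; stem layers may be frozen for transfer."""
        out = []
        stem_ids = {id(l) for l in self.stem}
        for layer in self.layers():
            frozen = id(layer) in self._frozen or (
                self._freeze_stem and id(layer) in stem_ids
            )
            out.extend([not frozen] * len(layer.params()))
        return out

    _freeze_stem = False

    def freeze_stem(self, flag: bool = True) -> None:
        self._freeze_stem = flag

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.copy() for p in self.parameters()]
        for layer in self.layers():
            if isinstance(layer, BatchNorm):
                ws.append(layer.run_mean.copy())
                ws.append(layer.run_var.copy())
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, w in zip(params, ws):
            p[...] = w
        extra = ws[len(params):]
        i = 0
        for layer in self.layers():
            if isinstance(layer, BatchNorm):
                layer.run_mean[...] = extra[i]
                layer.run_var[...] = extra[i + 1]
                i += 2

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model {self.input_shape}"
            )
        h = x
        for layer in self.stem:
            h = layer.forward(h, train)
        outs = []
        for br in self.branches:
            hb = h
            for layer in br:
                hb = layer.forward(hb, train)
            outs.append(hb)
        self._branch_widths = [o.shape[1] for o in outs]
        h = np.concatenate(outs, axis=1)
        for layer in self.head:
            h = layer.forward(h, train)
        return h

    def backward(self, g_logits: np.ndarray) -> None:
        g = g_logits
        for layer in reversed(self.head):
            g = layer.backward(g)
        gs = np.split(g, np.cumsum(self._branch_widths)[:-1], axis=1)
        g_stem = 0.0
        for br, gb in zip(self.branches, gs):
            for layer in reversed(br):
                gb = layer.backward(gb)
            g_stem = g_stem + gb
        for layer in reversed(self.stem):
            g_stem = layer.backward(g_stem)

    # -- serialization -----------------------------------------------------
    def architecture(self) -> dict[str, Any]:
        return {
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "arch": self.arch.__dict__,
            "stem": [l.spec() for l in self.stem],
            "branches": [[l.spec() for l in br] for br in self.branches],
            "head": [l.spec() for l in self.head],
        }

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.json`` (architecture) and ``<prefix>.npz`` (weights)."""
        prefix = Path(prefix)
        ws = self.get_weights()
        np.savez(prefix.with_suffix(".npz"), *ws)
        doc = self.architecture()
        doc["weights_checksum"] = int(
            sum(int(np.abs(w).sum() * 1e6) % (2**31) for w in ws) % (2**31)
        )
        prefix.with_suffix(".json").write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "PCNNModel":
        prefix = Path(prefix)
        doc = json.loads(prefix.with_suffix(".json").read_text())
        model = cls(tuple(doc["input_shape"]), doc["n_classes"], ArchConfig(**doc["arch"]))
        with np.load(prefix.with_suffix(".npz")) as npz:
            model.set_weights([npz[k] for k in npz.files])
        return model


def build_model(
    input_shape: tuple[int, int], n_classes: int, arch: ArchConfig = ArchConfig()
) -> PCNNModel:
    """Construct the parallel CNN for the given raster shape and class count."""
    return PCNNModel(input_shape, n_classes, arch)


def predict(model: PCNNModel, x: np.ndarray) -> np.ndarray:
    """Class-probability rows (softmax over logits) in inference mode."""
    return softmax(model.forward_logits(x, train=False))
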