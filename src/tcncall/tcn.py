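"""Temporal convolutional network for per-nucleotide sequence labeling.

The network maps a one-hot encoded code sequence (m+1 channels, the extra
channel being padding code 0) of length n to n softmax distributions over
the four per-base classes (normal, SNV, insertion, deletion). It is a
stack of residual blocks, one per dilation factor: each block applies
``convs_per_block`` repetitions of [weight-normalized dilated causal
convolution -> ReLU -> spatial dropout], adds a skip connection (identity
when channel counts match, a 1x1 convolution otherwise) and applies a
final ReLU. A 1x1 convolution and a position-shared affine map to the four
classes follow the blocks.

Causality: output position t depends only on input positions <= t, enforced
by left zero-padding of (K-1)*d per convolution. With dilations doubling
per block, the receptive field grows exponentially with depth:
1 + sum_blocks convs_per_block * (K-1) * d.

Everything here is NumPy: convolutions are im2col + BLAS matmuls, and each
layer carries an explicit backward pass, so training is exactly
reproducible from a seed on a single thread.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidArgumentError, InvalidStateError

DTYPE = np.float32

#: Absolute tolerance for float comparisons throughout the package.
FLOAT_ATOL = 1e-6


@dataclass
class TCNConfig:
    """Architecture hyperparameters.

    ``kernel_size`` is the number of taps per filter (called K to avoid a
    clash with the k-mer size k); ``in_dim`` is m+1 for the chosen k-mer
    table. Defaults follow the reference configuration: 128 kernels of
    size 16, dilations [1, 2, 4, 8, 16, 32], dropout 0.1.
    """

    n_channels: int = 128
    kernel_size: int = 16
    dilations: tuple = (1, 2, 4, 8, 16, 32)
    convs_per_block: int = 2
    dropout_rate: float = 0.1
    in_dim: int = 17            # m+1; 17 for 2-mers
    n_classes: int = 4
    seed: int = 0

    def validate(self) -> "TCNConfig":
        if any(d < 1 for d in self.dilations) or not self.dilations:
            raise ConfigError("dilations must be a non-empty positive list")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.n_classes != 4:
            raise ConfigError("the labeler is fixed at 4 classes")
        if min(self.n_channels, self.kernel_size, self.convs_per_block,
               self.in_dim) < 1:
            raise ConfigError("channel/kernel/block counts must be positive")
        return self


# ---------------------------------------------------------------------------
# Functional primitives
# ---------------------------------------------------------------------------

def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def weight_norm_apply(v: np.ndarray, g: float) -> np.ndarray:
    """Re-parameterize a filter as w = g * v / ||v|| (Euclidean norm).

    The effective weight's norm is |g| regardless of v's scale, which
    decouples the length of each filter from its direction.
    """
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise InvalidArgumentError("weight_norm_apply: zero-norm direction")
    return g * v / norm


def causal_dilated_conv(x: np.ndarray, f: np.ndarray, d: int,
                        bias: np.ndarray | None = None) -> np.ndarray:
    """Dilated causal convolution: y[t] = sum_i f[i] * x[t - d*i].

    ``x`` may be a 1-D signal (n,), a feature map (C_in, n) or a batch
    (B, C_in, n); ``f`` correspondingly (K,), (C_out, C_in, K) or the same.
    Inputs left of position 0 are taken as zero (left zero-padding of
    (K-1)*d), so output length equals input length and no output position
    depends on any later input position.
    """
    if d < 1:
        raise InvalidArgumentError(f"dilation must be >= 1, got {d}")
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    squeeze_1d = x.ndim == 1
    squeeze_batch = x.ndim == 2
    if squeeze_1d:
        x = x[None, None, :]
        f = f[None, None, :]
    elif squeeze_batch:
        x = x[None]
    if f.ndim != 3:
        raise InvalidArgumentError("filter must have shape (C_out, C_in, K)")
    y = _conv_forward(x, f, d)
    if bias is not None:
        y = y + np.asarray(bias)[None, :, None]
    if squeeze_1d:
        return y[0, 0]
    return y[0] if squeeze_batch else y


def _im2col(x: np.ndarray, K: int, d: int) -> np.ndarray:
    """(B, C, n) -> (B, C*K, n) patch matrix for a causal dilated conv.

    Patch row block i holds x shifted right by (K-1-i)*d, i.e. tap i of the
    filter sees x[t - d*i] when blocks are ordered so that block for tap i
    aligns with offset -d*i.
    """
    B, C, n = x.shape
    P = (K - 1) * d
    xp = np.zeros((B, C, n + P), dtype=x.dtype)
    xp[:, :, P:] = x
    cols = np.empty((B, C, K, n), dtype=x.dtype)
    for i in range(K):
        # tap i reads x[t - d*i]  ->  xp[:, :, P - d*i + t]
        cols[:, :, i, :] = xp[:, :, P - d * i : P - d * i + n]
    return cols.reshape(B, C * K, n)


def _conv_forward(x: np.ndarray, w: np.ndarray, d: int) -> np.ndarray:
    """Batched causal dilated conv via im2col + matmul.

    x: (B, C_in, n); w: (C_out, C_in, K) -> (B, C_out, n).
    """
    C_out, C_in, K = w.shape
    cols = _im2col(x, K, d)                      # (B, C_in*K, n)
    return np.matmul(w.reshape(C_out, C_in * K), cols)


def _conv_backward(dy: np.ndarray, cols: np.ndarray, w: np.ndarray, d: int,
                   n: int):
    """Gradients of the causal dilated conv.

    dy: (B, C_out, n); cols: the im2col matrix from the forward pass.
    Returns (dx, dw).
    """
    C_out, C_in, K = w.shape
    B = dy.shape[0]
    dw = np.tensordot(dy, cols, axes=([0, 2], [0, 2])).reshape(C_out, C_in, K)
    dcols = np.matmul(w.reshape(C_out, C_in * K).T, dy)   # (B, C_in*K, n)
    dcols = dcols.reshape(B, C_in, K, n)
    P = (K - 1) * d
    dxp = np.zeros((B, C_in, n + P), dtype=dy.dtype)
    for i in range(K):
        dxp[:, :, P - d * i : P - d * i + n] += dcols[:, :, i, :]
    return dxp[:, :, P:], dw


def spatial_dropout(x: np.ndarray, rate: float, rng: np.random.Generator,
                    training: bool = True):
    """Zero whole channels across all positions; scale survivors by 1/(1-p).

    Identity at inference. Returns (y, mask); the mask multiplies gradients
    in the backward pass.
    """
    if not 0.0 <= rate < 1.0:
        raise InvalidArgumentError(f"dropout rate must be in [0,1), got {rate}")
    if not training or rate == 0.0:
        return x, None
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    B, C, _ = xb.shape
    keep = (rng.random((B, C, 1)) >= rate).astype(xb.dtype) / (1.0 - rate)
    y = xb * keep
    return (y[0] if squeeze else y), keep


def receptive_field(cfg: TCNConfig) -> int:
    """Trailing input positions able to influence one output position:
    1 + sum over blocks of convs_per_block * (K-1) * d."""
    cfg.validate()
    return 1 + sum(cfg.convs_per_block * (cfg.kernel_size - 1) * d
                   for d in cfg.dilations)


# ---------------------------------------------------------------------------
# Trainable layers (forward caches what backward needs)
# ---------------------------------------------------------------------------

class _WNConv:
    """Weight-normalized dilated causal convolution with bias.

    Parameters are the direction tensor v (C_out, C_in, K), per-filter
    scales g (C_out,) and biases b. The effective weight of filter o is
    g[o] * v[o] / ||v[o]||, so ||w[o]|| = |g[o]| always.
    """

    def __init__(self, c_in, c_out, K, d, rng):
        std = np.sqrt(2.0 / (c_in * K))
        self.v = rng.normal(0.0, std, size=(c_out, c_in, K)).astype(DTYPE)
        # init g to ||v|| so the initial effective weight equals v
        self.g = np.linalg.norm(self.v.reshape(c_out, -1), axis=1).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.d = d
        self._zero_grads()

    def _zero_grads(self):
        self.dv = np.zeros_like(self.v)
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)

    def effective_weight(self) -> np.ndarray:
        c_out = self.v.shape[0]
        flat = self.v.reshape(c_out, -1)
        norms = np.linalg.norm(flat, axis=1)
        if np.any(norms == 0):
            raise InvalidStateError("zero-norm weight direction")
        return (self.g / norms)[:, None, None] * self.v

    def forward(self, x, training):
        C_out, C_in, K = self.v.shape
        w = self.effective_weight().astype(DTYPE)
        cols = _im2col(x, K, self.d)
        y = np.matmul(w.reshape(C_out, C_in * K), cols) + self.b[None, :, None]
        if training:
            self._cache = (cols, w, x.shape[2])
        return y

    def backward(self, dy):
        cols, w, n = self._cache
        dx, dw = _conv_backward(dy, cols, w, self.d, n)
        self.db += dy.sum(axis=(0, 2))
        # chain rule through w = g * v / ||v||
        c_out = self.v.shape[0]
        vf = self.v.reshape(c_out, -1).astype(np.float64)
        dwf = dw.reshape(c_out, -1)
        norms = np.linalg.norm(vf, axis=1)
        dot = (dwf * vf).sum(axis=1)
        self.dg += (dot / norms).astype(DTYPE)
        gv = self.g.astype(np.float64)
        dvf = (gv / norms)[:, None] * dwf - ((gv * dot) / norms ** 3)[:, None] * vf
        self.dv += dvf.reshape(self.v.shape).astype(DTYPE)
        return dx

    def params_and_grads(self):
        return [(self.v, self.dv), (self.g, self.dg), (self.b, self.db)]


class _Conv1x1:
    """Plain pointwise convolution (position-shared affine map)."""

    def __init__(self, c_in, c_out, rng):
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._zero_grads()

    def _zero_grads(self):
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training):
        if training:
            self._x = x
        return np.matmul(self.w, x) + self.b[None, :, None]

    def backward(self, dy):
        self.dw += np.tensordot(dy, self._x, axes=([0, 2], [0, 2]))
        self.db += dy.sum(axis=(0, 2))
        return np.matmul(self.w.T, dy)

    def params_and_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ResidualBlock:
    """convs_per_block x [WN causal conv -> ReLU -> spatial dropout],
    then o = ReLU(skip(x) + F(x)).

    The skip is the identity when input and output channel counts match;
    otherwise a 1x1 convolution projects the input.
    """

    def __init__(self, c_in, c_out, K, d, convs_per_block, dropout_rate, rng):
        self.convs = []
        c = c_in
        for _ in range(convs_per_block):
            self.convs.append(_WNConv(c, c_out, K, d, rng))
            c = c_out
        self.skip = None if c_in == c_out else _Conv1x1(c_in, c_out, rng)
        self.rate = dropout_rate
        self.d = d

    def forward(self, x, training, rng):
        self._caches = []
        h = x
        for conv in self.convs:
            z = conv.forward(h, training)
            a = relu(z)
            out, mask = spatial_dropout(a, self.rate, rng, training)
            if training:
                self._caches.append((z, mask))
            h = out
        s = x if self.skip is None else self.skip.forward(x, training)
        o = relu(s + h)
        if training:
            self._o = o
        return o

    def backward(self, do):
        dpre = do * (self._o > 0)
        ds, dh = dpre, dpre
        for conv, (z, mask) in zip(reversed(self.convs), reversed(self._caches)):
            if mask is not None:
                dh = dh * mask
            dh = dh * (z > 0)
            dh = conv.backward(dh)
        dx = dh
        if self.skip is None:
            dx = dx + ds
        else:
            dx = dx + self.skip.backward(ds)
        return dx

    def params_and_grads(self):
        out = []
        for conv in self.convs:
            out.extend(conv.params_and_grads())
        if self.skip is not None:
            out.extend(self.skip.params_and_grads())
        return out


class TCN:
    """The full per-nucleotide labeler.

    forward() maps one-hot input (B, in_dim, n) to logits (B, n_classes, n);
    predict_proba() applies the per-position softmax. The model is
    convolutional throughout, so any input length works at inference.
    """

    def __init__(self, cfg: TCNConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.blocks = []
        c = cfg.in_dim
        for d in cfg.dilations:
            self.blocks.append(ResidualBlock(c, cfg.n_channels, cfg.kernel_size,
                                             d, cfg.convs_per_block,
                                             cfg.dropout_rate, rng))
            c = cfg.n_channels
        self.conv1x1 = _Conv1x1(cfg.n_channels, cfg.n_channels, rng)
        self.head = _Conv1x1(cfg.n_channels, cfg.n_classes, rng)

    def forward(self, x, training=False, rng=None):
        if x.shape[1] != self.cfg.in_dim:
            raise InvalidStateError(
                f"model expects in_dim={self.cfg.in_dim}, got {x.shape[1]} channels"
            )
        if training and rng is None:
            rng = np.random.default_rng(0)
        h = x.astype(DTYPE)
        for blk in self.blocks:
            h = blk.forward(h, training, rng)
        z = self.conv1x1.forward(h, training)
        self._z1 = z if training else None
        a = relu(z)
        return self.head.forward(a, training)

    def backward(self, dlogits):
        da = self.head.backward(dlogits)
        dz = da * (self._z1 > 0)
        dh = self.conv1x1.backward(dz)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        return dh

    def predict_proba(self, x):
        logits = self.forward(x, training=False)
        return softmax(logits, axis=1)

    def params_and_grads(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params_and_grads())
        out.extend(self.conv1x1.params_and_grads())
        out.extend(self.head.params_and_grads())
        return out

    def zero_grads(self):
        for blk in self.blocks:
            for conv in blk.convs:
                conv._zero_grads()
            if blk.skip is not None:
                blk.skip._zero_grads()
        self.conv1x1._zero_grads()
        self.head._zero_grads()

    # -- persistence ------------------------------------------------------

    def save(self, directory):
        """Checkpoint: config manifest (JSON) + flat parameter arrays."""
        os.makedirs(directory, exist_ok=True)
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.cfg.__dict__.items()}
        with open(os.path.join(directory, "model_config.json"), "w") as fh:
            json.dump(cfg, fh, indent=1, sort_keys=True)
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params_and_grads())}
        np.savez(os.path.join(directory, "weights.npz"), **arrays)

    @classmethod
    def load(cls, directory):
        with open(os.path.join(directory, "model_config.json")) as fh:
            raw = json.load(fh)
        raw["dilations"] = tuple(raw["dilations"])
        model = cls(TCNConfig(**raw))
        with np.load(os.path.join(directory, "weights.npz")) as data:
            for i, (p, _) in enumerate(model.params_and_grads()):
                p[...] = data[f"p{i}"]
        return model

    def summary(self) -> str:
        lines = [f"TCN(in_dim={self.cfg.in_dim}, classes={self.cfg.n_classes})"]
        for blk in self.blocks:
            c_in = blk.convs[0].v.shape[1]
            c_out = blk.convs[0].v.shape[0]
            skip = "1x1" if blk.skip is not None else "identity"
            lines.append(f"  block d={blk.d}: {len(blk.convs)}x WNConv"
                         f"({c_in}->{c_out}, K={blk.convs[0].v.shape[2]}), skip={skip}")
        lines.append(f"  conv1x1 {self.cfg.n_channels}->{self.cfg.n_channels}, "
                     f"head ->{self.cfg.n_classes} (softmax per position)")
        lines.append(f"  receptive field: {receptive_field(self.cfg)}")
        return "\n".join(lines)


def softmax(z, axis=-1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_model(cfg: TCNConfig) -> TCN:
    """Construct a freshly seeded TCN for the given architecture config."""
    return TCN(cfg)


def residual_block(x, block: ResidualBlock, rng=None, training=False):
    """Functional application of a residual block to a (C, n) feature map."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    y = block.forward(xb.astype(DTYPE), training, rng or np.random.default_rng(0))
    return y[0] if squeeze else y
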