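"""Minimal numpy neural-network primitives used by the two models.

Contains exactly what the package needs: an embedding lookup, a single
bidirectional LSTM layer with full backpropagation through time, a linear
head with softmax cross-entropy, SGD with momentum, and a small
3D-convolutional clip network built from non-overlapping space-time
patches.  Everything is deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean negative log-likelihood of integer targets under row probs."""
    ll = np.log(np.clip(probs[np.arange(targets.size), targets], 1e-12, None))
    return float(-ll.mean())


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SGD:
    """SGD with momentum in the standard deep-learning convention:
    ``v = mu * v + g;  p -= lr * v``.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray], clip_norm: float | None = 5.0) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        for k, g in grads.items():
            v = self._v[k]
            v *= self.momentum
            v += g
            self.params[k] -= self.lr * v


# ---------------------------------------------------------------------------
# Bidirectional LSTM sequence classifier
# ---------------------------------------------------------------------------


class _LSTMCache:
    __slots__ = ("X", "xp", "i", "f", "g", "o", "c", "h", "tanh_c")


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run one LSTM direction over a whole (L, E) sequence."""
    L = X.shape[0]
    H = Wh.shape[0]
    cache = _LSTMCache()
    cache.X = X
    cache.xp = X @ Wx + b
    cache.i = np.empty((L, H))
    cache.f = np.empty((L, H))
    cache.g = np.empty((L, H))
    cache.o = np.empty((L, H))
    cache.c = np.empty((L, H))
    cache.h = np.empty((L, H))
    cache.tanh_c = np.empty((L, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(L):
        a = cache.xp[t] + h @ Wh
        i = _sigmoid(a[:H])
        f = _sigmoid(a[H : 2 * H])
        g = np.tanh(a[2 * H : 3 * H])
        o = _sigmoid(a[3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        cache.i[t], cache.f[t], cache.g[t], cache.o[t] = i, f, g, o
        cache.c[t], cache.h[t], cache.tanh_c[t] = c, h, tc
    return cache.h, cache


def _lstm_backward(dH: np.ndarray, cache: _LSTMCache, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop through time; returns (dX, dWx, dWh, db)."""
    L, H = dH.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.zeros_like(cache.X)
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    dA = np.empty((L, 4 * H))
    for t in range(L - 1, -1, -1):
        dh = dH[t] + dh_next
        i, f, g, o = cache.i[t], cache.f[t], cache.g[t], cache.o[t]
        tc = cache.tanh_c[t]
        dc = dh * o * (1.0 - tc * tc) + dc_next
        c_prev = cache.c[t - 1] if t > 0 else 0.0
        da = dA[t]
        da[:H] = dc * g * i * (1.0 - i)
        da[H : 2 * H] = dc * c_prev * f * (1.0 - f)
        da[2 * H : 3 * H] = dc * i * (1.0 - g * g)
        da[3 * H :] = dh * tc * o * (1.0 - o)
        dc_next = dc * f
        dh_next = da @ Wh.T
    # parameter grads in two big matmuls
    dWx += cache.X.T @ dA
    db += dA.sum(axis=0)
    H_prev = np.vstack([np.zeros((1, H)), cache.h[:-1]])
    dWh += H_prev.T @ dA
    dX = dA @ Wx.T
    return dX, dWx, dWh, db


class BiLSTMSequenceClassifier:
    """Embedding -> single bidirectional LSTM layer -> linear softmax head.

    Maps a sequence of phase ids (one per second) to per-second phase
    logits.  ``hidden_dim`` is the number of hidden-state features per
    direction; the head sees the forward/backward concatenation.
    """

    def __init__(
        self,
        n_classes: int = 7,
        embed_dim: int = 32,
        hidden_dim: int = 128,
        bidirectional: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.hidden_dim = hidden_dim
        self.bidirectional = bidirectional
        k = 1.0 / np.sqrt(hidden_dim)
        out_in = hidden_dim * (2 if bidirectional else 1)
        p: dict[str, np.ndarray] = {
            "emb": rng.normal(0.0, 1.0, size=(n_classes, embed_dim)),
            "Wx_f": rng.uniform(-k, k, size=(embed_dim, 4 * hidden_dim)),
            "Wh_f": rng.uniform(-k, k, size=(hidden_dim, 4 * hidden_dim)),
            "b_f": rng.uniform(-k, k, size=4 * hidden_dim),
            "W_out": rng.uniform(-k, k, size=(out_in, n_classes)),
            "b_out": rng.uniform(-k, k, size=n_classes),
        }
        if bidirectional:
            p["Wx_b"] = rng.uniform(-k, k, size=(embed_dim, 4 * hidden_dim))
            p["Wh_b"] = rng.uniform(-k, k, size=(hidden_dim, 4 * hidden_dim))
            p["b_b"] = rng.uniform(-k, k, size=4 * hidden_dim)
        self.params = p

    def forward(self, ids: np.ndarray, with_cache: bool = False):
        ids = np.asarray(ids, dtype=np.int64)
        p = self.params
        X = p["emb"][ids]
        Hf, cf = _lstm_forward(X, p["Wx_f"], p["Wh_f"], p["b_f"])
        if self.bidirectional:
            Hb_rev, cb = _lstm_forward(X[::-1], p["Wx_b"], p["Wh_b"], p["b_b"])
            Hcat = np.concatenate([Hf, Hb_rev[::-1]], axis=1)
        else:
            cb = None
            Hcat = Hf
        logits = Hcat @ p["W_out"] + p["b_out"]
        if with_cache:
            return logits, (ids, X, cf, cb, Hcat)
        return logits

    def loss_and_grads(self, ids: np.ndarray, targets: np.ndarray):
        """Per-second softmax cross-entropy loss and parameter gradients."""
        p = self.params
        logits, (ids, X, cf, cb, Hcat) = self.forward(ids, with_cache=True)
        L = logits.shape[0]
        probs = softmax(logits)
        loss = cross_entropy(probs, np.asarray(targets, dtype=np.int64))
        dlogits = probs.copy()
        dlogits[np.arange(L), targets] -= 1.0
        dlogits /= L
        grads: dict[str, np.ndarray] = {
            "W_out": Hcat.T @ dlogits,
            "b_out": dlogits.sum(axis=0),
        }
        dHcat = dlogits @ p["W_out"].T
        H = self.hidden_dim
        dXf, dWx_f, dWh_f, db_f = _lstm_backward(dHcat[:, :H], cf, p["Wx_f"], p["Wh_f"])
        grads.update(Wx_f=dWx_f, Wh_f=dWh_f, b_f=db_f)
        dX = dXf
        if self.bidirectional:
            dHb_rev = dHcat[::-1, H:]
            dXb_rev, dWx_b, dWh_b, db_b = _lstm_backward(dHb_rev, cb, p["Wx_b"], p["Wh_b"])
            grads.update(Wx_b=dWx_b, Wh_b=dWh_b, b_b=db_b)
            dX = dX + dXb_rev[::-1]
        demb = np.zeros_like(p["emb"])
        np.add.at(demb, ids, dX)
        grads["emb"] = demb
        return loss, grads

    def predict(self, ids: np.ndarray) -> np.ndarray:
        """Deterministic per-second class prediction (argmax of logits)."""
        logits = self.forward(ids)
        return np.asarray(np.argmax(logits, axis=1), dtype=np.int64)


# ---------------------------------------------------------------------------
# Tiny 3D-convolutional clip classifier
# ---------------------------------------------------------------------------


def _patchify(x: np.ndarray, k: tuple[int, int, int]) -> tuple[np.ndarray, tuple]:
    """Split (B, T, H, W, C) into non-overlapping (kt, kh, kw) patches.

    Returns (B, T', H', W', kt*kh*kw*C) plus the intermediate shape needed
    to invert the operation.  Trailing remainder voxels are cropped.
    """
    B, T, H, W, C = x.shape
    kt, kh, kw = k
    Tn, Hn, Wn = T // kt, H // kh, W // kw
    if Tn == 0 or Hn == 0 or Wn == 0:
        raise ValueError(f"input {x.shape[1:4]} smaller than patch kernel {k}")
    x = x[:, : Tn * kt, : Hn * kh, : Wn * kw]
    x = x.reshape(B, Tn, kt, Hn, kh, Wn, kw, C)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    shape6 = x.shape
    return x.reshape(B, Tn, Hn, Wn, kt * kh * kw * C), shape6


@dataclass
class TinyConv3DConfig:
    """Shape of the small 3D-conv test backbone (non-overlapping patches)."""

    kernel1: tuple[int, int, int] = (8, 4, 4)
    channels1: int = 16
    kernel2: tuple[int, int, int] = (2, 2, 2)
    channels2: int = 32
    n_classes: int = 7
    use_sdr: bool = False


class TinyConv3D:
    """A ~5-layer 3D-convolutional clip classifier.

    Two strided (patch) 3D convolution + ReLU blocks, global average
    pooling, an optional scalar progress feature (SDR) concatenated to the
    pooled vector, and a linear softmax head.  Small enough to train on a
    CPU; stands as the default desk-scale backbone behind the clip
    classifier contract (the full-scale spec is an inflated ResNet-50 with
    non-local blocks, documented but not instantiated here).
    """

    def __init__(self, config: TinyConv3DConfig | None = None, in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        cfg = config or TinyConv3DConfig()
        self.config = cfg
        self.in_channels = in_channels
        d1 = int(np.prod(cfg.kernel1)) * in_channels
        d2 = int(np.prod(cfg.kernel2)) * cfg.channels1
        head_in = cfg.channels2 + (1 if cfg.use_sdr else 0)
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / d1), size=(d1, cfg.channels1)),
            "b1": np.zeros(cfg.channels1),
            "W2": rng.normal(0.0, np.sqrt(2.0 / d2), size=(d2, cfg.channels2)),
            "b2": np.zeros(cfg.channels2),
            "W3": rng.normal(0.0, np.sqrt(1.0 / head_in), size=(head_in, cfg.n_classes)),
            "b3": np.zeros(cfg.n_classes),
        }

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    def forward(self, clips: np.ndarray, sdr: np.ndarray | None = None,
                with_cache: bool = False):
        """clips: (B, T, H, W, C) float array; sdr: (B,) progress ratios."""
        cfg = self.config
        p = self.params
        if cfg.use_sdr and sdr is None:
            raise ValueError("backbone configured with SDR but no SDR values given")
        x1, _ = _patchify(clips, cfg.kernel1)
        a1 = x1 @ p["W1"] + p["b1"]
        r1 = np.maximum(a1, 0.0)
        x2, _ = _patchify(r1, cfg.kernel2)
        a2 = x2 @ p["W2"] + p["b2"]
        r2 = np.maximum(a2, 0.0)
        n_cells = r2.shape[1] * r2.shape[2] * r2.shape[3]
        pooled = r2.reshape(r2.shape[0], n_cells, cfg.channels2).mean(axis=1)
        feat = pooled
        if cfg.use_sdr:
            feat = np.concatenate([pooled, np.asarray(sdr, dtype=float)[:, None]], axis=1)
        logits = feat @ p["W3"] + p["b3"]
        if with_cache:
            return logits, (x1, a1, r1, x2, a2, r2, feat, n_cells)
        return logits

    def loss_and_grads(self, clips: np.ndarray, targets: np.ndarray,
                       sdr: np.ndarray | None = None):
        cfg = self.config
        p = self.params
        logits, (x1, a1, r1, x2, a2, r2, feat, n_cells) = self.forward(
            clips, sdr=sdr, with_cache=True
        )
        B = logits.shape[0]
        probs = softmax(logits)
        targets = np.asarray(targets, dtype=np.int64)
        loss = cross_entropy(probs, targets)
        dlogits = probs.copy()
        dlogits[np.arange(B), targets] -= 1.0
        dlogits /= B
        grads = {
            "W3": feat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ p["W3"].T
        dpooled = dfeat[:, : cfg.channels2]
        dr2 = np.broadcast_to(
            dpooled[:, None, :] / n_cells, (B, n_cells, cfg.channels2)
        ).reshape(r2.shape)
        da2 = dr2 * (a2 > 0)
        grads["W2"] = np.tensordot(x2, da2, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        grads["b2"] = da2.sum(axis=(0, 1, 2, 3))
        dx2 = da2 @ p["W2"].T
        # invert the second patchify (pure reshape for non-overlapping patches)
        kt, kh, kw = cfg.kernel2
        Bp, T2, H2, W2_, _ = dx2.shape
        dr1 = dx2.reshape(Bp, T2, H2, W2_, kt, kh, kw, cfg.channels1)
        dr1 = dr1.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(
            Bp, T2 * kt, H2 * kh, W2_ * kw, cfg.channels1
        )
        # pad back cropped remainder, if any
        if dr1.shape[1:4] != a1.shape[1:4]:
            full = np.zeros_like(a1)
            full[:, : dr1.shape[1], : dr1.shape[2], : dr1.shape[3]] = dr1
            dr1 = full
        da1 = dr1 * (a1 > 0)
        grads["W1"] = np.tensordot(x1, da1, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
        grads["b1"] = da1.sum(axis=(0, 1, 2, 3))
        return loss, grads

    def predict_proba(self, clips: np.ndarray, sdr: np.ndarray | None = None) -> np.ndarray:
        return softmax(self.forward(clips, sdr=sdr))
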