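"""A small numpy implementation of the tagging network.

Architecture: name-internal feature rows pass through a 1-D convolution
(odd width, same padding, ReLU); the convolution output is concatenated
with per-token word embeddings (with optional channel dropout on the
embedding side during training); the concatenation feeds a bidirectional
LSTM; a shared dense layer with softmax produces per-token class
probabilities.  Training is mini-batch Adam on masked cross-entropy.

No deep-learning framework is assumed: forward and backward passes are
written out explicitly and vectorised over the batch, looping only over
time steps.  Shapes use (batch, time, features); padded positions are
masked out of both the recurrence carry and the loss.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class BiLSTMTagger:
    """Conv + concat + BiLSTM + dense-softmax tagger with manual backprop."""

    def __init__(
        self,
        feat_dim: int,
        embed_dim: int,
        conv_width: int = 3,
        conv_filters: int = 256,
        hidden: int = 64,
        n_classes: int = 5,
        embed_dropout: float = 0.0,
        seed: int = 0,
    ) -> None:
        if conv_width % 2 == 0:
            raise ValueError("conv_width must be odd")
        self.feat_dim = feat_dim
        self.embed_dim = embed_dim
        self.conv_width = conv_width
        self.conv_filters = conv_filters
        self.hidden = hidden
        self.n_classes = n_classes
        self.embed_dropout = embed_dropout
        self.seed = seed
        rng = np.random.default_rng(seed)
        D = conv_filters + embed_dim  # concat width fed to the BiLSTM
        H = hidden

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {
            "Wc": glorot((conv_width * feat_dim, conv_filters)),
            "bc": np.zeros(conv_filters),
            "Wo": glorot((2 * H, n_classes)),
            "bo": np.zeros(n_classes),
        }
        for d in ("f", "b"):  # forward / backward direction
            self.params[f"Wx_{d}"] = glorot((D, 4 * H))
            self.params[f"Wh_{d}"] = glorot((H, 4 * H))
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias init
            self.params[f"b_{d}"] = bias

    @property
    def concat_width(self) -> int:
        return self.conv_filters + self.embed_dim

    # -- forward pieces ----------------------------------------------------

    def _conv_forward(self, feats: np.ndarray):
        B, T, F = feats.shape
        w = self.conv_width
        half = w // 2
        padded = np.zeros((B, T + 2 * half, F))
        padded[:, half : half + T] = feats
        xw = np.concatenate([padded[:, i : i + T] for i in range(w)], axis=2)
        a = xw @ self.params["Wc"] + self.params["bc"]
        y = np.maximum(a, 0.0)
        return y, (xw, a)

    def _lstm_forward(self, x: np.ndarray, mask: np.ndarray, direction: str):
        """x: (B,T,D); mask: (B,T). Returns h (B,T,H) and a cache."""
        B, T, D = x.shape
        H = self.hidden
        Wx = self.params[f"Wx_{direction}"]
        Wh = self.params[f"Wh_{direction}"]
        b = self.params[f"b_{direction}"]
        steps = range(T) if direction == "f" else range(T - 1, -1, -1)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        for t in steps:
            m = mask[:, t : t + 1]
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((t, h.copy(), c.copy(), i, f, g, o, c_new, tc, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            hs[:, t] = h * m
        return hs, cache

    def _lstm_backward(self, dhs: np.ndarray, x: np.ndarray, cache, direction: str):
        B, T, D = x.shape
        H = self.hidden
        Wx = self.params[f"Wx_{direction}"]
        Wh = self.params[f"Wh_{direction}"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params[f"b_{direction}"])
        dx = np.zeros_like(x)
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        for t, h_prev, c_prev, i, f, g, o, c_new, tc, m in reversed(cache):
            dh_total = dhs[:, t] * m + dh_carry
            dc_total = dc_carry
            # h = m*h_new + (1-m)*h_prev ; hs output was h*m so dhs masked above
            dh_new = dh_total * m
            dh_prev_skip = dh_total * (1 - m)
            do = dh_new * tc
            dc_new = dh_new * o * (1 - tc * tc) + dc_total * m
            dc_prev_skip = dc_total * (1 - m)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_carry = dz @ Wh.T + dh_prev_skip
            dc_carry = dc_new * f + dc_prev_skip
        return dx, {f"Wx_{direction}": dWx, f"Wh_{direction}": dWh, f"b_{direction}": db}

    def forward(
        self,
        feats: np.ndarray,
        emb: np.ndarray,
        mask: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Compute per-token class probabilities; returns (probs, cache)."""
        conv, conv_cache = self._conv_forward(feats)
        emb_used = emb
        drop_mask = None
        if train and self.embed_dropout > 0:
            assert rng is not None
            keep = 1.0 - self.embed_dropout
            drop_mask = (rng.random((emb.shape[0], 1, emb.shape[2])) < keep) / keep
            emb_used = emb * drop_mask
        x = np.concatenate([conv, emb_used], axis=2)
        hf, cache_f = self._lstm_forward(x, mask, "f")
        hb, cache_b = self._lstm_forward(x, mask, "b")
        hcat = np.concatenate([hf, hb], axis=2)
        logits = hcat @ self.params["Wo"] + self.params["bo"]
        probs = softmax(logits)
        cache = (feats, conv_cache, x, cache_f, cache_b, hcat, probs, mask, drop_mask)
        return probs, cache

    def loss_and_grads(
        self,
        feats: np.ndarray,
        emb: np.ndarray,
        mask: np.ndarray,
        labels: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        """Masked cross-entropy loss and parameter gradients for one batch."""
        probs, cache = self.forward(feats, emb, mask, train=True, rng=rng)
        _, conv_cache, x, cache_f, cache_b, hcat, _, _, _ = cache
        B, T, C = probs.shape
        n_valid = max(mask.sum(), 1.0)
        onehot = np.eye(C)[labels]
        logp = np.log(np.clip(probs, 1e-12, None))
        loss = -float((onehot * logp * mask[..., None]).sum() / n_valid)

        dlogits = (probs - onehot) * mask[..., None] / n_valid
        grads: dict[str, np.ndarray] = {
            "Wo": hcat.reshape(-1, hcat.shape[2]).T @ dlogits.reshape(-1, C),
            "bo": dlogits.sum(axis=(0, 1)),
        }
        dhcat = dlogits @ self.params["Wo"].T
        H = self.hidden
        dxf, g_f = self._lstm_backward(dhcat[:, :, :H], x, cache_f, "f")
        dxb, g_b = self._lstm_backward(dhcat[:, :, H:], x, cache_b, "b")
        grads.update(g_f)
        grads.update(g_b)
        dx = dxf + dxb
        dconv = dx[:, :, : self.conv_filters]
        # conv backward
        xw, a = conv_cache
        da = dconv * (a > 0)
        grads["Wc"] = xw.reshape(-1, xw.shape[2]).T @ da.reshape(-1, self.conv_filters)
        grads["bc"] = da.sum(axis=(0, 1))
        return loss, grads

    # -- persistence -------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "format_version": 1,
                    "config": {
                        "feat_dim": self.feat_dim,
                        "embed_dim": self.embed_dim,
                        "conv_width": self.conv_width,
                        "conv_filters": self.conv_filters,
                        "hidden": self.hidden,
                        "n_classes": self.n_classes,
                        "embed_dropout": self.embed_dropout,
                        "seed": self.seed,
                    },
                    "params": self.params,
                    "metadata": metadata or {},
                },
                fh,
            )

    @classmethod
    def load(cls, path: str | Path) -> "BiLSTMTagger":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        net = cls(**blob["config"])
        net.set_weights(blob["params"])
        return net


def pad_batch(
    feats: Sequence[np.ndarray],
    embs: Sequence[np.ndarray],
    labels: Sequence[np.ndarray] | None = None,
):
    """Pad variable-length per-sentence arrays into batch tensors + mask."""
    B = len(feats)
    T = max((f.shape[0] for f in feats), default=0)
    if T == 0:
        T = 1
    F = feats[0].shape[1]
    E = embs[0].shape[1]
    fb = np.zeros((B, T, F))
    eb = np.zeros((B, T, E))
    mask = np.zeros((B, T))
    lb = np.zeros((B, T), dtype=np.int64)
    for i, (f, e) in enumerate(zip(feats, embs)):
        n = f.shape[0]
        fb[i, :n] = f
        eb[i, :n] = e
        mask[i, :n] = 1.0
        if labels is not None:
            lb[i, :n] = labels[i]
    return (fb, eb, mask, lb) if labels is not None else (fb, eb, mask)
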