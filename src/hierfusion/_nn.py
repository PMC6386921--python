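"""Minimal seeded neural-network core used by the classifier contracts.

Implements exactly what the recognition framework needs — a gated-memory
(LSTM) recurrent layer, dense layers, inverted dropout, softmax
cross-entropy, and an Adam optimizer — as plain numpy with hand-written
backward passes. Everything is deterministic given the initialization seed
and a single-threaded BLAS: parameter initialization draws from one
``numpy.random.Generator`` and training shuffles/dropout masks draw from a
second, so repeated runs with the same seed are bit-identical.

Conventions: batches are leading axes; sequences are (B, T, D); weights are
stored in a per-layer ``params`` dict mirrored by a ``grads`` dict. Input
weights use Glorot-uniform init, recurrent weights orthogonal init, forget
gates a +1 bias, and classifier output layers zero init (so an untrained
head emits exactly uniform probabilities).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "LSTM", "Dropout", "Adam", "softmax", "softmax_xent"]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    probs = softmax(logits)
    B = logits.shape[0]
    loss = -float(np.log(probs[np.arange(B), targets] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(B), targets] -= 1.0
    return loss, grad / B


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    return q if shape[0] >= shape[1] else q.T


class Dense:
    """Affine layer y = x @ W + b; zero-init option for softmax heads."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        if zero_init or rng is None:
            W = np.zeros((d_in, d_out))
        else:
            W = glorot_uniform(rng, (d_in, d_out))
        self.params = {"W": W, "b": np.zeros(d_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class LSTM:
    """Single LSTM layer over (B, T, D) returning the last hidden state (B, H).

    Gate order in the fused weight matrices is input, forget, cell, output.
    Backward is full BPTT from the gradient of the last hidden state.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        H = hidden
        self.d_in, self.hidden = d_in, H
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.params = {
            "Wx": glorot_uniform(rng, (d_in, 4 * H)),
            "Wh": np.concatenate(
                [orthogonal(rng, (H, H)) for _ in range(4)], axis=1
            ),
            "b": b,
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: dict | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        if train:
            cache = {"x": x, "i": [], "f": [], "g": [], "o": [],
                     "c": [], "ct": [], "h_prev": [], "c_prev": []}
        # precompute the input projection for the whole sequence at once
        xw = x.reshape(B * T, -1) @ Wx
        xw = xw.reshape(B, T, 4 * H)
        for t in range(T):
            z = xw[:, t, :] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            if train:
                cache["h_prev"].append(h)
                cache["c_prev"].append(c)
            c = f * c + i * g
            ct = np.tanh(c)
            h = o * ct
            if train:
                for key, val in (("i", i), ("f", f), ("g", g), ("o", o),
                                 ("c", c), ("ct", ct)):
                    cache[key].append(val)
        if train:
            self._cache = cache
        return h

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        cache = self._cache
        x = cache["x"]
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = dh_last
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            c, ct = cache["c"][t], cache["ct"][t]
            c_prev, h_prev = cache["c_prev"][t], cache["h_prev"][t]
            do = dh * ct
            dc = dc + dh * o * (1.0 - ct ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        return dx


class Adam:
    """Adaptive-moment optimizer over a list of layers with params/grads dicts."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.99, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]
        self._v = [{k: np.zeros_like(v) for k, v in lay.params.items()}
                   for lay in self.layers]

    def zero_grad(self) -> None:
        for lay in self.layers:
            for g in lay.grads.values():
                g.fill(0.0)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for lay, m, v in zip(self.layers, self._m, self._v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)
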