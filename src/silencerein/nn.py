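"""Minimal neural-network primitives with explicit backpropagation.

Just the layers the silencer classifier needs: same-padded 1-D convolution,
LeakyReLU, max pooling, dropout, dense layers, a mean-aggregation graph
layer and an Adam optimizer.  Forward passes cache what backward needs; all
arrays are plain NumPy, dtype configurable.  Correctness is guarded by a
finite-difference gradient test in the suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Conv1dSame",
    "Dense",
    "LeakyReLU",
    "MaxPool1d",
    "GlobalMaxPool1d",
    "Dropout",
    "MeanAggregate",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


def _init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    # He-style scaling, appropriate for leaky-ReLU stacks
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs; gradients are filled by backward()."""
        return []

    def l2_params(self) -> list[np.ndarray]:
        """Weight matrices subject to L2 regularization (biases excluded)."""
        return []


class Conv1dSame(Layer):
    """1-D convolution with 'same' output length (stride 1).

    Input/outputs are (n, channels, length).  For an even kernel the padding
    is split k//2-1 on the left and k//2 on the right.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 8, *, rng, dtype=np.float32):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.W = _init(rng, (out_ch, in_ch * kernel), in_ch * kernel, dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        # (n, c, L, k) windows -> (n, L, c*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        cols = win.transpose(0, 2, 1, 3).reshape(n * length, c * self.kernel)
        self._cols = cols
        self._shape = (n, c, length)
        out = cols @ self.W.T + self.b
        return out.reshape(n, length, self.out_ch).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        g = grad.transpose(0, 2, 1).reshape(n * length, self.out_ch)
        self.dW[...] = g.T @ self._cols
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W).reshape(n, length, c, self.kernel)
        dxp = np.zeros((n, c, length + self.kernel - 1), dtype=grad.dtype)
        for k in range(self.kernel):
            dxp[:, :, k : k + length] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, self.pad_left : self.pad_left + length]

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def l2_params(self):
        return [self.W]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng, dtype=np.float32):
        self.W = _init(rng, (n_out, n_in), n_in, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = grad.T @ self._x
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def l2_params(self):
        return [self.W]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool1d(Layer):
    """Non-overlapping max pooling along the last axis (remainder dropped)."""

    def __init__(self, width: int = 4):
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        out_len = length // self.width
        xt = x[:, :, : out_len * self.width].reshape(n, c, out_len, self.width)
        self._argmax = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._in_shape
        out_len = length // self.width
        dx = np.zeros((n, c, out_len, self.width), dtype=grad.dtype)
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=3)
        full = np.zeros(self._in_shape, dtype=grad.dtype)
        full[:, :, : out_len * self.width] = dx.reshape(n, c, out_len * self.width)
        return full


class GlobalMaxPool1d(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=2)
        self._in_shape = x.shape
        return x.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        n, c, _ = self._in_shape
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ii, jj, self._argmax] = grad
        return dx


class Dropout(Layer):
    def __init__(self, p: float, *, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class MeanAggregate(Layer):
    """Sparse row-stochastic neighbourhood averaging: H -> M @ H.

    Row v of M puts uniform weight on {v} ∪ N(v), implementing the mean
    aggregation over a node's own and its neighbours' representations.
    """

    def __init__(self, n_nodes: int, edges: np.ndarray, dtype=np.float32):
        neigh: list[set[int]] = [set() for _ in range(n_nodes)]
        for u, v in np.asarray(edges, dtype=np.int64).reshape(-1, 2):
            neigh[u].add(int(v))
            neigh[v].add(int(u))
        rows, cols, vals = [], [], []
        for v in range(n_nodes):
            members = sorted(neigh[v] | {v})
            w = 1.0 / len(members)
            rows.extend([v] * len(members))
            cols.extend(members)
            vals.extend([w] * len(members))
        self.M = sp.csr_matrix(
            (np.array(vals, dtype=dtype), (rows, cols)), shape=(n_nodes, n_nodes)
        )

    def forward(self, h: np.ndarray) -> np.ndarray:
        return self.M @ h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.M.T @ grad


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params  # list of (value, grad) pairs
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy, normalized by the weight sum.

    Returns (loss, dloss/dlogits).
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    w = class_weights[y]
    wsum = w.sum()
    eps = 1e-12
    loss = float(-(w * np.log(p[np.arange(n), y] + eps)).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(logits.dtype)
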