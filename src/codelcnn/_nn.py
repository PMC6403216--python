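"""Minimal NumPy layer library backing the ensemble network.

Implements exactly what the model needs — 1D convolution (valid/same),
ReLU, width-2 max pooling, global average pooling, dense layers, residual
blocks, softmax cross-entropy and Adam — with explicit forward/backward
passes in float32.  Convolutions are lowered to GEMM via an im2col view so
training stays tractable on a single CPU.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: forward caches what backward needs; params/grads paired."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []

    def out_shape(self, in_shape: Tuple[int, int]) -> Tuple[int, int]:
        """(channels, length) -> (channels, length) geometry propagation."""
        return in_shape


class Conv1d(Layer):
    """1D convolution on (N, C, L) tensors; padding 'valid' or 'same'.

    Three execution paths keep one-CPU training tractable: 1x1 kernels use
    batched matmul over the channel axis (no im2col); small kernels cache
    their im2col matrix for backward; large kernels (wide im2col) cache only
    the padded input and rebuild the matrix during backward, trading a cheap
    copy for hundreds of MB of cached activations.
    """

    # im2col width (in_ch * kernel) above which cols are not cached
    RECOMPUTE_COLS_ABOVE = 2048

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 padding: str = "valid", rng: Optional[np.random.Generator] = None,
                 name: str = "conv", zero_init: bool = False):
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = padding
        self.name = name
        fan_in = in_ch * kernel
        if zero_init:
            self.W = np.zeros((out_ch, fan_in), dtype=DTYPE)
        else:
            self.W = (rng.standard_normal((out_ch, fan_in))
                      * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None
        self._colbuf = [None]   # reused im2col scratch: repeated large
        self._dcolbuf = [None]  # allocations stall badly on some allocators

    def _pads(self) -> Tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        total = self.kernel - 1
        return total // 2, total - total // 2

    def out_shape(self, in_shape):
        c, length = in_shape
        if c != self.in_ch:
            raise ValueError(
                f"{self.name}: expected {self.in_ch} input channels, got {c}")
        pl, pr = self._pads()
        out_len = length + pl + pr - self.kernel + 1
        if out_len < 1:
            raise ValueError(
                f"{self.name}: kernel {self.kernel} larger than input "
                f"length {length}")
        return self.out_ch, out_len

    @staticmethod
    def _scratch(holder: list, size: int) -> np.ndarray:
        if holder[0] is None or holder[0].size < size:
            holder[0] = np.empty(size, dtype=DTYPE)
        return holder[0][:size]

    def _im2col(self, xp: np.ndarray) -> np.ndarray:
        n, c, lp = xp.shape
        k = self.kernel
        out_len = lp - k + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        buf = self._scratch(self._colbuf, n * out_len * c * k)
        np.copyto(buf.reshape(n, out_len, c, k), win.transpose(0, 2, 1, 3))
        return buf.reshape(n * out_len, c * k)

    def forward(self, x, train=False):
        n, c, length = x.shape
        pl, pr = self._pads()
        out_len = length + pl + pr - self.kernel + 1
        if out_len < 1:
            raise ValueError(
                f"{self.name}: kernel {self.kernel} larger than input "
                f"length {length}")
        if self.kernel == 1:
            y = np.matmul(self.W[None], x) + self.b[None, :, None]
            if train:
                self._cache = ("mm", x)
            return y
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        cols = self._im2col(xp)
        y = cols @ self.W.T + self.b
        if train:
            if self.W.shape[1] > self.RECOMPUTE_COLS_ABOVE:
                # cols live in a shared scratch buffer; keep the (small)
                # padded input instead and rebuild them during backward
                self._cache = ("input", xp, n, out_len, length)
            else:
                self._cache = ("cols", cols.copy(), n, out_len, length)
        return np.ascontiguousarray(
            y.reshape(n, out_len, self.out_ch).transpose(0, 2, 1))

    def backward(self, grad):
        kind = self._cache[0]
        if kind == "mm":
            x = self._cache[1]
            self.gW += np.tensordot(grad, x, axes=([0, 2], [0, 2]))
            self.gb += grad.sum(axis=(0, 2))
            self._cache = None
            return np.matmul(self.W.T[None], grad)
        if kind == "input":
            _, xp, n, out_len, length = self._cache
            cols = self._im2col(xp)
        else:
            _, cols, n, out_len, length = self._cache
        g = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(
            n * out_len, self.out_ch)
        self.gW += g.T @ cols
        self.gb += g.sum(axis=0)
        dcols = self._scratch(
            self._dcolbuf, n * out_len * self.in_ch * self.kernel).reshape(
                n * out_len, self.in_ch * self.kernel)
        np.matmul(g, self.W, out=dcols)
        dcols = dcols.reshape(n, out_len, self.in_ch, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)  # (N, C, out_len, k)
        pl, pr = self._pads()
        dx = np.zeros((n, self.in_ch, length + pl + pr), dtype=DTYPE)
        for j in range(self.kernel):
            dx[:, :, j:j + out_len] += dcols[:, :, :, j]
        if pl or pr:
            dx = dx[:, :, pl:length + pl]
        self._cache = None
        return dx

    def params_grads(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    """Width-2, stride-2 max pooling; a trailing odd element is dropped."""

    def forward(self, x, train=False):
        n, c, length = x.shape
        m = length // 2
        r = x[:, :, :2 * m].reshape(n, c, m, 2)
        if train:
            self._argmax = r.argmax(axis=3)
            self._in_len = length
        return r.max(axis=3)

    def backward(self, grad):
        n, c, m = grad.shape
        dr = np.zeros((n, c, m, 2), dtype=DTYPE)
        np.put_along_axis(dr, self._argmax[..., None],
                          grad[..., None].astype(DTYPE), axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=DTYPE)
        dx[:, :, :2 * m] = dr.reshape(n, c, 2 * m)
        return dx

    def out_shape(self, in_shape):
        c, length = in_shape
        if length < 2:
            raise ValueError(f"max pool: input length {length} < 2")
        return c, length // 2


class GlobalAvgPool(Layer):
    """(N, C, L) -> (N, C) by averaging over the spatial axis."""

    def forward(self, x, train=False):
        if train:
            self._in_len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        g = (grad / self._in_len).astype(DTYPE)
        return np.repeat(g[:, :, None], self._in_len, axis=2)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: Optional[np.random.Generator] = None,
                 name: str = "dense"):
        rng = rng or np.random.default_rng()
        self.in_dim, self.out_dim, self.name = in_dim, out_dim, name
        self.W = (rng.standard_normal((out_dim, in_dim))
                  * np.sqrt(2.0 / in_dim)).astype(DTYPE)
        self.b = np.zeros(out_dim, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.gW += grad.T @ self._x
        self.gb += grad.sum(axis=0)
        return (grad @ self.W).astype(DTYPE)

    def params_grads(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ResidualBlock(Layer):
    """1x1 -> 3x1(same) -> 1x1 bottleneck whose output adds a shortcut.

    The shortcut is a 1x1 projection when the channel count changes and the
    identity otherwise; zeroing all transform weights reduces the block to
    its shortcut map exactly.  The closing 1x1 conv starts at zero so a
    freshly built deep stack is an identity-like map with well-scaled
    activations (the usual residual-init trick).
    """

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int,
                 rng: Optional[np.random.Generator] = None,
                 name: str = "res"):
        self.name = name
        self.conv1 = Conv1d(in_ch, mid_ch, 1, "valid", rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv1d(mid_ch, mid_ch, 3, "same", rng, f"{name}.conv2")
        self.relu2 = ReLU()
        self.conv3 = Conv1d(mid_ch, out_ch, 1, "valid", rng, f"{name}.conv3",
                            zero_init=True)
        self.projection = (Conv1d(in_ch, out_ch, 1, "valid", rng,
                                  f"{name}.proj")
                           if in_ch != out_ch else None)
        self.relu_out = ReLU()

    def forward(self, x, train=False):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.relu2.forward(self.conv2.forward(h, train), train)
        h = self.conv3.forward(h, train)
        shortcut = (self.projection.forward(x, train)
                    if self.projection is not None else x)
        return self.relu_out.forward(h + shortcut, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        dx_main = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(
                self.relu2.backward(self.conv3.backward(grad)))))
        if self.projection is not None:
            return dx_main + self.projection.backward(grad)
        return dx_main + grad

    def params_grads(self):
        out = (self.conv1.params_grads() + self.conv2.params_grads()
               + self.conv3.params_grads())
        if self.projection is not None:
            out += self.projection.params_grads()
        return out

    def out_shape(self, in_shape):
        c, length = in_shape
        c, length = self.conv1.out_shape((c, length))
        c, length = self.conv2.out_shape((c, length))
        c, length = self.conv3.out_shape((c, length))
        return c, length


class Sequential(Layer):
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params_grads(self):
        return [pg for layer in self.layers for pg in layer.params_grads()]

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class Adam:
    def __init__(self, params_grads: List[Tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.pg = params_grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for _, g in self.pg:
            g[...] = 0
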