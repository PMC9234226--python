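"""Minimal CPU conv-net primitives (forward + backward) on numpy.

Layers follow a tiny convention: ``forward(x, train)`` caches whatever the
backward pass needs, ``backward(dy)`` returns ``dx`` and fills ``.grads``
parallel to ``.params``.  Tensors are float32 and channels-last
``(B, H, W, C)`` — convolutions then reduce to strided matmuls over the
channel axis, which is the fastest layout for BLAS-backed numpy.
"""

from __future__ import annotations

import numpy as np

# SeLU constants (self-normalizing networks)
SELU_LAMBDA = 1.0507009873554805
SELU_ALPHA = 1.6732632423543772


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []


class Conv2D(Layer):
    """k x k convolution, stride 1, zero 'same' padding.

    Implemented as a sum of k*k shifted channel-matmuls, avoiding the im2col
    gather copy.  Weight shape (k, k, C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        # LeCun normal: the init that keeps SeLU activations self-normalizing
        w = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._xp = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, pad = self.k, self.k // 2
        b, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
        if train:
            self._xp = xp
        W = self.params[0]
        if k == 1:
            y = x @ W[0, 0]
        else:
            y = np.zeros((b, h, w, self.c_out), dtype=x.dtype)
            for u in range(k):
                for v in range(k):
                    y += xp[:, u:u + h, v:v + w, :] @ W[u, v]
        return y + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        b, h, w, _ = dy.shape
        xp = self._xp
        W = self.params[0]
        dyf = dy.reshape(-1, self.c_out)
        if k == 1:
            self.grads[0][0, 0] = xp.reshape(-1, self.c_in).T @ dyf
            self.grads[1][...] = dyf.sum(axis=0)
            self._xp = None
            return dy @ W[0, 0].T
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(-1, k * k * self.c_in)
        self.grads[0][...] = (cols.T @ dyf).reshape(k, k, self.c_in, self.c_out)
        self.grads[1][...] = dyf.sum(axis=0)
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                dxp[:, u:u + h, v:v + w, :] += dy @ W[u, v].T
        self._xp = None
        return dxp[:, pad:pad + h, pad:pad + w, :]


class ConvTranspose2D(Layer):
    """2 x 2 transposed convolution with stride 2 (learnable upsampling).
    Weight shape (2, 2, C_in, C_out)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        w = rng.normal(0.0, np.sqrt(1.0 / c_in), size=(2, 2, c_in, c_out))
        self.params = [w.astype(np.float32), np.zeros(c_out, dtype=np.float32)]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        b, h, w, _ = x.shape
        y = np.empty((b, h, 2, w, 2, self.c_out), dtype=x.dtype)
        W = self.params[0]
        for u in range(2):
            for v in range(2):
                y[:, :, u, :, v, :] = x @ W[u, v]
        return y.reshape(b, 2 * h, 2 * w, self.c_out) + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h2, w2, o = dy.shape
        h, w = h2 // 2, w2 // 2
        dy6 = dy.reshape(b, h, 2, w, 2, o)
        x = self._x
        W = self.params[0]
        dx = np.zeros_like(x)
        for u in range(2):
            for v in range(2):
                d = dy6[:, :, u, :, v, :]
                self.grads[0][u, v] = np.tensordot(x, d, axes=([0, 1, 2], [0, 1, 2]))
                dx += d @ W[u, v].T
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        self._x = None
        return dx


class MaxPool2x2(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, h, w, c = x.shape
        v = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        v = v.reshape(b, h // 2, w // 2, c, 4)
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dv = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dv, self._idx[..., None], dy[..., None], axis=-1)
        dx = dv.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return dx.reshape(b, h, w, c)


class SeLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._y = None
        self._pos = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, SELU_LAMBDA * x,
                     SELU_LAMBDA * SELU_ALPHA * np.expm1(np.minimum(x, 0.0)))
        if train:
            self._y, self._pos = y, pos
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # for x <= 0: dy/dx = y + lambda*alpha
        grad = np.where(self._pos, SELU_LAMBDA, self._y + SELU_LAMBDA * SELU_ALPHA)
        self._y = self._pos = None
        return dy * grad


class AlphaDropout(Layer):
    """Dropout that preserves the self-normalizing property of SeLU nets:
    dropped units are set to the SeLU saturation value, then the output is
    affinely rescaled to keep zero mean / unit variance."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng
        self._mask = None
        q = 1.0 - self.rate
        self.alpha_p = -SELU_LAMBDA * SELU_ALPHA
        if self.rate > 0:
            self.a = (q + self.alpha_p ** 2 * q * (1 - q)) ** -0.5
            self.b = -self.a * (1 - q) * self.alpha_p
        else:
            self.a, self.b = 1.0, 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            return x
        mask = self.rng.uniform(size=x.shape) >= self.rate
        self._mask = mask
        return (self.a * np.where(mask, x, self.alpha_p) + self.b).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        dx = dy * (self.a * self._mask)
        self._mask = None
        return dx.astype(dy.dtype)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last (channel) axis."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) over a layer list."""

    def __init__(self, layers: list[Layer], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
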