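"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly what the two networks in this package need: 3x3/1x1
convolution (im2col + BLAS matmul), batch normalization, ReLU, 2x2 max
pooling, a dense layer, softmax cross entropy and Adam.  Arrays are
(N, C, H, W) float64 throughout; float64 keeps training bit-reproducible
across runs on one machine.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "Linear",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padding 2-D convolution with square kernels (stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        # He initialisation: appropriate for ReLU-activated conv stacks
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = Param(w)
        self.b = Param(np.zeros(out_ch))
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.w.value.reshape(self.out_ch, c * k * k)
        out = cols @ wmat.T + self.b.value
        if train:
            self._cols = cols
            self._xshape = x.shape
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        k = self.kernel
        p = k // 2
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.w.grad += (g2.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += g2.sum(axis=0)
        wmat = self.w.value.reshape(self.out_ch, -1)
        dcols = (g2 @ wmat).reshape(n, h, w, self.in_ch, k, k)
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p))
        # scatter-add the k*k shifted contributions (col2im)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[:, None, None]
        return (inv_std[:, None, None] * g / m) * (
            m * grad - dbeta[:, None, None] - xhat * dgamma[:, None, None]
        )


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; even spatial input required."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        self._cache = None
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim)))
        self.b = Param(np.zeros(out_dim))
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        self._x = None
        return grad @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (shift-invariant)."""
    shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                          axis: int = -1) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. the logits.

    ``labels`` holds integer class indices with the shape of ``logits``
    minus the class axis.  The gradient is (softmax - onehot) / count,
    where count is the number of classified elements (pixels or samples).
    """
    p = softmax(logits, axis=axis)
    lab = np.expand_dims(labels, axis=axis)
    picked = np.take_along_axis(p, lab, axis=axis)
    count = labels.size
    loss = float(-np.log(np.clip(picked, 1e-300, None)).sum() / count)
    grad = p.copy()
    np.put_along_axis(
        grad, lab,
        np.take_along_axis(grad, lab, axis=axis) - 1.0, axis=axis,
    )
    return loss, grad / count
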