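"""Minimal NumPy neural-network layers with explicit backward passes.

Implements exactly what the residual encoder / U-net decoder needs:
2D convolution, batch normalization, ReLU, 3x3/2 max pooling,
nearest-neighbour resizing, and the Adam optimizer. Data layout is NCHW,
float32. Convolution is evaluated as a sum of k*k shifted 1x1 products
(one BLAS matmul per kernel offset), which keeps peak memory far below an
im2col buffer at large image sizes.
"""
from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    train_mode: bool = False

    def parameters(self) -> list[Param]:
        return []

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


class Conv2d(Layer):
    """2D convolution, NCHW, zero padding, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = False, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Param(np.zeros(out_ch)) if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((n, self.weight.value.shape[0], oh * ow), dtype=np.float32)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i:i + s * (oh - 1) + 1:s, j:j + s * (ow - 1) + 1:s]
                xs = np.ascontiguousarray(xs).reshape(n, c, oh * ow)
                out += np.matmul(wv[:, :, i, j][None], xs)
        out = out.reshape(n, -1, oh, ow)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        if self.train_mode:
            self._cache = (xp, x.shape, (oh, ow))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, x_shape, (oh, ow) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        g = grad.reshape(n, -1, oh * ow)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                sl = np.s_[:, :, i:i + s * (oh - 1) + 1:s, j:j + s * (ow - 1) + 1:s]
                xs = np.ascontiguousarray(xp[sl]).reshape(n, c, oh * ow)
                self.weight.grad[:, :, i, j] += np.matmul(
                    g, xs.transpose(0, 2, 1)).sum(axis=0)
                dxs = np.matmul(wv[:, :, i, j].T[None], g).reshape(n, c, oh, ow)
                dxp[sl] += dxs
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if self.train_mode:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxh = grad * self.gamma.value[None, :, None, None]
        # standard batchnorm gradient through batch mean/var
        sum_g = gxh.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (gxh * xhat).sum(axis=(0, 2, 3), keepdims=True)
        inv_b = inv[None, :, None, None]
        return inv_b * (gxh - sum_g / m - xhat * sum_gx / m)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if self.train_mode:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2d(Layer):
    """k x k max pooling (default 3x3, stride 2, pad 1)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        out = np.full((n, c, oh, ow), -np.inf, dtype=np.float32)
        arg = np.zeros((n, c, oh, ow), dtype=np.uint8)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            xs = xp[:, :, i:i + s * (oh - 1) + 1:s, j:j + s * (ow - 1) + 1:s]
            better = xs > out
            out = np.where(better, xs, out)
            arg = np.where(better, np.uint8(idx), arg)
        if self.train_mode:
            self._cache = (arg, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, x_shape = self._cache
        self._cache = None
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = grad.shape[2], grad.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for idx in range(k * k):
            i, j = divmod(idx, k)
            sel = arg == idx
            dxp[:, :, i:i + s * (oh - 1) + 1:s,
                j:j + s * (ow - 1) + 1:s] += np.where(sel, grad, 0.0)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ResizeNearest(Layer):
    """Nearest-neighbour resize to an arbitrary target size.

    Exact 2x upsampling gets a fast repeat/reshape path in both directions;
    the general path covers the odd skip sizes of non-power-of-two inputs.
    """

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = out_hw
        exact2 = oh == 2 * h and ow == 2 * w
        if exact2:
            out = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        else:
            ir = np.minimum((np.arange(oh) * h) // oh, h - 1)
            ic = np.minimum((np.arange(ow) * w) // ow, w - 1)
            out = x[:, :, ir][:, :, :, ic]
        if self.train_mode:
            self._cache = (x.shape, exact2, out_hw)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, h, w), exact2, (oh, ow) = self._cache
        self._cache = None
        if exact2:
            return grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
        ir = np.minimum((np.arange(oh) * h) // oh, h - 1)
        ic = np.minimum((np.arange(ow) * w) // ow, w - 1)
        tmp = np.zeros((n, c, h, ow), dtype=np.float32)
        np.add.at(tmp, (slice(None), slice(None), ir), grad)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(dx.transpose(0, 1, 3, 2), (slice(None), slice(None), ic),
                  tmp.transpose(0, 1, 3, 2))
        return dx


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis (axis=1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


DICE_EPS = 1e-6


def dice_loss(pred_probs: np.ndarray, truth: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Dice-coefficient loss 1 - (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps).

    ``pred_probs`` is a per-pixel foreground probability map in [0, 1];
    ``truth`` a binary mask of the same shape. Returns a scalar in [0, 1].
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.size and (p.min() < -1e-6 or p.max() > 1 + 1e-6):
        raise ValueError("pred_probs must lie in [0, 1]")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def dice_loss_grad(pred_probs: np.ndarray, truth: np.ndarray,
                   eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Dice loss and its gradient w.r.t. the foreground probabilities."""
    p = np.asarray(pred_probs, dtype=np.float32)
    t = np.asarray(truth, dtype=np.float32)
    inter = float((p * t).sum())
    sp, st = float(p.sum()), float(t.sum())
    denom = sp + st + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    # d/dp [ (2*I+eps)/D ] = (2*t*D - (2*I+eps)) / D^2
    grad = -(2.0 * t * denom - (2.0 * inter + eps)) / (denom * denom)
    return loss, grad.astype(np.float32)


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 1e-10):
        self.params = params
        self.lr, self.b1, self.b2, self.eps, self.wd = lr, beta1, beta2, eps, weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.wd * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
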