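"""Layer primitives (NCHW, float32) with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "BatchNorm2d",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Sequential",
]


class Layer:
    """Base class; stateless layers only need forward/backward."""

    def parameters(self):
        """Yield (name, param_array, grad_array) triples."""
        return iter(())

    def buffers(self):
        """Yield (name, array) pairs of non-learnable state (e.g. BN stats)."""
        return iter(())

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False):
        raise NotImplementedError

    def backward(self, grad: np.ndarray, cache):
        raise NotImplementedError


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, C*kh*kw, oh*ow) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for a in range(kh):
        for b in range(kw):
            cols[:, :, a, b] = xp[:, :, a : a + oh * stride : stride, b : b + ow * stride : stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    g = cols.reshape(n, c, kh, kw, oh, ow)
    for a in range(kh):
        for b in range(kw):
            xp[:, :, a : a + oh * stride : stride, b : b + ow * stride : stride] += g[:, :, a, b]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale).astype(np.float32)
        self.dW = np.zeros_like(self.W)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self.db = np.zeros_like(self.b) if bias else None

    def parameters(self):
        yield "W", self.W, self.dW
        if self.b is not None:
            yield "b", self.b, self.db

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, k, s, oh, ow)
        wm = self.W.reshape(self.out_ch, -1)
        y = np.matmul(wm, cols)  # (N, out, oh*ow)
        if self.b is not None:
            y += self.b[None, :, None]
        return y.reshape(n, self.out_ch, oh, ow), (x.shape, cols, oh, ow)

    def backward(self, grad, cache, need_input: bool = True):
        x_shape, cols, oh, ow = cache
        n = x_shape[0]
        k, s, p = self.kernel, self.stride, self.pad
        g = grad.reshape(n, self.out_ch, oh * ow)
        self.dW += np.einsum("nol,nkl->ok", g, cols).reshape(self.W.shape)
        if self.b is not None:
            self.db += g.sum(axis=(0, 2))
        if not need_input:  # first learnable layer: input gradient unused
            return None
        dcols = np.matmul(self.W.reshape(self.out_ch, -1).T, g)
        return _col2im(dcols, x_shape, k, k, s, p, oh, ow)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.W = (rng.standard_normal((in_dim, out_dim)) * scale).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        yield "W", self.W, self.dW
        yield "b", self.b, self.db

    def forward(self, x, train=False):
        return x @ self.W + self.b, x

    def backward(self, grad, cache):
        x = cache
        self.dW += x.T @ grad
        self.db += grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        mask = x > 0
        return x * mask, mask

    def backward(self, grad, cache):
        return grad * cache


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def parameters(self):
        yield "gamma", self.gamma, self.dgamma
        yield "beta", self.beta, self.dbeta

    def buffers(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        y = self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]
        return y, (xhat, inv, train, x.shape)

    def backward(self, grad, cache):
        xhat, inv, train, shape = cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma += (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta += grad.sum(axis=(0, 2, 3))
        gg = grad * self.gamma[None, :, None, None]
        if not train:
            return gg * inv[None, :, None, None]
        # batch-statistics backward
        t1 = gg.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (gg * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (gg - t1 / m - xhat * t2 / m) * inv[None, :, None, None]


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        stack = np.empty((k * k, n, c, oh, ow), dtype=x.dtype)
        for a in range(k):
            for b in range(k):
                stack[a * k + b] = xp[:, :, a : a + oh * s : s, b : b + ow * s : s]
        idx = stack.argmax(axis=0)
        return np.take_along_axis(stack, idx[None], axis=0)[0], (idx, x.shape, oh, ow)

    def backward(self, grad, cache):
        idx, x_shape, oh, ow = cache
        n, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for a in range(k):
            for b in range(k):
                sel = idx == (a * k + b)
                sub = dxp[:, :, a : a + oh * s : s, b : b + ow * s : s]
                sub += grad * sel
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class AvgPool2d(Layer):
    def __init__(self, kernel: int):
        self.kernel = kernel

    def forward(self, x, train=False):
        k = self.kernel
        n, c, h, w = x.shape
        y = x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))
        return y, x.shape

    def backward(self, grad, cache):
        k = self.kernel
        return np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, grad, cache):
        n, c, h, w = cache
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class GlobalMomentPool(Layer):
    """(N,C,H,W) -> (N,2C): per-channel spatial mean and RMS.

    The second moment carries texture-energy information that a plain
    average erases, which matters when features must separate textures
    rather than shapes.
    """

    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, train=False):
        mean = x.mean(axis=(2, 3))
        rms = np.sqrt((x * x).mean(axis=(2, 3)) + self.eps)
        return np.concatenate([mean, rms], axis=1), (x, rms)

    def backward(self, grad, cache):
        x, rms = cache
        n, c, h, w = x.shape
        g_mean, g_rms = grad[:, :c], grad[:, c:]
        dx = np.broadcast_to(g_mean[:, :, None, None], x.shape) / (h * w)
        dx = dx + x * (g_rms / (rms * h * w))[:, :, None, None]
        return dx.astype(x.dtype)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, p, g in layer.parameters():
                yield f"{i}.{name}", p, g

    def buffers(self):
        for i, layer in enumerate(self.layers):
            for name, b in layer.buffers():
                yield f"{i}.{name}", b

    def forward(self, x, train=False):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, train=train)
            caches.append(cache)
        return x, caches

    def backward(self, grad, caches, need_input: bool = True):
        if need_input:
            first_param = -1
        else:
            # gradient below the first learnable layer is never consumed
            first_param = next((i for i, l in enumerate(self.layers)
                                if next(l.parameters(), None) is not None), -1)
        for i in range(len(self.layers) - 1, -1, -1):
            layer, cache = self.layers[i], caches[i]
            if i < first_param:
                break  # remaining layers are parameter-free
            if i == first_param and isinstance(layer, Conv2d):
                layer.backward(grad, cache, need_input=False)
                return None
            grad = layer.backward(grad, cache)
        return grad
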