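"""Neural-network layers and optimizers on top of :mod:`metascope.autodiff`.

Implements exactly the building blocks the deblurring network uses: 2-D
convolution (im2col), batch/instance normalization, 2x2 max pooling, bilinear
2x upsampling, a small linear layer for the attention bottleneck, and Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "InstanceNorm2d",
           "Linear", "max_pool2x2", "upsample_bilinear2x", "Adam", "conv2d"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Barebones module: tracks parameters and train/eval mode recursively."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {i: p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[i]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """NCHW convolution (cross-correlation), stride 1, via im2col matmul."""
    x = Tensor.as_tensor(x)
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    assert C == Cw, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wm = w.data.reshape(O, C * kh * kw).T
    out = cols @ wm
    if b is not None:
        out = out + b.data
    out_data = out.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if w.requires_grad:
            dw = (cols.T @ gm).T.reshape(O, C, kh, kw)
            w._accum(dw)
        if x.requires_grad:
            dcols = (gm @ wm.T).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + Ho, j:j + Wo] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True,
                 init: str = "he"):
        super().__init__()
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        elif init == "zero":
            w = np.zeros((out_ch, in_ch, kernel, kernel))
        elif init == "identity":
            assert in_ch == out_ch and kernel == 1
            w = np.eye(in_ch).reshape(out_ch, in_ch, 1, 1)
        else:
            raise ValueError(init)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization (no affine parameters)."""

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0, np.sqrt(1.0 / n_in), (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def max_pool2x2(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    N, C, H, W = x.data.shape
    assert H % 2 == 0 and W % 2 == 0, "max_pool2x2 needs even spatial size"
    v = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = v.max(axis=(3, 5))
    mask = (v == out_data[:, :, :, None, :, None])
    # break ties deterministically: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    first = np.zeros_like(flat)
    idx = flat.argmax(axis=-1)
    np.put_along_axis(first, idx[..., None], True, axis=-1)
    mask = (first.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5))

    def backward(g):
        gv = mask * g[:, :, :, None, :, None]
        x._accum(gv.reshape(N, C, H, W))

    return Tensor._make(out_data, (x,), backward)


_bilinear_cache: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix for 2x bilinear upsampling (align_corners=False)."""
    if n not in _bilinear_cache:
        M = np.zeros((2 * n, n))
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            lo = int(np.floor(src))
            frac = src - lo
            lo_c = min(max(lo, 0), n - 1)
            hi_c = min(max(lo + 1, 0), n - 1)
            M[i, lo_c] += 1.0 - frac
            M[i, hi_c] += frac
        _bilinear_cache[n] = M
    return _bilinear_cache[n]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    N, C, H, W = x.data.shape
    Mh, Mw = _bilinear_matrix(H), _bilinear_matrix(W)
    out_data = np.einsum("oh,nchw,pw->ncop", Mh, x.data, Mw, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", Mh, g, Mw, optimize=True))

    return Tensor._make(out_data, (x,), backward)


class Adam:
    """Adam with optional L2 penalty added to the gradient (classic weight decay)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + 2.0 * self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
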