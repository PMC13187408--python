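"""Minimal reverse-mode automatic differentiation on numpy arrays.

The co-design pipeline needs gradients that flow from an image-reconstruction
loss back through a convolutional network, the sensor-image convolution, the
Fourier-optics point-spread-function model and a piecewise-linear spectral
lookup, down to the nanopillar width perturbation of the meta-optic.  This
module provides the small dynamic-graph tensor engine that carries those
gradients.  Everything is double precision on CPU; graphs are built eagerly
and freed after :meth:`Tensor.backward`.

Only the operations the pipeline actually uses are implemented.  Each custom
operation's backward pass is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["Tensor", "concat", "conv_full2d", "conv_fixed2d", "fft_mag2d",
           "psf_intensity", "interp_lookup", "gather", "segment_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
        # free the graph
        for t in topo:
            t._backward = None
            t._parents = ()

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data ** 2)

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clamp(self, lo: float, hi: float):
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            self._accum(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by `pad` on each side."""
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]

        def backward(g):
            sl = [slice(None)] * (self.data.ndim - 2) + \
                 [slice(pad, g.shape[-2] - pad), slice(pad, g.shape[-1] - pad)]
            self._accum(g[tuple(sl)])

        return Tensor._make(np.pad(self.data, width), (self,), backward)


def concat(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


# ---------------------------------------------------------------------------
# Custom operations with hand-derived adjoints
# ---------------------------------------------------------------------------

def conv_full2d(x: Tensor, k: Tensor) -> Tensor:
    """Full 2-D linear convolution of two 2-D arrays, both differentiable.

    Adjoints: dL/dx = corr(g, k) 'valid', dL/dk = corr(g, x) 'valid'.
    """
    x = Tensor.as_tensor(x)
    k = Tensor.as_tensor(k)
    out_data = fftconvolve(x.data, k.data, mode="full")

    def backward(g):
        if x.requires_grad:
            x._accum(fftconvolve(g, k.data[::-1, ::-1], mode="valid"))
        if k.requires_grad:
            k._accum(fftconvolve(g, x.data[::-1, ::-1], mode="valid"))

    return Tensor._make(out_data, (x, k), backward)


def conv_fixed2d(x: Tensor, kernel: np.ndarray, mode: str = "same") -> Tensor:
    """Convolve the last two axes of `x` with a fixed (non-learnable) kernel."""
    x = Tensor.as_tensor(x)
    kernel = np.asarray(kernel, dtype=np.float64)
    kb = kernel.reshape((1,) * (x.data.ndim - 2) + kernel.shape)
    out_data = fftconvolve(x.data, kb, mode=mode, axes=(-2, -1))

    def backward(g):
        kr = kb[..., ::-1, ::-1]
        if mode == "same":
            x._accum(fftconvolve(g, kr, mode="same", axes=(-2, -1)))
        elif mode == "valid":
            x._accum(fftconvolve(g, kr, mode="full", axes=(-2, -1)))
        else:  # full
            x._accum(fftconvolve(g, kr, mode="valid", axes=(-2, -1)))

    return Tensor._make(out_data, (x,), backward)


def fft_mag2d(x: Tensor) -> Tensor:
    """Magnitude of the unshifted 2-D DFT of a real array (last two axes)."""
    x = Tensor.as_tensor(x)
    A = np.fft.fft2(x.data)
    M = np.abs(A)

    def backward(g):
        n = x.data.shape[-2] * x.data.shape[-1]
        W = g * A / np.maximum(M, 1e-30)
        x._accum(np.real(np.fft.ifft2(W)) * n)

    return Tensor._make(M, (x,), backward)


def psf_intensity(phase: Tensor, mask: np.ndarray) -> Tensor:
    """Incoherent PSF intensity |F{mask * exp(i*phase)}|^2, centred layout.

    `phase` and `mask` are 2-D with the optical axis at index (n//2, n//2).
    The output is the zero-frequency-centred intensity (not normalised).
    """
    phase = Tensor.as_tensor(phase)
    mask = np.asarray(mask, dtype=np.float64)
    u_c = np.fft.ifftshift(mask * np.exp(1j * phase.data))
    A = np.fft.fft2(u_c)
    out_data = np.fft.fftshift((A * A.conj()).real)

    def backward(g):
        n = u_c.shape[0] * u_c.shape[1]
        G = np.fft.ifftshift(g)
        B = np.fft.ifft2(G * A) * n      # adjoint DFT of G.A
        dphi_c = -2.0 * np.imag(np.conj(B) * u_c)
        phase._accum(np.fft.fftshift(dphi_c))

    return Tensor._make(out_data, (phase,), backward)


def interp_lookup(gamma: Tensor, xp: np.ndarray, fp: np.ndarray) -> Tensor:
    """Differentiable piecewise-linear table lookup (gradient = segment slope)."""
    gamma = Tensor.as_tensor(gamma)
    xp = np.asarray(xp, dtype=np.float64)
    fp = np.asarray(fp, dtype=np.float64)
    out_data = np.interp(gamma.data, xp, fp)
    seg = np.clip(np.searchsorted(xp, gamma.data, side="right") - 1,
                  0, len(xp) - 2)
    slope = (fp[seg + 1] - fp[seg]) / (xp[seg + 1] - xp[seg])
    # outside the table np.interp clamps: zero slope there
    slope = np.where((gamma.data < xp[0]) | (gamma.data > xp[-1]), 0.0, slope)

    def backward(g):
        gamma._accum(g * slope)

    return Tensor._make(out_data, (gamma,), backward)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """out[i] = x[idx[i]]; adjoint scatter-adds."""
    x = Tensor.as_tensor(x)
    idx = np.asarray(idx)

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        x._accum(full)

    return Tensor._make(x.data[idx], (x,), backward)


def segment_mean(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    """Per-segment mean of a flat tensor; entries with seg < 0 are ignored."""
    x = Tensor.as_tensor(x)
    seg = np.asarray(seg)
    valid = seg >= 0
    counts = np.bincount(seg[valid], minlength=n_seg).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    sums = np.bincount(seg[valid], weights=x.data[valid], minlength=n_seg)

    def backward(g):
        full = np.zeros_like(x.data)
        full[valid] = g[seg[valid]] / counts[seg[valid]]
        x._accum(full)

    return Tensor._make(sums / counts, (x,), backward)
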