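"""Deblurring network: three-level encoder–decoder with spectral attention.

Architecture (multispectral default):

1. per-channel instance normalization of the sensor image;
2. a 1×1 cross-channel mixing convolution initialized to the identity;
3. a Fourier-domain channel-attention block — per-channel sigmoid gates
   computed from the pooled magnitude spectrum of each channel;
4. a three-level U-Net body: each encoder level is 2×2 max-pooling followed
   by two 3×3 conv + batch-norm + ReLU layers, feature widths growing
   32 → 64 → 128; the decoder mirrors it with bilinear upsampling, skip
   concatenation and the same double-convolution;
5. a final 1×1 projection back to the input channel count, squashed through
   tanh and added to the raw sensor image (residual head, zero-initialized
   so the network starts as the identity map), then clamped to [0, 1].

The single-channel variant omits the attention block (no cross-channel
reweighting is possible with one channel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, fft_mag2d
from . import nn

__all__ = ["ReconstructorSpec", "Reconstructor", "FourierChannelAttention",
           "build_reconstructor", "reconstruct"]


@dataclass(frozen=True)
class ReconstructorSpec:
    """Static description of the network; parameter count is a pure function
    of this spec."""

    channels: int = 4
    widths: tuple = (32, 64, 128)
    attention: bool = True
    residual: bool = True
    attention_reduction: int = 2

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if len(self.widths) != 3 or list(self.widths) != sorted(set(self.widths)):
            raise ValueError("widths must be three strictly increasing values")

    @property
    def levels(self) -> int:
        return len(self.widths)

    @property
    def use_attention(self) -> bool:
        return self.attention and self.channels > 1


class FourierChannelAttention(nn.Module):
    """Per-channel gates from pooled magnitude spectra.

    Each channel's DFT magnitude is log-pooled to a scalar; a two-layer
    bottleneck shared across channels maps (own statistic, cross-channel
    mean) to a sigmoid gate in (0, 1) that reweights the channel.  Sharing
    the weights makes the block permutation-equivariant, so identical
    channels always receive identical gates.  An ε in the log-pooling guards
    all-zero channels.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(2, channels // reduction)
        self.fc1 = nn.Linear(2, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        mag = fft_mag2d(x)                                # (N, C, H, W)
        pooled = ((mag + 1e-8).log()).mean(axis=(2, 3))   # (N, C)
        n, c = pooled.shape
        own = pooled.reshape(n, c, 1)
        ctx = pooled.mean(axis=1, keepdims=True)          # (N, 1)
        ctx = (ctx * np.ones((1, c))).reshape(n, c, 1)
        feats = concat([own, ctx], axis=2)                # (N, C, 2)
        gates = self.fc2(self.fc1(feats).relu()).sigmoid()
        return x * gates.reshape(n, c, 1, 1)


class _DoubleConv(nn.Module):
    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x):
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class Reconstructor(nn.Module):
    """See module docstring.  Input (N, C, H, W) with H, W divisible by 4."""

    def __init__(self, spec: ReconstructorSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        c = spec.channels
        w1, w2, w3 = spec.widths
        self.in_norm = nn.InstanceNorm2d()
        self.mix = nn.Conv2d(c, c, 1, rng, init="identity")
        self.attention = (FourierChannelAttention(c, spec.attention_reduction, rng)
                          if spec.use_attention else None)
        self.enc1 = _DoubleConv(c, w1, rng)
        self.enc2 = _DoubleConv(w1, w2, rng)
        self.enc3 = _DoubleConv(w2, w3, rng)
        self.dec2 = _DoubleConv(w3 + w2, w2, rng)
        self.dec1 = _DoubleConv(w2 + w1, w1, rng)
        self.head = nn.Conv2d(w1, c, 1, rng, init="zero")

    def forward(self, x) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.spec.channels:
            raise ValueError("channel count mismatch")
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("spatial size must be divisible by 4 "
                             "(three resolution levels)")
        h = self.in_norm(x)
        h = self.mix(h)
        if self.attention is not None:
            h = self.attention(h)
        s1 = self.enc1(h)
        s2 = self.enc2(nn.max_pool2x2(s1))
        s3 = self.enc3(nn.max_pool2x2(s2))
        d2 = self.dec2(concat([nn.upsample_bilinear2x(s3), s2], axis=1))
        d1 = self.dec1(concat([nn.upsample_bilinear2x(d2), s1], axis=1))
        residual = self.head(d1).tanh()
        out = x + residual if self.spec.residual else residual
        return out.clamp(0.0, 1.0)


def build_reconstructor(spec: ReconstructorSpec, seed: int = 0) -> Reconstructor:
    """Construct the network and assert the identity-at-initialization
    contract of the zero-initialized residual head."""
    net = Reconstructor(spec, seed=seed)
    probe = np.random.default_rng(seed).uniform(0.1, 0.9,
                                                (1, spec.channels, 8, 8))
    net.eval()
    out = net(Tensor(probe)).data
    net.train()
    if spec.residual:
        assert np.allclose(out, np.clip(probe, 0, 1), atol=1e-12), \
            "residual head must start as the identity map"
    return net


def reconstruct(net: Reconstructor, sensor_values: np.ndarray) -> np.ndarray:
    """Evaluation-mode reconstruction of a (C, H, W) sensor image."""
    was_training = net.training
    net.eval()
    out = net(Tensor(sensor_values[None])).data[0]
    net.train(was_training)
    return out
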