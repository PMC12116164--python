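"""Channel/spatial attention blocks.

CBAM gates a feature map first per channel — a shared two-layer MLP applied
to the global average- and max-pooled channel descriptors, summed and passed
through a sigmoid — then per spatial location, via a 7x7 convolution over the
stacked channel-wise average and max maps.  ECA gates channels only, with a
1-D convolution of channel-count-adaptive kernel size over the global
average-pooled channel vector.
"""

from __future__ import annotations

import numpy as np

from ..nn import autograd as ag
from ..nn.layers import Conv2d, Linear, Module
from ..nn.autograd import Tensor

__all__ = ["CBAM", "ECA", "cbam", "eca", "eca_kernel_size"]


class CBAM(Module):
    """Convolutional Block Attention Module (sequential channel + spatial gate)."""

    def __init__(self, channels: int, reduction: int = 16, spatial_kernel: int = 7,
                 rng=None, dtype=np.float32):
        super().__init__()
        if channels < reduction:
            raise ValueError(
                f"CBAM requires channels >= reduction (got C={channels}, r={reduction})")
        if channels % reduction:
            raise ValueError(
                f"CBAM requires channels divisible by reduction (got C={channels}, r={reduction})")
        rng = rng if rng is not None else np.random.default_rng(0)
        hidden = channels // reduction
        self.channels = channels
        self.reduction = reduction
        # shared MLP over pooled channel descriptors
        self.fc1 = Linear(channels, hidden, bias=False, rng=rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, bias=False, rng=rng, dtype=dtype)
        pad = spatial_kernel // 2
        self.spatial_conv = Conv2d(2, 1, spatial_kernel, padding=pad, bias=False,
                                   rng=rng, dtype=dtype)

    def channel_gain(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = ag.mean(x, axis=(2, 3))          # (N, C)
        mx = ag.amax(x, axis=(2, 3))           # (N, C)
        shared = lambda v: self.fc2(ag.relu(self.fc1(v)))
        gain = ag.sigmoid(ag.add(shared(avg), shared(mx)))
        return ag.reshape(gain, (n, c, 1, 1))

    def spatial_gain(self, x: Tensor) -> Tensor:
        avg = ag.mean(x, axis=1, keepdims=True)   # (N,1,H,W)
        mx = ag.amax(x, axis=1, keepdims=True)
        stacked = ag.concat([avg, mx], axis=1)
        return ag.sigmoid(self.spatial_conv(stacked))

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        x_ca = ag.mul(x, self.channel_gain(x))
        return ag.mul(x_ca, self.spatial_gain(x_ca))


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel size: nearest odd integer >= |log2(C)/gamma + b/gamma|.

    Follows the standard ECA rule: t = |log2(C)/gamma + b/gamma|, k = t if the
    integer part is odd else the next odd number.
    """
    if channels < 1:
        raise ValueError("channels must be >= 1")
    t = abs(np.log2(channels) / gamma + b / gamma)
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class ECA(Module):
    """Efficient Channel Attention: 1-D conv over the GAP channel vector."""

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.k = eca_kernel_size(channels, gamma, b)
        # 1-D conv along the channel axis, realised as a (1,k) 2-D conv
        self.conv = Conv2d(1, 1, 1, bias=False, rng=rng, dtype=dtype)
        # replace square kernel with a (1,1,1,k) kernel
        std = np.sqrt(2.0 / self.k)
        self.conv.weight = Tensor(
            (rng.standard_normal((1, 1, 1, self.k)) * std).astype(dtype),
            requires_grad=True)
        self.conv.padding = 0

    def channel_gain(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        gap = ag.mean(x, axis=(2, 3))                 # (N, C)
        v = ag.reshape(gap, (n, 1, 1, c))             # conv along last axis
        # edge-replicate padding along the channel axis: keeps the gate
        # channel-symmetric (a channel-constant descriptor yields equal
        # gains at the edge channels too, which zero padding would break)
        pad = self.k // 2
        if pad:
            first = ag.narrow(v, 3, 0, 1)
            last = ag.narrow(v, 3, c - 1, 1)
            v = ag.concat([*([first] * pad), v, *([last] * pad)], axis=3)
        out = ag.conv2d(v, self.conv.weight, None, stride=1, padding=0)
        gain = ag.sigmoid(out)
        return ag.reshape(gain, (n, c, 1, 1))

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        return ag.mul(x, self.channel_gain(x))


def _apply_single(block: Module, feature_map: np.ndarray) -> np.ndarray:
    arr = np.asarray(feature_map, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("feature_map must be C x H x W")
    block.eval()
    out = block(Tensor(arr[None]))
    return out.data[0]


def cbam(feature_map: np.ndarray, reduction: int = 16, seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised CBAM block to a single C x H x W array."""
    c = np.asarray(feature_map).shape[0]
    block = CBAM(c, reduction=reduction, rng=np.random.default_rng(seed), dtype=np.float64)
    return _apply_single(block, feature_map)


def eca(feature_map: np.ndarray, gamma: float = 2.0, b: float = 1.0,
        seed: int = 0) -> np.ndarray:
    """Apply a freshly initialised ECA block to a single C x H x W array."""
    c = np.asarray(feature_map).shape[0]
    block = ECA(c, gamma=gamma, b=b, rng=np.random.default_rng(seed), dtype=np.float64)
    return _apply_single(block, feature_map)
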