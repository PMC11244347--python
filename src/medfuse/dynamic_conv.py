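"""Multi-dimensional dynamic convolution (MDC) and the DCB block.

A dynamic convolution keeps a bank of ``n`` candidate kernels and mixes
them per input sample. The multi-dimensional variant additionally learns
three sigmoid-gated attentions over the kernel's spatial footprint, its
input channels and its output channels, plus a softmax attention over the
kernel bank, all computed in parallel from one pooled descriptor:

    W~(x) = sum_i  alpha_w,i(x) * (alpha_s(x) ⊙ alpha_c(x) ⊙ alpha_f(x) ⊙ W_i)

The aggregated kernel is applied once as a same-padded, per-sample
convolution (mathematically identical to running the n kernels separately
and mixing the outputs, but a single conv call).

DCB = MDC → instance normalization → GELU.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import InstanceNorm2d, Linear, Module, Parameter, fan_in_uniform_, gelu, relu, sigmoid


class MDConv2d(Module):
    """Multi-dimensional dynamic convolution layer (the MDC kernel bank).

    Parameters
    ----------
    in_channels, out_channels, kernel_size
        Static shape of every candidate kernel.
    n_kernels
        Size of the kernel bank (attention over this axis is a softmax,
        so the bank is mixed as a convex combination).
    reduction
        Bottleneck divisor of the squeeze projection; the hidden width is
        ``max(in_channels // reduction, 1)`` (floored because the fusion
        network uses widths as small as 2–3 channels).
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, n_kernels: int = 4, reduction: int = 4):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.n_kernels = n_kernels
        fan_in = in_channels * kernel_size * kernel_size
        self.kernels = Parameter(
            fan_in_uniform_(rng, (n_kernels, out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels))
        hidden = max(in_channels // reduction, 1)
        self.squeeze = Linear(in_channels, hidden, rng, init="fan_in")
        self.head_spatial = Linear(hidden, kernel_size * kernel_size, rng, init="fan_in")
        self.head_in = Linear(hidden, in_channels, rng, init="fan_in")
        self.head_out = Linear(hidden, out_channels, rng, init="fan_in")
        self.head_kernel = Linear(hidden, n_kernels, rng, init="fan_in")

    # ------------------------------------------------------------ attentions
    def compute_attention(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """The four kernel attentions from a global-average-pooled descriptor.

        Returns ``(alpha_s, alpha_c, alpha_f, alpha_w)`` shaped to broadcast
        over ``(B, n, C_out, C_in, k, k)``: spatial and channel gates are
        sigmoids in (0,1); the kernel attention is a softmax simplex.
        """
        x = ad.as_tensor(x)
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        B = x.shape[0]
        k = self.kernel_size
        desc = relu(self.squeeze(x.mean(axis=(2, 3))))  # (B, hidden)
        alpha_s = sigmoid(self.head_spatial(desc)).reshape(B, 1, 1, 1, k, k)
        alpha_c = sigmoid(self.head_in(desc)).reshape(B, 1, 1, self.in_channels, 1, 1)
        alpha_f = sigmoid(self.head_out(desc)).reshape(B, 1, self.out_channels, 1, 1, 1)
        alpha_w = ad.softmax(self.head_kernel(desc), axis=-1).reshape(B, self.n_kernels, 1, 1, 1, 1)
        return alpha_s, alpha_c, alpha_f, alpha_w

    def aggregate_kernel(self, attention) -> Tensor:
        """Per-sample aggregated kernel W~ of shape (B, C_out, C_in, k, k)."""
        alpha_s, alpha_c, alpha_f, alpha_w = attention
        bank = self.kernels.reshape(1, self.n_kernels, self.out_channels,
                                    self.in_channels, self.kernel_size, self.kernel_size)
        return (alpha_w * (alpha_s * alpha_c * alpha_f * bank)).sum(axis=1)

    def forward(self, x: Tensor, attention_override=None) -> Tensor:
        """Dynamic convolution; ``attention_override`` freezes the four
        attentions to caller-supplied tensors (used by equivalence checks)."""
        x = ad.as_tensor(x)
        if x.shape[2] < self.kernel_size or x.shape[3] < self.kernel_size:
            raise ValueError(
                f"spatial size {x.shape[2:]} smaller than kernel {self.kernel_size}"
            )
        attention = attention_override if attention_override is not None else self.compute_attention(x)
        w = self.aggregate_kernel(attention)
        return ad.conv2d_samplewise(x, w, self.bias, padding=self.kernel_size // 2)


class DCB(Module):
    """Dynamic convolutional block: MDC → instance norm → GELU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, n_kernels: int = 4, norm_eps: float = 1e-5):
        super().__init__()
        self.conv = MDConv2d(in_channels, out_channels, kernel_size, rng, n_kernels=n_kernels)
        self.norm = InstanceNorm2d(out_channels, eps=norm_eps)

    def forward(self, x: Tensor) -> Tensor:
        return gelu(self.norm(self.conv(x)))


class VanillaConvBlock(Module):
    """Ablation stand-in for DCB: plain conv → instance norm → GELU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, norm_eps: float = 1e-5):
        super().__init__()
        from .nn import Conv2d

        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.norm = InstanceNorm2d(out_channels, eps=norm_eps)

    def forward(self, x: Tensor) -> Tensor:
        return gelu(self.norm(self.conv(x)))


__all__ = ["MDConv2d", "DCB", "VanillaConvBlock"]
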