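"""Residual hybrid transformer blocks.

Two sub-blocks are composed per stack:

* RHTA — ``r = CAM(LN(x)) + W-MSA(LN(x)) + x`` then ``y = MLP(LN(r)) + r``:
  window self-attention (local fitting) in parallel with a
  squeeze-excitation channel-attention conv path (global statistics).
* RHTB — ``r = OAM(LN(x)) + x`` then ``y = MLP(LN(r)) + r``: overlapping
  cross attention, whose queries come from non-overlapping M×M windows
  while keys/values come from enlarged windows of size round((1+γ)·M)
  extracted with stride M, so neighboring windows exchange information
  without shifted-window masking.

A full stack is three RHTA blocks followed by one RHTB block. Features are
(B, C, H, W) at block boundaries; tokens are channels-last with LayerNorm
over the channel axis. Arbitrary image sizes are handled by reflective
padding to the next multiple of the window size, cropped after attention.

All residual sub-paths end in a zero-initialized projection, so a freshly
built block is the identity map — a stable starting point for the fusion
residuals and an exactly testable contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, LayerNorm, Linear, Mlp, Module, ModuleList, Parameter, gelu, relu, sigmoid


@dataclass
class RHTConfig:
    """Geometry and width of one residual hybrid transformer stack."""

    embed_dim: int = 3
    window_size: int = 8
    num_heads: int = 1
    overlap_ratio: float = 0.5
    mlp_ratio: float = 2.0
    cam_reduction: int = 1
    cab_scale: float = 0.01
    depth_a: int = 3
    outer_residual: bool = False

    def __post_init__(self):
        if self.embed_dim % self.num_heads:
            raise ValueError(f"embed_dim {self.embed_dim} not divisible by num_heads {self.num_heads}")
        if not 0.0 <= self.overlap_ratio < 1.0:
            raise ValueError(f"overlap_ratio must be in [0, 1), got {self.overlap_ratio}")

    @property
    def overlap_window_size(self) -> int:
        return int(round((1.0 + self.overlap_ratio) * self.window_size))


# --------------------------------------------------------------- partitioning
def window_partition(x: Tensor, window_size: int) -> Tensor:
    """(B, H, W, C) → (B·nH·nW, M², C); H and W must be multiples of M."""
    x = ad.as_tensor(x)
    B, H, W, C = x.shape
    M = window_size
    if H % M or W % M:
        raise ValueError(f"spatial dims ({H},{W}) not divisible by window size {M}")
    x = x.reshape(B, H // M, M, W // M, M, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B * (H // M) * (W // M), M * M, C)


def window_reverse(windows: Tensor, window_size: int, B: int, H: int, W: int) -> Tensor:
    """Exact inverse of :func:`window_partition`."""
    M = window_size
    C = windows.shape[-1]
    x = windows.reshape(B, H // M, W // M, M, M, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(B, H, W, C)


def _pad_to_multiple(x: Tensor, multiple: int) -> tuple[Tensor, int, int]:
    """Reflect-pad (B, H, W, C) so H and W divide ``multiple``."""
    _, H, W, _ = x.shape
    ph = (-H) % multiple
    pw = (-W) % multiple
    if ph or pw:
        x = ad.pad2d(x, (0, ph, 0, pw), mode="reflect", axes=(1, 2))
    return x, H, W


def _relative_position_index(q_size: int, k_size: int) -> np.ndarray:
    """Index into a ((q+k−1)²,) bias table for every (query, key) token pair.

    Query tokens live on a q_size grid, key tokens on a k_size grid centered
    on it (k_size ≥ q_size); with q_size == k_size this is the standard
    window-attention relative position index.
    """
    off = (k_size - q_size) // 2
    cq = np.stack(np.meshgrid(np.arange(q_size), np.arange(q_size), indexing="ij"), axis=-1).reshape(-1, 2)
    ck = np.stack(np.meshgrid(np.arange(k_size) - off, np.arange(k_size) - off, indexing="ij"), axis=-1).reshape(-1, 2)
    rel = cq[:, None, :] - ck[None, :, :] + (q_size - 1 + off)
    span = q_size + k_size - 1
    return (rel[..., 0] * span + rel[..., 1]).astype(np.int64)


# ------------------------------------------------------------------ attention
class WindowAttention(Module):
    """W-MSA: multi-head self-attention inside non-overlapping M×M windows,
    with a learned relative position bias."""

    def __init__(self, dim: int, window_size: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.window_size = window_size
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim**-0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng, zero_init=True)
        span = 2 * window_size - 1
        self.rel_bias_table = Parameter(np.zeros((span * span, num_heads)))
        self.rel_index = _relative_position_index(window_size, window_size)

    def attend(self, windows: Tensor) -> Tensor:
        """Attention on pre-partitioned windows: (nW, M², C) → (nW, M², C)."""
        windows = ad.as_tensor(windows)
        nW, N, C = windows.shape
        if C != self.dim:
            raise ValueError(f"token dim {C} != embed dim {self.dim}")
        h, d = self.num_heads, self.head_dim
        qkv = self.qkv(windows).reshape(nW, N, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (nW, h, N, d)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = ad.embedding(self.rel_bias_table, self.rel_index)  # (N, N, h)
        attn = attn + bias.transpose(2, 0, 1).reshape(1, h, N, N)
        attn = ad.softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nW, N, C)
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        """(B, H, W, C) → (B, H, W, C), padding/cropping handled internally."""
        B = x.shape[0]
        xp, H, W = _pad_to_multiple(x, self.window_size)
        Hp, Wp = xp.shape[1], xp.shape[2]
        out = self.attend(window_partition(xp, self.window_size))
        out = window_reverse(out, self.window_size, B, Hp, Wp)
        if (Hp, Wp) != (H, W):
            out = out[:, :H, :W, :]
        return out


class OverlappingAttention(Module):
    """OAM: queries from non-overlapping M×M windows, keys/values from
    enlarged Mo×Mo windows (Mo = round((1+γ)M)) extracted with stride M."""

    def __init__(self, dim: int, window_size: int, overlap_ratio: float,
                 num_heads: int, rng: np.random.Generator):
        super().__init__()
        self.dim = dim
        self.window_size = window_size
        self.overlap_win = int(round((1.0 + overlap_ratio) * window_size))
        if (self.overlap_win - window_size) % 2:
            raise ValueError(
                f"overlap window {self.overlap_win} minus window {window_size} must be even"
            )
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim**-0.5
        self.q = Linear(dim, dim, rng)
        self.kv = Linear(dim, 2 * dim, rng)
        self.proj = Linear(dim, dim, rng, zero_init=True)
        span = window_size + self.overlap_win - 1
        self.rel_bias_table = Parameter(np.zeros((span * span, num_heads)))
        self.rel_index = _relative_position_index(window_size, self.overlap_win)

    def forward(self, x: Tensor) -> Tensor:
        """(B, H, W, C) → (B, H, W, C)."""
        B = x.shape[0]
        M, Mo = self.window_size, self.overlap_win
        pad = (Mo - M) // 2
        xp, H, W = _pad_to_multiple(x, M)
        Hp, Wp = xp.shape[1], xp.shape[2]
        h, d = self.num_heads, self.head_dim

        q_tok = window_partition(xp, M)  # (nW, M², C)
        nW, Nq, C = q_tok.shape
        q = self.q(q_tok).reshape(nW, Nq, h, d).transpose(0, 2, 1, 3)

        kv = self.kv(xp)  # (B, Hp, Wp, 2C)
        kv = kv.transpose(0, 3, 1, 2)  # (B, 2C, Hp, Wp)
        kv = ad.unfold2d(kv, kernel=Mo, stride=M, padding=pad)  # (B, 2C, nH, nW, Mo, Mo)
        kv = kv.transpose(0, 2, 3, 4, 5, 1).reshape(nW, Mo * Mo, 2 * C)
        k = kv[:, :, :C].reshape(nW, Mo * Mo, h, d).transpose(0, 2, 1, 3)
        v = kv[:, :, C:].reshape(nW, Mo * Mo, h, d).transpose(0, 2, 1, 3)

        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        bias = ad.embedding(self.rel_bias_table, self.rel_index)  # (M², Mo², h)
        attn = attn + bias.transpose(2, 0, 1).reshape(1, h, Nq, Mo * Mo)
        attn = ad.softmax(attn, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nW, Nq, C)
        out = self.proj(out)
        out = window_reverse(out, M, B, Hp, Wp)
        if (Hp, Wp) != (H, W):
            out = out[:, :H, :W, :]
        return out


class ChannelAttentionModule(Module):
    """CAM: conv → GELU → conv feature path, gated per channel by a
    squeeze-excitation sigmoid and scaled by a small constant before the
    residual sum (so the conv path perturbs rather than dominates the
    attention stream)."""

    def __init__(self, dim: int, rng: np.random.Generator, reduction: int = 1,
                 se_reduction: int = 4, scale: float = 0.01):
        super().__init__()
        hidden = max(dim // reduction, 1)
        self.scale = scale
        self.conv1 = Conv2d(dim, hidden, 3, rng)
        self.conv2 = Conv2d(hidden, dim, 3, rng, zero_init=True)
        se_hidden = max(dim // se_reduction, 1)
        self.se_fc1 = Linear(dim, se_hidden, rng, init="fan_in")
        self.se_fc2 = Linear(se_hidden, dim, rng, init="fan_in")

    def channel_gate(self, feat: Tensor) -> Tensor:
        """Per-channel sigmoid gate in (0,1) from globally pooled features."""
        pooled = feat.mean(axis=(2, 3))  # (B, C)
        return sigmoid(self.se_fc2(relu(self.se_fc1(pooled))))

    def forward(self, x: Tensor, gate_override: Tensor | None = None) -> Tensor:
        """(B, C, H, W) → (B, C, H, W)."""
        feat = self.conv2(gelu(self.conv1(x)))
        gate = gate_override if gate_override is not None else self.channel_gate(feat)
        B, C = gate.shape
        return feat * gate.reshape(B, C, 1, 1) * self.scale


class RHTA(Module):
    """Hybrid attention sub-block: channel attention ∥ window self-attention."""

    def __init__(self, cfg: RHTConfig, rng: np.random.Generator):
        super().__init__()
        dim = cfg.embed_dim
        self.ln1 = LayerNorm(dim)
        self.wmsa = WindowAttention(dim, cfg.window_size, cfg.num_heads, rng)
        self.cam = ChannelAttentionModule(dim, rng, reduction=cfg.cam_reduction, scale=cfg.cab_scale)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * cfg.mlp_ratio), rng, zero_init_out=True)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) → (B, C, H, W)."""
        tok = x.transpose(0, 2, 3, 1)  # BHWC
        n1 = self.ln1(tok)
        cam_out = self.cam(n1.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1)
        r = cam_out + self.wmsa(n1) + tok
        y = self.mlp(self.ln2(r)) + r
        return y.transpose(0, 3, 1, 2)


class RHTB(Module):
    """Overlapping cross-attention sub-block."""

    def __init__(self, cfg: RHTConfig, rng: np.random.Generator):
        super().__init__()
        dim = cfg.embed_dim
        self.ln1 = LayerNorm(dim)
        self.oam = OverlappingAttention(dim, cfg.window_size, cfg.overlap_ratio, cfg.num_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * cfg.mlp_ratio), rng, zero_init_out=True)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C, H, W) → (B, C, H, W)."""
        tok = x.transpose(0, 2, 3, 1)
        r = self.oam(self.ln1(tok)) + tok
        y = self.mlp(self.ln2(r)) + r
        return y.transpose(0, 3, 1, 2)


class RHTStack(Module):
    """``depth_a`` RHTA blocks followed by one RHTB block; optionally an
    extra outer residual around the whole stack."""

    def __init__(self, cfg: RHTConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.blocks_a = ModuleList([RHTA(cfg, rng) for _ in range(cfg.depth_a)])
        self.block_b = RHTB(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = x
        for blk in self.blocks_a:
            y = blk(y)
        y = self.block_b(y)
        if self.cfg.outer_residual:
            y = y + x
        return y


__all__ = [
    "RHTConfig", "window_partition", "window_reverse",
    "WindowAttention", "OverlappingAttention", "ChannelAttentionModule",
    "RHTA", "RHTB", "RHTStack",
]
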