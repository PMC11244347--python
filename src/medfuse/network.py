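"""The three-branch multi-scale fusion network.

Input is the channel concatenation of the functional luma and the
structural image (each normalized to [−1, 1]). A shared stem DCB
(MDConv1: k3, 2→3, GELU) lifts the pair into a 3-channel feature space;
three parallel branches of increasing depth (1/2/3 DCBs of type MDConv2:
k3, 3→3, GELU, each followed by a residual hybrid transformer stack)
extract features at different depths; the branch outputs are summed and a
1×1 dynamic convolution head (MDConv3: k1, 3→1) with a Tanh activation
emits the fused luma in [−1, 1].

"Multi-scale" here is depth-scale: all branches run at full spatial
resolution and are summed directly; there are no strided or resampling
layers in the architecture.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from . import colorspace
from .autodiff import Tensor
from .colorspace import ImagePair
from .dynamic_conv import DCB, MDConv2d, VanillaConvBlock
from .nn import Conv2d, Module, ModuleList
from .rht import RHTConfig, RHTStack


@dataclass
class FusionNetworkConfig:
    """Widths, depths, window geometry and ablation toggles of the network."""

    in_channels: int = 2
    mid_channels: int = 3
    out_channels: int = 1
    n_kernels: int = 4
    branch_dcb_counts: tuple[int, ...] = (1, 2, 3)
    window_size: int = 8
    overlap_ratio: float = 0.5
    num_heads: int = 1
    mlp_ratio: float = 2.0
    use_mdc: bool = True
    use_rht: bool = True
    multi_scale: bool = True
    single_branch_index: int = 0
    outer_residual: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.in_channels < 1 or self.mid_channels < 1 or self.out_channels < 1:
            raise ValueError("channel widths must be positive")
        if self.mid_channels % self.num_heads:
            raise ValueError(
                f"mid_channels {self.mid_channels} must be divisible by num_heads {self.num_heads}"
            )

    def rht_config(self) -> RHTConfig:
        return RHTConfig(
            embed_dim=self.mid_channels,
            window_size=self.window_size,
            num_heads=self.num_heads,
            overlap_ratio=self.overlap_ratio,
            mlp_ratio=self.mlp_ratio,
            outer_residual=self.outer_residual,
        )


class _Branch(Module):
    def __init__(self, cfg: FusionNetworkConfig, n_dcb: int, rng: np.random.Generator):
        super().__init__()
        mk_block = DCB if cfg.use_mdc else VanillaConvBlock
        kw = {"n_kernels": cfg.n_kernels} if cfg.use_mdc else {}
        self.dcbs = ModuleList(
            [mk_block(cfg.mid_channels, cfg.mid_channels, 3, rng, **kw) for _ in range(n_dcb)]
        )
        self.rht = RHTStack(cfg.rht_config(), rng) if cfg.use_rht else None

    def forward(self, x: Tensor) -> Tensor:
        for blk in self.dcbs:
            x = blk(x)
        if self.rht is not None:
            x = self.rht(x)
        return x


class FusionNetwork(Module):
    """Maps a (functional-luma, structural) pair to fused luma in [−1, 1]."""

    def __init__(self, cfg: FusionNetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        mk_block = DCB if cfg.use_mdc else VanillaConvBlock
        kw = {"n_kernels": cfg.n_kernels} if cfg.use_mdc else {}
        self.stem = mk_block(cfg.in_channels, cfg.mid_channels, 3, rng, **kw)
        counts = cfg.branch_dcb_counts if cfg.multi_scale else (
            cfg.branch_dcb_counts[cfg.single_branch_index],
        )
        self.branches = ModuleList([_Branch(cfg, n, rng) for n in counts])
        if cfg.use_mdc:
            self.head = MDConv2d(cfg.mid_channels, cfg.out_channels, 1, rng, n_kernels=cfg.n_kernels)
        else:
            self.head = Conv2d(cfg.mid_channels, cfg.out_channels, 1, rng)

    def forward(self, y_func: Tensor, structural: Tensor) -> Tensor:
        """Both inputs (B, 1, H, W) in [−1, 1] → fused luma (B, 1, H, W)."""
        y_func = ad.as_tensor(y_func)
        structural = ad.as_tensor(structural)
        if y_func.shape != structural.shape:
            raise ValueError(f"input shapes differ: {y_func.shape} vs {structural.shape}")
        x = ad.concat([y_func, structural], axis=1)
        x = self.stem(x)
        out = None
        for branch in self.branches:
            bx = branch(x)
            out = bx if out is None else out + bx
        return self.head(out).tanh()

    # --------------------------------------------------------------- reports
    def parameter_manifest(self) -> dict[str, int]:
        """Per-submodule parameter counts (construction audit trail)."""
        manifest = {"stem": self.stem.num_parameters()}
        for i, b in enumerate(self.branches):
            manifest[f"branch{i}"] = b.num_parameters()
        manifest["head"] = self.head.num_parameters()
        manifest["total"] = self.num_parameters()
        return manifest


def build_network(cfg: FusionNetworkConfig) -> FusionNetwork:
    """Deterministic construction: the same config (incl. seed) gives
    bit-identical initial parameters."""
    return FusionNetwork(cfg)


# ------------------------------------------------------------ normalization
def to_network_range(img01: np.ndarray) -> np.ndarray:
    """[0, 1] image → the network's [−1, 1] input range (dtype preserved)."""
    img01 = np.asarray(img01)
    if img01.dtype not in (np.float32, np.float64):
        img01 = img01.astype(np.float64)
    return img01 * 2.0 - 1.0


def from_network_range(out: np.ndarray) -> np.ndarray:
    """Tanh-head output in [−1, 1] → [0, 1] luma."""
    return (np.asarray(out, dtype=np.float64) + 1.0) / 2.0


def fuse_pair(pair: ImagePair, network: FusionNetwork) -> np.ndarray:
    """Fuse one registered pair; returns an H×W×3 RGB float array in [0, 1].

    Splits the functional image into luma + retained chroma, runs the
    network on (functional luma, structural), rescales the fused luma to
    the 0–255 scale and recomposes with the original chroma.
    """
    y, structural, (cb, cr) = colorspace.split_for_fusion(pair)
    network.eval()
    yb = to_network_range(y)[None, None]
    sb = to_network_range(structural)[None, None]
    fused = network(Tensor(yb), Tensor(sb)).data[0, 0]
    if not np.all(np.isfinite(fused)):
        raise FloatingPointError("network produced non-finite fused luma")
    fused_y255 = from_network_range(fused) * 255.0
    rgb255 = colorspace.recompose(fused_y255, (cb, cr))
    return rgb255 / 255.0


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(path, network: FusionNetwork, extra: dict | None = None) -> None:
    """Write weights + embedded config (NumPy archive with a JSON header)."""
    cfg = asdict(network.cfg)
    cfg["branch_dcb_counts"] = list(cfg["branch_dcb_counts"])
    header = {"config": cfg, "extra": extra or {}}
    state = {f"param/{k}": v for k, v in network.state_dict().items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[FusionNetwork, dict]:
    """Rebuild the network from an embedded config and load its weights."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    cfg_dict = header["config"]
    cfg_dict["branch_dcb_counts"] = tuple(cfg_dict["branch_dcb_counts"])
    net = FusionNetwork(FusionNetworkConfig(**cfg_dict))
    net.load_state_dict(state)
    return net, header.get("extra", {})


__all__ = [
    "FusionNetworkConfig", "FusionNetwork", "build_network", "fuse_pair",
    "to_network_range", "from_network_range", "save_checkpoint", "load_checkpoint",
]
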