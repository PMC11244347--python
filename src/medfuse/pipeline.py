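"""Unsupervised training loop and batch evaluation.

Training follows the protocol the network was designed for: Adam at a
fixed learning rate of 1e-4, batch size 16, 100 epochs over randomly
cropped patch pairs, minimizing perceptual + SSIM loss against both
sources. All of it is configurable (and the test suite runs a heavily
scaled-down version); every random stream is derived from one seed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import colorspace, metrics, network as network_mod
from .autodiff import Tensor
from .colorspace import ImagePair, load_image
from .losses import PerceptualExtractor, SSIMParams, ssim_loss, perceptual_loss
from .network import (FusionNetwork, FusionNetworkConfig, build_network,
                      fuse_pair, to_network_range)
from .nn import Adam
from .synthetic import random_crop_patches


@dataclass
class TrainingConfig:
    """Trainer defaults reproduce the reference protocol exactly."""

    lr: float = 1e-4
    batch_size: int = 16
    epochs: int = 100
    optimizer: str = "adam"
    patch_size: int = 64
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (perceptual, ssim)
    perceptual_backend: str = "random"
    perceptual_widths: tuple[int, int, int] = (8, 16, 32)
    grad_clip: float | None = None
    dtype: str = "float32"                # training precision
    max_steps: int | None = None          # cap for desk-scale runs
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def load_manifest(manifest_dir) -> tuple[list[ImagePair], list[ImagePair]]:
    """Read a synthesized dataset directory back into (train, test) pairs."""
    manifest_dir = Path(manifest_dir)
    manifest = json.loads((manifest_dir / "manifest.json").read_text())
    if not manifest["pairs"]:
        raise ValueError("empty manifest")
    train, test = [], []
    for row in manifest["pairs"]:
        pair = ImagePair(
            structural=load_image(manifest_dir / row["structural"]),
            functional=load_image(manifest_dir / row["functional"]),
            seed=row["seed"],
        )
        (test if row["split"] == "test" else train).append(pair)
    return train, test


def _pair_arrays(pairs: list[ImagePair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into (functional-luma, structural) arrays in [0, 1]."""
    ys, ss = [], []
    for p in pairs:
        y, s, _ = colorspace.split_for_fusion(p)
        ys.append(y)
        ss.append(s)
    return np.stack(ys)[:, None], np.stack(ss)[:, None]


def make_patches(pairs: list[ImagePair], patch: int, per_pair: int, seed: int) -> list[ImagePair]:
    """Random crops, ``per_pair`` from each pair, registration preserved."""
    out = []
    for i, p in enumerate(pairs):
        out.extend(random_crop_patches(p, patch, per_pair, seed=(seed * 9973 + i) % (2**31)))
    return out


def train(patches: list[ImagePair], net_cfg: FusionNetworkConfig,
          train_cfg: TrainingConfig,
          network: FusionNetwork | None = None) -> tuple[FusionNetwork, list[dict]]:
    """Minimize perceptual + SSIM loss over patch pairs.

    Returns the trained network and the per-step loss log (a list of dicts
    with step / total / perceptual / ssim). Raises on an empty patch list
    and aborts with a diagnostic if the loss goes non-finite.
    """
    if not patches:
        raise ValueError("no training patches given")
    net = network if network is not None else build_network(net_cfg)
    net.train()
    dtype = np.float32 if train_cfg.dtype == "float32" else np.float64
    net.astype(dtype)
    opt = Adam(net.parameters(), lr=train_cfg.lr)
    extractor = PerceptualExtractor(backend=train_cfg.perceptual_backend,
                                    seed=train_cfg.seed,
                                    widths=train_cfg.perceptual_widths).astype(dtype)
    ssim_params = SSIMParams()
    wp, ws = train_cfg.loss_weights
    ys, ss = _pair_arrays(patches)
    ys = ys.astype(dtype)
    ss = ss.astype(dtype)
    rng = np.random.default_rng(train_cfg.seed)
    log: list[dict] = []
    step = 0
    done = False
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(patches))
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            yb = Tensor(to_network_range(ys[idx]))
            sb = Tensor(to_network_range(ss[idx]))
            fused01 = (net(yb, sb) + 1.0) * 0.5
            y01 = Tensor(ys[idx])
            s01 = Tensor(ss[idx])
            lp = perceptual_loss(fused01, s01, y01, extractor)
            ls = ssim_loss(fused01, s01, y01, ssim_params)
            loss = wp * lp + ws * ls
            if not math.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at step {step} (perceptual={lp.item()}, ssim={ls.item()})"
                )
            opt.zero_grad()
            loss.backward()
            if train_cfg.grad_clip is not None:
                total_sq = sum(float((p.grad**2).sum()) for p in net.parameters() if p.grad is not None)
                norm = math.sqrt(total_sq)
                if norm > train_cfg.grad_clip:
                    scale = train_cfg.grad_clip / (norm + 1e-12)
                    for p in net.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            log.append({"step": step, "epoch": epoch, "total": loss.item(),
                        "perceptual": lp.item(), "ssim": ls.item()})
            step += 1
            if train_cfg.max_steps is not None and step >= train_cfg.max_steps:
                done = True
                break
        if done:
            break
    if train_cfg.log_path:
        write_loss_log(train_cfg.log_path, log)
    if train_cfg.checkpoint_path:
        network_mod.save_checkpoint(train_cfg.checkpoint_path, net,
                                    extra={"train_config": asdict(train_cfg)})
    return net, log


def write_loss_log(path, log: list[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "epoch", "total", "perceptual", "ssim"])
        writer.writeheader()
        writer.writerows(log)


def smoothed_loss(log: list[dict], window: int = 10, key: str = "total") -> tuple[float, float]:
    """(initial, final) moving-average loss over ``window`` steps."""
    vals = [row[key] for row in log]
    w = min(window, len(vals))
    return float(np.mean(vals[:w])), float(np.mean(vals[-w:]))


def mean_test_loss(net: FusionNetwork, pairs: list[ImagePair],
                   extractor: PerceptualExtractor,
                   weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Mean total loss of the network's fused output over a pair list."""
    net.eval()
    params = SSIMParams()
    wp, ws = weights
    total = 0.0
    for p in pairs:
        y, s, _ = colorspace.split_for_fusion(p)
        fused = net(Tensor(to_network_range(y)[None, None]),
                    Tensor(to_network_range(s)[None, None]))
        fused01 = (fused + 1.0) * 0.5
        lp = perceptual_loss(fused01, Tensor(s[None, None]), Tensor(y[None, None]), extractor)
        ls = ssim_loss(fused01, Tensor(s[None, None]), Tensor(y[None, None]))
        total += wp * lp.item() + ws * ls.item()
    return total / len(pairs)


def evaluate_run(net: FusionNetwork, test_pairs: list[ImagePair],
                 cfg: metrics.MetricConfig | None = None,
                 csv_path=None) -> tuple[list[metrics.MetricReport], dict[str, float]]:
    """Fuse every test pair and score it against both sources.

    Sources for the metrics are the structural plane and the functional
    luma. Returns per-pair reports and the column means; optionally writes
    a CSV with one row per pair plus a mean row.
    """
    if not test_pairs:
        raise ValueError("no test pairs given")
    cfg = cfg or metrics.MetricConfig()
    reports = []
    for pair in test_pairs:
        fused_rgb = fuse_pair(pair, net)
        fused_y = colorspace.rgb_to_ycbcr(fused_rgb * 255.0).y / 255.0
        y, s, _ = colorspace.split_for_fusion(pair)
        reports.append(metrics.evaluate_all(fused_y, s, y, cfg))
    means = {k: float(np.mean([r.values()[k] for r in reports]))
             for k in metrics.MetricReport.METRIC_FIELDS}
    if csv_path is not None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["pair", *metrics.MetricReport.METRIC_FIELDS])
            writer.writeheader()
            for i, r in enumerate(reports):
                writer.writerow({"pair": i, **{k: f"{v:.6f}" for k, v in r.values().items()}})
            writer.writerow({"pair": "mean", **{k: f"{v:.6f}" for k, v in means.items()}})
    return reports, means


__all__ = [
    "TrainingConfig", "train", "load_manifest", "make_patches", "write_loss_log",
    "smoothed_loss", "mean_test_loss", "evaluate_run",
]
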