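"""Unsupervised training objective: perceptual + structural-similarity loss.

    L_all = L_PERCE + L_SSIM

* L_SSIM = (1 − SSIM(F, MRI)) + (1 − SSIM(F, PET_Y)) with the standard
  single-scale SSIM (11×11 Gaussian window, σ=1.5, C1=(0.01·L)²,
  C2=(0.03·L)²).
* L_PERCE = ‖ϕ(F)−ϕ(MRI)‖² + ‖ϕ(F)−ϕ(PET_Y)‖², squared Euclidean distance
  in the feature space of a fixed convolutional extractor ϕ, mean-reduced
  over feature elements so the two loss terms live on comparable scales.

The extractor ϕ is a frozen VGG-style conv/conv/pool stack. The intended
backend is a 16-layer pretrained network read from a weights file; the
default backend is a seeded-random stack of the same topology, which keeps
the objective well-defined, deterministic and dependency-free (a random
deep feature distance is still a meaningful perceptual discrepancy, and
the loss is exactly zero iff the images agree).

Everything here is differentiable through :mod:`medfuse.autodiff`; the
same SSIM kernel backs the evaluation metrics (single- and multi-scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module, ModuleList, relu


# ------------------------------------------------------------------- SSIM
def gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    """Normalized 2-D Gaussian weighting window (weights sum to 1)."""
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


@dataclass
class SSIMParams:
    """Stabilizers and window of the SSIM index.

    ``data_range`` is the dynamic range L of the luma values (1.0 for
    images in [0, 1]); C1=(0.01·L)² and C2=(0.03·L)².
    """

    data_range: float = 1.0
    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2

    def window(self) -> np.ndarray:
        return gaussian_window(self.window_size, self.sigma)


def _as_batched(x) -> Tensor:
    x = ad.as_tensor(x)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, *x.shape[1:])
    return x


def ssim_components(a, b, params: SSIMParams | None = None) -> tuple[Tensor, Tensor]:
    """Mean SSIM and mean contrast-structure term over valid windows.

    The luminance·contrast-structure factorization is what multi-scale
    SSIM combines across scales; single-scale SSIM is the first element.
    """
    params = params or SSIMParams()
    a = _as_batched(a)
    b = _as_batched(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[-1] < params.window_size or a.shape[-2] < params.window_size:
        raise ValueError(
            f"image {a.shape[-2:]} smaller than SSIM window {params.window_size}"
        )
    w = Tensor(params.window()[None, None].astype(a.data.dtype))
    c1, c2 = params.c1, params.c2
    mu_a = ad.conv2d(a, w)
    mu_b = ad.conv2d(b, w)
    var_a = ad.conv2d(a * a, w) - mu_a * mu_a
    var_b = ad.conv2d(b * b, w) - mu_b * mu_b
    cov = ad.conv2d(a * b, w) - mu_a * mu_b
    lum = (2.0 * mu_a * mu_b + c1) / (mu_a * mu_a + mu_b * mu_b + c1)
    cs = (2.0 * cov + c2) / (var_a + var_b + c2)
    return (lum * cs).mean(), cs.mean()


def ssim(a, b, params: SSIMParams | None = None) -> Tensor:
    """Mean single-scale SSIM between two equally shaped images."""
    return ssim_components(a, b, params)[0]


def ssim_loss(fused, structural, functional_y, params: SSIMParams | None = None) -> Tensor:
    """(1 − SSIM(F, MRI)) + (1 − SSIM(F, PET_Y)); bounded in [0, 4]."""
    params = params or SSIMParams()
    return (1.0 - ssim(fused, structural, params)) + (1.0 - ssim(fused, functional_y, params))


# -------------------------------------------------------------- perceptual
#: ImageNet channel statistics used by pretrained VGG-style backends.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


class PerceptualExtractor(Module):
    """Frozen multi-layer conv feature map ϕ for the perceptual loss.

    Topology follows the first three stages of a 16-layer VGG-style net
    (conv-conv-pool, conv-conv-pool, conv-conv-conv), with features taken
    after the third stage ("relu3_3"-style). Backends:

    * ``"random"`` (default) — seeded-random frozen weights at reduced
      widths (default 8/16/32 channels), fully offline and deterministic.
    * ``"vgg16"`` — load pretrained conv weights from an ``.npz`` file
      whose keys are ``conv{i}/weight`` and ``conv{i}/bias`` for the first
      seven conv layers (full widths 64/128/256). Raises a clear error if
      no weights file is given.

    Single-channel images are replicated to three channels and normalized
    with the ImageNet mean/std before ϕ.
    """

    def __init__(self, backend: str = "random", seed: int = 0,
                 widths: tuple[int, int, int] = (8, 16, 32),
                 weights_path=None):
        super().__init__()
        self.backend = backend
        self.seed = seed
        rng = np.random.default_rng(seed)
        if backend == "vgg16":
            if weights_path is None:
                raise ValueError(
                    "the 'vgg16' backend needs a pretrained-weights .npz file; "
                    "pass weights_path=... or select the seeded-random backend "
                    "(backend='random')"
                )
            widths = (64, 128, 256)
        w1, w2, w3 = widths
        plan = [(3, w1), (w1, w1), (w1, w2), (w2, w2), (w2, w3), (w3, w3), (w3, w3)]
        self.convs = ModuleList([Conv2d(cin, cout, 3, rng) for cin, cout in plan])
        #: stage boundaries after which a 2×2 average pool is applied
        self._pool_after = {1, 3}
        if backend == "vgg16":
            data = np.load(weights_path)
            state = {}
            for i in range(len(plan)):
                state[f"convs.{i}.weight"] = data[f"conv{i}/weight"]
                state[f"convs.{i}.bias"] = data[f"conv{i}/bias"]
            self.load_state_dict(state)
        elif backend != "random":
            raise ValueError(f"unknown perceptual backend {backend!r}")
        for p in self.parameters():
            p.requires_grad = False

    @staticmethod
    def _pool2(x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def features(self, x) -> Tensor:
        """ϕ(x) for a single-channel image batch (B, 1, H, W) in [0, 1]."""
        x = _as_batched(x)
        x3 = ad.concat([x, x, x], axis=1)
        mean = Tensor(IMAGENET_MEAN.reshape(1, 3, 1, 1).astype(x.data.dtype))
        std = Tensor(IMAGENET_STD.reshape(1, 3, 1, 1).astype(x.data.dtype))
        y = (x3 - mean) / std
        for i, conv in enumerate(self.convs):
            y = relu(conv(y))
            if i in self._pool_after:
                y = self._pool2(y)
        return y


def perceptual_loss(fused, structural, functional_y, extractor: PerceptualExtractor) -> Tensor:
    """Mean squared feature distance of F to each source, summed."""
    f = extractor.features(fused)
    s = extractor.features(structural)
    p = extractor.features(functional_y)
    ds = f - s
    dp = f - p
    return (ds * ds).mean() + (dp * dp).mean()


@dataclass
class LossReport:
    total: float
    perceptual: float
    ssim: float


def total_loss(fused, structural, functional_y,
               params: SSIMParams | None = None,
               extractor: PerceptualExtractor | None = None,
               weights: tuple[float, float] = (1.0, 1.0)) -> tuple[Tensor, LossReport]:
    """L_all = w_p·L_PERCE + w_s·L_SSIM (unit weights by default).

    Returns the differentiable total plus a per-term numeric report.
    """
    extractor = extractor or PerceptualExtractor()
    lp = perceptual_loss(fused, structural, functional_y, extractor)
    ls = ssim_loss(fused, structural, functional_y, params)
    wp, ws = weights
    tot = wp * lp + ws * ls
    return tot, LossReport(total=tot.item(), perceptual=lp.item(), ssim=ls.item())


__all__ = [
    "SSIMParams", "gaussian_window", "ssim", "ssim_components", "ssim_loss",
    "PerceptualExtractor", "perceptual_loss", "total_loss", "LossReport",
    "IMAGENET_MEAN", "IMAGENET_STD",
]
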