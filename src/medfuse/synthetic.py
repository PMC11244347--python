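"""Seeded generator of registered structural/functional image pairs.

Emulates the statistics of registered MRI + SPECT/PET (or phase-contrast +
GFP fluorescence) pairs so the trainer, fuser and metrics are exercisable
without any external data:

* the structural plane is a union of anti-aliased geometric shapes
  (soft-edged ellipses) overlaid with band-passed noise texture — a
  high-spatial-frequency grayscale channel;
* the functional plane is a smooth field of Gaussian intensity blobs whose
  centers lie (with a configurable overlap fraction) inside the structural
  shapes, mapped through a smooth colormap: hot-metal hues for the
  SPECT/PET-like mode, green fluorescence over dark background for the
  GFP mode.

Both planes share the H×W grid, are registered by construction and are
fully reproducible from (seed, params).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .colorspace import ImagePair, save_image

__all__ = ["PairParams", "generate_pair", "identity_pair", "generate_dataset",
           "random_crop_patches", "ImagePair"]


@dataclass
class PairParams:
    """Knobs of the pair generator (defaults emulate SPECT/PET + MRI)."""

    n_shapes: int = 5
    n_blobs: int = 4
    blob_sigma_frac: float = 0.08      # blob width as a fraction of min(H, W)
    texture_strength: float = 0.25     # band-passed noise amplitude on [0,1]
    texture_low_sigma: float = 1.0     # band-pass: difference of Gaussians
    texture_high_sigma: float = 4.0
    edge_softness: float = 1.0         # anti-aliasing width in pixels
    overlap_fraction: float = 1.0      # fraction of blob centers inside shapes
    mode: str = "spect"                # "spect" | "gfp"


def _hot_colormap(t: np.ndarray) -> np.ndarray:
    """Hot-metal colormap: black → red → yellow → white on [0, 1]."""
    r = np.clip(3.0 * t, 0, 1)
    g = np.clip(3.0 * t - 1.0, 0, 1)
    b = np.clip(3.0 * t - 2.0, 0, 1)
    return np.stack([r, g, b], axis=-1)


def _gfp_colormap(t: np.ndarray) -> np.ndarray:
    """Fluorescence-like: dark background, bright green signal."""
    return np.stack([0.1 * t, t, 0.12 * t], axis=-1)


def _normalize01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _draw_shapes(h: int, w: int, rng: np.random.Generator, params: PairParams) -> np.ndarray:
    """Soft union of random ellipses in [0, 1]."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    field = np.zeros((h, w))
    for _ in range(params.n_shapes):
        cy, cx = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
        ry = rng.uniform(0.08, 0.25) * h
        rx = rng.uniform(0.08, 0.25) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        d = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
        # signed distance in pixels (approximate), softened for anti-aliasing
        edge = (1.0 - d) * min(rx, ry)
        level = rng.uniform(0.4, 1.0)
        field = np.maximum(field, level / (1.0 + np.exp(-edge / params.edge_softness)))
    return field


def generate_pair(h: int, w: int, seed: int, params: PairParams | None = None) -> ImagePair:
    """Generate one registered pair; bit-identical for identical arguments."""
    if h < 32 or w < 32:
        raise ValueError(f"image size must be at least 32×32, got {h}×{w}")
    params = params or PairParams()
    rng = np.random.default_rng(seed)

    shapes = _draw_shapes(h, w, rng, params)
    noise = rng.standard_normal((h, w))
    band = (ndimage.gaussian_filter(noise, params.texture_low_sigma)
            - ndimage.gaussian_filter(noise, params.texture_high_sigma))
    band = band / (np.abs(band).max() + 1e-12)
    mask = shapes > 0.3
    structural = np.clip(shapes + params.texture_strength * band * mask, 0.0, 1.0)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sigma = params.blob_sigma_frac * min(h, w)
    intensity = np.zeros((h, w))
    inside = np.argwhere(mask)
    centers = []
    for i in range(params.n_blobs):
        use_inside = (i < round(params.overlap_fraction * params.n_blobs)) and len(inside) > 0
        if use_inside:
            cy, cx = inside[rng.integers(len(inside))]
        else:
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        centers.append((float(cy), float(cx)))
        amp = rng.uniform(0.5, 1.0)
        s = sigma * rng.uniform(0.7, 1.3)
        intensity += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s)))
    intensity = _normalize01(intensity)
    cmap = _gfp_colormap if params.mode == "gfp" else _hot_colormap
    functional = np.clip(cmap(intensity), 0.0, 1.0)

    return ImagePair(
        structural=structural,
        functional=functional,
        seed=seed,
        metadata={
            "blob_count": params.n_blobs,
            "shape_count": params.n_shapes,
            "texture_strength": params.texture_strength,
            "overlap_fraction": params.overlap_fraction,
            "mode": params.mode,
            "blob_centers": centers,
        },
    )


def identity_pair(h: int, w: int, seed: int, params: PairParams | None = None) -> ImagePair:
    """A known-optimum fixture: the functional image is the gray replica of
    the structural one, so its luma equals the structural plane and the
    identity fusion F = input attains total loss 0."""
    base = generate_pair(h, w, seed, params)
    gray = np.repeat(base.structural[:, :, None], 3, axis=2)
    return ImagePair(structural=base.structural, functional=gray, seed=seed,
                     metadata={**base.metadata, "identity_fixture": True})


def generate_dataset(n_pairs: int, size: int = 128, seed: int = 0,
                     test_fraction: float = 40.0 / 350.0,
                     params: PairParams | None = None,
                     out_dir=None) -> tuple[list[ImagePair], dict]:
    """Generate ``n_pairs`` independent pairs with a recorded train/test split.

    Pair seeds are derived deterministically from ``seed`` and are disjoint
    between train and test. If ``out_dir`` is given, PNG pairs and a JSON
    manifest are written there.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    params = params or PairParams()
    n_test = int(round(test_fraction * n_pairs))
    n_test = min(max(n_test, 0), n_pairs)
    pairs = []
    rows = []
    for i in range(n_pairs):
        pair_seed = (seed * 100003 + i) % (2**31)
        split = "test" if i >= n_pairs - n_test else "train"
        pair = generate_pair(size, size, pair_seed, params)
        pairs.append(pair)
        rows.append({"index": i, "seed": pair_seed, "split": split,
                     "structural": f"pair{i:04d}_structural.png",
                     "functional": f"pair{i:04d}_functional.png"})
    manifest = {"n_pairs": n_pairs, "size": size, "seed": seed,
                "params": asdict(params), "pairs": rows}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pair, row in zip(pairs, rows):
            save_image(out_dir / row["structural"], pair.structural)
            save_image(out_dir / row["functional"], pair.functional)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return pairs, manifest


def random_crop_patches(pair: ImagePair, patch: int, count: int, seed: int) -> list[ImagePair]:
    """``count`` random patch pairs with identical crop windows in both
    modalities (registration preserved)."""
    h, w = pair.shape
    if patch > min(h, w):
        raise ValueError(f"patch {patch} larger than image {h}×{w}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        top = int(rng.integers(0, h - patch + 1))
        left = int(rng.integers(0, w - patch + 1))
        out.append(ImagePair(
            structural=pair.structural[top:top + patch, left:left + patch].copy(),
            functional=pair.functional[top:top + patch, left:left + patch].copy(),
            seed=pair.seed,
            metadata={**pair.metadata, "crop": (top, left, patch)},
        ))
    return out
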