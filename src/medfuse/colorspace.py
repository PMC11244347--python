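"""Luma/chroma separation for color-preserving fusion.

A functional image (SPECT/PET-like RGB) is converted to YCbCr; fusion runs
on the luminance plane Y together with the structural (MRI-like) grayscale
image, while the chrominance planes Cb/Cr are retained untouched and
recombined afterwards, so the functional color information survives fusion.

The forward transform is the full-range (JPEG-style) YCbCr affine map

    [Y ]   [ 0.299  0.587  0.114] [R]   [  0]
    [Cb] = [-0.169 -0.331  0.500] [G] + [128]
    [Cr]   [ 0.500 -0.419 -0.081] [B]   [128]

on the 0–255 scale. The default inverse is the exact matrix inverse of the
forward map (so the float round trip is the identity to machine precision);
the widely quoted rounded inverse coefficients (1.400 / −0.343 / −0.711 /
1.765) are available via ``matrix="printed"``.

All core math is float64; clipping and 8-bit quantization happen only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RGB_TO_YCBCR_MATRIX",
    "YCBCR_OFFSET",
    "YCBCR_TO_RGB_MATRIX_EXACT",
    "YCBCR_TO_RGB_MATRIX_PRINTED",
    "YCbCrDecomposition",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "split_for_fusion",
    "recompose",
    "load_image",
    "save_image",
]

RGB_TO_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.169, -0.331, 0.500],
        [0.500, -0.419, -0.081],
    ]
)
YCBCR_OFFSET = np.array([0.0, 128.0, 128.0])

#: Exact inverse of the forward matrix — float round trip is the identity.
YCBCR_TO_RGB_MATRIX_EXACT = np.linalg.inv(RGB_TO_YCBCR_MATRIX)

#: The rounded inverse coefficients commonly quoted alongside the forward map.
YCBCR_TO_RGB_MATRIX_PRINTED = np.array(
    [
        [1.000, 0.000, 1.400],
        [1.000, -0.343, -0.711],
        [1.000, 1.765, 0.000],
    ]
)

NEUTRAL_CHROMA = 128.0


@dataclass
class YCbCrDecomposition:
    """Y/Cb/Cr planes on the 0–255 scale, all of identical shape."""

    y: np.ndarray
    cb: np.ndarray
    cr: np.ndarray

    def __post_init__(self):
        if not (self.y.shape == self.cb.shape == self.cr.shape):
            raise ValueError(
                f"plane shapes differ: y={self.y.shape} cb={self.cb.shape} cr={self.cr.shape}"
            )


def rgb_to_ycbcr(rgb: np.ndarray) -> YCbCrDecomposition:
    """Convert an H×W×3 RGB image on the 0–255 scale to YCbCr planes.

    Pure affine map in float64; no clipping (Cr of saturated red is 255.5).
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected H×W×3 RGB array, got shape {rgb.shape}")
    if not np.all(np.isfinite(rgb)):
        raise ValueError("RGB input contains non-finite values")
    ycc = rgb @ RGB_TO_YCBCR_MATRIX.T + YCBCR_OFFSET
    return YCbCrDecomposition(y=ycc[..., 0], cb=ycc[..., 1], cr=ycc[..., 2])


def ycbcr_to_rgb(dec: YCbCrDecomposition, matrix: str = "exact", clip: bool = False) -> np.ndarray:
    """Invert the YCbCr map back to H×W×3 RGB on the 0–255 scale.

    ``matrix="exact"`` (default) uses the exact inverse of the forward
    matrix; ``"printed"`` uses the rounded textbook coefficients. ``clip``
    bounds the result to [0, 255] (display/file boundary only).
    """
    if matrix == "exact":
        m = YCBCR_TO_RGB_MATRIX_EXACT
    elif matrix == "printed":
        m = YCBCR_TO_RGB_MATRIX_PRINTED
    else:
        raise ValueError(f"matrix must be 'exact' or 'printed', got {matrix!r}")
    ycc = np.stack([dec.y, dec.cb - 128.0, dec.cr - 128.0], axis=-1)
    rgb = ycc @ m.T
    if clip:
        rgb = np.clip(rgb, 0.0, 255.0)
    return rgb


@dataclass
class ImagePair:
    """A registered structural/functional pair with values in [0, 1].

    ``structural`` is H×W grayscale (MRI-like, high spatial frequency);
    ``functional`` is H×W×3 RGB (SPECT/PET-like) or H×W grayscale.
    """

    structural: np.ndarray
    functional: np.ndarray
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.structural.ndim != 2:
            raise ValueError(f"structural image must be H×W, got shape {self.structural.shape}")
        if self.functional.ndim not in (2, 3):
            raise ValueError(f"functional image must be H×W or H×W×3, got shape {self.functional.shape}")
        if self.functional.shape[:2] != self.structural.shape:
            raise ValueError(
                "pair is not registered: structural "
                f"{self.structural.shape} vs functional {self.functional.shape[:2]}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.structural.shape


def split_for_fusion(pair: ImagePair) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Separate a registered pair into (functional luma, structural, chroma).

    Returns ``(y_func, structural, (cb, cr))`` where both image planes are
    in [0, 1] ready for network normalization and the chroma planes stay on
    the native 0–255 scale. Grayscale functional inputs pass through as Y
    with neutral chroma (128).
    """
    structural = np.asarray(pair.structural, dtype=np.float64)
    functional = np.asarray(pair.functional, dtype=np.float64)
    if functional.ndim == 2:
        y = functional
        cb = np.full_like(y, NEUTRAL_CHROMA)
        cr = np.full_like(y, NEUTRAL_CHROMA)
    else:
        dec = rgb_to_ycbcr(functional * 255.0)
        y = dec.y / 255.0
        cb, cr = dec.cb, dec.cr
    return y, structural, (cb, cr)


def recompose(fused_y: np.ndarray, chroma: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Recombine a fused luma plane (0–255 scale) with retained chroma.

    Returns an H×W×3 RGB array clipped to [0, 255].
    """
    cb, cr = chroma
    fused_y = np.asarray(fused_y, dtype=np.float64)
    if fused_y.shape != np.asarray(cb).shape or fused_y.shape != np.asarray(cr).shape:
        raise ValueError(
            f"shape mismatch: fused_y {fused_y.shape}, cb {np.asarray(cb).shape}, cr {np.asarray(cr).shape}"
        )
    dec = YCbCrDecomposition(y=fused_y, cb=np.asarray(cb, dtype=np.float64), cr=np.asarray(cr, dtype=np.float64))
    return ycbcr_to_rgb(dec, clip=True)


# ------------------------------------------------------------------ file I/O
def load_image(path) -> np.ndarray:
    """Read an 8- or 16-bit PNG/TIFF into a float array in [0, 1].

    Grayscale files come back H×W; color files H×W×3 (alpha dropped).
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        return np.asarray(arr, dtype=np.float64)
    return arr.astype(np.float64) / scale


def save_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit PNG/TIFF (clipping here only).

    16-bit color images need a TIFF target (PNG writers only take 16-bit
    grayscale).
    """
    image = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 8:
        out = np.round(image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(image * 65535.0).astype(np.uint16)
        if out.ndim == 3 and str(path).lower().endswith(".png"):
            raise ValueError("16-bit color output requires a .tif/.tiff path")
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, out)
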