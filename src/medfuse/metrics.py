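"""Fusion-quality indicators.

Nine reference-based / no-reference indicators of fused-image quality,
each a deterministic function of (fused F, source A, source B) or of F
alone, on images with values in [0, 1]:

* MI — normalized mutual information of F with each source, summed:
  Σ_S 2·I(F;S)/(H(F)+H(S)), 256-bin histograms. Identical triple → 2.
* NCIE — nonlinear correlation information entropy from the eigenvalues
  of the 3×3 nonlinear correlation matrix of (F, A, B).
* SCD — sum of the correlations of differences, r(F−B, A) + r(F−A, B).
* MS-SSIM — multi-scale structural similarity (standard 5-scale exponent
  weights), averaged over both sources; shares the SSIM kernel with the
  training loss.
* EN — Shannon entropy of the 256-bin histogram of F (bits).
* VIF — pixel-domain visual information fidelity of F against each
  source, averaged.
* QTE — Tsallis-entropy mutual measure of order q (default 1.85), summed
  over both sources; converges to Shannon MI (nats) as q→1.
* QAB/F — Xydeas–Petrović edge-preservation measure (Sobel strength and
  orientation, sigmoid preservation model, source-strength weighting).
* QG — the same preservation model driven by first-order derivative
  gradients, emphasizing gradient-information retention.

For QAB/F and QG the per-pixel preservation sigmoids are normalized by
their value at perfect preservation, so a fused image identical to both
sources scores exactly 1 (the ideal value both metrics are defined
against). Histogram-based measures quantize to 256 gray levels first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .losses import SSIMParams, ssim_components

#: Standard 5-scale MS-SSIM exponent weights.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

#: Preservation-sigmoid constants (edge strength / orientation).
QABF_CONSTANTS = {"gamma_g": 0.9994, "kappa_g": -15.0, "sigma_g": 0.5,
                  "gamma_a": 0.9879, "kappa_a": -22.0, "sigma_a": 0.8}


@dataclass
class MetricConfig:
    bins: int = 256
    tsallis_q: float = 1.85
    ssim: SSIMParams = field(default_factory=SSIMParams)
    ms_ssim_scales: int = 5
    vif_scales: int = 4
    vif_sigma_nsq: float = 2.0
    qabf: dict = field(default_factory=lambda: dict(QABF_CONSTANTS))


@dataclass
class MetricReport:
    """The nine indicator values for one (fused, A, B) triple."""

    mi: float
    ncie: float
    scd: float
    ms_ssim: float
    en: float
    vif: float
    qte: float
    qabf: float
    qg: float
    config: dict = field(default_factory=dict)

    METRIC_FIELDS = ("mi", "ncie", "scd", "ms_ssim", "en", "vif", "qte", "qabf", "qg")

    def values(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.METRIC_FIELDS}


# ----------------------------------------------------------------- histogram
def _quantize(img: np.ndarray, bins: int = 256) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    return np.clip(np.round(img * (bins - 1)), 0, bins - 1).astype(np.intp)


def _hist(img_q: np.ndarray, bins: int) -> np.ndarray:
    h = np.bincount(img_q.ravel(), minlength=bins).astype(np.float64)
    return h / h.sum()


def _hist2(a_q: np.ndarray, b_q: np.ndarray, bins: int) -> np.ndarray:
    h = np.bincount(a_q.ravel() * bins + b_q.ravel(), minlength=bins * bins).astype(np.float64)
    return (h / h.sum()).reshape(bins, bins)


def _entropy(p: np.ndarray, base: float = 2.0) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def en(fused: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the 256-level histogram; in [0, 8]."""
    return _entropy(_hist(_quantize(fused, bins), bins))


def shannon_mi(a: np.ndarray, b: np.ndarray, bins: int = 256, base: float = 2.0) -> float:
    """I(A;B) from the joint 256-bin histogram."""
    aq, bq = _quantize(a, bins), _quantize(b, bins)
    pj = _hist2(aq, bq, bins)
    return _entropy(_hist(aq, bins), base) + _entropy(_hist(bq, bins), base) - _entropy(pj.ravel(), base)


def mi(fused: np.ndarray, a: np.ndarray, b: np.ndarray, bins: int = 256) -> float:
    """Normalized MI summed over both sources: Σ_S 2·I(F;S)/(H(F)+H(S))."""
    total = 0.0
    hf = en(fused, bins)
    for src in (a, b):
        hs = en(src, bins)
        if hf + hs == 0.0:
            warnings.warn("degenerate (zero-entropy) image in MI; contributes 0")
            continue
        total += 2.0 * shannon_mi(fused, src, bins) / (hf + hs)
    return total


# --------------------------------------------------------------- correlation
def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel() - x.mean()
    y = y.ravel() - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def scd(fused: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Sum of correlations of differences: r(F−B, A) + r(F−A, B) ∈ [−2, 2]."""
    fused = np.asarray(fused, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return _pearson(fused - b, a) + _pearson(fused - a, b)


# ------------------------------------------------------------------ MS-SSIM
def _downsample2(img: np.ndarray) -> np.ndarray:
    H, W = img.shape
    img = img[: H - H % 2, : W - W % 2]
    return img.reshape(H // 2, 2, W // 2, 2).mean(axis=(1, 3))


def _ms_ssim_single(f: np.ndarray, s: np.ndarray, params: SSIMParams, scales: int) -> float:
    weights = np.asarray(MS_SSIM_WEIGHTS[:scales])
    if scales < len(MS_SSIM_WEIGHTS):
        weights = weights / weights.sum()
    vals = []
    for j in range(scales):
        ssim_m, cs_m = ssim_components(f, s, params)
        vals.append(ssim_m.item() if j == scales - 1 else cs_m.item())
        if j < scales - 1:
            f, s = _downsample2(f), _downsample2(s)
    # negative contrast-structure terms are floored at 0 (anti-correlated
    # structure carries no similarity credit); keeps the exponent real
    vals = np.maximum(np.asarray(vals), 0.0)
    return float(np.prod(vals**weights))


def ms_ssim_metric(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
                   params: SSIMParams | None = None, scales: int = 5) -> float:
    """Mean over sources of multi-scale SSIM; ideal value 1.

    If the image is too small for the requested number of dyadic scales the
    scale count is reduced (with a warning); at one scale this equals plain
    SSIM averaged over the two sources.
    """
    params = params or SSIMParams()
    fused = np.asarray(fused, dtype=np.float64)
    min_side = min(fused.shape)
    max_scales = 1
    while max_scales < scales and (min_side >> max_scales) >= params.window_size:
        max_scales += 1
    if max_scales < scales:
        warnings.warn(f"image too small for {scales} scales; using {max_scales}")
        scales = max_scales
    return 0.5 * (_ms_ssim_single(fused, np.asarray(a, dtype=np.float64), params, scales)
                  + _ms_ssim_single(fused, np.asarray(b, dtype=np.float64), params, scales))


# ----------------------------------------------------- edge/gradient metrics
def _preservation_sigmoid(x: np.ndarray, kappa: float, sigma: float) -> np.ndarray:
    """Sigmoid preservation term normalized so perfect preservation (x=1)
    scores exactly 1 (the metric's stated ideal value)."""
    return (1.0 + np.exp(kappa * (1.0 - sigma))) / (1.0 + np.exp(kappa * (x - sigma)))


def _edge_strength_orientation(img: np.ndarray, operator: str) -> tuple[np.ndarray, np.ndarray]:
    if operator == "sobel":
        sx = ndimage.sobel(img, axis=1)
        sy = ndimage.sobel(img, axis=0)
    elif operator == "gradient":
        sy, sx = np.gradient(img)
    else:
        raise ValueError(operator)
    g = np.hypot(sx, sy)
    alpha = np.arctan2(sy, sx + (sx == 0) * (g == 0))  # 0 where both are 0
    return g, alpha


def _edge_preservation(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
                       operator: str, constants: dict) -> float:
    fused = np.asarray(fused, dtype=np.float64)
    gF, aF = _edge_strength_orientation(fused, operator)
    num = 0.0
    den = 0.0
    for src in (a, b):
        src = np.asarray(src, dtype=np.float64)
        gS, aS = _edge_strength_orientation(src, operator)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(gS > gF, np.divide(gF, gS, out=np.zeros_like(gF), where=gS != 0),
                             np.divide(gS, gF, out=np.zeros_like(gS), where=gF != 0))
        ratio = np.where((gS == 0) & (gF == 0), 0.0, ratio)
        ratio = np.where(np.isclose(gS, gF) & (gS > 0), 1.0, ratio)
        dalpha = np.abs(aS - aF)
        dalpha = np.minimum(dalpha, np.pi - dalpha)  # orientation is axial
        ang = 1.0 - dalpha / (np.pi / 2.0)
        q_g = _preservation_sigmoid(ratio, constants["kappa_g"], constants["sigma_g"])
        q_a = _preservation_sigmoid(ang, constants["kappa_a"], constants["sigma_a"])
        q = np.clip(q_g * q_a, 0.0, 1.0)
        w = gS
        num += float((q * w).sum())
        den += float(w.sum())
    if den == 0.0:
        warnings.warn("no edges in either source; edge-preservation metric is 0")
        return 0.0
    return num / den


def qabf(fused: np.ndarray, a: np.ndarray, b: np.ndarray, constants: dict | None = None) -> float:
    """Edge-based similarity measure (Sobel edges); in [0, 1], ideal 1."""
    return _edge_preservation(fused, a, b, "sobel", constants or QABF_CONSTANTS)


def qg(fused: np.ndarray, a: np.ndarray, b: np.ndarray, constants: dict | None = None) -> float:
    """Gradient-based measure (first-order derivatives); in [0, 1], ideal 1."""
    return _edge_preservation(fused, a, b, "gradient", constants or QABF_CONSTANTS)


# ----------------------------------------------------------------- NCIE/VIF
def _ncc(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    """Nonlinear correlation coefficient: H_b(A)+H_b(B)−H_b(A,B), log base
    = bin count, clipped to [0, 1]."""
    aq, bq = _quantize(a, bins), _quantize(b, bins)
    h = (_entropy(_hist(aq, bins), bins) + _entropy(_hist(bq, bins), bins)
         - _entropy(_hist2(aq, bq, bins).ravel(), bins))
    return float(np.clip(h, 0.0, 1.0))


def ncie(fused: np.ndarray, a: np.ndarray, b: np.ndarray, bins: int = 256,
         eig_floor: float = 1e-12) -> float:
    """Nonlinear correlation information entropy of (F, A, B) ∈ [0, 1].

    Eigenvalues λ of the 3×3 nonlinear correlation matrix give
    NCIE = 1 + Σ (λ/3)·log_b(λ/3) with b = bin count; the floor (mutually
    independent images, R = I) is 1 − log_b 3.
    """
    r_fa = _ncc(fused, a, bins)
    r_fb = _ncc(fused, b, bins)
    r_ab = _ncc(a, b, bins)
    R = np.array([[1.0, r_fa, r_fb], [r_fa, 1.0, r_ab], [r_fb, r_ab, 1.0]])
    lam = np.clip(np.linalg.eigvalsh(R), eig_floor, None)
    frac = lam / 3.0
    return float(1.0 + (frac * np.log(frac) / np.log(bins)).sum())


def vif(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
        scales: int = 4, sigma_nsq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity, averaged over sources.

    Each source acts as the reference and the fused image as the test
    signal; identical images give exactly 1 per source. Computed on the
    0–255 scale as in the original formulation.
    """
    return 0.5 * (_vif_single(a, fused, scales, sigma_nsq) + _vif_single(b, fused, scales, sigma_nsq))


def _vif_single(ref: np.ndarray, dist: np.ndarray, scales: int, sigma_nsq: float) -> float:
    ref = np.asarray(ref, dtype=np.float64) * 255.0
    dist = np.asarray(dist, dtype=np.float64) * 255.0
    num = 0.0
    den = 0.0
    for scale in range(1, scales + 1):
        N = 2 ** (scales - scale + 1) + 1
        sd = N / 5.0
        if scale > 1:
            ref = ndimage.gaussian_filter(ref, sd)[::2, ::2]
            dist = ndimage.gaussian_filter(dist, sd)[::2, ::2]
        mu1 = ndimage.gaussian_filter(ref, sd)
        mu2 = ndimage.gaussian_filter(dist, sd)
        s1 = ndimage.gaussian_filter(ref * ref, sd) - mu1 * mu1
        s2 = ndimage.gaussian_filter(dist * dist, sd) - mu2 * mu2
        s12 = ndimage.gaussian_filter(ref * dist, sd) - mu1 * mu2
        s1 = np.maximum(s1, 0.0)
        s2 = np.maximum(s2, 0.0)
        g = s12 / (s1 + 1e-10)
        sv = s2 - g * s12
        g = np.where(s1 < 1e-10, 0.0, g)
        sv = np.where(s1 < 1e-10, s2, sv)
        sv = np.where(g < 0, s2, sv)
        g = np.maximum(g, 0.0)
        sv = np.maximum(sv, 1e-10)
        num += float(np.log10(1.0 + g * g * s1 / (sv + sigma_nsq)).sum())
        den += float(np.log10(1.0 + s1 / sigma_nsq).sum())
    if den == 0.0:
        return 0.0
    return num / den


def tsallis_mi(a: np.ndarray, b: np.ndarray, q: float, bins: int = 256) -> float:
    """Order-q Tsallis mutual information (joint vs product of marginals);
    → Shannon MI in nats as q → 1."""
    if abs(q - 1.0) < 1e-12:
        return shannon_mi(a, b, bins, base=np.e)
    aq, bq = _quantize(a, bins), _quantize(b, bins)
    pj = _hist2(aq, bq, bins)
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    prod = np.outer(pa, pb)
    mask = pj > 0
    s = float((pj[mask] ** q * prod[mask] ** (1.0 - q)).sum())
    return (s - 1.0) / (q - 1.0)


def qte(fused: np.ndarray, a: np.ndarray, b: np.ndarray, q: float = 1.85, bins: int = 256) -> float:
    """Tsallis-entropy fusion indicator: I_q(F;A) + I_q(F;B)."""
    return tsallis_mi(fused, a, q, bins) + tsallis_mi(fused, b, q, bins)


def aux_metrics(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
                cfg: MetricConfig | None = None) -> tuple[float, float, float]:
    """(NCIE, VIF, QTE) in one call."""
    cfg = cfg or MetricConfig()
    return (
        ncie(fused, a, b, bins=cfg.bins),
        vif(fused, a, b, scales=cfg.vif_scales, sigma_nsq=cfg.vif_sigma_nsq),
        qte(fused, a, b, q=cfg.tsallis_q, bins=cfg.bins),
    )


def evaluate_all(fused: np.ndarray, a: np.ndarray, b: np.ndarray,
                 cfg: MetricConfig | None = None) -> MetricReport:
    """Run all nine indicators on one (fused, A, B) triple."""
    cfg = cfg or MetricConfig()
    fused = np.asarray(fused, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if not (fused.shape == a.shape == b.shape):
        raise ValueError(f"shape mismatch: {fused.shape}, {a.shape}, {b.shape}")
    n_cie, v, q_te = aux_metrics(fused, a, b, cfg)
    return MetricReport(
        mi=mi(fused, a, b, bins=cfg.bins),
        ncie=n_cie,
        scd=scd(fused, a, b),
        ms_ssim=ms_ssim_metric(fused, a, b, params=cfg.ssim, scales=cfg.ms_ssim_scales),
        en=en(fused, bins=cfg.bins),
        vif=v,
        qte=q_te,
        qabf=qabf(fused, a, b, constants=cfg.qabf),
        qg=qg(fused, a, b, constants=cfg.qabf),
        config={"bins": cfg.bins, "tsallis_q": cfg.tsallis_q,
                "ssim_window": cfg.ssim.window_size, "qabf": dict(cfg.qabf)},
    )


__all__ = [
    "MetricConfig", "MetricReport", "en", "mi", "shannon_mi", "scd",
    "ms_ssim_metric", "qabf", "qg", "ncie", "vif", "tsallis_mi", "qte",
    "aux_metrics", "evaluate_all", "MS_SSIM_WEIGHTS", "QABF_CONSTANTS",
]
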