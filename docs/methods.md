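# Methods

This note documents the model implemented by `medfuse`, the parameter
choices made where the design was open, what the synthetic data generator
does and does not emulate, and the numerical conventions the test suite
relies on.

## Problem setting

Registered pairs of a structural image (single-channel, high spatial
frequency: MRI, phase contrast) and a functional image (3-channel color,
smooth, blob-like support: SPECT, PET, GFP fluorescence) are fused into one
image. Clinically useful output must keep the structural detail *and* the
functional color. The approach: fuse only luminance, carry chroma through
untouched.

## Color pipeline

RGB → YCbCr uses the full-range (JPEG-style) affine map

    Y  =  0.299 R + 0.587 G + 0.114 B
    Cb = −0.169 R − 0.331 G + 0.500 B + 128
    Cr =  0.500 R − 0.419 G − 0.081 B + 128

computed in float64 with no clipping inside the core (saturated inputs can
leave [0, 255]; clipping happens only at file write). The inverse is the
**exact matrix inverse** of the forward map, so the float round trip is the
identity to machine precision and the 8-bit round trip is exact up to
output quantization (≤ 0.5 gray level). The rounded textbook inverse
coefficients (1.400 / −0.343 / −0.711 / 1.765) are also available
(`matrix="printed"`); they are *not* the default because they are a
truncation of the true inverse and leave up to ~0.9 gray level of
round-trip error in the blue channel. Grayscale functional inputs pass
through as Y with neutral chroma 128.

## Multi-dimensional dynamic convolution

`MDConv2d` keeps `n = 4` candidate kernels (the cited omni-dimensional
dynamic convolution design; the count is configurable). One global-average
pooled descriptor per sample feeds a bottleneck projection (hidden width
`max(C_in // 4, 1)` — the floor matters because the fusion network uses 2–3
channel features) and four parallel heads:

| attention | over | gate |
|---|---|---|
| α_s | k×k spatial footprint | sigmoid |
| α_c | input channels | sigmoid |
| α_f | output channels | sigmoid |
| α_w | kernel bank (length n) | softmax (temperature 1) |

The four attentions multiply elementwise (their product commutes, so
"sequential" vs "parallel" application is unobservable) and the bank is
collapsed to one per-sample kernel W~ before a single same-padded grouped
convolution — mathematically identical to running n convolutions and mixing
outputs, at one conv call. DCB = MDC → instance norm (ε = 1e-5, learnable
affine) → exact (erf) GELU.

## Residual hybrid transformer

Tokens are channels-last with LayerNorm over the channel axis (the
normalization axis is a design choice; channel-wise LN is the vision
transformer convention). Defaults: embed dim 3, window M = 8, 1 head
(3 channels must be divisible by head count), MLP ratio 2, overlap ratio
γ = 0.5, so OAM key/value windows are round((1+γ)M) = 12 pixels extracted
with stride M and zero padding (Mo−M)/2 = 2 — the standard unfold
semantics. Query-side spatial padding is reflective, to the next multiple
of M, cropped after attention; arbitrary image sizes are therefore total.
Both W-MSA and OAM carry learned relative position bias tables ((2M−1)²
and (M+Mo−1)² entries), zero-initialized.

CAM is conv3×3 → GELU → conv3×3 gated per channel by a squeeze-excitation
sigmoid and scaled by a constant 0.01 before the residual sum, so the conv
path perturbs rather than overwhelms the attention stream.

One stack is RHTA×3 then RHTB×1, composed without an outer residual (a
config flag adds one; the equations define the stack without it). Every
residual sub-path (attention projection, MLP second linear, CAM second
conv) is **zero-initialized**, making a fresh block the exact identity.
This gives a stable training start — the untrained network is already a
reasonable luma blend — and an exactly testable contract. Remaining
attention/MLP weights are truncated normal (σ = 0.02); convolutions are
fan-in uniform.

## Network

Input is concat(functional luma, structural), both mapped from [0, 1] to
[−1, 1]. Stem DCB (k3, 2→3) → three branches of 1/2/3 DCBs (k3, 3→3) each
ending in one RHT stack → elementwise branch sum → 1×1 MDC (3→1) → Tanh.
Output maps back to luma via (x+1)/2. "Multi-scale" is depth-scale: all
branches run at full resolution and the architecture has no strided or
resampling layers, consistent with branch outputs being summed directly.
The Tanh head (bounded, symmetric) pairs with the [−1, 1] input
normalization. Ablation toggles: `use_mdc=False` swaps every MDC for a
plain convolution of equal geometry; `use_rht=False` drops the stacks;
`multi_scale=False` keeps a single branch.

## Loss

`L = w_p·L_PERCE + w_s·L_SSIM` with unit weights by default.

* SSIM uses the de-facto standard constants: 11×11 Gaussian window
  σ = 1.5, C1 = (0.01 L)², C2 = (0.03 L)², L = 1 for [0, 1] luma. The
  implementation matches `skimage.metrics.structural_similarity`
  (gaussian_weights, no sample covariance) to machine precision, and the
  same kernel backs the MS-SSIM evaluation metric.
* The perceptual term is the mean (not sum) squared feature distance —
  mean reduction keeps the two loss terms on comparable scales. The
  extractor ϕ is the first three stages of a 16-layer VGG-style stack
  (conv-conv-pool ×2, conv-conv-conv), features taken after the third
  stage. The default backend is **seeded-random frozen weights** at widths
  (8, 16, 32): deterministic, dependency-free, and exactly zero iff the
  images agree, which is what the unsupervised objective needs. A
  pretrained backend can be loaded from an `.npz` file at full widths
  (64, 128, 256) for perceptual quality work; random features trade some
  perceptual alignment for reproducibility.

## Training

Defaults mirror the reference protocol: Adam, fixed lr 1e-4, batch 16,
100 epochs over random 64×64 crops (~61 per training pair), no LR schedule,
gradient clipping off (flag available). All randomness derives from one
seed. Training runs in float32 by default (`dtype="float64"` available);
analytic tests run the core in float64. The desk-scale sanity protocol used
by the tests and the acceptance script is 3 seeds × 50 steps at batch 4 on
20 patches — sized for a single CPU — and checks (a) the 10-step smoothed
loss decreases and (b) the trained model beats a freshly initialized one on
held-out pairs.

## Evaluation metrics

All indicators quantize to 256 gray levels where histograms are involved.
Choices made where the literature has variants:

* **MI** — Hossny-style normalized MI per source, summed:
  Σ_S 2 I(F;S)/(H(F)+H(S)) ∈ [0, 2]. Raw Shannon MI (bits/nats) is exposed
  separately (`shannon_mi`).
* **NCIE** — nonlinear correlation coefficient
  NCC = H_b(X)+H_b(Y)−H_b(X,Y) (256 bins, log base 256, clipped to [0,1]);
  eigenvalues λ of the 3×3 NCC matrix give 1 + Σ (λ/3) log_b(λ/3), with an
  eigenvalue floor ε = 1e-12 for singular matrices. Floor for independent
  images: 1 − log_b 3.
* **SCD** — r(F−B, A) + r(F−A, B); a zero-variance difference contributes 0.
* **MS-SSIM** — standard 5-scale exponent weights (0.0448 … 0.1333),
  2× mean-pool between scales, contrast-structure terms floored at 0
  (anti-correlated structure earns no credit); scale count reduces with a
  warning when the image is too small, renormalizing the weights.
* **VIF** — pixel-domain VIF, 4 scales, σ²_noise = 2, on the 0–255 scale;
  identical signals score exactly 1 per source.
* **QTE** — Tsallis mutual information of order q (default 1.85, a common
  choice in the fusion literature), summed over both sources; q → 1
  recovers Shannon MI in nats.
* **QAB/F and QG** — the Xydeas–Petrović preservation model: per-pixel
  edge-strength ratio and orientation agreement pushed through sigmoids
  (Γ_g=0.9994, κ_g=−15, σ_g=0.5; Γ_α=0.9879, κ_α=−22, σ_α=0.8), weighted
  by source edge strength. The sigmoids are **normalized by their value at
  perfect preservation**, so a fused image identical to both sources scores
  exactly 1 — the ideal value both metrics are defined against (the raw
  sigmoid tops out near 0.975). QAB/F uses Sobel operators; QG uses
  first-order central differences, emphasizing gradient rather than edge
  preservation. Orientation differences are treated axially
  (min(Δ, π−Δ)).

## Synthetic data

The generator emulates the *statistics* of registered pairs, not anatomy:
soft-edged random ellipses plus band-passed noise (difference of Gaussians,
σ 1–4 px) for the structural plane; Gaussian blobs (width ~8% of image
size) mapped through a hot-metal colormap (or green-fluorescence map in
GFP mode) for the functional plane, with blob centers drawn from the shape
support (overlap fraction configurable, default 1.0). Structural planes
carry measurably more high-frequency energy than functional ones (Sobel
energy ratio > 1 across seeds), matching the modality contrast the fusion
problem is about. Not emulated: anatomical structure, registration error,
modality-specific noise models, intensity calibration. Passing tests
demonstrate the machinery is correct and trainable on data with the right
spectral contrast; they say nothing about clinical image quality.

A known-optimum fixture (`identity_pair`) sets the functional image to the
gray replica of the structural one, making F = input the global minimizer
(total loss 0) — used to sanity-check the objective.

Datasets record a train/test split (default test fraction 40/350) with
disjoint derived seeds; random crops use identical windows in both
modalities.

## Numerical conventions and degenerate inputs

* Color core, metrics: float64. Training: float32 by default.
* Zero-entropy images contribute 0 to MI (with a warning); edge-free
  source pairs make QAB/F/QG 0 (with a warning); constant difference
  images contribute 0 to SCD.
* SSIM requires images at least the window size (11); MS-SSIM degrades
  scale count instead of failing.
* The autodiff core is validated against central-difference gradients for
  every primitive; attention/convolution implementations are validated
  against brute-force dense oracles at small sizes.

## Known limitations

* NumPy-based training is CPU-bound: ~2.5 s per 64×64/batch-4 step. The
  architecture is small (≈8.5k parameters at defaults), so desk-scale
  experiments are practical, but 100-epoch full-dataset training is not
  the intended use of this implementation.
* The random perceptual backend is a reproducibility device; perceptual
  fidelity claims require the pretrained backend.
* Metric variants (MI normalization, NCIE binning, Tsallis order) follow
  one defensible reading of the cited metric literature; published tables
  using other variants are comparable only up to those choices.
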