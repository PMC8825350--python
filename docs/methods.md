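# Methods

This note records the models, conventions and open design choices behind
`dwtpet`, in the order the pipeline uses them.

## Dose-reduction model

Clinically, low-dose PET arises from list-mode data reconstructed at a
fraction of the full acquisition time; the full reconstruction chain (OSEM,
TOF, PSF modelling, attenuation/scatter/decay corrections) is out of scope
here. The package emulates its *statistical* effect in image space:

    low = Poisson(blur(activity) · c · f) / (c · f)

where `f` is the dose fraction, `blur` is an isotropic Gaussian PSF
(default σ = 1.5 px), and `c` (`counts_per_unit`, default 60) converts
activity units to expected full-dose counts per pixel. This gives exactly
the two properties the restoration problem rests on: the low-dose image is
an unbiased estimate of the scanner-resolution truth, and its noise
variance scales as 1/f. The stored full-dose ground truth is the *noise-free*
PSF-blurred activity map — the ideal image the 100 %-dose scan estimates —
so that comparisons against "truth" measure noise, not resolution mismatch.

`c = 60` was calibrated once so that input PSNR versus the truth spans
roughly the mid-20s to mid-30s dB across fractions 2.5–50 % on the default
phantoms, bracketing the range reported for clinical low-dose pelvic PET.
A pure Poisson model necessarily spreads 10·log10(20) ≈ 13 dB across that
fraction range — wider than clinical tables, where reconstruction
regularization compresses the spread; no attempt is made to match specific
clinical values.

## Phantoms and the structural prior

Each synthetic subject is a pelvic-like 2D phantom of ellipse primitives:
a soft-tissue body (activity 1), two low-uptake bone structures, a
high-uptake bladder, and one hot lesion (activity 8–12), on background
0.05. Geometry, rotations and intensities are drawn from seeded uniform
ranges. The structural prior is rendered on the *same* geometry with its
own tissue contrast (bones bright, bladder dark — T1-like rather than
activity-like) plus a smooth seeded random field (8 % of the prior's
dynamic range, correlation length ≈ shape/12), so PET and prior correlate
anatomically without being affine copies. ROI/background masks for CNR come
from the generator: the lesion ellipse (shrunk to 90 %) is the ROI and the
body interior minus all structures (dilated 1.6×) is the background.

What the phantoms do *not* emulate: attenuation/scatter artifacts,
inter-slice correlation, anatomical variability beyond ellipses,
registration error (the prior is perfectly co-registered by construction,
matching the coaxial-scanner assumption), and tracer kinetics. Passing
tests therefore demonstrate the method's statistical behaviour under
Poisson dose reduction, not clinical performance.

## The DWTN network

The network is a 4-level self-guided multi-scale CNN. Resampling uses the
orthonormal Haar transform: for each 2×2 block [A B; C D],

    ll = (A+B+C+D)/2,  lh = (A+B−C−D)/2,
    hl = (A−B+C−D)/2,  hh = (A−B−C+D)/2,

which conserves energy exactly and whose adjoint is its inverse — the
backward pass of the downsampling layer is the upsampling layer. The ÷2
orthonormal scaling was chosen (over the unnormalized ÷1 or ÷4 variants)
precisely so that energy conservation is a testable invariant; subband
order (ll, lh, hl, hh) is fixed and recorded in a convention tag. Pixel
shuffle/unshuffle utilities are provided as an alternative resampler, but
the wavelet path is the default.

Layer layout (all convolutions 3×3 stride 1 except the final 1×1):

* stem conv on the input stack (low-dose PET, plus the prior as a second
  channel when enabled) → base features;
* an analysis cascade: levels l = 1..3 receive the l-fold channelwise Haar
  transform of the stem features (channels ×4 per level);
* the top level applies two convs + leaky ReLU + one DCR block; middle
  levels fuse the inverse-transformed coarser output with their own subband
  stack (concat + conv) before the same body;
* full resolution: fusion, two DCR blocks, then a main branch (conv +
  leaky ReLU) and an attention branch (two DCR blocks + tanh) whose outputs
  are added, three residual blocks, a closing conv, and the activation-free
  1×1 output conv.

A DCR block is three conv + leaky-ReLU stages with dense connectivity
(stage k sees the block input and all previous stage outputs) and restores
its input channel count; it carries no extra identity skip, so zeroed
weights give a zero output. The network predicts the restored image
directly rather than a residual.

Choices the architecture description leaves open — channel widths (default
32, desk scale 8), per-level DCR multiplicity, the number of full-resolution
DCR/residual blocks (2/3), the leaky-ReLU slope (0.2), and whether lower
levels receive transformed *features* or transformed *images* (features
here) — are config-exposed defaults of this implementation, not claimed
values of the original design. The prior is injected by channel
concatenation at the stem, the minimal mechanism consistent with
"prior-guided" restoration.

## Compute engine

The model runs on a small reverse-mode autodiff engine over NumPy arrays
(`dwtpet.nn`): stride-1 same-padding convolution via im2col + BLAS matmul,
leaky ReLU, tanh, concatenation, the Haar feature resamplers, mean-square
reductions, and Adam. Float64 throughout; gradients are verified against
central finite differences in the test suite. This keeps the package
dependency-light and bit-reproducible for a given seed.

## Losses

    L = w_mse·L_MSE + w_vgg·L_per + w_kl·L_ker,   (w) = (0.5, 0.5, 1e-4)

* `L_MSE` is the pixelwise mean squared error.
* `L_per` is the MSE in the feature space of a *fixed* extractor. The
  default extractor is a frozen, seeded stack of random 3×3 convolutions
  with leaky ReLU: it satisfies the same contract as a pretrained
  classifier backbone (deterministic, non-trained, multi-scale features)
  while keeping the package self-contained and offline-buildable; random
  convolutional features are a standard device for perceptual-style
  penalties. A pretrained backbone can be plugged in through the same
  callable protocol, and the tap depth is configurable. An identity
  extractor is also provided; with it the perceptual loss reduces exactly
  (bit-for-bit) to the MSE.
* `L_ker` is ambiguous in the restoration literature between an output
  energy penalty E(ŷ²) and hidden-layer weight decay; both readings are
  implemented behind a `subject` switch, with the output-energy form as
  default.

## Training protocol

Adam with default moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), lr₀ = 1e-3,
halved every 25 epochs; batch 4; Gaussian weight initialization (zero-mean;
std fan-in-scaled √(2/fan_in) by default, or a fixed value via config) with
zero biases; ×4 flip augmentation (identity, up-down, left-right, both)
applied jointly to input, prior and target; 90/10 train/test split.

The split is *subject-level* by default: pooled-slice (image-level)
splitting puts near-duplicate adjacent slices of one subject on both sides
of the split and inflates test scores. Image-level splitting is available
for comparability with pooled protocols. One model is trained per dose
level by default (restoration difficulty differs per dose); pooled
multi-dose training is possible by not filtering the manifest. Early
stopping is deliberately absent — training runs a fixed epoch count.

Inputs are max-normalized per sample, with the full-dose target divided by
the same scale so the mapping is learned on a [0, ~1] range and inverted
exactly afterwards; the prior is min-max normalized independently.

## Metrics

* PSNR = 10·log10(peak²/MSE). `peak` is (2ⁿ−1) when a bit depth is
  configured, else the ground-truth data range — appropriate for float
  images, since an 8-bit peak on [0, 1] data would shift every value by a
  constant ≈ 48 dB. Identical images return an infinity sentinel.
* SSIM is computed from *global* whole-image statistics with additive
  constants c1 = 0.01, c2 = 0.03. This is deliberately not the windowed
  SSIM with c = (kL)²; a windowed variant (scikit-image) is available
  behind a flag. Self-similarity is exactly 1.
* NMSE = Σ(x−y)²/Σy² (asymmetric by construction).
* CNR = (X̄_ROI − X̄_bg)/X̄_ROI is a mean-normalized contrast, not the
  noise-SD-normalized CNR; RCNR = CNR_x/CNR_y equals 1 when contrast is
  preserved. Zero denominators raise named errors.

## Desk-scale experiment sizes

The end-to-end checks and `scripts/acceptance.py` run the pipeline at desk
scale as this package's standard experiment: 20 subjects, 64×64 grids
(the working grid is a config value; 512×512 mirrors full scale), base
width 8, quarter-dose training for 36 epochs ≈ 650 Adam steps at lr₀ = 2e-3
(the step schedule halves it at epoch 25). These sizes train the small
network to convergence on the phantom task; with them, held-out restored
PSNR exceeds the input by 1.5–3.5 dB across seeds, with SSIM and NMSE
improving in step — the scaled-down analogue of the clinical finding that
restored quarter-dose images approach full-dose quality. Numbers quoted
here are produced by the test suite and the acceptance script, not stored.

## Numerical conventions

* Bicubic resizing is separable Keys cubic convolution (a = −0.5) with
  half-pixel sample centers and clamp-to-edge boundaries; kernel rows are
  renormalized so constants are reproduced to round-off. Resizing to the
  current shape returns the image unchanged.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; dataset builds, network init, batch order and Poisson sampling are
  reproducible bit-for-bit.
* Degenerate inputs fail loudly: NaN pixels at load, all-zero images in
  max-normalization, zero CNR denominators, odd dimensions at the wavelet
  boundary, spatial sizes not divisible by 2^(levels−1) at the network
  input.

## Known limitations

* 2D slice-wise only; no 3D context.
* The image-space Poisson model ignores reconstruction-induced noise
  correlation and non-stationarity; real low-dose PET noise is spatially
  correlated.
* The random-convolution perceptual extractor is not a semantically
  pretrained feature space.
* Training at full scale (512×512, base 32, 100 epochs) is possible but
  slow on the NumPy engine; the architecture and protocol are the same at
  both scales.
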