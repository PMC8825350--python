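# dwtpet

Restoring low-dose PET images to full-dose quality with a wavelet-based
convolutional network guided by a structural (MRI-like) prior.

## The problem

PET image quality is limited by the number of coincidence counts collected,
which is proportional to the injected tracer activity and the acquisition
time. Cutting the dose (or the scan time) by a factor 1/f multiplies the
count-noise variance by f, degrading lesion contrast and quantitative
indices. On hybrid PET/MRI scanners a co-registered structural image is
acquired for free, and its anatomical detail can guide the restoration of a
low-dose PET slice toward its full-dose counterpart.

`dwtpet` implements this restoration pipeline end to end for 2D slices:

* **DWTN**, a self-guided multi-scale CNN that uses the orthonormal Haar
  wavelet transform as its lossless down/upsampling operator. Feature maps
  are analyzed into (LL, LH, HL, HH) subbands across 4 resolution levels;
  coarse features are synthesized back up and fused with finer ones. Each
  level applies densely connected residual (DCR) blocks — three conv +
  leaky-ReLU stages where stage *k* sees the concatenation of the block
  input and all previous stages. At full resolution a main branch and a
  tanh-gated attention branch are summed, refined by residual blocks, and a
  final activation-free 1×1 convolution emits the restored slice. The
  structural prior enters as a second input channel.
* **The composite objective** `L = w_mse·L_MSE + w_vgg·L_per + w_kl·L_ker`
  with default weights (0.5, 0.5, 1e-4): pixel MSE, a feature-space
  (perceptual) MSE through a fixed extractor, and a kernel penalty
  `E(ŷ²)` (a weight-decay variant is available).
* **The training protocol**: Adam (default moments), batch 4, learning rate
  halved every 25 epochs, Gaussian weight initialization, 90/10
  subject-level split, ×4 flip augmentation.
* **Metrics**: PSNR, SSIM computed from global image statistics with
  constants c1 = 0.01, c2 = 0.03, NMSE = Σ(x−y)²/Σy², mean-normalized CNR =
  (X̄_ROI − X̄_bg)/X̄_ROI and its ratio RCNR between a compared image and the
  ground truth, plus signed relative difference maps (x−y)/max(y).
* **A synthetic cohort**: pelvic-like ellipse phantoms (body, bones,
  bladder, hot lesion) with decoupled PET/structural contrast, Gaussian PSF
  blur and Poisson count thinning at dose fractions 2.5–100%, replacing the
  clinical data the method targets.

The network, its autodiff engine and the Adam optimizer are implemented in
pure NumPy, so the package runs anywhere NumPy does — no GPU or deep
learning framework required.

## Worked example

Generate one phantom, thin it to three dose levels, and score the inputs
against the noise-free full-dose truth:

```python
import numpy as np
from scipy.ndimage import gaussian_filter
from dwtpet import DoseLevel, generate_phantom_pair, simulate_dose
from dwtpet.io_formats import ImageGrid
from dwtpet.metrics import ROISpec, psnr, ssim_global, nmse, rcnr
from dwtpet.synthetic_data import sample_phantom_spec, phantom_masks

spec = sample_phantom_spec((128, 128), np.random.default_rng(0))
activity, prior = generate_phantom_pair(spec, seed=0)
truth = ImageGrid(gaussian_filter(activity.pixels, 1.5))   # scanner-resolution truth
roi = ROISpec(*phantom_masks(spec))
for frac in (0.05, 0.25, 0.5):
    low = simulate_dose(activity, DoseLevel(frac), seed=1)
    print(f"{frac*100:5.1f}%  PSNR {psnr(low, truth):5.2f} dB   "
          f"SSIM {ssim_global(low, truth):.3f}   NMSE {nmse(low, truth):.4f}   "
          f"RCNR {rcnr(low, truth, roi):.3f}")
```

prints

```
  5.0%  PSNR 27.13 dB   SSIM 0.939   NMSE 0.1025   RCNR 0.998
 25.0%  PSNR 33.90 dB   SSIM 0.987   NMSE 0.0216   RCNR 1.002
 50.0%  PSNR 36.97 dB   SSIM 0.993   NMSE 0.0106   RCNR 1.001
```

i.e. image quality rises monotonically with dose while mean lesion contrast
(RCNR ≈ 1) is unbiased — the Poisson model only adds noise. Training the
network on quarter-dose pairs then raises held-out PSNR above the input by
1.7–3.4 dB depending on the seed (see below), with SSIM and NMSE improving
accordingly: the restored image recovers most of the quality lost to the
dose reduction.

The same pipeline is scriptable from the shell:

```bash
dwtpet simulate --config run.yaml --out data/
dwtpet train    --config run.yaml --data data/ --out run/
dwtpet restore  --checkpoint run/checkpoint.npz --input low.nii --prior prior.nii --out restored.nii
dwtpet evaluate --config run.yaml --data data/ --checkpoint restored+prior run/checkpoint.npz --out report.csv
```

## Layout

| module | contents |
| --- | --- |
| `dwtpet.io_formats` | `ImageGrid`, NIfTI/DICOM/NPZ I/O, bicubic resize, normalization |
| `dwtpet.synthetic_data` | phantom specs, Poisson dose simulation, dataset builder |
| `dwtpet.wavelet_ops` | orthonormal Haar DWT/IDWT, pixel (un)shuffle |
| `dwtpet.nn` | NumPy autodiff engine + Adam |
| `dwtpet.dwtn_model` | the DWTN architecture, checkpoints |
| `dwtpet.losses` | MSE / perceptual / kernel losses, feature extractors |
| `dwtpet.training` | split, augmentation, LR schedule, training loop |
| `dwtpet.metrics` | PSNR, global SSIM, NMSE, CNR/RCNR, batch reports |
| `dwtpet.cli` | `dwtpet simulate/train/restore/evaluate` |

See `docs/methods.md` for the modelling choices and their rationale.
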