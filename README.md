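# vwdenoise

Denoising of compressed-sensing (CS) vessel-wall MR images when no
pixel-aligned clean reference exists, and the evaluation machinery to judge
the result without one.

High-resolution proton-density-weighted (HRPD) imaging of intracranial
vessel walls is slow; compressed-SENSE acceleration shortens the scan but
degrades the image. Because an accelerated scan and a conventional scan of
the same subject are acquired minutes apart, they are never aligned
pixel-wise, so the standard supervised training recipe (and reference-based
metrics such as PSNR/SSIM) cannot be used. This package implements and
compares the two training strategies that survive that constraint:

* **self-supervised** — corrupt clean images with synthetic zero-mean
  Gaussian noise, `x̂ = y + g(μ=0, σ)`, with σ drawn per image as a fraction
  (default 25–35%) of the image's arithmetic mean, and train a single-channel
  U-Net `f_θ` by `argmin_θ Σᵢ L(f_θ(x̂ᵢ), yᵢ)` with MSE loss; the trained
  network is then applied to genuinely noisy images. The Gaussian model is
  itself checked by estimating noise in an air region of interest and testing
  normality with the D'Agostino–Pearson omnibus test (accepted at p > 0.01).
* **unsupervised** — a CycleGAN between the unpaired noisy domain A and
  clean domain B: generators `G_AB`, `G_BA` and discriminators `D_A`, `D_B`
  trained with least-squares adversarial losses and an L1 cycle-consistency
  penalty, `L = L_GAN(G_AB, D_B) + L_GAN(G_BA, D_A) + λ·L_cyclic`, λ = 10.

Since the clinical data behind the original study are not shareable, the
package ships a synthetic-phantom module that generates HRPD-like slices
(bright vessel-wall rings, dark lumina, bright CSF pockets, textured
parenchyma, an air background) with exact region-of-interest ground truth,
in both pixel-aligned and deliberately misaligned flavours. Everything —
training, evaluation, statistics — runs on one CPU; the neural networks are
implemented in NumPy with explicit forward/backward passes.

Evaluation is entirely no-reference:

* vessel-wall SNR = peak wall intensity / lumen standard deviation; region
  SNR = ROI mean / ROI std (CSF, parenchyma);
* blockwise noise maps (5×5-pixel local standard deviation);
* BRISQUE natural-scene statistics (36 MSCN features over two scales) with a
  self-contained corpus scorer in [0, 100], lower = better;
* radiomic reproducibility: 465 features per image (18 first-order, 75
  texture across GLCM/GLRLM/GLSZM/NGTDM/GLDM, and the same 93 on each Haar
  wavelet sub-band), compared between conditions with Lin's concordance
  correlation coefficient; a feature counts as reproducible when CCC > 0.8;
* paired *t* tests at α = 0.05 and Kolmogorov–Smirnov normality checks.

## Worked example

```python
from vwdenoise import (PhantomSpec, NoiseSpec, generate_phantom, add_noise,
                       estimate_air_noise, evaluate_image)

spec = PhantomSpec(size=(300, 300), n_vessels=3, seed=7)
clean, rois = generate_phantom(spec)
noisy, sigma = add_noise(clean, NoiseSpec(), seed=7, return_sigma=True)
print(f"injected sigma: {sigma:.2f} ({sigma / clean.pixels.mean():.1%} of the image mean)")

sigma_hat, normality = estimate_air_noise(noisy, rois["air"])
print(f"air-ROI sigma estimate: {sigma_hat:.2f} "
      f"(D'Agostino-Pearson p = {normality.p_value:.3f})")

row = evaluate_image(noisy, rois).regions["parenchyma"]
print(f"noisy parenchyma noise {row['noise']:.2f}, SNR {row['snr']:.2f}")
```

prints

```
injected sigma: 17.77 (31.3% of the image mean)
air-ROI sigma estimate: 17.63 (D'Agostino-Pearson p = 0.754)
noisy parenchyma noise 20.45, SNR 4.90
```

The injected noise (31.3% of the image mean) is recovered from the air ROI
to within 1%, and its normality test confirms the Gaussian corruption model.
The parenchyma "noise" (20.45) exceeds σ because the ROI standard deviation
also contains the phantom's intrinsic texture.

The full study — simulate, train both denoisers, evaluate, radiomics,
statistics — runs from one command:

```
vwdenoise run-all --seed 1 --out-dir out/
```

On the desk-scale defaults (64×64 phantoms, 200 training pairs, 20 epochs)
this takes a few minutes on one CPU and writes per-condition quality tables,
CCC reports, trained model checkpoints, a summary JSON, per-file checksums
and the four headline directional checks. Typical seed-1 output: parenchyma
noise drops from 19.2 (noisy input) to 8.5 after self-supervised denoising
(paired-t p ≈ 1e-16) with SNR rising from 5.3 to 12.3, and the per-class mean
CCC against the original improves from 0.11 to 0.26 (texture) and 0.23 to
0.43 (wavelet). The small unsupervised model reliably shifts global noise
statistics toward the clean domain but, at this scale, does not reliably
lower local parenchyma noise; `compare_conditions` reports each directional
finding as an explicit pass/fail. A `--paper-scale` flag selects the
full-scale configuration (300×300 images, 1,500/300/300 splits, 200 epochs),
which takes hours.

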