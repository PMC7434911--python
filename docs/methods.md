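# Methods

## The problem being modelled

Accelerated (compressed-SENSE) vessel-wall MR acquisitions are noisy;
conventional acquisitions of the same anatomy are cleaner but acquired at a
different time, so the two are never pixel-aligned. The package implements
the two denoising strategies that work without aligned pairs — a
self-supervised U-Net trained on synthetically corrupted copies of clean
images, and an unsupervised CycleGAN between unpaired noisy and clean
domains — together with a no-reference evaluation suite. All experiments run
on synthetic phantoms, so every quantitative claim made by the tests is a
claim about the method's behaviour under the phantom's assumptions, not
about clinical images.

## Synthetic phantoms

`phantom.generate_phantom` renders a 2-D slice with the contrast structure
the metrics need: an elliptical "brain" of parenchyma (mean 100, arbitrary
units) carrying a Gaussian-correlated texture field (amplitude 10, correlation
length 3 px — enough structure for non-trivial radiomics), bright CSF discs
(160), vessels drawn as bright wall annuli (200) around dark lumina (30), and
an air background at exactly 0. Intensity ordering air < lumen < parenchyma <
wall is enforced, matching proton-density-like contrast. Pixel spacing
defaults to 0.4 mm. The full-scale geometry is 300×300; the desk scale is
64×64 with two vessels of lumen radius 2.5–4.5 px.

What the phantom does **not** emulate: anatomy (no atlas), partial-volume
edges, coil-sensitivity shading, aliasing artefacts of real CS
reconstruction, or Rician magnitude statistics (available as an optional
noise family but not used by default). Passing tests therefore demonstrate
correctness of the algorithms and the direction of their effects under
controlled conditions; they are not evidence about clinical image quality.

Misaligned "second acquisitions" are produced by `deform`: a coarse random
vector field (grid ≈ size/16) is upsampled, smoothed, stripped of its mean
(no bulk shift) and scaled so the mean displacement-vector norm equals the
requested magnitude (default 2 px), then applied with bilinear resampling.

## Corruption model and its calibration

`corruption.add_noise` implements `x̂ = y + g(μ, σ)` with μ = 0 and σ drawn
uniformly per image from 25–35% of the image's arithmetic mean — the range
reported to train the best-performing network. σ is drawn per image, not per
pixel or per patch, giving the denoiser blind-σ robustness. Outputs are not
clipped by default (clipping is opt-in). An optional smooth multiplicative
field on σ emulates parallel-imaging noise inhomogeneity; a Rician family is
available for magnitude statistics.

Calibration: `estimate_air_noise` takes an air ROI (≥ 20 pixels; the
omnibus normality test is unreliable below that), returns the sample
standard deviation and the D'Agostino–Pearson test, with "Gaussian-
modellable" declared at p > 0.01. Monte-Carlo tests verify < 2% relative
bias at n = 10⁴ and ≥ 99% correct verdicts for Gaussian vs uniform noise.

The comparison corruption is k-space undersampling: a variable-density
Poisson-disk mask (exclusion radius doubling from centre to edge, fully
sampled calibration centre, Hermitian-symmetrised so real images reconstruct
real, fraction trimmed to 1/acceleration) followed by zero-filled
reconstruction. With the signed-real output option the operation is exactly
linear and idempotent for a fixed mask; the default returns the magnitude.

## Self-supervised denoiser

A single-channel U-Net: `depth` encoder levels (two 3×3 convolutions per
level, batch normalisation before each ReLU), 2×2 max-pool down-sampling,
2×2 transposed-convolution up-sampling, skip connections at matching
resolutions, channels doubling from `base_channels`. Kernel size, activation
and optimiser (Adam) are fixed choices where the source description is
silent. Training minimises MSE between the network output on the corrupted
patch and the clean patch; images are z-scored per image before the network
and the transform inverted afterwards (the scaling convention is otherwise
unspecified). Patches are random crops, one per image per epoch.

Scale: the reported full-scale recipe is 200 epochs, learning rate 0.002,
256×256 patches, 1,500/300/300 train/validation/test images. The desk scale
used throughout the tests and the acceptance script is 200 training pairs of
64×64, depth 3, base 8 channels, batch 8, 20 epochs, same learning rate —
about two minutes on one CPU; both scales are plain configuration values.

After the epoch loop a single calibration sweep replaces the batch-norm
running statistics with the aggregate batch statistics over the training
set; with few training steps the momentum-driven running estimates are
otherwise far from converged and inference quality suffers.

The noisy-target variant (`noisy_targets=True`) retrains the same
architecture against independently re-corrupted copies of the clean images.
Because the corruption is zero-mean (`E[ŷ|x̂] = y`), the MSE minimiser is
unchanged in expectation, and the acceptance suite verifies that held-out
MSE to ground truth stays within 25% of the clean-target model's.

## Unsupervised denoiser

CycleGAN with two U-Net generators (same architecture as above) and two
discriminators: five 4×4 stride-2 convolutions (channel progression c, 2c,
4c, 8c, 8c; instance normalisation and leaky-ReLU 0.2 after each except no
normalisation on the first), a 1×1 "fully connected" convolution, then a
global average pool to one scalar — layer order as described for the source
discriminator, including the unusual FC-before-pool placement. Losses:
least-squares GAN terms plus λ·L1 cycle loss, λ = 10 (unstated in the
source; logged in every run). One discriminator step per generator step,
batch size 1, Adam(0.5, 0.999), no identity loss and no image buffer.
Desk scale: 20+20 unpaired 64×64 images, 8 epochs. Probing longer training
(16/24 epochs) did not systematically improve local noise, so 8 is kept.

At desk scale the GAN reliably learns the *global* noise statistics of the
clean domain (its translated images' noise-map distribution moves toward
domain B's in the majority of seeds) but does not reliably lower local
parenchyma noise — seed-to-seed variability is large, which the experiment
module reports honestly through its per-check pass/fail table.

## Quality metrics

* Vessel-wall SNR: signal = maximum intensity in the wall ROI ("peak"),
  noise = lumen standard deviation; a 99th-percentile peak is available for
  outlier robustness. Zero noise raises an explicit undefined-SNR error,
  never ±∞.
* Region SNR (CSF, parenchyma): ROI mean over ROI standard deviation. ROI
  standard deviations use the n−1 convention throughout.
* Noise maps: non-overlapping 5×5 tiles of sample standard deviation (a
  sliding variant exists). For i.i.d. noise the tile mean equals the
  c₄-corrected σ; tests check agreement within 5%.
* BRISQUE: intensities rescaled to [0, 255]; MSCN with the canonical 7×7
  Gaussian window (σ = 7/6) and stabiliser C = 1; GGD fit (2 parameters) of
  the MSCN map plus AGGD fits (4 parameters × 4 orientations) of pairwise
  products, at two scales → 36 features. A measured property worth knowing:
  because each pixel participates in its own local-σ estimate, the MSCN of
  pure Gaussian noise is mildly platykurtic and fits a shape parameter near 3
  at this window (approaching 2 as the window grows); the moment-matched
  fitter itself recovers α = 2.0 on raw Gaussian samples.
* Scoring: the externally pretrained regressor of the original BRISQUE is
  not bundled; the package provides a corpus scorer — features standardised
  by a pristine corpus, Ledoit–Wolf shrinkage covariance, and score =
  100·d/(d + 3·median corpus distance) for Mahalanobis distance d. The map
  is strictly monotone and bounded in [0, 100]; scores are comparable only
  within one corpus, which is sufficient for the within-study deltas used
  here.
* Statistics: two-sided paired *t* tests (α = 0.05; identical inputs return
  t = 0, p = 1; constant non-zero differences are signalled as errors), KS
  normality on standardised samples, and the D'Agostino–Pearson omnibus test.

## Radiomics

Grey levels are discretised to a fixed bin count (32, equal width over the
ROI range), which makes all texture features exactly invariant to adding a
constant to the image. Families and sizes: GLCM 24 (symmetric, distance 1,
features averaged over the four 2-D directions, including the maximal
correlation coefficient), GLRLM 16 (four directions, averaged), GLSZM 16
(8-connected zones), NGTDM 5 and GLDM 14 (distance-1 neighbourhood,
dependence = 1 + dependent-neighbour count) — 75 texture features, plus 18
first-order features. A single-level orthonormal Haar transform (periodised,
so Parseval holds exactly) contributes the same 93 features per sub-band
(LL, LH, HL, HH; first letter = row filter), 372 in all, for a 465-column
table. Degenerate single-level ROIs emit 0 for features whose formula
divides by zero, with a warning, keeping tables rectangular. The default
parenchyma ROI is a centred box: 40×40 (1,600 pixels) at full scale, shrunk
to 32×32 on 64×64 phantoms so it stays inside the brain.

Reproducibility: Lin's CCC with population (1/n) moments (sample-moment
variant by flag), reproducible at CCC > 0.8, summarised per class
(first-order / texture / wavelet) as mean ± sd and reproducible fractions.
GLCM/GLRLM matrices and the CCC are verified against brute-force
enumeration / direct moment evaluation in the test suite.

## The orchestrated study

`experiment.run_experiment` executes simulate → corrupt → train both
denoisers → evaluate → radiomics → statistics from one config and one seed
(stage seeds derived via a seed sequence; a rerun is bit-identical). Test
images are evaluated under four conditions: noisy input, self-supervised
output, unsupervised output, and target. The target condition carries a 5%
noise floor: real "clean" acquisitions are themselves noisy (this is exactly
why noisy-target training works), and a literally noiseless target would
make the lumen-based SNR undefined. The unsupervised trainer receives only
the unpaired dataset — by construction it never sees a clean counterpart of
a noisy image. Desk sizes: 200 train / 20 validation (BRISQUE corpus) / 20
test phantoms, 20+20 unpaired. p-values are reported raw, with a
Holm-corrected column alongside. `compare_conditions` reduces the study to
four directional pass/fail findings (both methods beat the input on
parenchyma noise/SNR; self-supervised noise below unsupervised; unsupervised
CCC above input for texture and wavelet; both methods lower BRISQUE).

## Known limitations

* The NumPy networks are small and CPU-bound; the full-scale configuration
  is expressible but takes hours.
* The desk-scale CycleGAN is too small to be a reliable local denoiser; its
  directional findings vary across seeds and are reported, not guaranteed.
* BRISQUE scores from the corpus scorer are study-internal quantities; they
  are not comparable with scores from the original pretrained regressor.
* Phantom realism is deliberately minimal (see above); 3-D volumes, coil
  physics and reconstruction artefacts are out of scope.
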