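# Methods

This note records the scientific model behind `chromstem`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not demonstrate.

## Synthetic chromatin fibers

Training data come from a seeded geometric sampler, not molecular dynamics.
A chromatin fragment is a chain of nucleosomes — rigid disks of radius
5.5 nm and height 6 nm — connected by linker DNA of contour length
`(NRL − 147) bp × 0.34 nm/bp`. Consecutive centers are placed at a spacing
interpolated between the excluded-volume contact (5.5 nm) and the geometric
maximum (linker contour + one disk diameter) by a `compaction` parameter in
[0, 1], with chain directions blending an ideal extended zig-zag
(compaction 0) into isotropic random steps (compaction 1). Placements that
bring any two nucleosome centers closer than 5.5 nm are rejected; after
1000 failed proposals for one nucleosome the sampler raises rather than
silently degrading. At the ~3 nm voxel scale of STEM tomography only the
local scattering-mass distribution matters, so each nucleosome is
represented by ~500 pseudo-atoms drawn uniformly in its cylinder (sampled
as antipodal pairs so the template centroid is exactly the origin), and
linkers by evenly spaced points at 6 atoms/bp. Two idealized
tetranucleosome folding motifs are available: the compact α-tetrahedron
(centers on a regular 7 nm-edge tetrahedron) and the planar β-rhombus
(9 nm sides, 7 nm short diagonal), either free-standing or inserted rigidly
into a sampled chain.

The dataset sampler draws, per fiber, the nucleosome count uniformly from
{4…16}, the NRL uniformly from {150…200} bp, and compaction uniformly from
[0, 1] — the study conditions for all benchmark runs.

What this emulates: the image-level statistics (blob sizes, spacings,
cluster densities) of nucleosome-resolution tomogram patches. What it does
not: force-field energetics, sequence effects, realistic linker paths under
torsional constraints, or inter-fiber crowding. Benchmarks passed on this
generator therefore demonstrate that the denoiser learns and inverts the
*noise model* on *this image class*; transfer to experimental tomograms
additionally depends on how well the class matches real data.

## Voxelization and normalization

Voxel intensity is the count of pseudo-atoms inside the voxel's half-open
axis-aligned box (atoms on an upper grid boundary are dropped), making
`sum(intensity) == in-bounds atom count` an exact conservation law that the
tests exploit. Default geometry is 28×28×9 voxels at 3 nm — the size of an
experimental sub-volume — with the grid centered on the cloud centroid.
Normalization to [0, 1] is monotone: per-stack min–max by default, or
quantile matching to a packaged synthetic experimental-like reference
histogram (right-skewed, mode near 0.1) when intensity *distributions* must
align; exact zeros stay zero in both modes.

The 2D images used for training are whole-fiber snapshots: the stack is
collapsed along the beam (z) axis — atom counts summed over its 9 slices —
and histogram-matched to the experimental-like reference distribution, so
every nucleosome of the fragment is visible in one 28×28 image and the
intensity scale resembles a tomogram patch. (Per-image max normalization
was rejected: a single outlier-bright voxel where nucleosomes overlap then
compresses the rest of the fiber into the lowest intensities, which starves
both the autoencoder's reconstruction and the similarity metrics.) A single 3 nm slice of a centred fragment is nearly empty
(a handful of bright voxels) and carries too little structure to train or
score a denoiser meaningfully; the collapsed snapshot matches the image
class the benchmark statistics describe. Trained models are nevertheless
applied to 3D stacks slice-by-slice at inference, which is a deliberate
train/inference distribution gap inherited from training on 2D snapshots.

## Noise model

Corruption is composed in a fixed order, then clipped to [0, 1]:

1. **Shot noise** `I → Poisson(I · c) / c`, with `c` (`counts_scale`) the
   expected detector count at unit intensity. Zero pixels remain exactly
   zero.
2. **Gaussian layer** `+ a · N(μ, σ)` i.i.d. per pixel, with μ the image
   mean and σ = 0.8 *detector counts*; on the normalized scale the weight
   is therefore `a = 1/c` by default (an explicit `gaussian_amplitude`
   overrides it). The μ term makes the layer a signal-level-dependent
   background pedestal plus spread.
3. **Scan-line shifts**: each row resampled at an offset drawn from
   `U[−shift_max, shift_max)` (default 1 subpixel) with linear
   interpolation and clamp-to-edge boundaries — the standard model of beam
   positioning error; a single global offset is available as an alternative
   mode.

Dataset corruption sweeps `c` log-uniformly over [2, 20] counts per image.
This sweep was chosen so that the noisy test images span heavily corrupted
(~15 dB PSNR at the lowest count budgets, where classical denoisers begin
to fail) through moderately corrupted acquisitions, the regime in which the
three-way benchmark is informative; a fixed mild noise level would leave nothing to denoise, and
uniformly extreme noise would leave nothing for patch-based baselines to
match. Stronger or weaker regimes are a one-argument change
(`counts_range`).

## Denoising autoencoder

Encoder: three blocks of 3×3 same-padding convolution (ReLU) + 2×2 max
pooling with 256, 128, 64 filters; decoder mirrors with three conv +
2× nearest-neighbour-upsampling blocks and a final 1-filter conv with
sigmoid. There are no dense layers, so any input size is accepted: images
are reflect-padded to the next multiple of 8 (three poolings) and cropped
after. For a 28×28 input the latent embedding is 64 channels at 4×4.
Choices made where the architecture description was open:

* upsampling = nearest-neighbour followed by convolution (avoids
  checkerboard artifacts of transposed convolutions);
* final activation sigmoid, required for binary cross-entropy on [0, 1]
  intensities; BCE clips predictions at ε = 10⁻⁷;
* 3D stacks are processed slice-by-slice with the 2D model.

Training: Adam (lr 10⁻³, β = 0.9/0.999), batch 32, seeded 20% validation
hold-out, early stopping once validation loss fails to improve by at least
`min_delta` (default 10⁻⁴) for `patience` (default 5) epochs,
best-validation weights restored. Both
images of a pair are padded identically, so the reported loss includes the
reflected border. The benchmark training budget is 50 epochs maximum; in
practice validation loss plateaus after roughly 5–15 epochs at the 400-pair
scale.

The network, backpropagation and Adam are implemented directly on NumPy:
convolutions run as one BLAS matrix product per kernel offset on
channels-last tensors (an im2col path handles few-channel layers), max-pool
argmax indices are cached for exact gradient routing, and gradients are
verified against central finite differences in the test suite. Training is
reproducible for a fixed seed up to BLAS summation order.

## Quality metrics

MSE and PSNR (`10·log10(R²/MSE)`, R = 1 for normalized images, `inf`
sentinel at zero MSE) are standard. SSIM is computed from **global** image
statistics — means, population standard deviations, and cross-covariance of
the whole image — combined as luminance × contrast × structure with
C₁ = (0.01 L)², C₂ = (0.03 L)², C₃ = C₂/2, L = 1. This whole-image form is
the printed definition for scoring 28×28 patches; it is stricter than the
common sliding-window variant on sparse images (a uniform background
pedestal in the denoised image depresses the luminance term globally), and
a `windowed=True` flag provides the scikit-image variant for
comparability. The PSD profile is the modulus of the unnormalized 2D DFT
along the diagonal `P(k) = |F(k, k)|` — the modulus, not the modulus
squared, matching the definition it implements — restricted to square
images.

The benchmark harness scores arbitrary denoiser callables on (clean, noisy)
pairs and aggregates mean ± std per method. Non-local means comes from
scikit-image at library defaults with the noise σ estimated per image
(wavelet-MAD estimator); BM3D is implemented in `chromstem.bm3d` as the
standard two-stage collaborative filter (grouping by block matching,
separable 2D-DCT + 1D-DCT group transform, hard thresholding at 2.7σ, then
Wiener filtering against the first-stage estimate, inverse-variance
aggregation), with an 8×8 block, step-3 reference grid, and groups of up to
16 — a profile suited to the small images scored here. The wavelet σ
estimate is biased low on clipped, signal-dependent noise; both baselines
receive the same estimate, and the bias is part of what the benchmark
measures (a practitioner denoising a real tomogram has no oracle σ either).

## Packing-domain analysis

On a normalized stack the pipeline computes, per domain: the local
chromatin intensity map (Gaussian smoothing at σ = 12 nm + adaptive
histogram equalization with half-volume tiles, which equalizes regional
brightness without displacing peaks), centroids as local maxima above an
Otsu threshold with 30 nm non-maximum suppression, the cumulative mass
profile M(r) in physical nm (anisotropy-aware distances, 3 nm bins,
r_max = 150 nm), and:

* **D and R_f⁽¹⁾** — least-squares fits of log M vs log r over growing
  ranges [12 nm, r]; the first radius at which any fitted bin deviates more
  than 5% (relative) from the fitted power law is R_f⁽¹⁾, and D is the
  slope of the last clean fit. The 12 nm lower cutoff (4 voxels) exists
  because discrete shells below it contain too few voxels to follow a
  power law; zero-mass bins are excluded from the log fit.
* **R_f⁽²⁾** — the first interior minimum of the 3-bin-smoothed radial
  density profile *that is followed by a subsequent rise* (2% of the
  profile range), i.e. a genuine boundary with a neighbouring domain;
  profiles that merely decay return r_max.
* **R_f = min(R_f⁽¹⁾, R_f⁽²⁾)** and **CVC** — the fraction of voxels in the
  R_f-ball with intensity above 0.05 (denoiser outputs are never exactly
  zero; a literal nonzero rule is available by setting the threshold to 0).
  Domains whose R_f-ball crosses the stack boundary are flagged truncated.

Radial quantities are evaluated in 3D; for very thin stacks the spherical
shells become plane-dominated, which is handled by the physical-distance
binning but should be kept in mind when comparing D across stack depths.

Validation is by parameter recovery on planted phantoms: radial density
`ρ(r) ∝ r^(D−3)` inside a known radius gives an exact analytic
`M(r) ∝ r^D`, so detection rate (≥ 90% required), exponent error (≤ 0.15)
and size error (≤ 15%) are scored against ground truth on fields of ~20
planted domains.

## Problem sizes

The end-to-end benchmark uses 500 fibers (400 training / 100 held-out
pairs), the full 256/128/64 architecture, up to 50 epochs with patience 5,
and scores all three denoisers on the hold-out; this is the configuration
run by `scripts/acceptance.py` and the heavyweight acceptance test. Unit
and property tests use compact architectures (e.g. 16/12/8 filters) and
datasets of 40–60 images, which exercise every code path at a fraction of
the cost.

## Known limitations

* The conformation sampler is geometric; quantitative agreement with
  MD-derived image statistics is approximate, so benchmark scores carry a
  generator-dependent offset.
* The global-statistics SSIM punishes background pedestals harshly on
  sparse images; comparisons with windowed-SSIM literature values need the
  `windowed=True` variant.
* BM3D here is a compact reimplementation tuned for small patches; on
  large natural images the reference implementations with Kaiser-window
  aggregation and adaptive profiles will outperform it.
* Seeded training is bit-reproducible only for a fixed BLAS; across
  machines expect metric agreement to ~1%.
* The domain pipeline assumes approximately isotropic voxels per axis
  (anisotropy is handled in distances, not in the smoothing kernel shape).
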