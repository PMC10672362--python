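# Methods

This note records the models implemented in `octshot`, their assumptions,
the defaults that matter, and the choices made where the design was
genuinely open.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Imaging model

A tomogram is modeled as the log intensity of the ideal complex
reflectivity convolved with a spatially invariant separable PSF,

    Y = 10 log10 |f * α|²,      X = 10 log10 (|f|² * |α|²),

where `X` is the speckle-free image (the incoherent mean over scatterer
phase realizations, i.e. the limit of angular compounding).  The model
deliberately ignores attenuation, multiple scattering, refraction, sensor
noise and motion: it isolates the speckle process itself.

The PSF factorizes into

* a **lateral** Gaussian `exp(−2x²/ωx²)` with waist `ωx` (µm), sampled at
  the lateral pitch `δx` (µm/pixel), truncated where the amplitude falls
  below 1% of the peak;
* an **axial** profile equal to the centered magnitude FFT of a Hanning
  window of `NH` measured spectral points zero-padded to `NFFT` bins,
  peak-normalized and truncated at the same 1% threshold.  For the shipped
  system parameters this truncation yields visible supports of about 7
  pixels, consistent with the window arithmetic (main-lobe width scales
  with `NFFT/NH`).

Six acquisition systems ship as YAML files (bench "chicken" system,
chicken-skin, cucumber, retina, and two intravascular catheter systems).
Their tables print the axial grain size `pz` rather than an axial width, so
the files carry `omega_z_um = pz · delta_z_um`; the axial width is treated
as a user-supplied system property throughout, and the Hanning-FFT profile
is used for simulation only.  No single standard width definition (FWHM,
−3 dB, null-to-null) reproduces `pz = 3` from `NH/NFFT` across all six
systems, which is why the width is an input and not derived.

## Speckle simulator

Reflectivity phantoms (`generate_phantom`) are deterministic in their seed.
The `layered` style emulates stratified tissue: 4–6 strata with log-spaced
mean amplitudes in [0.15, 1], boundaries undulating laterally by ±1–3
pixels, and multiplicative log-normal texture (σ = 0.2) standing in for
sub-resolution scatterer density fluctuations.  `blobs` and `constant`
cover unstructured and statistics-only experiments.

A speckle realization populates each pixel with a 3×3 grid of sub-pixel
scatterers carrying the pixel's amplitude (power-preserving split) and
i.i.d. phases uniform on [0, 2π), convolves the complex field with the PSF
interpolated to the sub-pixel grid (power-matched so the incoherent
expectation equals the pixel-grid closed form), samples back at pixel
centers, and takes `10 log10(|·|² + 1e−12)`.  The sub-resolution grid is
what makes interior speckle *fully developed*: with one scatterer per pixel
(available as `oversample=1`, and used for closed-form single-scatterer
checks) the narrow PSFs of real systems mix only ~8 phasors, leaving the
intensity measurably sub-exponential (contrast ≈ 0.93).  With the default
grid the simulator passes a KS exponentiality test at the 1% level for all
six systems and has speckle contrast within 5% of one; both are verified in
the test suite, as is the expectation identity
`E|Σ a e^{jφ} α|² = Σ a² |α|²` (spatial energy bookkeeping and a 500-
realization Monte-Carlo comparison whose RMS relative deviation is within
3/√500).

Convolution uses reflected boundaries to avoid dark borders in training
crops.  All simulator outputs are bit-reproducible under fixed seeds.

## Analysis patches and despecklers

An analysis patch is the `Lt × Nx` window whose bottom row and column `nL`
sit on the anchor pixel (`nL + nR = Nx − 1`; defaults 15×15, symmetric
`nL = nR = 7`).  Borders are replicate-padded so every pixel yields an
instance — dataset size is exactly the region area, and reconstruction by
overlap averaging drops the padded votes.  Training inputs and targets are
normalized to [0, 1] by the *noisy training image's* min–max; at inference
an image is normalized by its own min–max, which makes the model robust to
brightness offsets between systems.  This normalization contract is
deliberately isolated in one code path (`patching.Normalization`).

Four predictors share the patch contract:

* **RNN** (patch-to-pixel): hidden width 1000 by default (1 031 015
  parameters), ReLU cell, linear head, trained on the full depth segment
  and read out at the last step.
* **DRNN**: the identical architecture fed a 7×7, σ=1 Gaussian-blurred
  tomogram (kernel normalized to unit sum, reflect boundary), applied at
  train and inference time — despeckling recast as deblurring.
* **RNN-GAN** (patch-to-patch, `P = Nx`): content stage, then adversarial
  refinement against a two-FC-layer discriminator (hidden width 128,
  sigmoid output, non-saturating BCE — the loss form is a standard choice;
  the balance weight defaults to λ = 1e-3 following the SRGAN convention).
  Overlapping patch predictions are averaged at inference (stride 1 by
  default; configurable for speed).
* **U-Net**: a conventional 4-level encoder–decoder (two 3×3 convolutions
  per block, 2×2 max pooling, 2×2 transposed-convolution upsampling, base
  32 channels), 7 759 521 parameters — within 8% of the ~8.2 million, and
  roughly eight times the RNN's count.  The exact layout behind that
  printed figure is unknown; only the order of magnitude is enforced.  It
  trains on random 64×64 crops of the single pair (≥1000 crops under the
  default schedule).

All networks and their training loops are NumPy implementations with
hand-derived backward passes, verified against finite differences and a
scalar-loop recurrence oracle; identical seeds yield byte-identical
parameters.  Weight initialization is uniform scaled by fan-in, seeded.

Training uses Adam with β₁ = 0.5, β₂ = 0.9, initial learning rate 1e-4,
batches of 256 analysis patches, 8 content epochs (useful range 5–12) and
20 adversarial epochs (range 10–30).  Early stopping halts the content
stage when the epoch loss improves by less than 1% twice in a row: training
a one-shot model for too long over-fits the single image and blurs the
output.  Divergence (non-finite loss) aborts with a diagnostic.

## Domain awareness

`px = [ω/δ]` (round half away from zero, floored at 1; the half case does
not occur for any shipped system) is the grain size in pixels.  A trained
patch model's output inherits the *source* grain size, so per axis:
`source < target` risks artificially enhanced detail, `source > target`
blurs, equal is matched (`predict_output_regime`).

`plan_resampling` aligns grain sizes by resampling one image per axis with
an exact rational factor (new pitch over old).  The factor is chosen as the
fraction that actually lands the moving image's integer ratio on the
counterpart's, with the smallest denominator up to `max_denominator`
(default 3) and, among those, closest to the exact quotient
`(ω/δ)/p_desired`; when no such fraction exists under the bound the
denominator is escalated with a warning.  Choosing only the nearest
rational to the quotient — without the feasibility check — fails for the
catheter system (real ratio 2.459 adapted to grain 3 requires a factor in
(0.703, 0.984], which contains no fraction with denominator ≤ 3).  The
implemented rule reproduces the canonical factors 4/3, 8/3 and 2 for the
shipped systems and aligns every ordered system pair, which the test suite
checks exhaustively.  Resampling itself is polyphase windowed-sinc
filtering (anti-aliased decimation, band-limited interpolation) with
output length `ceil(n·den/num)` — 113 columns for a 300-column image
decimated by 8/3 — and pitch metadata scaled by the factor.  Identity plans
are bit-exact no-ops.

Exact complementary kernels linking two Hanning-FFT axial PSFs need not
exist; the rational plan is the discrete surrogate and is only claimed to
align integer grain sizes.

## Metrics

PSNR and SSIM are computed on a normalized representation: both images are
mapped by the reference's min–max affine and compared with `data_range=1`
(PSNR = `10 log10(1/MSE)`, capped at a 99 dB sentinel for identical
inputs; SSIM with Gaussian window σ = 1.5, K₁ = 0.01, K₂ = 0.03).  The dB
scale itself has no canonical peak, so absolute scores depend on this
convention; gains and method comparisons do not, and no comparability with
scores computed under other conventions is claimed.  Tiled evaluation
scores non-overlapping 256×256 tiles from the top-left corner, excluding
remainder strips.

## Validation problem sizes

The synthetic validation suite uses 128×256 tomograms on the bench-system
PSF (grain size 3), training on the first 100 columns of a single pair
(seed 0) and evaluating on five held-out pairs with fresh phantoms and
phase draws.  The RNN-family models run with hidden width 128 there —
ample capacity at this image size — and the U-Net with 3 levels, base 8,
32-pixel crops and learning rate 1e-3 for 40 epochs (at this reduced size
the default rate undertrains within the schedule).  The efficacy bar is a
mean gain over the speckled input of at least +3 dB PSNR and +0.10 SSIM;
the measured gains clear it by a wide margin (roughly +10 dB / +0.25 on
the RNN).  The cross-system check trains on the grain-3 system and scores
grain-1 cucumber-system fixtures with and without the planned lateral
interpolation by 3, asserting the adapted SSIM is strictly higher on every
fixture — a directional claim only.

## Known limitations

* The spatially invariant PSF ignores depth-dependent blurring,
  attenuation, and light–matter interaction; phantoms are stylized strata,
  not tissue, so passing tests demonstrate correctness of the pipeline and
  the physics it implements, not clinical image quality.
* Speckle decorrelation between systems is modeled only through the PSF
  and sampling grid; contrast differences and ground-truth character
  (compounded vs. algorithmic references) are not emulated.
* Patch-level ergodicity — the implicit assumption that one image's patch
  statistics represent the tissue — holds for the simulator's stationary
  phantoms by construction and is not otherwise tested.
* 3D analysis volumes and multi-image curricula are out of scope.
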