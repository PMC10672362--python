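# octshot

Few-shot speckle suppression for optical coherence tomography (OCT), with
built-in awareness of the acquisition system's sampling and resolution.

OCT B-scans are corrupted by speckle: a granular interference pattern caused
by sub-resolution scatterers, with grains as large as the system resolution.
Supervised denoisers work well but normally demand thousands of paired
images — and they silently break when deployed on a system with a different
sampling space or point-spread function (PSF). `octshot` targets both
problems for researchers and system builders who have, at best, *one*
speckled/clean image pair per tissue and system:

* **One-shot patch despecklers.** Four trainable predictors that learn from
  a single image (or part of one): a patch-to-pixel recurrent
  encoder–decoder (RNN), its deblurring variant (DRNN), a patch-averaging
  RNN refined with a tiny GAN stage (RNN-GAN), and a one-shot U-Net trained
  on random crops.
* **A physics-based speckle simulator.** Layered tissue phantoms, coherent
  sub-resolution scatterer fields, separable PSFs (Gaussian lateral,
  Hanning-FFT axial), log tomograms and their incoherent-mean ground truths
  — so everything is trainable and testable with no external data.
* **Domain planning across systems.** Sampling-resolution ratios, rational
  resampling plans, and predictions of what happens when a model trained on
  one system is deployed on another.

## The model

A measured tomogram is the log intensity of the ideal complex reflectivity
`f` blurred by the system PSF `α`:

    Y[m,n] = 10 log10 | f[m,n] * α[m,n] |²

and its speckle-free counterpart is the incoherent mean over scatterer
phase realizations,

    X[m,n] = 10 log10 ( |f[m,n]|² * |α[m,n]|² ).

In fully developed regions the intensity is exponentially distributed
(`p(y|x) = (1/x) e^{−y/x}`): the fluctuations are as large as the signal,
which is what makes speckle so destructive.

The despecklers are *patch-based*: an `Lt × Nx` **analysis patch** of the
noisy image predicts the clean value at its anchor pixel (or the whole
patch).  A recurrent cell

    z_t = ReLU(W_zy^T y_t + W_zz^T z_{t−1} + b),   x_t = FC(z_t)

walks the patch depth-first, one row of `Nx` lateral neighbors per step.
Training minimizes the MSE against the clean targets (Adam, β₁=0.5, β₂=0.9,
lr 1e-4); the GAN variant adds a second stage with generator loss
`L_G = L_MSE + λ·L_ADV` against a two-layer patch discriminator.

The **sampling resolution ratio** `px = [ωx/δx]` (PSF width over sampling
space, nearest integer) is the speckle grain size in pixels.  A trained
patch model imprints its *source* grain size on every output: deployed on a
finer-grained target it blurs, on a coarser-grained one it may hallucinate
detail.  The remedy is rational resampling of one image (e.g. lateral
decimation by 4/3 takes a grain-3 image to grain 2), which `octshot` plans
and applies with polyphase filtering.

## Worked example

```python
import octshot as ot
from octshot.estimators import RNNDespeckler

spec = ot.load_system("chicken")                    # bench system, grain size 3
noisy, clean = ot.make_pair(spec, 128, 256, seed=0)  # one synthetic pair

est = RNNDespeckler(hidden=128, region=((0, 128), (0, 100)), random_state=0)
est.fit(noisy, clean)                                # trains in seconds on a CPU

test_noisy, test_clean = ot.make_pair(spec, 128, 256, seed=101, phantom_seed=51)
out = est.transform(test_noisy)
print(f"input : PSNR {ot.psnr(test_clean, test_noisy):5.2f} dB  SSIM {ot.ssim(test_clean, test_noisy):.3f}")
print(f"output: PSNR {ot.psnr(test_clean, out):5.2f} dB  SSIM {ot.ssim(test_clean, out):.3f}")
```

prints

```
input : PSNR 10.52 dB  SSIM 0.065
output: PSNR 20.52 dB  SSIM 0.310
```

a ten-decibel PSNR gain on a *held-out* tomogram after training on 100
columns of a single image.  Cross-system planning is one call:

```python
plans = ot.plan_resampling(spec, ot.load_system("cucumber"), applied_to="target")
for p in plans:
    print(f"{p.axis}: factor {p.factor} ({p.direction.value})")
# axial: factor 1 (identity)
# lateral: factor 1/3 (interpolate)
```

The same functionality is available from the shell:

```bash
octshot simulate --spec chicken --rows 128 --cols 256 --seed 0 \
        --out-noisy noisy.tiff --out-clean clean.tiff
octshot train --method rnn --noisy noisy.tiff --clean clean.tiff \
        --region cols:0:100 --out model.h5
octshot denoise --model model.h5 --in noisy.tiff --out despeckled.tiff
octshot evaluate --ref clean.tiff --test despeckled.tiff --tile 64
octshot plan --source chicken --target cucumber
```

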