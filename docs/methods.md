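# Methods

## Problem setting

Diffusion-weighted MRI (DWI) of small anatomy such as the prostate is
acquired at two or more b-values, along several diffusion-encoding
directions, with each (b, direction) image repeated N times to recover
SNR. The complex-valued reconstructed images carry zero-mean Gaussian
noise whose standard deviation varies across the field of view (parallel
imaging amplifies noise anisotropically, the g-factor effect). High-b
images are the diagnostically interesting ones and the noisiest.
Supervised denoising is blocked by the absence of noise-free targets;
this package implements a fully self-supervised route.

## Model

Let `x ∈ R^D` be the unknown clean image and `y ~ N(x, Σ)` the observed
phase-corrected, repetition-averaged image, with `Σ = diag(σ_d²)` given
by a per-pixel noise map. For any denoiser `f`, Stein's unbiased risk
estimator generalized to spatially variant noise satisfies

    E[ 1/D ‖f(y) − x‖² ]
      = E[ 1/D ( ‖f(y) − y‖² − Σ_d σ_d² + 2 div_y(σ² ⊙ f(y)) ) ],

so the right-hand side — computable without `x` — is the training loss.
The constant `Σσ²` is dropped during optimization and restored when the
value is reported as an MSE estimate. The divergence is estimated with a
Monte-Carlo probe `b` (i.i.d., zero mean, unit variance):

    div ≈ bᵀ( σ² ⊙ (f(y + εb) − f(y)) / ε ),   ε = max(y)·10⁻³.

Defaults and their rationale:

* **Probe distribution** — Rademacher. Any zero-mean unit-variance i.i.d.
  probe is unbiased; Rademacher probes are bounded and make the estimate
  exact for denoisers with diagonal Jacobians (the identity), which gives
  sharp unit tests. Gaussian probes are available and agree in
  expectation (property-tested).
* **ε rule** — `max(y)·10⁻³` taken over the target channel of the batch.
  For linear denoisers the estimator is exactly ε-independent; for smooth
  nonlinear ones the ε-sensitivity is below probe noise (tested).
* **One probe per optimization step**, fresh each step: stochastic
  gradient descent averages over steps, so probe averaging inside a step
  buys little; validation uses `n_probes` ≥ 1 with a fixed seed so epoch
  values are comparable.

## Preprocessing chain

1. **Phase correction.** Each complex repetition is rotated by its
   low-frequency phase, estimated as the phase of the boxcar-filtered
   (default 15×15, reflect boundaries) complex image. The rotation is
   unitary, so the corrected real channel keeps the original Gaussian
   noise law — the property SURE depends on. The corrected imaginary
   channel is noise-only and discarded. The kernel size is configurable;
   15 px suppresses noise phase while following smooth background phase.
2. **Averaging.** Arithmetic mean of the corrected real repetitions.
   Magnitude averaging is implemented only as a foil: over pure-noise
   pixels its expectation is σ·√(π/2) ≈ 1.2533σ (the Rician floor)
   instead of the ≈1.2533σ/√N of complex averaging.
3. **Noise map.** Per-pixel sample std across repetitions (ddof=1 — N is
   as small as 4), scaled by 1/√N to describe the average, then
   Gaussian-blurred (σ = 10 px, reflect) to keep only the smooth spatial
   noise profile. Scaling and blurring are both linear, so their order is
   immaterial; we scale first. Externally supplied maps (e.g. propagated
   from a scanner noise prescan) enter through `accept_external_noise_map`
   with a caller-provided scale; the propagation itself is out of scope.
4. **Trace image.** Geometric mean across directions, with negative
   pixels (possible after phase correction at low SNR) clipped to zero
   inside the trace computation only — network inputs keep signed values
   to preserve Gaussianity.

## Architectures

DnCNN-style residual CNN (3×3 convs + ReLU, no normalization layers,
global residual: the network predicts the noise subtracted from the
target channel) and a U-Net (double-conv blocks, 2×2 max-pool,
nearest-neighbour upsampling, skip concatenation, no normalization).
Layers, backpropagation and Adam are implemented in numpy
(`dwisure/_net.py`), a compact CPU autodiff engine whose gradients are
verified against finite differences in float64. The final layer of a
residual network is initialized at 1% of He scale: the network starts
*near* the identity denoiser, which stabilizes early SURE training, while
keeping a nonzero gradient path into the hidden layers (an exactly-zero
init can stall the MSE strategies on a loss plateau — the identity and
the ideal denoiser have equal Half2Full loss, see below).

Reference-scale defaults are `dncnn(depth=17, width=64)` and a 4-level
U-Net; the desk-scale profile used throughout the tests is
`dncnn(depth=6, width=32)`. Published parameter counts for comparable
pipelines are not reproducible without the exact depth/width, so these
are approximations by construction.

## Training strategies

All strategies consume phase-corrected per-direction averages; the
matched-direction low-b average is concatenated as a guidance channel
(configurable: `matched` or `none`; using individual directions instead
of the trace preserves Gaussian noise).

* **sure** — minimizes the SURE loss with the repetition-derived noise
  map; needs no reference.
* **noise2noise** — even-index repetitions averaged as input, odd-index
  as reference, MSE loss. The even/odd partition is a fixed convention.
* **half2full** — first half of the repetitions averaged as input, all
  repetitions as reference; at inference the full average is the input.
  Note the structural ceiling: writing the input noise as e_h and the
  reference noise as e_f with cov(e_h, e_f) = σ_f², the optimum of
  E[(f − y_full)²] over denoisers of the form x + α·e_h is α = 1/2 — the
  objective rewards removing only *half* the input noise. Half2Full
  therefore under-denoises by design, which the corrected-residual
  variance makes visible (≈0.26 vs ≈0.80 for SURE in the shipped runs).

Samples and their σ-maps are jointly divided by a per-sample robust scale
(99th percentile of the guidance channel); joint scaling leaves the SURE
objective's meaning intact. Validation uses a 25% split; early stopping
on the validation loss with patience 10 (reference-scale) / 20 (desk-scale),
restoring the best-epoch weights. The reference-scale optimizer settings
are Adam with learning rate 5·10⁻⁵ and batch 64; the desk-scale profile
is Adam 3·10⁻³, batch 4, ≤150 epochs, chosen once for the small
phantom problem (24 samples of 64×64) where larger steps are stable and
the small batch gives more updates per epoch.

## Self-supervised evaluation

If denoising is ideal, the removed residual `(y − f(y))/σ` is standard
normal. We report its sample variance (ideal 1; < 1 indicates
under-denoising, > 1 indicates removal of image content or noise
over-estimation) and the mean standard-normal log density
(ideal −(1 + log 2π)/2 ≈ −1.4189; a zero residual gives
−log(2π)/2 ≈ −0.9189; structure in the residual lowers it). Pixels with
σ below 5% of the map maximum are masked. Statistics are computed on
per-direction images, where the Gaussian model holds, and pooled.
`oracle_mse` against ground truth exists only for synthetic phantoms and
is the only function allowed to touch the truth.

## Synthetic phantom

The generator emulates the study conditions: two b-values (50 and
1000 s/mm², with 4 and 12 repetitions), three directions,
monoexponential decay S = S0·exp(−b·ADC) over nested ellipses with
distinct S0 and ADC (body / peripheral-zone / transition-zone / lesion
values in 0.7–2.0·10⁻³ mm²/s, mild per-direction anisotropy), a smooth
random polynomial background phase (order 2), per-repetition random
linear phase instabilities of scale 0.3 rad (real instabilities have no
published magnitude; 0.3 rad is enough to cause visible cancellation
without correction), and complex Gaussian noise with a shared σ-map for
the real and imaginary parts, by default a centre-peaked radial ramp
(σ 0.02–0.06 against S0 ≈ 1, i.e. single-repetition SNR ≈ 2–7 at
b1000) standing in for g-factor amplification. Noise is added in the
image domain; k-space sampling, coil combination, EPI distortion and
inter-repetition motion are not modelled. Consequently the tests
demonstrate correctness of the estimator and pipeline mechanics under
the assumed noise model, not robustness to motion, reconstruction
artifacts or non-Gaussian residuals in real scans.

## Numerical choices and degenerate inputs

* Engine arithmetic float32; all reductions (losses, statistics) in
  float64. Gradient checks run the engine in float64.
* σ = 0 is allowed (noise-free phantoms for exactness tests); the SURE
  loss degenerates gracefully to the fidelity term, and ε falls back to
  an absolute 10⁻⁶ when `max(y) ≤ 0`.
* Noise-map estimation refuses N < 2 and directs the caller to the
  external-map route.
* Geometric mean clips negatives; empty direction lists, even boxcar
  kernels, shape mismatches and unknown config keys raise immediately.
* All randomness descends from one seed through named `SeedSequence`
  substreams (init / split / batches / probes / validation); identical
  seeds give bit-identical training histories.

## Problem sizes

Desk-scale runs use 8 phantom subjects × 3 directions of 64×64 images
for training (≈10⁵ residual pixels pooled for evaluation), 10³ noise
draws for the unbiasedness check, 10⁴ probes for the divergence oracle,
and 128×128 grids (≥1.6·10⁴ pixels) for the noise-map and Rician-floor
calibrations. These sizes keep every Monte-Carlo standard error several
times smaller than the tolerance it guards.

## Known limitations

* The numpy engine is single-threaded-BLAS bound; reference-scale
  architectures (depth 17 / width 64, 4-level U-Net) build and train but
  are impractical for large volumes here.
* Half2Full and Noise2Noise models are trained on half-repetition inputs
  and applied to full averages, whose noise level is lower — the usual
  domain shift of these strategies, visible in their residual statistics.
* The phantom's phase instabilities are low-order polynomials; shot-to-
  shot phase from cardiac pulsation or eddy currents in vivo can be
  rougher, and phase correction quality would degrade accordingly.
* No Rician-bias correction is attempted for magnitude data; magnitude
  averaging exists only to quantify the floor the pipeline avoids.
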