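# Methods

## Problem and model

Pre-treatment patient-specific quality assurance (prePSQA) verifies that the
dose a treatment planning system (TPS) intends to deliver (RTDose) will
actually be delivered; the reference is a measured/reconstructed dose
distribution (MDose). `scoredose` models the *conditional distribution of
the measured dose given the planned dose* with a score-based diffusion
model and predicts MDose by sampling from it.

The forward diffusion perturbs the target field with Gaussian noise along a
stochastic differential equation `dx = f(x,t) dt + g(t) dw`. Two standard
parameterizations are implemented behind one `NoiseSchedule` interface:

* **Variance exploding (VE, default).** Perturbation kernel
  `N(x0, sigma(t)^2 I)` with geometrically spaced scales
  `sigma_0 < ... < sigma_N`. The default scale range is
  `sigma_min = 0.01`, `sigma_max = 0.6` on the normalized dose scale.
* **Variance preserving (VP).** Linear ramp `beta(t)` on `[beta_min,
  beta_max] = [0.1, 20]`; kernel mean coefficient
  `m(t) = exp(-t^2 (beta_max - beta_min)/4 - t beta_min / 2)`, std
  `sqrt(1 - m(t)^2)`. The signal coefficient decays toward zero while the
  total variance of a unit-variance input is preserved.

VE is the default because the sampler updates (below) are written in the
sigma-indexed variance-exploding form and the "initial noise scale" only has
its usual meaning there; the VP form is provided for completeness and is
covered by the same kernel/moment tests. Time is internally discrete
(`N + 1` scales, `t = i/N`); `N = 1500` is the package default, the fixture
experiment uses `N = 300`.

A time-conditioned U-Net `s_Theta(x, sigma)` estimates the score
`grad_x log p_t(x)` of the noised target channel. The input is a channel
stack: channel 0 the noised MDose, channel 1 the clean RTDose, channel 2
optionally CT. Training minimizes denoising score matching,

    E_i E_x0 E_z [ lambda(sigma_i) || s_Theta(x_stack, sigma_i)
                   - grad log p(x_t | x_0) ||^2 ],

with the analytic Gaussian-kernel score `-(x_t - m x_0)/std^2` as target.
`lambda(sigma) = sigma^2` (default) makes the target unit scale at every
noise level — the zero model's loss is exactly `E||z||^2 / n_pixels = 1` —
so no scale dominates the objective. Conditioning channels are never
noised.

Sampling starts from `x ~ N(0, sigma_max^2)` and anneals down the schedule.
Per outer step `i = N-1 .. 0`:

* predictor (reverse-SDE discretization, VE form):
  `x <- x + (sigma_{i+1}^2 - sigma_i^2) s + sqrt(sigma_{i+1}^2 - sigma_i^2) z`
* `M` corrector (annealed Langevin) steps:
  `x <- x + eps s + sqrt(2 eps) z`
* data consistency (DC) after every update: the conditioning channels of
  the stack are overwritten with the clean inputs, so only the target
  channel ever evolves.

The corrector score is evaluated at the scale index the predictor consumed
(`sigma_{i+1}`), matching the published update exactly; for the geometric
schedules used here (`N >= 100`) the variance bias of that choice is below
2% and is verified against the analytic-score oracle.

## Numerical and design choices

* **Corrector step size.** The published corrector leaves `eps_i` open; we
  use the standard signal-to-noise rule
  `eps = 2 (r ||z|| / ||s||)^2` with `r = 0.16`, per-sample norms, and a
  fallback `sigma_i^2 * 1e-4` (with a logged warning) if the score norm is
  exactly zero. `M = 1` corrector step per outer iteration by default.
* **Final denoise.** A noise-free step `x + sigma_0^2 s(x, sigma_0)` is
  applied at the end (toggleable); it removes most of the residual
  `sigma_min`-scale noise.
* **Clipping.** Outputs are clipped to `[0, 1.2]` of the normalized dose
  scale: physical dose is non-negative and measured dose may slightly
  exceed the planned maximum.
* **Normalization.** Each case is scaled so its RTDose maximum is 1; MDose
  may mildly exceed 1. RMSE/MAE are reported in percent of this scale; the
  convention is recorded in every dataset manifest.
* **Network.** Standard score-model U-Net: residual blocks with group
  normalization and SiLU, sinusoidal embedding of `log sigma` through a
  2-layer MLP injected per block as a per-channel scale/shift, factor-2
  average-pool downsampling, nearest-neighbour upsampling, concatenation
  skips, zero-initialized output head. Default width/depth follow the
  published setting (128 channels, depth 4, multipliers 1/2/2/4, 3x3
  kernels); odd spatial sizes are reflection-padded and cropped back.
* **Autodiff backend.** The network runs on a small in-repo reverse-mode
  tape over numpy (float32, channels-last, im2col + BLAS sgemm
  convolutions, fused group-norm). Every op is verified against central
  finite differences at double precision.
* **Optimization.** Adam (lr `2e-4` default, `1e-3` in the fixture run)
  with linear warmup and cosine decay of the learning rate (constant
  available), global gradient-norm clipping at 1, EMA of weights with
  decay 0.999 and the usual `(1+n)/(10+n)` warmup correction; uniform
  discrete sampling of the scale index. The decaying schedule matters at
  desk scale: the late low-noise phase is what the EMA weights average
  over, and a constant step size there leaves seed-dependent scatter in
  final prediction quality. All randomness flows through explicit
  `numpy.random.Generator` instances seeded from the configs — there is no
  global random state anywhere.
* **SSIM.** Gaussian windows (size 11, sigma 1.5), `K1 = 0.01`,
  `K2 = 0.03`, `data_range = 1`, computed over the whole grid by default
  (background included); a body-mask-restricted variant is available.
  Quartile summaries use linear interpolation and 1.5 IQR outlier fences.

## Synthetic study conditions

Clinical paired (planned, measured) dose data is not publicly available, so
the package ships a phantom generator whose planned-to-measured transform is
known exactly. Each case: an elliptical CT body with internal structures;
RTDose as a sum of anisotropic Gaussian target kernels, zeroed outside the
body and normalized to max 1; and

    MDose = clip(calib ⊙ shift(blur(RTDose)) + noise, 0, inf)

with defaults blur sigma 1.5 px (detector resolution), rigid shift
(0.5, 0.5) px (setup error), a fixed smooth multiplicative calibration
field of amplitude 0.05 and period 16 px (response drift), and additive
noise of sd 0.01. Blur, shift and calibration are deterministic properties
of the error model — identical across cases, hence learnable — while the
additive noise is per-case random and sets an irreducible error floor
(~0.8% MAE). Cases carry anatomical-site labels (H&N/chest/abdomen) used
for stratified 4:1 train/test splitting (largest-remainder allocation; 300
cases split exactly 240/60) and per-site box summaries.

The reference experiment (`scoredose.recipes.run_reference_experiment`,
also what `scripts/acceptance.py` runs) uses 600 cases on 32x32 grids, a
VE schedule with 300 scales, a 16-wide depth-2 U-Net, 90 epochs of batch-16
Adam at lr 1e-3 (warmup + cosine decay), and 300-step predictor-corrector
sampling of 20 held-out cases with three corrector steps per scale.
The extra Langevin refinement matters at this scale: with a single
corrector step, individual trajectories can commit early to a slightly
wrong dose-blob amplitude and the small-sigma steps are too short to
relax it, which shows up as large sampler-seed variance in per-case MAE
even when the learned denoiser itself is accurate; three corrector steps
per scale let each trajectory equilibrate to the learned conditional and
make the evaluation stable across seeds. These sizes are chosen so the full run completes in minutes on a
single CPU core while the learning problem stays non-trivial: the trained
model must predict the measured dose *better than the planned dose does*
(lower mean MAE), which is impossible without actually learning the
blur/shift/calibration transform.

## What the synthetic fixture does and does not show

The generator reproduces the *structure* of the prediction task — aligned
conditional image-to-image regression with a smooth, spatially varying,
partly stochastic plan-to-delivery discrepancy — but not clinical
complexity: no realistic beam/arc geometry, no detector-array sampling, no
3-D volumes (2-D slices are the unit of processing), and a far smaller
dynamic range of anatomies. Passing tests therefore demonstrate that the
method is implemented correctly and can learn a known transform end to end;
they do not certify clinical accuracy on real VMAT cohorts.

## Known limitations

* CPU-only numpy training limits practical network size; the published
  full-size configuration (128 channels, 1500 scales) is supported but slow
  to train at realistic image sizes.
* The three-channel mode's non-CT variant (what the third channel should
  carry when CT is absent) is left open by the source method; the config
  allows an auxiliary slice channel but no default semantics are imposed.
* DICOM RTDOSE/RTSTRUCT ingestion, gamma-index computation and DVH
  reconstruction are out of scope; NIfTI and plain-array containers are the
  supported interchange formats.
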