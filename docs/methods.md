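# Methods

## Problem

`flowct` reconstructs a 3D CT-like volume x from one or two 2D projection
images y^j — ultra-sparse-view reconstruction.  With so few views the
inverse problem is massively underdetermined, so the reconstruction is
maximum a posteriori (MAP): maximize log p(x | y) = log p(y | x) + log p(x),
where p(y | x) is a Gaussian projection-consistency likelihood and p(x) is a
generative prior learned from a cohort of volumes.  Because the prior is a
normalizing flow, log p(x) is exact (no ELBO, no adversarial surrogate), and
the posterior can be ascended by gradient descent in the flow's latent space.

## Intensity conventions

* HU: calibrated CT numbers; gradation reduction maps HU to 0–255 by
  `255 * (clip(v, -1000, max) + 1000) / (max + 1000)`, so air (-1000 HU)
  maps to 0 and the volume maximum to 255.  Values stay floating point
  until an explicit k-bit quantization `floor(v / 2^(8-k))` — floor binning
  avoids double rounding across progressive stages.
* Model space: k-bit levels map to [0, 1) as `(v + u) / 2^k` with
  u ~ Uniform[0,1) during training (dequantization, required for a
  continuous density to be well defined on quantized data) and u = 0.5
  (bin centers) when likelihoods are evaluated during reconstruction, so
  that reconstruction is deterministic.

## The flow prior (3D GLOW)

A K-level multi-scale invertible network.  Each level: a 3D squeeze
(factor 2 per axis, channels x8) followed by `depth` steps of
actnorm -> invertible 1x1x1 convolution -> affine coupling; every level but
the last factors out half its channels ("split") under a conditional
diagonal Gaussian parameterized by a zero-initialized convolution of the
retained half; the final latent has a learned unconditional Gaussian
(mean mu_theta, diagonal scale Sigma_theta).  Design notes:

* The affine-coupling scale is the stabilized `sigmoid(raw + 2.0) + eps`
  with eps = 1e-3, bounded in (eps, 1 + eps]; the inverse pass can never
  divide by zero and the forward log-det is exactly `sum log(scale)`.
  At zero initialization the scale is sigmoid(2) + eps ≈ 0.8818, so the
  initial flow is identity up to a known per-coupling contraction — the
  test suite uses this closed form.
* The 1x1x1 channel-mixing convolution is LU-parameterized (fixed
  permutation, unit lower- and upper-triangular factors, signed
  log-diagonal), giving an O(C) log-determinant and guaranteed
  invertibility during training.
* Actnorm uses data-dependent initialization (zero mean, unit variance per
  channel on the first batch).  It is a standard component of this layer
  family; the architecture is unusable without a normalization layer at
  these depths.
* Coupling networks are conv(3^3) -> relu -> conv(1^3) -> relu -> conv(3^3)
  with a zero-initialized final layer.
* Reference full-scale configuration: 128^3 input, 5 levels, depth 8,
  width 512.  The desk-scale default used by the tests and the study
  driver is 16^3, 2 levels, depth 3, width 32 — small enough for a single
  CPU with the pure-numpy autodiff backend (see below).

log p(x) = sum_k log p(z_k) + log |det dz/dx| in nats; bits per voxel uses
the constant Tb^2 = 1/(ln 2 · D·H·W).

### Autodiff backend

The package carries its own compact reverse-mode automatic differentiation
tape over numpy arrays (`flowct.tape`): the flow layers, the NLL loss and
the reconstruction objective are all expressed in its operations, so one
code path serves training (gradients w.r.t. parameters) and reconstruction
(gradients w.r.t. latents through the decoder).  Convolutions use
`sliding_window_view` + BLAS contractions; every operation's gradient is
checked against central finite differences in the test suite, and the
composed flow's analytic log-determinant is checked against a numerically
differentiated full Jacobian on small inputs.

## Progressive training

Stages of increasing bit depth — reference schedule (2 bits, 96 epochs),
(3, 324), (4, 24), (8, 144); desk schedule (2,1), (3,1), (4,1), (8,3) —
with model parameters carried across stages and the Adam optimizer state
reset at each stage boundary (the objective changes with the data
distribution).  Adam uses a linear warmup to the steady rate (1e-4 at
reference scale; 1e-3 for the short desk runs, where 1e-4 would leave the
model far from convergence within the few desk epochs), a global-norm
gradient clip of 100 for robustness on small batches, and batch size 4 on
CPU (reference: 1 per device).  Validation NLL (at bin centers, so it is
deterministic) is monitored per epoch; the best-validation checkpoint is
kept and a stage stops early after 10 non-improving epochs.  A non-finite
training loss aborts the stage and returns the last finite checkpoint.

The warm-start benefit is measured directly: validation bits/dim at the
start of the final 8-bit stage is lower for the progressively trained model
than for a fresh one (reported by the study driver).

## Observation model

Projection is the axis mean: coronal `y(h,w) = mean_d x(d,h,w)`, sagittal
`y(h,d) = mean_w x(d,h,w)` — a linear, mean-preserving operator standing in
for a DRR; no attenuation physics.  The ultra-low-dose protocol adds
i.i.d. N(0, sigma^2) pixel noise on the 8-bit scale with sigma^2 = 100.
(The noise amplitude is interpreted as a standard deviation sigma — the
only reading consistent with N(0, 10^2) at sigma^2 = 100.)

## MAP reconstruction

Objective (multi-view generalization: independent Gaussian likelihoods per
view, the only consistent extension under i.i.d. noise):

    E(z) = sum_j ||y^j - P_j G(z)||^2 / (2 sigma^2) - Tb^2 log p(G(z))

with the cycle term computed on the unit intensity scale (sigma^2 converted
from its 8-bit definition) and the prior weighted by bits-per-dim so its
magnitude is resolution-independent.  Iteration:

    z <- z - alpha(n) grad_z E,   alpha(n) = A (1 - e^(-0.01 n)),

initialized at a temperature-0.5 sample of the prior, model parameters
frozen.  Stopping: summed squared residual (8-bit scale) at or below
tau^2 · N · H2D · W2D with tau = 3 gray levels RMS per pixel, or n > 1000, or a
relative latent step below 1e-4 — the latter only once n >= 1/rate, since
the alpha ramp makes early steps small by construction.  The residual
threshold is summed over views (the threshold scales with the view count N).

* Standard-dose protocol: the sigma^2 -> 0 limit; the prior term vanishes
  and A·sigma^2 cancels against 1/sigma^2, leaving
  z <- z - 0.2 (1 - e^(-0.01 n)) grad 1/2 sum_j ||r_j||^2.
* Ultra-low-dose: full objective, A = 0.9, sigma^2 = 100.

Both protocols initialize at temperature 0.5.

### Desk-scale amplitudes and backtracking

The reference amplitudes implicitly target a deep 128^3 decoder whose
Jacobian strongly damps latent steps; a shallow desk-scale decoder sees
much larger effective steps from the same coefficients, and plain gradient
descent can overshoot.  Two measures (`ReconSettings.desk`):

* A backtracking safeguard (optional, on by default) halves the amplitude
  whenever a step would increase E, then keeps the reduced value — plain
  monotone line search, making one iteration scheme robust across model
  sizes.  The limit-equivalence property (ultralow at sigma^2 -> 0 matches
  the standard path) is verified with the safeguard off.
* Desk standard amplitude starts at the 0-255-scale reading of the
  reference coefficient (0.2·255^2 on the unit-scale cycle) and lets
  backtracking find the largest stable value — appropriate because this
  protocol is pure projection-consistency descent with E the residual
  itself.  Desk ultralow uses the sigma^2-cancelling analogue of the
  standard limit, A = 0.2 sigma^2 on the model's intensity scale, which
  reproduces the full-scale gentle-step behavior: under noise the residual
  settles near the noise floor (~sigma^2·N·H·W) instead of being driven to
  the noiseless threshold — the protocol does not overfit noise.

## Phantoms

The generator emulates a chest-CT cohort only in the weak sense the method
needs — a learnable, structured image distribution: body ellipsoid (soft
tissue ~120), two lung ellipsoids (~35), heart sphere (~140), spine
cylinder (~220), a scanner-bed slab near the posterior face (~80), light
Gaussian blur (sigma 0.7 voxel), and per-subject jitter of positions
(±3%), sizes (±10%) and intensities (±10 gray).  One volume per subject;
splits follow the 384:32:34 proportions of a 450-subject cohort with
largest-remainder rounding.  Not modeled: anatomy beyond ellipsoids,
pathology, attenuation physics, scanner noise in the volumes themselves.
Consequently, passing desk-scale tests demonstrates the correctness and
the qualitative behavior of the machinery (prior helps, two views beat
one, noise costs accuracy, residual control works) — not clinical-grade
reconstruction of real chest CT; fine structures such as bronchovascular
detail remain hard for this family of methods.

## Metrics

SSIM (Wang, 7^3 uniform window, K1=0.01, K2=0.03, data range 1.0 — the
common defaults), PSNR = 10 log10(1/MSE) dB capped at 100 dB for exact
matches, MAE, and NRMSE normalized by the ground-truth intensity range (the
common convention).  Cohort summaries
report means and population variances (n divisor).

## Desk-study problem sizes

The study driver (`flowct.study`) uses 16^3 volumes, 100 subjects
(85/7/8 split), the 4-stage desk schedule above, five held-out test
subjects, and the four conditions {standard, ultralow} x {uniplanar,
biplanar}; noisy-protocol runs typically use the full 1000-iteration
budget while noiseless standard runs stop by residual within ~100
iterations.  These sizes are the package's desk-scale defaults; the
full-scale configuration remains expressible through the same interfaces.

## Known limitations

* Pure-numpy training is single-threaded per op; the reference 128^3
  five-level configuration is expressible but impractical to train here.
* Phantom realism as above; no claim transfers to clinical data without
  retraining on real volumes.
* Only axis-aligned mean projections (two views tested); the objective
  supports any differentiable operator in principle.
* One latent trajectory per reconstruction (restarts available by seed
  list but not studied); no posterior uncertainty quantification.
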