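# Methods

## Model

The package models a multichannel inertial recording Y ∈ R^{N×D} (D = 16:
two sensor units, each with tri-axial acceleration, tri-axial angular
velocity and the two magnitude channels) as noisy observations of a
low-dimensional latent trajectory X ∈ R^{N×m} governed by two Gaussian
processes: a transition map x_{t+1} = f_X(x_t) and an observation map
y_t = g_Y(x_t).  Marginalizing the GP weights yields the closed-form
decoder likelihood and dynamics prior given in the README; both are
functions of kernel matrices only.  Kernels are

* transitions: squared-exponential + constant + linear + white noise,
  hyperparameters α₁..α₅.  The linear term carries a linear (oscillatory)
  dynamical mode, the SE term smooth nonlinearity, the constant term a
  shared offset, and the white-noise term per-step process noise;
* decoder: squared-exponential + white noise, hyperparameters β₁..β₃,
  with β₃ acting as the observation-noise variance;
* encoder features: ARD squared-exponential against P inducing inputs in
  observation space, with per-channel lengthscales so that uninformative
  sensor channels can be switched off.

The Kronecker delta in the white-noise terms is an *index* identity
(a point against itself on a Gram diagonal), so duplicated latent values
at different times still receive independent noise.

Modelling decisions the formulation leaves open, resolved as follows:

* p(x₁) is standard normal on R^m — the proper-prior convention of the
  GPDM literature.
* Hyperpriors for the MAP objective are scale-invariant, p(θ) ∝ 1/θ per
  positive parameter (configurable; `flat` drops them).
* Output scales W default to the identity and are not optimized; the
  channels are Z-scored first, which removes the scale disparities W is
  meant to absorb.
* Latent dimension defaults to m = 2, matching the planar structure of
  gait cycles; it is configurable.
* With multiple training sequences the dynamics prior applies per
  sequence (no transition across boundaries); the decoder pools frames.

## Variational training

The encoder defines a frame-wise diagonal-Gaussian encoding distribution:
features φ(y) ∈ R^P, mean μ = W_m φ + b_m, variance
s = 10⁻⁶ + exp(W_v φ + b_v).  The floor keeps entropies finite; the
exponential keeps s positive with unconstrained parameters.  The training
objective is the Monte-Carlo evidence lower bound with reparameterized
samples x = μ + √s ⊙ ε (default 3 draws per step) plus a
transition-consistency penalty: the transition GP's predictive mean at
its own inputs is X_out − α₅ K_X⁻¹ X_out, so the mean squared one-step
residual has the closed form α₅² ‖K_X⁻¹ X_out‖²_F / (N−1).  Its weight λ
defaults to 1.  The entropy of q is closed-form; the dynamics expectation
is estimated at the same samples (no closed-form KL against a GP prior
exists).

All gradients are analytic.  For any scalar with kernel-matrix
sensitivity G = ∂L/∂K the hyperparameter gradients are Frobenius products
of G with ∂K/∂θ, the latent gradients follow the standard GPLVM algebra
(for the SE block, −2·amp·invwidth·(diag(rowsum(G∘E))X − (G∘E)X)), and the
chain into the encoder runs through the reparameterization and the ARD
feature map.  A finite-difference check (relative 10⁻⁴ on a tiny instance
at fixed seed) guards every gradient path in the test suite.

Optimization is Adam (default rate 0.02) over contiguous minibatches of
50 frames for 500 iterations, the batch placement, Monte-Carlo draws and
initialization all driven by one seed; training is bit-reproducible.
Kernel hyperparameters start at 1 (α₁..₅ = β₁..₃ = 1) and are optimized in
log space.  Inducing inputs (default P = 20) start at k-means centres of
the observations; ARD lengthscales start at √D; the mean readout starts
small-random so the untrained model predicts near the channel mean and
the latent geometry is genuinely learned rather than built in by a clever
initialization; the log-variance readout starts at log 0.1.  Iteration
count, learning rate and Monte-Carlo sample count are package defaults —
the reference configuration specifies only the batch size, inducing count
and unit initial hyperparameters.

After the final iteration one full pass over the training data fixes the
latent support (encoder posterior means, used for decoding and transition
prediction) and draws the cached latent samples (frames × MC draws) that
the novelty detector recycles.

## Novelty detection and alarms

A zero-mean SE-kernel GP is regressed on the recycled latent samples with
all targets equal to 1 (noise variance σ_n² = 0.1); its predictive mean
is the membership score.  Two defaults matter:

* **Lengthscale** — twice the median distance to the 10th-nearest
  neighbour of the support.  A local scale is essential: the trained
  walking support is a loop whose diameter is an order of magnitude
  larger than its local sample spacing, and a diameter-scale kernel
  flattens the score to ≈1 across the loop's interior.  The interior is
  exactly where out-of-distribution frames land, because the ARD-feature
  encoder maps far-away observations toward its readout bias (all kernel
  features vanish), i.e. towards the centroid of the training latents.
* **Threshold** — 0.5 × the 1st-percentile score of held-in normal
  points.  Held-in scores crowd the interpolation value ≈1/(1+σ_n²), so a
  bare percentile leaves no slack and new normal walking realizations
  (which stray a fraction of a lengthscale off the support) trip false
  alarms; the factor 0.5 grants roughly one lengthscale of slack
  (an SE score decays by exp(−½) ≈ 0.61 one lengthscale out).

Both defaults were validated jointly across 8 generator seeds × 4 fall
directions: AUC ≥ 0.985 for walking vs post-onset frames, alarms within
10 frames of onset, no false alarms on held-out walks.  The alarm itself
debounces single-frame dips: it fires at the first frame opening a run of
≥3 consecutive below-threshold frames.  Supports above 2000 points are
subsampled (the fit is cubic in the support size).

## Synthetic data

The generator emulates the statistical structure the model assumes, not
gait biomechanics.  A planar limit cycle z(t) = r(t)(cos θ, sin θ) with
phase jitter (sd 0.02 rad/frame) and AR(1) radial jitter (sd 0.05) drives
the 12 raw axes through a fixed 12×2 loading matrix (amplitudes 0.3–0.9,
phases spread over the cycle) on top of a 1 g gravity baseline on the
vertical accelerometer axes; i.i.d. Gaussian noise (sd 0.05 g / rad s⁻¹)
is added to raw axes only, and the magnitude channels are *computed* from
the noisy axes exactly as for real data.  Defaults: 1 Hz cadence sampled
at 10 Hz for 10 s (100 frames), accelerometer noise at the scale of
consumer MEMS sensors.  Falls superpose a direction-signed acceleration
transient (peak 3 g, the scale used by threshold-based detectors, decay
0.5 s) and gyro spike on the lateral or longitudinal axes, fade the gait
oscillation, and rotate the gravity baseline to a lying-like axis;
postures carry the gravity baseline plus sub-0.5 Hz sway.

What the generator does **not** emulate: harmonic-rich real gait spectra,
left/right step asymmetry, sensor drift and calibration error,
subject-to-subject variability, or soft-tissue artefacts.  Passing tests
therefore demonstrate that the machinery recovers low-dimensional
periodic structure and flags regime changes under realistic noise — not
clinical-grade fall-detection performance on human data.

## Numerical choices

* Gram matrices are exactly symmetrized and receive relative jitter
  10⁻⁸ × mean(diag) before Cholesky factorization; predictive variances
  are clipped at 0.
* Z-scoring uses the population (divide-by-N) standard deviation;
  channels with sd < 10⁻¹² map to zeros; held-out data reuses training
  statistics.
* The encoder's white-noise level is stored but inert away from exact
  coincidence with an inducing input.
* Degenerate threshold inputs (all scores equal) fall back to the common
  value minus 10⁻⁶.
* Training aborts with the partial trace if the objective goes
  non-finite.

## Evaluation sizes

The bundled evaluation runs at deliberately small scale so the full suite
completes in minutes on one CPU: 100-frame training sequences, 500
training iterations, 20-instance oracle sweeps, 20 quadrature trials
(N = 3, m = 1, 40³ Gauss–Hermite nodes), 200 Monte-Carlo samples per ELBO
estimate.  At these sizes the quadrature oracle is stable to ~10⁻² nats
(checked against a denser 60³, σ = 4 grid) and the Jensen margin is ≥1
nat, far above Monte-Carlo error.

## Known limitations

* The encoder is frame-wise; it cannot disambiguate observations that
  coincide at a single frame but differ in context (a window- or
  recurrence-based encoder would).
* Out-of-distribution inputs map to the latent centroid rather than to a
  dedicated "far" region; detection relies on the support not covering
  its own interior, which holds for loop-shaped gait manifolds but need
  not for arbitrary activities.
* W is fixed at identity; channel-specific noise scales are only
  captured through Z-scoring.
* The MAP (non-variational) GPDM objective is provided for completeness
  but no optimizer is bundled for it.
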