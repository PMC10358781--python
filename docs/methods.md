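# Methods

This note documents the models, the generative simulation, the evaluation
protocols, and the numerical and design choices behind them.

## The problem

Calcium imaging reports each neuron's spiking only indirectly: spikes drive a
calcium transient that decays over hundreds of milliseconds and is read out as
noisy fluorescence. Dimensionality reduction methods developed for spiking
activity (factor analysis, latent linear dynamical systems) therefore face a
temporal confound when applied to fluorescence: slow shared dynamics in the
data may reflect either slow latent activity or the indicator's decay. The
package implements a model family that addresses this confound by estimating
deconvolution and latent dynamics jointly, along with the baselines needed to
quantify the benefit.

## Models

All four models observe a q-neuron fluorescence vector y_t over T time points
per trial and extract a p-dimensional latent time course z_t (p < q). Trials
are independent given parameters.

**LDS** (`models.lds`): y_t = A z_t + b + ε_t with ε ~ N(0, R), latent chain
z_t = D z_{t−1} + v_t, v ~ N(0, P), z_1 ~ N(h1, G1). R is diagonal
(independent per-neuron variability); D, P, G1 are constrained diagonal as a
regularizer. Fit by EM with exact Kalman/RTS E-steps and closed-form M-steps;
A, b, R initialized from factor analysis, D from 0.999 I (a stable system),
P from the matching unit-stationary-variance level.

**deconv-LDS** (`models.deconv_lds`): two stages. Each neuron's fluorescence
is deconvolved independently under the AR(1) observation model
y_t = a c_t + b + ε, c_t = γ c_{t−1} + s_t with s_t ≥ 0 and an L1 penalty on
spikes (`deconvolution`); the stacked spike estimates then enter a standard
LDS. The fitted deconvolution parameters are retained so the same kernel is
applied to new data at inference time.

**CILDS** (`models.cilds`): the joint model. Fluorescence observes a latent
per-neuron calcium state, y_t = B c_t + ε_t, and the calcium recursion is
driven by the shared latents instead of observed spikes:
c_t = Γ c_{t−1} + A z_t + b + w_t, w ~ N(0, Q), c_1 ~ N(μ1, V1), with
z_t = D z_{t−1} + v_t and z_2 ~ N(h2, G2). B, R, Γ, Q, V1 are diagonal so
each coordinate of c is one neuron's calcium; D, P, G2 diagonal as in the
LDS. The first latent is z_2, because c_2 is the first calcium state that
receives a latent drive. A z_t plays the role of shared activity and w_t of
activity independent to each neuron.

**CIFA** (`models.cilds.cifa_fit`): identical to CILDS except the latent
dynamics are removed — z_t ~ N(0, I) independently per time point.
Implemented as CILDS with D = 0, P = I, h2 = 0, G2 = I held fixed. There is
no loss of generality in the standard-normal prior. Unlike classical FA, CIFA
still requires a time series, because the calcium recursion couples adjacent
time points.

### Inference: the augmented chain

CILDS and CIFA are special cases of a linear-Gaussian state-space model on the
augmented state x_t = [c_t; z_t]. Because c_t depends on the *current* z_t,
substituting the latent transition into the calcium equation gives the
stationary transition and correlated process noise

    F = [[Γ, A D], [0, D]],     N = [[A P Aᵀ + Q, A P], [P Aᵀ, P]].

Time alignment: x_1 = [c_1; z_2] with prior N([μ1; h2], blockdiag(V1, G2)),
and the first transition carries z_2 through deterministically
(F1 = [[Γ, A], [0, I]], noise [[Q, 0], [0, 0]]), so y_1 stays in the
likelihood of a single chain and one well-tested smoother serves every model.
The construction is validated against brute-force joint-Gaussian conditioning
built directly from the model equations (tests, max abs error < 1e−6 on
randomized tiny instances; observed ~1e−14).

E-steps are exact (Kalman filter + RTS smoother, exact log likelihood).
M-steps are closed-form under the diagonality constraints: per-neuron joint
least squares for (γ_j, a_j, b_j) from expected sufficient statistics
(neurons decouple because Q is diagonal, so this is the exact constrained
maximizer, not a projection), scalar regressions for B and R, per-coordinate
updates for D and P, moment updates for the initial conditions.

Two structural facts make EM cheap on many same-length trials: the covariance
recursions are observation-independent, so they are computed once and shared
while mean recursions are vectorized across trials; and for time-invariant
parameters the filter covariance converges, after which cached gains are
reused and the remaining sequential work runs in compiled (numba) kernels.
Both shortcuts are exact to ~1e−12 and are regression-tested against the
uncached path.

**Initialization.** CILDS warm-starts from a deconv-LDS fit (100 EM
iterations by default): B and R from the per-neuron deconvolution gain and
residual noise, Γ from the fitted decays, A, b, D, P and the initial latent
moments from the stage-2 LDS, Q from the stage-2 independent-noise variances
(the spiking variability that model attributes to each neuron), μ1/V1 from
the deconvolved calcium at the first frame. CIFA warm-starts analogously from
deconv-FA. The mapping is a design choice; only the use of a 100-iteration
two-stage fit is inherited.

**Convergence.** All fitters stop when the log-likelihood increase falls
below 1e−6 or after 1500 iterations (both configurable). EM monotonicity is
asserted in the tests at relative tolerance 1e−8. Numerical hygiene:
covariance symmetrization every step, variance floors at 1e−9, escalating
jitter on near-singular innovation covariances (hard error if singularity
persists), Γ clipped to (1e−6, 1 − 1e−6) in M-steps.

## Deconvolution

`deconvolution.deconvolve_ar1` solves, for fixed (a, b, γ, λ),

    min_c ½‖y − a c − b‖² + λ Σ_t s_t    s.t. s_t = c_t − γ c_{t−1} ≥ 0, c_1 ≥ 0

exactly by pool-adjacent-violators merging (the L1 term is absorbed by
subtracting λ(1−γ) from every sample and λ from the last). Correctness is
checked against exhaustive active-set enumeration on small instances and by
KKT residuals (dual feasibility and complementary slackness) on random
solves. Optional parameter optimization is coordinate descent with at most 10
outer rounds: b as the residual mean; γ by bounded scalar minimization of the
residual sum of squares over (0.5, 0.9999) at frozen λ; λ, when not fixed, by
binary search so the residual RMS matches the noise estimate (the standard
noise-constrained convention); a minimum spike size s_min, when requested, by
iterative hard-thresholding (spikes below s_min are pinned to zero via forced
pool merges and the problem re-solved) with a small residual-criterion grid.
The noise sd estimator is the square root of the mean power spectral density
over the upper quartile of frequencies — a convention, stated as such; it is
scale-equivariant and returns a flagged zero on constant traces.

Per-trial traces are deconvolved independently (calcium restarts at zero each
trial); per-neuron parameters are optimized against the summed objective over
that neuron's trials.

## Simulation framework

`simulation` generates fluorescence with deliberate model mismatch so that no
fitted model is evaluated against its own generative assumptions:

1. **Latents**: p independent GPs with squared-exponential covariance
   K(Δ) = σ_f² exp(−Δ²/(2τ²)) + σ_n² δ, at 1 ms resolution, with
   σ_f² = 1 − σ_n² and σ_n² = 1e−9 so the marginal variance is 1. Exact
   Cholesky sampling for T ≤ 4096; circulant-embedding FFT sampling beyond
   (padding 6τ, numerically negative embedding eigenvalues clipped — with the
   diagonal noise term these are negligible; distributional equivalence to the
   exact path is tested by two-sample KS on decorrelated marginals and lag
   products).
2. **Rates**: softplus readout log(1 + exp(W z_t + μ)), spikes/s.
3. **Spikes**: binary, per-1 ms-bin Bernoulli with p = 1 − exp(−rate·dt),
   the exact thinning of an inhomogeneous Poisson process to a binary train.
4. **Calcium and fluorescence**: c_t = Γ c_{t−1} + s_t,
   y_t = B c_t + b + ε with diagonal Gaussian ε; defaults B = I, b = 0.
5. **Imaging rate**: non-overlapping bin means reduce 1 kHz to 40 Hz
   (decimation available as an option).

Two independent long traces per configuration serve as training and test
sets, each cut into `n_trials` trials, so evaluation is always on held-out
data with matched statistics.

Parameter conventions, all configurable:

- **Indicator decay** (τ in ms, per-step γ = exp(−dt/τ)):
  gcamp6f 200, gcamp6m 500, gcamp6s 1000. These are order-of-magnitude
  approximations to the published indicator kinetics, not transcriptions.
- **Noise regimes** low/medium/high: the per-neuron fluorescence noise
  variance is set so the SNR (signal sd / noise sd) *at the imaging rate*
  is 10 / 3 / 1 (bin-mean downsampling shrinks the noise sd by √factor,
  which the mapping accounts for). Documented as an approximate convention.
- **Loading matrices**: Gaussian entries with column norms u_k √q,
  u_k ~ U(0.5, 1.5), giving each neuron a latent drive of sd ≈ √(Σ u_k²) —
  rate modulation of the same order as the mean rate, as in strongly tuned
  cortical populations. The offsets μ are solved per neuron (Gauss–Hermite
  quadrature + root finding) so the expected softplus rate under
  unit-variance latents equals the target mean rate (default 10 spikes/s).
- **Stimulus schedules**: K = |orientations| × |spatial frequencies| classes
  (reference grid 12 × 15 = 180) presented back-to-back in per-trial random
  order, fixed-duration windows (250 ms at 40 Hz = 10 frames), a configured
  number of repeats per class per trial. Class identity enters the simulation
  as a class-specific additive shift of the latent mean during each
  presentation window; a zero shift yields label-free data (decoders must
  then sit at chance, which is tested).

What the generator does *not* emulate: optics and point-spread functions,
movement artifacts, neuropil contamination, non-Poisson spiking statistics,
nonstationary baselines. Passing tests on these simulations demonstrate
correct inference under the stated generative process and its deliberate
mismatches (GP latents, binary Poisson spikes), not performance on any
particular real preparation.

## Evaluation

**Alignment and R²** (`evaluation.align_latents`): latents are identified
only up to invertible linear remixing, so estimates are first aligned by
least squares, W = (Z Z̃ᵀ)(Z̃ Z̃ᵀ)⁻¹, with W fit on one inner half of the
test data and applied to the other (both directions, pooled) before computing
per-latent R² = 1 − Σ(z − ẑ)²/Σ(z − z̄)². R² may be negative for
cross-validated estimates. The inner halves split the test-fold *trial list*
(first half / second half), a choice the alternatives to which (time-level
splits) differ from only in estimation error. Rank-deficient Gram matrices
fall back to the pseudo-inverse and are flagged.

**Leave-neuron-out** (`evaluation.lno_evaluate`): k-fold over trials (5 by
default); on each validation trial every neuron is held out once, latents are
inferred from the remaining q−1 neurons under the row-deleted submodel, and
the held-out trace is predicted: LDS/FA by A_j ẑ_t + b_j; CILDS/CIFA by
propagating the deterministic AR(1) recursion ĉ_t = Γ_jj ĉ_{t−1} + A_j ẑ_t
+ b_j from μ1_j and reading out B_jj ĉ_t (the reconstruction rule for a
held-out neuron is a design choice of this package); deconv-LDS by predicting
the held-out neuron's spike drive and re-convolving through its fitted
deconvolution kernel. Scores are per-neuron per-trial Pearson correlations;
zero-variance cells are NaN-flagged and excluded. Comparisons use paired
two-tailed t-tests per neuron across trials and across the neuron population
on trial means; identical inputs give t = 0, p = 1, and constant non-zero
differences are flagged undefined. A Benjamini–Hochberg column is provided as
a clearly-labeled extension beyond the raw p < 0.05 convention.

**Likelihood comparisons** are allowed only across latent dimensionalities
within one model family; `compare_likelihoods` refuses cross-model requests,
because the observation models place likelihoods on different scales.
`select_dimensionality` implements the nested-CV inner loop on this basis.

**Decoding** (`evaluation.gnb_*`): Gaussian Naive Bayes with per-class means
and a single shared diagonal covariance (pooled ML estimate), uniform priors,
argmax posterior with ties to the lowest class index. Features are latent
means over (lag-shifted) presentation windows; windows shifted outside the
trial are dropped with a count. Lag selection maximizes cross-validated
accuracy over a grid, ties to the smallest lag.

## Packaged studies and problem sizes

`experiments` bundles three end-to-end studies at desk scale; the sizes below
are the package's own defaults, chosen so each study completes in minutes on
one CPU while leaving the scientific contrasts intact:

- **Method comparison** (`method_comparison_replicate`): q = 20 neurons,
  p = 4 latents, τ = 200 ms, fast-indicator decay, medium noise, 10 trials of
  10 s per train/test half, EM capped at 150 iterations (CILDS warm-started
  from the full deconv-LDS fit, sharing stage 1). Reported as mean aligned R²
  per model; across 30 seeded replicates CILDS ≥ deconv-LDS ≥ LDS with
  paired sign tests at α = 0.05 (asserted in the acceptance tests).
- **Parameter recovery** (`cilds_parameter_recovery`): data drawn from a
  known CILDS with q = 20, p = 2, 40 trials × 400 points, Γ = 0.98 I;
  recovery of every per-neuron decay within ±0.01 and aligned latent
  R² ≥ 0.8.
- **Decay-bias sweep** (`cifa_decay_bias_sweep`): latent timescales
  {50, 200, 1000, 5000} ms with the true decay fixed. CIFA, lacking latent
  dynamics, can only explain slowly varying fluorescence by inflating its
  fitted decay; its implied time constant (median of −dt/ln γ̂_jj, averaged
  over 3 simulations per timescale) grows monotonically with the latent
  timescale, while CILDS stays within ±20% of the truth. The study uses a
  slow indicator (GCaMP6s-like, τ ≈ 1 s) and 8 trials of 20 s: the
  decay/latent confound is expressed most strongly when the indicator
  kinetics overlap the latent timescales. With a fast indicator the inflation
  saturates once the latents are much slower than the decay — the per-time
  latent posterior of CIFA absorbs a well-resolved slow signal, so the
  residual pressure on γ̂ stops growing (we observed a plateau near +15%
  between 1 s and 5 s latents for a 200 ms indicator, with the gap below
  seed-to-seed variability).

## Known limitations

- AR(1) kinetics only: indicator rise times (AR(2)) are out of scope, as are
  L0-regularized and template-based deconvolution algorithms.
- Diagonal D and P only; the general (coupled) latent dynamics variant is a
  reserved configuration hook, not implemented.
- The GP latent generator returns exact draws only up to clipping of
  numerically negative circulant-embedding eigenvalues (immaterial at the
  default σ_n² but worth rechecking for exotic kernels).
- Likelihoods, and therefore dimensionality selection, assume Gaussian
  observation noise; heavy-tailed imaging artifacts are not modeled.
- The EM iteration caps used by the packaged studies trade a small amount of
  final-fit quality for runtime; rerunning with the library defaults
  (tolerance 1e−6, up to 1500 iterations) tightens every estimate at
  proportional cost.
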