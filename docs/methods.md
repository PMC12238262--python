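# Methods

This note documents the models, estimators and numerical choices behind
`lptraj`, and what the synthetic study conditions do and do not establish
about real liquid-phase TEM (LPTEM) data.

## Trajectories and normalization

A trajectory is a uniformly sampled 2-D position series
`r(t) = (x(t), y(t))`, `t = 0..T-1`, in arbitrary length units with
optional acquisition metadata (electron-dose rate in e⁻/Å²·s, particle
length in nm).  Before any model sees a trajectory it is normalized by

1. shifting it to start at the origin, and
2. dividing both components by the pooled (x and y concatenated)
   population standard deviation of the lag-1 displacements,

so the normalized path starts at (0, 0) and has pooled step SD exactly 1.
The affine record (origin, scale) inverts the map exactly.  This
convention — the one used by the AnDi-challenge benchmark datasets — makes
every downstream statistic invariant to the original units.  A trajectory
whose pooled step SD is zero (constant position, or an exactly uniform
drift) cannot be normalized and is rejected as degenerate.

Long recordings are analyzed by segmentation into consecutive
non-overlapping 200-frame windows (remainder dropped), each segment
normalized and treated as an independent short trajectory.  200 frames
balances statistical content per segment against the number of segments a
recording yields.

## Benchmark diffusion simulators

Six seeded generators cover the standard anomalous-diffusion benchmark.
All are 2-D with independent components except the Lévy walk, whose
components couple only through the shared flight heading.

* **BM** — cumulative sums of i.i.d. standard-normal steps per component
  (step variance 1, i.e. D = 1/2, per-axis MSD = t).
* **FBM** — increments are exact fractional Gaussian noise with Hurst
  exponent H = α/2, synthesized through the Cholesky factor of the
  closed-form Toeplitz autocovariance
  γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).  O(T³) but exact at every
  lag; ample for the few-hundred-frame trajectories used here.
* **CTRW** — renewal waits drawn by inverse transform from a Pareto law
  with survival exponent α and minimum 1 frame; after each wait the walker
  takes an independent standard-normal jump per component; positions are
  regularized onto the frame grid with a zero-order hold (the particle
  sits still between renewals).
* **Lévy walk** — flights of constant speed and heading; durations are
  Pareto with survival exponent σ = 3 − α (σ ~ U(0, 3) at α = 2, keeping
  the duration density integrable while spanning ballistic-to-diffusive
  tails), headings uniform on [0, 2π), and the per-flight speed follows a
  half-normal with unit scale — the speed distribution is not critical
  because downstream normalization removes absolute scale.
* **ATTM** — piecewise diffusivity: per segment, D is drawn from
  P(D) ∝ D^{σ/γ−1} on (0, 1] with γ = 1.5 and σ = αγ (the benchmark
  regime with α = σ/γ < 1), the segment lasts t = D^{−γ} frames (rounded
  up, truncated at the window), and within the segment the walk is
  Brownian with per-frame variance 2·D·t/n_frames, so the per-segment
  displacement variance is exactly 2Dt per component.  An early variant
  distributed each segment's displacement linearly across its frames;
  that creates constant-velocity runs and a spuriously *superdiffusive*
  short-lag MSD, so the Brownian refinement is used instead.  A point-mass
  option (`fixed_D`) exposes the degenerate limit for validation.
* **SBM** — Gaussian steps with variance σ²[(i+1)^α − i^α] at step i; the
  telescoping sum makes the ensemble variance exactly σ²·n^α at frame n.

The balanced benchmark builder draws each trajectory's α uniformly from
its class range (subdiffusive [0.1, 1] for FBM/CTRW/ATTM/SBM, [1, 2] for
LW) and normalizes every trajectory.  A draw that is constant inside the
window — mainly CTRWs at small α whose first renewal falls beyond the
window — is redrawn with a fresh sub-seed, which conditions the benchmark
on "at least one jump observed"; at α = 0.1 this discards about half of
the raw CTRW draws and is the one intentional departure from the raw
renewal process.

## Statistical functionals

All statistics use population (1/n) moment conventions and non-excess
kurtosis (Gaussian = 3).  The velocity at frame t is identified with the
lag-1 displacement; no separate velocity timescale exists in the data.

* displacement moments and median per component,
* velocity autocorrelation C_v(τ) = ⟨v(t)·v(t+τ)⟩/⟨v²⟩ and positional
  autocorrelation C_r(τ) = ⟨r(t)·r(t+τ)⟩/⟨r²⟩, time averages over all
  valid start frames (maximum overlap), pooled over trajectories in batch
  mode.  C_v is translation invariant, C_r deliberately is not,
* the x–y displacement correlation (Pearson, lag 1),
* the ensemble non-Gaussianity ξ(τ) = ⅓·⟨δr⁴⟩/⟨δr²⟩² − 1 per component,
  pooled over all lag-τ displacements of the batch,
* the ensemble MSD with fitted log–log slope.  Two estimators are
  provided: the time-averaged MSD (default, appropriate for processes
  with stationary increments) and the from-origin ensemble MSD.  The
  distinction matters: for ageing processes (SBM, CTRW, ATTM) the
  time-averaged curve grows linearly in lag regardless of α, and only the
  from-origin estimator recovers the t^α law.  The slope fit uses the
  strictly positive MSD entries (a CTRW whose waits have a one-frame
  minimum has MSD(1) = 0 from the origin).

Degenerate inputs (zero displacement variance, zero autocorrelation
denominators) yield flagged zero values rather than NaNs.

## Physics-informed objective

Exact reconstruction of a stochastic path through a 12-dimensional
bottleneck is not a meaningful target; the objective instead matches
*statistics* between input x and reconstruction x̂:

L = 0.1·MSE + w_kl·KL + Σ_s ⟨(s(x) − s(x̂))²⟩_batch,

where s ranges over the four displacement moments, the displacement
median, the C_v and C_r curves (compared pointwise over lags 1..25 and
averaged), and the x–y correlation, each computed per trajectory and per
component.  The KL term is the closed-form Gaussian relative entropy
½Σ(μ² + σ² − 1 − ln σ²) averaged over the batch, linearly warmed up over
the first 10% of epochs.  The low MSE weight (0.1 vs 1.0 for every
statistic term) keeps a weak pixel-level anchor without forcing pointwise
reconstruction.  All weights are configurable; the defaults were fixed by
monitoring validation-loss convergence on surrogate data.

Every term is differentiated by the package's own reverse-mode autodiff
core (`lptraj.nn`), a compact numpy engine with the exact operations these
models need (broadcast arithmetic, reductions, batched matmul, gather,
strided 1-D convolution and transpose convolution); all its primitives are
finite-difference checked in the test suite.  The median enters through
the subgradient of its middle order statistic(s); statistic terms whose
input or reconstruction is degenerate (zero variance) contribute exactly
zero so early-training pathologies cannot inject non-finite gradients.
Float64 is used throughout — the models are small enough that precision is
cheaper than float32 conditioning headaches.

## Trajectory VAE

The encoder presents a trajectory as a single-channel sequence of length
2T (x series then y series), lifts it to the embedding dimension with a
strided patch convolution, adds a learned positional embedding, applies
two pre-norm multi-headed self-attention blocks (unmasked — trajectories
are processed offline, so bidirectional context is appropriate), and
compresses through two strided convolutions (kernels 7 and 2) and a dense
layer into the mean and log-SD of a diagonal-Gaussian 12-d posterior.
The decoder mirrors the path: dense upsampling, transpose convolutions
(kernels 2 then 7) exactly inverting the encoder strides, one attention
block, and a transpose patch convolution back to the 2T sequence.
Sampling uses the standard reparameterization z = μ + σ⊙ε.  Training is
Adam with a 10% validation split; the checkpoint with the lowest total
validation loss is retained.

The decoder's final output is interpreted as per-frame *increments*, and
positions are recovered by an in-graph cumulative sum
(`decoder_output="increments"`, the default; `"positions"` emits raw
paths).  The increment parameterization puts step statistics — variance,
tails, short-lag correlation — directly under the output layer's control;
a position-painting decoder tends to produce over-smooth paths whose
differentiated steps are too small and too anticorrelated.

Reference configuration: T = 200, embedding 128, 8 heads, 2 encoder
attention layers, latent dimension 12, 200 epochs.  The *study
configuration* used by the test suite and the acceptance script scales
this to embedding 32, 4 heads, patch 10 (40 tokens), batch 64, 50 epochs
on 2000 surrogate trajectories, learning rate 2e-3 — sizes chosen so a
full study runs on a single CPU core in minutes while preserving the
architecture's shape.  The study runs train with KL weight 4 (the other
statistic weights at their defaults): at weight 1 the converged posterior
sits ~6–7 nats from the prior and prior samples decode to noticeably
biased ensembles; weight 4 roughly halves that divergence and was
selected by monitoring validation loss and prior-sample ensemble
statistics during development.  Training at the reference scale behaves
identically mechanically but has not been characterized here.

## Surrogate liquid-cell ensemble

Real LPTEM nanoparticle trajectories show prolonged confinement with
anticorrelated steps and rare large escape jumps.  The surrogate generator
reproduces exactly these two signatures: an over-damped spring pulls the
particle toward the current trap centre (stiffness k = 0.8, giving lag-1
velocity autocorrelation ≈ −k/2 during dwells) with unit thermal kicks,
and with per-frame probability 0.03 the particle takes a Pareto-amplitude
jump (scale 10, tail index 6 — heavy-tailed but with a finite fourth
moment, so ensemble statistics converge) that relocates the trap.  Half
the trajectories are jump-enabled and half purely confined, mimicking the
heterogeneity of experimental ensembles.  With these defaults a
2000-trajectory ensemble has ξ(1) ≈ 7 and C_v(1) ≈ −0.24, inside the
range reported for real liquid-cell data.

What the surrogate does *not* emulate: localization noise, frame-rate and
dose-rate dependence, particle-size effects, drift, or any coupling
between confinement strength and jump statistics.  Tests passing on the
surrogate therefore establish that the pipeline learns and evaluates
heavy-tailed anticorrelated motion end to end — not that the model
reproduces any particular experimental dataset.

## Classifier

The diffusion classifier consumes the lag-1 displacement series (2
channels) of a normalized trajectory — diffusion class is a property of
increments.  Three parallel two-layer convolution stacks with dilation
rates 1, 2 and 4 (kernel 5, 32 filters) cover short-, mid- and long-range
temporal structure; their concatenation is averaged over 8 temporal
segments (coarse position-aware pooling, which preserves the slow variance
decay that distinguishes ageing processes such as SBM), flattened, and
mapped through a 128-unit dense layer — the feature layer — to class
logits.  Training is Adam on cross-entropy with a stratified 90/10 split,
12 epochs (validation accuracy plateaus by then on the six-class
benchmark).  Argmax ties break to the first class in sorted-label order.
Weighted F1 is computed one-vs-rest with class-frequency weights.

## Evaluation

* **Fréchet distance** between Gaussian fits (sample mean, 1/(n−1)
  covariance) of penultimate-layer features:
  d² = ‖μ_a − μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_aΣ_b)^{1/2}).  The square root
  is computed symmetrically via the eigendecomposition of
  Σ_a^{1/2} Σ_b Σ_a^{1/2}; eigenvalues above −10⁻⁶·λ_max are clamped to
  zero, stronger indefiniteness raises.  Note d(A, A) is numerically the
  square root of an O(ε) residual, so "zero" means ≲10⁻⁶.
* **Statistic-discrepancy tables**: squared differences of
  ensemble-averaged loss statistics between two batches, totalled with and
  without the loss weights.
* **Latent sweeps**: one latent coordinate is set to each value of a
  13-point grid spanning [−3, 3] while the other coordinates are drawn
  once per trajectory from the prior and held fixed across grid points, so
  points differ only in the swept coordinate; per point, ξ(1) and C_v(1)
  are measured per component on 1000 decoded trajectories (default) and
  summarized by the R² of a least-squares quadratic.  R² is undefined
  (flagged) for a constant response.
* **Condition profiles**: long trajectories are segmented into 200-frame
  pieces, encoded, and the posterior means collected per condition tag;
  the two coordinates that track non-Gaussianity are summarized by their
  arithmetic mean per segment, alongside the anticorrelation coordinate.
  Which coordinates those are is a property of a particular trained model;
  the defaults (1st, 5th; 4th) are conventional positions, overridable per
  model.

## Study conditions and their limits

The package's own evaluation (test suite and `scripts/acceptance.py`)
runs: simulator scaling-law checks at 2000–10⁴ trajectories of 400
frames; the six-class benchmark classifier at 1000 trajectories per class
(held-out weighted F1 ≈ 0.9, against a ≥ 0.75 requirement); the
generative study at 2000 surrogate trajectories × 50 epochs with a
seven-class (six simulated + surrogate) classifier at 400 per class for
feature-space evaluation.  These sizes were chosen so the full pipeline
completes in well under an hour on one CPU core.

One caution on the generative fidelity check: comparing a generated
ensemble's statistic against the *bootstrap IQR* of the training
ensemble's statistic is a strict test — the IQR measures estimator noise,
and even a perfect generator's independent sample lands inside it only
with moderate probability, before any systematic model error.  Heavy
tails widen the kurtosis/ξ IQRs (the surrogate's fourth moments are
finite but slow-mixing), while C_v(1) has a tight IQR and is the binding
constraint in practice.

## Known limitations

* The autodiff engine is single-threaded numpy; training beyond ~10⁴
  trajectories or embedding 128 at T = 200 is slow on one core.
* FBM synthesis is O(T³); fine to ~10³ frames, wrong tool beyond.
* The surrogate generator is a two-state caricature of liquid-cell
  physics; it grounds the pipeline, not any physical claim.
* Latent-coordinate roles (which z_i encodes which statistic) vary
  between training runs; condition-profile defaults must be checked
  against a sweep for each trained model.
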