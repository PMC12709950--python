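# Methods

## Observation model

Cumulative germination of one seed lot is modelled as
y(t) = g(t, θ) + η with the Gompertz sigmoid
g(t, θ) = a·exp(−b·exp(−c·t)) and i.i.d. centred Gaussian noise
η ~ N(0, σ_η²). Units are hours and percent throughout, with the time
origin at sowing. The canonical acquisition grid is 0, 2, …, 168 h
(N = 85 points). The parameters are a > 0 (final germination rate, %),
b > 0 (dimensionless shape factor related to germination speed) and
c > 0 (h⁻¹, homogeneity of the lot); since t₅₀ couples all three, the
docstrings deliberately avoid over-interpreting b and c individually.
Observed values are *never* clipped to [0, 100]: the noise is Gaussian,
so small excursions outside the physical range are part of the model,
and clipping would bias the estimators' likelihoods.

t₅₀ = −(1/c)·ln(−(1/b)·ln(50/a)) requires a > 50 and raises an error
otherwise rather than returning NaN; silent NaNs would otherwise leak
into cohort bias averages. A negative t₅₀ (curve crossing 50 % before
t = 0) is allowed and returned as-is.

## Least-squares fitting

`fit_gompertz` minimises the residual sum of squares over (a, b, c)
with positivity bounds. Initialisation: a₀ = max(y) (floored at 1),
then b₀, c₀ from a linear fit of ln(−ln(y/a₀′)) against t over the
rising part of the sigmoid, with a small multi-start grid
(b₀, c₀ scaled by ×0.5/×2) as fallback. The residual std uses
denominator n − 3. The fit is deterministic; degenerate inputs (flat
data, < 4 points) raise a fit-failure error carrying the best iterate.

## Priors from the training cohort

All prior knowledge comes from one normal-speed training cohort
(default size 99). Per-curve fits give the importance-sampling particle
set, their mean/covariance the Kalman initialisation, their exact
min/max the uniform bounds for Metropolis and the particle filter
(an optional widening factor exists, default 0 for reproducibility),
and the per-curve residual stds give σ_η's training average and its
[min, max] bounds — the only cohort statistic available for a σ_η
prior. The raw curves (including any that failed to fit — the GP is
data-centric, not fit-dependent) give the empirical mean curve and
85×85 covariance, regularised with 1e-8 diagonal jitter.

Speed groups use t₅₀ quartiles with the linear-interpolation quantile
convention (group membership can shift at ties): fast below Q1, slow
above Q3, normal between.

## The five estimators

The predictive standard deviation σ_{ŷₙ|ỹ} is the uncertainty of a
*future noisy measurement*, so observation noise is folded into it by
default (`includes_noise=True`, recorded in every estimate); the
latent-curve convention is available by flag.

* **IS** — particles are the training fits; log-weights are the
  Gaussian log-likelihood of the kept data with σ_η fixed to the
  training average, normalised by log-sum-exp (mandatory in all weight
  computations here). Diagnostics: effective sample size 1/Σw², max
  weight.
* **MCMC** — random-walk Metropolis over (a, b, c, σ_η) under uniform
  priors on the training bounds, initialised at the training means.
  Proposal std per coordinate is 5 % of its bound width (zero-width
  coordinates stay fixed), burn-in 20 %, no thinning; the acceptance
  rate is exposed so users can retune. Out-of-bound proposals have
  prior density zero and are rejected. The predictive variance is
  Var(g draws) + E[σ_η²] over the posterior draws — deterministic
  given the chain. The inner loop is numba-compiled because the
  acquisition loop reruns a chain at every candidate.
* **GP** — the joint prior over the grid measurement vector is
  N(curve mean, curve covariance + σ_η²·I); prediction is partitioned-
  Gaussian conditioning on the kept coordinates, with jitter escalation
  (up to 1e-4) if the conditioning block is singular. This empirical,
  non-stationary prior is the default because germination curves are
  strongly non-stationary; it is data-centric rather than kernel-based.
  Because bias metrics need a parameter vector from every method, the
  GP bridges back by least-squares fitting its full-grid posterior
  mean.
* **EKF** — static state θ with identity transition; process noise
  Q = q·I with q = 0 by default (a small q is available to guard
  divergence). Initial state/covariance are the training fit moments;
  the measurement is linearised through the analytic parameter
  gradient; updates use the Joseph form plus symmetrisation, and the
  state is floored at 1e-6 to stay in the Gompertz domain. σ_η is
  fixed to the training average.
* **SIR** — 2000 particles over (a, b, c, σ_η) drawn uniformly inside
  the training bounds; static dynamics, likelihood weight updates,
  systematic resampling (the lowest-variance standard scheme) when the
  effective sample size falls below half the particle count, followed
  by Gaussian roughening with std 1 % of each bound width (clipped back
  to bounds) against static-parameter impoverishment.

Default sampler sizes are 99 (IS, the training-cohort fits), 10 000
(MCMC) and 2000 (SIR). On the linear sub-case where only `a` is
uncertain, EKF and GP coincide exactly with the conjugate-Gaussian
posterior predictive, and IS/MCMC/SIR agree within Monte-Carlo error —
the main correctness anchor of the test suite.

## Acquisition loop

Three seed measurements at 0, 8 and 16 h (grid values y₁, y₅, y₉)
bootstrap the posterior; they guarantee non-zero observed signal. Every
other grid time is then visited in time order; the estimator is queried
for σ_{ŷₙ|ỹ} *before* the value is observed (the decision can never
depend on the value it decides about), and the point is kept iff
σ_{ŷₙ|ỹ} > σ_T (strict: ties skip, a measure-zero event in practice).
Batch estimators (IS, MCMC, GP) recondition on the whole kept set at
every candidate; sequential ones (EKF, SIR) assimilate kept points as
they arrive. The loop ends at the last grid point (168 h). A
curve-source abstraction delivers values on demand, so skipped
candidates are provably never read — in a deployment the camera is
simply not triggered. Per-candidate MCMC seeds are derived
deterministically from the run seed, making replays bit-identical.

The final reconstruction ŷ is g(t, θ̂) over the full grid from the
final posterior parameter estimate (for GP: the posterior mean curve,
with θ̂ from the bridge fit).

## Metrics

Compression rate N_s/N; distortion MSE(ŷ, y) against the *observed*
full curve (zero MSE would mean standard periodic sampling);
t₅₀ error t₅₀(θ) − t₅₀(θ̂) (positive ⇒ germination appears faster than
it is) and parameter biases a − â etc., where the reference θ is the
full-grid least-squares fit, i.e. what periodic sampling would have
estimated. Cohort values are means over test instances with the 95 %
half-width U = t₉₅%·Std/√N_ex (sample std, ddof 1) — U is interpreted
as the conventional standard-error-based confidence half-width.
Instances with undefined t₅₀ are excluded from the bias averages and
counted. Reported "log MSE" is the natural log of the mean MSE (log10
by flag). When a table is requested at a target compression (default
0.2), each instance contributes its sweep entry with compression
nearest the target, ties breaking toward the lower threshold.

## Synthetic cohorts

The generator draws, per curve, a ~ N(95, 3²) truncated to (50, 100]
(t₅₀ must exist), ln b ~ N(ln 20, 0.3²), c ~ N(0.08, 0.015²) truncated
positive, and adds noise with σ_η = 2 %. These presets describe a
well-germinating lot with ~9 h spread in t₅₀; they are package
defaults chosen to be biologically plausible for temperate forage
seed, not estimates from any particular data set — when real training
CSVs are supplied, priors are built from them instead. Fast/slow
cohorts scale c by ×1.6/×0.6, moving the cohort's t₅₀ across the
quartile boundaries while leaving the final-rate distribution fixed,
mimicking genotype or temperature effects. What the simulator does
*not* emulate: counting quantisation (real germination counts are
integer-valued steps), autocorrelated detection errors, and plateau
heteroscedasticity — so passing tests demonstrate correctness of the
inference machinery under the stated model, not robustness to every
artefact of real imaging data.

## Experiment scale and numerics

Threshold sweeps default to 240 linearly spaced values in [0.1, 12] %
(linear is the simplest reading of the range; log spacing by flag),
wide enough to span compression from the 3-seed floor 3/85 to 1.
The package's own experiments run the MCMC sampler at chain length
2000 for sweep-scale studies — the acceptance script and the heavier
tests use a 99-curve training cohort, a 20-curve test cohort and this
chain length — while the single-run default stays at 10 000. Per-cell
sweep seeds derive from (master seed, curve index, threshold index).
Degenerate situations are surfaced, not smoothed over: underflowed
weights, stuck chains, non-PSD covariances and unfittable curves all
raise typed errors.

## Known limitations

* The GP's parameter bridge (fit of the posterior mean) inherits the
  fit's sensitivity when few points are kept early in a run.
* Static-parameter SIR remains vulnerable to impoverishment at very
  long kept sequences despite roughening.
* The EKF linearisation can bias predictions when the prior is wide
  relative to the curvature of g in θ.
* A kernel-based GP variant and an unscented filter are deliberately
  out of scope.
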