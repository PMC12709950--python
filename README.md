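# germisample

Bayesian adaptive sampling for seed-germination monitoring.

## The problem

Germination phenotyping rigs image trays of seeds on a fixed cadence —
here every 2 h for a week, a timeline **t** = [0, 2, …, 168] h of
N = 85 acquisitions — and count the cumulative percentage of germinated
seeds. Most of those images are redundant: before imbibition nothing
happens, and after the plateau nothing changes. `germisample` decides
*online* which acquisitions are worth taking. A Bayesian estimator,
fed the measurements kept so far plus priors from a historical training
cohort, predicts the next measurement ŷₙ and its uncertainty
σ_{ŷₙ|ỹ}; the camera fires only when σ_{ŷₙ|ỹ} exceeds a threshold
σ_T. Skipped time points are never measured at all.

## The model

Cumulative germination follows a Gompertz sigmoid observed under
i.i.d. Gaussian noise:

    y(t) = g(t, θ) + η,   g(t, θ) = a·exp(−b·exp(−c·t)),   η ~ N(0, σ_η²)

with θ = (a, b, c): `a` the final germination rate (%), `b` a
speed-related shape factor, `c` the homogeneity rate (h⁻¹). The
certification metric t₅₀ = −(1/c)·ln(−(1/b)·ln(50/a)) is the time to
50 % germination; cohorts are classed fast/normal/slow by t₅₀
quartiles.

Five interchangeable estimators drive the acquisition loop, all
conditioning on a normal-speed training cohort:

| method | posterior machinery | prior from training set |
|--------|--------------------|--------------------------|
| IS     | importance sampling, 99 particles | per-curve Gompertz fits |
| MCMC   | random-walk Metropolis, 10 000 iterations | uniform on parameter min/max |
| GP     | Gaussian conditioning on the 2-h grid | empirical curve mean/covariance |
| EKF    | extended Kalman filter, static state | Gaussian (fit mean/covariance) |
| SIR    | particle filter, 2000 particles | uniform on parameter min/max |

Runs are scored by compression rate N_s/N (fraction of acquisitions
kept), distortion MSE(ŷ, y) against the fully sampled signal, and bias
of t₅₀ and (a, b, c) against the full-data least-squares fit, with
95 % half-widths U = t₉₅% · Std/√N_ex.

## Worked example

```python
import numpy as np
import germisample as gs

# historical training cohort and one new lot to monitor
train, _ = gs.generate_cohort(gs.CohortSpec(n_curves=99, rng_seed=42))
priors = gs.build_priors(train)
lot = gs.simulate_curve(gs.GompertzParams(95, 20, 0.08), 2.0,
                        gs.Timeline.canonical(), rng=7)

cfg = gs.EstimatorConfig(method="MCMC", n_samples=2000)
res = gs.run_adaptive(lot, cfg, priors, sigma_T=2.65)
print(f"kept {res.n_kept}/85 acquisitions (compression {res.compression:.3f})")
print(f"distortion MSE = {gs.mse(res.y_hat, lot.values):.2f} %^2")
print(f"theta_hat = {res.theta_hat.theta_hat}")
```

prints

```
kept 18/85 acquisitions (compression 0.212)
distortion MSE = 3.04 %^2
theta_hat = GompertzParams(a=94.30621473982067, b=20.795321305080392, c=0.07952105020669588)
```

i.e. at threshold σ_T = 2.65 % the sampler kept 18 of 85 images — a
compression rate close to 0.2 — while reconstructing the germination
curve to within roughly the σ_η = 2 % observation-noise floor
(MSE ≈ σ_η²), and recovering parameters close to the simulated truth
(95, 20, 0.08).

The same pipeline is scriptable from a shell:

```
germisample simulate  --n-curves 99 --seed 42 --out train.csv
germisample simulate  --n-curves 20 --seed 43 --out test.csv
germisample fit-priors --training-csv train.csv --out priors.json
germisample sweep  --test-csv test.csv --priors-json priors.json \
                   --method MCMC --mcmc-samples 2000 --seed 0 --out sweep.csv
germisample report --sweep-csv sweep.csv --out-dir report/
```

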