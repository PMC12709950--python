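"""Five Bayesian predictive-uncertainty estimators.

All five answer the same question during adaptive acquisition: given the
measurements kept so far (values ``kept_y`` at hours ``kept_t``) and the
training-cohort priors, what are the mean and standard deviation of the
*next measurement* at a query time?  The predictive std is the quantity
compared against the acquisition threshold, so by default it includes
the observation-noise floor (``includes_noise=True``): it is the
uncertainty of a future noisy reading, not of the latent curve.

Methods and their priors:

* IS  — importance sampling over the 99 per-curve training fits;
        noise std fixed to the training average.
* MCMC — random-walk Metropolis over (a, b, c, sigma_eta) under uniform
        priors bounded by the training min/max; chain of 10 000 by
        default, 20 % burn-in.  The inner loop is numba-compiled because
        the acquisition loop reruns a chain at every 2-h candidate.
* GP  — Gaussian conditioning on the acquisition grid under the
        empirical mean/covariance of the raw training curves (plus
        sigma_eta^2 on the diagonal); non-parametric and data-centric.
* EKF — extended Kalman filter with static parameter state theta,
        Gaussian prior N(training mean, training covariance), Gompertz
        measurement linearised through its parameter gradient.
* SIR — sequential importance resampling particle filter: 2000
        particles over (a, b, c, sigma_eta) drawn from the uniform
        training-bound priors, systematic resampling below half
        effective sample size, Gaussian roughening against static-state
        impoverishment.

IS, MCMC and GP are batch methods (recondition on the whole kept set);
EKF and SIR are sequential (assimilate measurements one by one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .model import (
    GompertzParams,
    Timeline,
    fit_gompertz,
    gompertz,
    gompertz_jacobian,
)
from .priors import PriorLibrary

__all__ = [
    "DegenerateWeightsError",
    "ChainStuckError",
    "FilterDivergenceError",
    "GPConditioningError",
    "PredictiveEstimate",
    "ThetaEstimate",
    "EstimatorConfig",
    "DEFAULT_SAMPLES",
    "is_predict",
    "mcmc_predict",
    "gp_predict",
    "gp_posterior_curve",
    "ExtendedKalmanFilter",
    "SIRParticleFilter",
    "ekf_run",
    "sir_run",
]


class DegenerateWeightsError(RuntimeError):
    """All importance/particle weights underflowed to zero."""


class ChainStuckError(RuntimeError):
    """Metropolis chain accepted no proposal over the whole run."""


class FilterDivergenceError(RuntimeError):
    """Kalman covariance lost positive semidefiniteness."""


class GPConditioningError(RuntimeError):
    """GP conditioning matrix stayed singular beyond the jitter budget."""


@dataclass(frozen=True)
class PredictiveEstimate:
    """Predictive mean/std (percent) of the measurement at the query time."""

    mean: float
    std: float
    includes_noise: bool = True


@dataclass
class ThetaEstimate:
    """Posterior point estimate of (theta, sigma_eta) with diagnostics."""

    theta_hat: GompertzParams
    sigma_eta_hat: float
    method: str
    diagnostics: Dict[str, float] = field(default_factory=dict)


DEFAULT_SAMPLES = {"IS": 99, "MCMC": 10_000, "SIR": 2_000}

METHODS = ("IS", "MCMC", "GP", "EKF", "SIR")


@dataclass
class EstimatorConfig:
    """Tunables shared by the five estimators.

    ``n_samples`` defaults per method (IS 99, MCMC 10 000, SIR 2000);
    for IS the particle set is the training fits themselves, so the
    effective count is the training-cohort size.
    """

    method: str = "MCMC"
    n_samples: Optional[int] = None
    burn_in_fraction: float = 0.2
    proposal_scale_fraction: float = 0.05
    process_noise: float = 0.0
    roughening_scale: float = 0.01
    resample_threshold_fraction: float = 0.5
    includes_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.n_samples is not None and self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for name in ("burn_in_fraction", "resample_threshold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def resolved_samples(self) -> int:
        if self.n_samples is not None:
            return int(self.n_samples)
        return DEFAULT_SAMPLES.get(self.method, 1)


def _as_1d(x) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if a.ndim != 1:
        raise ValueError("expected a 1-D vector")
    return a


def _gompertz_mat(t: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """g(t_i, theta_j) for t (n,) and thetas (m, 3) -> (m, n)."""
    a = thetas[:, 0:1]
    b = thetas[:, 1:2]
    c = thetas[:, 2:3]
    return a * np.exp(-b * np.exp(-c * t[None, :]))


# ---------------------------------------------------------------------------
# Importance sampling
# ---------------------------------------------------------------------------

def is_predict(
    kept_t,
    kept_y,
    t_query: float,
    priors: PriorLibrary,
    cfg: Optional[EstimatorConfig] = None,
) -> Tuple[PredictiveEstimate, ThetaEstimate]:
    """Importance sampling over the training parameter fits.

    Particles are the per-curve training fits; weights are the Gaussian
    likelihood of the kept data with sigma_eta fixed to the training
    average.  With no kept data the weights are uniform and the
    prediction is the prior predictive over the particle set.
    """
    cfg = cfg or EstimatorConfig(method="IS")
    kt, ky = _as_1d(kept_t), _as_1d(kept_y)
    if kt.size != ky.size:
        raise ValueError("kept_t and kept_y must have equal length")
    thetas = np.array([p.as_array() for p in priors.param_samples])
    sigma = priors.sigma_eta_mean
    m = thetas.shape[0]

    if kt.size == 0:
        logw = np.zeros(m)
    else:
        g = _gompertz_mat(kt, thetas)
        logw = -0.5 * np.sum(((ky[None, :] - g) / sigma) ** 2, axis=1)

    norm = logsumexp(logw)
    if not np.isfinite(norm):
        raise DegenerateWeightsError("all importance weights underflowed")
    w = np.exp(logw - norm)

    gq = _gompertz_mat(np.array([t_query]), thetas)[:, 0]
    mean = float(np.sum(w * gq))
    var = float(np.sum(w * (gq - mean) ** 2))
    if cfg.includes_noise:
        var += sigma**2
    theta_hat = GompertzParams.from_array(w @ thetas)
    est = ThetaEstimate(
        theta_hat=theta_hat,
        sigma_eta_hat=sigma,
        method="IS",
        diagnostics={
            "ess": float(1.0 / np.sum(w**2)),
            "max_weight": float(w.max()),
        },
    )
    return PredictiveEstimate(mean, float(np.sqrt(var)), cfg.includes_noise), est


# ---------------------------------------------------------------------------
# Random-walk Metropolis (numba-compiled inner loop)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _loglik(kept_t, kept_y, a, b, c, sigma):  # pragma: no cover - jitted
    n = kept_t.size
    if n == 0:
        return 0.0
    ll = -n * np.log(sigma)
    for i in range(n):
        g = a * np.exp(-b * np.exp(-c * kept_t[i]))
        r = (kept_y[i] - g) / sigma
        ll -= 0.5 * r * r
    return ll


@njit(cache=True)
def _rw_metropolis(kept_t, kept_y, lo, hi, init, scales, n_iter, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    d = 4
    chain = np.empty((n_iter, d))
    cur = init.copy()
    cur_ll = _loglik(kept_t, kept_y, cur[0], cur[1], cur[2], cur[3])
    n_acc = 0
    prop = np.empty(d)
    for m in range(n_iter):
        ok = True
        for k in range(d):
            if scales[k] == 0.0:
                prop[k] = cur[k]
            else:
                prop[k] = cur[k] + scales[k] * np.random.standard_normal()
                if prop[k] < lo[k] or prop[k] > hi[k]:
                    ok = False
        if ok:
            pll = _loglik(kept_t, kept_y, prop[0], prop[1], prop[2], prop[3])
            if np.log(np.random.random()) < pll - cur_ll:
                for k in range(d):
                    cur[k] = prop[k]
                cur_ll = pll
                n_acc += 1
        chain[m, :] = cur
    return chain, n_acc


def _mcmc_bounds(priors: PriorLibrary) -> Tuple[np.ndarray, np.ndarray]:
    lo = np.append(priors.param_bounds[:, 0], priors.sigma_eta_bounds[0])
    hi = np.append(priors.param_bounds[:, 1], priors.sigma_eta_bounds[1])
    return lo, hi


def mcmc_predict(
    kept_t,
    kept_y,
    t_query: float,
    priors: PriorLibrary,
    cfg: Optional[EstimatorConfig] = None,
) -> Tuple[PredictiveEstimate, ThetaEstimate]:
    """Random-walk Metropolis over (a, b, c, sigma_eta).

    Uniform priors on the training min/max bounds; chain initialised at
    the training means; per-coordinate proposal std is
    ``proposal_scale_fraction`` of the bound width (coordinates with
    zero-width bounds stay fixed).  The predictive distribution at the
    query time is summarised from the post-burn-in draws; its variance
    adds the posterior mean of sigma_eta^2 when ``includes_noise``.
    """
    cfg = cfg or EstimatorConfig(method="MCMC")
    kt, ky = _as_1d(kept_t), _as_1d(kept_y)
    if kt.size != ky.size:
        raise ValueError("kept_t and kept_y must have equal length")
    lo, hi = _mcmc_bounds(priors)
    init = np.append(priors.param_mean, priors.sigma_eta_mean)
    init = np.clip(init, lo, hi)
    if init[3] <= 0:
        init[3] = max(init[3], 1e-6)
    scales = cfg.proposal_scale_fraction * (hi - lo)
    n_iter = cfg.resolved_samples()
    seed = int(cfg.rng_seed) % (2**31 - 1)

    chain, n_acc = _rw_metropolis(kt, ky, lo, hi, init, scales, n_iter, seed)
    movable = np.any(scales > 0)
    if movable and n_acc == 0:
        raise ChainStuckError("Metropolis chain accepted no proposal")

    burn = int(cfg.burn_in_fraction * n_iter)
    draws = chain[burn:]
    gq = _gompertz_mat(np.array([t_query]), draws[:, :3])[:, 0]
    mean = float(gq.mean())
    var = float(gq.var())
    if cfg.includes_noise:
        var += float(np.mean(draws[:, 3] ** 2))
    post = draws.mean(axis=0)
    est = ThetaEstimate(
        theta_hat=GompertzParams.from_array(post[:3]),
        sigma_eta_hat=float(post[3]),
        method="MCMC",
        diagnostics={"acceptance_rate": n_acc / n_iter, "n_iter": float(n_iter)},
    )
    return PredictiveEstimate(mean, float(np.sqrt(var)), cfg.includes_noise), est


# ---------------------------------------------------------------------------
# Gaussian process on the acquisition grid
# ---------------------------------------------------------------------------

_GP_JITTERS = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


def _gp_condition(
    kept_idx: np.ndarray,
    kept_y: np.ndarray,
    query_idx: np.ndarray,
    priors: PriorLibrary,
) -> Tuple[np.ndarray, np.ndarray]:
    """Partitioned-Gaussian conditioning of the grid measurement vector.

    The joint prior over the full measurement vector is
    N(curve_mean, curve_cov + sigma_eta^2 I); conditioning on the kept
    coordinates gives the posterior mean and variance at the queries.
    """
    mu = priors.curve_mean
    C = priors.curve_cov + priors.sigma_eta_mean**2 * np.eye(mu.size)
    if kept_idx.size == 0:
        return mu[query_idx], np.diag(C)[query_idx].copy()
    Ckk = C[np.ix_(kept_idx, kept_idx)]
    Cqk = C[np.ix_(query_idx, kept_idx)]
    resid = kept_y - mu[kept_idx]
    for jit in _GP_JITTERS:
        try:
            L = np.linalg.cholesky(Ckk + jit * np.eye(kept_idx.size))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise GPConditioningError("conditioning matrix singular beyond jitter 1e-4")
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, resid))
    V = np.linalg.solve(L, Cqk.T)
    mean = mu[query_idx] + Cqk @ alpha
    var = np.diag(C)[query_idx] - np.sum(V**2, axis=0)
    return mean, np.clip(var, 0.0, None)


def gp_posterior_curve(
    kept_t,
    kept_y,
    priors: PriorLibrary,
) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior mean/variance of the full-grid measurement vector."""
    kt, ky = _as_1d(kept_t), _as_1d(kept_y)
    kidx = np.array([priors.timeline.index_of(t) for t in kt], dtype=int)
    qidx = np.arange(priors.timeline.n_total)
    return _gp_condition(kidx, ky, qidx, priors)


def gp_predict(
    kept_t,
    kept_y,
    t_query: float,
    priors: PriorLibrary,
    cfg: Optional[EstimatorConfig] = None,
    estimate_theta: bool = True,
) -> Tuple[PredictiveEstimate, Optional[ThetaEstimate]]:
    """Gaussian-process prediction on the 2-h grid.

    Non-parametric: the prior is the empirical mean/covariance of the
    raw training curves.  Because a Gompertz parameter vector is still
    needed for bias metrics, ``estimate_theta=True`` bridges back to the
    parametric world by least-squares fitting the full-grid posterior
    mean (skip it during acquisition walks, where only the std is used).
    """
    cfg = cfg or EstimatorConfig(method="GP")
    kt, ky = _as_1d(kept_t), _as_1d(kept_y)
    if kt.size != ky.size:
        raise ValueError("kept_t and kept_y must have equal length")
    kidx = np.array([priors.timeline.index_of(t) for t in kt], dtype=int)
    qidx = np.array([priors.timeline.index_of(t_query)], dtype=int)
    mean, var = _gp_condition(kidx, ky, qidx, priors)
    pred = PredictiveEstimate(float(mean[0]), float(np.sqrt(var[0])), cfg.includes_noise)

    est = None
    if estimate_theta:
        post_mean, _ = gp_posterior_curve(kt, ky, priors)
        theta_hat, _ = fit_gompertz(priors.timeline.times, post_mean)
        est = ThetaEstimate(
            theta_hat=theta_hat,
            sigma_eta_hat=priors.sigma_eta_mean,
            method="GP",
            diagnostics={"n_kept": float(kt.size)},
        )
    return pred, est


# ---------------------------------------------------------------------------
# Extended Kalman filter
# ---------------------------------------------------------------------------

_EKF_FLOOR = 1e-6


class ExtendedKalmanFilter:
    """EKF with static Gompertz-parameter state.

    State theta = (a, b, c); identity transition with process noise
    Q = process_noise * I (0 by default, i.e. truly static).  The
    measurement h(theta) = g(t, theta) is linearised through the
    parameter gradient; sigma_eta is fixed to the training average.
    The state is floored at a tiny positive value so it stays inside
    the Gompertz parameter domain after updates.
    """

    def __init__(self, priors: PriorLibrary, cfg: Optional[EstimatorConfig] = None):
        cfg = cfg or EstimatorConfig(method="EKF")
        self.cfg = cfg
        self.x = priors.param_mean.copy()
        self.P = priors.param_cov.copy()
        self.sigma_eta = priors.sigma_eta_mean
        self.Q = cfg.process_noise * np.eye(3)
        self.n_updates = 0

    def _theta(self) -> GompertzParams:
        return GompertzParams.from_array(np.maximum(self.x, _EKF_FLOOR))

    def predict(self, t_query: float) -> PredictiveEstimate:
        theta = self._theta()
        H = gompertz_jacobian(t_query, theta)
        var = float(H @ self.P @ H)
        if self.cfg.includes_noise:
            var += self.sigma_eta**2
        return PredictiveEstimate(
            float(gompertz(t_query, theta)), float(np.sqrt(max(var, 0.0))),
            self.cfg.includes_noise,
        )

    def assimilate(self, t: float, y: float) -> None:
        self.P = self.P + self.Q
        theta = self._theta()
        H = gompertz_jacobian(t, theta)
        S = float(H @ self.P @ H) + self.sigma_eta**2
        K = (self.P @ H) / S
        self.x = self.x + K * (y - gompertz(t, theta))
        IKH = np.eye(3) - np.outer(K, H)
        # Joseph form keeps P symmetric positive semidefinite
        self.P = IKH @ self.P @ IKH.T + self.sigma_eta**2 * np.outer(K, K)
        self.P = 0.5 * (self.P + self.P.T)
        if np.min(np.linalg.eigvalsh(self.P)) < -1e-8:
            raise FilterDivergenceError("covariance lost positive semidefiniteness")
        self.x = np.maximum(self.x, _EKF_FLOOR)
        self.n_updates += 1

    def theta_estimate(self) -> ThetaEstimate:
        return ThetaEstimate(
            theta_hat=self._theta(),
            sigma_eta_hat=self.sigma_eta,
            method="EKF",
            diagnostics={"trace_P": float(np.trace(self.P)),
                         "n_updates": float(self.n_updates)},
        )


def ekf_run(
    kept_stream: Iterable[Tuple[float, float]],
    query_times: Sequence[float],
    priors: PriorLibrary,
    cfg: Optional[EstimatorConfig] = None,
) -> Tuple[List[PredictiveEstimate], ThetaEstimate]:
    """Assimilate a (t, y) stream in order, then predict at each query time."""
    f = ExtendedKalmanFilter(priors, cfg)
    for t, y in kept_stream:
        f.assimilate(t, y)
    preds = [f.predict(t) for t in query_times]
    return preds, f.theta_estimate()


# ---------------------------------------------------------------------------
# SIR particle filter
# ---------------------------------------------------------------------------

class SIRParticleFilter:
    """Sequential importance resampling over (a, b, c, sigma_eta).

    Particles are drawn uniformly inside the training bounds; dynamics
    are static, so weights accumulate likelihood terms until the
    effective sample size drops below ``resample_threshold_fraction`` of
    the particle count, triggering systematic resampling followed by
    Gaussian roughening (std = ``roughening_scale`` x bound width per
    coordinate, clipped back into the bounds) to fight impoverishment.
    """

    def __init__(self, priors: PriorLibrary, cfg: Optional[EstimatorConfig] = None):
        cfg = cfg or EstimatorConfig(method="SIR")
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.rng_seed)
        lo, hi = _mcmc_bounds(priors)
        self.lo, self.hi = lo, hi
        n = cfg.resolved_samples()
        self.particles = self.rng.uniform(lo, hi, size=(n, 4))
        if np.any(self.particles[:, 3] <= 0):
            self.particles[:, 3] = np.maximum(self.particles[:, 3], 1e-6)
        self.logw = np.zeros(n)
        self.n_resample = 0

    def _weights(self) -> np.ndarray:
        norm = logsumexp(self.logw)
        if not np.isfinite(norm):
            raise DegenerateWeightsError("all particle weights underflowed")
        return np.exp(self.logw - norm)

    def ess(self) -> float:
        w = self._weights()
        return float(1.0 / np.sum(w**2))

    def predict(self, t_query: float) -> PredictiveEstimate:
        w = self._weights()
        gq = _gompertz_mat(np.array([float(t_query)]), self.particles[:, :3])[:, 0]
        mean = float(np.sum(w * gq))
        var = float(np.sum(w * (gq - mean) ** 2))
        if self.cfg.includes_noise:
            var += float(np.sum(w * self.particles[:, 3] ** 2))
        return PredictiveEstimate(mean, float(np.sqrt(var)), self.cfg.includes_noise)

    def assimilate(self, t: float, y: float) -> None:
        g = _gompertz_mat(np.array([float(t)]), self.particles[:, :3])[:, 0]
        sig = self.particles[:, 3]
        self.logw = self.logw - np.log(sig) - 0.5 * ((y - g) / sig) ** 2
        n = self.particles.shape[0]
        if self.ess() < self.cfg.resample_threshold_fraction * n:
            self._resample()

    def _resample(self) -> None:
        w = self._weights()
        n = w.size
        positions = (self.rng.random() + np.arange(n)) / n
        idx = np.searchsorted(np.cumsum(w), positions)
        idx = np.clip(idx, 0, n - 1)
        self.particles = self.particles[idx]
        if self.cfg.roughening_scale > 0:
            width = self.hi - self.lo
            jitter = self.rng.normal(0.0, 1.0, size=self.particles.shape)
            self.particles = self.particles + self.cfg.roughening_scale * width * jitter
            self.particles = np.clip(self.particles, self.lo, self.hi)
            self.particles[:, 3] = np.maximum(self.particles[:, 3], 1e-6)
        self.logw = np.zeros(n)
        self.n_resample += 1

    def theta_estimate(self) -> ThetaEstimate:
        w = self._weights()
        post = w @ self.particles
        return ThetaEstimate(
            theta_hat=GompertzParams.from_array(np.maximum(post[:3], 1e-9)),
            sigma_eta_hat=float(post[3]),
            method="SIR",
            diagnostics={"ess": self.ess(), "n_resample": float(self.n_resample)},
        )


def sir_run(
    kept_stream: Iterable[Tuple[float, float]],
    query_times: Sequence[float],
    priors: PriorLibrary,
    cfg: Optional[EstimatorConfig] = None,
) -> Tuple[List[PredictiveEstimate], ThetaEstimate]:
    """Assimilate a (t, y) stream in order, then predict at each query time."""
    f = SIRParticleFilter(priors, cfg)
    for t, y in kept_stream:
        f.assimilate(t, y)
    preds = [f.predict(t) for t in query_times]
    return preds, f.theta_estimate()
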