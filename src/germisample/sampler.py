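"""Threshold-based adaptive acquisition over the 2-h grid.

The loop walks the acquisition grid, asks the configured estimator for
the predictive standard deviation of the candidate measurement *before*
looking at it, and keeps (i.e. triggers the camera for) the measurement
only when that uncertainty exceeds the threshold sigma_T.  Three seed
measurements at 0, 8 and 16 h bootstrap the posterior; everything later
is conditional on what was actually kept, so the same loop can drive a
stored curve or a live rig through the curve-source abstraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Protocol, Union

import numpy as np

from .estimators import (
    EstimatorConfig,
    ExtendedKalmanFilter,
    PredictiveEstimate,
    SIRParticleFilter,
    ThetaEstimate,
    gp_posterior_curve,
    gp_predict,
    is_predict,
    mcmc_predict,
)
from .model import GerminationCurve, GompertzParams, Timeline, gompertz
from .priors import PriorLibrary

__all__ = [
    "CurveSource",
    "ArraySource",
    "SigmaRecord",
    "AdaptiveResult",
    "run_adaptive",
    "reconstruct",
    "SEED_TIMES",
]

SEED_TIMES = (0.0, 8.0, 16.0)

_BATCH = {"IS": is_predict, "MCMC": mcmc_predict}
_SEQUENTIAL = {"EKF": ExtendedKalmanFilter, "SIR": SIRParticleFilter}


class CurveSource(Protocol):
    """Anything that can be measured at a grid index on demand."""

    timeline: Timeline

    def read(self, index: int) -> float:  # pragma: no cover - protocol
        ...


class ArraySource:
    """Curve source backed by an already-recorded :class:`GerminationCurve`."""

    def __init__(self, curve: GerminationCurve):
        self.timeline = curve.timeline
        self._values = curve.values

    def read(self, index: int) -> float:
        return float(self._values[index])


class SigmaRecord(NamedTuple):
    time: float
    predictive_std: float
    kept: bool


@dataclass
class AdaptiveResult:
    """Outcome of one adaptive run: what was kept and what was inferred."""

    kept_times: np.ndarray
    kept_values: np.ndarray
    n_kept: int
    sigma_trace: List[SigmaRecord]
    theta_hat: ThetaEstimate
    y_hat: np.ndarray
    threshold: float
    estimator: str

    @property
    def compression(self) -> float:
        return self.n_kept / self.y_hat.size


def reconstruct(theta_hat: GompertzParams, timeline: Timeline) -> np.ndarray:
    """Model reconstruction over the full grid from a parameter estimate."""
    return np.asarray(gompertz(timeline.times, theta_hat))


def _candidate_seed(base_seed: int, index: int) -> int:
    # decorrelates per-candidate chains while staying reproducible
    return int((base_seed * 1_000_003 + index * 7919 + 1) % (2**31 - 1))


def run_adaptive(
    curve: Union[GerminationCurve, CurveSource],
    estimator_cfg: EstimatorConfig,
    priors: PriorLibrary,
    sigma_T: float,
) -> AdaptiveResult:
    """Run the acquisition loop at threshold ``sigma_T`` (percent).

    Candidates are every grid time outside the three seeds, visited in
    time order; a candidate is kept iff its predictive std strictly
    exceeds the threshold, and its value is read from the source only
    then.  Batch estimators (IS, MCMC, GP) recondition on the whole kept
    set at every candidate; sequential ones (EKF, SIR) assimilate kept
    points as they arrive.  MCMC derives a fresh per-candidate seed from
    ``estimator_cfg.rng_seed`` so replays are bit-identical.
    """
    if sigma_T < 0:
        raise ValueError("sigma_T must be >= 0")
    source: CurveSource = ArraySource(curve) if isinstance(curve, GerminationCurve) else curve
    timeline = source.timeline
    method = estimator_cfg.method

    seed_idx = [timeline.index_of(t) for t in SEED_TIMES]
    kept_idx: List[int] = list(seed_idx)
    kept_y: List[float] = [source.read(i) for i in seed_idx]

    seq = None
    if method in _SEQUENTIAL:
        seq = _SEQUENTIAL[method](priors, estimator_cfg)
        for i, y in zip(kept_idx, kept_y):
            seq.assimilate(timeline.times[i], y)

    trace: List[SigmaRecord] = []
    candidates = [i for i in range(timeline.n_total) if i not in set(seed_idx)]
    for j in candidates:
        t_q = float(timeline.times[j])
        kt = timeline.times[kept_idx]
        if method == "GP":
            pred, _ = gp_predict(kt, kept_y, t_q, priors, estimator_cfg,
                                 estimate_theta=False)
        elif method in _BATCH:
            cfg_j = estimator_cfg
            if method == "MCMC":
                cfg_j = EstimatorConfig(
                    **{**estimator_cfg.__dict__,
                       "rng_seed": _candidate_seed(estimator_cfg.rng_seed, j)}
                )
            pred, _ = _BATCH[method](kt, kept_y, t_q, priors, cfg_j)
        else:
            pred = seq.predict(t_q)
        keep = pred.std > sigma_T
        trace.append(SigmaRecord(t_q, pred.std, keep))
        if keep:
            y = source.read(j)
            kept_idx.append(j)
            kept_y.append(y)
            if seq is not None:
                seq.assimilate(t_q, y)

    kt = timeline.times[kept_idx]
    ky = np.array(kept_y)
    if method == "GP":
        post_mean, _ = gp_posterior_curve(kt, ky, priors)
        _, theta_est = gp_predict(kt, ky, float(timeline.times[-1]), priors,
                                  estimator_cfg, estimate_theta=True)
        y_hat = post_mean
    elif method in _BATCH:
        cfg_f = estimator_cfg
        if method == "MCMC":
            cfg_f = EstimatorConfig(
                **{**estimator_cfg.__dict__,
                   "rng_seed": _candidate_seed(estimator_cfg.rng_seed, timeline.n_total)}
            )
        _, theta_est = _BATCH[method](kt, ky, float(timeline.times[-1]), priors, cfg_f)
        y_hat = reconstruct(theta_est.theta_hat, timeline)
    else:
        theta_est = seq.theta_estimate()
        y_hat = reconstruct(theta_est.theta_hat, timeline)

    return AdaptiveResult(
        kept_times=kt,
        kept_values=ky,
        n_kept=len(kept_idx),
        sigma_trace=trace,
        theta_hat=theta_est,
        y_hat=y_hat,
        threshold=float(sigma_T),
        estimator=method,
    )
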