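"""Prior knowledge built from a normal-speed training cohort.

Every estimator draws on the same training set, but through different
summaries: per-curve Gompertz fits (importance-sampling particle set),
their mean and covariance (Kalman initialisation), their min/max bounds
(uniform priors for Metropolis and the particle filter), the average
residual noise level, and the raw empirical mean/covariance of the
training curves on the acquisition grid (the Gaussian-process prior).
This module also classifies cohorts into fast/normal/slow germination
speed via t50 quartiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .model import (
    FitFailureError,
    GerminationCurve,
    GompertzParams,
    Timeline,
    fit_gompertz,
    t50,
)

__all__ = [
    "InsufficientTrainingError",
    "PriorLibrary",
    "SpeedLabel",
    "build_priors",
    "classify_speed",
]

logger = logging.getLogger(__name__)

_CURVE_COV_JITTER = 1e-8


class InsufficientTrainingError(RuntimeError):
    """Fewer than 4 training curves could be fitted."""


@dataclass
class PriorLibrary:
    """All training-cohort summaries the five estimators condition on."""

    param_samples: List[GompertzParams]
    param_mean: np.ndarray          # (3,)
    param_cov: np.ndarray           # (3, 3)
    param_bounds: np.ndarray        # (3, 2) min/max per parameter
    sigma_eta_mean: float
    sigma_eta_bounds: np.ndarray    # (2,)
    curve_mean: np.ndarray          # (N,) empirical mean germination curve
    curve_cov: np.ndarray           # (N, N) empirical covariance of curves
    timeline: Timeline
    n_train: int

    def to_json(self) -> str:
        doc = {
            "param_samples": [list(p.as_array()) for p in self.param_samples],
            "param_mean": self.param_mean.tolist(),
            "param_cov": self.param_cov.tolist(),
            "param_bounds": self.param_bounds.tolist(),
            "sigma_eta_mean": self.sigma_eta_mean,
            "sigma_eta_bounds": self.sigma_eta_bounds.tolist(),
            "curve_mean": self.curve_mean.tolist(),
            "curve_cov": self.curve_cov.tolist(),
            "times": self.timeline.times.tolist(),
            "n_train": self.n_train,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PriorLibrary":
        doc = json.loads(text)
        return cls(
            param_samples=[GompertzParams.from_array(p) for p in doc["param_samples"]],
            param_mean=np.array(doc["param_mean"]),
            param_cov=np.array(doc["param_cov"]),
            param_bounds=np.array(doc["param_bounds"]),
            sigma_eta_mean=float(doc["sigma_eta_mean"]),
            sigma_eta_bounds=np.array(doc["sigma_eta_bounds"]),
            curve_mean=np.array(doc["curve_mean"]),
            curve_cov=np.array(doc["curve_cov"]),
            timeline=Timeline(doc["times"]),
            n_train=int(doc["n_train"]),
        )


@dataclass(frozen=True)
class SpeedLabel:
    """Germination-speed group of one curve: fast / normal / slow."""

    label: str
    t50_value: float


def build_priors(
    training_curves: Sequence[GerminationCurve],
    bound_widening: float = 0.0,
) -> PriorLibrary:
    """Aggregate a training cohort into a :class:`PriorLibrary`.

    Each curve is fitted by nonlinear least squares; curves whose fit
    fails are dropped from the parameter summaries (with a warning) but
    still contribute to the data-centric mean/covariance of the raw
    curves.  ``bound_widening`` optionally widens the min/max parameter
    bounds by that fraction of the observed range on each side (default
    0: bounds are the exact training min/max).
    """
    if len(training_curves) < 4:
        raise InsufficientTrainingError("need at least 4 training curves")
    timeline = training_curves[0].timeline
    for c in training_curves:
        if c.timeline != timeline:
            raise ValueError("all training curves must share one timeline")

    samples: List[GompertzParams] = []
    sigmas: List[float] = []
    for i, curve in enumerate(training_curves):
        try:
            theta_hat, sigma_hat = fit_gompertz(timeline.times, curve.values)
        except FitFailureError as exc:
            logger.warning("training curve %d (%s) failed to fit: %s", i, curve.label, exc)
            continue
        samples.append(theta_hat)
        sigmas.append(sigma_hat)

    if len(samples) < 4:
        raise InsufficientTrainingError(
            f"only {len(samples)} of {len(training_curves)} training curves fitted"
        )

    mat = np.array([p.as_array() for p in samples])
    param_mean = mat.mean(axis=0)
    param_cov = np.cov(mat, rowvar=False, ddof=1)
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    if bound_widening > 0:
        span = hi - lo
        lo, hi = lo - bound_widening * span, hi + bound_widening * span
    param_bounds = np.column_stack([lo, hi])

    sig = np.array(sigmas)
    raw = np.array([c.values for c in training_curves])
    curve_mean = raw.mean(axis=0)
    curve_cov = np.cov(raw, rowvar=False, ddof=1)
    curve_cov = curve_cov + _CURVE_COV_JITTER * np.eye(timeline.n_total)

    return PriorLibrary(
        param_samples=samples,
        param_mean=param_mean,
        param_cov=param_cov,
        param_bounds=param_bounds,
        sigma_eta_mean=float(sig.mean()),
        sigma_eta_bounds=np.array([sig.min(), sig.max()]),
        curve_mean=curve_mean,
        curve_cov=curve_cov,
        timeline=timeline,
        n_train=len(training_curves),
    )


def classify_speed(params_per_curve: Sequence[GompertzParams]) -> List[SpeedLabel]:
    """Label each curve fast/normal/slow by its t50 against cohort quartiles.

    Fast: t50 strictly below the first quartile; slow: strictly above the
    third; normal otherwise.  Quartiles use the linear-interpolation
    convention, so group membership can shift at ties.
    """
    if len(params_per_curve) < 4:
        raise ValueError("need at least 4 curves to form quartiles")
    vals = []
    for i, p in enumerate(params_per_curve):
        try:
            vals.append(t50(p))
        except Exception as exc:
            raise type(exc)(f"curve {i}: {exc}") from exc
    t50s = np.array(vals)
    q1, q3 = np.quantile(t50s, [0.25, 0.75])
    labels = []
    for v in t50s:
        if v < q1:
            lab = "fast"
        elif v > q3:
            lab = "slow"
        else:
            lab = "normal"
        labels.append(SpeedLabel(lab, float(v)))
    return labels
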