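"""Gompertz germination model.

Cumulative germination of a seed lot is modelled as a three-parameter
Gompertz sigmoid observed under i.i.d. Gaussian noise::

    y(t) = a * exp(-b * exp(-c * t)) + eta,   eta ~ N(0, sigma_eta^2)

with ``a`` the final germination rate (percent), ``b`` a dimensionless
shape factor tied to germination speed, and ``c`` (per hour) the
homogeneity of the lot.  This module holds the forward model, its
parameter gradient (used by the extended Kalman filter), the t50
certification metric, and nonlinear least-squares fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ParameterDomainError",
    "UndefinedT50Error",
    "FitFailureError",
    "GompertzParams",
    "NoiseModel",
    "Timeline",
    "GerminationCurve",
    "gompertz",
    "gompertz_jacobian",
    "t50",
    "fit_gompertz",
]


class ParameterDomainError(ValueError):
    """A Gompertz parameter is outside its domain (a, b, c must be > 0)."""


class UndefinedT50Error(ValueError):
    """t50 requested for a curve whose final rate never reaches 50 %."""


class FitFailureError(RuntimeError):
    """Nonlinear least squares failed; ``best_params`` holds the best iterate."""

    def __init__(self, message: str, best_params: Optional["GompertzParams"] = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class GompertzParams:
    """Parameter vector theta = (a, b, c) of the Gompertz growth model.

    a : final germination rate, percent, > 0
    b : germination-speed shape factor, dimensionless, > 0
    c : homogeneity rate, per hour, > 0
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterDomainError(
                    f"Gompertz parameter {name}={v!r} must be finite and > 0"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "GompertzParams":
        a, b, c = (float(x) for x in arr)
        return cls(a, b, c)


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: i.i.d. centred Gaussian with std ``sigma_eta`` (percent).

    The full-timeline covariance is diagonal, sigma_eta^2 * I.
    """

    sigma_eta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_eta) or self.sigma_eta < 0:
            raise ValueError(f"sigma_eta={self.sigma_eta!r} must be finite and >= 0")


class Timeline:
    """A uniform acquisition grid in hours.

    The canonical grid used throughout is 0, 2, ..., 168 h (85 points),
    matching a camera that images every 2 h for one week.
    """

    def __init__(self, times: Sequence[float]):
        t = np.asarray(times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("timeline needs at least two points")
        d = np.diff(t)
        if np.any(d <= 0):
            raise ValueError("timeline must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise ValueError("timeline must be uniformly spaced")
        self.times = t
        self.times.setflags(write=False)

    @classmethod
    def canonical(cls) -> "Timeline":
        return cls(np.arange(0.0, 168.0 + 1e-9, 2.0))

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_total(self) -> int:
        return int(self.times.size)

    def index_of(self, t: float) -> int:
        """Exact grid index of time ``t``; raises if ``t`` is off-grid."""
        idx = int(round((t - self.times[0]) / self.step))
        if idx < 0 or idx >= self.n_total or abs(self.times[idx] - t) > 1e-6:
            raise ValueError(f"time {t} h is not on the acquisition grid")
        return idx

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Timeline) and np.array_equal(self.times, other.times)

    def __len__(self) -> int:
        return self.n_total

    def __repr__(self) -> str:
        return (
            f"Timeline({self.times[0]:g}..{self.times[-1]:g} h, "
            f"step {self.step:g} h, n={self.n_total})"
        )


@dataclass
class GerminationCurve:
    """One seed lot's cumulative germination along a timeline.

    Values are percentages but are *not* clipped to [0, 100]: the noise is
    Gaussian, so observations may spill slightly outside.  ``true_params``
    and ``true_noise`` are set for simulated curves.
    """

    timeline: Timeline
    values: np.ndarray
    true_params: Optional[GompertzParams] = None
    true_noise: Optional[NoiseModel] = None
    label: str = field(default="")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.timeline.n_total,):
            raise ValueError(
                f"values length {self.values.size} != timeline length "
                f"{self.timeline.n_total}"
            )


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def gompertz(t, theta: GompertzParams):
    """Evaluate g(t, theta) = a*exp(-b*exp(-c*t)).

    ``t`` may be a scalar or array of non-negative hours.  The output is
    monotone non-decreasing in t and bounded in (0, a).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = theta.a * np.exp(-theta.b * np.exp(-theta.c * t))
    return out if out.ndim else float(out)


def gompertz_jacobian(t, theta: GompertzParams) -> np.ndarray:
    """Gradient of g with respect to (a, b, c), shape (..., 3).

    dg/da = exp(-b e^{-ct}),  dg/db = -a e^{-ct} exp(-b e^{-ct}),
    dg/dc = a b t e^{-ct} exp(-b e^{-ct}).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    ect = np.exp(-theta.c * t)
    core = np.exp(-theta.b * ect)
    da = core
    db = -theta.a * ect * core
    dc = theta.a * theta.b * t * ect * core
    return np.stack(np.broadcast_arrays(da, db, dc), axis=-1)


def t50(theta: GompertzParams) -> float:
    """Time (hours) at which the curve crosses 50 % germination.

    Closed form: t50 = -(1/c) * ln(-(1/b) * ln(50/a)).  Defined only when
    a > 50; may be negative when the model crosses 50 % before sowing.
    """
    if theta.a <= 50.0:
        raise UndefinedT50Error(
            f"t50 undefined: final rate a={theta.a:g} does not exceed 50 %"
        )
    inner = -math.log(50.0 / theta.a) / theta.b
    return -math.log(inner) / theta.c


# ---------------------------------------------------------------------------
# Nonlinear least-squares fitting
# ---------------------------------------------------------------------------

_BOUND_LO = 1e-8


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # a0 from the plateau; b0, c0 from the linearisation
    # ln(-ln(y/a)) = ln b - c t over the rising part of the sigmoid.
    a0 = max(float(np.max(y)), 1.0)
    a_ref = a0 * 1.001
    frac = y / a_ref
    mask = (frac > 0.01) & (frac < 0.995)
    if mask.sum() >= 2:
        z = np.log(-np.log(frac[mask]))
        slope, intercept = np.polyfit(t[mask], z, 1)
        c0 = max(-float(slope), 1e-4)
        b0 = float(np.exp(np.clip(intercept, -20, 20)))
        b0 = min(max(b0, 1e-3), 1e6)
    else:
        b0, c0 = 8.0, 0.05
    return a0, b0, c0


def fit_gompertz(
    curve_times: Sequence[float],
    curve_values: Sequence[float],
    init: Optional[GompertzParams] = None,
) -> tuple[GompertzParams, float]:
    """Least-squares Gompertz fit; returns (theta_hat, sigma_hat).

    ``sigma_hat`` is the residual standard deviation with denominator
    (n - 3).  Deterministic given inputs.  Initialisation follows a
    log-log linearisation with a small multi-start fallback; degenerate
    inputs (flat data, fewer than 4 points) raise :class:`FitFailureError`.
    """
    t = np.asarray(curve_times, dtype=float)
    y = np.asarray(curve_values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D with equal length")
    if t.size < 4:
        raise FitFailureError("need at least 4 points to fit 3 parameters")
    if np.ptp(y) < 1e-12 or np.max(y) <= 0:
        raise FitFailureError("degenerate data: values are flat or non-positive")

    def resid(p):
        return p[0] * np.exp(-p[1] * np.exp(-p[2] * t)) - y

    if init is not None:
        starts = [init.as_array()]
    else:
        a0, b0, c0 = _initial_guess(t, y)
        starts = [np.array([a0, b0, c0])]
        for fb in (0.5, 2.0):
            for fc in (0.5, 2.0):
                starts.append(np.array([a0, b0 * fb, c0 * fc]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, _BOUND_LO * 10, None)
        try:
            sol = least_squares(
                resid,
                x0,
                bounds=(_BOUND_LO, np.inf),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
        except Exception:  # pragma: no cover - scipy internal failures
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-18:
            break

    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("Gompertz fit did not converge")
    theta_hat = GompertzParams.from_array(best.x)
    dof = max(t.size - 3, 1)
    sigma_hat = float(np.sqrt(2.0 * best.cost / dof))
    return theta_hat, sigma_hat
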