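"""Synthetic germination cohorts.

Simulated curves follow the observation model exactly: a Gompertz mean
curve plus i.i.d. centred Gaussian noise on the 2-h acquisition grid.
Cohort parameters are drawn per curve from a unimodal distribution whose
defaults emulate a well-germinating temperate seed lot; they are artifact
presets, not estimates from any particular data set:

* ``a  ~ N(95, 3^2)`` truncated to (50, 100]  (final rate, percent)
* ``ln b ~ N(ln 20, 0.3^2)``                  (speed shape factor)
* ``c  ~ N(0.08, 0.015^2)`` truncated > 0     (homogeneity, per hour)
* ``sigma_eta = 2``                           (noise std, percent)

Fast and slow cohorts rescale ``c`` (x1.6 / x0.6) so the cohort's t50
moves across the quartile boundaries that define the speed groups while
the final-rate distribution stays put, mimicking genotype or temperature
shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .model import GerminationCurve, GompertzParams, NoiseModel, Timeline

__all__ = ["CohortSpec", "simulate_curve", "generate_cohort", "SPEED_C_SCALE"]

SPEED_C_SCALE = {"normal": 1.0, "fast": 1.6, "slow": 0.6}

_MAX_REDRAWS = 1000


@dataclass
class CohortSpec:
    """Recipe for one simulated cohort.

    ``a_mean/a_sd`` act on the linear scale (truncated to (50, 100]),
    ``log_b_mean/log_b_sd`` on the log scale, ``c_mean/c_sd`` linear
    truncated positive.  ``speed`` applies the preset c-scaling.
    """

    n_curves: int = 20
    speed: str = "normal"
    a_mean: float = 95.0
    a_sd: float = 3.0
    log_b_mean: float = math.log(20.0)
    log_b_sd: float = 0.3
    c_mean: float = 0.08
    c_sd: float = 0.015
    sigma_eta: float = 2.0
    timeline: Timeline = field(default_factory=Timeline.canonical)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.speed not in SPEED_C_SCALE:
            raise ValueError(f"speed must be one of {sorted(SPEED_C_SCALE)}")
        if self.sigma_eta < 0:
            raise ValueError("sigma_eta must be >= 0")


def simulate_curve(
    theta: GompertzParams,
    sigma_eta: float,
    timeline: Timeline,
    rng: np.random.Generator | int | None = None,
) -> GerminationCurve:
    """One observed curve: y_i = g(t_i, theta) + eps_i, eps_i ~ N(0, sigma_eta^2).

    Values are left unclipped, as the Gaussian noise model dictates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean = theta.a * np.exp(-theta.b * np.exp(-theta.c * timeline.times))
    noise = rng.normal(0.0, sigma_eta, size=timeline.n_total) if sigma_eta > 0 else 0.0
    return GerminationCurve(
        timeline=timeline,
        values=mean + noise,
        true_params=theta,
        true_noise=NoiseModel(sigma_eta),
    )


def _draw_theta(spec: CohortSpec, rng: np.random.Generator) -> GompertzParams:
    c_scale = SPEED_C_SCALE[spec.speed]
    for _ in range(_MAX_REDRAWS):
        a = rng.normal(spec.a_mean, spec.a_sd)
        if not (50.0 < a <= 100.0):
            continue
        b = float(np.exp(rng.normal(spec.log_b_mean, spec.log_b_sd)))
        c = rng.normal(spec.c_mean, spec.c_sd) * c_scale
        if c <= 0:
            continue
        return GompertzParams(a, b, c)
    raise RuntimeError(
        "could not draw valid Gompertz parameters (a in (50,100], c > 0) "
        f"after {_MAX_REDRAWS} attempts; check the cohort distribution"
    )


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[List[GerminationCurve], List[GompertzParams]]:
    """Draw ``spec.n_curves`` curves with ground-truth parameters.

    Reproducible: the same spec (including ``rng_seed``) yields an
    identical cohort.
    """
    rng = np.random.default_rng(spec.rng_seed)
    curves: List[GerminationCurve] = []
    params: List[GompertzParams] = []
    for i in range(spec.n_curves):
        theta = _draw_theta(spec, rng)
        curve = simulate_curve(theta, spec.sigma_eta, spec.timeline, rng)
        curve.label = f"{spec.speed}_{i:03d}"
        curves.append(curve)
        params.append(theta)
    return curves, params
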