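"""Compression, distortion, and bias metrics.

The adaptive sampler is judged against standard periodic sampling on
three axes: how few samples it kept (compression rate N_s/N), how far
its reconstruction strays from the fully sampled signal (mean squared
error), and how biased its parameter and t50 estimates are relative to
the full-data fit.  Cohort-level numbers are means over test instances
with a Student-t 95 % confidence half-width U = t_{0.975} * s / sqrt(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .model import GompertzParams, UndefinedT50Error, t50

__all__ = [
    "compression_rate",
    "mse",
    "t50_error",
    "param_bias",
    "uncertainty_halfwidth",
    "InstanceMetrics",
    "EvaluationReport",
    "aggregate_report",
]

logger = logging.getLogger(__name__)


def compression_rate(n_kept: int, n_total: int) -> float:
    """N_s / N: 1 means nothing was skipped."""
    if not 0 < n_kept <= n_total:
        raise ValueError(f"need 0 < n_kept <= n_total, got {n_kept}/{n_total}")
    return n_kept / n_total


def mse(y_hat: Sequence[float], y: Sequence[float]) -> float:
    """Mean squared error between reconstruction and full signal (percent^2)."""
    a = np.asarray(y_hat, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def t50_error(theta_true: GompertzParams, theta_hat: GompertzParams) -> float:
    """t50(theta) - t50(theta_hat), hours.

    Positive means germination *appears faster* than it is (the estimate
    crosses 50 % earlier than the reference); negative means it appears
    slower.
    """
    return t50(theta_true) - t50(theta_hat)


def param_bias(theta_true: GompertzParams, theta_hat: GompertzParams) -> Dict[str, float]:
    """bias(a) = a - a_hat, likewise for b and c."""
    return {
        "bias_a": theta_true.a - theta_hat.a,
        "bias_b": theta_true.b - theta_hat.b,
        "bias_c": theta_true.c - theta_hat.c,
    }


def uncertainty_halfwidth(metric_values: Sequence[float]) -> float:
    """95 % confidence half-width t_{0.975, n-1} * s / sqrt(n), ddof=1."""
    v = np.asarray(metric_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence half-width")
    crit = stats.t.ppf(0.975, v.size - 1)
    return float(crit * v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class InstanceMetrics:
    """Metrics of one adaptive run on one test curve."""

    compression: float
    mse: float
    t50_error: Optional[float] = None
    bias_a: Optional[float] = None
    bias_b: Optional[float] = None
    bias_c: Optional[float] = None


@dataclass
class EvaluationReport:
    """Cohort-level means with Student-t half-widths.

    ``log_mse`` is the natural log of the *mean* MSE (use
    ``log_base10=True`` in :func:`aggregate_report` for log10);
    ``n_t50_excluded`` counts instances whose t50 was undefined and were
    dropped from the t50/bias averages.
    """

    compression: float
    mse: float
    log_mse: float
    t50_error: float
    bias_a: float
    bias_b: float
    bias_c: float
    halfwidths: Dict[str, float] = field(default_factory=dict)
    n_instances: int = 0
    n_t50_excluded: int = 0
    single_instance: bool = False


def _mean_and_u(values: List[float]) -> tuple[float, float]:
    if not values:
        return float("nan"), 0.0
    if len(values) == 1:
        return float(values[0]), 0.0
    return float(np.mean(values)), uncertainty_halfwidth(values)


def aggregate_report(
    per_instance: Sequence[InstanceMetrics],
    log_base10: bool = False,
) -> EvaluationReport:
    """Average instance metrics into a cohort report with half-widths."""
    if not per_instance:
        raise ValueError("no instances to aggregate")
    comp = [m.compression for m in per_instance]
    mses = [m.mse for m in per_instance]
    t50s = [m.t50_error for m in per_instance if m.t50_error is not None]
    n_excl = sum(1 for m in per_instance if m.t50_error is None)
    if n_excl:
        logger.info("excluded %d instance(s) with undefined t50 from bias averages", n_excl)
    biases = {
        k: [getattr(m, k) for m in per_instance if getattr(m, k) is not None]
        for k in ("bias_a", "bias_b", "bias_c")
    }

    hw: Dict[str, float] = {}
    comp_m, hw["compression"] = _mean_and_u(comp)
    mse_m, hw["mse"] = _mean_and_u(mses)
    t50_m, hw["t50_error"] = _mean_and_u(t50s)
    bias_m = {}
    for k, vals in biases.items():
        bias_m[k], hw[k] = _mean_and_u(vals)

    log_fn = np.log10 if log_base10 else np.log
    return EvaluationReport(
        compression=comp_m,
        mse=mse_m,
        log_mse=float(log_fn(mse_m)) if mse_m > 0 else float("-inf"),
        t50_error=t50_m,
        bias_a=bias_m["bias_a"],
        bias_b=bias_m["bias_b"],
        bias_c=bias_m["bias_c"],
        halfwidths=hw,
        n_instances=len(per_instance),
        n_t50_excluded=n_excl,
        single_instance=len(per_instance) == 1,
    )
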