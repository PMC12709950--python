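"""End-to-end threshold-sweep experiments.

A sweep runs the adaptive sampler for every (threshold, test curve)
pair, recording compression, distortion against the fully sampled
signal, and parameter/t50 bias against the full-data least-squares fit
(the standard periodic-sampling reference).  Reports condense sweeps
into compression-distortion curves, threshold-compression bands, and
per-method tables at a target compression ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .estimators import EstimatorConfig
from .metrics import (
    InstanceMetrics,
    aggregate_report,
    mse,
    param_bias,
    t50_error,
    uncertainty_halfwidth,
)
from .model import (
    FitFailureError,
    GerminationCurve,
    UndefinedT50Error,
    fit_gompertz,
)
from .priors import PriorLibrary
from .sampler import run_adaptive

__all__ = [
    "default_thresholds",
    "SweepResult",
    "run_sweep",
    "mean_compression_by_threshold",
    "select_at_compression",
    "table_at_compression",
    "compression_mse_curve",
    "threshold_compression_band",
]

logger = logging.getLogger(__name__)

DEFAULT_N_THRESHOLDS = 240
THRESHOLD_RANGE = (0.1, 12.0)


def default_thresholds(n: int = DEFAULT_N_THRESHOLDS, log_spacing: bool = False) -> np.ndarray:
    """The sweep grid: ``n`` thresholds spanning 0.1-12 percent."""
    lo, hi = THRESHOLD_RANGE
    if log_spacing:
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


@dataclass
class SweepResult:
    """Tidy per-(threshold, curve) records of one sweep."""

    records: pd.DataFrame
    method: str
    speed_group: str = "normal"
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))


def _derived_seed(master: int, curve_i: int, thr_i: int) -> int:
    return int((master * 99_991 + curve_i * 613 + thr_i) % (2**31 - 1))


def run_sweep(
    test_curves: Sequence[GerminationCurve],
    estimator_cfg: EstimatorConfig,
    priors: PriorLibrary,
    thresholds: Optional[Sequence[float]] = None,
    master_seed: int = 0,
    speed_group: str = "normal",
) -> SweepResult:
    """Adaptive runs over every (threshold, curve) pair.

    The bias reference per curve is the full-grid least-squares fit.
    Per-cell randomness derives deterministically from ``master_seed``,
    the curve index, and the threshold index.  Estimator failures are
    recorded (``failed=True``) and the sweep continues.
    """
    thr = np.asarray(
        thresholds if thresholds is not None else default_thresholds(), dtype=float
    )
    if np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")

    refs = []
    for curve in test_curves:
        theta_ref, _ = fit_gompertz(curve.timeline.times, curve.values)
        refs.append(theta_ref)

    rows = []
    for ci, curve in enumerate(test_curves):
        theta_ref = refs[ci]
        for ti, sigma_T in enumerate(thr):
            cfg = replace(estimator_cfg, rng_seed=_derived_seed(master_seed, ci, ti))
            row = {
                "threshold_index": ti,
                "threshold": float(sigma_T),
                "curve_index": ci,
                "curve": curve.label or f"curve_{ci:03d}",
                "failed": False,
            }
            try:
                res = run_adaptive(curve, cfg, priors, float(sigma_T))
                row["n_kept"] = res.n_kept
                row["compression"] = res.n_kept / curve.timeline.n_total
                row["mse"] = mse(res.y_hat, curve.values)
                theta_hat = res.theta_hat.theta_hat
                biases = param_bias(theta_ref, theta_hat)
                row.update(biases)
                try:
                    row["t50_error"] = t50_error(theta_ref, theta_hat)
                except UndefinedT50Error:
                    row["t50_error"] = np.nan
            except Exception as exc:  # estimator failure: keep sweeping
                logger.warning(
                    "sweep cell failed (curve %d, threshold %.3g): %s", ci, sigma_T, exc
                )
                row["failed"] = True
                for k in ("n_kept", "compression", "mse", "t50_error",
                          "bias_a", "bias_b", "bias_c"):
                    row[k] = np.nan
            rows.append(row)
        logger.info("sweep: curve %d/%d done", ci + 1, len(test_curves))

    return SweepResult(
        records=pd.DataFrame(rows),
        method=estimator_cfg.method,
        speed_group=speed_group,
        thresholds=thr,
    )


def mean_compression_by_threshold(sweep: SweepResult) -> pd.DataFrame:
    """Mean/min/max compression per threshold across test instances."""
    g = sweep.records.groupby("threshold")["compression"]
    out = g.agg(["mean", "min", "max"]).reset_index()
    return out.rename(columns={"mean": "compression_mean",
                               "min": "compression_min",
                               "max": "compression_max"})


def select_at_compression(sweep: SweepResult, target: float = 0.2) -> pd.DataFrame:
    """Per instance, the sweep record whose compression is nearest ``target``.

    Ties break toward the lower threshold.
    """
    picks = []
    ok = sweep.records[~sweep.records["failed"]]
    for ci, grp in ok.groupby("curve_index"):
        dist = (grp["compression"] - target).abs()
        best = dist.min()
        cand = grp[dist == best].sort_values("threshold")
        picks.append(cand.iloc[0])
    return pd.DataFrame(picks).reset_index(drop=True)


def table_at_compression(
    sweeps: Dict[str, SweepResult],
    target: float = 0.2,
    log_base10: bool = False,
) -> pd.DataFrame:
    """Tables of distortion/bias per method at a target compression.

    One row per method x metric with mean, half-width U, and n, in the
    layout used to compare methods across speed groups.
    """
    rows = []
    for method, sweep in sweeps.items():
        sel = select_at_compression(sweep, target)
        inst = [
            InstanceMetrics(
                compression=r["compression"],
                mse=r["mse"],
                t50_error=None if np.isnan(r["t50_error"]) else r["t50_error"],
                bias_a=r["bias_a"],
                bias_b=r["bias_b"],
                bias_c=r["bias_c"],
            )
            for _, r in sel.iterrows()
        ]
        rep = aggregate_report(inst, log_base10=log_base10)
        for metric, value in [
            ("compression", rep.compression),
            ("log_mse", rep.log_mse),
            ("mse", rep.mse),
            ("t50_error", rep.t50_error),
            ("bias_a", rep.bias_a),
            ("bias_b", rep.bias_b),
            ("bias_c", rep.bias_c),
        ]:
            rows.append({
                "method": method,
                "speed_group": sweep.speed_group,
                "metric": metric,
                "mean": value,
                "U": rep.halfwidths.get(metric, 0.0),
                "n": rep.n_instances,
                "single_instance": rep.single_instance,
            })
    return pd.DataFrame(rows)


def compression_mse_curve(sweep: SweepResult) -> pd.DataFrame:
    """Mean (compression, MSE) per threshold: the L-curve data."""
    ok = sweep.records[~sweep.records["failed"]]
    g = ok.groupby("threshold")[["compression", "mse"]].mean().reset_index()
    return g


def threshold_compression_band(sweep: SweepResult) -> pd.DataFrame:
    """Threshold vs compression with a min/max envelope over instances."""
    return mean_compression_by_threshold(sweep)


def plot_report(
    sweeps: Dict[str, SweepResult],
    out_dir,
    fmt: str = "svg",
) -> List[str]:
    """Write compression-MSE and threshold-compression figures per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, sweep in sweeps.items():
        cur = compression_mse_curve(sweep)
        ax.plot(cur["compression"], cur["mse"], marker=".", label=method)
    ax.set_xlabel("compression rate $N_s/N$")
    ax.set_ylabel("MSE (%$^2$)")
    ax.set_yscale("log")
    ax.legend()
    p = out_dir / f"compression_mse.{fmt}"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, sweep in sweeps.items():
        band = threshold_compression_band(sweep)
        (line,) = ax.plot(band["threshold"], band["compression_mean"], label=method)
        ax.fill_between(band["threshold"], band["compression_min"],
                        band["compression_max"], alpha=0.2, color=line.get_color())
    ax.set_xlabel(r"threshold $\sigma_T$ (%)")
    ax.set_ylabel("compression rate")
    ax.legend()
    p = out_dir / f"threshold_compression.{fmt}"
    fig.savefig(p, bbox_inches="tight")
    plt.close(fig)
    written.append(str(p))
    return written
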