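"""Reading and writing germination tables.

Curves travel as plain CSV: first column ``time_h`` on the 2-h grid,
one column per seed lot, cumulative germination in percent.  Comma and
semicolon delimiters are both accepted.  Ground truth for simulated
cohorts goes to a JSON sidecar; prior libraries serialise to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from .model import GerminationCurve, GompertzParams, NoiseModel, Timeline
from .priors import PriorLibrary

__all__ = [
    "CurveParseError",
    "load_curves_csv",
    "write_cohort_csv",
    "write_ground_truth",
    "load_ground_truth",
    "save_priors",
    "load_priors",
]

TIME_COLUMN = "time_h"


class CurveParseError(ValueError):
    """A curve table violated the expected dialect or grid."""


def _read_table(path: Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = ";" if header.count(";") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_curves_csv(
    path, timeline: Optional[Timeline] = None
) -> List[GerminationCurve]:
    """Load one curve per value column; times must match the grid exactly.

    Off-grid or gapped time values are an error (never interpolated),
    reported with the offending row; missing values likewise.
    """
    path = Path(path)
    df = _read_table(path)
    if TIME_COLUMN not in df.columns:
        raise CurveParseError(f"{path}: missing required column '{TIME_COLUMN}'")
    if df.shape[1] < 2:
        raise CurveParseError(f"{path}: no curve columns beside '{TIME_COLUMN}'")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise CurveParseError(f"{path}: missing values at rows {rows[:5]}")

    times = df[TIME_COLUMN].to_numpy(dtype=float)
    grid = (timeline or Timeline.canonical()).times
    if times.size != grid.size or not (abs(times - grid) < 1e-6).all():
        bad = next(
            (i for i in range(min(times.size, grid.size))
             if abs(times[i] - grid[i]) >= 1e-6),
            min(times.size, grid.size),
        )
        raise CurveParseError(
            f"{path}: time column does not match the acquisition grid "
            f"(first mismatch at row {bad}); resampling is not performed"
        )
    tl = Timeline(times)
    return [
        GerminationCurve(timeline=tl, values=df[col].to_numpy(dtype=float), label=str(col))
        for col in df.columns
        if col != TIME_COLUMN
    ]


def write_cohort_csv(path, curves: Sequence[GerminationCurve]) -> None:
    """Write curves in the dialect :func:`load_curves_csv` reads."""
    path = Path(path)
    timeline = curves[0].timeline
    for c in curves:
        if c.timeline != timeline:
            raise ValueError("all curves must share one timeline")
    data = {TIME_COLUMN: timeline.times}
    for i, c in enumerate(curves):
        data[c.label or f"curve_{i:03d}"] = c.values
    pd.DataFrame(data).to_csv(path, index=False)


def write_ground_truth(path, curves: Sequence[GerminationCurve]) -> None:
    doc = {}
    for i, c in enumerate(curves):
        key = c.label or f"curve_{i:03d}"
        entry = {}
        if c.true_params is not None:
            entry["theta"] = list(c.true_params.as_array())
        if c.true_noise is not None:
            entry["sigma_eta"] = c.true_noise.sigma_eta
        doc[key] = entry
    Path(path).write_text(json.dumps(doc, indent=1))


def load_ground_truth(path) -> dict:
    doc = json.loads(Path(path).read_text())
    out = {}
    for key, entry in doc.items():
        theta = GompertzParams.from_array(entry["theta"]) if "theta" in entry else None
        noise = NoiseModel(entry["sigma_eta"]) if "sigma_eta" in entry else None
        out[key] = (theta, noise)
    return out


def save_priors(path, priors: PriorLibrary) -> None:
    Path(path).write_text(priors.to_json())


def load_priors(path) -> PriorLibrary:
    return PriorLibrary.from_json(Path(path).read_text())
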