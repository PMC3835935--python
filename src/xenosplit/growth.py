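"""Exponential tumor-growth fitting and doubling-time estimation.

Volumes V(t) are modeled as V0 * exp(k t); the fit is ordinary least
squares of ln(volume) against time, so k is the slope, V0 = exp(intercept)
and the doubling time Td = ln 2 / k.  Goodness of fit (R^2) is computed on
the log scale, consistent with the linearized model.  A series with
R^2 < 0.5 — or one that is not growing at all (k <= 0) — is classified as
non-exponential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "fit_exponential",
    "classify_growth",
    "load_growth_tsv",
    "fit_report",
]


@dataclass
class GrowthSeries:
    """One tumor's volume time series (days, consistent volume units)."""

    sample_id: str
    timepoints: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.timepoints.shape != self.volumes.shape:
            raise ValueError("timepoints and volumes must have equal length")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class GrowthFit:
    """Fitted exponential parameters for one series.

    ``doubling_time`` is NaN when the series is flat or shrinking (k <= 0);
    the sign of k is then the only meaningful statement.
    """

    sample_id: str
    V0: float
    k: float  # per day
    doubling_time: float  # days; NaN if k <= 0
    r_squared: float
    classification: str  # "exponential" | "non_exponential"


def fit_exponential(series: GrowthSeries) -> GrowthFit:
    """Least-squares fit of ln(volume) vs time.

    Requires at least 3 points.  A perfectly flat series gets k = 0 and
    R^2 = 0 (no variance to explain).
    """
    t, v = series.timepoints, series.volumes
    if t.size < 3:
        raise ValueError("need at least 3 points to fit growth")
    logv = np.log(v)
    slope, intercept = np.polyfit(t, logv, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logv - fitted) ** 2))
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    k = float(slope)
    td = math.log(2) / k if k > 0 else float("nan")
    fit = GrowthFit(
        sample_id=series.sample_id,
        V0=float(np.exp(intercept)),
        k=k,
        doubling_time=td,
        r_squared=r2,
        classification="",
    )
    fit.classification = classify_growth(fit)
    return fit


def classify_growth(fit: GrowthFit) -> str:
    """Non-exponential iff R^2 < 0.5 (strict) or the series is not growing."""
    if fit.k <= 0 or fit.r_squared < 0.5:
        return "non_exponential"
    return "exponential"


def load_growth_tsv(path: str | Path) -> list[GrowthSeries]:
    """Read series from TSV columns sample_id, day, volume."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "day", "volume"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("day")
        out.append(
            GrowthSeries(
                sample_id=str(sid),
                timepoints=grp["day"].to_numpy(float),
                volumes=grp["volume"].to_numpy(float),
            )
        )
    return out


def fit_report(series_list: list[GrowthSeries]) -> pd.DataFrame:
    """Fit every series and tabulate V0, k, Td, R^2 and the classification."""
    rows = []
    for s in series_list:
        f = fit_exponential(s)
        rows.append(
            {
                "sample_id": f.sample_id,
                "V0": f.V0,
                "k_per_day": f.k,
                "doubling_time_days": f.doubling_time,
                "r_squared": f.r_squared,
                "classification": f.classification,
            }
        )
    return pd.DataFrame(rows)
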