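"""Window averaging and treatment-level descriptive statistics.

Reporting conventions for replicated whole-tree experiments: values are first
averaged within each individual (so pseudo-replicated time series never
inflate n), then summarised across individuals as mean +/- standard error per
treatment.  Time-of-day windows (e.g. daytime 09:00-14:00, nighttime
00:00-05:00) are half-open ``[start, end)`` so adjacent windows never double
count a boundary sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowSpec",
    "window_mean",
    "treatment_stats",
    "percent_difference",
    "ols_slope",
]

#: Conventional reporting windows (hours of day, half-open).
DAYTIME_WINDOW = (9.0, 14.0)
NIGHTTIME_WINDOW = (0.0, 5.0)
MIDDAY_GROWTH_WINDOW = (5.0, 17.0)


@dataclass(frozen=True)
class WindowSpec:
    """A named half-open time-of-day window ``[start_hour, end_hour)``."""

    name: str
    start_hour: float
    end_hour: float

    def __post_init__(self):
        if not (0 <= self.start_hour < self.end_hour <= 24):
            raise ValueError("window must satisfy 0 <= start < end <= 24")

    def contains(self, hour) -> np.ndarray:
        h = np.asarray(hour, dtype=float)
        return (h >= self.start_hour) & (h < self.end_hour)


def window_mean(
    series: pd.DataFrame,
    window: WindowSpec,
    value: str,
    by: tuple[str, ...] = ("tree_id",),
) -> pd.DataFrame:
    """Per-tree, per-day mean of ``value`` inside a time-of-day window.

    Masked (NaN) points are excluded; a tree-day with no valid point inside
    the window is reported as NaN, never as zero.
    """
    s = series.copy()
    ts = pd.to_datetime(s["timestamp"])
    s["date"] = ts.dt.normalize()
    hour = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    s = s[window.contains(hour)]
    keys = list(by) + ["date"]
    out = s.groupby(keys, as_index=False)[value].mean()
    return out.rename(columns={value: f"{value}_{window.name}"})


def treatment_stats(
    per_tree: pd.DataFrame,
    value: str,
    group: tuple[str, ...] = ("treatment",),
) -> pd.DataFrame:
    """Mean and standard error across individuals for each group.

    ``per_tree`` must hold one row per individual (already averaged within
    tree).  SE = sd / sqrt(n); with a single tree the SE is undefined (NaN).
    """
    def _agg(g: pd.Series) -> pd.Series:
        v = g.dropna()
        n = len(v)
        return pd.Series(
            {
                "mean": v.mean() if n else np.nan,
                "se": v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n": n,
            }
        )

    out = per_tree.groupby(list(group))[value].apply(_agg).unstack().reset_index()
    out["n"] = out["n"].astype(int)
    return out


def percent_difference(treatment_mean: float, control_mean: float) -> float:
    """Relative difference of a treatment mean from control, in percent.

    ``100 * (treatment - control) / |control|``; negative means the treatment
    is below the control.
    """
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; percent difference undefined")
    return 100.0 * (treatment_mean - control_mean) / abs(control_mean)


def ols_slope(x, y) -> tuple[float, float]:
    """Ordinary least-squares slope and its standard error.

    Used for rate-style summaries (final-window carbon accumulation rates,
    midday growth rates).  Requires at least 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("OLS slope needs at least 3 valid points")
    res = stats.linregress(x[ok], y[ok])
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), stderr
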