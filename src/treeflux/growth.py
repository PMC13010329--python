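"""Zero-growth dendrometer analysis and Huber-value tracking.

Point dendrometers record stem diameter continuously, but the raw trace mixes
irreversible radial growth with reversible water-related shrinking and
swelling.  The *zero-growth* concept resolves the two: growth is assumed to
occur only while the stem exceeds its previously recorded maximum size; any
excursion below that maximum is elastic dehydration, quantified as the *tree
water deficit* (TWD = running maximum minus current size).

All growth quantities are carried in basal-area units (mm2): displacement is
converted to absolute diameter against the initial caliper reading and then to
cross-sectional area assuming a circular stem.  Basal area also serves as the
sapwood-area proxy for the Huber value (sapwood area : leaf area), the
hydraulic supply-to-demand ratio that gates stomatal conductance and daytime
growth in the experiments this package targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .summaries import ols_slope

__all__ = [
    "to_basal_area",
    "zero_growth",
    "daily_growth",
    "recovery_mask",
    "diurnal_partition",
    "huber_series",
    "start_of_day_hv",
]


def to_basal_area(
    displacement: pd.DataFrame, initial_diameter_mm: float
) -> pd.DataFrame:
    """Convert a displacement trace (um) to diameter (mm) and basal area (mm2).

    ``diameter = initial + displacement/1000``; ``area = pi * d^2 / 4``.
    Raises if any implied diameter is non-positive.
    """
    if initial_diameter_mm <= 0:
        raise ValueError("initial diameter must be positive")
    out = displacement.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    out["diameter_mm"] = initial_diameter_mm + out["displacement_um"] / 1000.0
    if (out["diameter_mm"] <= 0).any():
        raise ValueError("displacement implies non-positive diameter")
    out["basal_area_mm2"] = np.pi * out["diameter_mm"] ** 2 / 4.0
    return out


def zero_growth(dendro: pd.DataFrame) -> pd.DataFrame:
    """Decompose a basal-area trace into growth and tree water deficit.

    growth_cum(t)       = runmax(area)(t) - area(t0)      (non-decreasing)
    twd_mm2(t)          = runmax(area)(t) - area(t)       (>= 0)
    growth_increment(t) = first difference of growth_cum   (>= 0)

    Growth is booked only when the stem exceeds every size previously seen;
    the running maximum is never reset, so rehydration back to a pre-drought
    maximum does not count as growth.

    Input must be a single tree's trace with strictly increasing timestamps
    and a ``basal_area_mm2`` column.
    """
    ts = pd.to_datetime(dendro["timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    area = dendro["basal_area_mm2"].to_numpy(dtype=float)
    runmax = np.maximum.accumulate(area)
    out = dendro.copy()
    out["growth_cum_mm2"] = runmax - area[0]
    out["twd_mm2"] = runmax - area
    out["growth_increment_mm2"] = np.diff(out["growth_cum_mm2"], prepend=0.0)
    return out


def daily_growth(growth: pd.DataFrame) -> pd.DataFrame:
    """Per-day growth (mm2 d-1): the sum of zero-growth increments each date."""
    if growth.empty:
        raise ValueError("empty growth series")
    g = growth.copy()
    g["date"] = pd.to_datetime(g["timestamp"]).dt.normalize()
    out = (
        g.groupby("date", as_index=False)["growth_increment_mm2"]
        .sum()
        .rename(columns={"growth_increment_mm2": "growth_mm2_d"})
    )
    return out


def recovery_mask(growth: pd.DataFrame, recovery_start) -> pd.DataFrame:
    """Exclude the first recovery day's increments from reported growth.

    On rewatering, a dehydrated stem swells back towards its pre-drought
    maximum within hours.  The running maximum already prevents rehydration
    below the old maximum from registering as growth; the first recovery day
    is additionally masked outright so that any same-day overshoot is not
    reported as growth either.
    """
    day1 = pd.Timestamp(recovery_start).normalize()
    out = growth.copy()
    ts = pd.to_datetime(out["timestamp"]).dt.normalize()
    out.loc[ts == day1, "growth_increment_mm2"] = 0.0
    return out


def diurnal_partition(
    growth: pd.DataFrame, day_window: tuple[float, float] = (5.0, 17.0)
) -> dict:
    """Partition daily growth into the midday window and its complement.

    The window is half-open in hours, default 05:00–17:00 (the midday window
    over which growth-rate regressions are reported).  Returns

    ``daytime_rate``      OLS slope (mm2 h-1) of the mean within-day cumulative
                          growth composite against hour, inside the window;
    ``nighttime_rate``    complement growth divided by complement duration;
    ``daytime_fraction``  in-window share of total growth, NaN when the trace
                          shows no growth at all.

    The composite averages, per hour-of-day, the cumulative growth since
    midnight over all days present — the per-week regression traces reduce to
    this when applied to one week of data.
    """
    start, end = day_window
    if not (0 <= start < end <= 24):
        raise ValueError("day window must satisfy 0 <= start < end <= 24")
    g = growth.copy()
    ts = pd.to_datetime(g["timestamp"])
    g["date"] = ts.dt.normalize()
    g["hour"] = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    inc = g["growth_increment_mm2"].to_numpy(dtype=float)

    in_day = ((g["hour"] >= start) & (g["hour"] < end)).to_numpy()
    day_total = float(inc[in_day].sum())
    night_total = float(inc[~in_day].sum())
    total = day_total + night_total  # summed per window so the partition is exact

    # mean within-day cumulative composite for the regression-style day rate
    g["cum_in_day"] = g.groupby("date")["growth_increment_mm2"].cumsum()
    composite = g.groupby("hour")["cum_in_day"].mean()
    comp_day = composite[(composite.index >= start) & (composite.index < end)]
    if len(comp_day) >= 3:
        daytime_rate, _ = ols_slope(comp_day.index.to_numpy(), comp_day.to_numpy())
    elif len(comp_day) == 2:
        daytime_rate = float(np.diff(comp_day.to_numpy())[0] / np.diff(comp_day.index)[0])
    else:
        daytime_rate = np.nan

    n_days = g["date"].nunique()
    night_hours = (24.0 - (end - start)) * n_days
    nighttime_rate = night_total / night_hours if night_hours > 0 else np.nan
    daytime_fraction = day_total / total if total > 0 else np.nan
    return {
        "daytime_rate": daytime_rate,
        "nighttime_rate": nighttime_rate,
        "daytime_fraction": daytime_fraction,
        "daytime_growth_mm2": day_total,
        "nighttime_growth_mm2": night_total,
        "total_growth_mm2": total,
    }


def huber_series(
    dendro: pd.DataFrame,
    leaf_area_m2: float,
    sapwood_rule: str = "running_max",
) -> pd.DataFrame:
    """Huber value series: sapwood area per unit leaf area.

    Basal area stands in for sapwood area (the stems are juvenile; bark is
    included because dendrometers measure over bark).  ``sapwood_rule`` is
    ``"running_max"`` (default — sapwood does not shrink when the stem
    dehydrates) or ``"instantaneous"``.

    Unit convention: mm2 sapwood per cm2 leaf area, which puts seedling-scale
    values near the ~0.08 operating point at which maximal stomatal
    conductance and daytime growth become possible.
    """
    if leaf_area_m2 <= 0:
        raise ValueError("leaf area must be positive")
    if sapwood_rule not in ("running_max", "instantaneous"):
        raise ValueError(f"unknown sapwood rule {sapwood_rule!r}")
    area = dendro["basal_area_mm2"].to_numpy(dtype=float)
    sapwood = np.maximum.accumulate(area) if sapwood_rule == "running_max" else area
    out = dendro[["timestamp", "tree_id"]].copy() if "tree_id" in dendro else dendro[
        ["timestamp"]
    ].copy()
    out["hv_mm2_cm2"] = sapwood / (leaf_area_m2 * 1e4)
    return out


def start_of_day_hv(
    huber: pd.DataFrame, hour: float = 5.0, tolerance: str = "1h"
) -> pd.DataFrame:
    """Sample the Huber value at a start-of-day hour, one value per date.

    Uses the exact sample at ``hour`` when present, otherwise the nearest
    sample within ``tolerance``; dates with nothing that close report NaN.
    """
    h = huber.copy()
    ts = pd.to_datetime(h["timestamp"])
    h["date"] = ts.dt.normalize()
    target = h["date"] + pd.Timedelta(hours=hour)
    offset = (ts - target).abs()
    h["_offset"] = offset
    tol = pd.Timedelta(tolerance)
    rows = []
    for date, grp in h.groupby("date"):
        best = grp.loc[grp["_offset"].idxmin()]
        rows.append(
            {
                "date": date,
                "hv_mm2_cm2": best["hv_mm2_cm2"]
                if best["_offset"] <= tol
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
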