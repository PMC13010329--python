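"""Daily and cumulative whole-plant carbon budgets.

The chamber system yields molar CO2 fluxes for the shoot and root compartment
of each tree.  The daily net carbon exchange of an individual is the sum of
the daily *average* molar fluxes of its compartments scaled to a day of
carbon mass:

    C_daily = (Fbar_shoot + Fbar_root) * M_C * s_day

with M_C = 12.01 g mol-1 and s_day = 86 400 s.  Cumulative plant carbon up to
day d is the running sum of C_daily.  Integration is mean-of-valid-samples
(not trapezoidal): hours masked upstream are excluded from the daily average,
and a day's coverage is tracked so thin days can be flagged rather than
silently trusted.

Sign convention: positive = net carbon gain by the plant, so root respiration
appears as a negative daily rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .summaries import ols_slope, treatment_stats

__all__ = [
    "M_C",
    "SECONDS_PER_DAY",
    "daily_carbon",
    "cumulative_carbon",
    "period_summary",
    "tail_accumulation_rate",
]

M_C = 12.01  # g mol-1, molar mass of carbon
SECONDS_PER_DAY = 86_400.0


def daily_carbon(
    flux: pd.DataFrame, min_valid_hours: int = 12
) -> pd.DataFrame:
    """Per-tree daily compartment and whole-plant carbon rates (g C d-1).

    For each tree and date, the valid (non-masked) hourly fluxes of each
    compartment are averaged and scaled by ``M_C * s_day``.  ``C_plant`` is
    the sum of the shoot and root rates.  ``n_valid_hours`` is the smaller of
    the two compartments' valid counts, and ``flagged`` marks days below
    ``min_valid_hours`` or with a compartment entirely missing; flagged days
    keep their (unreliable) values so callers decide how to treat them.
    """
    f = flux.copy()
    f["date"] = pd.to_datetime(f["timestamp"]).dt.normalize()
    grouped = (
        f.groupby(["tree_id", "date", "compartment"])["f_co2_mol_s"]
        .agg(mean_flux="mean", n_valid="count")
        .reset_index()
    )
    grouped["rate_gc_d"] = grouped["mean_flux"] * M_C * SECONDS_PER_DAY

    rate = grouped.pivot_table(
        index=["tree_id", "date"], columns="compartment", values="rate_gc_d"
    )
    nval = grouped.pivot_table(
        index=["tree_id", "date"], columns="compartment", values="n_valid"
    )
    out = pd.DataFrame(
        {
            "c_shoot_gc_d": rate.get("shoot"),
            "c_root_gc_d": rate.get("root"),
        },
        index=rate.index,
    ).reset_index()
    out["c_plant_gc_d"] = out["c_shoot_gc_d"].fillna(0.0) + out["c_root_gc_d"].fillna(0.0)
    n = nval.reindex(columns=["shoot", "root"]).fillna(0)
    out["n_valid_hours"] = n.min(axis=1).to_numpy().astype(int)
    out["flagged"] = (out["n_valid_hours"] < min_valid_hours) | out[
        ["c_shoot_gc_d", "c_root_gc_d"]
    ].isna().any(axis=1)
    return out


def cumulative_carbon(daily: pd.DataFrame) -> pd.DataFrame:
    """Running cumulative plant carbon (g C) per tree.

    Days flagged as unreliable contribute zero to the running sum but remain
    flagged in the output.  Duplicate dates within a tree are an error.
    """
    out = []
    for tree_id, grp in daily.groupby("tree_id"):
        g = grp.sort_values("date").copy()
        if g["date"].duplicated().any():
            raise ValueError(f"duplicate dates for tree {tree_id!r}")
        contrib = np.where(g["flagged"], 0.0, g["c_plant_gc_d"].fillna(0.0))
        g["c_cum_gc"] = np.cumsum(contrib)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def period_summary(
    daily: pd.DataFrame,
    trees: pd.DataFrame,
    periods: dict[str, tuple],
    drop_flagged: bool = True,
) -> pd.DataFrame:
    """Treatment x compartment x period carbon-rate table (g C d-1).

    ``periods`` maps a period name to a half-open date interval
    ``[start, end)``.  Per individual, daily rates are averaged within the
    period first; the treatment mean and standard error are then taken across
    individuals — never across pooled tree-days.

    Returns rows (treatment, compartment in {shoot, root, plant}, period,
    mean_rate, se_rate, n_trees).
    """
    d = daily if not drop_flagged else daily[~daily["flagged"]]
    d = d.merge(trees[["tree_id", "treatment"]], on="tree_id")
    rows = []
    comp_cols = {
        "shoot": "c_shoot_gc_d",
        "root": "c_root_gc_d",
        "plant": "c_plant_gc_d",
    }
    for period, (start, end) in periods.items():
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        sel = d[(d["date"] >= start) & (d["date"] < end)]
        if sel.empty:
            continue
        per_tree = sel.groupby(["treatment", "tree_id"], as_index=False)[
            list(comp_cols.values())
        ].mean()
        for comp, col in comp_cols.items():
            st = treatment_stats(per_tree, col)
            for _, r in st.iterrows():
                rows.append(
                    {
                        "treatment": r["treatment"],
                        "compartment": comp,
                        "period": period,
                        "mean_rate_gc_d": r["mean"],
                        "se_rate_gc_d": r["se"],
                        "n_trees": int(r["n"]),
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no daily data inside any period (empty treatment groups?)")
    return out


def tail_accumulation_rate(
    cumulative: pd.DataFrame, window_days: int = 10
) -> pd.DataFrame:
    """Final-window carbon accumulation rate per tree (g C d-1).

    OLS slope of cumulative plant carbon against day number over the last
    ``window_days`` days of each tree's series — the standard way to report
    the carbon accumulation rate attained by the end of a recovery period.
    """
    rows = []
    for tree_id, grp in cumulative.groupby("tree_id"):
        g = grp.sort_values("date")
        if window_days > len(g):
            raise ValueError(
                f"window of {window_days} d exceeds series length {len(g)}"
            )
        tail = g.iloc[-window_days:]
        days = (tail["date"] - tail["date"].iloc[0]).dt.days.to_numpy(dtype=float)
        slope, se = ols_slope(days, tail["c_cum_gc"].to_numpy())
        rows.append(
            {"tree_id": tree_id, "slope_gc_d": slope, "slope_se_gc_d": se}
        )
    return pd.DataFrame(rows)
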