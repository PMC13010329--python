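"""Chamber gas-exchange flux computation.

Converts raw open-flow chamber records (reference vs. sample airstream CO2 and
H2O mole fractions plus molar flow) into per-compartment CO2 fluxes and
leaf-area-normalised gas exchange (net assimilation ``A_net``, transpiration
``E``, stomatal conductance ``g_sw``, intrinsic water-use efficiency
``WUE_i``).

The mass balance for a well-stirred flow-through chamber gives the molar CO2
flux of a compartment as

    F_CO2 = -mdot * (C_sample - C_reference)

with both mole fractions on a *dry-air* basis (water dilution corrected) and
``mdot`` the molar air flow (mol s-1).  Positive flux means the compartment
removes CO2 from the airstream (net uptake); root respiration is therefore
negative.  Background fluxes measured in plant-free (blank) chambers are
subtracted from the sample-minus-reference differential before the flux is
formed.

All internal computation uses SI mole fractions; the public table interface
speaks ppm (umol mol-1) for CO2 and mmol mol-1 for water vapour, matching the
instrument conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "dry_mole_fraction",
    "background_correct",
    "compartment_co2_flux",
    "transpiration",
    "stomatal_conductance",
    "net_assimilation",
    "wue_i",
    "saturation_vapor_pressure",
    "vapor_pressure_deficit",
    "resample_cycle",
    "compute_fluxes",
]

#: Columns of a raw chamber table (one row per chamber reading).
CHAMBER_COLUMNS = [
    "timestamp",
    "tree_id",
    "compartment",
    "c_ref_ppm",
    "c_sample_ppm",
    "w_ref_mmol",
    "w_sample_mmol",
    "flow_mol_s",
    "t_air_C",
    "p_kpa",
    "par_umol",
]

#: Columns of the derived flux table.
FLUX_COLUMNS = [
    "timestamp",
    "tree_id",
    "compartment",
    "f_co2_mol_s",
    "e_mmol_m2_s",
    "gsw_mmol_m2_s",
    "anet_umol_m2_s",
    "wuei_umol_mol",
    "vpd_kpa",
]


class InvalidHumidityError(ValueError):
    """Water-vapour mole fraction at or above 1000 mmol mol-1 (pure water)."""


class MissingBlankError(ValueError):
    """No blank-chamber record within the matching tolerance window."""


def dry_mole_fraction(c_wet, w_mmol):
    """Convert a mole fraction in moist air to a dry-air basis.

    Parameters
    ----------
    c_wet : float or array
        Mole fraction in moist air (any unit; typically umol mol-1 CO2).
    w_mmol : float or array
        Water-vapour mole fraction of the same airstream, mmol mol-1 moist air.

    Returns
    -------
    Mole fraction per mole of *dry* air, ``c_wet / (1 - w/1000)``.
    """
    w = np.asarray(w_mmol, dtype=float)
    if np.any(w >= 1000.0) or np.any(w < 0.0):
        raise InvalidHumidityError(
            "water mole fraction must satisfy 0 <= w < 1000 mmol mol-1"
        )
    out = np.asarray(c_wet, dtype=float) / (1.0 - w / 1000.0)
    if np.isscalar(c_wet) and np.isscalar(w_mmol):
        return float(out)
    return out


def background_correct(dc_sample, dc_blank):
    """Remove the blank-chamber background from a sample differential.

    Both arguments are sample-minus-reference differentials (CO2 or H2O, any
    consistent unit); the blank differential is measured in a plant-free
    chamber of the same compartment section and is subtracted so that only the
    plant signal remains.  The reference stream is untouched.
    """
    return np.asarray(dc_sample, dtype=float) - np.asarray(dc_blank, dtype=float)


def compartment_co2_flux(flow_mol_s, c_sample_dry_ppm, c_ref_dry_ppm):
    """Molar CO2 flux of a chamber compartment, mol CO2 s-1.

    ``F = -mdot * (C_sample - C_ref)`` with dry-basis mole fractions.
    Positive flux = net CO2 uptake by the compartment.
    """
    flow = np.asarray(flow_mol_s, dtype=float)
    if np.any(flow <= 0):
        raise ValueError("molar flow must be positive")
    dc = (
        np.asarray(c_sample_dry_ppm, dtype=float)
        - np.asarray(c_ref_dry_ppm, dtype=float)
    ) * 1e-6  # ppm -> mol mol-1
    out = -flow * dc
    if np.isscalar(flow_mol_s) and np.isscalar(c_sample_dry_ppm):
        return float(out)
    return out


def transpiration(flow_mol_s, w_ref_mmol, w_sample_mmol, leaf_area_m2):
    """Transpiration per unit leaf area, mmol H2O m-2 s-1.

    Open-flow chamber water balance: the plant adds
    ``mdot * (x_s - x_r) / (1 - x_s)`` mol H2O s-1 to the airstream (the
    denominator accounts for the flow increase caused by the added vapour),
    normalised by leaf area.  Positive when the plant releases water.
    """
    if np.any(np.asarray(leaf_area_m2, dtype=float) <= 0):
        raise ValueError("leaf area must be positive")
    x_r = np.asarray(w_ref_mmol, dtype=float) * 1e-3
    x_s = np.asarray(w_sample_mmol, dtype=float) * 1e-3
    flow = np.asarray(flow_mol_s, dtype=float)
    e_mol = flow * (x_s - x_r) / (1.0 - x_s) / np.asarray(leaf_area_m2, dtype=float)
    out = e_mol * 1e3  # mol -> mmol
    if np.isscalar(flow_mol_s) and np.isscalar(w_sample_mmol):
        return float(out)
    return out


def saturation_vapor_pressure(t_C):
    """Saturation vapour pressure over water (kPa), Tetens form.

    ``e_sat(T) = 0.6108 * exp(17.27 T / (T + 237.3))`` — accurate within the
    0–40 degC range of greenhouse experiments.
    """
    t = np.asarray(t_C, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    if np.isscalar(t_C):
        return float(out)
    return out


def vapor_pressure_deficit(t_air_C, w_air_mmol, p_kpa):
    """Chamber air VPD (kPa) from air temperature and vapour mole fraction."""
    e_air = np.asarray(w_air_mmol, dtype=float) / 1000.0 * np.asarray(p_kpa, dtype=float)
    return saturation_vapor_pressure(t_air_C) - e_air


def stomatal_conductance(e_mmol_m2_s, t_air_C, w_sample_mmol, p_kpa):
    """Stomatal conductance to water vapour, mmol m-2 s-1.

    ``g_sw = E / dw`` with ``dw`` the leaf-to-air water mole-fraction deficit
    ``(e_sat(T_air) - e_air) / P``.  Leaf temperature is taken equal to air
    temperature (ventilated chamber, no boundary-layer term).  Where the
    chamber is saturated (``dw <= 0``) the conductance is undefined and NaN is
    returned so downstream aggregates can mask the point.
    """
    vpd = vapor_pressure_deficit(t_air_C, w_sample_mmol, p_kpa)
    dw = np.asarray(vpd, dtype=float) / np.asarray(p_kpa, dtype=float)
    e = np.asarray(e_mmol_m2_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(dw > 0, e / dw, np.nan)
    if np.isscalar(e_mmol_m2_s) and np.isscalar(t_air_C):
        return float(g)
    return g


def net_assimilation(f_co2_mol_s, leaf_area_m2):
    """Net CO2 assimilation per unit leaf area, umol m-2 s-1."""
    if np.any(np.asarray(leaf_area_m2, dtype=float) <= 0):
        raise ValueError("leaf area must be positive")
    out = np.asarray(f_co2_mol_s, dtype=float) * 1e6 / np.asarray(
        leaf_area_m2, dtype=float
    )
    if np.isscalar(f_co2_mol_s):
        return float(out)
    return out


def wue_i(anet_umol_m2_s, gsw_mmol_m2_s):
    """Intrinsic water-use efficiency ``A_net / g_sw``, umol CO2 mol-1 H2O.

    Undefined (NaN) where ``g_sw`` is zero or missing.  May legitimately be
    negative under net daytime respiration.
    """
    a = np.asarray(anet_umol_m2_s, dtype=float)
    g = np.asarray(gsw_mmol_m2_s, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(g > 0, a / (g / 1000.0), np.nan)
    if np.isscalar(anet_umol_m2_s) and np.isscalar(gsw_mmol_m2_s):
        return float(out)
    return out


def resample_cycle(
    series: pd.DataFrame,
    value_columns: list[str],
    target_interval: str = "1h",
    max_gap: str = "3h",
) -> pd.DataFrame:
    """Interpolate one chamber's irregular readings onto a common clock.

    The measurement system cycles through all chambers (a full cycle takes on
    the order of 80 min), so per-chamber timestamps are irregular.  Each value
    column is linearly interpolated onto a regular grid; stretches between
    consecutive source points longer than ``max_gap`` are left missing rather
    than bridged.

    ``series`` must carry a ``timestamp`` column; other non-value columns are
    forwarded unchanged (taken from the first row).
    """
    if len(series) < 2:
        raise ValueError("resampling needs at least 2 points per series")
    ts = pd.to_datetime(series["timestamp"])
    if not ts.is_monotonic_increasing:
        series = series.sort_values("timestamp")
        ts = pd.to_datetime(series["timestamp"])
    step = pd.Timedelta(target_interval)
    grid = pd.date_range(ts.iloc[0].ceil(step), ts.iloc[-1].floor(step), freq=step)
    t_src = ts.astype("int64").to_numpy() / 1e9
    t_new = grid.astype("int64").to_numpy() / 1e9

    gap_limit = pd.Timedelta(max_gap).total_seconds()
    # a grid point is masked when its bracketing source points are further
    # apart than the gap limit
    idx = np.searchsorted(t_src, t_new, side="right")
    idx = np.clip(idx, 1, len(t_src) - 1)
    bracket = t_src[idx] - t_src[idx - 1]
    on_source = np.isin(t_new, t_src)
    masked = (bracket > gap_limit) & ~on_source

    out = pd.DataFrame({"timestamp": grid})
    for col in value_columns:
        v = np.interp(t_new, t_src, series[col].to_numpy(dtype=float))
        v[masked] = np.nan
        out[col] = v
    for col in series.columns:
        if col not in out.columns and col not in value_columns:
            out[col] = series[col].iloc[0]
    return out


def _match_blanks(
    records: pd.DataFrame, blanks: pd.DataFrame, tolerance: str
) -> pd.DataFrame:
    """Attach the nearest-in-time blank differentials to each record."""
    b = blanks.sort_values("timestamp")[
        ["timestamp", "dc_blank_ppm", "dw_blank_mmol"]
    ]
    merged = pd.merge_asof(
        records.sort_values("timestamp"),
        b,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(tolerance),
    )
    if merged["dc_blank_ppm"].isna().any():
        n = int(merged["dc_blank_ppm"].isna().sum())
        raise MissingBlankError(
            f"{n} records have no blank-chamber match within {tolerance}"
        )
    return merged


def compute_fluxes(
    chamber: pd.DataFrame,
    trees: pd.DataFrame,
    blank_tolerance: str = "90min",
) -> pd.DataFrame:
    """Derive the full flux table from raw chamber records.

    Steps, per compartment section (shoot / root):

    1. convert CO2 mole fractions to a dry-air basis (water dilution);
    2. subtract the time-matched blank-chamber differential (background
       fluxes of the plant-free chamber) from the sample-minus-reference
       differentials, CO2 on the dry basis and H2O on the wet basis;
    3. form the mass-balance flux ``F = -mdot * dC``;
    4. for shoot compartments, normalise by leaf area to ``A_net``, compute
       ``E``, ``g_sw`` (masked where the chamber is vapour-saturated) and
       ``WUE_i`` (masked where ``g_sw`` is zero or masked).

    Blank chambers are identified by ``compartment == "blank"``; the section a
    blank serves is the suffix of its ``tree_id`` (``blank_shoot`` /
    ``blank_root``).

    Parameters
    ----------
    chamber : DataFrame
        Raw records with :data:`CHAMBER_COLUMNS`.
    trees : DataFrame
        Per-tree metadata with at least ``tree_id`` and ``leaf_area_m2``.
    blank_tolerance : str
        Maximum time offset when pairing a record with its blank (default one
        measurement cycle, 90 min).

    Returns
    -------
    DataFrame with :data:`FLUX_COLUMNS`; undefined quantities are NaN.
    """
    df = chamber.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["c_ref_dry"] = dry_mole_fraction(df["c_ref_ppm"], df["w_ref_mmol"])
    df["c_sample_dry"] = dry_mole_fraction(df["c_sample_ppm"], df["w_sample_mmol"])
    df["dc_ppm"] = df["c_sample_dry"] - df["c_ref_dry"]
    df["dw_mmol"] = df["w_sample_mmol"] - df["w_ref_mmol"]

    is_blank = df["compartment"] == "blank"
    blanks = df[is_blank].copy()
    plants = df[~is_blank].copy()
    if plants.empty:
        raise ValueError("no plant chamber records")

    leaf_area = trees.set_index("tree_id")["leaf_area_m2"]

    parts = []
    for section in ("shoot", "root"):
        sec = plants[plants["compartment"] == section].copy()
        if sec.empty:
            continue
        sec_blank = blanks[blanks["tree_id"].str.endswith(section)]
        if sec_blank.empty:
            raise MissingBlankError(f"no blank chamber for section {section!r}")
        b = sec_blank.rename(
            columns={"dc_ppm": "dc_blank_ppm", "dw_mmol": "dw_blank_mmol"}
        )
        sec = _match_blanks(sec, b, blank_tolerance)
        sec["dc_corr_ppm"] = background_correct(sec["dc_ppm"], sec["dc_blank_ppm"])
        sec["dw_corr_mmol"] = background_correct(sec["dw_mmol"], sec["dw_blank_mmol"])
        sec["f_co2_mol_s"] = -sec["flow_mol_s"].to_numpy() * (
            sec["dc_corr_ppm"].to_numpy() * 1e-6
        )
        la = sec["tree_id"].map(leaf_area)
        if la.isna().any():
            missing = sorted(set(sec.loc[la.isna(), "tree_id"]))
            raise KeyError(f"trees missing from metadata: {missing}")
        if (la <= 0).any():
            raise ValueError("leaf area must be positive")
        if section == "shoot":
            w_corr = sec["w_ref_mmol"] + sec["dw_corr_mmol"]
            sec["e_mmol_m2_s"] = transpiration(
                sec["flow_mol_s"].to_numpy(),
                sec["w_ref_mmol"].to_numpy(),
                w_corr.to_numpy(),
                la.to_numpy(),
            )
            sec["gsw_mmol_m2_s"] = stomatal_conductance(
                sec["e_mmol_m2_s"].to_numpy(),
                sec["t_air_C"].to_numpy(),
                sec["w_sample_mmol"].to_numpy(),
                sec["p_kpa"].to_numpy(),
            )
            sec["anet_umol_m2_s"] = net_assimilation(
                sec["f_co2_mol_s"].to_numpy(), la.to_numpy()
            )
            sec["wuei_umol_mol"] = wue_i(
                sec["anet_umol_m2_s"].to_numpy(), sec["gsw_mmol_m2_s"].to_numpy()
            )
        else:
            sec["e_mmol_m2_s"] = np.nan
            sec["gsw_mmol_m2_s"] = np.nan
            sec["anet_umol_m2_s"] = np.nan
            sec["wuei_umol_mol"] = np.nan
        sec["vpd_kpa"] = vapor_pressure_deficit(
            sec["t_air_C"], sec["w_sample_mmol"], sec["p_kpa"]
        )
        parts.append(sec[FLUX_COLUMNS])

    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["tree_id", "compartment", "timestamp"]).reset_index(
        drop=True
    )
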