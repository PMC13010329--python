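"""Synthetic drought–recovery scenario generator.

Emulates a greenhouse chamber experiment: juvenile conifers in whole-tree gas
flux chambers (separate shoot and root compartments, plus plant-free blank
chambers), point dendrometers on every stem, soil water content probes, and
periodic destructive sampling of midday water potential, foliar ABA and
branch nonstructural carbohydrates.  Trees are split into a well-watered
control, a mild drought and a severe drought treatment; drought lasts
``drought_days`` (default 28) and is followed by ``recovery_days`` (default
35) of rewatering.

The generator works backwards from *true* quantities to observables:

* true compartment CO2 fluxes (a truncated sinusoid over the 15 h photoperiod
  for shoot assimilation, constant dark respiration terms, a constant root
  respiration) are inverted through the chamber mass balance to produce the
  sample-stream CO2 depletion/enrichment, including water dilution by the
  prescribed transpiration and a small constant background flux that the
  blank chambers record;
* true basal-area growth (treatment- and phase-specific daily rates placed
  within the day) is combined with reversible diurnal shrink/swell and, in
  the severe treatment, a drought contraction, then expressed as dendrometer
  displacement.

Every true quantity is retained in a :class:`GroundTruth` object that the
analysis pipeline never sees — it exists so tests can check that the pipeline
recovers what was injected.  The drought contraction is only applied while
the true growth rate is zero, and diurnal shrinkage vanishes at night, so the
running maximum of the generated stem size at midnight equals the injected
growth envelope exactly: the zero-growth decomposition is invertible on
noise-free traces.

A single scenario seed expands into independent per-tree, per-instrument
child streams, so adding a tree or turning one instrument's noise off never
perturbs the other streams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NoiseConfig",
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_scenario",
    "write_scenario",
    "read_scenario",
]

TREATMENTS = ("control", "mild", "severe")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel Gaussian noise standard deviations (0 = noise-free)."""

    c_ref_ppm: float = 0.2       # supply stability of the CO2 feed
    c_sample_ppm: float = 0.3    # analyser noise on the sample stream
    w_ref_mmol: float = 0.01
    w_sample_mmol: float = 0.05
    dendro_um: float = 1.5       # dendrometer resolution
    swc_pct: float = 0.5
    psi_mpa: float = 0.15
    aba_ng_g: float = 5.0
    nsc_pct_dw: float = 0.35

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"noise sd {name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(**{k: 0.0 for k in asdict(cls())})


def _default_n_trees() -> dict:
    # chamber sample sizes of the emulated experiment
    return {"control": 6, "mild": 5, "severe": 4}


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic drought–recovery scenario.

    Flux magnitudes are expressed per unit leaf area (so tree size enters
    through the sampled leaf areas): peak light-saturated assimilation
    ``anet_peak_umol``, dark respiration ``rd_umol``, and peak transpiration
    ``e_peak_mmol``.  Treatment effects are daily multiplicative trajectories
    in [0, 1] applied to the control flux profile (see
    :meth:`flux_effect_by_day`): the mild treatment ramps to ~0.45 by the end
    of drought and recovers to ~0.95; the severe treatment ramps to ~0 and
    recovers to 0.5, holding 0.5 for the final 10 days so the end-of-recovery
    accumulation-rate ratio to control is exactly the configured
    ``severe_recovery_plateau``.
    """

    n_trees_per_treatment: dict = field(default_factory=_default_n_trees)
    start_date: str = "2023-06-06"
    drought_days: int = 28
    recovery_days: int = 35
    sampling_interval_min: int = 60
    dendro_interval_min: int = 10
    seed: int = 0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    # chamber supply and environment; flow is high enough that a whole tree
    # raises chamber humidity by only a few mmol mol-1
    flow_mol_s: float = 0.1
    c_supply_ppm: float = 445.6
    w_supply_mmol: float = 8.0
    t_air_day_C: float = 23.0
    t_air_amplitude_C: float = 2.0
    p_kpa: float = 94.0           # ~700 m a.s.l. greenhouse
    par_peak_umol: float = 900.0
    lights_on_hour: float = 5.0
    photoperiod_h: float = 15.0

    # background (blank-chamber) fluxes; negative CO2 flux = release
    background_co2_mol_s: float = -1.5e-8   # ~ +0.15 ppm at 0.1 mol s-1
    background_h2o_mol_s: float = 3.0e-6    # ~ +0.03 mmol at 0.1 mol s-1

    # true gas-exchange profile, per leaf area
    anet_peak_umol: float = 7.5
    rd_umol: float = 0.5
    e_peak_mmol: float = 3.0
    e_night_mmol: float = 0.05
    root_resp_mol_s: float = 5.8e-8   # per mean-size tree, positive magnitude

    # treatment trajectory endpoints (flux multipliers in [0, 1])
    mild_drought_floor: float = 0.45
    mild_recovery_plateau: float = 0.95
    severe_drought_floor: float = 0.02
    severe_recovery_start: float = 0.10
    severe_recovery_plateau: float = 0.5
    severe_plateau_days: int = 10

    # growth (basal area, mm2 d-1) per treatment and phase
    growth_drought: dict = field(
        default_factory=lambda: {"control": 0.58, "mild": 0.28, "severe": 0.0}
    )
    growth_recovery: dict = field(
        default_factory=lambda: {"control": 0.80, "mild": 0.61, "severe": 0.40}
    )
    severe_growth_initial: float = 0.2    # fades over the first drought days
    severe_growth_fade_days: int = 5
    severe_regrowth_delay_days: int = 7   # growth resumes in week 2 of recovery
    daytime_growth_fraction: dict = field(
        default_factory=lambda: {"control": 0.30, "mild": 0.10, "severe": 0.0}
    )
    shrink_amplitude_um: dict = field(
        default_factory=lambda: {"control": 5.0, "mild": 12.0, "severe": 20.0}
    )
    severe_contraction_um: float = 200.0  # max drought contraction, diameter um
    rehydration_days: float = 1.5

    # tree allometry
    leaf_area_mean_m2: float = 0.10
    leaf_area_sd_m2: float = 0.010
    initial_diameter_mean_mm: float = 10.0
    initial_diameter_sd_mm: float = 0.5
    sla_cm2_g: float = 60.0
    shoot_wood_mass_g: float = 12.0
    root_shoot_ratio: dict = field(
        default_factory=lambda: {"control": 0.67, "mild": 0.42, "severe": 0.37}
    )

    # soil water content (% volumetric) targets
    swc_start_pct: float = 22.0
    swc_mild_floor_pct: float = 10.0
    swc_severe_floor_pct: float = 0.5
    swc_refill_days: float = 2.0

    destructive_days: tuple = (0, 14, 28, 30, 42, 63)
    n_pilot_per_treatment: int = 5

    def __post_init__(self):
        if isinstance(self.n_trees_per_treatment, int):
            self.n_trees_per_treatment = {
                t: self.n_trees_per_treatment for t in TREATMENTS
            }
        for t, n in self.n_trees_per_treatment.items():
            if t not in TREATMENTS:
                raise ValueError(f"unknown treatment {t!r}")
            if n < 1:
                raise ValueError("need at least one tree per treatment")
        if (24 * 60) % self.sampling_interval_min != 0:
            raise ValueError("sampling interval must divide 24 h")
        if (24 * 60) % self.dendro_interval_min != 0:
            raise ValueError("dendrometer interval must divide 24 h")
        if self.leaf_area_mean_m2 <= 0:
            raise ValueError("leaf area must be positive")

    # ------------------------------------------------------------------
    @property
    def total_days(self) -> int:
        return self.drought_days + self.recovery_days

    @property
    def recovery_start(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date) + pd.Timedelta(days=self.drought_days)

    @property
    def experiment_end(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date) + pd.Timedelta(days=self.total_days)

    def flux_effect_by_day(self, treatment: str) -> np.ndarray:
        """Daily flux multiplier trajectory (length ``total_days``)."""
        d = np.arange(self.drought_days, dtype=float)
        r = np.arange(self.recovery_days, dtype=float)
        if treatment == "control":
            return np.ones(self.total_days)
        if treatment == "mild":
            drought = 1.0 - (1.0 - self.mild_drought_floor) * d / max(
                self.drought_days - 1, 1
            )
            ramp = self.mild_recovery_plateau - 0.2 * np.clip(1.0 - r / 10.0, 0, 1)
            return np.concatenate([drought, ramp])
        if treatment == "severe":
            drought = 1.0 - (1.0 - self.severe_drought_floor) * d / max(
                self.drought_days - 1, 1
            )
            rise_days = max(self.recovery_days - self.severe_plateau_days, 1)
            ramp = self.severe_recovery_start + (
                self.severe_recovery_plateau - self.severe_recovery_start
            ) * np.clip(r / rise_days, 0, 1)
            return np.concatenate([drought, ramp])
        raise ValueError(f"unknown treatment {treatment!r}")

    def growth_rate_by_day(self, treatment: str) -> np.ndarray:
        """Daily true basal-area growth rate (mm2 d-1), length ``total_days``."""
        out = np.empty(self.total_days)
        if treatment == "severe":
            d = np.arange(self.drought_days, dtype=float)
            fade = self.severe_growth_initial * np.clip(
                1.0 - d / self.severe_growth_fade_days, 0, 1
            )
            out[: self.drought_days] = fade
            rec = np.full(self.recovery_days, self.growth_recovery["severe"])
            rec[: self.severe_regrowth_delay_days] = 0.0
            out[self.drought_days:] = rec
        else:
            out[: self.drought_days] = self.growth_drought[treatment]
            out[self.drought_days:] = self.growth_recovery[treatment]
        return out

    def swc_by_day(self, treatment: str) -> np.ndarray:
        d = np.arange(self.total_days, dtype=float)
        swc = np.full(self.total_days, self.swc_start_pct)
        dd = self.drought_days
        if treatment == "mild":
            swc[:dd] = np.maximum(
                self.swc_mild_floor_pct,
                self.swc_start_pct
                - (self.swc_start_pct - self.swc_mild_floor_pct) * d[:dd] / (dd / 2),
            )
        elif treatment == "severe":
            swc[:dd] = (
                self.swc_start_pct
                - (self.swc_start_pct - self.swc_severe_floor_pct) * d[:dd] / (dd - 1)
            )
        if treatment != "control":
            r = d[dd:] - dd
            floor = swc[dd - 1]
            swc[dd:] = floor + (self.swc_start_pct - floor) * np.clip(
                r / self.swc_refill_days, 0, 1
            )
        return swc


@dataclass
class GroundTruth:
    """True quantities retained for recovery tests; never fed to the pipeline."""

    fluxes: pd.DataFrame        # timestamp, tree_id, compartment, f_co2_mol_s
    transpiration: pd.DataFrame  # timestamp, tree_id, e_mmol_m2_s
    daily_growth: pd.DataFrame  # date, tree_id, growth_mm2_d
    flux_effects: pd.DataFrame  # date, treatment, flux_effect


@dataclass
class Scenario:
    """One generated dataset: observables plus retained ground truth."""

    chamber: pd.DataFrame
    dendro: pd.DataFrame
    trees: pd.DataFrame
    soil: pd.DataFrame
    destructive: pd.DataFrame
    truth: GroundTruth
    config: ScenarioConfig


# ----------------------------------------------------------------------
def _child_rng(seed: int, *streams: str) -> np.random.Generator:
    """Independent child generator keyed by (seed, stream names).

    crc32-based keys make the stream assignment stable under insertion of
    new trees or instruments.
    """
    key = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(s.encode()) for s in streams]
    return np.random.default_rng(key)


def _photo_sin(hour: np.ndarray, on: float, length: float) -> np.ndarray:
    """Truncated sinusoid over the photoperiod, 0 at night."""
    phase = (hour - on) / length
    return np.where((phase >= 0) & (phase < 1), np.sin(np.pi * phase), 0.0)


def _timestamps(cfg: ScenarioConfig, interval_min: int) -> pd.DatetimeIndex:
    n = cfg.total_days * 24 * 60 // interval_min
    return pd.date_range(cfg.start_date, periods=n, freq=f"{interval_min}min")


def _sample_trees(cfg: ScenarioConfig) -> pd.DataFrame:
    rows = []
    for treatment in TREATMENTS:
        n = cfg.n_trees_per_treatment.get(treatment, 0)
        for i in range(1, n + 1):
            tree_id = f"{treatment}_{i:02d}"
            rng = _child_rng(cfg.seed, tree_id, "meta")
            la = max(
                0.02, rng.normal(cfg.leaf_area_mean_m2, cfg.leaf_area_sd_m2)
            )
            d0 = max(
                4.0,
                rng.normal(cfg.initial_diameter_mean_mm, cfg.initial_diameter_sd_mm),
            )
            leaf_mass = la * 1e4 / cfg.sla_cm2_g
            shoot_wood = cfg.shoot_wood_mass_g * (la / cfg.leaf_area_mean_m2)
            root = cfg.root_shoot_ratio[treatment] * (leaf_mass + shoot_wood)
            rows.append(
                {
                    "tree_id": tree_id,
                    "treatment": treatment,
                    "leaf_area_m2": la,
                    "initial_diameter_mm": d0,
                    "dry_mass_leaf_g": leaf_mass,
                    "dry_mass_shoot_wood_g": shoot_wood,
                    "dry_mass_root_g": root,
                }
            )
    return pd.DataFrame(rows)


def _invert_chamber(
    cfg: ScenarioConfig,
    f_co2: np.ndarray,
    water_flux_mol_s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-stream wet mole fractions produced by given chamber fluxes.

    Water first: the added vapour dilutes the stream, so the sample CO2 wet
    mole fraction is the dry depletion re-expressed on the moist basis.
    Returns (c_sample_wet_ppm, w_sample_mmol).
    """
    x_r = cfg.w_supply_mmol * 1e-3
    w_rel = water_flux_mol_s / cfg.flow_mol_s
    x_s = (x_r + w_rel) / (1.0 + w_rel)
    c_ref_dry = cfg.c_supply_ppm / (1.0 - x_r)
    total_co2 = f_co2 + cfg.background_co2_mol_s
    c_s_dry = c_ref_dry - total_co2 / cfg.flow_mol_s * 1e6
    return c_s_dry * (1.0 - x_s), x_s * 1e3


def _chamber_for_tree(
    cfg: ScenarioConfig,
    tree: pd.Series,
    ts: pd.DatetimeIndex,
    hour: np.ndarray,
    day_idx: np.ndarray,
    effect_day: np.ndarray,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Raw shoot and root records plus the truth tables for one tree."""
    la = tree["leaf_area_m2"]
    eff = effect_day[day_idx]
    s = _photo_sin(hour, cfg.lights_on_hour, cfg.photoperiod_h)

    f_shoot = eff * la * 1e-6 * (cfg.anet_peak_umol * s - cfg.rd_umol)
    size_factor = la / cfg.leaf_area_mean_m2
    f_root = -eff * cfg.root_resp_mol_s * size_factor
    e_true = eff * (cfg.e_peak_mmol * s) + cfg.e_night_mmol  # mmol m-2 s-1

    t_air = cfg.t_air_day_C + cfg.t_air_amplitude_C * (s - 0.5)
    par = cfg.par_peak_umol * s

    rng = _child_rng(cfg.seed, str(tree["tree_id"]), "chamber")
    nz = cfg.noise
    frames = []
    for comp, f_true in (("shoot", f_shoot), ("root", f_root)):
        if comp == "shoot":
            water = e_true * 1e-3 * la + cfg.background_h2o_mol_s
        else:
            water = np.full_like(f_true, cfg.background_h2o_mol_s)
        c_s, w_s = _invert_chamber(cfg, f_true, water)
        n = len(ts)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "tree_id": tree["tree_id"],
                    "compartment": comp,
                    "c_ref_ppm": cfg.c_supply_ppm
                    + rng.normal(0, nz.c_ref_ppm, n) * (nz.c_ref_ppm > 0),
                    "c_sample_ppm": c_s
                    + rng.normal(0, nz.c_sample_ppm, n) * (nz.c_sample_ppm > 0),
                    "w_ref_mmol": cfg.w_supply_mmol
                    + rng.normal(0, nz.w_ref_mmol, n) * (nz.w_ref_mmol > 0),
                    "w_sample_mmol": w_s
                    + rng.normal(0, nz.w_sample_mmol, n) * (nz.w_sample_mmol > 0),
                    "flow_mol_s": cfg.flow_mol_s,
                    "t_air_C": t_air if comp == "shoot" else 21.0,
                    "p_kpa": cfg.p_kpa,
                    "par_umol": par if comp == "shoot" else 0.0,
                }
            )
        )
    truth_flux = pd.DataFrame(
        {
            "timestamp": np.tile(ts, 2),
            "tree_id": tree["tree_id"],
            "compartment": np.repeat(["shoot", "root"], len(ts)),
            "f_co2_mol_s": np.concatenate([f_shoot, f_root]),
        }
    )
    truth_e = pd.DataFrame(
        {"timestamp": ts, "tree_id": tree["tree_id"], "e_mmol_m2_s": e_true}
    )
    return frames, truth_flux, truth_e


def _blank_chambers(
    cfg: ScenarioConfig, ts: pd.DatetimeIndex, hour: np.ndarray
) -> list[pd.DataFrame]:
    s = _photo_sin(hour, cfg.lights_on_hour, cfg.photoperiod_h)
    zero = np.zeros(len(ts))
    c_s, w_s = _invert_chamber(
        cfg, zero, np.full(len(ts), cfg.background_h2o_mol_s)
    )
    nz = cfg.noise
    frames = []
    for section in ("shoot", "root"):
        rng = _child_rng(cfg.seed, f"blank_{section}", "chamber")
        n = len(ts)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": ts,
                    "tree_id": f"blank_{section}",
                    "compartment": "blank",
                    "c_ref_ppm": cfg.c_supply_ppm
                    + rng.normal(0, nz.c_ref_ppm, n) * (nz.c_ref_ppm > 0),
                    "c_sample_ppm": c_s
                    + rng.normal(0, nz.c_sample_ppm, n) * (nz.c_sample_ppm > 0),
                    "w_ref_mmol": cfg.w_supply_mmol
                    + rng.normal(0, nz.w_ref_mmol, n) * (nz.w_ref_mmol > 0),
                    "w_sample_mmol": w_s
                    + rng.normal(0, nz.w_sample_mmol, n) * (nz.w_sample_mmol > 0),
                    "flow_mol_s": cfg.flow_mol_s,
                    "t_air_C": cfg.t_air_day_C
                    + cfg.t_air_amplitude_C * (s - 0.5)
                    if section == "shoot"
                    else 21.0,
                    "p_kpa": cfg.p_kpa,
                    "par_umol": cfg.par_peak_umol * s if section == "shoot" else 0.0,
                }
            )
        )
    return frames


def _dendro_for_tree(
    cfg: ScenarioConfig, tree: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Displacement trace plus the per-day true growth for one tree."""
    treatment = tree["treatment"]
    ts = _timestamps(cfg, cfg.dendro_interval_min)
    t_days = (ts - ts[0]) / pd.Timedelta(days=1)
    t_days = t_days.to_numpy()
    hour = ts.hour + ts.minute / 60.0
    day_idx = np.minimum(t_days.astype(int), cfg.total_days - 1)

    rng = _child_rng(cfg.seed, str(tree["tree_id"]), "dendro")
    jitter = max(0.0, rng.normal(1.0, 0.05))
    rate_day = cfg.growth_rate_by_day(treatment) * jitter  # mm2 d-1

    # place each day's growth within the day: a fraction inside the 05-17 h
    # midday window, the rest at night, piecewise-uniform
    f_day = cfg.daytime_growth_fraction[treatment]
    in_day = (hour >= 5.0) & (hour < 17.0)
    step_d = cfg.dendro_interval_min / (24.0 * 60.0)  # in days
    w = np.where(in_day, f_day / 0.5, (1.0 - f_day) / 0.5)  # per-day weight
    inc = rate_day[day_idx] * w * step_d
    envelope_area = np.concatenate([[0.0], np.cumsum(inc[:-1])])  # growth since t0

    d0 = tree["initial_diameter_mm"]
    a0 = np.pi * d0**2 / 4.0
    diam_env = np.sqrt(4.0 * (a0 + envelope_area) / np.pi)

    # reversible diurnal shrink (um of diameter), zero at night
    shrink = cfg.shrink_amplitude_um[treatment] * np.clip(
        np.sin(np.pi * (hour - 7.0) / 12.0), 0.0, None
    ) * np.where((hour >= 7.0) & (hour < 19.0), 1.0, 0.0)

    # severe drought contraction: only while the growth envelope is flat
    contraction = np.zeros_like(t_days)
    if treatment == "severe":
        end_d = float(cfg.drought_days)
        onset = min(float(cfg.severe_growth_fade_days), end_d)
        denom = max(end_d - onset, 1e-9)
        ramp = np.clip((t_days - onset) / denom, 0.0, 1.0)
        release = np.clip(
            1.0 - (t_days - end_d) / cfg.rehydration_days, 0.0, 1.0
        )
        contraction = cfg.severe_contraction_um * np.where(
            t_days < end_d, ramp, release
        )

    displacement = (diam_env - d0) * 1e3 - shrink - contraction
    nz = cfg.noise.dendro_um
    if nz > 0:
        displacement = displacement + rng.normal(0, nz, len(ts))

    trace = pd.DataFrame(
        {"timestamp": ts, "tree_id": tree["tree_id"], "displacement_um": displacement}
    )
    # true daily growth, booked the way dendrometer daily sums are formed:
    # the growth between consecutive readings belongs to the day of the
    # *later* reading, so day d closes at its last reading of the day
    dates = pd.date_range(cfg.start_date, periods=cfg.total_days, freq="D")
    steps_per_day = 24 * 60 // cfg.dendro_interval_min
    close_idx = np.arange(1, cfg.total_days + 1) * steps_per_day - 1
    boundary = envelope_area[close_idx]
    truth = pd.DataFrame(
        {
            "date": dates,
            "tree_id": tree["tree_id"],
            "growth_mm2_d": np.diff(boundary, prepend=0.0),
        }
    )
    return trace, truth


def _soil(cfg: ScenarioConfig, trees: pd.DataFrame) -> pd.DataFrame:
    dates = pd.date_range(cfg.start_date, periods=cfg.total_days, freq="D")
    frames = []
    for _, tree in trees.iterrows():
        swc = cfg.swc_by_day(tree["treatment"])
        rng = _child_rng(cfg.seed, str(tree["tree_id"]), "soil")
        if cfg.noise.swc_pct > 0:
            swc = swc + rng.normal(0, cfg.noise.swc_pct, len(swc))
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": dates,
                    "tree_id": tree["tree_id"],
                    "swc_pct": np.clip(swc, 0.0, None),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# treatment-level destructive-sample means, keyed by sampling day relative to
# drought start; intermediate days interpolate linearly
_DESTRUCTIVE_CURVES = {
    "psi_md_mpa": {
        "control": {0: -1.0, 14: -1.0, 28: -1.0, 30: -1.0, 42: -1.0, 63: -1.0},
        "mild": {0: -1.0, 14: -1.1, 28: -1.2, 30: -1.0, 42: -1.0, 63: -1.0},
        "severe": {0: -1.0, 14: -2.2, 28: -3.8, 30: -1.1, 42: -1.0, 63: -1.0},
    },
    "aba_ng_g": {
        "control": {0: 40, 14: 40, 28: 40, 30: 40, 42: 40, 63: 40},
        "mild": {0: 40, 14: 45, 28: 45, 30: 40, 42: 40, 63: 40},
        "severe": {0: 40, 14: 90, 28: 110, 30: 45, 42: 40, 63: 40},
    },
    "sugar_pct_dw": {
        "control": {0: 3.5, 14: 3.5, 28: 3.5, 30: 3.5, 42: 3.5, 63: 3.5},
        "mild": {0: 3.5, 14: 3.6, 28: 3.6, 30: 3.5, 42: 3.5, 63: 3.5},
        "severe": {0: 3.5, 14: 8.0, 28: 5.5, 30: 3.6, 42: 3.5, 63: 3.5},
    },
    "starch_pct_dw": {
        "control": {0: 3.4, 14: 3.4, 28: 3.4, 30: 3.4, 42: 3.4, 63: 3.4},
        "mild": {0: 3.4, 14: 3.3, 28: 3.3, 30: 3.4, 42: 3.4, 63: 3.4},
        "severe": {0: 3.4, 14: 1.0, 28: 0.0, 30: 3.4, 42: 4.5, 63: 3.5},
    },
}


def _destructive(cfg: ScenarioConfig) -> pd.DataFrame:
    start = pd.Timestamp(cfg.start_date)
    rows = []
    sd_by_var = {
        "psi_md_mpa": cfg.noise.psi_mpa,
        "aba_ng_g": cfg.noise.aba_ng_g,
        "sugar_pct_dw": cfg.noise.nsc_pct_dw,
        "starch_pct_dw": cfg.noise.nsc_pct_dw,
    }
    for day in cfg.destructive_days:
        day = min(day, cfg.total_days)
        date = start + pd.Timedelta(days=day)
        for treatment in TREATMENTS:
            for pilot in range(1, cfg.n_pilot_per_treatment + 1):
                rng = _child_rng(
                    cfg.seed, "destructive", treatment, f"p{pilot}", f"d{day}"
                )
                row = {
                    "date": date,
                    "treatment": treatment,
                    "pilot_id": f"{treatment}_pilot_{pilot:02d}",
                }
                for var, curves in _DESTRUCTIVE_CURVES.items():
                    curve = curves[treatment]
                    xs = np.array(sorted(curve))
                    ys = np.array([curve[x] for x in xs], dtype=float)
                    mean = float(np.interp(day, xs, ys))
                    sd = sd_by_var[var]
                    v = mean + (rng.normal(0, sd) if sd > 0 else 0.0)
                    if var != "psi_md_mpa":
                        v = max(v, 0.0)
                    row[var] = v
                rows.append(row)
    return pd.DataFrame(rows)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate one full synthetic dataset plus its ground truth.

    Deterministic for a fixed config (the seed lives in the config): calling
    twice yields bit-identical tables.
    """
    cfg = config
    trees = _sample_trees(cfg)
    ts = _timestamps(cfg, cfg.sampling_interval_min)
    hour = (ts.hour + ts.minute / 60.0).to_numpy()
    day_idx = np.minimum(
        ((ts - ts[0]) / pd.Timedelta(days=1)).to_numpy().astype(int),
        cfg.total_days - 1,
    )

    chamber_frames: list[pd.DataFrame] = []
    truth_flux_frames: list[pd.DataFrame] = []
    truth_e_frames: list[pd.DataFrame] = []
    dendro_frames: list[pd.DataFrame] = []
    truth_growth_frames: list[pd.DataFrame] = []

    effects = {t: cfg.flux_effect_by_day(t) for t in TREATMENTS}
    for _, tree in trees.iterrows():
        frames, tf, te = _chamber_for_tree(
            cfg, tree, ts, hour, day_idx, effects[tree["treatment"]]
        )
        chamber_frames.extend(frames)
        truth_flux_frames.append(tf)
        truth_e_frames.append(te)
        trace, tg = _dendro_for_tree(cfg, tree)
        dendro_frames.append(trace)
        truth_growth_frames.append(tg)
    chamber_frames.extend(_blank_chambers(cfg, ts, hour))

    dates = pd.date_range(cfg.start_date, periods=cfg.total_days, freq="D")
    effect_table = pd.concat(
        [
            pd.DataFrame(
                {"date": dates, "treatment": t, "flux_effect": effects[t]}
            )
            for t in TREATMENTS
        ],
        ignore_index=True,
    )

    truth = GroundTruth(
        fluxes=pd.concat(truth_flux_frames, ignore_index=True),
        transpiration=pd.concat(truth_e_frames, ignore_index=True),
        daily_growth=pd.concat(truth_growth_frames, ignore_index=True),
        flux_effects=effect_table,
    )
    return Scenario(
        chamber=pd.concat(chamber_frames, ignore_index=True),
        dendro=pd.concat(dendro_frames, ignore_index=True),
        trees=trees,
        soil=_soil(cfg, trees),
        destructive=_destructive(cfg),
        truth=truth,
        config=cfg,
    )


# ----------------------------------------------------------------------
# disk round trip

_FILES = {
    "chamber": "chamber.csv",
    "dendro": "dendro.csv",
    "trees": "trees.csv",
    "soil": "soil.csv",
    "destructive": "destructive.csv",
}


def _df_to_jsonable(df: pd.DataFrame) -> dict:
    out = {}
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_datetime64_any_dtype(s):
            out[col] = s.dt.strftime("%Y-%m-%dT%H:%M:%S").tolist()
        else:
            out[col] = s.tolist()
    return out


def _df_from_jsonable(d: dict, time_cols: tuple) -> pd.DataFrame:
    df = pd.DataFrame(d)
    for col in time_cols:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_scenario(scenario: Scenario, directory) -> list[Path]:
    """Write a scenario to CSV files (plus truth.json) in ``directory``.

    Floats are written at full round-trip precision so that
    ``read_scenario(write_scenario(s))`` reproduces every numeric column
    exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        path = directory / fname
        getattr(scenario, attr).to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    truth_path = directory / "truth.json"
    payload = {
        "fluxes": _df_to_jsonable(scenario.truth.fluxes),
        "transpiration": _df_to_jsonable(scenario.truth.transpiration),
        "daily_growth": _df_to_jsonable(scenario.truth.daily_growth),
        "flux_effects": _df_to_jsonable(scenario.truth.flux_effects),
    }
    truth_path.write_text(json.dumps(payload))
    written.append(truth_path)
    return written


def read_scenario(directory) -> Scenario:
    """Read a scenario directory written by :func:`write_scenario`.

    The configuration is not round-tripped (only data), so the returned
    scenario carries a default config with the file contents.
    """
    directory = Path(directory)
    tables = {}
    time_cols = {"chamber": ("timestamp",), "dendro": ("timestamp",),
                 "trees": (), "soil": ("timestamp",), "destructive": ("date",)}
    for attr, fname in _FILES.items():
        df = pd.read_csv(directory / fname)
        for col in time_cols[attr]:
            df[col] = pd.to_datetime(df[col])
        tables[attr] = df
    truth_file = directory / "truth.json"
    if truth_file.exists():
        payload = json.loads(truth_file.read_text())
        truth = GroundTruth(
            fluxes=_df_from_jsonable(payload["fluxes"], ("timestamp",)),
            transpiration=_df_from_jsonable(payload["transpiration"], ("timestamp",)),
            daily_growth=_df_from_jsonable(payload["daily_growth"], ("date",)),
            flux_effects=_df_from_jsonable(payload["flux_effects"], ("date",)),
        )
    else:
        empty = pd.DataFrame()
        truth = GroundTruth(empty, empty, empty, empty)
    return Scenario(config=ScenarioConfig(), truth=truth, **tables)
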