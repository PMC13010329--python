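"""End-to-end orchestration: simulate -> fluxes -> budgets -> growth -> summaries.

A run is driven by a :class:`RunConfig` (loadable from YAML) and produces a
directory of plain CSV artifacts plus a JSON manifest recording the
configuration hash, the seed and package versions.  Identical config and seed
give bit-identical artifact directories; the manifest carries a digest over
all output files so determinism can be checked by hash equality.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon import cumulative_carbon, daily_carbon, period_summary, tail_accumulation_rate
from .flux import CHAMBER_COLUMNS, compute_fluxes
from .growth import (
    daily_growth,
    huber_series,
    recovery_mask,
    start_of_day_hv,
    to_basal_area,
    zero_growth,
)
from .simulate import Scenario, ScenarioConfig, generate_scenario, read_scenario, write_scenario
from .summaries import (
    DAYTIME_WINDOW,
    NIGHTTIME_WINDOW,
    WindowSpec,
    treatment_stats,
    window_mean,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "simulate_to_dir"]

log = logging.getLogger("treeflux")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Period boundaries are half-open dates: the drought period is
    ``[drought_start, recovery_start)``, recovery ``[recovery_start,
    experiment_end)``, and the experimental period spans both.
    """

    drought_start: str = "2023-06-06"
    recovery_start: str = "2023-07-04"
    experiment_end: str = "2023-08-08"
    resample_interval: str = "1h"
    gap_limit: str = "3h"
    blank_tolerance: str = "90min"
    min_valid_hours: int = 12
    tail_window_days: int = 10
    daytime_window: tuple = DAYTIME_WINDOW
    nighttime_window: tuple = NIGHTTIME_WINDOW
    hv_sapwood_rule: str = "running_max"
    start_of_day_hour: float = 5.0
    seed: int = 0

    def __post_init__(self):
        dates = [
            pd.Timestamp(self.drought_start),
            pd.Timestamp(self.recovery_start),
            pd.Timestamp(self.experiment_end),
        ]
        if not (dates[0] < dates[1] < dates[2]):
            raise ValueError("period dates must be ordered")
        if self.min_valid_hours <= 0 or self.tail_window_days <= 0:
            raise ValueError("thresholds must be positive")

    @property
    def periods(self) -> dict:
        d0, r0, e0 = (
            pd.Timestamp(self.drought_start),
            pd.Timestamp(self.recovery_start),
            pd.Timestamp(self.experiment_end),
        )
        return {
            "drought": (d0, r0),
            "recovery": (r0, e0),
            "experimental": (d0, e0),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _directory_digest(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def simulate_to_dir(config: ScenarioConfig, out_dir) -> Scenario:
    """Generate a scenario and write it (with a manifest) to ``out_dir``."""
    scenario = generate_scenario(config)
    written = write_scenario(scenario, out_dir)
    manifest = {
        "stage": "simulate",
        "seed": config.seed,
        "treeflux_version": __version__,
        "digest": _directory_digest(written),
    }
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return scenario


def validate_inputs(directory) -> list[dict]:
    """Schema and plausibility checks on a scenario directory.

    Returns a machine-readable issue list; empty means valid.  Checks: files
    present, required columns, positive flow, CO2 in a plausible 300-1000 ppm
    band, water mole fraction below 1000 mmol, per-chamber timestamp
    monotonicity, positive leaf areas.
    """
    directory = Path(directory)
    issues: list[dict] = []

    def issue(file, kind, detail, row=None):
        entry = {"file": file, "kind": kind, "detail": detail}
        if row is not None:
            entry["row"] = int(row)
        issues.append(entry)

    required = {
        "chamber.csv": CHAMBER_COLUMNS,
        "dendro.csv": ["timestamp", "tree_id", "displacement_um"],
        "trees.csv": ["tree_id", "treatment", "leaf_area_m2", "initial_diameter_mm"],
        "soil.csv": ["timestamp", "tree_id", "swc_pct"],
    }
    tables = {}
    for fname, cols in required.items():
        path = directory / fname
        if not path.exists():
            issue(fname, "missing-file", f"{fname} not found")
            continue
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            issue(fname, "missing-columns", f"columns absent: {missing}")
            continue
        tables[fname] = df

    ch = tables.get("chamber.csv")
    if ch is not None:
        bad_flow = ch.index[ch["flow_mol_s"] <= 0]
        for r in bad_flow[:5]:
            issue("chamber.csv", "non-positive-flow", "flow_mol_s must be > 0", r)
        for col in ("c_ref_ppm", "c_sample_ppm"):
            out = ch.index[(ch[col] < 300) | (ch[col] > 1000)]
            for r in out[:5]:
                issue("chamber.csv", "implausible-co2", f"{col} outside 300-1000 ppm", r)
        for col in ("w_ref_mmol", "w_sample_mmol"):
            out = ch.index[(ch[col] < 0) | (ch[col] >= 1000)]
            for r in out[:5]:
                issue("chamber.csv", "invalid-humidity", f"{col} outside [0, 1000)", r)
        for (tree, comp), grp in ch.groupby(["tree_id", "compartment"]):
            ts = pd.to_datetime(grp["timestamp"])
            if not ts.is_monotonic_increasing:
                issue(
                    "chamber.csv",
                    "non-monotonic-timestamps",
                    f"chamber {tree}/{comp} timestamps not sorted",
                )
    tr = tables.get("trees.csv")
    if tr is not None:
        for r in tr.index[tr["leaf_area_m2"] <= 0][:5]:
            issue("trees.csv", "non-positive-leaf-area", "leaf_area_m2 must be > 0", r)
        for r in tr.index[tr["initial_diameter_mm"] <= 0][:5]:
            issue("trees.csv", "non-positive-diameter", "initial_diameter_mm must be > 0", r)
    return issues


def run_pipeline(config: RunConfig, in_dir, out_dir) -> dict:
    """Analyze a scenario directory and write all derived artifacts.

    Stages: flux computation (with blank subtraction), daily/cumulative
    carbon budgets and period summaries, zero-growth extraction with Huber
    series, and window-averaged gas-exchange summaries.  Returns the manifest
    dictionary.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    issues = validate_inputs(in_dir)
    if issues:
        raise ValueError(f"input validation failed: {issues[:3]} ...")
    scenario = read_scenario(in_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
        log.info("%s: %d rows", name, len(df))

    # ---- gas exchange ------------------------------------------------
    flux = compute_fluxes(
        scenario.chamber, scenario.trees, blank_tolerance=config.blank_tolerance
    )
    emit(flux, "flux.csv")

    # ---- carbon budget ----------------------------------------------
    daily = daily_carbon(flux, min_valid_hours=config.min_valid_hours)
    cum = cumulative_carbon(daily)
    emit(cum, "daily_carbon.csv")
    summary = period_summary(daily, scenario.trees, config.periods)
    emit(summary, "period_summary.csv")
    tail = tail_accumulation_rate(cum, window_days=config.tail_window_days)
    tail = tail.merge(scenario.trees[["tree_id", "treatment"]], on="tree_id")
    emit(tail, "tail_rates.csv")

    # ---- growth ------------------------------------------------------
    growth_frames, daily_growth_frames, hv_frames, sod_frames = [], [], [], []
    for _, tree in scenario.trees.iterrows():
        trace = scenario.dendro[scenario.dendro["tree_id"] == tree["tree_id"]]
        dendro = to_basal_area(trace, tree["initial_diameter_mm"])
        g = zero_growth(dendro)
        g = recovery_mask(g, config.recovery_start)
        growth_frames.append(
            g[["timestamp", "tree_id", "basal_area_mm2", "growth_cum_mm2", "twd_mm2"]]
        )
        dg = daily_growth(g)
        dg.insert(1, "tree_id", tree["tree_id"])
        daily_growth_frames.append(dg)
        hv = huber_series(
            dendro, tree["leaf_area_m2"], sapwood_rule=config.hv_sapwood_rule
        )
        hv_frames.append(hv)
        sod = start_of_day_hv(hv, hour=config.start_of_day_hour)
        sod.insert(1, "tree_id", tree["tree_id"])
        sod_frames.append(sod)
    emit(pd.concat(growth_frames, ignore_index=True), "growth.csv")
    emit(pd.concat(daily_growth_frames, ignore_index=True), "daily_growth.csv")
    emit(pd.concat(hv_frames, ignore_index=True), "huber.csv")
    emit(pd.concat(sod_frames, ignore_index=True), "huber_start_of_day.csv")

    # ---- window summaries -------------------------------------------
    day_w = WindowSpec("daytime", *config.daytime_window)
    night_w = WindowSpec("nighttime", *config.nighttime_window)
    shoot = flux[flux["compartment"] == "shoot"]
    summary_frames = []
    for var in ("gsw_mmol_m2_s", "anet_umol_m2_s", "wuei_umol_mol", "e_mmol_m2_s"):
        for w in (day_w, night_w):
            per_day = window_mean(shoot, w, var)
            col = f"{var}_{w.name}"
            per_tree = per_day.groupby("tree_id", as_index=False)[col].mean()
            per_tree = per_tree.merge(
                scenario.trees[["tree_id", "treatment"]], on="tree_id"
            )
            st = treatment_stats(per_tree, col)
            st.insert(0, "window", w.name)
            st.insert(0, "variable", var)
            summary_frames.append(st)
    emit(pd.concat(summary_frames, ignore_index=True), "summaries.csv")

    manifest = {
        "stage": "analyze",
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "treeflux_version": __version__,
        "pandas_version": pd.__version__,
        "numpy_version": np.__version__,
        "artifacts": [p.name for p in written],
        "digest": _directory_digest(written),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
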