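"""Scenario generator tests: determinism, invertibility, ground-truth honesty."""

import numpy as np
import pandas as pd
import pytest

from treeflux.carbon import M_C, SECONDS_PER_DAY, daily_carbon
from treeflux.flux import compute_fluxes, dry_mole_fraction
from treeflux.growth import to_basal_area, zero_growth
from treeflux.simulate import (
    NoiseConfig,
    ScenarioConfig,
    _invert_chamber,
    generate_scenario,
    read_scenario,
    write_scenario,
)


def tiny_config(**kwargs):
    defaults = dict(
        n_trees_per_treatment=1,
        drought_days=3,
        recovery_days=4,
        dendro_interval_min=60,
        noise=NoiseConfig.zero(),
        seed=3,
    )
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


class TestConfigValidation:
    def test_bad_treatment_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_trees_per_treatment={"flooded": 3})

    def test_zero_trees_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_trees_per_treatment={"control": 0})

    def test_interval_must_divide_day(self):
        with pytest.raises(ValueError):
            ScenarioConfig(sampling_interval_min=77)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig(c_ref_ppm=-0.1)

    def test_effect_multipliers_bounded(self):
        cfg = ScenarioConfig()
        for t in ("control", "mild", "severe"):
            eff = cfg.flux_effect_by_day(t)
            assert len(eff) == cfg.total_days
            assert np.all((eff >= 0) & (eff <= 1))


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg = tiny_config(noise=NoiseConfig())
        a, b = generate_scenario(cfg), generate_scenario(cfg)
        for attr in ("chamber", "dendro", "trees", "soil", "destructive"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))

    def test_seed_changes_noise(self):
        a = generate_scenario(tiny_config(noise=NoiseConfig(), seed=1))
        b = generate_scenario(tiny_config(noise=NoiseConfig(), seed=2))
        assert not np.allclose(a.chamber["c_sample_ppm"], b.chamber["c_sample_ppm"])

    def test_adding_trees_preserves_existing_streams(self):
        small = generate_scenario(tiny_config(noise=NoiseConfig()))
        big = generate_scenario(
            tiny_config(noise=NoiseConfig(), n_trees_per_treatment=2)
        )
        a = small.chamber[small.chamber["tree_id"] == "control_01"]
        b = big.chamber[big.chamber["tree_id"] == "control_01"]
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


class TestChamberInversion:
    def test_zero_flux_zero_background(self):
        # no plant, no background: the sample stream equals the supply
        cfg = tiny_config(
            anet_peak_umol=0.0, rd_umol=0.0, e_peak_mmol=0.0, e_night_mmol=0.0,
            background_co2_mol_s=0.0, background_h2o_mol_s=0.0,
        )
        sc = generate_scenario(cfg)
        shoot = sc.chamber[sc.chamber["compartment"] == "shoot"]
        c_s = dry_mole_fraction(shoot["c_sample_ppm"], shoot["w_sample_mmol"])
        c_r = dry_mole_fraction(shoot["c_ref_ppm"], shoot["w_ref_mmol"])
        assert np.abs(c_s - c_r).max() < 1e-9

    def test_constant_flux_differential(self):
        # 1e-7 mol/s through 0.01 mol/s of dry airflow depletes 10 ppm
        cfg = tiny_config(flow_mol_s=0.01, background_co2_mol_s=0.0,
                          background_h2o_mol_s=0.0)
        c_sample_wet, w_sample = _invert_chamber(
            cfg, np.array([1e-7]), np.array([0.0])
        )
        c_s_dry = dry_mole_fraction(c_sample_wet[0], w_sample[0])
        c_r_dry = dry_mole_fraction(cfg.c_supply_ppm, cfg.w_supply_mmol)
        assert c_r_dry - c_s_dry == pytest.approx(10.0, rel=1e-12)

    def test_noise_free_flux_recovery(self, oracle_scenario):
        flux = compute_fluxes(oracle_scenario.chamber, oracle_scenario.trees)
        m = flux.merge(
            oracle_scenario.truth.fluxes,
            on=["timestamp", "tree_id", "compartment"],
            suffixes=("", "_true"),
        )
        err = np.abs(m["f_co2_mol_s"] - m["f_co2_mol_s_true"]).max()
        scale = m["f_co2_mol_s_true"].abs().max()
        assert err / scale < 1e-12

    def test_noisy_daily_rates_unbiased(self, noisy_scenario):
        # over ~60 simulated days the daily-rate error has mean within 2 SE of 0
        flux = compute_fluxes(noisy_scenario.chamber, noisy_scenario.trees)
        daily = daily_carbon(flux)
        truth = noisy_scenario.truth.fluxes.copy()
        truth["date"] = pd.to_datetime(truth["timestamp"]).dt.normalize()
        truth_daily = (
            truth.groupby(["tree_id", "date"])["f_co2_mol_s"].mean()
            * M_C
            * SECONDS_PER_DAY
            * 2  # shoot + root mean over both compartments -> sum of means
        ).rename("true_plant_gc_d").reset_index()
        m = daily.merge(truth_daily, on=["tree_id", "date"])
        err = m["c_plant_gc_d"] - m["true_plant_gc_d"]
        assert abs(err.mean()) < 2 * err.std(ddof=1) / np.sqrt(len(err))


class TestDendroTruth:
    def test_running_max_equals_injected_growth(self, oracle_scenario):
        for _, tree in oracle_scenario.trees.iterrows():
            trace = oracle_scenario.dendro[
                oracle_scenario.dendro["tree_id"] == tree["tree_id"]
            ]
            dendro = to_basal_area(trace, tree["initial_diameter_mm"])
            area = dendro["basal_area_mm2"]
            injected = oracle_scenario.truth.daily_growth
            total = injected[injected["tree_id"] == tree["tree_id"]][
                "growth_mm2_d"
            ].sum()
            assert area.cummax().iloc[-1] - area.iloc[0] == pytest.approx(
                total, abs=1e-9
            )

    def test_daily_growth_matches_truth(self, oracle_scenario):
        from treeflux.growth import daily_growth

        tree = oracle_scenario.trees.iloc[0]
        trace = oracle_scenario.dendro[
            oracle_scenario.dendro["tree_id"] == tree["tree_id"]
        ]
        g = zero_growth(to_basal_area(trace, tree["initial_diameter_mm"]))
        recovered = daily_growth(g)
        truth = oracle_scenario.truth.daily_growth
        truth = truth[truth["tree_id"] == tree["tree_id"]]
        m = recovered.merge(truth, on="date", suffixes=("_rec", "_true"))
        assert np.abs(
            m["growth_mm2_d_rec"] - m["growth_mm2_d_true"]
        ).max() < 1e-9


class TestRoundTrip:
    def test_file_set(self, tmp_path):
        sc = generate_scenario(tiny_config())
        written = write_scenario(sc, tmp_path)
        names = {p.name for p in written}
        assert {"chamber.csv", "dendro.csv", "trees.csv", "soil.csv",
                "destructive.csv", "truth.json"} <= names

    def test_numeric_round_trip(self, tmp_path):
        sc = generate_scenario(tiny_config(noise=NoiseConfig()))
        write_scenario(sc, tmp_path)
        back = read_scenario(tmp_path)
        for attr in ("chamber", "dendro", "soil"):
            orig, rt = getattr(sc, attr), getattr(back, attr)
            for col in orig.columns:
                if pd.api.types.is_float_dtype(orig[col]):
                    assert np.abs(orig[col] - rt[col]).max() < 1e-9
        pd.testing.assert_frame_equal(
            sc.truth.daily_growth, back.truth.daily_growth
        )

    def test_empty_destructive_header_only(self, tmp_path):
        sc = generate_scenario(tiny_config())
        sc.destructive = sc.destructive.iloc[0:0]
        write_scenario(sc, tmp_path)
        lines = (tmp_path / "destructive.csv").read_text().strip().splitlines()
        assert len(lines) == 1 and "treatment" in lines[0]
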