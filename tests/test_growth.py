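"""Zero-growth decomposition, diurnal partitioning and Huber-value tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from treeflux.growth import (
    daily_growth,
    diurnal_partition,
    huber_series,
    recovery_mask,
    start_of_day_hv,
    to_basal_area,
    zero_growth,
)


def area_of(diameter_mm):
    return np.pi * np.asarray(diameter_mm, dtype=float) ** 2 / 4.0


def trace_from_areas(areas, freq="1h", start="2023-06-06"):
    ts = pd.date_range(start, periods=len(areas), freq=freq)
    return pd.DataFrame(
        {"timestamp": ts, "tree_id": "t1", "basal_area_mm2": np.asarray(areas, float)}
    )


def brute_force_zero_growth(areas):
    """Independent oracle: explicit loop tracking the running maximum."""
    growth, twd = [], []
    m = areas[0]
    for a in areas:
        m = max(m, a)
        growth.append(m - areas[0])
        twd.append(m - a)
    return np.array(growth), np.array(twd)


class TestBasalArea:
    def test_initial_area(self):
        out = to_basal_area(
            pd.DataFrame(
                {"timestamp": ["2023-06-06"], "tree_id": "t1", "displacement_um": [0.0]}
            ),
            10.0,
        )
        assert out["basal_area_mm2"].iloc[0] == pytest.approx(78.5398, abs=1e-4)

    def test_displacement_shift(self):
        out = to_basal_area(
            pd.DataFrame(
                {"timestamp": ["2023-06-06"], "tree_id": "t1",
                 "displacement_um": [1000.0]}
            ),
            10.0,
        )
        assert out["diameter_mm"].iloc[0] == pytest.approx(11.0)
        assert out["basal_area_mm2"].iloc[0] == pytest.approx(95.0332, abs=1e-4)

    def test_constant_trace_constant_area(self):
        out = to_basal_area(
            pd.DataFrame(
                {
                    "timestamp": pd.date_range("2023-06-06", periods=5, freq="1h"),
                    "tree_id": "t1",
                    "displacement_um": 40.0,
                }
            ),
            10.0,
        )
        assert out["basal_area_mm2"].nunique() == 1

    def test_rejects_bad_inputs(self):
        df = pd.DataFrame(
            {"timestamp": ["2023-06-06"], "tree_id": "t1",
             "displacement_um": [-20000.0]}
        )
        with pytest.raises(ValueError):
            to_basal_area(df, 10.0)
        with pytest.raises(ValueError):
            to_basal_area(df, -1.0)


class TestZeroGrowth:
    def test_shrink_then_regrow(self):
        # growth is booked only on the two steps that exceed the prior max
        g = zero_growth(trace_from_areas(area_of([10.0, 10.1, 10.05, 10.2])))
        inc = g["growth_increment_mm2"].to_numpy()
        assert inc[0] == 0 and inc[2] == 0
        assert inc[1] > 0 and inc[3] > 0
        # cumulative growth spans area(10.2) - area(10.0) = 3.17301 mm2
        assert g["growth_cum_mm2"].iloc[-1] == pytest.approx(3.17301, abs=1e-4)

    def test_monotone_shrink(self):
        g = zero_growth(trace_from_areas([80, 79, 78, 77.5]))
        assert (g["growth_cum_mm2"] == 0).all()
        assert (g["twd_mm2"].iloc[1:] > 0).all()

    def test_monotone_growth(self):
        areas = [78, 79, 80.5, 81]
        g = zero_growth(trace_from_areas(areas))
        assert g["growth_cum_mm2"].iloc[-1] == pytest.approx(3.0)
        assert (g["twd_mm2"] == 0).all()

    def test_unsorted_rejected(self):
        t = trace_from_areas([78, 79, 80])
        with pytest.raises(ValueError):
            zero_growth(t.iloc[::-1])

    @given(
        arrays(
            np.float64,
            st.integers(10, 400),
            elements=st.floats(50.0, 150.0, allow_nan=False),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, areas):
        g = zero_growth(trace_from_areas(areas, freq="10min"))
        growth, twd = brute_force_zero_growth(areas)
        assert np.array_equal(g["growth_cum_mm2"].to_numpy(), growth)
        assert np.array_equal(g["twd_mm2"].to_numpy(), twd)
        # structural invariants on arbitrary traces
        assert (np.diff(g["growth_cum_mm2"]) >= 0).all()
        assert (g["twd_mm2"] >= 0).all()


class TestDailyGrowth:
    def test_step_jump(self):
        areas = np.full(72, 80.0)
        areas[30:] = 81.0  # one 1-mm2 jump on day 2
        dg = daily_growth(zero_growth(trace_from_areas(areas)))
        assert dg["growth_mm2_d"].to_numpy() == pytest.approx([0.0, 1.0, 0.0])

    def test_pure_shrink_swell_below_max(self):
        hours = np.arange(96)
        areas = 80.0 - 0.5 * np.clip(np.sin(np.pi * (hours % 24 - 7) / 12), 0, None)
        dg = daily_growth(zero_growth(trace_from_areas(areas)))
        assert (dg["growth_mm2_d"] == 0).all()

    def test_linear_growth_rate_recovered(self):
        rate = 0.58  # mm2 d-1
        hours = np.arange(24 * 10)
        areas = 78.0 + rate * hours / 24.0
        dg = daily_growth(zero_growth(trace_from_areas(areas)))
        # interior days carry exactly the injected rate
        assert dg["growth_mm2_d"].iloc[1:-1].to_numpy() == pytest.approx(rate)


class TestRecoveryMask:
    def _growth_with_jump(self, jump_day):
        areas = np.full(24 * 5, 80.0)
        areas[24 * jump_day:] = 82.0
        return zero_growth(trace_from_areas(areas))

    def test_rehydration_not_growth(self):
        # shrink during "drought", return to the old maximum on recovery day 1
        areas = np.concatenate(
            [np.full(48, 80.0), np.full(24, 78.0), np.full(24, 80.0)]
        )
        g = zero_growth(trace_from_areas(areas))
        g = recovery_mask(g, "2023-06-09")
        dg = daily_growth(g)
        assert (dg["growth_mm2_d"] == 0).all()

    def test_day1_overshoot_masked(self):
        g = self._growth_with_jump(jump_day=2)
        masked = recovery_mask(g, "2023-06-08")  # jump lands on recovery day 1
        dg = daily_growth(masked)
        assert (dg["growth_mm2_d"] == 0).all()

    def test_control_unaffected(self):
        g = self._growth_with_jump(jump_day=2)
        dg_masked = daily_growth(recovery_mask(g, "2023-06-10"))
        dg_raw = daily_growth(g)
        assert dg_masked["growth_mm2_d"].to_numpy() == pytest.approx(
            dg_raw["growth_mm2_d"].to_numpy()
        )


class TestDiurnalPartition:
    def _hourly_growth(self, weight_fn, days=4):
        ts = pd.date_range("2023-06-06", periods=24 * days, freq="1h")
        inc = np.array([weight_fn(t.hour) for t in ts], dtype=float)
        return pd.DataFrame(
            {
                "timestamp": ts,
                "tree_id": "t1",
                "growth_increment_mm2": inc,
                "growth_cum_mm2": np.cumsum(inc),
            }
        )

    def test_night_only_growth(self):
        g = self._hourly_growth(lambda h: 0.01 if h < 5 else 0.0)
        out = diurnal_partition(g)
        assert out["daytime_rate"] == pytest.approx(0.0, abs=1e-12)
        assert out["daytime_fraction"] == pytest.approx(0.0)

    def test_uniform_growth_splits_half(self):
        out = diurnal_partition(self._hourly_growth(lambda h: 0.01))
        assert out["daytime_fraction"] == pytest.approx(0.5)

    def test_thirty_percent_fixture(self):
        # 30% of each day's growth placed in the 05-17 window
        total = 0.48
        day_inc = 0.30 * total / 12
        night_inc = 0.70 * total / 12
        g = self._hourly_growth(lambda h: day_inc if 5 <= h < 17 else night_inc)
        out = diurnal_partition(g)
        assert out["daytime_fraction"] == pytest.approx(0.30, abs=1e-9)

    def test_partition_completeness(self, rng):
        g = self._hourly_growth(lambda h: 0.0)
        g["growth_increment_mm2"] = rng.uniform(0, 0.01, len(g))
        out = diurnal_partition(g)
        assert out["daytime_growth_mm2"] + out["nighttime_growth_mm2"] == pytest.approx(
            out["total_growth_mm2"], rel=1e-12
        )

    def test_no_growth_fraction_undefined(self):
        out = diurnal_partition(self._hourly_growth(lambda h: 0.0))
        assert np.isnan(out["daytime_fraction"])

    def test_bad_window(self):
        with pytest.raises(ValueError):
            diurnal_partition(self._hourly_growth(lambda h: 0.01), day_window=(17, 5))


class TestHuber:
    def _dendro(self, areas):
        return trace_from_areas(areas)

    def test_operating_point(self):
        # 78.5 mm2 of sapwood over 981 cm2 of leaves is Hv ~ 0.080
        hv = huber_series(self._dendro([78.5]), leaf_area_m2=0.0981)
        assert hv["hv_mm2_cm2"].iloc[0] == pytest.approx(0.080, abs=5e-4)

    def test_leaf_area_scaling(self):
        a = huber_series(self._dendro([78.5]), 0.0981)["hv_mm2_cm2"].iloc[0]
        b = huber_series(self._dendro([78.5]), 2 * 0.0981)["hv_mm2_cm2"].iloc[0]
        assert b == pytest.approx(a / 2)

    def test_running_max_never_decreases(self):
        areas = [80, 81, 79, 78, 82, 80]
        hv = huber_series(self._dendro(areas), 0.1, sapwood_rule="running_max")
        assert (np.diff(hv["hv_mm2_cm2"]) >= 0).all()
        hv_inst = huber_series(self._dendro(areas), 0.1, sapwood_rule="instantaneous")
        assert (np.diff(hv_inst["hv_mm2_cm2"]) < 0).any()

    def test_invalid_rule(self):
        with pytest.raises(ValueError):
            huber_series(self._dendro([80.0]), 0.1, sapwood_rule="bark_only")


class TestStartOfDayHv:
    def _hv(self, hours, values, start="2023-06-06"):
        ts = [pd.Timestamp(start) + pd.Timedelta(hours=h) for h in hours]
        return pd.DataFrame({"timestamp": ts, "hv_mm2_cm2": values})

    def test_constant_series(self):
        hv = self._hv(np.arange(48), np.full(48, 0.08))
        out = start_of_day_hv(hv)
        assert (out["hv_mm2_cm2"] == 0.08).all()
        assert len(out) == 2

    def test_step_at_noon_reports_morning_value(self):
        values = np.where(np.arange(24) < 12, 0.08, 0.10)
        out = start_of_day_hv(self._hv(np.arange(24), values))
        assert out["hv_mm2_cm2"].iloc[0] == pytest.approx(0.08)

    def test_gap_rule(self):
        # missing 05:00 sample: nearest within 1 h is used, farther is missing
        out_near = start_of_day_hv(self._hv([0.0, 4.5, 12.0], [0.07, 0.08, 0.09]))
        assert out_near["hv_mm2_cm2"].iloc[0] == pytest.approx(0.08)
        out_far = start_of_day_hv(self._hv([0.0, 10.0, 12.0], [0.07, 0.08, 0.09]))
        assert np.isnan(out_far["hv_mm2_cm2"].iloc[0])
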