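"""Standing length, increments, mortality and morphology arithmetic."""

import numpy as np
import pandas as pd
import pytest

from rootdyn.dynamics import (
    GrowthSeries,
    elongation_rate,
    logit_transform,
    ln_transform,
    morphology_summary,
    mortality,
    net_increment,
    standing_length,
)
from rootdyn.records import ImagingSchedule, RootObservationSet
from rootdyn.simulate import DemographyParams, gaussian_season_intensity, simulate_root_demography

FRAME_AREA = 46 * 0.013 * 0.018  # 46 frames of 13 x 18 mm^2


class TestStandingLength:
    def test_no_live_roots_zero_everywhere(self, three_root_set, schedule):
        none = three_root_set.subset(seedling_id="nope")
        series = standing_length(none, schedule)
        assert np.all(series.values == 0.0)

    def test_frame_area_normalization(self, schedule):
        """0.010 m + 0.020 m live in a 0.010764 m^2 frame -> 2.787 m/m^2."""
        rows = [
            ("s1", "r1", "live", 0.010, 0, "short", "Cool"),
            ("s1", "r2", "live", 0.020, 0, "short", "Cool"),
        ]
        df = pd.DataFrame(rows, columns=["seedling_id", "root_id", "status",
                                         "length_m", "session_day", "root_class", "treatment"])
        obs = RootObservationSet(df)
        series = standing_length(obs, schedule)
        assert series.values[0] == pytest.approx(0.030 / FRAME_AREA, rel=1e-6)
        assert series.values[0] == pytest.approx(2.787, abs=0.001)

    def test_class_reassignment_conserves_total(self, three_root_table, schedule):
        obs1 = RootObservationSet(three_root_table)
        flipped = three_root_table.copy()
        flipped.loc[flipped.root_id == "r2", "root_class"] = "long"
        obs2 = RootObservationSet(flipped)
        tot1 = standing_length(obs1, schedule).values
        tot2 = standing_length(obs2, schedule).values
        assert np.allclose(tot1, tot2)
        short1 = standing_length(obs1, schedule, root_class="short").values
        short2 = standing_length(obs2, schedule, root_class="short").values
        assert not np.allclose(short1, short2)

    def test_root_id_permutation_invariance(self, three_root_table, schedule):
        shuffled = three_root_table.sample(frac=1.0, random_state=0)
        a = standing_length(RootObservationSet(three_root_table), schedule).values
        b = standing_length(RootObservationSet(shuffled), schedule).values
        assert np.array_equal(a, b)


class TestIncrementsAndRates:
    def test_net_increment_zero_at_season_start(self):
        s = GrowthSeries([0, 21, 42], [1.0, 2.5, 2.0])
        inc = net_increment(s, 0)
        assert inc.values[0] == 0.0
        assert inc.values[2] == pytest.approx(1.0)

    def test_constant_series_all_zeros(self):
        inc = net_increment(GrowthSeries([0, 21, 42], [3.0, 3.0, 3.0]), 0)
        assert np.allclose(inc.values, 0.0)

    def test_rate_arithmetic(self):
        r = elongation_rate(GrowthSeries([0.0, 10.0], [1.0, 3.0]))
        assert r.values[0] == pytest.approx(0.2)

    def test_declining_series_negative_rate(self):
        r = elongation_rate(GrowthSeries([0.0, 10.0], [3.0, 1.0]))
        assert r.values[0] < 0

    def test_rates_telescope(self):
        rng = np.random.default_rng(0)
        days = np.cumsum(rng.integers(5, 25, 10)).astype(float)
        vals = rng.normal(5, 1, 10)
        s = GrowthSeries(days, vals)
        assert np.sum(s.rates * np.diff(days)) == pytest.approx(vals[-1] - vals[0])

    def test_non_increasing_days_rejected(self):
        with pytest.raises(ValueError):
            GrowthSeries([0, 0, 21], [1, 2, 3])


class TestMortality:
    def test_no_deaths_share_zero(self, three_root_set, schedule):
        live_only = three_root_set.subset(root_class="long")  # r3 never dies
        m = mortality(live_only, schedule)
        assert np.all(m.share == 0.0)

    def test_share_thirds(self, schedule):
        """live 2.0, cumulative dead 1.0 -> share 1/3; all dead -> share 1."""
        area = schedule.frame_area_m2
        rows = [
            ("s1", "dies", "live", 1.0 * area, 0, "short", "Cool"),
            ("s1", "dies", "dead", 0.0, 21, "short", "Cool"),
            ("s1", "lives", "live", 2.0 * area, 0, "short", "Cool"),
            ("s1", "lives", "live", 2.0 * area, 21, "short", "Cool"),
        ]
        df = pd.DataFrame(rows, columns=["seedling_id", "root_id", "status",
                                         "length_m", "session_day", "root_class", "treatment"])
        m = mortality(RootObservationSet(df), ImagingSchedule(session_days=np.array([0, 21])))
        assert m.share[1] == pytest.approx(1.0 / 3.0)
        only_dead = df[df.root_id == "dies"]
        m2 = mortality(RootObservationSet(only_dead), ImagingSchedule(session_days=np.array([0, 21])))
        assert m2.share[1] == pytest.approx(1.0)

    def test_dead_length_uses_last_live_length(self, three_root_set, schedule):
        m = mortality(three_root_set.subset(root_class="short"), schedule)
        # r1 last live 0.015 at day 42, dead at 63; r2 last live 0.007 at 21,
        # disappeared at 42
        assert m.dead_length[np.nonzero(schedule.session_days == 63)[0][0]] \
            == pytest.approx(0.015 / FRAME_AREA)
        assert m.dead_length[np.nonzero(schedule.session_days == 42)[0][0]] \
            == pytest.approx(0.007 / FRAME_AREA)

    def test_conservation_of_length(self):
        """l_area(t) - l_area(t0) equals production minus mortality when
        every root's growth and death are fully observed."""
        sched = ImagingSchedule(session_days=np.arange(0, 400, 21), seasons={"GS": (0, 399)})
        params = DemographyParams(
            n_seedlings=2, schedule=sched,
            appearance_intensity=gaussian_season_intensity(80, 40, 25, 0, 399),
            longevity_weibull={"Cool": (1.5, 150.0)},
            treatment_of_seedling=lambda s: "Cool", seed=3,
        )
        obs, _ = simulate_root_demography(params)
        sl = standing_length(obs, sched)
        mort = mortality(obs, sched)
        # production per interval: sum over roots of positive length change
        prod = np.zeros(len(sched.session_days))
        for _, root in obs.table.groupby("root_id"):
            lengths = root.length_m.to_numpy()
            prod[1:] += np.maximum(np.diff(lengths), 0.0)
        prod /= sched.frame_area_m2
        lhs = sl.values - sl.values[0]
        rhs = np.cumsum(prod) - np.cumsum(mort.dead_length)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestMorphology:
    SCAN = pd.DataFrame({
        "diameter_class": ["d<=0.5", "0.5<d<=1", "1<d<=2", "2<d<=4.5"],
        "length_m": [20.0, 10.0, 5.5, 1.0],
        "surface_m2": [0.3, 0.2, 0.15, 0.05],
        "volume_cm3": [40.0, 30.0, 30.0, 10.0],
        "tips": [50_000.0, 20_000.0, 8_000.0, 1_000.0],
    })

    def test_srl_ratio(self):
        s = morphology_summary(self.SCAN, {"d<=2": 1.0})
        assert s.srl_m_per_g["d<=2"] == pytest.approx(35.5)

    def test_tissue_density_units(self):
        s = morphology_summary(self.SCAN, {"d<=2": 9.5})
        assert s.tissue_density_kg_m3["d<=2"] == pytest.approx(95.0)

    def test_identity_upscale(self):
        s = morphology_summary(self.SCAN, {"d<=2": 1.0}, 100.0, 100.0)
        assert s.upscale_factor == 1.0
        assert s.table["length_m"].sum() == pytest.approx(36.5)

    def test_upscale_by_volume_ratio(self):
        s = morphology_summary(self.SCAN, {"d<=2": 1.0}, 100.0, 250.0)
        assert s.table["length_m"].sum() == pytest.approx(36.5 * 2.5)

    def test_zero_mass_with_length_rejected(self):
        with pytest.raises(ValueError, match="zero mass"):
            morphology_summary(self.SCAN, {"d<=2": 0.0})


def test_transforms_roundtrip():
    x = np.array([0.5, 1.0, 2.0])
    assert np.allclose(np.exp(ln_transform(x)), x)
    p = np.array([0.2, 0.5, 0.9])
    assert np.allclose(1 / (1 + np.exp(-logit_transform(p))), p)
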