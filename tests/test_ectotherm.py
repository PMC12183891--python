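"""Operative-temperature energy balance: geometry, convection, root solving."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vipertherm import MonthlyClimate, TaxonTraits, build_hourly_environment
from vipertherm.ectotherm import (
    BracketError,
    annual_operative_series,
    convective_coefficient,
    cylinder_geometry,
    energy_residual,
    operative_temperature,
    solve_operative,
)
from vipertherm.io import SiteCell
from vipertherm.microclimate import EnvironmentHour


def brute_force_te(ta, solar, sky, sub, wind, geom, traits, step=0.001):
    """Independent oracle: argmin |f| over a dense grid of candidate Te."""
    grid = np.arange(ta - 50.0, ta + 100.0 + step, step)
    resid = np.abs(energy_residual(grid, ta, solar, sky, sub, wind, geom, traits))
    return grid[int(np.argmin(resid))]


class TestGeometry:
    def test_hundred_gram_cylinder(self, viper_geom):
        assert viper_geom.radius == pytest.approx(0.011675, abs=1e-5)
        assert viper_geom.length == pytest.approx(0.23350, abs=2e-4)
        assert viper_geom.area_silhouette == pytest.approx(
            2 * viper_geom.radius * viper_geom.length, rel=1e-12
        )
        assert viper_geom.area_lateral == pytest.approx(
            2 * np.pi * viper_geom.radius * viper_geom.length, rel=1e-12
        )

    def test_mass_scaling_law(self):
        r1 = cylinder_geometry(TaxonTraits("a", 33, 50)).radius
        r2 = cylinder_geometry(TaxonTraits("a", 33, 100)).radius
        assert r2 / r1 == pytest.approx(2 ** (1 / 3), rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            TaxonTraits("a", 33, 0.0)
        with pytest.raises(ValueError):
            TaxonTraits("a", 33, 100.0, density=-1)


class TestConvection:
    def test_still_air_floor(self):
        assert convective_coefficient(0.0, 0.02) == 5.0

    def test_reference_value(self):
        # Re = 1 * 0.02 / 1.5e-5 = 1333; Nu = 0.615 Re^0.466; h = Nu k / d
        assert convective_coefficient(1.0, 0.02) == pytest.approx(22.9, abs=0.2)

    def test_monotone_in_wind(self):
        winds = np.linspace(0, 10, 50)
        h = convective_coefficient(winds, 0.02)
        assert (np.diff(h) >= 0).all()

    def test_bad_diameter(self):
        with pytest.raises(ValueError):
            convective_coefficient(1.0, 0.0)


class TestOperativeTemperature:
    def test_equilibrium_at_air_temperature(self, viper_geom, viper_traits):
        env = EnvironmentHour(air_temp=20.0, solar=0.0, sky_temp=20.0, substrate_temp=20.0, wind=1.0)
        te = operative_temperature(env, viper_geom, viper_traits)
        assert te == pytest.approx(20.0, abs=1e-5)

    def test_monotone_in_solar_load(self, viper_geom, viper_traits):
        tes = [
            operative_temperature(
                EnvironmentHour(25.0, s, 10.0, 30.0, 1.0), viper_geom, viper_traits
            )
            for s in (0, 200, 400, 800)
        ]
        assert all(a < b for a, b in zip(tes, tes[1:]))

    def test_reference_case_matches_brute_force(self, viper_geom, viper_traits):
        te = operative_temperature(
            EnvironmentHour(25.0, 800.0, 10.0, 41.0, 1.0), viper_geom, viper_traits
        )
        oracle = brute_force_te(25.0, 800.0, 10.0, 41.0, 1.0, viper_geom, viper_traits)
        assert te == pytest.approx(oracle, abs=0.01)

    def test_residual_below_tolerance(self, viper_geom, viper_traits, rng):
        ta = rng.uniform(-10, 40, 50)
        solar = rng.uniform(0, 1200, 50)
        sky = ta - rng.uniform(0, 40, 50)
        sub = ta + solar / 50 * rng.uniform(0.5, 1.5, 50)
        wind = rng.uniform(0.1, 5, 50)
        te = solve_operative(ta, solar, sky, sub, wind, viper_geom, viper_traits)
        resid = energy_residual(te, ta, solar, sky, sub, wind, viper_geom, viper_traits)
        assert np.abs(resid).max() < 1e-6

    def test_bracket_sign_change_holds_broadly(self, viper_geom, viper_traits, rng):
        n = 10_000
        ta = rng.uniform(-30, 50, n)
        solar = rng.uniform(0, 1300, n)
        sky = ta - rng.uniform(0, 50, n)
        sub = ta + rng.uniform(-10, 30, n)
        wind = rng.uniform(0, 10, n)
        f_lo = energy_residual(ta - 50, ta, solar, sky, sub, wind, viper_geom, viper_traits)
        f_hi = energy_residual(ta + 100, ta, solar, sky, sub, wind, viper_geom, viper_traits)
        assert (f_lo > 0).all() and (f_hi < 0).all()

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        ta=st.floats(-10, 40),
        solar=st.floats(0, 1200),
        sky_drop=st.floats(0, 40),
        sub_rise=st.floats(0, 25),
        bump=st.floats(0.5, 10),
        which=st.sampled_from(["air_temp", "solar", "sky_temp", "substrate_temp"]),
    )
    def test_monotone_in_each_driver(self, ta, solar, sky_drop, sub_rise, bump, which):
        traits = TaxonTraits(name="viper", vtmax=33.0, mass=100.0)
        geom = cylinder_geometry(traits)
        base = dict(air_temp=ta, solar=solar, sky_temp=ta - sky_drop, substrate_temp=ta + sub_rise, wind=1.0)
        hotter = dict(base)
        hotter[which] += bump if which != "solar" else bump * 50
        te0 = operative_temperature(EnvironmentHour(**base), geom, traits)
        te1 = operative_temperature(EnvironmentHour(**hotter), geom, traits)
        assert te1 >= te0 - 1e-6


class TestAnnualSeries:
    @staticmethod
    def _site(tavg_level=15.0):
        site = SiteCell("s1", "viper", 42.0, 20.0, 300.0)
        site.climate["current"] = MonthlyClimate(
            tavg=np.full(12, tavg_level), dtr=np.full(12, 8.0)
        )
        return site

    def test_length_and_labels(self, viper_traits):
        env = build_hourly_environment(self._site(), "current")
        ser = annual_operative_series(env, viper_traits, site_id="s1", scenario="current")
        assert ser.te.shape == (8760,)
        assert ser.taxon == "viper"

    def test_uniform_warming_raises_te_by_at_most_the_offset(self, viper_traits, rng):
        site = self._site()
        env = build_hourly_environment(site, "current")
        c = 3.0
        warmed = build_hourly_environment(site, "current")
        warmed.air_temp = env.air_temp + c
        warmed.sky_temp = env.sky_temp + c
        warmed.substrate_temp = env.substrate_temp + c
        te0 = annual_operative_series(env, viper_traits).te
        te1 = annual_operative_series(warmed, viper_traits).te
        idx = rng.integers(0, 8760, 100)
        gain = te1[idx] - te0[idx]
        assert (gain > 0).all()
        assert (gain <= c + 1e-3).all()

    def test_night_radiative_deficit_cools_below_air(self, viper_traits, viper_geom):
        te = operative_temperature(
            EnvironmentHour(air_temp=15.0, solar=0.0, sky_temp=-10.0, substrate_temp=12.0, wind=1.0),
            viper_geom,
            viper_traits,
        )
        assert te < 15.0
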