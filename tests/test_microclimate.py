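"""Microclimate reconstruction: offsets, solar geometry, diurnal cycle."""

import numpy as np
import pytest

from vipertherm import MonthlyClimate, WarmOffsets, apply_offsets, delta_offsets
from vipertherm.io import SiteCell
from vipertherm.microclimate import (
    MONTH_MIDPOINTS,
    build_hourly_environment,
    clear_sky_irradiance,
    hourly_air_temperature,
    monthly_to_daily,
    sky_substrate,
    solar_declination,
    sunrise_hour,
)

MONTH_EDGES = [0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334, 365]


def make_site(lat=40.0, elev=0.0, tavg=None, dtr=8.0):
    clim = MonthlyClimate(
        tavg=np.full(12, 15.0) if tavg is None else np.asarray(tavg, float),
        dtr=np.full(12, dtr),
    )
    site = SiteCell("s1", "t1", lat, 20.0, elev)
    site.climate["current"] = clim
    return site


class TestOffsets:
    def test_delta_identity_shift_and_subtraction(self):
        base = MonthlyClimate(tavg=np.arange(12.0), dtr=np.full(12, 8.0))
        assert np.allclose(delta_offsets(base, base).values, 0.0)
        shifted = MonthlyClimate(tavg=base.tavg + 1.5, dtr=base.dtr)
        assert np.allclose(delta_offsets(shifted, base).values, 1.5)
        fine = MonthlyClimate(tavg=np.r_[3.2, base.tavg[1:]], dtr=base.dtr)
        coarse = MonthlyClimate(tavg=np.r_[1.0, base.tavg[1:]], dtr=base.dtr)
        assert delta_offsets(fine, coarse).values[0] == pytest.approx(2.2)

    def test_apply_offsets_round_trip(self):
        coarse = MonthlyClimate(tavg=np.arange(12.0), dtr=np.full(12, 8.0))
        fine = MonthlyClimate(tavg=np.arange(12.0) + 2.0, dtr=np.full(12, 8.0))
        rebuilt = apply_offsets(coarse, delta_offsets(fine, coarse))
        assert np.allclose(rebuilt.tavg, fine.tavg)
        assert np.allclose(rebuilt.dtr, coarse.dtr)  # DTR untouched
        same = apply_offsets(coarse, WarmOffsets(np.zeros(12)))
        assert np.allclose(same.tavg, coarse.tavg)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            MonthlyClimate(tavg=np.zeros(11), dtr=np.zeros(11))
        with pytest.raises(ValueError):
            WarmOffsets(np.zeros(13))


class TestSolarGeometry:
    def test_declination_anchor_days(self):
        assert solar_declination(81) == pytest.approx(0.0, abs=1e-9)
        assert solar_declination(172) == pytest.approx(23.45, abs=0.01)
        assert solar_declination(355) == pytest.approx(-23.449, abs=0.01)

    def test_declination_rejects_bad_doy(self):
        with pytest.raises(ValueError):
            solar_declination(0)
        with pytest.raises(ValueError):
            solar_declination(366)

    def test_sunrise_equator_and_equinox(self):
        for doy in (1, 100, 200, 300):
            assert sunrise_hour(0.0, doy) == pytest.approx(6.0, abs=1e-6)
        assert sunrise_hour(45.0, 81) == pytest.approx(6.0, abs=1e-3)

    def test_polar_clamps(self):
        assert sunrise_hour(70.0, 172) == 0.0  # polar day
        assert sunrise_hour(70.0, 355) == 12.0  # polar night

    def test_overhead_sun_at_sea_level(self):
        # equator, equinox, solar noon: cos z = 1, air mass 1
        total = clear_sky_irradiance(0.0, 81, 12, 0.0)
        direct = 1361.0 * 0.70
        diffuse = 0.3 * 1361.0 * 0.30
        assert total == pytest.approx(direct + diffuse, abs=0.5)

    def test_night_is_dark_and_elevation_brightens(self):
        assert clear_sky_irradiance(45.0, 172, 0, 0.0) == 0.0
        low = clear_sky_irradiance(45.0, 172, 12, 0.0)
        high = clear_sky_irradiance(45.0, 172, 12, 2000.0)
        assert high > low > 0


class TestDiurnalCycle:
    def test_sunrise_hits_tmin(self):
        assert hourly_air_temperature(10, 20, 6.0, 12.0, 6.0) == pytest.approx(10.0)

    def test_flat_day(self):
        for h in range(24):
            assert hourly_air_temperature(15, 15, 6.0, 12.0, h) == pytest.approx(15.0)

    def test_peak_hits_tmax_at_lagged_noon(self):
        # sine argument reaches pi/2 at h_sr + (DL + 2p)/2 = 13.5
        assert hourly_air_temperature(10, 20, 6.0, 12.0, 13.5) == pytest.approx(20.0)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            hourly_air_temperature(20, 10, 6.0, 12.0, 12.0)

    def test_night_decays_monotonically_to_tmin(self):
        vals = [hourly_air_temperature(10, 20, 6.0, 12.0, h) for h in (19, 21, 23, 1, 3, 5)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] > 10.0
        # continuous at the following sunrise
        assert hourly_air_temperature(10, 20, 6.0, 12.0, 5.999) == pytest.approx(10.0, abs=0.01)


class TestMonthlyToDaily:
    def test_constant_monthlies_give_constant_days(self):
        clim = MonthlyClimate(tavg=np.full(12, 10.0), dtr=np.full(12, 6.0))
        tmin, tmax = monthly_to_daily(clim)
        assert np.allclose(tmin, 7.0) and np.allclose(tmax, 13.0)

    def test_midpoints_are_interpolation_knots(self):
        tavg = np.arange(12.0) * 2.0
        clim = MonthlyClimate(tavg=tavg, dtr=np.zeros(12))
        tmin, tmax = monthly_to_daily(clim)
        for m, day in enumerate(MONTH_MIDPOINTS):
            assert tmin[day - 1] == pytest.approx(tavg[m])

    def test_halfway_day_is_mean_of_neighbouring_months(self):
        tavg = np.zeros(12)
        tavg[0], tavg[1] = 4.0, 10.0
        clim = MonthlyClimate(tavg=tavg, dtr=np.zeros(12))
        tmin, _ = monthly_to_daily(clim)
        # Jan midpoint day 15, Feb midpoint day 46; halfway = day 30.5, so
        # days 30 and 31 straddle the arithmetic mean 7.0
        assert (tmin[29] + tmin[30]) / 2 == pytest.approx(7.0, abs=0.11)


class TestSkySubstrate:
    def test_dark_substrate_equals_air(self):
        sky, sub = sky_substrate(12.0, 0.0)
        assert sub == pytest.approx(12.0)

    def test_substrate_solar_coupling(self):
        _, sub = sky_substrate(20.0, 500.0)
        assert sub == pytest.approx(30.0)

    def test_sky_colder_than_air(self):
        sky, _ = sky_substrate(20.0, 0.0)
        assert sky < 20.0


class TestBuildEnvironment:
    def test_record_count_and_physical_bounds(self):
        env = build_hourly_environment(make_site(), "current")
        assert len(env.air_temp) == 8760
        assert (env.solar >= 0).all()
        assert env.solar.max() <= 1361.0 * 1.3
        assert (env.wind == 1.0).all()

    def test_uniform_offset_shifts_air_exactly(self):
        site = make_site(tavg=np.linspace(0, 22, 12))
        base = build_hourly_environment(site, "current")
        site.climate["warm"] = apply_offsets(
            site.climate["current"], WarmOffsets(np.full(12, 2.0))
        )
        warm = build_hourly_environment(site, "warm")
        assert np.allclose(warm.air_temp - base.air_temp, 2.0, atol=1e-12)

    def test_equatorial_sun_is_dark_before_six(self):
        env = build_hourly_environment(make_site(lat=0.0), "current")
        solar = env.solar.reshape(365, 24)
        assert (solar[:, :6] == 0).all()
        assert (solar[:, 12] > 0).all()

    def test_missing_scenario_names_site(self):
        with pytest.raises(KeyError, match="s1.*rcp"):
            build_hourly_environment(make_site(), "rcp85")

    def test_monthly_mean_fidelity(self):
        tavg = 12.0 + 7.0 * (np.cos(2 * np.pi * (np.arange(1, 13) - 7) / 12) - 0)
        env = build_hourly_environment(make_site(tavg=tavg), "current")
        air = env.air_temp.reshape(365, 24)
        for m, (a, b) in enumerate(zip(MONTH_EDGES[:-1], MONTH_EDGES[1:])):
            assert abs(air[a:b].mean() - tavg[m]) < 0.3

    def test_constant_climate_is_24h_periodic(self):
        # constant Tmin/Tmax and constant day length (equator): exact 24 h cycle
        env = build_hourly_environment(make_site(lat=0.0), "current")
        air = env.air_temp.reshape(365, 24)
        assert np.allclose(air[100], air[101], atol=1e-9)
        # continuous across the sunrise boundary
        diffs = np.abs(np.diff(env.air_temp[100 * 24 : 102 * 24]))
        assert diffs.max() < 2.5  # no jump larger than the hourly slew
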