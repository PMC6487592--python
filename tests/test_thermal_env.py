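import math

import numpy as np
import pytest

from wheatlar.thermal_env import (
    TemperatureResponse,
    WeatherSeries,
    beta_response,
    daily_thermal_time,
    daylength,
    par_flux_to_daily,
    photothermal_quotient,
    srad_to_par,
)

from conftest import brute_force_thermal_time

import pandas as pd


class TestBetaResponse:
    def test_optimum_gives_one_and_bounds_give_zero(self, resp):
        assert beta_response(27.5, resp) == 1.0
        assert beta_response(0.0, resp) == 0.0
        assert beta_response(40.0, resp) == 0.0

    def test_value_at_20C_matches_direct_evaluation(self, resp):
        # independent arithmetic: alpha = ln2/ln(40/27.5), f = 2 x^a - x^(2a)
        alpha = math.log(2) / math.log(40 / 27.5)
        x = 20.0 / 27.5
        expected = 2 * x**alpha - x ** (2 * alpha)
        assert beta_response(20.0, resp) == pytest.approx(expected, abs=1e-12)
        assert beta_response(20.0, resp) == pytest.approx(0.802, abs=5e-4)

    def test_bounded_unimodal_continuous(self, resp):
        grid = np.linspace(-5.0, 45.0, 20001)
        f = beta_response(grid, resp)
        assert np.all(f >= 0) and np.all(f <= 1)
        assert grid[np.argmax(f)] == pytest.approx(27.5, abs=0.01)
        assert np.max(np.abs(np.diff(f))) < 1e-3  # no jumps on a dense grid
        # unique maximum: strictly below 1 away from the optimum
        away = np.abs(grid - 27.5) > 0.1
        assert np.all(f[away] < 1.0)

    def test_rejects_non_finite(self, resp):
        with pytest.raises(ValueError):
            beta_response(float("nan"), resp)

    def test_invalid_cardinals_rejected(self):
        with pytest.raises(ValueError):
            TemperatureResponse(t_min=30.0, t_opt=27.5, t_max=40.0)


class TestDailyThermalTime:
    def test_constant_at_optimum_gives_topt(self, resp):
        assert daily_thermal_time(np.full(144, 27.5), resp) == pytest.approx(27.5)

    def test_constant_at_tmin_gives_zero(self, resp):
        assert daily_thermal_time(np.full(144, 0.0), resp) == 0.0

    def test_square_wave_matches_brute_force(self, resp):
        # 28 degC for 8 h / 24 degC for 16 h
        t = np.where(np.arange(144) < 48, 28.0, 24.0)
        expected = brute_force_thermal_time(28.0, 24.0, 8.0, resp)
        got = daily_thermal_time(t, resp)
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(26.6, abs=0.05)

    def test_empty_series_rejected(self, resp):
        with pytest.raises(ValueError):
            daily_thermal_time([], resp)

    def test_additivity_of_half_day_means(self, resp):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 40, 144)
        whole = daily_thermal_time(t, resp)
        halves = 0.5 * (daily_thermal_time(t[:72], resp) + daily_thermal_time(t[72:], resp))
        assert whole == pytest.approx(halves, abs=1e-9)

    def test_agrees_with_one_minute_integrator_on_random_square_waves(self, resp):
        rng = np.random.default_rng(42)
        hours = (np.arange(144) + 0.5) / 6.0
        for _ in range(50):
            day_t = rng.uniform(5.0, 38.0)
            night_t = rng.uniform(0.0, day_t)
            photoperiod = float(rng.integers(6, 19))  # whole-hour photoperiods
            half = photoperiod / 2.0
            t = np.where((hours >= 12 - half) & (hours < 12 + half), day_t, night_t)
            oracle = brute_force_thermal_time(day_t, night_t, photoperiod, resp)
            if oracle < 1e-6:
                continue
            assert daily_thermal_time(t, resp) == pytest.approx(oracle, rel=5e-3)


class TestPtq:
    @pytest.mark.parametrize(
        "par,tt,expected",
        [(9.4, 24.5, 0.38), (15.9, 10.3, 1.54)],  # published chamber rows
    )
    def test_published_chamber_values(self, par, tt, expected):
        assert round(photothermal_quotient(par, tt), 2) == expected

    def test_zero_radiation_gives_zero(self):
        assert photothermal_quotient(0.0, 20.0) == 0.0

    def test_zero_thermal_time_is_an_error(self):
        with pytest.raises(ValueError):
            photothermal_quotient(10.0, 0.0)

    def test_homogeneity(self):
        base = photothermal_quotient(12.0, 15.0)
        assert photothermal_quotient(24.0, 15.0) == pytest.approx(2 * base)
        assert photothermal_quotient(12.0, 30.0) == pytest.approx(base / 2)


class TestDaylength:
    def test_equator_is_near_12h_all_year(self):
        for doy in (1, 100, 200, 300):
            assert daylength(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_equinox_is_near_12h_everywhere(self):
        for lat in (-60, -30, 0, 30, 60):
            assert daylength(lat, 80) == pytest.approx(12.0, abs=0.3)

    def test_matches_sunrise_root_finding_oracle(self):
        # independent oracle: bisection on solar elevation for sunset hour angle
        lat, doy = -43.75, 355
        phi = math.radians(lat)
        decl = math.radians(-23.44) * math.cos(2 * math.pi * (doy + 10) / 365)

        def elevation_sin(hour_angle):
            return math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(
                decl
            ) * math.cos(hour_angle)

        lo, hi = 0.0, math.pi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if elevation_sin(mid) > 0:
                lo = mid
            else:
                hi = mid
        oracle_hours = 2 * lo * 12 / math.pi
        assert daylength(lat, doy) == pytest.approx(oracle_hours, abs=1e-6)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            daylength(70.0, 100)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "flux,hours,expected", [(320, 8, 9.216), (0, 10, 0.0), (170, 16, 9.792)]
    )
    def test_par_flux_to_daily(self, flux, hours, expected):
        assert par_flux_to_daily(flux, hours) == pytest.approx(expected)

    def test_srad_to_par_standard_conversion(self):
        assert srad_to_par(10.0) == pytest.approx(10 * 0.5 * 4.57)


class TestWeatherSeriesInvariants:
    def test_non_monotone_dates_rejected(self):
        df = pd.DataFrame(
            {"date": ["2020-01-02", "2020-01-01"], "tmin_c": [1, 2],
             "tmax_c": [10, 11], "par_mol_m2": [5, 5]}
        )
        with pytest.raises(ValueError, match="increasing"):
            WeatherSeries(data=df, kind="daily")

    def test_negative_par_rejected(self):
        df = pd.DataFrame(
            {"date": ["2020-01-01"], "tmin_c": [1], "tmax_c": [10],
             "par_mol_m2": [-1.0]}
        )
        with pytest.raises(ValueError, match="PAR"):
            WeatherSeries(data=df, kind="daily")

    def test_non_uniform_subdaily_step_rejected(self):
        ts = pd.to_datetime(
            ["2020-01-01 00:00", "2020-01-01 00:10", "2020-01-01 00:25"]
        )
        df = pd.DataFrame(
            {"timestamp": ts, "tair_c": [20, 20, 20], "par_umol_m2_s": [0, 0, 0]}
        )
        with pytest.raises(ValueError, match="uniform"):
            WeatherSeries(data=df, kind="subdaily")

    def test_daily_summaries_ptq_consistency(self, chamber_ht_sd_320, resp):
        s = chamber_ht_sd_320.daily_summaries(resp)
        np.testing.assert_allclose(
            s["ptq"], s["daily_par"] / s["daily_tt"], rtol=1e-12
        )
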