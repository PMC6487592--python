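"""Growth-chamber treatments and synthetic field weather.

Two kinds of forcing are generated here.  *Chamber* scenarios reproduce
the square-wave day/night conditions of the growth-chamber experiments
that established the LAR–PTQ relationship (constant day and night air
temperature, fixed photoperiod, constant PAR flux during the light
period, optionally a one-time irradiance swap triggered at a Haun
stage).  *Field* scenarios emulate multi-sowing-date field experiments:
sinusoidal annual and diurnal temperature structure with Gaussian daily
noise, and radiation from a clear-sky fraction of extraterrestrial
radiation, so that sowing date moves the crop through realistic seasonal
cycles of temperature, daylength and photothermal quotient.

``TABLE1`` packages the chamber treatments with their *measured* mean
daily PAR, thermal time and PTQ (measured values differ slightly from
set-point arithmetic and are treated as inputs, never regenerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .thermal_env import (
    SUBDAILY_STEPS,
    TemperatureResponse,
    WeatherSeries,
    daylength,
    srad_to_par,
)

__all__ = [
    "ChamberScenario",
    "FieldScenario",
    "SwapSpec",
    "TABLE1",
    "table1_frame",
    "chamber_preset",
    "field_preset",
    "build_chamber_weather",
    "build_field_weather",
    "chamber_weather_with_swap",
    "early_window_ptq",
]


@dataclass(frozen=True)
class SwapSpec:
    """One-time change of PAR flux when the crop reaches a trigger Haun stage."""

    new_par_flux: float
    trigger_haun_stage: float

    def __post_init__(self) -> None:
        if self.trigger_haun_stage <= 0:
            raise ValueError("swap trigger Haun stage must be > 0")


@dataclass(frozen=True)
class ChamberScenario:
    """Square-wave growth-chamber treatment (day/night set points)."""

    name: str
    day_temp: float
    night_temp: float
    photoperiod: float          # h
    par_flux: float             # µmol m-2 s-1 during the light period
    co2_ppm: float = 400.0      # metadata only; no CO2 response term
    duration_days: int = 60
    swap: SwapSpec | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.photoperiod <= 24.0):
            raise ValueError("photoperiod must be in (0, 24] h")
        if self.par_flux < 0:
            raise ValueError("PAR flux must be >= 0")


@dataclass(frozen=True)
class FieldScenario:
    """Synthetic multi-sowing field weather recipe.

    Temperature: annual sinusoid (``annual_mean`` ± ``annual_amplitude``,
    peaking at ``peak_doy``) plus a diurnal range of ``diurnal_amplitude``
    split evenly around the daily mean, plus iid Gaussian noise of SD
    ``temp_noise_sd`` on the daily mean.  Radiation: ``clear_sky_fraction``
    of extraterrestrial solar radiation plus Gaussian noise of SD
    ``rad_noise_sd`` (MJ m⁻² d⁻¹), truncated at zero, converted to PAR.
    Southern-hemisphere presets shift the seasonal peak by 182 days.
    """

    latitude: float
    sowing_doys: tuple[int, ...]
    annual_mean: float = 15.0
    annual_amplitude: float = 8.0
    diurnal_amplitude: float = 10.0
    temp_noise_sd: float = 1.5
    clear_sky_fraction: float = 0.65
    rad_noise_sd: float = 2.0
    season_days: int = 160
    seed: int = 0
    name: str = "field"

    @property
    def peak_doy(self) -> int:
        """Day of year of the warmest day; hemisphere-dependent."""
        return 200 if self.latitude >= 0 else 200 - 182


# ---------------------------------------------------------------------------
# Chamber treatments with their measured Table-1 forcing.
# measured_par (mol m-2 d-1), measured_tt (°Cd) and printed ptq are the
# published measurements; lar_i is the initial LAR of cv. Paragon
# (x 1e-3 leaves °Cd-1, mean of 4-6 replicates).  ptq_consistent marks rows
# where round(measured_par / measured_tt, 2) equals the printed PTQ.
# ---------------------------------------------------------------------------
_T1 = [
    # name, experiment, Tday, Tnight, flux, photoperiod, co2, par, tt, ptq, lar_i
    ("HT.SD.320", 1, 28, 24, 320, 8, 400, 9.4, 24.5, 0.38, 6.61),
    ("HT.LD.170", 1, 28, 24, 170, 16, 400, 9.6, 26.2, 0.37, 6.63),
    ("HT.LD.280", 1, 28, 24, 280, 16, 400, 16.5, 26.2, 0.63, 7.94),
    ("LT.LD.280", 1, 18, 14, 280, 16, 400, 15.9, 10.3, 1.54, 10.84),
    ("HT.MD.450", 1, 28, 24, 450, 14, 400, 22.5, 26.4, 0.85, 7.75),
    ("LT.MD.320", 1, 18, 14, 320, 14, 400, 15.7, 10.5, 1.50, 9.17),
    ("HT.aCO2", 2, 28, 24, 600, 14, 400, 32.3, 27.2, 1.19, 10.80),
    ("HT.eCO2", 2, 28, 24, 600, 14, 800, 27.8, 27.2, 1.02, 11.90),
    ("LT.aCO2", 2, 18, 14, 600, 14, 400, 31.5, 10.6, 2.97, 11.20),
    ("LT.eCO2", 2, 18, 14, 600, 14, 800, 30.0, 10.6, 2.83, 15.80),
    ("HT.SD", 3, 28, 24, 190, 8, 400, 4.9, 25.5, 0.20, 5.00),
    ("HT.LD", 3, 28, 24, 190, 16, 400, 11.1, 26.7, 0.42, 6.62),
    ("LT.SD", 3, 18, 14, 190, 8, 400, 5.7, 8.9, 0.64, 6.58),
    ("LT.LD", 3, 18, 14, 190, 16, 400, 10.6, 10.1, 1.05, 8.40),
]

TABLE1: dict[str, dict] = {
    name: {
        "experiment": exp,
        "day_temp": td,
        "night_temp": tn,
        "par_flux": flux,
        "photoperiod": pp,
        "co2_ppm": co2,
        "measured_par": par,
        "measured_tt": tt,
        "ptq": ptq,
        "lar_i_e3": lar,
        "ptq_consistent": round(par / tt, 2) == ptq,
    }
    for (name, exp, td, tn, flux, pp, co2, par, tt, ptq, lar) in _T1
}

_SWAPS = {
    "280to170": ("HT.LD.280", SwapSpec(new_par_flux=170, trigger_haun_stage=3.5)),
    "170to280": ("HT.LD.170", SwapSpec(new_par_flux=280, trigger_haun_stage=3.5)),
}


def table1_frame() -> pd.DataFrame:
    """The chamber treatments and their measured forcing as a DataFrame."""
    return pd.DataFrame.from_dict(TABLE1, orient="index").rename_axis("treatment")


def chamber_preset(name: str, duration_days: int = 60) -> ChamberScenario:
    """Named chamber treatment, including the irradiance-swap treatments."""
    if name in _SWAPS:
        base_name, swap = _SWAPS[name]
        base = chamber_preset(base_name, duration_days)
        return replace(base, name=name, swap=swap)
    try:
        row = TABLE1[name]
    except KeyError:
        raise KeyError(
            f"unknown chamber treatment {name!r}; known: "
            f"{sorted(TABLE1) + sorted(_SWAPS)}"
        ) from None
    return ChamberScenario(
        name=name,
        day_temp=row["day_temp"],
        night_temp=row["night_temp"],
        photoperiod=row["photoperiod"],
        par_flux=row["par_flux"],
        co2_ppm=row["co2_ppm"],
        duration_days=duration_days,
    )


def field_preset(name: str, seed: int = 0) -> FieldScenario:
    """Field-weather presets.

    ``hsc-like``: hot semi-arid site at 33°N with eight sowings spread over
    the year (midsummer excluded), spanning a wide range of temperature,
    photoperiod and PTQ.  ``nz2020-like``: temperate site at 43.75°S with
    late-summer to mid-autumn sowings.
    """
    if name == "hsc-like":
        return FieldScenario(
            latitude=33.07,
            sowing_doys=(5, 47, 89, 131, 215, 257, 299, 341),
            annual_mean=19.5,
            annual_amplitude=11.5,
            diurnal_amplitude=16.0,
            temp_noise_sd=1.5,
            clear_sky_fraction=0.72,
            rad_noise_sd=2.0,
            season_days=170,
            seed=seed,
            name=name,
        )
    if name == "nz2020-like":
        return FieldScenario(
            latitude=-43.75,
            sowing_doys=(55, 75, 95, 115),
            annual_mean=11.0,
            annual_amplitude=5.5,
            diurnal_amplitude=9.0,
            temp_noise_sd=1.5,
            clear_sky_fraction=0.55,
            rad_noise_sd=2.0,
            season_days=240,
            seed=seed,
            name=name,
        )
    raise KeyError(f"unknown field preset {name!r}; known: hsc-like, nz2020-like")


def build_chamber_weather(
    scenario: ChamberScenario,
    swap_day: int | None = None,
    step_minutes: int = 10,
    start: str = "2017-01-01",
) -> WeatherSeries:
    """Sub-daily square-wave weather for a chamber treatment.

    The light period is centred on solar noon.  If the scenario has a swap
    spec, ``swap_day`` (0-based day index when the trigger Haun stage is
    reached) must be supplied — use :func:`chamber_weather_with_swap` to
    determine it by simulation.
    """
    if scenario.swap is not None and swap_day is None:
        raise ValueError(
            "scenario has a swap spec; supply swap_day or use "
            "chamber_weather_with_swap"
        )
    steps_per_day = int(24 * 60 / step_minutes)
    minutes = np.arange(steps_per_day) * step_minutes + step_minutes / 2.0
    hours = minutes / 60.0
    half = scenario.photoperiod / 2.0
    is_day = (hours >= 12.0 - half) & (hours < 12.0 + half)
    t_day = np.where(is_day, scenario.day_temp, scenario.night_temp)

    frames = []
    for day in range(scenario.duration_days):
        flux = scenario.par_flux
        if scenario.swap is not None and swap_day is not None and day >= swap_day:
            flux = scenario.swap.new_par_flux
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": pd.Timestamp(start)
                    + pd.Timedelta(days=day)
                    + pd.to_timedelta(minutes, unit="m"),
                    "tair_c": t_day,
                    "par_umol_m2_s": np.where(is_day, flux, 0.0),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return WeatherSeries(
        data=data,
        kind="subdaily",
        meta={"scenario": scenario.name, "co2_ppm": scenario.co2_ppm,
              "photoperiod_h": scenario.photoperiod},
    )


def chamber_weather_with_swap(
    scenario: ChamberScenario,
    model,
    config=None,
    resp: TemperatureResponse = TemperatureResponse(),
) -> tuple[WeatherSeries, int]:
    """Two-pass construction of a swap treatment's weather.

    The swap trigger is a Haun stage, not a date, so the pre-swap weather is
    simulated first with ``model`` to find the day the trigger is crossed;
    the swapped series and that day index are returned.
    """
    from .simulate import SimConfig, simulate_haun

    if scenario.swap is None:
        return build_chamber_weather(scenario), -1
    config = config or SimConfig()
    pre = build_chamber_weather(replace(scenario, swap=None))
    traj = simulate_haun(pre, model, config, resp=resp)
    crossed = traj.data["haun_stage"] >= scenario.swap.trigger_haun_stage
    if not crossed.any():
        raise ValueError(
            f"trigger Haun stage {scenario.swap.trigger_haun_stage} never reached "
            f"within {scenario.duration_days} days"
        )
    swap_day = int(np.argmax(crossed.to_numpy()))
    return build_chamber_weather(scenario, swap_day=swap_day), swap_day


def early_window_ptq(
    weather: WeatherSeries,
    resp: TemperatureResponse = TemperatureResponse(),
    tt_budget: float = 500.0,
) -> float:
    """Mean PTQ over the early-development window of a weather series.

    Aggregate PAR over aggregate thermal time from the start of the series
    until ``tt_budget`` °Cd have accumulated (default 500 °Cd ≈ the first
    five leaves at a 100 °Cd phyllochron) — the window over which the
    initial leaf appearance rate is defined.
    """
    s = weather.daily_summaries(resp)
    tt = s["daily_tt"].to_numpy()
    cum = np.cumsum(tt)
    stop = int(np.searchsorted(cum, tt_budget)) + 1
    tt_sum = float(tt[:stop].sum())
    if tt_sum <= 0:
        raise ValueError("no thermal time accumulated in the early window")
    return float(s["daily_par"].to_numpy()[:stop].sum() / tt_sum)


def _extraterrestrial_radiation(latitude: float, doy: np.ndarray) -> np.ndarray:
    """Daily extraterrestrial solar radiation Ra (MJ m⁻² d⁻¹), FAO-56 form."""
    phi = np.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0))
    return (
        24.0 * 60.0 / np.pi * 0.0820 * dr
        * (ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    )


def build_field_weather(
    scenario: FieldScenario, year: int = 2018
) -> dict[int, WeatherSeries]:
    """Daily weather series, one per sowing date, reproducible for a fixed seed.

    Each series starts on the sowing day-of-year and runs for
    ``scenario.season_days`` days.  Returns ``{sowing_doy: WeatherSeries}``.
    """
    out: dict[int, WeatherSeries] = {}
    for i, sow_doy in enumerate(scenario.sowing_doys):
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, i, sow_doy])
        )
        n = scenario.season_days
        doy = (sow_doy - 1 + np.arange(n)) % 365 + 1
        tmean = (
            scenario.annual_mean
            + scenario.annual_amplitude
            * np.cos(2.0 * np.pi * (doy - scenario.peak_doy) / 365.0)
            + rng.normal(0.0, scenario.temp_noise_sd, size=n)
        )
        tmin = tmean - scenario.diurnal_amplitude / 2.0
        tmax = tmean + scenario.diurnal_amplitude / 2.0
        ra = _extraterrestrial_radiation(scenario.latitude, doy)
        srad = np.maximum(
            0.0,
            scenario.clear_sky_fraction * ra
            + rng.normal(0.0, scenario.rad_noise_sd, size=n),
        )
        par = srad_to_par(srad)
        dates = pd.Timestamp(f"{year}-01-01") + pd.to_timedelta(
            sow_doy - 1 + np.arange(n), unit="D"
        )
        dl = np.array([daylength(scenario.latitude, int(d)) for d in doy])
        data = pd.DataFrame(
            {
                "date": dates,
                "tmin_c": tmin,
                "tmax_c": tmax,
                "par_mol_m2": par,
                "srad_mj_m2": srad,
                "daylength_h": dl,
                "doy": doy,
            }
        )
        out[sow_doy] = WeatherSeries(
            data=data,
            kind="daily",
            latitude=scenario.latitude,
            meta={"scenario": scenario.name, "sowing_doy": sow_doy,
                  "seed": scenario.seed},
        )
    return out
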