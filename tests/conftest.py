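import logging

import numpy as np
import pytest

from wheatlar import (
    M3Params,
    SimConfig,
    TemperatureResponse,
    build_chamber_weather,
    build_field_weather,
    chamber_preset,
    field_preset,
)

# the soil/canopy -> air fallback is exercised deliberately throughout
logging.getLogger("wheatlar.simulate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def resp():
    return TemperatureResponse()


@pytest.fixture(scope="session")
def chamber_ht_sd_320():
    """Sub-daily weather for the short-day, high-temperature chamber treatment."""
    return build_chamber_weather(chamber_preset("HT.SD.320", duration_days=45))


@pytest.fixture(scope="session")
def hsc_weather():
    """Synthetic multi-sowing field weather (hot semi-arid preset, seed 1)."""
    return build_field_weather(field_preset("hsc-like", seed=1))


@pytest.fixture(scope="session")
def m3_default():
    return M3Params()


def brute_force_thermal_time(day_temp, night_temp, photoperiod, resp, step_min=1):
    """Independent 1-minute-step integrator for a day/night square wave."""
    n = 24 * 60 // step_min
    minutes = (np.arange(n) + 0.5) * step_min
    hours = minutes / 60.0
    half = photoperiod / 2.0
    t = np.where((hours >= 12 - half) & (hours < 12 + half), day_temp, night_temp)
    total = 0.0
    for temp in t:
        x = (temp - resp.t_min) / (resp.t_opt - resp.t_min)
        if resp.t_min < temp < resp.t_max:
            f = max(0.0, 2.0 * x**resp.alpha - x ** (2 * resp.alpha))
        else:
            f = 0.0
        total += f
    return resp.t_opt * total / n
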