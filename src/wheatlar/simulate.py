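"""Daily-step Haun-stage simulation from emergence to the flag leaf.

Each day the simulator accumulates thermal time from the appropriate
temperature source (a soil proxy until the apex rises above the ground
around Haun stage 4, a canopy proxy after), evaluates the active LAR
model, and advances the Haun stage by ``LAR × ΔT_t``.  For the carbon
supply/demand model (M3) it additionally tracks canopy green area,
Beer-law light interception, and the trailing thermal-time buffer window
over which intercepted PAR and thermal time are integrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lar_models import (
    CM2_PER_M2,
    M1Params,
    M2Params,
    M3Params,
    effective_gai,
    CanopyState,
    light_interception_fraction,
    m1_lar,
    m2_lar,
    m3_lar,
    lar_from_ptq,
)
from .thermal_env import TemperatureResponse, WeatherSeries

__all__ = ["SimConfig", "HaunTrajectory", "simulate_haun", "select_temperature_source"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``final_leaf_cap`` — main-stem leaf number at which simulation stops.
    ``switch_stage`` — Haun stage at which the developmental temperature
    source switches from the soil proxy to the canopy proxy (the apex sits
    near the soil surface until about four leaves have appeared).
    ``initial_haun_stage`` — Haun stage assigned at emergence (0 by
    convention; comparisons with observations use HS > 1 only, so the
    pre-leaf-1 convention does not affect scoring).
    ``gai_per_haun`` — slope of the internal default GAI trajectory,
    ``GAI = gai_per_haun × HS × PD × A_pot_juv × 1e-4`` (a linear stand-in
    for a full leaf-growth model; supply ``gai_series`` to override).
    ``pin_supply_demand`` — force the M3 demand scaling ``S_C/GAI / GAI_eff``
    to 1, reducing M3 exactly to the LAR–PTQ response evaluated on
    window-intercepted PTQ (used to verify that the supply/demand model
    generalizes the chamber relationship).
    ``sowing_doy`` — day-of-year of sowing for the M2 correction; taken
    from weather metadata or the first weather date when None.
    """

    final_leaf_cap: float = 20.0
    switch_stage: float = 4.0
    initial_haun_stage: float = 0.0
    gai_per_haun: float = 1.0
    pin_supply_demand: bool = False
    sowing_doy: int | None = None

    def __post_init__(self) -> None:
        if not (self.final_leaf_cap > self.switch_stage > 0):
            raise ValueError("need final_leaf_cap > switch_stage > 0")


@dataclass
class HaunTrajectory:
    """Simulated (or observed) Haun-stage time course.

    ``data`` columns: date, daily_tt, tt_cum, haun_stage, lar, plus for M3
    gai, gai_eff and window_ptq (windowed intercepted PAR / thermal time).
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def final_haun_stage(self) -> float:
        return float(self.data["haun_stage"].iloc[-1])

    def lar_at_rank(self, rank: float) -> float:
        """LAR in effect on the day leaf ``rank`` appears (HS first >= rank)."""
        hs = self.data["haun_stage"].to_numpy()
        idx = np.searchsorted(hs, rank)
        if idx >= len(hs):
            raise ValueError(f"leaf rank {rank} never reached (final HS {hs[-1]:.2f})")
        return float(self.data["lar"].iloc[idx])


def select_temperature_source(hs: float, config: SimConfig, sources) -> str:
    """Temperature source for developmental thermal time at Haun stage ``hs``.

    Soil proxy before the switch stage, canopy proxy after; falls back to
    air (with a logged warning) when the preferred series is absent.
    """
    sources = list(sources)
    if "air" not in sources:
        raise ValueError("at least the air temperature series must exist")
    preferred = "soil" if hs < config.switch_stage else "canopy"
    if preferred in sources:
        return preferred
    if "apex" in sources:  # chamber experiments measure apex temperature directly
        return "apex"
    logger.warning(
        "no %r temperature series available at Haun stage %.2f; using air",
        preferred, hs,
    )
    return "air"


def _summaries_by_source(weather: WeatherSeries, resp: TemperatureResponse):
    out = {}
    for src in weather.temperature_columns():
        out[src] = weather.daily_summaries(resp, source=src)
    if weather.kind == "subdaily" and "tapex_c" in weather.data.columns:
        out["apex"] = weather.daily_summaries(resp, source="apex")
    return out


def simulate_haun(
    weather: WeatherSeries,
    model: M1Params | M2Params | M3Params,
    config: SimConfig = SimConfig(),
    resp: TemperatureResponse = TemperatureResponse(),
    gai_series: np.ndarray | None = None,
    summaries: dict[str, pd.DataFrame] | None = None,
) -> HaunTrajectory:
    """Simulate the Haun stage day by day under ``model``.

    ``gai_series`` optionally supplies an observed/external daily GAI for
    M3; otherwise GAI grows linearly with the simulated Haun stage.
    ``summaries`` may carry precomputed per-source daily summaries (as from
    ``weather.daily_summaries``) to avoid recomputation in repeated calls.
    Stops at the final-leaf cap or the end of the weather series.
    """
    if summaries is None:
        summaries = _summaries_by_source(weather, resp)
    sources = list(summaries)
    n_days = len(next(iter(summaries.values())))
    if n_days == 0:
        raise ValueError("weather series covers no complete day")
    if gai_series is not None and len(gai_series) < n_days:
        raise ValueError("gai_series shorter than the weather series")

    tt_by_src = {s: df["daily_tt"].to_numpy(float) for s, df in summaries.items()}
    par = next(iter(summaries.values()))["daily_par"].to_numpy(float)
    dates = next(iter(summaries.values()))["date"].to_numpy()

    sowing_doy = config.sowing_doy
    if sowing_doy is None:
        sowing_doy = int(
            weather.meta.get("sowing_doy", pd.Timestamp(dates[0]).dayofyear)
        )

    # source availability is fixed for the whole run: resolve (and warn) once
    src_early = select_temperature_source(0.0, config, sources)
    src_late = select_temperature_source(config.switch_stage, config, sources)

    is_m3 = isinstance(model, M3Params)
    hs = config.initial_haun_stage
    tt_cum = 0.0
    rows = []
    tt_hist: list[float] = []
    ipar_hist: list[float] = []
    gai_hist: list[float] = []
    windowed_gai_means: list[float] = []

    for i in range(n_days):
        src = src_early if hs < config.switch_stage else src_late
        tt_day = tt_by_src[src][i]

        if isinstance(model, M1Params):
            lar = m1_lar(model)
            extra = {}
        elif isinstance(model, M2Params):
            next_rank = float(np.floor(hs)) + 1.0
            lar = m2_lar(next_rank, sowing_doy, model)
            extra = {}
        elif is_m3:
            gai = (
                float(gai_series[i])
                if gai_series is not None
                else config.gai_per_haun * hs * model.pd * model.a_pot_juv * CM2_PER_M2
            )
            f_int = light_interception_fraction(gai, model.k)
            tt_hist.append(tt_day)
            ipar_hist.append(par[i] * f_int)
            gai_hist.append(gai)
            lo = _window_start(tt_hist, model.d)
            w_tt = float(np.sum(tt_hist[lo:]))
            w_ipar = float(np.sum(ipar_hist[lo:]))
            w_gai = float(np.mean(gai_hist[lo:]))
            windowed_gai_means.append(w_gai)
            state = CanopyState(
                leaf_number=hs, gai=gai, windowed_mean_gai=windowed_gai_means
            )
            gai_eff = effective_gai(state, model)
            if w_tt > 0:
                x = w_ipar / w_tt
                if config.pin_supply_demand:
                    lar = lar_from_ptq(x, model.response)
                else:
                    lar = m3_lar(w_ipar, w_tt, gai_eff, model)
            else:
                lar = model.response.lar_min  # development stalls at minimum rate
                x = np.nan
            extra = {"gai": gai, "gai_eff": gai_eff, "window_ptq": x}
        else:
            raise TypeError(f"unknown model parameter type {type(model).__name__}")

        increment = min(lar * tt_day, config.final_leaf_cap - hs)
        hs += increment
        tt_cum += tt_day
        rows.append(
            {"date": dates[i], "daily_tt": tt_day, "tt_cum": tt_cum,
             "haun_stage": hs, "lar": lar, "temp_source": src, **extra}
        )
        if hs >= config.final_leaf_cap:
            break

    data = pd.DataFrame(rows)
    return HaunTrajectory(
        data=data,
        meta={
            "model": type(model).__name__,
            "sowing_doy": sowing_doy,
            "weather": dict(weather.meta),
            "config": config,
        },
    )


def _window_start(tt_hist: list[float], d: float) -> int:
    """Index of the first day inside the trailing d-°Cd window (>= 1 day).

    At the start of the simulation, when less than d °Cd of history exists,
    the whole history from emergence is used.
    """
    total = 0.0
    lo = len(tt_hist)
    while lo > 0 and total < d:
        lo -= 1
        total += tt_hist[lo]
    return lo
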