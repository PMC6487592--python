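"""Thermal-time engine, daylength and photothermal-quotient arithmetic.

Wheat development is driven not by calendar time but by *thermal time*
(degree-days, °Cd) accumulated through a non-linear, beta-shaped response
of leaf initiation and growth to organ temperature, bounded by cardinal
temperatures (minimum, optimum, maximum).  Daily thermal time is the
optimum temperature multiplied by the mean of that response over sub-daily
(reference: 144 ten-minute) temperature readings.  The photothermal
quotient (PTQ, mol m⁻² °Cd⁻¹) — daily photosynthetically active radiation
(PAR) divided by daily thermal time — indexes the carbon supply available
per unit of developmental demand and is the central covariate of the
carbon-limited leaf-appearance-rate model in :mod:`wheatlar.lar_models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureResponse",
    "WeatherSeries",
    "DailySummary",
    "beta_response",
    "daily_thermal_time",
    "photothermal_quotient",
    "daylength",
    "par_flux_to_daily",
    "diurnal_course",
    "srad_to_par",
    "SUBDAILY_STEPS",
    "PAR_FRACTION_OF_SRAD",
    "MOL_PAR_PER_MJ",
]

#: Reference sub-daily discretization: 144 ten-minute steps per day.
SUBDAILY_STEPS = 144

#: Fraction of global solar radiation that is PAR (community convention).
PAR_FRACTION_OF_SRAD = 0.50

#: Quantum content of PAR energy, mol PAR per MJ PAR (community convention).
MOL_PAR_PER_MJ = 4.57


@dataclass(frozen=True)
class TemperatureResponse:
    """Cardinal temperatures of the beta-shaped development response.

    The shape exponent ``alpha`` is fully determined by the cardinals:
    ``alpha = ln 2 / ln((T_max - T_min)/(T_opt - T_min))``, which places
    the response maximum (value 1) exactly at ``t_opt``.

    Default cardinals are 0 / 27.5 / 40 °C, the values used for wheat
    leaf initiation and growth.
    """

    t_min: float = 0.0
    t_opt: float = 27.5
    t_max: float = 40.0

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError(
                f"cardinal temperatures must satisfy t_min < t_opt < t_max, "
                f"got ({self.t_min}, {self.t_opt}, {self.t_max})"
            )

    @property
    def alpha(self) -> float:
        """Shape exponent derived from the cardinal temperatures."""
        return math.log(2.0) / math.log(
            (self.t_max - self.t_min) / (self.t_opt - self.t_min)
        )


def beta_response(t, resp: TemperatureResponse = TemperatureResponse()):
    """Beta-shaped temperature response f(T) in [0, 1].

    ``f(T) = max(0, 2 x^alpha - x^(2 alpha))`` with
    ``x = (T - T_min)/(T_opt - T_min)``; zero at and outside the cardinal
    bounds, 1 at ``T_opt``.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite temperature passed to beta_response")
    a = resp.alpha
    x = (t - resp.t_min) / (resp.t_opt - resp.t_min)
    inside = (t > resp.t_min) & (t < resp.t_max)
    xs = np.where(inside, x, 1.0)  # dummy 1.0 avoids 0**alpha warnings
    f = np.where(inside, 2.0 * xs**a - xs ** (2.0 * a), 0.0)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def daily_thermal_time(
    subdaily_t, resp: TemperatureResponse = TemperatureResponse()
) -> float:
    """Daily thermal time ΔT_t (°Cd) from one day of sub-daily temperatures.

    ``ΔT_t = T_opt × mean(f(T_i))`` over the day's uniform-step readings.
    The series must cover exactly one day; the reference step is 10 min
    (144 readings) but any uniform step that divides 24 h is accepted.
    """
    t = np.asarray(subdaily_t, dtype=float)
    if t.size == 0:
        raise ValueError("empty sub-daily temperature series")
    return float(resp.t_opt * np.mean(beta_response(t, resp)))


def photothermal_quotient(daily_par: float, daily_tt: float) -> float:
    """PTQ (mol m⁻² °Cd⁻¹) = daily PAR / daily thermal time.

    Raises if ``daily_tt <= 0``: with no thermal time, development is
    stalled and the quotient is undefined rather than infinite.
    """
    if daily_tt <= 0:
        raise ValueError(
            f"PTQ undefined: daily thermal time must be > 0, got {daily_tt}"
        )
    if daily_par < 0:
        raise ValueError("daily PAR must be >= 0")
    return daily_par / daily_tt


def daylength(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength (h) from standard solar declination geometry.

    Valid for |latitude| <= 66°; polar day/night latitudes are rejected.
    """
    if abs(latitude) > 66.0:
        raise ValueError(f"latitude {latitude} outside supported range |lat| <= 66")
    phi = math.radians(latitude)
    decl = math.radians(-23.44) * math.cos(2.0 * math.pi * (day_of_year + 10) / 365.0)
    cos_h0 = -math.tan(phi) * math.tan(decl)
    cos_h0 = min(1.0, max(-1.0, cos_h0))
    return 24.0 / math.pi * math.acos(cos_h0)


def par_flux_to_daily(par_flux: float, photoperiod: float) -> float:
    """Daily PAR (mol m⁻² d⁻¹) from a constant flux (µmol m⁻² s⁻¹) over a photoperiod (h)."""
    if par_flux < 0 or photoperiod < 0:
        raise ValueError("PAR flux and photoperiod must be >= 0")
    return par_flux * photoperiod * 3600.0 * 1e-6


def srad_to_par(
    srad_mj_m2: float,
    par_fraction: float = PAR_FRACTION_OF_SRAD,
    mol_per_mj: float = MOL_PAR_PER_MJ,
) -> float:
    """Daily PAR (mol m⁻² d⁻¹) from global solar radiation (MJ m⁻² d⁻¹)."""
    return srad_mj_m2 * par_fraction * mol_per_mj


def diurnal_course(
    tmin: float, tmax: float, n_steps: int = SUBDAILY_STEPS
) -> np.ndarray:
    """Sine-based sub-daily course between daily minimum and maximum temperature.

    Minimum at 03:00, maximum at 15:00 — a standard stand-in for the diurnal
    temperature wave when only daily extremes are recorded.  Swappable: any
    callable producing one day of sub-daily temperatures can replace it in
    :meth:`WeatherSeries.daily_summaries`.
    """
    hours = (np.arange(n_steps) + 0.5) * (24.0 / n_steps)
    mean = 0.5 * (tmin + tmax)
    amp = 0.5 * (tmax - tmin)
    return mean + amp * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)


@dataclass(frozen=True)
class DailySummary:
    """One day of derived forcing: thermal time, PAR and their quotient."""

    daily_tt: float
    daily_par: float

    @property
    def ptq(self) -> float:
        return photothermal_quotient(self.daily_par, self.daily_tt)


@dataclass
class WeatherSeries:
    """Environmental forcing for simulation, daily or sub-daily.

    ``kind='daily'`` tables carry ``date, tmin_c, tmax_c, par_mol_m2`` (plus
    optional ``tsoil_*``/``tcanopy_*`` analogues and ``daylength_h``);
    ``kind='subdaily'`` tables carry ``timestamp, tair_c, par_umol_m2_s``
    (plus optional ``tapex_c``).  Temperatures in °C, daily PAR in
    mol m⁻² d⁻¹, sub-daily PAR flux in µmol m⁻² s⁻¹.
    """

    data: pd.DataFrame
    kind: str = "daily"
    latitude: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("daily", "subdaily"):
            raise ValueError(f"unknown weather kind {self.kind!r}")
        df = self.data
        if self.kind == "daily":
            required = {"date", "tmin_c", "tmax_c", "par_mol_m2"}
            time_col = "date"
        else:
            required = {"timestamp", "tair_c", "par_umol_m2_s"}
            time_col = "timestamp"
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weather table missing columns: {sorted(missing)}")
        times = pd.to_datetime(df[time_col])
        if not times.is_monotonic_increasing or times.duplicated().any():
            raise ValueError("weather timestamps must be strictly increasing")
        par_col = "par_mol_m2" if self.kind == "daily" else "par_umol_m2_s"
        if (df[par_col] < 0).any():
            raise ValueError("PAR must be >= 0")
        if self.kind == "subdaily":
            steps = np.unique(
                np.round(times.diff().dropna().dt.total_seconds(), 6)
            )
            if len(steps) > 1:
                raise ValueError("sub-daily weather must have a uniform time step")
            if len(steps) == 1 and (86400.0 % steps[0]) != 0:
                raise ValueError("sub-daily step must divide 24 h evenly")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_days(self) -> int:
        if self.kind == "daily":
            return len(self.data)
        return len(pd.to_datetime(self.data["timestamp"]).dt.normalize().unique())

    def temperature_columns(self) -> list[str]:
        """Names of the temperature source series present ('air' always)."""
        cols = ["air"]
        prefix = {"daily": ("tsoil", "tcanopy"), "subdaily": ("tsoil", "tcanopy")}
        for name in prefix[self.kind]:
            if self.kind == "daily":
                if f"{name}_min_c" in self.data.columns:
                    cols.append(name[1:])  # 'soil' / 'canopy'
            else:
                if f"{name}_c" in self.data.columns:
                    cols.append(name[1:])
        return cols

    def daily_summaries(
        self,
        resp: TemperatureResponse = TemperatureResponse(),
        source: str = "air",
        course=diurnal_course,
    ) -> pd.DataFrame:
        """Per-day thermal time, PAR and PTQ using one temperature source.

        ``source`` is 'air', 'soil' or 'canopy' (daily dialect) or 'air' /
        'apex' (sub-daily dialect; 'apex' uses the ``tapex_c`` column).
        Daily weather is expanded to 144 ten-minute readings with ``course``.
        Returns columns ``date, daily_tt, daily_par, ptq`` (ptq is NaN on
        zero-thermal-time days).
        """
        if self.kind == "daily":
            if source == "air":
                lo, hi = "tmin_c", "tmax_c"
            else:
                lo, hi = f"t{source}_min_c", f"t{source}_max_c"
                if lo not in self.data.columns:
                    raise KeyError(f"no {source!r} temperature series in weather")
            tmin = self.data[lo].to_numpy(float)
            tmax = self.data[hi].to_numpy(float)
            sub = np.stack([course(a, b) for a, b in zip(tmin, tmax)])
            f = beta_response(sub, resp)
            tt = resp.t_opt * f.mean(axis=1)
            par = self.data["par_mol_m2"].to_numpy(float)
            dates = pd.to_datetime(self.data["date"])
        else:
            col = "tair_c" if source in ("air",) else f"t{source}_c"
            if col not in self.data.columns:
                raise KeyError(f"no {source!r} temperature series in weather")
            ts = pd.to_datetime(self.data["timestamp"])
            day = ts.dt.normalize()
            t = self.data[col].to_numpy(float)
            f = beta_response(t, resp)
            step_s = (ts.iloc[1] - ts.iloc[0]).total_seconds() if len(ts) > 1 else 600.0
            grp = pd.DataFrame(
                {
                    "day": day,
                    "f": f,
                    "par_mol": self.data["par_umol_m2_s"].to_numpy(float)
                    * step_s
                    * 1e-6,
                }
            ).groupby("day", sort=True)
            tt = (resp.t_opt * grp["f"].mean()).to_numpy()
            par = grp["par_mol"].sum().to_numpy()
            dates = pd.Series(grp["f"].mean().index)
        with np.errstate(divide="ignore", invalid="ignore"):
            ptq = np.where(tt > 0, par / np.where(tt > 0, tt, 1.0), np.nan)
        return pd.DataFrame(
            {"date": pd.to_datetime(dates).to_numpy(), "daily_tt": tt,
             "daily_par": par, "ptq": ptq}
        )
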