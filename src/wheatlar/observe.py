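"""Observation-side calculations: Haun stage, initial LAR, spline LAR, CC_night.

The Haun stage scores main-stem development as the number of ligulated
leaves plus the fractional elongation of the youngest visible blade
relative to the youngest ligulated blade.  The initial leaf appearance
rate (LAR_i) is the ordinary-least-squares slope of Haun stage against
thermal time over the early, linear window (Haun stage 1.5–5, before
final leaf length starts increasing).  The time course of LAR is obtained
as the first derivative of a smoothing spline fitted to Haun stage versus
thermal time.  Night carbohydrate consumption (CC_night) is the drop in
shoot carbohydrate concentration over the night per unit of night thermal
time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "LeafMeasurement",
    "CarbSample",
    "haun_stage",
    "initial_lar",
    "lar_spline",
    "cc_night",
]


@dataclass(frozen=True)
class LeafMeasurement:
    """Blade lengths and ligulated-leaf count for one plant on one date."""

    ligulated_count: int
    expanding_len_cm: float
    ligulated_len_cm: float

    def __post_init__(self) -> None:
        if self.ligulated_count < 0:
            raise ValueError("ligulated_count must be >= 0")
        if self.expanding_len_cm < 0:
            raise ValueError("expanding blade length must be >= 0")


@dataclass(frozen=True)
class CarbSample:
    """Paired end-of-day / end-of-night carbohydrate concentrations (mg g⁻¹)."""

    end_of_day: float
    end_of_night: float
    night_thermal_time: float

    def __post_init__(self) -> None:
        if self.end_of_day < 0 or self.end_of_night < 0:
            raise ValueError("concentrations must be >= 0")
        if self.night_thermal_time <= 0:
            raise ValueError("night thermal time must be > 0")


def haun_stage(m: LeafMeasurement) -> float:
    """Decimal Haun stage: ligulated count + clamp(expanding/ligulated, 0, 1)."""
    if m.ligulated_len_cm <= 0:
        raise ValueError("ligulated blade length must be > 0")
    frac = min(max(m.expanding_len_cm / m.ligulated_len_cm, 0.0), 1.0)
    return m.ligulated_count + frac


def initial_lar(
    tt,
    hs=None,
    hs_min: float = 1.5,
    hs_max: float = 5.0,
) -> tuple[float, float]:
    """Initial LAR (leaves °Cd⁻¹) and its standard error.

    OLS slope of Haun stage against cumulative thermal time restricted to
    ``hs_min <= HS <= hs_max`` (default 1.5–5, the early linear phase).
    Accepts a :class:`~wheatlar.simulate.HaunTrajectory` or paired arrays.
    """
    if hs is None:  # a trajectory object
        df = tt.data
        tt, hs = df["tt_cum"].to_numpy(float), df["haun_stage"].to_numpy(float)
    tt = np.asarray(tt, dtype=float)
    hs = np.asarray(hs, dtype=float)
    mask = (hs >= hs_min) & (hs <= hs_max)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 observations with {hs_min} <= HS <= {hs_max}, "
            f"got {int(mask.sum())}"
        )
    res = stats.linregress(tt[mask], hs[mask])
    return float(res.slope), float(res.stderr)


def lar_spline(
    tt,
    hs,
    lam: float | None = None,
    grid_n: int = 200,
    respect_monotone: bool = True,
) -> pd.DataFrame:
    """LAR(t) as the derivative of a smoothing spline of HS versus thermal time.

    A cubic smoothing spline is fitted with the penalty chosen by
    generalized cross-validation when ``lam`` is None (pass ``lam``
    explicitly to override).  Because leaf appearance cannot run backwards,
    when the input Haun stages are non-decreasing and the GCV fit still
    undulates to a negative derivative (sparse or clustered sampling), the
    penalty is escalated minimally — decade by decade — until the
    derivative is nonnegative over the evaluation grid
    (``respect_monotone=False`` disables this safeguard).  Duplicate
    thermal-time abscissae are collapsed by averaging.  Returns a DataFrame
    with columns ``tt`` (uniform grid over the observed span),
    ``haun_stage`` (fitted) and ``lar`` (spline first derivative).
    """
    tt = np.asarray(tt, dtype=float)
    hs = np.asarray(hs, dtype=float)
    df = pd.DataFrame({"tt": tt, "hs": hs}).groupby("tt", as_index=False).mean()
    x, y = df["tt"].to_numpy(), df["hs"].to_numpy()
    if len(x) < 5:
        raise ValueError("spline LAR needs >= 5 distinct thermal-time points")
    grid = np.linspace(x[0], x[-1], grid_n)
    spl = make_smoothing_spline(x, y, lam=lam)
    deriv = spl.derivative()(grid)
    if (
        respect_monotone
        and lam is None
        and np.all(np.diff(y) >= 0)
        and deriv.min() < -1e-10
    ):
        # smallest penalty on a geometric ladder that keeps LAR >= 0
        for trial in np.geomspace(1e-6, 1e14, 41):
            spl = make_smoothing_spline(x, y, lam=float(trial))
            deriv = spl.derivative()(grid)
            if deriv.min() >= -1e-10:
                break
    return pd.DataFrame({"tt": grid, "haun_stage": spl(grid), "lar": deriv})


def cc_night(s: CarbSample) -> tuple[float, bool]:
    """Night carbohydrate consumption (mg g⁻¹ °Cd⁻¹) and an accumulation flag.

    ``(end_of_day − end_of_night) / night thermal time``; negative values
    mean the shoot accumulated carbohydrate overnight and are flagged.
    """
    rate = (s.end_of_day - s.end_of_night) / s.night_thermal_time
    return rate, rate < 0
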