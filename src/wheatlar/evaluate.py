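"""Model-evaluation statistics and RMSRE-minimizing parameter estimation.

The mean squared error between simulated and observed Haun stages is
decomposed, following the Gauch scheme, into squared bias (SB), non-unity
slope (NU) and lack of correlation (LC) — respectively translation,
rotation and scatter components — using the regression of observed on
simulated values.  Model skill is summarized by the Nash–Sutcliffe
modeling efficiency (EF) and by the root-mean-squared relative error
(RMSRE, %), the latter computed over observations with Haun stage > 1
(very early stages make relative errors unstable).  Parameters are
estimated by minimizing RMSRE with a seeded, bounded, derivative-free
global optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .lar_models import LarPtqResponse, M1Params, M2Params, M3Params
from .simulate import SimConfig, simulate_haun
from .thermal_env import TemperatureResponse, WeatherSeries

__all__ = [
    "EvaluationResult",
    "FitSpec",
    "FitResult",
    "mse_decomposition",
    "rmsre",
    "nash_sutcliffe",
    "select_hs5",
    "estimate_params",
    "evaluate_pair",
]


@dataclass(frozen=True)
class EvaluationResult:
    """MSE and its decomposition, RMSRE (%), EF and the sample size."""

    mse: float
    sb: float
    nu: float
    lc: float
    rmsre_pct: float
    ef: float
    n: int
    degenerate: bool = False  # zero simulated variance: NU undefined, LC absorbs

    def as_dict(self) -> dict:
        return {
            "mse": self.mse, "sb": self.sb, "nu": self.nu, "lc": self.lc,
            "rmsre_pct": self.rmsre_pct, "ef": self.ef, "n": self.n,
        }


def mse_decomposition(simulated, observed) -> tuple[float, float, float, float, bool]:
    """MSE = SB + NU + LC (Gauch decomposition).

    With the regression of observed on simulated (slope b, correlation r)
    and population (1/n) moments:
    ``SB = (mean(sim) − mean(obs))²``, ``NU = (1 − b)² · msd(sim)``,
    ``LC = (1 − r²) · msd(obs)``.  Returns (mse, sb, nu, lc, degenerate);
    when the simulated values have zero variance the slope is undefined,
    NU is reported as 0 with LC absorbing the residual, and the degenerate
    flag is set.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise ValueError("simulated and observed must be paired 1-D arrays")
    n = sim.size
    if n < 3:
        raise ValueError("decomposition needs n >= 3 pairs")
    mse = float(np.mean((sim - obs) ** 2))
    sb = float((sim.mean() - obs.mean()) ** 2)
    msd_sim = float(np.mean((sim - sim.mean()) ** 2))
    msd_obs = float(np.mean((obs - obs.mean()) ** 2))
    if msd_sim == 0.0:
        return mse, sb, 0.0, mse - sb, True
    b = float(np.mean((sim - sim.mean()) * (obs - obs.mean())) / msd_sim)
    nu = (1.0 - b) ** 2 * msd_sim
    if msd_obs == 0.0:
        lc = 0.0
    else:
        r2 = (b**2) * msd_sim / msd_obs
        lc = (1.0 - r2) * msd_obs
    return mse, sb, nu, lc, False


def rmsre(simulated, observed, threshold: float = 1.0) -> float:
    """Root-mean-squared relative error in percent.

    ``100 · sqrt(mean(((sim − obs)/obs)²))`` over pairs with
    ``obs > threshold`` (default: Haun stage > 1.0).
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    mask = obs > threshold
    if not mask.any():
        raise ValueError(f"no observations above threshold {threshold}")
    if np.any(obs[mask] == 0):
        raise ValueError("relative error undefined for zero observations")
    return float(100.0 * np.sqrt(np.mean(((sim[mask] - obs[mask]) / obs[mask]) ** 2)))


def nash_sutcliffe(simulated, observed) -> float:
    """Nash–Sutcliffe modeling efficiency: 1 − SSE / SS about the observed mean."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    ss_obs = float(np.sum((obs - obs.mean()) ** 2))
    if ss_obs == 0.0:
        raise ValueError("observed variance is zero; EF undefined")
    return float(1.0 - np.sum((obs - sim) ** 2) / ss_obs)


def select_hs5(observations: pd.DataFrame, target: float = 5.0) -> pd.Series:
    """The observation whose Haun stage is closest to ``target`` (default 5).

    Ties are broken toward the earlier date.  Expects columns
    ``haun_stage`` and (for tie-breaking) ``date``; rows are otherwise
    passed through unchanged.
    """
    if len(observations) == 0:
        raise ValueError("empty observation series")
    df = observations
    if "date" in df.columns:
        df = df.sort_values("date", kind="stable")
    dist = (df["haun_stage"] - target).abs().to_numpy()
    return df.iloc[int(np.argmin(dist))]


def evaluate_pair(
    simulated, observed, rmsre_threshold: float = 1.0
) -> EvaluationResult:
    """Full evaluation of paired simulated/observed values."""
    mse, sb, nu, lc, degenerate = mse_decomposition(simulated, observed)
    return EvaluationResult(
        mse=mse, sb=sb, nu=nu, lc=lc,
        rmsre_pct=rmsre(simulated, observed, rmsre_threshold),
        ef=nash_sutcliffe(simulated, observed),
        n=len(np.asarray(observed)),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Parameter estimation
# ---------------------------------------------------------------------------

_RESPONSE_FIELDS = {"lar_min", "lar_max", "ptq_hf"}


@dataclass(frozen=True)
class FitSpec:
    """What to estimate and how.

    ``free`` maps parameter names to finite (lower, upper) bounds.
    Recognized names: ``phyllochron`` (M1), ``base_phyllochron`` (M2),
    ``lar_min`` / ``lar_max`` / ``ptq_hf`` / ``s_c_gai`` (M3).  By default
    only the single headline parameter of each model is freed (phyllochron
    for M1/M2, lar_min for M3).  The objective is the pooled RMSRE over
    observations with Haun stage above ``threshold``.
    """

    free: dict[str, tuple[float, float]]
    seed: int = 0
    threshold: float = 1.0
    maxiter: int = 60
    popsize: int = 12
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one free parameter is required")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")


@dataclass
class FitResult:
    """Fitted model parameters, the objective at the optimum, and a trace."""

    params: M1Params | M2Params | M3Params
    objective: float  # RMSRE, %
    values: dict[str, float]
    n_obs: int
    success: bool
    message: str
    trace: list[float] = field(default_factory=list)


def _apply_free(base, names, theta):
    """Return a copy of ``base`` with the named parameters set to ``theta``."""
    updates = dict(zip(names, theta))
    if isinstance(base, M3Params):
        resp_updates = {k: v for k, v in updates.items() if k in _RESPONSE_FIELDS}
        other = {k: v for k, v in updates.items() if k not in _RESPONSE_FIELDS}
        resp = (
            replace(base.response, **resp_updates) if resp_updates else base.response
        )
        return replace(base, response=resp, **other)
    return replace(base, **updates)


def _aligned_pairs(traj, obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    sim = traj.data[["date", "haun_stage"]].copy()
    sim["date"] = pd.to_datetime(sim["date"]).dt.normalize()
    o = obs.copy()
    o["date"] = pd.to_datetime(o["date"]).dt.normalize()
    merged = o.merge(sim, on="date", suffixes=("_obs", "_sim"), how="inner")
    return (
        merged["haun_stage_sim"].to_numpy(float),
        merged["haun_stage_obs"].to_numpy(float),
    )


def estimate_params(
    spec: FitSpec,
    weather,
    observations,
    base_params: M1Params | M2Params | M3Params,
    config: SimConfig = SimConfig(),
    resp: TemperatureResponse = TemperatureResponse(),
) -> FitResult:
    """Estimate LAR-model parameters by minimizing RMSRE of simulated Haun stage.

    ``weather`` is a :class:`WeatherSeries` or a dict of them (multi-sowing
    calibration); ``observations`` is a matching DataFrame (columns
    ``date``, ``haun_stage``) or dict of DataFrames.  Optimization uses
    seeded differential evolution within the bounds of ``spec.free``
    (derivative-free and global within bounds), so results are
    reproducible for a fixed seed and invariant to observation ordering.
    """
    if isinstance(weather, WeatherSeries):
        weather = {"_single": weather}
        observations = {"_single": observations}
    if set(weather) != set(observations):
        raise ValueError("weather and observations keys must match")

    from .simulate import _summaries_by_source

    cached = {k: _summaries_by_source(w, resp) for k, w in weather.items()}
    names = list(spec.free)
    bounds = [spec.free[n] for n in names]
    trace: list[float] = []

    n_obs = sum(
        int((pd.to_numeric(o["haun_stage"]) > spec.threshold).sum())
        for o in observations.values()
    )
    if n_obs < 5:
        raise ValueError(
            f"need >= 5 observations above Haun stage {spec.threshold}, got {n_obs}"
        )

    def objective(theta) -> float:
        params = _apply_free(base_params, names, theta)
        rel_sq, count = 0.0, 0
        for key, w in weather.items():
            traj = simulate_haun(w, params, config, resp, summaries=cached[key])
            sim, obs = _aligned_pairs(traj, observations[key])
            mask = obs > spec.threshold
            if mask.any():
                rel_sq += float(np.sum(((sim[mask] - obs[mask]) / obs[mask]) ** 2))
                count += int(mask.sum())
        if count == 0:
            return 1e6
        val = 100.0 * np.sqrt(rel_sq / count)
        trace.append(val)
        return val

    res = optimize.differential_evolution(
        objective,
        bounds=bounds,
        seed=spec.seed,
        maxiter=spec.maxiter,
        popsize=spec.popsize,
        tol=spec.tol,
        polish=True,
    )
    fitted = _apply_free(base_params, names, res.x)
    return FitResult(
        params=fitted,
        objective=float(res.fun),
        values=dict(zip(names, (float(v) for v in res.x))),
        n_obs=n_obs,
        success=bool(res.success),
        message=str(res.message),
        trace=trace,
    )
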