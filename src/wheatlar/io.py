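"""Readers, writers, parameter files and the synth → simulate → evaluate pipeline.

Tabular data travels as RFC-4180 CSV, reports as JSON, and model
parameters as one JSON document with ``m1`` / ``m2`` / ``m3`` blocks.
All stochastic stages draw from the single seed recorded in every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import evaluate_pair
from .lar_models import LarPtqResponse, M1Params, M2Params, M3Params
from .observe import initial_lar
from .scenarios import build_field_weather, chamber_preset, field_preset
from .simulate import HaunTrajectory, SimConfig, simulate_haun
from .thermal_env import TemperatureResponse, WeatherSeries, srad_to_par

__all__ = [
    "RunConfig",
    "read_weather",
    "write_weather",
    "read_observations",
    "write_trajectory",
    "read_params",
    "write_params",
    "default_params",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_DAILY_REQUIRED = ["date", "tmin_c", "tmax_c"]
_SUBDAILY_REQUIRED = ["timestamp", "tair_c", "par_umol_m2_s"]


class WeatherFormatError(ValueError):
    """Malformed weather file (missing columns, bad dates, bad values)."""


def read_weather(
    path, dialect: str = "daily", latitude: float | None = None
) -> WeatherSeries:
    """Read a weather CSV in the daily or sub-daily dialect.

    Daily columns: ``date, tmin_c, tmax_c`` and one of ``par_mol_m2`` /
    ``srad_mj_m2`` (solar radiation is converted to PAR with the standard
    0.50 PAR fraction and 4.57 mol MJ⁻¹).  Sub-daily columns:
    ``timestamp, tair_c, par_umol_m2_s``.  Distinct failure modes raise
    distinct messages: missing columns, non-monotone dates, date gaps
    (naming the date), negative radiation.
    """
    df = pd.read_csv(path)
    required = _DAILY_REQUIRED if dialect == "daily" else _SUBDAILY_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"{path}: missing columns {missing}")
    if dialect == "daily":
        if "par_mol_m2" not in df.columns:
            if "srad_mj_m2" not in df.columns:
                raise WeatherFormatError(
                    f"{path}: missing columns ['par_mol_m2' or 'srad_mj_m2']"
                )
            df["par_mol_m2"] = srad_to_par(df["srad_mj_m2"].to_numpy(float))
        dates = pd.to_datetime(df["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise WeatherFormatError(f"{path}: dates are not strictly increasing")
        gaps = dates.diff().dropna()
        bad = gaps[gaps != pd.Timedelta(days=1)]
        if len(bad):
            where = dates.iloc[bad.index[0]].date()
            raise WeatherFormatError(f"{path}: date gap at {where}")
        if (df["par_mol_m2"] < 0).any():
            raise WeatherFormatError(f"{path}: negative radiation values")
        df["date"] = dates
        return WeatherSeries(data=df, kind="daily", latitude=latitude)
    if (df["par_umol_m2_s"] < 0).any():
        raise WeatherFormatError(f"{path}: negative radiation values")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return WeatherSeries(data=df, kind="subdaily", latitude=latitude)


def write_weather(weather: WeatherSeries, path) -> None:
    df = weather.data.copy()
    time_col = "date" if weather.kind == "daily" else "timestamp"
    fmt = "%Y-%m-%d" if weather.kind == "daily" else "%Y-%m-%dT%H:%M:%S"
    df[time_col] = pd.to_datetime(df[time_col]).dt.strftime(fmt)
    df.to_csv(path, index=False, float_format="%.6f")


def read_observations(path) -> pd.DataFrame:
    """Observed Haun-stage CSV: columns ``date, haun_stage`` (replicate id optional)."""
    df = pd.read_csv(path)
    missing = [c for c in ("date", "haun_stage") if c not in df.columns]
    if missing:
        raise WeatherFormatError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


_TRAJ_COLS = ["date", "tt_cum", "haun_stage", "lar", "gai", "gai_eff"]


def write_trajectory(traj: HaunTrajectory, path) -> None:
    df = traj.data.copy()
    for col in ("gai", "gai_eff"):
        if col not in df.columns:
            df[col] = np.nan
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df[_TRAJ_COLS].to_csv(path, index=False, float_format="%.8f")


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------


def default_params() -> dict:
    """Default parameter document with m1 / m2 / m3 blocks."""
    m3 = M3Params()
    return {
        "m1": asdict(M1Params()),
        "m2": asdict(M2Params()),
        "m3": asdict(m3),
    }


def write_params(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_params(path) -> dict:
    return json.loads(Path(path).read_text())


def params_for(kind: str, doc: dict | None = None):
    """Instantiate M1/M2/M3 parameters from a parameter document."""
    doc = doc if doc is not None else default_params()
    block = dict(doc.get(kind, {}))
    if kind == "m1":
        return M1Params(**block)
    if kind == "m2":
        for key in ("phase_multipliers", "phase_breaks", "correction_window"):
            if key in block:
                block[key] = tuple(block[key])
        return M2Params(**block)
    if kind == "m3":
        if "response" in block:
            block["response"] = LarPtqResponse(**block["response"])
        return M3Params(**block)
    raise ValueError(f"unknown model kind {kind!r} (expected m1, m2 or m3)")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: forcing, model, parameters, outputs, seed."""

    out_dir: str
    model: str = "m3"
    scenario: str | None = None       # e.g. 'table1:HT.SD.320', 'hsc-like'
    weather_path: str | None = None
    weather_dialect: str = "daily"
    obs_path: str | None = None       # single file, or a directory with
                                      # obs_<sowing_doy>.csv for field presets
    params_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.weather_path is None):
            raise ValueError("exactly one of scenario / weather_path is required")


def _load_forcing(config: RunConfig) -> dict[str, WeatherSeries]:
    if config.weather_path is not None:
        return {"run": read_weather(config.weather_path, config.weather_dialect)}
    name = config.scenario
    if name.startswith("table1:"):
        scen = chamber_preset(name.split(":", 1)[1])
        if scen.swap is not None:
            raise ValueError(
                "swap treatments need a model to time the trigger; use "
                "scenarios.chamber_weather_with_swap directly"
            )
        from .scenarios import build_chamber_weather

        return {scen.name: build_chamber_weather(scen)}
    scen = field_preset(name, seed=config.seed)
    return {
        f"sowing_{doy:03d}": w for doy, w in build_field_weather(scen).items()
    }


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run forcing → simulation → (optional) evaluation; write artifacts.

    Writes one trajectory CSV per weather series, a summary JSON (initial
    LAR and final stage per series, parameter echo, seed, version) and,
    when observations are supplied, an evaluation JSON per series.
    Outputs are deterministic for identical config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    doc = read_params(config.params_path) if config.params_path else default_params()
    params = params_for(config.model, doc)
    sim_config = SimConfig()
    forcing = _load_forcing(config)

    artifacts: dict[str, Path] = {}
    summary: dict = {
        "seed": config.seed,
        "model": config.model,
        "package_version": _pkg_version("wheatlar"),
        "params": doc[config.model],
        "series": {},
    }
    obs_dir = Path(config.obs_path) if config.obs_path else None

    for name, weather in forcing.items():
        traj = simulate_haun(weather, params, sim_config)
        traj_path = out / f"trajectory_{name}_{config.model}.csv"
        write_trajectory(traj, traj_path)
        artifacts[f"trajectory_{name}"] = traj_path
        entry: dict = {"final_haun_stage": round(traj.final_haun_stage, 6),
                       "n_days": len(traj)}
        try:
            slope, se = initial_lar(traj)
            entry["lar_i"] = round(slope, 8)
            entry["lar_i_se"] = round(se, 8)
        except ValueError:
            entry["lar_i"] = None
        summary["series"][name] = entry

        obs_file = None
        if obs_dir is not None:
            if obs_dir.is_dir():
                cand = obs_dir / f"obs_{name}.csv"
                obs_file = cand if cand.exists() else None
            else:
                obs_file = obs_dir
        if obs_file is not None:
            obs = read_observations(obs_file)
            sim_df = traj.data[["date", "haun_stage"]].copy()
            sim_df["date"] = pd.to_datetime(sim_df["date"]).dt.normalize()
            obs["date"] = obs["date"].dt.normalize()
            merged = obs.merge(sim_df, on="date", suffixes=("_obs", "_sim"))
            if len(merged) >= 3:
                result = evaluate_pair(
                    merged["haun_stage_sim"], merged["haun_stage_obs"]
                )
                report_path = out / f"evaluation_{name}_{config.model}.json"
                report_path.write_text(
                    json.dumps(result.as_dict(), indent=2, sort_keys=True) + "\n"
                )
                artifacts[f"evaluation_{name}"] = report_path

    summary_path = out / f"summary_{config.model}.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    artifacts["summary"] = summary_path
    return artifacts
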