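"""Leaf-appearance-rate models: constant, segmented-linear, carbon supply/demand.

Three competing models of the main-stem leaf appearance rate (LAR,
leaves °Cd⁻¹) of wheat:

* **M1** — constant LAR in thermal time (a fixed phyllochron), the default
  in most crop growth models.
* **M2** — the Sirius segmented-linear model: three phyllochron phases by
  leaf rank (leaves 1–3 faster than 4–8, which are faster than >8) with an
  empirical sowing-date correction standing in for apex–air temperature
  differences of winter sowings.
* **M3** — the carbon supply/demand model: LAR saturates with the ratio of
  canopy-intercepted PAR to thermal time (both integrated over a trailing
  buffer window of d °Cd, representing stored soluble carbohydrate), scaled
  by the ratio of a demand parameter to the effective green area index
  (GAI_eff).  GAI_eff is floored at the potential juvenile canopy (the GAI
  at ~3.5 leaves, just after the first tiller appears) and never decreases,
  so senescence cannot inflate the supply/demand ratio.

The saturating backbone shared by M3 and the chamber-data analysis is the
three-parameter asymptotic LAR–PTQ response
``LAR = LAR_min + (LAR_max − LAR_min) · PTQ / (PTQ_hf + PTQ)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LarPtqResponse",
    "M1Params",
    "M2Params",
    "M3Params",
    "CanopyState",
    "LarPtqFit",
    "lar_from_ptq",
    "fit_lar_ptq",
    "m1_lar",
    "m2_lar",
    "effective_gai",
    "light_interception_fraction",
    "m3_lar",
    "CM2_PER_M2",
]

#: cm² per m², for the juvenile-leaf-area unit conversion.
CM2_PER_M2 = 1e-4


@dataclass(frozen=True)
class LarPtqResponse:
    """Asymptotic LAR–PTQ response parameters.

    ``lar_min`` is the LAR maintained at zero PTQ (leaves develop at a
    minimum rate even without carbon supply), ``lar_max`` the asymptote as
    PTQ grows without bound, and ``ptq_hf`` the half-saturation PTQ at
    which LAR is midway between the two.

    Defaults are package defaults calibrated to chamber-scale behaviour
    (LAR ≈ 5e-3 leaves °Cd⁻¹ in deep shade rising towards ≈ 2.4e-2 at
    very high PTQ, half-saturation near 2 mol m⁻² °Cd⁻¹); all three are
    varietal parameters users should fit to their own data.
    """

    lar_min: float = 4.996e-3
    lar_max: float = 2.364e-2
    ptq_hf: float = 1.98

    def __post_init__(self) -> None:
        if not (0.0 <= self.lar_min < self.lar_max):
            raise ValueError("need 0 <= lar_min < lar_max")
        if self.ptq_hf <= 0:
            raise ValueError("ptq_hf must be > 0")


def lar_from_ptq(ptq, resp: LarPtqResponse = LarPtqResponse()):
    """LAR (leaves °Cd⁻¹) from the photothermal quotient.

    Strictly increasing and concave in PTQ, bounded in
    (``lar_min``, ``lar_max``); equals ``(lar_min + lar_max)/2`` at
    ``ptq = ptq_hf``.  Accepts scalars or arrays.
    """
    ptq = np.asarray(ptq, dtype=float)
    if np.any(ptq < 0):
        raise ValueError("PTQ must be >= 0")
    out = resp.lar_min + (resp.lar_max - resp.lar_min) * ptq / (resp.ptq_hf + ptq)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LarPtqFit:
    """Result of fitting LAR–PTQ points: estimates, SEs and diagnostics."""

    form: str                      # 'linear' or 'asymptotic'
    params: dict[str, float]
    std_errors: dict[str, float]
    identifiable: bool = True
    message: str = ""

    def predict(self, ptq):
        ptq = np.asarray(ptq, dtype=float)
        if self.form == "linear":
            return self.params["intercept"] + self.params["slope"] * ptq
        return lar_from_ptq(
            ptq,
            LarPtqResponse(
                self.params["lar_min"], self.params["lar_max"], self.params["ptq_hf"]
            ),
        )


def fit_lar_ptq(ptq, lar, form: str = "asymptotic") -> LarPtqFit:
    """Least-squares fit of LAR versus PTQ points.

    ``form='linear'`` fits ``LAR = a + b·PTQ`` (adequate over narrow PTQ
    ranges, e.g. a single chamber experiment); ``form='asymptotic'`` fits
    the three-parameter saturating response.  Standard errors are the
    asymptotic (delta-method) SEs.  For the asymptotic form the fit is
    flagged non-identifiable when the estimated half-saturation PTQ lies
    beyond the observed PTQ range or the covariance is singular — with no
    curvature in the data the asymptote and half-saturation trade off
    freely.
    """
    ptq = np.asarray(ptq, dtype=float)
    lar = np.asarray(lar, dtype=float)
    if ptq.shape != lar.shape or ptq.ndim != 1:
        raise ValueError("ptq and lar must be 1-D arrays of equal length")
    n_distinct = len(np.unique(ptq))

    if form == "linear":
        if n_distinct < 2:
            raise ValueError("linear fit needs >= 2 distinct PTQ values")
        res = stats.linregress(ptq, lar)
        return LarPtqFit(
            form="linear",
            params={"intercept": float(res.intercept), "slope": float(res.slope)},
            std_errors={
                "intercept": float(res.intercept_stderr),
                "slope": float(res.stderr),
            },
        )
    if form != "asymptotic":
        raise ValueError(f"unknown fit form {form!r}")
    if n_distinct < 3:
        raise ValueError("asymptotic fit needs >= 3 distinct PTQ values")

    def model(x, lar_min, lar_max, ptq_hf):
        return lar_min + (lar_max - lar_min) * x / (ptq_hf + x)

    lmin0 = max(float(lar.min()), 1e-6)
    lmax0 = max(float(lar.max()) * 1.2, lmin0 * 2)
    p0 = (lmin0, lmax0, max(float(np.median(ptq)), 1e-3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, pcov = optimize.curve_fit(
            model, ptq, lar, p0=p0,
            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    se = np.sqrt(np.diag(pcov))
    identifiable = bool(np.all(np.isfinite(se))) and popt[2] <= float(ptq.max())
    msg = "" if identifiable else (
        "PTQ_hf not identifiable: estimated half-saturation lies beyond the "
        "observed PTQ range or covariance is singular"
    )
    return LarPtqFit(
        form="asymptotic",
        params={"lar_min": float(popt[0]), "lar_max": float(popt[1]),
                "ptq_hf": float(popt[2])},
        std_errors={"lar_min": float(se[0]), "lar_max": float(se[1]),
                    "ptq_hf": float(se[2])},
        identifiable=identifiable,
        message=msg,
    )


# ---------------------------------------------------------------------------
# M1: constant LAR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class M1Params:
    """Constant-phyllochron model: one phyllochron (°Cd leaf⁻¹)."""

    phyllochron: float = 100.0

    def __post_init__(self) -> None:
        if self.phyllochron <= 0:
            raise ValueError("phyllochron must be > 0")


def m1_lar(params: M1Params) -> float:
    """Constant LAR = 1 / phyllochron, independent of rank and weather."""
    return 1.0 / params.phyllochron


# ---------------------------------------------------------------------------
# M2: Sirius segmented-linear model with sowing-date correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class M2Params:
    """Segmented-linear phyllochron with sowing-date correction.

    Leaves 1–3 appear faster than 4–8, which appear faster than >8:
    the effective phyllochron is ``base_phyllochron`` times a phase
    multiplier keyed on leaf rank.  Phase multipliers default to
    (0.75, 1.0, 1.3); the published varietal values live in material not
    reproduced here, so these are documented placeholders.

    The sowing-date correction is a surrogate for apex–air temperature
    differences in winter sowings: the phyllochron is reduced linearly
    with sowing day-of-year, reaching its maximum reduction
    (``max_reduction``) at ``min_phyllochron_doy`` (~mid-July in the
    Northern hemisphere); sowings after that day are uncorrected.
    ``hemisphere='south'`` mirrors all days by 182.
    """

    base_phyllochron: float = 100.0
    phase_multipliers: tuple[float, float, float] = (0.75, 1.0, 1.3)
    phase_breaks: tuple[int, int] = (3, 8)
    max_reduction: float = 0.25
    min_phyllochron_doy: int = 196
    correction_window: tuple[int, int] = (1, 196)
    hemisphere: str = "north"

    def __post_init__(self) -> None:
        if self.base_phyllochron <= 0:
            raise ValueError("base_phyllochron must be > 0")
        if any(m <= 0 for m in self.phase_multipliers):
            raise ValueError("phase multipliers must be > 0")
        m1_, m2_, m3_ = self.phase_multipliers
        if not (m1_ < m2_ < m3_):
            raise ValueError(
                "phase multipliers must increase with rank "
                "(early leaves appear fastest)"
            )
        if not 0.0 <= self.max_reduction < 1.0:
            raise ValueError("max_reduction must be in [0, 1)")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")

    def phase_multiplier(self, leaf_rank: float) -> float:
        b1, b2 = self.phase_breaks
        if leaf_rank <= b1:
            return self.phase_multipliers[0]
        if leaf_rank <= b2:
            return self.phase_multipliers[1]
        return self.phase_multipliers[2]

    def sowing_factor(self, sowing_doy: int) -> float:
        doy = int(sowing_doy)
        if self.hemisphere == "south":
            doy = (doy - 1 + 182) % 365 + 1
        lo, hi = self.correction_window
        if not (lo <= doy <= hi):
            return 1.0
        frac = min(doy, self.min_phyllochron_doy) / self.min_phyllochron_doy
        return 1.0 - self.max_reduction * frac


def m2_lar(leaf_rank: float, sowing_doy: int, params: M2Params = M2Params()) -> float:
    """LAR (leaves °Cd⁻¹) for the segmented-linear model.

    Effective phyllochron = base × phase multiplier(rank) × sowing factor.
    """
    if leaf_rank < 0:
        raise ValueError("leaf_rank must be >= 0")
    rank = max(leaf_rank, 1.0)  # the first phase covers leaves 1-3
    phyllochron = (
        params.base_phyllochron
        * params.phase_multiplier(rank)
        * params.sowing_factor(sowing_doy)
    )
    return 1.0 / phyllochron


# ---------------------------------------------------------------------------
# M3: carbon supply/demand model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class M3Params:
    """Parameters of the carbon supply/demand LAR model.

    ``response`` — the saturating LAR–PTQ backbone.
    ``s_c_gai`` (m² ground m⁻² leaf) — empirical constant scaling carbon
    demand to green area index; the supply term is multiplied by
    ``s_c_gai / GAI_eff``.
    ``d`` (°Cd) — trailing thermal-time window over which intercepted PAR,
    thermal time and GAI are integrated, representing the buffering
    capacity of stored soluble carbohydrates; default 70 °Cd.
    ``k`` — canopy light-extinction coefficient of the exponential
    (Beer-law) interception relation; 0.45 is typical of wheat canopies.
    ``ln_eff`` (leaves) — main-stem leaf number below which GAI_eff is
    held at the juvenile floor (~3.5, just after the first tiller).
    ``a_pot_juv`` (cm²) — potential area of a juvenile leaf (varietal).
    ``pd`` (plants m⁻²) — plant density.
    ``gai_form`` — where the demand scaling enters the LAR algebra:
    'divisor' (default; the saturating term is multiplied by
    ``s_c_gai/GAI_eff``, so LAR grows without bound as GAI → 0, hence the
    juvenile floor) or 'supply' (GAI_eff scales the supply ratio inside
    the saturation).
    """

    response: LarPtqResponse = field(default_factory=LarPtqResponse)
    s_c_gai: float = 0.525
    d: float = 70.0
    k: float = 0.45
    ln_eff: float = 3.5
    a_pot_juv: float = 10.0
    pd: float = 150.0
    gai_form: str = "divisor"

    def __post_init__(self) -> None:
        if min(self.d, self.k, self.ln_eff, self.pd, self.s_c_gai) <= 0:
            raise ValueError("d, k, ln_eff, pd and s_c_gai must all be > 0")
        if self.a_pot_juv <= 0:
            raise ValueError("a_pot_juv must be > 0")
        if self.gai_form not in ("divisor", "supply"):
            raise ValueError("gai_form must be 'divisor' or 'supply'")

    @property
    def juvenile_gai_floor(self) -> float:
        """GAI of the potential juvenile canopy: LN_eff × A_pot_juv × PD."""
        return self.ln_eff * self.a_pot_juv * CM2_PER_M2 * self.pd


@dataclass
class CanopyState:
    """Canopy bookkeeping for GAI_eff: emerged leaves and windowed-mean GAI."""

    leaf_number: float
    gai: float
    windowed_mean_gai: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.leaf_number < 0 or self.gai < 0:
            raise ValueError("leaf_number and gai must be >= 0")


def effective_gai(state: CanopyState, params: M3Params) -> float:
    """Effective GAI: juvenile floor before LN_eff, running-max windowed mean after.

    Below ``ln_eff`` emerged leaves the demand proxy is the potential
    juvenile canopy ``ln_eff × a_pot_juv × pd``; from ``ln_eff`` on it is
    the running maximum of the d-windowed mean GAI, so GAI_eff never
    decreases even when senescence outpaces expansion.
    """
    floor = params.juvenile_gai_floor
    if state.leaf_number < params.ln_eff:
        return floor
    if not state.windowed_mean_gai:
        return max(floor, state.gai)
    return max(floor, max(state.windowed_mean_gai))


def light_interception_fraction(gai: float, k: float = 0.45) -> float:
    """Fraction of incident PAR intercepted: 1 − exp(−k·GAI) (Beer's law)."""
    if gai < 0:
        raise ValueError("GAI must be >= 0")
    if k <= 0:
        raise ValueError("extinction coefficient k must be > 0")
    return 1.0 - float(np.exp(-k * gai))


def m3_lar(
    intercepted_par: float,
    thermal_time: float,
    gai_eff: float,
    params: M3Params = M3Params(),
) -> float:
    """LAR of the carbon supply/demand model.

    ``intercepted_par`` (mol m⁻² ground) and ``thermal_time`` (°Cd) are
    cumulated over the trailing buffer window d; their ratio X is the
    intercepted-light analogue of PTQ.  Default ('divisor') algebra::

        LAR = LAR_min + [(LAR_max − LAR_min) · X / (PTQ_hf + X)] · S_C/GAI / GAI_eff

    which reduces exactly to the chamber LAR–PTQ response whenever
    ``s_c_gai / gai_eff == 1``, and diverges as GAI_eff → 0 — hence the
    juvenile floor, which callers must enforce (``gai_eff`` at or above
    ``params.juvenile_gai_floor``).  The 'supply' alternative applies the
    demand scaling to X inside the saturation, keeping LAR ≤ LAR_max.
    """
    if thermal_time <= 0:
        raise ValueError("windowed thermal time must be > 0")
    if intercepted_par < 0:
        raise ValueError("intercepted PAR must be >= 0")
    if gai_eff <= 0:
        raise ValueError("gai_eff must be > 0 (the juvenile floor must prevent 0)")
    r = params.response
    x = intercepted_par / thermal_time
    scale = params.s_c_gai / gai_eff
    if params.gai_form == "divisor":
        sat = (r.lar_max - r.lar_min) * x / (r.ptq_hf + x)
        return r.lar_min + sat * scale
    xs = x * scale
    return r.lar_min + (r.lar_max - r.lar_min) * xs / (r.ptq_hf + xs)
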