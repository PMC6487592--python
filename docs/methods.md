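# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `wheatlar`, and what the test suite does and does not
establish about real field data.

## Thermal time and the temperature response

Development is driven by thermal time accumulated through a beta-shaped
response `f(T)` of leaf initiation and growth to organ temperature:

```
f(T) = max(0, 2 x^α − x^{2α}),   x = (T − T_min)/(T_opt − T_min),
α = ln 2 / ln((T_max − T_min)/(T_opt − T_min))
```

with cardinals `T_min = 0`, `T_opt = 27.5`, `T_max = 40 °C` by default
(config-exposed).  The shape exponent α is fully determined by the
cardinals, so the response always peaks at exactly 1 at `T_opt` and is
zero at and beyond both bounds.  Daily thermal time is
`ΔT_t = T_opt · mean(f(T_i))` over one day of uniform sub-daily
readings; the reference discretization is 144 ten-minute steps.  When
only daily minimum/maximum temperatures are available they are expanded
to a sine-based diurnal course (minimum at 03:00, maximum at 15:00), a
standard stand-in that is swappable via the `course` argument of
`WeatherSeries.daily_summaries`.  Square-wave chamber forcing at the
ten-minute step agrees with a one-minute brute-force integration to
machine precision when the photoperiod sits on the ten-minute grid, as
chamber photoperiods do.

Apex temperature drives development.  In the field the apex sits near
the soil surface until about four leaves have appeared, so the simulator
switches its temperature source from a soil proxy to a canopy proxy at
Haun stage 4 (configurable).  Energy-balance calculation of those
proxies is out of scope; callers may supply `tsoil_*`/`tcanopy_*`
columns, and the simulator falls back to air temperature with a logged
warning when they are absent.  In growth chambers the measured apex
temperature (`tapex_c`) is used directly when present.

## Photothermal quotient

`PTQ = daily PAR / ΔT_t` (mol m⁻² °Cd⁻¹) is the supply of
photosynthetically active radiation per unit of temperature-driven
developmental demand.  A day with `ΔT_t = 0` has no development and the
quotient is treated as an error, not infinity.  PAR from global solar
radiation uses the community conventions 0.50 (PAR fraction of
shortwave) and 4.57 mol MJ⁻¹, both config-exposed.

## The three LAR models

**M1** holds LAR constant: one phyllochron (default 100 °Cd leaf⁻¹).

**M2** multiplies a base phyllochron by a phase factor keyed on leaf
rank — boundaries at ranks 3 and 8, defaults (0.75, 1.0, 1.3) — and by a
sowing-date factor.  The published varietal multipliers and correction
slope are not reproducible from openly available material, so the
defaults are documented placeholders.  The sowing correction, a
surrogate for apex–air temperature differences of winter sowings,
reduces the phyllochron linearly with sowing day-of-year, reaching its
maximum reduction (default 25 %) at day 196 (mid-July, Northern
hemisphere); we apply the ramp over days 1–196 and leave later sowings
uncorrected, because the correction must attain its configured minimum
at the minimum-phyllochron day while the winter-sowing window the
correction stands in for covers days 1–90.  A hemisphere flag mirrors
all dates by 182 days.

**M3** is the carbon supply/demand model.  The saturating backbone is
the three-parameter asymptotic LAR–PTQ response

```
LAR(PTQ) = LAR_min + (LAR_max − LAR_min) · PTQ / (PTQ_hf + PTQ)
```

with `LAR_min` the rate maintained at zero supply, `LAR_max` the
asymptote, and `PTQ_hf` the half-saturation quotient.  In the field the
supply argument is the windowed intercepted quotient
`X = Ī_int(d)/T̄_t(d)`: PAR intercepted by the canopy (Beer's law,
`1 − exp(−k·GAI)`, `k = 0.45`, typical of wheat canopies) and thermal
time are both cumulated over the trailing `d = 70 °Cd` of development —
a buffer representing the pool of stored soluble carbohydrates that
smooths day-to-day weather.  At the start of a run, when fewer than
`d` °Cd of history exist, the whole history from emergence is used, with
a minimum of one day.

The demand side enters as `S_C/GAI / GAI_eff(d)` multiplying the
saturating term (the `divisor` form, the default): carbon demand scales
with plant size, approximated by the green area index, so LAR falls as
the canopy grows at fixed supply, and would diverge as GAI → 0.  That
divergence is why `GAI_eff` is floored at the potential juvenile canopy
`LN_eff × A^pot_juv × PD` (defaults 3.5 leaves × 10 cm² × 150 plants
m⁻² = 0.525 m² m⁻²; `S_C/GAI` defaults to the same value so the scale
starts at 1).  From `LN_eff` leaves onward, `GAI_eff` is the running
maximum of the `d`-windowed mean GAI — it never decreases, so late-season
senescence cannot re-accelerate leaf appearance.  An alternative
typographic reading, with `GAI_eff` scaling the supply ratio inside the
saturation (bounded by `LAR_max`), is available via
`M3Params(gai_form="supply")`.

Default response parameters (`LAR_min = 4.996e-3`, `LAR_max = 2.364e-2`
leaves °Cd⁻¹, `PTQ_hf = 1.98` mol m⁻² °Cd⁻¹) are package defaults of
chamber-scale magnitude; all are varietal and should be refit to data.
No CO₂ response term is included: elevated CO₂ acts on LAR through
assimilation, which this model does not simulate.

The simulator needs a GAI trajectory for M3.  A full leaf-growth model
is out of scope, so the internal default grows GAI linearly with the
simulated Haun stage, `GAI = c · HS · PD · A^pot_juv · 1e-4` with
`c = gai_per_haun` (default 1) config-exposed; an observed or external
daily GAI series can be supplied instead.  With the demand scale pinned
to 1 (`SimConfig(pin_supply_demand=True)`) the model reduces exactly to
the LAR–PTQ response evaluated at `X`, which the tests verify
numerically in every chamber treatment.

## Simulation

Daily step: the Haun stage advances by `LAR · ΔT_t` each day, with LAR
held constant within a day and thermal time integrated sub-daily inside
it.  Emergence is Haun stage 0 (the convention is isolated in
`SimConfig.initial_haun_stage`; all comparisons with observations use
stages above 1, so it does not affect scoring).  Simulation stops at a
final-leaf cap (default 20) or the end of the weather series.  Chamber
swap treatments (irradiance changed when the crop reaches a trigger
Haun stage) are generated in two passes: simulate the pre-swap forcing
to find the trigger day, then emit the swapped series.

## Observation-side statistics

The Haun stage of a plant is the ligulated-leaf count plus the ratio of
the youngest expanding blade length to the youngest ligulated blade
length, clamped to [0, 1].  The initial LAR is the OLS slope of Haun
stage on thermal time restricted to stages 1.5–5 (both bounds are
arguments): below 1.5 establishment noise dominates, above 5 final leaf
length grows and confounds the rate.  LAR over time is the first
derivative of a cubic smoothing spline of Haun stage versus thermal
time, with the penalty chosen by generalized cross-validation.  Because
leaf appearance cannot run backwards, when the input series is
non-decreasing and the GCV fit still undulates to a negative derivative
(sparse or clustered sampling), the penalty is escalated decade by
decade until the derivative is nonnegative over the evaluation grid;
`respect_monotone=False` restores plain GCV, and an explicit `lam`
overrides both.  Night carbohydrate consumption is the end-of-day minus
end-of-night concentration divided by night thermal time; negative
values (net accumulation) are flagged, not rejected.

## Evaluation statistics and estimation

`MSE = mean((sim − obs)²)` is decomposed, per the Gauch scheme, using
the regression of observed on simulated values (slope `b`, correlation
`r`) and population moments: `SB = (mean sim − mean obs)²`,
`NU = (1 − b)² · msd(sim)`, `LC = (1 − r²) · msd(obs)`; the identity
`MSE = SB + NU + LC` holds to 1e-10 and is asserted on a thousand random
vectors.  The regression direction matters — regressing simulated on
observed changes the NU/LC split — and the observed-on-simulated
convention is used here.  If the simulated values have zero variance the
slope is undefined; NU is reported as 0, LC absorbs the remainder and
the result is flagged.  RMSRE is `100·sqrt(mean(((sim−obs)/obs)²))` over
observations with Haun stage > 1 (the per-observation relative form,
isolated in one function).  Nash–Sutcliffe efficiency is
`1 − SSE/SS_obs`, equal to `1 − MSE/var(obs)` with population variance.
For single-point model comparison the observation closest to Haun stage
5 is selected per treatment, ties broken toward the earlier date, to
avoid autocorrelation and growth/development confounding.

Parameters are estimated by minimizing RMSRE of simulated versus
observed Haun stages with seeded differential evolution — a bounded,
derivative-free, global stochastic optimizer — deterministic for a fixed
seed and invariant to observation ordering.  By default only the
headline parameter of each model is free (phyllochron for M1/M2,
`LAR_min` for M3), mirroring single-site calibration practice;
additional parameters are opt-in via `FitSpec.free`.  The LAR–PTQ
response itself is fitted to (PTQ, LAR) point sets by least squares
(`curve_fit`), with asymptotic standard errors from the covariance; the
asymptotic form is flagged non-identifiable when the fitted `PTQ_hf`
lies beyond the observed PTQ range, where asymptote and half-saturation
trade off freely.

## Synthetic data

The chamber generator emits square-wave day/night forcing centred on
solar noon from the packaged treatment table (day/night temperature,
photoperiod, PAR flux, CO₂ as metadata).  The table also stores the
published *measured* mean daily PAR, thermal time and PTQ, which differ
slightly from set-point arithmetic; measured values are treated as
inputs and never regenerated, and the one row whose printed PTQ does not
round-trip from its own PAR and thermal-time entries is flagged and
excluded from exact-arithmetic checks.

The field generator produces daily weather per sowing date: temperature
as an annual sinusoid (peak at day 200, mirrored by 182 days in the
Southern hemisphere) plus a fixed diurnal range and iid Gaussian noise
on the daily mean; radiation as a clear-sky fraction of extraterrestrial
solar radiation (FAO-56 form) plus Gaussian noise truncated at zero,
converted to PAR.  Two presets are provided.  `hsc-like` emulates a hot
semi-arid site at 33 °N (annual mean 19.5 °C, amplitude 11.5 °C, diurnal
range 16 °C, clear-sky fraction 0.72) with eight sowings spread over the
year excluding midsummer; its early-development PTQ (aggregated until
500 °Cd, the window of the first five leaves) spans at least a two-fold
range across sowings and overlaps 1.2–3.8 mol m⁻² °Cd⁻¹.  `nz2020-like`
emulates a temperate site at 43.75 °S with late-summer to mid-autumn
sowings.  Limitations, deliberately accepted: no day-to-day
autocorrelation in the noise (sufficient to exercise the 70 °Cd buffer
window, not a calibrated weather generator), no humidity or VPD, no
soil/canopy energy balance.  Consequently the test suite demonstrates
*directional* field behaviour — late-autumn sowings develop their first
leaves at lower PTQ and, under M3 only, lower initial LAR than spring
sowings — but not the published field-experiment error statistics, which
require the real datasets.

## Numerical choices and degenerate inputs

Problem sizes: chamber runs use 40–60 days at 144 steps per day; field
runs use 160–240 days per sowing; recovery experiments use three sowings
observed every five days, estimation with differential evolution
(population 10–12, up to 40–60 generations).  Ties in `select_hs5` break
toward the earlier date.  Duplicate spline abscissae are averaged.
Sub-daily weather must divide 24 h evenly; daily weather must be
gap-free (the gap date is named in the error).  PTQ at zero thermal
time, relative error at zero observations, EF at zero observed variance,
and M3 evaluation at zero windowed thermal time or zero effective GAI
are all errors with distinct messages rather than silent infinities.
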