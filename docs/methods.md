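# Methods

This note documents the models implemented in `phenospring`, the
defaults and the reasoning behind the open design choices, and what the
synthetic test bed does and does not demonstrate.

## Onset model

The spring-index family of models predicts the onset of a phenophase as
the day the accumulated thermo-photoperiodic forcing crosses a species
threshold. Our parametrisation:

* **Diurnal interpolation.** Hourly temperatures are a single symmetric
  cosine between tmin (hour 0) and tmax (hour 12). This is the simplest
  curve with exact test anchors: a constant day is flat, hour 6 equals
  the midpoint, and the 24-hour mean equals (tmin+tmax)/2, which gives
  the closed form GDH = 24·(T_mean − T_b) whenever T_b ≤ tmin. The
  daylength-dependent asymmetric curves used elsewhere in the
  spring-index literature are not reproduced; the module keeps the
  diurnal curve behind one function so an alternative can be swapped in.
* **Daylength.** Cosine solar-declination approximation
  δ = −23.44°·cos(2π(doy+10)/year_length), hour angle
  ω = arccos(clamp(−tanφ·tanδ, ±1)), L = 24ω/π, clamped to [0, 24] so
  polar day/night degrade gracefully. Accuracy is a few minutes of
  daylight at mid-latitudes, far below the model's sensitivity.
* **Forcing and onset.** f(d) = GDH(d; T_b) · (L/12)^k, accumulated from
  `start_doy` (default Jan 1 for all species; no chilling/dormancy
  submodel). Onset is the first day the running sum reaches F*; if the
  sum never crosses by Dec 31 the year is reported "not reached" and is
  penalised as Dec 31 during calibration (a bounded penalty that keeps
  the objective finite).
* **Units.** Onsets are 1-based day of year (Feb 29 = 60 in leap
  years); F* is in °C·h of daylength-weighted degree hours; T_b in °C.

## Calibration

One parameter set per species across the whole network (the network is
climatically coherent; per-station parameters would absorb observation
noise). The grid is T_b ∈ {−2…5} °C × k ∈ {0, 0.5, 1, 1.5, 2}; for each
pair the threshold F* is searched exactly: the RMSE is piecewise
constant in F* with breakpoints at cumulative-forcing values, so the
search scans the thresholds that reproduce each observation exactly
(the cumulative forcing at every observed onset day) and then sweeps
all breakpoints between the best candidate's neighbours. Golden-section
or other continuous line searches are ill-posed on a piecewise-constant
objective, which is why the breakpoint scan is used. Ties resolve
deterministically: smallest k, then smallest T_b, then smallest F*.

With noise-free data any F* inside an interval reproduces the same
integer onsets, so F* is identified only up to that interval; T_b and k
are recovered exactly in the recovery tests, and the returned F*
predicts identically to the generating one (training RMSE 0).

Station-years enter calibration only when fewer than 10 % of the days
in the Jan 1–Jun 30 window are missing; remaining gaps are filled by
linear interpolation in time (nearest-value extension at year edges).
This usability rule is a declared convention, not an estimate of any
particular network's practice.

Cross-validation is year-stratified k-fold (years assigned round-robin
in sorted order), guarding against the calibration period's trend
leaking into skill estimates.

## Quantile-mapping bias correction

Per station, variable (tmin/tmax) and ensemble member. For each
calendar day c (1..365 on the common-year calendar; Feb 29 values join
the Mar 1 pool and Feb 29 is corrected with the Mar 1 transfer), all
reference-period values within ±30 days of c — wrapping across the year
boundary — are pooled and 100 empirical quantiles at centred
probabilities (j−0.5)/100 are taken by linear interpolation of order
statistics, for model and observations separately. Correction maps a
value through its model quantile onto the observed quantile curve;
beyond the calibrated range the constant correction of the nearest
extreme class applies, which keeps a warming trend intact (verified by
a trend-preservation diagnostic: a 0.4 °C/decade trend survives
correction of a stationary bias to within 0.05 °C/decade) and removes a
pure additive bias exactly at interior quantiles. Transfers are fitted
on 1981–2005 ("historical simulation" span); each member gets its own
transfer set because biases are model-specific. tmin and tmax are
corrected independently; the rare ordering violations this can produce
are repaired by swapping the pair and logged.

## Period deviations and rates

Projected onsets (1981–2100, per species × scenario × member × station)
are summarised as the signed difference between the 30-year period mean
and the 1981–2010 reference mean (negative = earlier). Each window must
contain ≥ 20 usable years per member; "not reached" years are excluded
and counted. Member deviations are averaged unweighted (six members),
then across stations; the "maximum modelled deviation" is the most
negative station-level member deviation in the period. Advancement
rates divide the period-mean advancement by the period-midpoint
separation from the reference midpoint — exactly 30, 60, 90 years for
the three periods — and scale to a decade; temperature sensitivity
divides by the midpoint of the projected warming range.

## Elevation gradient

The regression unit is the station: member deviations are averaged
per station first, and the station means are regressed on elevation by
OLS, with the slope in days per 100 m. Member scatter feeds only the
per-station min/mean/max summaries. A percentile bootstrap over
stations gives the slope interval; the steepening diagnostic flags a
scenario when all three period slopes are ≤ 0 and each later period's
slope is at least as negative as the previous one.

## Synthetic study region

The generator emulates the structure of a small alpine-to-lowland
network, not its weather: 46 stations spanning 55–1050 m a.s.l.
(endpoints pinned), latitudes 45.4–46.9°. Daily means are a sea-level
sinusoid (annual mean 12 °C, half-range 10 °C, minimum mid-January)
plus a constant −6.5 K/km lapse to station elevation plus AR(1) noise
(stationary sd 3 °C, coefficient 0.7); tmin/tmax sit ±4 °C (jittered)
around the mean; 5 % of days are missing. Observations are true-model
onsets plus rounded Gaussian noise (sd 4 days), 5 % of station-years
dropped. Ensembles add a linear warming trend (0.25 / 0.45 °C per
decade for the moderate/high scenario, centred on the 1995.5 reference
midpoint), a constant member bias drawn from N(0, 1.5²), member
variance inflation, and optionally a seasonal bias cycle or an
elevation-amplified warming rate. The generating onset parameters were
fixed once so that network-mean onsets land on the observed climatology
of the three phenophases (hazel ≈ DOY 51, dandelion ≈ 100, lilac ≈
120): (T_b, k, F*) = (0, 0, 1560), (2, 1, 4200), (4, 1, 5600).

Every output is a pure function of (config, seed); each product draws
from its own derived seed stream.

Not emulated: weather regimes and spells, spatial correlation between
stations, elevation-dependent seasonality, chilling physiology,
observer effects. Consequently, green pipeline tests demonstrate
internal correctness (the stages compose, invert biases, and recover
known signals at realistic noise), not predictive skill on real
networks.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at reduced
network size — typically 6–11 stations and, for the full
ensemble-to-deviation chain, one or two scenarios of 6 members over
1981–2100 — chosen so each stage still has its full structure (all
species, all periods, all members) while a complete run stays fast and
deterministic. Elevation-gradient recovery uses the full 46-station
network because the slope estimate needs the elevation spread.

Tolerances: statistics are compared with brute-force oracles to 1e-10;
QM self-correction is required to land within one quantile-class width;
the zero-warming null pipeline must stay within ±1 day of zero for all
species and periods; noisy calibration must reach held-out RMSE ≤ 1.5×
the injected noise. Degenerate inputs (constant series, zero rank
variance, < 2 pairs) raise a dedicated undefined-statistic signal
rather than returning NaN.

## Known limitations

* One national parameter set per species; regional heterogeneity is not
  modelled.
* No chilling requirement: under strong warming the model can only
  advance onsets, whereas real species with unmet chilling may stall.
* The diurnal cosine underestimates morning asymmetry of real
  temperature curves; GDH totals inherit that bias.
* QM is univariate per variable; inter-variable dependence survives
  only through the shared underlying series, and tmin/tmax ordering is
  enforced by repair rather than jointly corrected.
* The constant lapse-rate elevation adjustment ignores inversions and
  horizontal gradients.
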