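# phenospring

Climate-driven modelling and projection of spring plant phenology.

`phenospring` estimates and projects the onset of spring phenophases —
first flowering of common hazel catkins (*Corylus avellana*), dandelion
(*Taraxacum officinale*) and common lilac (*Syringa vulgaris*) — from
daily minimum/maximum air temperature over a station network spanning an
elevation gradient. It is aimed at agro- and forest-meteorologists who
want a tested, reproducible pipeline from station observations to
end-of-century scenario projections, without depending on any external
dataset: a built-in synthetic generator emulates the full study region.

## The model

Daily forcing is photoperiod-weighted growing degree hours (GDH). With a
symmetric cosine diurnal course between tmin and tmax,

    T(h) = (tmax+tmin)/2 − ((tmax−tmin)/2)·cos(πh/12),   h = 0..23
    GDH(d) = Σ_h max(0, T(h) − T_b)
    f(d)   = GDH(d) · (L(φ, d)/12)^k

where `T_b` is the species base temperature, `L(φ, d)` the daylength at
latitude φ from the cosine solar-declination approximation, and `k ≥ 0`
the photoperiod exponent (`k = 0` gives a pure thermal-time model). The
predicted onset is the first day of year `d*` with

    Σ_{d ≤ d*} f(d) ≥ F*,

`F*` being the species forcing threshold. `(T_b, k, F*)` are calibrated
per species by grid search minimising the RMSE against observed onset
days (in DOY, Jan 1 = 1).

Around the model the package provides:

* **Quantile-mapping bias correction** of projection ensembles: per
  station, variable and member, empirical transfer functions per
  calendar day (61-day moving window, 100 quantile classes, 1981–2005
  reference), with constant-shift extrapolation outside the calibrated
  range so long-term trends pass through.
* **Scenario period analysis**: onset deviations of the 30-year periods
  2011–2040, 2041–2070, 2071–2100 from the 1981–2010 reference mean,
  per ensemble member, with days-per-decade and days-per-°C rate
  conversions via period midpoints.
* **Elevation-gradient regression**: OLS of station-mean deviation on
  elevation (days per 100 m), with bootstrap intervals and a
  period-steepening diagnostic.
* **Evaluation statistics**: average-rank Spearman ρ with t-based
  significance, R² (squared Pearson correlation), RMSE, trailing 6-year
  moving averages, per-station and pooled reports.
* **Synthetic study region**: 46 stations at 55–1050 m a.s.l.,
  lapse-rate temperature climatology with AR(1) noise, observations
  from known true parameters, and biased warming ensembles (2 scenarios
  × 6 members, 1981–2100).

## Worked example

Calibrating on a synthetic 6-station network with 4-day observation
noise (`python examples/02_calibrate_and_evaluate.py`):

```
143 observations; generating params: t_base=2.0, f_star=4200, k_photo=1.0
calibrated: t_base=2.0, f_star=4188, k_photo=1.0; training RMSE 4.03 d (n=143)
5-fold held-out RMSE: 4.17 d
pooled: n=143 rho=0.94*** R2=0.93 RMSE=4.03 d delta_avr=0.77
```

The grid search recovers the generating base temperature and
photoperiod exponent exactly and a threshold within its identifiability
interval; the held-out RMSE of ≈4 days equals the injected observation
noise, i.e. the model explains everything except the irreducible error.
`examples/04_project_future_onsets.py` projects the calibrated model through
bias-corrected warming ensembles; e.g. dandelion under the high-forcing
scenario advances by 7.7 days (2011–2040), 15.7 days (2041–2070) and
23.5 days (2071–2100) relative to 1981–2010 on that small synthetic
network, with higher stations advancing more
(`examples/05_elevation_gradient.py`).

The same stages are scriptable from the shell:

```sh
phenospring simulate --seed 1 --outdir data/
phenospring calibrate --stations data/stations.csv --climate data/climate.csv \
    --phenology data/phenology.csv --outdir fits/
phenospring biascorrect --observed data/climate.csv \
    --ensemble data/ensemble_rcp85.csv --outdir corrected/
phenospring project --stations data/stations.csv \
    --ensemble corrected/ensemble_corrected.csv --params fits/ --outdir proj/
```

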