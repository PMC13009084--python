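"""Self-contained synthetic test bed for the whole pipeline.

Emulates a small alpine-to-lowland phenological network: 46 stations
spanning 55-1050 m a.s.l., a sea-level seasonal temperature cycle with a
constant vertical lapse rate and AR(1) day-to-day noise, phenological
observations produced by the onset model itself under known "true"
parameters plus observation noise, and warming projection ensembles
whose members carry constant biases and inflated variance so that
quantile mapping has real work to do.

Every output is a pure function of (config, seed): each generator draws
from its own seed stream derived from the config seed, so regenerating
any one product never perturbs the others.

What the generator does *not* emulate: weather regimes and fronts,
spatial correlation between stations, seasonal bias cycles (unless
``seasonal_member_bias_amp_degC`` is set), chilling physiology, or
observer-specific reporting habits. Pipeline results on this test bed
demonstrate internal correctness, not skill on real observations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climate_io import (
    DataError,
    DailyTemperatureSeries,
    PhenoObservation,
    StationRecord,
    write_climate,
    write_phenology,
    write_stations,
)
from .phenomodel import SpeciesModelParams, predict_onsets_multi

__all__ = [
    "SyntheticConfig",
    "default_true_params",
    "generate_network",
    "generate_observed_climate",
    "generate_observations",
    "generate_projection_ensemble",
    "generate_station_deviations",
    "write_fixture_set",
]

# seed-stream codes, one per generator product
_S_NETWORK, _S_CLIMATE, _S_OBS, _S_ENSEMBLE, _S_DEV = 1, 2, 3, 4, 5


def default_true_params() -> dict[str, SpeciesModelParams]:
    """Generating parameters whose network-mean onsets fall near the
    observed climatology of the three phenophases (hazel ~ DOY 51,
    dandelion ~ DOY 100, lilac ~ DOY 120)."""
    return {
        "hazel_catkins": SpeciesModelParams("hazel_catkins", t_base=0.0,
                                            f_star=1560.0, k_photo=0.0),
        "dandelion": SpeciesModelParams("dandelion", t_base=2.0,
                                        f_star=4200.0, k_photo=1.0),
        "lilac": SpeciesModelParams("lilac", t_base=4.0,
                                    f_star=5600.0, k_photo=1.0),
    }


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study region; defaults are the study
    conditions (46 stations, 55-1050 m, 1971-2020 observed, 1981-2100
    projected, two warming scenarios with six biased members each)."""

    n_stations: int = 46
    elevation_range_m: tuple[float, float] = (55.0, 1050.0)
    latitude_range_deg: tuple[float, float] = (45.4, 46.9)
    longitude_range_deg: tuple[float, float] = (13.4, 16.6)
    years_observed: tuple[int, int] = (1971, 2020)
    years_projection: tuple[int, int] = (1981, 2100)
    seasonal_mean_degC: float = 12.0      # sea-level annual mean
    seasonal_amp_degC: float = 10.0       # sea-level seasonal half-range
    lapse_rate_K_per_km: float = -6.5
    daily_noise_sd_degC: float = 3.0      # stationary sd of the AR(1) noise
    ar1_coefficient: float = 0.7
    diurnal_half_range_degC: float = 4.0
    warming_degC_per_decade: dict = field(
        default_factory=lambda: {"rcp45": 0.25, "rcp85": 0.45}
    )
    n_members: int = 6
    member_bias_spread_degC: float = 1.5
    member_variance_inflation_max: float = 0.3
    seasonal_member_bias_amp_degC: float = 0.0
    warming_elevation_amplification_per_km: float = 0.0
    true_params: dict = field(default_factory=default_true_params)
    obs_noise_sd_days: float = 4.0
    missing_rate: float = 0.05
    # direct deviation-level generator (elevation-gradient recovery)
    elevation_response_gradient_days_per_100m: float | None = None
    base_deviation_days: float = -5.0
    deviation_noise_sd_days: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise DataError("n_stations must be >= 2")
        for name in ("daily_noise_sd_degC", "obs_noise_sd_days",
                     "member_bias_spread_degC", "deviation_noise_sd_days"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise DataError("ar1_coefficient must lie in [0, 1)")
        lo, hi = self.elevation_range_m
        if not hi > lo:
            raise DataError("elevation range must have positive width")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise DataError("missing_rate must lie in [0, 1]")


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def generate_network(config: SyntheticConfig) -> list[StationRecord]:
    """Station network spanning the configured elevation range; the
    lowest and highest stations sit exactly at the range endpoints."""
    rng = _rng(config, _S_NETWORK)
    lo, hi = config.elevation_range_m
    elev = np.sort(rng.uniform(lo, hi, size=config.n_stations))
    elev[0], elev[-1] = lo, hi
    lat = rng.uniform(*config.latitude_range_deg, size=config.n_stations)
    lon = rng.uniform(*config.longitude_range_deg, size=config.n_stations)
    return [
        StationRecord(f"S{i:03d}", round(float(lat[i]), 4),
                      round(float(lon[i]), 4), round(float(elev[i]), 1))
        for i in range(config.n_stations)
    ]


def _seasonal_mean(config: SyntheticConfig, index: pd.DatetimeIndex,
                   elevation: float) -> np.ndarray:
    doy = index.dayofyear.to_numpy(float)
    year_len = np.where(index.is_leap_year, 366.0, 365.0)
    cycle = -np.cos(2.0 * np.pi * (doy - 15.0) / year_len)  # min mid-January
    return (config.seasonal_mean_degC
            + config.seasonal_amp_degC * cycle
            + config.lapse_rate_K_per_km * elevation / 1000.0)


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], innov)


def _make_series(config: SyntheticConfig, station: StationRecord,
                 index: pd.DatetimeIndex, rng: np.random.Generator,
                 extra: np.ndarray | float = 0.0,
                 noise_scale: float = 1.0,
                 missing_rate: float | None = None,
                 provenance: str = "observed",
                 scenario: str | None = None,
                 member: str | None = None) -> DailyTemperatureSeries:
    n = len(index)
    mean = _seasonal_mean(config, index, station.elevation) + extra
    mean = mean + noise_scale * _ar1(rng, n, config.daily_noise_sd_degC,
                                     config.ar1_coefficient)
    half = config.diurnal_half_range_degC + 0.8 * rng.standard_normal(n)
    np.clip(half, 0.5, None, out=half)
    df = pd.DataFrame({"tmin": mean - half, "tmax": mean + half}, index=index)
    rate = config.missing_rate if missing_rate is None else missing_rate
    if rate > 0:
        gaps = rng.random(n) < rate
        df.loc[gaps, ["tmin", "tmax"]] = np.nan
    return DailyTemperatureSeries(station.station_id, df, provenance=provenance,
                                  scenario=scenario, member=member)


def generate_observed_climate(
    config: SyntheticConfig, stations: list[StationRecord]
) -> dict[str, DailyTemperatureSeries]:
    """Observed-period daily Tmin/Tmax per station: seasonal sinusoid
    lapsed to station elevation, AR(1) noise, jittered diurnal range and
    injected missing days."""
    y0, y1 = config.years_observed
    index = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    out = {}
    for i, st in enumerate(stations):
        rng = _rng(config, _S_CLIMATE, i)
        out[st.station_id] = _make_series(config, st, index, rng)
    return out


def generate_observations(
    config: SyntheticConfig,
    stations: list[StationRecord],
    climate: dict[str, DailyTemperatureSeries],
) -> list[PhenoObservation]:
    """Phenological observations: true-model onsets plus rounded
    Gaussian noise, with station-years dropped at the missing rate."""
    obs: list[PhenoObservation] = []
    for i, st in enumerate(stations):
        series = climate[st.station_id]
        for j, (species, params) in enumerate(sorted(config.true_params.items())):
            rng = _rng(config, _S_OBS, i, j)
            onsets = predict_onsets_multi(series, st.latitude, params)
            for year in sorted(onsets):
                doy = onsets[year]
                if rng.random() < config.missing_rate:
                    continue
                if doy is None:
                    continue  # threshold never reached: no observation
                noisy = doy + round(rng.normal(0.0, config.obs_noise_sd_days)) \
                    if config.obs_noise_sd_days > 0 else doy
                obs.append(PhenoObservation(st.station_id, species, year,
                                            int(np.clip(noisy, 1, 365))))
    return obs


def generate_projection_ensemble(
    config: SyntheticConfig,
    stations: list[StationRecord],
    scenarios: list[str] | None = None,
) -> dict[str, dict[str, dict[str, DailyTemperatureSeries]]]:
    """Biased warming ensembles: scenario -> member -> station -> series.

    Each member is the observed-climate process plus a linear warming
    trend (centred on the 1981-2010 reference midpoint so the reference
    mean is unchanged), a constant member bias drawn once from
    N(0, member_bias_spread^2), member-specific variance inflation and,
    optionally, a seasonal bias cycle. With
    ``warming_elevation_amplification_per_km`` set, the warming rate
    grows linearly with station elevation.
    """
    scenarios = scenarios or list(config.warming_degC_per_decade)
    y0, y1 = config.years_projection
    index = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    yearfrac = index.year.to_numpy(float) + (index.dayofyear.to_numpy(float) - 0.5) \
        / np.where(index.is_leap_year, 366.0, 365.0)
    decades_since_ref = (yearfrac - 1995.5) / 10.0
    doy_phase = 2.0 * np.pi * index.dayofyear.to_numpy(float) / 365.25

    out: dict[str, dict[str, dict[str, DailyTemperatureSeries]]] = {}
    for s_idx, scenario in enumerate(scenarios):
        rate = config.warming_degC_per_decade[scenario]
        members: dict[str, dict[str, DailyTemperatureSeries]] = {}
        for m in range(config.n_members):
            mrng = _rng(config, _S_ENSEMBLE, s_idx, m)
            bias = mrng.normal(0.0, config.member_bias_spread_degC)
            inflation = 1.0 + config.member_variance_inflation_max * mrng.random()
            seas_amp = config.seasonal_member_bias_amp_degC
            seas_phase = mrng.uniform(0.0, 2.0 * np.pi)
            member_id = f"m{m + 1}"
            by_station: dict[str, DailyTemperatureSeries] = {}
            for i, st in enumerate(stations):
                amp = 1.0 + config.warming_elevation_amplification_per_km \
                    * st.elevation / 1000.0
                extra = rate * amp * decades_since_ref + bias
                if seas_amp:
                    extra = extra + seas_amp * np.sin(doy_phase + seas_phase)
                rng = _rng(config, _S_ENSEMBLE, s_idx, m, i)
                by_station[st.station_id] = _make_series(
                    config, st, index, rng, extra=extra, noise_scale=inflation,
                    missing_rate=0.0, provenance="ensemble",
                    scenario=scenario, member=member_id,
                )
            members[member_id] = by_station
        out[scenario] = members
    return out


def generate_station_deviations(
    config: SyntheticConfig, stations: list[StationRecord]
) -> pd.DataFrame:
    """Station/member period deviations with a built-in elevation
    gradient, for gradient-recovery exercises.

    dev(station, member) = base + gradient * elevation/100 + noise.
    Requires ``elevation_response_gradient_days_per_100m`` to be set.
    Returns columns station_id, member, deviation.
    """
    g = config.elevation_response_gradient_days_per_100m
    if g is None:
        raise DataError("elevation_response_gradient_days_per_100m is not set")
    rng = _rng(config, _S_DEV)
    rows = []
    for st in stations:
        for m in range(config.n_members):
            dev = (config.base_deviation_days + g * st.elevation / 100.0
                   + rng.normal(0.0, config.deviation_noise_sd_days))
            rows.append((st.station_id, f"m{m + 1}", dev))
    return pd.DataFrame(rows, columns=["station_id", "member", "deviation"])


def write_fixture_set(config: SyntheticConfig, outdir,
                      scenarios: list[str] | None = None,
                      include_ensemble: bool = True) -> dict[str, str]:
    """Emit the full CSV fixture set into ``outdir``; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stations = generate_network(config)
    climate = generate_observed_climate(config, stations)
    observations = generate_observations(config, stations, climate)

    paths = {}
    write_stations(stations, outdir / "stations.csv")
    paths["stations"] = str(outdir / "stations.csv")
    write_climate(list(climate.values()), outdir / "climate.csv")
    paths["climate"] = str(outdir / "climate.csv")
    write_phenology(observations, outdir / "phenology.csv")
    paths["phenology"] = str(outdir / "phenology.csv")
    if include_ensemble:
        ens = generate_projection_ensemble(config, stations, scenarios)
        for scenario, members in ens.items():
            series = [s for by_st in members.values() for s in by_st.values()]
            p = outdir / f"ensemble_{scenario}.csv"
            write_climate(series, p)
            paths[f"ensemble_{scenario}"] = str(p)
    return paths
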