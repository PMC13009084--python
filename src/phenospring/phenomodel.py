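"""Spring-onset model: photoperiod-weighted growing-degree-hour accumulation.

The model family follows the spring-index tradition: daily forcing is the
sum of hourly temperature exceedances over a species base temperature
(growing degree hours, GDH), weighted by relative daylength raised to a
photoperiod exponent,

    f(d) = GDH(d; t_base) * (daylength(lat, d) / 12)**k_photo

and the onset of a phenophase is the first day of year on which the
forcing accumulated from ``start_doy`` reaches the species threshold
``f_star``. With ``k_photo = 0`` the model reduces to a pure thermal-time
(degree-hour) model.

The diurnal course between tmin and tmax is a single symmetric cosine
(minimum at hour 0, maximum at hour 12), so that for ``t_base <= tmin``
the daily GDH equals exactly ``24 * ((tmin + tmax)/2 - t_base)``.

Calibration is a per-species grid search over ``(t_base, k_photo)`` with
an exact threshold scan for ``f_star`` (see :func:`calibrate_species`),
minimising the RMSE between predicted and observed onset days.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .climate_io import (
    DataError,
    DailyTemperatureSeries,
    PhenoObservation,
    StationRecord,
    year_frame,
)

__all__ = [
    "SpeciesModelParams",
    "OnsetPrediction",
    "CalibrationGrid",
    "CalibrationResult",
    "UnusableStationYear",
    "daylength",
    "diurnal_temperatures",
    "daily_gdh",
    "predict_onset",
    "predict_onsets_multi",
    "calibrate_species",
    "cross_validate",
]

log = logging.getLogger(__name__)

_HOURS = np.arange(24.0)
_COS_H = np.cos(np.pi * _HOURS / 12.0)  # diurnal shape, min at h=0


class UnusableStationYear(Exception):
    """Skip signal: station-year fails the spring data-coverage rule."""


@dataclass(frozen=True)
class SpeciesModelParams:
    """Calibrated onset-model parameters for one species.

    t_base   : base temperature (degC) below which no forcing accrues
    f_star   : forcing threshold (degC*h, daylength-weighted GDH units)
    k_photo  : photoperiod exponent (dimensionless, >= 0); 0 disables
               the daylength weighting
    start_doy: day of year accumulation starts (default Jan 1)
    """

    species: str
    t_base: float
    f_star: float
    k_photo: float = 0.0
    start_doy: int = 1

    def __post_init__(self) -> None:
        if self.f_star <= 0:
            raise DataError("f_star must be positive")
        if self.k_photo < 0:
            raise DataError("k_photo must be >= 0")
        if not 1 <= self.start_doy <= 366:
            raise DataError("start_doy outside [1, 366]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesModelParams":
        keys = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in keys})

    def save(self, path, provenance: dict | None = None) -> None:
        doc = self.to_dict()
        if provenance:
            doc["provenance"] = provenance
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SpeciesModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class OnsetPrediction:
    """Predicted onset for one station-year; ``predicted_doy`` is None
    when the forcing sum never reaches the threshold by Dec 31."""

    station_id: str
    species: str
    year: int
    predicted_doy: int | None
    cumulative_forcing_trace: np.ndarray | None = None

    @property
    def reached(self) -> bool:
        return self.predicted_doy is not None


def daylength(latitude_deg, doy, year_length: float = 365.0):
    """Hours of daylight from the cosine solar-declination approximation.

    delta = -23.44 deg * cos(2 pi (doy + 10) / year_length);
    the hour angle is clamped so polar day/night give 24 h / 0 h.
    Scalar or array ``doy`` accepted.
    """
    lat = np.deg2rad(latitude_deg)
    if not np.all(np.abs(latitude_deg) <= 90.0):
        raise DataError("latitude outside [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / year_length))
    cos_omega = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    out = 24.0 * np.arccos(cos_omega) / np.pi
    return float(out) if out.ndim == 0 else out


def diurnal_temperatures(tmin: float, tmax: float) -> np.ndarray:
    """24 hourly temperatures: symmetric cosine between tmin and tmax.

    T(h) = (tmax+tmin)/2 - ((tmax-tmin)/2) * cos(pi h / 12), h = 0..23;
    minimum at h=0, maximum at h=12, daily mean (tmin+tmax)/2.
    """
    if tmin > tmax:
        raise DataError(f"tmin {tmin} > tmax {tmax}")
    mean = 0.5 * (tmax + tmin)
    amp = 0.5 * (tmax - tmin)
    return mean - amp * _COS_H


def _gdh_array(tmin: np.ndarray, tmax: np.ndarray, t_base: float) -> np.ndarray:
    """Vectorised daily GDH for day arrays (no input validation)."""
    mean = 0.5 * (tmax + tmin)
    amp = 0.5 * (tmax - tmin)
    hourly = mean[:, None] - amp[:, None] * _COS_H[None, :]
    np.subtract(hourly, t_base, out=hourly)
    np.clip(hourly, 0.0, None, out=hourly)
    return hourly.sum(axis=1)


def daily_gdh(tmin, tmax, t_base: float):
    """Growing degree hours for one day (or arrays of days).

    Sum over the 24 hourly cosine-interpolated temperatures of
    ``max(0, T(h) - t_base)``. When ``t_base <= tmin`` this equals
    exactly ``24 * ((tmin + tmax)/2 - t_base)`` because the cosine sums
    to zero over a full period.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmin > tmax):
        raise DataError("tmin > tmax")
    out = _gdh_array(np.atleast_1d(tmin), np.atleast_1d(tmax), t_base)
    return float(out[0]) if tmin.ndim == 0 else out


def _forcing(tmin, tmax, dl, params: SpeciesModelParams) -> np.ndarray:
    f = _gdh_array(tmin, tmax, params.t_base)
    if params.k_photo != 0.0:
        f = f * (dl / 12.0) ** params.k_photo
    if params.start_doy > 1:
        f = f.copy()
        f[: params.start_doy - 1] = 0.0
    return f


def _first_crossing(cum: np.ndarray, f_star: float) -> int | None:
    idx = int(np.searchsorted(cum, f_star, side="left"))
    return idx + 1 if idx < len(cum) else None


def predict_onset(
    series: DailyTemperatureSeries,
    latitude_deg: float,
    params: SpeciesModelParams,
    year: int,
    keep_trace: bool = False,
) -> OnsetPrediction:
    """Predict the onset day of year for one station-year.

    Raises :class:`UnusableStationYear` when the spring window has too
    many missing days (remaining gaps are interpolated).
    """
    yf = year_frame(series, year)
    if yf is None:
        log.info("skip %s %s %s: unusable station-year", series.station_id,
                 params.species, year)
        raise UnusableStationYear(f"{series.station_id}/{year}")
    n = len(yf)
    dl = daylength(latitude_deg, np.arange(1, n + 1), year_length=float(n))
    f = _forcing(yf["tmin"].to_numpy(), yf["tmax"].to_numpy(), dl, params)
    cum = np.cumsum(f)
    doy = _first_crossing(cum, params.f_star)
    return OnsetPrediction(
        series.station_id, params.species, year, doy,
        cumulative_forcing_trace=cum if keep_trace else None,
    )


def predict_onsets_multi(
    series: DailyTemperatureSeries,
    latitude_deg: float,
    params: SpeciesModelParams,
    years: list[int] | None = None,
) -> dict[int, int | None]:
    """Onsets for many years of one series; unusable years are absent
    from the result, not-reached years map to None.

    Fast numpy path with the same semantics as calling
    :func:`predict_onset` year by year: the coverage rule applies per
    year and gaps are linearly interpolated within the year.
    """
    from .climate_io import MAX_MISSING_FRACTION

    df = series.data
    idx_year = df.index.year.to_numpy()
    idx_doy = df.index.dayofyear.to_numpy()
    tmin_all = df["tmin"].to_numpy()
    tmax_all = df["tmax"].to_numpy()
    targets = set(years) if years is not None else set(series.years())
    dl_cache: dict[int, np.ndarray] = {}
    out: dict[int, int | None] = {}
    for y in sorted(targets):
        sel = idx_year == y
        if not sel.any():
            continue
        n_days = 366 if pd.Timestamp(year=y, month=12, day=31).dayofyear == 366 else 365
        tmin = np.full(n_days, np.nan)
        tmax = np.full(n_days, np.nan)
        tmin[idx_doy[sel] - 1] = tmin_all[sel]
        tmax[idx_doy[sel] - 1] = tmax_all[sel]
        miss = np.isnan(tmin) | np.isnan(tmax)
        spring_len = 182 if n_days == 366 else 181  # Jan 1 - Jun 30
        if miss[:spring_len].mean() >= MAX_MISSING_FRACTION:
            log.info("skip %s %s %s: unusable station-year",
                     series.station_id, params.species, y)
            continue
        if miss.any():
            days = np.arange(n_days)
            for arr in (tmin, tmax):
                good = np.flatnonzero(~np.isnan(arr))
                arr[:] = np.interp(days, good, arr[good])
        if n_days not in dl_cache:
            dl_cache[n_days] = daylength(latitude_deg,
                                         np.arange(1, n_days + 1),
                                         float(n_days))
        f = _forcing(tmin, tmax, dl_cache[n_days], params)
        out[y] = _first_crossing(np.cumsum(f), params.f_star)
    return out


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationGrid:
    """Candidate parameter values for the per-species grid search."""

    t_base: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    k_photo: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    start_doy: int = 1
    max_candidates: int = 400


@dataclass
class CalibrationResult:
    params: SpeciesModelParams
    rmse_days: float
    spearman_rho: float | None
    p_value: float | None
    r_squared: float | None
    n: int
    n_skipped: int


@dataclass
class _Pair:
    station_id: str
    year: int
    obs_doy: int
    tmin: np.ndarray
    tmax: np.ndarray
    dl: np.ndarray
    year_length: int


def _collect_pairs(observations, climate, stations) -> tuple[list[_Pair], int]:
    lat = {s.station_id: s.latitude for s in stations}
    pairs, skipped = [], 0
    for obs in observations:
        series = climate.get(obs.station_id)
        if series is None:
            raise DataError(f"no climate series for station {obs.station_id!r}")
        yf = year_frame(series, obs.year)
        if yf is None:
            skipped += 1
            log.info("skip %s/%s: unusable station-year", obs.station_id, obs.year)
            continue
        n = len(yf)
        dl = daylength(lat[obs.station_id], np.arange(1, n + 1), float(n))
        pairs.append(
            _Pair(obs.station_id, obs.year, obs.onset_doy,
                  yf["tmin"].to_numpy(), yf["tmax"].to_numpy(), dl, n)
        )
    return pairs, skipped


def _scan_f_star(cums: list[np.ndarray], obs: np.ndarray,
                 max_candidates: int) -> tuple[float, float]:
    """Best threshold for fixed (t_base, k_photo): exact scan.

    The RMSE as a function of f_star is piecewise constant with
    breakpoints at cumulative-forcing values; scanning the accumulated
    forcing at each observed onset day visits every threshold that
    reproduces at least one observation exactly, then a local sweep over
    all breakpoints between the best candidate's neighbours makes the
    search exact in that region. Ties resolve to the smallest f_star.
    """
    cands = np.unique([c[min(o, len(c)) - 1] for c, o in zip(cums, obs)])
    cands = cands[cands > 0]
    if cands.size == 0:
        return np.inf, 1.0
    if cands.size > max_candidates:
        cands = cands[np.linspace(0, cands.size - 1, max_candidates).astype(int)]

    def sse(fs: np.ndarray) -> np.ndarray:
        total = np.zeros(fs.size)
        for c, o in zip(cums, obs):
            idx = np.searchsorted(c, fs, side="left")
            pred = np.where(idx < len(c), idx + 1, len(c))
            total += (pred - o) ** 2
        return total

    err = sse(cands)
    best = int(np.argmin(err))
    lo = cands[best - 1] if best > 0 else cands[best] * 0.9
    hi = cands[best + 1] if best < cands.size - 1 else cands[best] * 1.1
    # local exhaustive sweep over breakpoints in [lo, hi]
    local = []
    for c in cums:
        i0, i1 = np.searchsorted(c, [lo, hi])
        local.append(c[i0: i1 + 1])
    local = np.unique(np.concatenate(local + [cands[[best]]]))
    local = local[local > 0]
    if local.size > 2000:
        local = local[np.linspace(0, local.size - 1, 2000).astype(int)]
    lerr = sse(local)
    i = int(np.argmin(lerr))
    if lerr[i] < err[best]:
        return float(local[i]), float(lerr[i])
    return float(cands[best]), float(err[best])


def calibrate_species(
    observations: list[PhenoObservation],
    climate: dict[str, DailyTemperatureSeries],
    stations: list[StationRecord],
    search_grid: CalibrationGrid | None = None,
) -> CalibrationResult:
    """Grid-search calibration of one species' onset parameters.

    Minimises RMSE between predicted and observed onset DOY over all
    usable station-years; not-reached predictions are penalised as
    Dec 31. Deterministic tie-break: smallest k_photo, then smallest
    t_base, then smallest f_star.
    """
    grid = search_grid or CalibrationGrid()
    species = {o.species for o in observations}
    if len(species) != 1:
        raise DataError(f"calibrate_species needs one species, got {sorted(species)}")
    species = species.pop()
    pairs, skipped = _collect_pairs(observations, climate, stations)
    if not pairs:
        raise DataError("no usable (station, year) pairs for calibration")

    obs = np.array([p.obs_doy for p in pairs])
    best = None  # (sse, k, tb, fs)
    for tb in sorted(grid.t_base):
        gdh = [_gdh_array(p.tmin, p.tmax, tb) for p in pairs]
        for k in sorted(grid.k_photo):
            if k == 0.0:
                f = gdh
            else:
                f = [g * (p.dl / 12.0) ** k for g, p in zip(gdh, pairs)]
            if grid.start_doy > 1:
                f = [np.concatenate([np.zeros(grid.start_doy - 1),
                                     fi[grid.start_doy - 1:]]) for fi in f]
            cums = [np.cumsum(fi) for fi in f]
            fs, sse = _scan_f_star(cums, obs, grid.max_candidates)
            if not np.isfinite(sse):
                continue
            cand = (sse, k, tb, fs)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise DataError("calibration found no feasible threshold")
    sse, k, tb, fs = best
    params = SpeciesModelParams(species, t_base=tb, f_star=fs, k_photo=k,
                                start_doy=grid.start_doy)
    pred = _predict_pairs(pairs, params)
    return _fit_result(params, obs, pred, skipped)


def _predict_pairs(pairs: list[_Pair], params: SpeciesModelParams) -> np.ndarray:
    out = np.empty(len(pairs))
    for i, p in enumerate(pairs):
        cum = np.cumsum(_forcing(p.tmin, p.tmax, p.dl, params))
        doy = _first_crossing(cum, params.f_star)
        out[i] = doy if doy is not None else p.year_length
    return out


def _fit_result(params, obs, pred, skipped) -> CalibrationResult:
    rmse = evaluation.rmse(obs, pred)
    try:
        rho, p = evaluation.spearman(obs, pred)
        r2 = evaluation.r_squared(obs, pred)
    except evaluation.UndefinedStatisticError:
        rho = p = r2 = None
    return CalibrationResult(params, rmse, rho, p, r2, len(obs), skipped)


def cross_validate(
    observations: list[PhenoObservation],
    climate: dict[str, DailyTemperatureSeries],
    stations: list[StationRecord],
    search_grid: CalibrationGrid | None = None,
    n_folds: int = 5,
) -> list[CalibrationResult]:
    """Year-stratified k-fold cross-validation of the calibration.

    Years are assigned to folds round-robin in sorted order; each fold's
    report carries metrics of the fold-held-out predictions under
    parameters calibrated on the remaining years.
    """
    years = sorted({o.year for o in observations})
    if n_folds < 2:
        raise DataError("n_folds must be >= 2")
    if n_folds > len(years):
        raise DataError(f"n_folds {n_folds} exceeds number of years {len(years)}")
    fold_of = {y: i % n_folds for i, y in enumerate(years)}
    reports = []
    for fold in range(n_folds):
        train = [o for o in observations if fold_of[o.year] != fold]
        test = [o for o in observations if fold_of[o.year] == fold]
        if not train or not test:
            continue
        fit = calibrate_species(train, climate, stations, search_grid)
        pairs, skipped = _collect_pairs(test, climate, stations)
        if not pairs:
            continue
        obs = np.array([p.obs_doy for p in pairs])
        pred = _predict_pairs(pairs, fit.params)
        reports.append(_fit_result(fit.params, obs, pred, skipped))
    return reports
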