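"""Long-term trends, 30-year climate-period deviations and rate conversions.

Projected onsets are summarised over three 30-year climate periods
(2011-2040, 2041-2070, 2071-2100) as signed deviations from the
1981-2010 reference mean (negative = earlier = phenological
advancement). Deviations are computed per ensemble member and station,
then averaged unweighted across the 6 members and across stations; the
maximum modelled deviation is the most negative station-level member
deviation within the period. Period midpoints are separated from the
reference midpoint by exactly 30, 60 and 90 years, which converts a
period-mean advancement into a days-per-decade rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate_io import DataError, DailyTemperatureSeries, StationRecord
from .phenomodel import SpeciesModelParams, predict_onsets_multi

__all__ = [
    "PERIODS",
    "REFERENCE_SPAN",
    "PeriodDeviation",
    "linear_trend",
    "period_mean_deviation",
    "rate_per_decade",
    "temperature_sensitivity",
    "project_onsets",
    "period_deviations_table",
]

#: The three future climate periods, keyed by their printed label.
PERIODS: dict[str, tuple[int, int]] = {
    "2011-2040": (2011, 2040),
    "2041-2070": (2041, 2070),
    "2071-2100": (2071, 2100),
}

#: Reference window for deviations.
REFERENCE_SPAN = (1981, 2010)

#: Minimum usable years required in each window of a member series.
MIN_YEARS_PER_WINDOW = 20


@dataclass
class PeriodDeviation:
    """Deviation of one species/scenario/period from the reference mean.

    ``mean_deviation_days`` is signed (negative = earlier);
    ``max_deviation_days`` is the most negative station-level member
    deviation; ``rate_days_per_decade`` is the advancement rate implied
    by the period-midpoint separation (positive = advancing).
    """

    species: str
    scenario: str
    period: str
    station_id: str  # "network" for the station mean
    mean_deviation_days: float
    max_deviation_days: float
    rate_days_per_decade: float
    n_members: int
    n_stations: int


def _midpoint(span: tuple[int, int]) -> float:
    return 0.5 * (span[0] + span[1])


def linear_trend(series: pd.Series) -> tuple[float, float]:
    """OLS trend of an annual onset series in days per decade, with R^2.

    ``series`` is indexed by calendar year; missing years allowed but at
    least 10 non-missing values are required. The slope is signed
    (negative = advancing); R^2 is the squared correlation.
    """
    s = pd.Series(series, dtype=float).dropna()
    if len(s) < 10:
        raise DataError(f"linear_trend needs >= 10 years, got {len(s)}")
    res = stats.linregress(s.index.to_numpy(float), s.to_numpy())
    return float(res.slope * 10.0), float(res.rvalue ** 2)


def rate_per_decade(
    mean_advancement_days: float,
    period: str,
    reference: tuple[int, int] = REFERENCE_SPAN,
) -> float:
    """Convert a period-mean advancement into days per decade.

    Divides by the separation between the period midpoint and the
    reference midpoint (exactly 30, 60, 90 years for the three standard
    periods) and scales to a decade.
    """
    if period not in PERIODS:
        raise DataError(f"unknown period {period!r}; expected one of {list(PERIODS)}")
    sep = _midpoint(PERIODS[period]) - _midpoint(reference)
    return mean_advancement_days / sep * 10.0


def temperature_sensitivity(
    advancement_days: float, warming_range_degC: tuple[float, float]
) -> float:
    """Days of advancement per degree of warming (2 d.p.).

    The warming is taken at the midpoint of the projected range.
    """
    lo, hi = warming_range_degC
    if lo > hi:
        raise DataError("warming range must satisfy low <= high")
    mid = 0.5 * (lo + hi)
    if mid <= 0:
        raise DataError("warming midpoint must be positive")
    return round(advancement_days / mid, 2)


def project_onsets(
    corrected_ensembles: dict[str, dict[str, dict[str, DailyTemperatureSeries]]],
    params_by_species: dict[str, SpeciesModelParams],
    stations: list[StationRecord],
) -> pd.DataFrame:
    """Run the onset model over every scenario/member/station/year.

    ``corrected_ensembles`` maps scenario -> member -> station_id ->
    series (bias-corrected, 1981-2100). Returns a long DataFrame with
    columns species, scenario, member, station_id, year, onset_doy
    (NaN where the threshold is not reached; unusable station-years are
    absent).
    """
    lat = {s.station_id: s.latitude for s in stations}
    rows = []
    for scenario, members in corrected_ensembles.items():
        for member, by_station in members.items():
            for sid, series in by_station.items():
                for species, params in params_by_species.items():
                    onsets = predict_onsets_multi(series, lat[sid], params)
                    for year, doy in onsets.items():
                        rows.append((species, scenario, member, sid, year,
                                     np.nan if doy is None else float(doy)))
    df = pd.DataFrame(rows, columns=["species", "scenario", "member",
                                     "station_id", "year", "onset_doy"])
    if df.empty:
        raise DataError("projection produced no onsets")
    return df


def period_mean_deviation(
    projections: pd.DataFrame,
    species: str,
    scenario: str,
    period: str,
    reference: tuple[int, int] = REFERENCE_SPAN,
) -> PeriodDeviation:
    """Network deviation of one species/scenario/period from the reference.

    Per (station, member): mean onset in the period minus mean onset in
    the reference window, each window requiring at least 20 usable years
    (not-reached years are excluded). Member deviations are averaged
    unweighted per station, then across stations.
    """
    if period not in PERIODS:
        raise DataError(f"unknown period {period!r}")
    sub = projections[(projections["species"] == species)
                      & (projections["scenario"] == scenario)]
    if sub.empty:
        raise DataError(f"no projections for ({species}, {scenario})")
    devs = _member_station_deviations(sub, PERIODS[period], reference)
    if devs.empty:
        raise DataError(
            f"no (station, member) with >= {MIN_YEARS_PER_WINDOW} usable years "
            f"in both windows for ({species}, {scenario}, {period})"
        )
    station_means = devs.groupby("station_id")["deviation"].mean()
    mean_dev = float(station_means.mean())
    return PeriodDeviation(
        species=species, scenario=scenario, period=period,
        station_id="network",
        mean_deviation_days=mean_dev,
        max_deviation_days=float(devs["deviation"].min()),
        rate_days_per_decade=rate_per_decade(-mean_dev, period, reference),
        n_members=int(devs["member"].nunique()),
        n_stations=int(devs["station_id"].nunique()),
    )


def _member_station_deviations(sub: pd.DataFrame, period: tuple[int, int],
                               reference: tuple[int, int]) -> pd.DataFrame:
    rows = []
    for (sid, member), grp in sub.groupby(["station_id", "member"], sort=True):
        s = grp.set_index("year")["onset_doy"].dropna()
        per = s[(s.index >= period[0]) & (s.index <= period[1])]
        ref = s[(s.index >= reference[0]) & (s.index <= reference[1])]
        if len(per) < MIN_YEARS_PER_WINDOW or len(ref) < MIN_YEARS_PER_WINDOW:
            continue
        rows.append((sid, member, float(per.mean() - ref.mean())))
    return pd.DataFrame(rows, columns=["station_id", "member", "deviation"])


def period_deviations_table(
    projections: pd.DataFrame,
    reference: tuple[int, int] = REFERENCE_SPAN,
    per_station: bool = False,
) -> pd.DataFrame:
    """All species/scenario/period deviations as a tidy table.

    With ``per_station`` the table carries one row per station (members
    averaged) in addition to the network rows.
    """
    rows = []
    for (species, scenario), _ in projections.groupby(["species", "scenario"],
                                                      sort=True):
        for period in PERIODS:
            dev = period_mean_deviation(projections, species, scenario,
                                        period, reference)
            rows.append({
                "species": species, "scenario": scenario, "period": period,
                "station_id": "network",
                "mean_dev": dev.mean_deviation_days,
                "max_dev": dev.max_deviation_days,
                "rate_per_decade": dev.rate_days_per_decade,
            })
            if per_station:
                sub = projections[(projections["species"] == species)
                                  & (projections["scenario"] == scenario)]
                devs = _member_station_deviations(sub, PERIODS[period], reference)
                for sid, grp in devs.groupby("station_id", sort=True):
                    mean_dev = float(grp["deviation"].mean())
                    rows.append({
                        "species": species, "scenario": scenario,
                        "period": period, "station_id": sid,
                        "mean_dev": mean_dev,
                        "max_dev": float(grp["deviation"].min()),
                        "rate_per_decade": rate_per_decade(-mean_dev, period,
                                                           reference),
                    })
    return pd.DataFrame(rows)
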