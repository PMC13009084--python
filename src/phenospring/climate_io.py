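"""Station metadata, daily temperature series and phenological observations.

Plain-text CSV formats (comma separated, dot decimal, UTF-8):

* ``stations.csv``  — ``station_id,latitude,longitude,elevation``
* ``climate.csv``   — ``station_id,date,tmin,tmax[,scenario,member]``
* ``phenology.csv`` — ``station_id,species,year,onset_doy``

Missing numeric values are encoded as empty fields and kept as explicit
NaN flags in memory; a date that should exist but has no row is also a
flagged gap (series are re-indexed to a gap-free daily calendar).

Grid or reanalysis temperatures are brought to station elevation with a
constant vertical lapse rate (default -6.5 K/km); horizontal
interpolation is out of scope.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES",
    "DataError",
    "StationRecord",
    "DailyTemperatureSeries",
    "PhenoObservation",
    "read_stations",
    "write_stations",
    "read_daily_temperature",
    "read_climate_table",
    "write_climate",
    "read_phenology",
    "write_phenology",
    "adjust_to_station_elevation",
    "year_frame",
    "usable_years",
]

#: Species handled by the pipeline, ordered by typical onset (earliest first).
SPECIES = ("hazel_catkins", "dandelion", "lilac")

#: Default vertical temperature lapse rate, K per km of elevation gain.
DEFAULT_LAPSE_RATE = -6.5

#: A station-year is usable for onset prediction when less than this
#: fraction of days in the Jan 1 - Jun 30 window is missing; the remaining
#: gaps are filled by linear interpolation in time.
MAX_MISSING_FRACTION = 0.10


class DataError(ValueError):
    """Raised when an input file or record violates a format invariant."""


@dataclass(frozen=True)
class StationRecord:
    """Identity, coordinates and elevation of one phenological station."""

    station_id: str
    latitude: float
    longitude: float
    elevation: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise DataError(
                f"station {self.station_id!r}: latitude {self.latitude} "
                "outside [-90, 90]"
            )
        if not math.isfinite(self.elevation):
            raise DataError(f"station {self.station_id!r}: non-finite elevation")


@dataclass(frozen=True)
class PhenoObservation:
    """One observed onset: (station, species, year, day-of-year).

    ``onset_doy`` is the 1-based calendar day of the year (Jan 1 = 1,
    Feb 29 = 60 in leap years).
    """

    station_id: str
    species: str
    year: int
    onset_doy: int

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise DataError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        if not 1 <= self.onset_doy <= 366:
            raise DataError(
                f"onset_doy {self.onset_doy} outside [1, 366] "
                f"({self.station_id}, {self.species}, {self.year})"
            )


@dataclass
class DailyTemperatureSeries:
    """Calendar-indexed daily Tmin/Tmax for one station.

    ``data`` is a DataFrame with a gap-free daily DatetimeIndex and
    columns ``tmin``/``tmax``; missing values are NaN (explicit flags).
    ``provenance`` is ``"observed"`` or ``"ensemble"``; ensemble series
    carry ``scenario`` and ``member``.
    """

    station_id: str
    data: pd.DataFrame
    provenance: str = "observed"
    scenario: str | None = None
    member: str | None = None

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise DataError("series index must be a DatetimeIndex")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise DataError(
                f"station {self.station_id!r}: duplicated date {dup.date()}"
            )
        if not df.index.is_monotonic_increasing:
            df = df.sort_index()
        # re-index to a gap-free daily calendar: absent rows become flagged NaN
        full = pd.date_range(df.index[0], df.index[-1], freq="D")
        if len(full) != len(df):
            df = df.reindex(full)
        df = df[["tmin", "tmax"]].astype(float)
        bad = df["tmin"] > df["tmax"]
        if bad.any():
            dates = ", ".join(d.date().isoformat() for d in df.index[bad][:5])
            raise DataError(
                f"station {self.station_id!r}: tmin > tmax on {int(bad.sum())} "
                f"date(s): {dates}"
            )
        self.data = df

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def tmin(self) -> np.ndarray:
        return self.data["tmin"].to_numpy()

    @property
    def tmax(self) -> np.ndarray:
        return self.data["tmax"].to_numpy()

    def n_missing(self) -> int:
        return int(self.data.isna().any(axis=1).sum())

    def years(self) -> list[int]:
        return sorted(set(self.data.index.year))


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise DataError(f"{path}: non-numeric {col!r} at row {row}")
    return out


def read_stations(path) -> list[StationRecord]:
    """Read ``stations.csv`` into a list of validated StationRecord."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, ("station_id", "latitude", "longitude", "elevation"), path)
    dup = df["station_id"][df["station_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate station_id {dup.iloc[0]!r}")
    for col in ("latitude", "longitude", "elevation"):
        df[col] = _numeric(df, col, path)
    if df[["latitude", "longitude", "elevation"]].isna().any().any():
        raise DataError(f"{path}: missing coordinate or elevation value")
    return [
        StationRecord(r.station_id, r.latitude, r.longitude, r.elevation)
        for r in df.itertuples(index=False)
    ]


def write_stations(stations: list[StationRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in stations]).to_csv(path, index=False)


def _parse_climate_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        bad = df["date"][dates.isna()].iloc[0]
        raise DataError(f"{path}: invalid calendar date {bad!r}")
    out = df.copy()
    out["date"] = dates
    out["tmin"] = _numeric(df, "tmin", path)
    out["tmax"] = _numeric(df, "tmax", path)
    return out


def read_daily_temperature(path, station_id: str | None = None) -> DailyTemperatureSeries:
    """Read one station's daily series from ``climate.csv``.

    The file may contain several stations; ``station_id`` selects one
    (mandatory in that case). Rows violating tmin <= tmax or duplicating
    a date raise :class:`DataError`.
    """
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, ("station_id", "date", "tmin", "tmax"), path)
    ids = df["station_id"].unique()
    if station_id is None:
        if len(ids) > 1:
            raise DataError(
                f"{path}: {len(ids)} stations present; pass station_id"
            )
    else:
        df = df[df["station_id"] == station_id]
        if df.empty:
            raise DataError(f"{path}: no rows for station {station_id!r}")
    df = _parse_climate_frame(df, path)
    sid = df["station_id"].iloc[0]
    return DailyTemperatureSeries(sid, df.set_index("date")[["tmin", "tmax"]])


def read_climate_table(path) -> dict[str, DailyTemperatureSeries]:
    """Read a multi-station ``climate.csv`` into per-station series."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, ("station_id", "date", "tmin", "tmax"), path)
    df = _parse_climate_frame(df, path)
    out = {}
    for sid, sub in df.groupby("station_id", sort=True):
        out[sid] = DailyTemperatureSeries(
            sid, sub.set_index("date")[["tmin", "tmax"]]
        )
    return out


def write_climate(series: DailyTemperatureSeries | list[DailyTemperatureSeries], path) -> None:
    """Write one or more series to ``climate.csv`` (ensemble columns added
    when any series carries scenario/member provenance)."""
    if isinstance(series, DailyTemperatureSeries):
        series = [series]
    frames = []
    with_prov = any(s.scenario is not None for s in series)
    for s in series:
        df = s.data.reset_index(names="date")
        df.insert(0, "station_id", s.station_id)
        df["date"] = df["date"].dt.strftime("%Y-%m-%d")
        if with_prov:
            df["scenario"] = s.scenario or ""
            df["member"] = s.member or ""
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.3f")


def read_phenology(path) -> list[PhenoObservation]:
    df = pd.read_csv(path, dtype={"station_id": str, "species": str})
    _require_columns(df, ("station_id", "species", "year", "onset_doy"), path)
    dup = df.duplicated(subset=["station_id", "species", "year"])
    if dup.any():
        r = df[dup].iloc[0]
        raise DataError(
            f"{path}: duplicate observation ({r.station_id}, {r.species}, {r.year})"
        )
    return [
        PhenoObservation(r.station_id, r.species, int(r.year), int(r.onset_doy))
        for r in df.itertuples(index=False)
    ]


def write_phenology(observations: list[PhenoObservation], path) -> None:
    pd.DataFrame([dataclasses.asdict(o) for o in observations]).to_csv(path, index=False)


def adjust_to_station_elevation(
    series: DailyTemperatureSeries,
    source_elevation_m: float,
    target_elevation_m: float,
    lapse_rate_K_per_km: float = DEFAULT_LAPSE_RATE,
) -> DailyTemperatureSeries:
    """Shift a series from a source to a target elevation.

    Applies ``delta = lapse_rate * (target - source) / 1000`` to both tmin
    and tmax; with the default negative lapse rate a higher target is
    colder. Linear in the elevation difference, so two adjustments
    compose additively and the operation is exactly invertible.
    """
    for e in (source_elevation_m, target_elevation_m):
        if not math.isfinite(e):
            raise DataError("elevations must be finite")
    delta = lapse_rate_K_per_km * (target_elevation_m - source_elevation_m) / 1000.0
    return DailyTemperatureSeries(
        series.station_id,
        series.data + delta,
        provenance=series.provenance,
        scenario=series.scenario,
        member=series.member,
    )


def year_frame(
    series: DailyTemperatureSeries,
    year: int,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> pd.DataFrame | None:
    """Extract one calendar year, gap-filled, or None if unusable.

    A station-year is usable when less than ``max_missing_fraction`` of
    the days in the Jan 1 - Jun 30 window are missing. Remaining gaps
    anywhere in the year are filled by linear interpolation in time
    (nearest-value extension at the year edges).
    """
    df = series.data
    sub = df[df.index.year == year]
    full = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    sub = sub.reindex(full)
    spring = sub.loc[: f"{year}-06-30"]
    frac = spring.isna().any(axis=1).mean()
    if frac >= max_missing_fraction:
        return None
    if sub.isna().any().any():
        sub = sub.interpolate(method="time", limit_direction="both")
    return sub


def usable_years(series: DailyTemperatureSeries) -> list[int]:
    """Years of the series passing the spring-coverage rule."""
    out = []
    for y in series.years():
        sub = series.data[series.data.index.year == y]
        full = pd.date_range(f"{y}-01-01", f"{y}-06-30", freq="D")
        frac = sub.reindex(full).isna().any(axis=1).mean()
        if frac < MAX_MISSING_FRACTION:
            out.append(y)
    return out
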