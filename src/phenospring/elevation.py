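"""Elevation dependence of projected phenological advancement.

For each species, scenario and climate period, the station-level mean
deviations (members averaged first) are regressed on station elevation
by ordinary least squares; the slope is reported in days per 100 m.
A negative slope means higher stations advance more. Member-level
scatter feeds only the per-station min/mean/max summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .climate_io import DataError, StationRecord

__all__ = [
    "ElevationGradientFit",
    "fit_elevation_gradient",
    "gradient_progression",
    "bootstrap_slope_ci",
]


@dataclass
class ElevationGradientFit:
    species: str
    scenario: str
    period: str
    slope_days_per_100m: float
    intercept_days: float
    r_squared: float
    n_stations: int
    #: per-station (elevation, min, mean, max) deviation across members
    station_summary: pd.DataFrame = field(repr=False, default=None)


def fit_elevation_gradient(
    station_deviations: pd.DataFrame,
    stations: list[StationRecord],
    species: str = "",
    scenario: str = "",
    period: str = "",
) -> ElevationGradientFit:
    """OLS fit of station mean deviation against elevation.

    ``station_deviations`` has columns ``station_id``, ``deviation`` and
    optionally ``member``; deviations are averaged per station before
    the fit. At least 3 stations and non-degenerate elevation spread are
    required.
    """
    elev = {s.station_id: s.elevation for s in stations}
    g = station_deviations.groupby("station_id")["deviation"]
    summary = g.agg(["min", "mean", "max"]).reset_index()
    summary["elevation"] = summary["station_id"].map(elev)
    if summary["elevation"].isna().any():
        missing = summary.loc[summary["elevation"].isna(), "station_id"].iloc[0]
        raise DataError(f"no station record for {missing!r}")
    if len(summary) < 3:
        raise DataError(f"need >= 3 stations, got {len(summary)}")
    x = summary["elevation"].to_numpy()
    y = summary["mean"].to_numpy()
    if np.ptp(x) == 0:
        raise DataError("zero elevation variance")
    res = stats.linregress(x, y)
    return ElevationGradientFit(
        species=species, scenario=scenario, period=period,
        slope_days_per_100m=float(res.slope * 100.0),
        intercept_days=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_stations=len(summary),
        station_summary=summary,
    )


def gradient_progression(fits: dict[str, ElevationGradientFit],
                         periods: tuple[str, ...] = ("2011-2040", "2041-2070",
                                                     "2071-2100")) -> dict:
    """Ordered slopes across the three periods with a steepening flag.

    ``steepening`` is True when all slopes are <= 0 and each later
    period's slope is at least as negative as the previous one.
    """
    missing = [p for p in periods if p not in fits]
    if missing:
        raise DataError(f"missing period fit(s): {missing}")
    slopes = [fits[p].slope_days_per_100m for p in periods]
    steepening = all(s <= 0 for s in slopes) and all(
        b <= a for a, b in zip(slopes, slopes[1:])
    )
    return {"periods": list(periods), "slopes": slopes, "steepening": steepening}


def bootstrap_slope_ci(
    station_deviations: pd.DataFrame,
    stations: list[StationRecord],
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the elevation slope (days / 100 m).

    Stations are resampled with replacement; degenerate resamples (all
    one elevation) are redrawn implicitly by yielding NaN and being
    dropped.
    """
    rng = rng or np.random.default_rng()
    elev = {s.station_id: s.elevation for s in stations}
    means = station_deviations.groupby("station_id")["deviation"].mean()
    x = means.index.map(elev).to_numpy(float)
    y = means.to_numpy()
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    var = (xc ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = (xc * yb).sum(axis=1) / var * 100.0
    slopes = slopes[np.isfinite(slopes)]
    lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
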