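"""Agreement statistics between observed and modelled onset days.

Conventions:

* Spearman's rho uses average ranks; its p-value comes from the
  t-approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees
  of freedom.
* R^2 is the squared Pearson correlation of observed and simulated
  values (not 1 - SSE/SST), so it is invariant to affine maps of the
  simulation.
* The moving average is trailing with a coverage rule: a window value is
  reported only when at least 4 of the 6 years are non-missing.
* The network-average correlation (delta_avr) is the unweighted mean of
  per-station Spearman coefficients over stations with >= 5 pairs; the
  pooled coefficient over all pairs is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate_io import DataError, PhenoObservation

__all__ = [
    "UndefinedStatisticError",
    "FitReport",
    "spearman",
    "rmse",
    "r_squared",
    "moving_average",
    "significance_stars",
    "evaluate",
    "EvaluationResult",
]

#: Minimum pairs for a station to enter the delta_avr station mean.
MIN_PAIRS_FOR_STATION_RHO = 5


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given data (n too small or zero
    variance)."""


@dataclass
class FitReport:
    """Agreement metrics for one scope (a station, or the pooled set)."""

    species: str
    scope: str  # station_id or "pooled"
    n: int
    spearman_rho: float | None
    p_value: float | None
    r_squared: float | None
    rmse_days: float
    stars: str = ""
    delta_avr: float | None = None  # pooled rows only: station-mean rho


def _as_arrays(obs, sim, min_n: int):
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise DataError(f"length mismatch: {obs.shape} vs {sim.shape}")
    if obs.size < min_n:
        raise UndefinedStatisticError(f"need at least {min_n} pairs, got {obs.size}")
    return obs, sim


def spearman(obs, sim) -> tuple[float, float]:
    """Average-rank Spearman correlation with t-approximation p-value."""
    obs, sim = _as_arrays(obs, sim, 2)
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        raise UndefinedStatisticError("zero rank variance")
    res = stats.spearmanr(obs, sim)
    return float(res.statistic), float(res.pvalue)


def rmse(obs, sim) -> float:
    """Root mean square error, in days when inputs are onset DOY."""
    obs, sim = _as_arrays(obs, sim, 1)
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def r_squared(obs, sim) -> float:
    """Squared Pearson correlation between observed and simulated values."""
    obs, sim = _as_arrays(obs, sim, 2)
    if np.ptp(obs) == 0 or np.ptp(sim) == 0:
        raise UndefinedStatisticError("zero variance")
    r = np.corrcoef(obs, sim)[0, 1]
    return float(r * r)


def moving_average(annual_series: pd.Series, window: int = 6,
                   min_coverage: int = 4) -> pd.Series:
    """Trailing moving average of a year-indexed series with gaps.

    The index is completed to consecutive years; a window mean is
    reported only where at least ``min_coverage`` of the ``window``
    years are non-missing, else NaN.
    """
    if window < 1:
        raise DataError("window must be >= 1")
    s = pd.Series(annual_series, dtype=float)
    s.index = s.index.astype(int)
    s = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
    return s.rolling(window, min_periods=min(min_coverage, window)).mean()


def significance_stars(p_value: float | None) -> str:
    if p_value is None or not np.isfinite(p_value):
        return ""
    for thr, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p_value < thr:
            return mark
    return ""


@dataclass
class EvaluationResult:
    reports: list[FitReport]

    def pooled(self, species: str) -> FitReport:
        for r in self.reports:
            if r.species == species and r.scope == "pooled":
                return r
        raise KeyError(species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": r.species, "scope": r.scope, "n": r.n,
                    "rho": r.spearman_rho, "p": r.p_value, "stars": r.stars,
                    "r2": r.r_squared, "rmse": r.rmse_days,
                    "delta_avr": r.delta_avr,
                }
                for r in self.reports
            ]
        )


def evaluate(
    observations: list[PhenoObservation],
    predictions: dict[tuple[str, str, int], float],
    grouping: str = "station",
) -> EvaluationResult:
    """Per-station and pooled agreement between observations and
    predictions matched on (station, species, year).

    ``predictions`` maps (station_id, species, year) to predicted DOY.
    For each species, one report per station with matched pairs (rho
    requires n >= 2 and rank variance) plus a pooled report; the pooled
    report carries delta_avr, the unweighted mean of per-station rho
    over stations with at least 5 pairs.
    """
    rows = [
        (o.station_id, o.species, o.year, o.onset_doy,
         predictions[(o.station_id, o.species, o.year)])
        for o in observations
        if (o.station_id, o.species, o.year) in predictions
    ]
    if not rows:
        raise DataError("no matched (station, species, year) pairs")
    df = pd.DataFrame(rows, columns=["station_id", "species", "year", "obs", "sim"])

    reports: list[FitReport] = []
    for species, sub in df.groupby("species", sort=True):
        station_rhos = []
        for sid, ss in sub.groupby("station_id", sort=True):
            rep = _report(species, str(sid), ss["obs"].to_numpy(),
                          ss["sim"].to_numpy())
            reports.append(rep)
            if rep.n >= MIN_PAIRS_FOR_STATION_RHO and rep.spearman_rho is not None:
                station_rhos.append(rep.spearman_rho)
        pooled = _report(species, "pooled", sub["obs"].to_numpy(),
                         sub["sim"].to_numpy())
        pooled.delta_avr = float(np.mean(station_rhos)) if station_rhos else None
        reports.append(pooled)
    return EvaluationResult(reports)


def _report(species: str, scope: str, obs: np.ndarray, sim: np.ndarray) -> FitReport:
    try:
        rho, p = spearman(obs, sim)
        r2 = r_squared(obs, sim)
    except UndefinedStatisticError:
        rho = p = r2 = None
    return FitReport(
        species=species, scope=scope, n=len(obs),
        spearman_rho=rho, p_value=p, r_squared=r2,
        rmse_days=rmse(obs, sim), stars=significance_stars(p),
    )
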