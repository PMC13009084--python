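"""Empirical quantile mapping of ensemble temperatures to observations.

Per station, variable (tmin/tmax) and ensemble member, a transfer
function is fitted for every calendar day from the reference years
(default 1981-2005): all values within a moving 61-day window centred on
the day (wrapping across the year boundary) are pooled, and 100
empirical quantiles at centred probabilities (j - 0.5)/100 are computed
for both the model and the observed pool by linear interpolation of
order statistics. Correcting a value maps it through its model quantile
onto the observed quantile curve; outside the calibrated range the
constant correction of the nearest extreme class applies, so a pure
additive bias is removed exactly and long-term trends pass through.

Leap handling: calendar days are numbered 1..365 on the common-year
calendar; Feb 29 values join the Mar 1 (day 60) pool and Feb 29 itself
is corrected with the Mar 1 transfer.

tmin and tmax are corrected independently; the rare ordering violations
this can create are repaired by swapping the pair and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_io import DataError, DailyTemperatureSeries

__all__ = [
    "QMTransfer",
    "fit_qm",
    "apply_qm",
    "qm_diagnostics",
    "calendar_day",
    "transfers_to_frame",
    "transfers_from_frame",
]

log = logging.getLogger(__name__)

N_CAL_DAYS = 365
VARIABLES = ("tmin", "tmax")


def calendar_day(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map dates to common-year calendar days 1..365 (Feb 29 -> 60)."""
    doy = dates.dayofyear.to_numpy()
    leap = dates.is_leap_year
    return doy - (leap & (doy > 60)).astype(int)


@dataclass
class QMTransfer:
    """Quantile-mapping transfer for one (station, variable, member).

    ``model_quantiles`` and ``observed_quantiles`` are (365, n_classes)
    arrays; row c-1 holds the calendar-day-c quantiles at centred
    probabilities (j - 0.5)/n_classes.
    """

    station_id: str
    variable: str
    member: str | None
    model_quantiles: np.ndarray
    observed_quantiles: np.ndarray
    reference_span: tuple[int, int] = (1981, 2005)

    def __post_init__(self) -> None:
        for name in ("model_quantiles", "observed_quantiles"):
            q = getattr(self, name)
            if q.shape[0] != N_CAL_DAYS:
                raise DataError(f"{name}: expected {N_CAL_DAYS} calendar days")
            if np.any(np.diff(q, axis=1) < -1e-9):
                raise DataError(f"{name}: quantiles not non-decreasing")

    @property
    def n_classes(self) -> int:
        return self.model_quantiles.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        n = self.n_classes
        return (np.arange(1, n + 1) - 0.5) / n


def _window_pools(values: np.ndarray, cal: np.ndarray, window_days: int):
    """Yield for each calendar day c (1..365) the pooled values within
    +/- half-window of c, wrapping across Dec 31 / Jan 1."""
    half = window_days // 2
    by_day = [values[cal == c] for c in range(1, N_CAL_DAYS + 1)]
    for c in range(N_CAL_DAYS):
        idx = (np.arange(c - half, c + half + 1)) % N_CAL_DAYS
        yield np.concatenate([by_day[i] for i in idx])


def fit_qm(
    model_hist: DailyTemperatureSeries,
    observed: DailyTemperatureSeries,
    window_days: int = 61,
    n_classes: int = 100,
    reference_span: tuple[int, int] = (1981, 2005),
) -> dict[str, QMTransfer]:
    """Fit per-calendar-day transfer functions, one per variable.

    Both series must cover the reference span; the window length must be
    odd. Returns ``{"tmin": QMTransfer, "tmax": QMTransfer}``.
    """
    if window_days % 2 == 0:
        raise DataError("window_days must be odd")
    y0, y1 = reference_span
    probs = (np.arange(1, n_classes + 1) - 0.5) / n_classes
    out: dict[str, QMTransfer] = {}
    for var in VARIABLES:
        qs = []
        for series in (model_hist, observed):
            df = series.data
            mask = (df.index.year >= y0) & (df.index.year <= y1)
            sub = df.loc[mask, var].dropna()
            if sub.empty:
                raise DataError(
                    f"{series.station_id}/{var}: no data in reference span {reference_span}"
                )
            cal = calendar_day(sub.index)
            vals = sub.to_numpy()
            q = np.empty((N_CAL_DAYS, n_classes))
            for c, pool in enumerate(_window_pools(vals, cal, window_days)):
                if pool.size < n_classes:
                    raise DataError(
                        f"{series.station_id}/{var}: only {pool.size} values in "
                        f"window of calendar day {c + 1}; reference too short"
                    )
                q[c] = np.quantile(pool, probs)
            qs.append(q)
        out[var] = QMTransfer(
            station_id=model_hist.station_id, variable=var,
            member=model_hist.member, model_quantiles=qs[0],
            observed_quantiles=qs[1], reference_span=reference_span,
        )
    return out


def _correct_values(values: np.ndarray, cal: np.ndarray, tr: QMTransfer) -> np.ndarray:
    probs = tr.probabilities
    out = np.full_like(values, np.nan, dtype=float)
    for c in np.unique(cal[~np.isnan(values)]):
        mq = tr.model_quantiles[c - 1]
        oq = tr.observed_quantiles[c - 1]
        sel = (cal == c) & ~np.isnan(values)
        v = values[sel]
        corr = np.interp(np.interp(v, mq, probs), probs, oq)
        # constant-shift extrapolation beyond the calibrated range
        low, high = v < mq[0], v > mq[-1]
        corr[low] = v[low] + (oq[0] - mq[0])
        corr[high] = v[high] + (oq[-1] - mq[-1])
        out[sel] = corr
    return out


def apply_qm(
    transfers: dict[str, QMTransfer],
    series: DailyTemperatureSeries,
) -> DailyTemperatureSeries:
    """Bias-correct a series with fitted transfers (one per variable).

    Missing transfers raise; post-correction tmin > tmax pairs are
    repaired by swapping and logged.
    """
    cal = calendar_day(series.data.index)
    corrected = {}
    for var in VARIABLES:
        if var not in transfers:
            raise DataError(
                f"missing transfer for ({series.station_id}, {var})"
            )
        tr = transfers[var]
        if tr.station_id != series.station_id:
            raise DataError(
                f"transfer station {tr.station_id!r} does not match "
                f"series station {series.station_id!r}"
            )
        corrected[var] = _correct_values(series.data[var].to_numpy(), cal, tr)
    tmin, tmax = corrected["tmin"], corrected["tmax"]
    swap = tmin > tmax
    if swap.any():
        log.info(
            "%s: swapped %d corrected tmin/tmax pairs", series.station_id,
            int(swap.sum()),
        )
        tmin[swap], tmax[swap] = tmax[swap], tmin[swap].copy()
    df = pd.DataFrame({"tmin": tmin, "tmax": tmax}, index=series.data.index)
    return DailyTemperatureSeries(
        series.station_id, df, provenance=series.provenance,
        scenario=series.scenario, member=series.member,
    )


def qm_diagnostics(
    transfers: dict[str, QMTransfer],
    corrected_hist: DailyTemperatureSeries,
    observed: DailyTemperatureSeries,
    raw_projection: DailyTemperatureSeries | None = None,
    corrected_projection: DailyTemperatureSeries | None = None,
) -> dict:
    """Self-correction and trend-preservation diagnostics.

    Reports, per variable, the RMSE across calendar days and quantile
    classes between the corrected-historical and observed per-day
    quantiles over the reference span. When raw and corrected projection
    series are given, also reports the difference in their linear annual
    mean trends (degC/decade), which should be near zero.
    """
    report: dict = {}
    for var, tr in transfers.items():
        qc = _per_day_quantiles(corrected_hist, var, tr)
        qo = _per_day_quantiles(observed, var, tr)
        report[f"{var}_quantile_rmse"] = float(np.sqrt(np.mean((qc - qo) ** 2)))
    if raw_projection is not None and corrected_projection is not None:
        for var in VARIABLES:
            raw_tr = _annual_trend(raw_projection, var)
            cor_tr = _annual_trend(corrected_projection, var)
            report[f"{var}_trend_change_degC_per_decade"] = cor_tr - raw_tr
    return report


def _per_day_quantiles(series: DailyTemperatureSeries, var: str,
                       tr: QMTransfer) -> np.ndarray:
    y0, y1 = tr.reference_span
    df = series.data
    mask = (df.index.year >= y0) & (df.index.year <= y1)
    sub = df.loc[mask, var].dropna()
    cal = calendar_day(sub.index)
    vals = sub.to_numpy()
    probs = tr.probabilities
    q = np.empty((N_CAL_DAYS, tr.n_classes))
    for c, pool in enumerate(_window_pools(vals, cal, 61)):
        q[c] = np.quantile(pool, probs)
    return q


def _annual_trend(series: DailyTemperatureSeries, var: str) -> float:
    ann = series.data[var].groupby(series.data.index.year).mean().dropna()
    slope = np.polyfit(ann.index.to_numpy(float), ann.to_numpy(), 1)[0]
    return float(slope * 10.0)


def transfers_to_frame(transfers: list[QMTransfer]) -> pd.DataFrame:
    """Serialize transfers to the long CSV layout
    (station_id,variable,member,calendar_day,class_index,model_q,observed_q)."""
    rows = []
    for tr in transfers:
        for c in range(N_CAL_DAYS):
            for j in range(tr.n_classes):
                rows.append((tr.station_id, tr.variable, tr.member or "",
                             c + 1, j + 1, tr.model_quantiles[c, j],
                             tr.observed_quantiles[c, j]))
    return pd.DataFrame(rows, columns=["station_id", "variable", "member",
                                       "calendar_day", "class_index",
                                       "model_q", "observed_q"])


def transfers_from_frame(df: pd.DataFrame,
                         reference_span=(1981, 2005)) -> list[QMTransfer]:
    out = []
    for (sid, var, member), sub in df.groupby(
            ["station_id", "variable", "member"], sort=True):
        n_classes = sub["class_index"].max()
        piv_m = sub.pivot(index="calendar_day", columns="class_index",
                          values="model_q").sort_index()
        piv_o = sub.pivot(index="calendar_day", columns="class_index",
                          values="observed_q").sort_index()
        out.append(QMTransfer(str(sid), str(var), str(member) or None,
                              piv_m.to_numpy(), piv_o.to_numpy(),
                              reference_span=reference_span))
    return out
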