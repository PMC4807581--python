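"""Exposure and outcome preprocessing.

Derives the analysis-ready variables used by every model downstream:
apparent temperature from dry-bulb and dew-point temperature, lagged
daily pollutant features at each study visit, interquartile-range (IQR)
scaling of exposures, mean arterial pressure, averaging of duplicate
blood-pressure readings, and natural-log transformation of the
heart-rate-variability (HRV) outcomes, which are approximately
log-normal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError

logger = logging.getLogger(__name__)

#: Pollutant columns of a daily exposure series.
POLLUTANTS = ("pm10", "no2", "so2")
#: Meteorological columns of a daily exposure series.
MET_VARS = ("mean_temp", "dew_point")
#: Raw HRV outcome columns (positive, log-normal).
HRV_RAW = ("sdnn", "rmssd", "lf", "hf")
#: Blood-pressure outcome columns.
BP_OUTCOMES = ("sbp", "dbp", "map")
#: Log-scale HRV outcome columns used in models.
HRV_OUTCOMES = tuple(f"log_{v}" for v in HRV_RAW)


def apparent_temperature(mean_temp, dew_point):
    """Apparent temperature (°C) from daily mean and dew-point temperature.

    AT = -2.653 + 0.994*T + 0.0153*D**2, the standard summer apparent
    temperature used in air-pollution epidemiology. Note the quadratic
    dew-point term, which makes AT symmetric in dew point about 0 °C.
    """
    t = np.asarray(mean_temp, dtype=float)
    d = np.asarray(dew_point, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(d))):
        raise DataError("apparent_temperature requires finite inputs")
    out = -2.653 + 0.994 * t + 0.0153 * d**2
    return out if out.ndim else float(out)


def mean_arterial_pressure(sbp, dbp):
    """MAP = SBP/3 + 2*DBP/3 (mmHg). Raises if any SBP < DBP."""
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    if np.any(s < d):
        raise DataError("systolic below diastolic: readings look transposed")
    out = s / 3.0 + 2.0 * d / 3.0
    return out if out.ndim else float(out)


def average_bp(first, second):
    """Mean of two same-visit BP readings.

    A missing reading (NaN) falls back to the available one with a
    logged warning; only subjects with *no* reading at all are excluded
    upstream.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    n_single = int(np.sum(np.isnan(a) ^ np.isnan(b)))
    if n_single:
        logger.warning("average_bp: %d visit(s) with a single reading; using it as-is", n_single)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isnan(a), b, np.where(np.isnan(b), a, (a + b) / 2.0))
    return out if out.ndim else float(out)


def validate_exposure_series(series: pd.DataFrame) -> pd.DataFrame:
    """Check daily resolution and strictly increasing, gap-free dates."""
    if "date" not in series.columns:
        raise DataError("exposure series needs a 'date' column")
    s = series.copy()
    s["date"] = pd.to_datetime(s["date"])
    diffs = s["date"].diff().dropna()
    if len(diffs) and not (diffs == pd.Timedelta(days=1)).all():
        bad = s["date"][1:][diffs != pd.Timedelta(days=1)]
        raise DataError(f"exposure series not daily/increasing around {bad.iloc[0].date()}")
    return s


def with_apparent_temperature(series: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the daily series with an ``at`` column appended."""
    s = series.copy()
    s["at"] = apparent_temperature(s["mean_temp"].to_numpy(), s["dew_point"].to_numpy())
    return s


def build_lag_features(series: pd.DataFrame, dates, max_lag: int = 3,
                       variables=POLLUTANTS) -> pd.DataFrame:
    """Tidy table of lagged daily values for each visit date.

    One row per (date, variable, lag) with lag k holding the series
    value k days before the visit.  The series must cover
    [min(dates) - max_lag, max(dates)] without gaps.
    """
    s = validate_exposure_series(series).set_index("date")
    dates = pd.to_datetime(pd.Series(list(dates))).drop_duplicates().sort_values()
    rows = []
    for lag in range(max_lag + 1):
        lagged = dates - pd.Timedelta(days=lag)
        missing = lagged[~lagged.isin(s.index)]
        if len(missing):
            raise CoverageError(
                f"exposure series does not cover {missing.iloc[0].date()} "
                f"(lag {lag} of a visit date)")
        block = s.loc[lagged, list(variables)].reset_index(drop=True)
        block.insert(0, "date", dates.to_numpy())
        block = block.melt(id_vars="date", var_name="variable", value_name="value")
        block["lag"] = lag
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    return out[["date", "variable", "lag", "value"]]


def attach_lagged_exposures(panel: pd.DataFrame, series: pd.DataFrame,
                            max_lag: int = 3) -> pd.DataFrame:
    """Merge wide lagged exposure columns onto a visit-level panel.

    Adds ``{var}_lag{k}`` for each pollutant, apparent temperature
    (``at``) and mean temperature, for k = 0..max_lag, joined on the
    visit date.
    """
    if "date" not in panel.columns:
        raise DataError("panel needs a 'date' column to join exposures")
    s = with_apparent_temperature(validate_exposure_series(series))
    variables = list(POLLUTANTS) + ["at", "mean_temp"]
    tidy = build_lag_features(s, panel["date"].unique(), max_lag, variables)
    wide = tidy.assign(col=lambda d: d["variable"] + "_lag" + d["lag"].astype(str))
    wide = wide.pivot(index="date", columns="col", values="value").reset_index()
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"])
    return out.merge(wide, on="date", how="left")


def iqr_scale(values, quantile_method: str = "linear"):
    """Scale values by their interquartile range.

    Returns ``(values / iqr, iqr)`` where IQR = Q3 - Q1 computed with
    linear interpolation (numpy's default, R type 7) unless another
    numpy quantile method is requested.  Effects estimated on the scaled
    variable are then "per IQR increase".
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(np.unique(v)) < 4:
        raise DataError("iqr_scale needs at least 4 distinct values")
    q1, q3 = np.quantile(v, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    if iqr <= 0:
        raise DataError("IQR is zero: exposure is degenerate")
    return np.asarray(values, dtype=float) / iqr, float(iqr)


def log_transform_hrv(panel: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log columns for the HRV outcomes present in the panel.

    Raw columns stay untouched.  Non-positive values are a hard error
    (they cannot be log-normal) and the offending rows are listed.
    """
    out = panel.copy()
    for var in HRV_RAW:
        if var not in out.columns:
            continue
        col = out[var]
        bad = out.index[col.notna() & (col <= 0)]
        if len(bad):
            raise DataError(f"non-positive {var} at rows {list(bad[:10])}")
        out[f"log_{var}"] = np.log(col)
    return out


def prepare_outcomes(panel: pd.DataFrame) -> pd.DataFrame:
    """Derive modelled outcomes from raw measurements.

    Averages duplicate BP readings (``sbp_1``/``sbp_2`` style columns)
    when present, computes mean arterial pressure, and log-transforms
    the HRV outcomes.
    """
    out = panel.copy()
    for var in ("sbp", "dbp"):
        r1, r2 = f"{var}_1", f"{var}_2"
        if r1 in out.columns and r2 in out.columns:
            out[var] = average_bp(out[r1].to_numpy(), out[r2].to_numpy())
    if "sbp" in out.columns and "dbp" in out.columns:
        out["map"] = mean_arterial_pressure(out["sbp"].to_numpy(), out["dbp"].to_numpy())
    return log_transform_hrv(out)
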