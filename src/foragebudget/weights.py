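"""Ingest, filter, smooth and align precision-scale body-weight records.

In-pasture walk-over scales at a water point yield an irregular stream
of per-animal weights: multiple visits some days, none on others, and
occasional spurious readings (partial mounts, two animals on the
platform).  This module turns that stream into the gap-free daily BW
panel the intake ledger requires:

1. ``filter_spurious_weights`` — per-animal robust linear trend
   (Huber M-estimator); records far from the trend are flagged.
2. ``align_daily`` — average same-day visits, linearly interpolate
   missing days, carry edge values; long gaps raise a warning.
3. ``smooth_weights`` — short centered rolling mean to damp day-to-day
   rumen-fill fluctuation that is not growth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import GrazingPeriod, HerdWeightMatrix

__all__ = [
    "RECORD_COLUMNS",
    "CleanWeightSeries",
    "DataQualityWarning",
    "read_weight_records",
    "filter_spurious_weights",
    "smooth_weights",
    "align_daily",
    "assemble_herd",
    "clean_herd",
]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["animal_id", "day", "weight_kg"]

#: minimum records per animal for a robust trend fit to be meaningful
MIN_RECORDS_FOR_FIT = 8


class DataQualityWarning(UserWarning):
    """Gaps or degeneracies in the weight stream worth a human look."""


class WeightFormatError(ValueError):
    """Input file does not have the expected columns."""


@dataclass
class CleanWeightSeries:
    """One animal's gap-free daily BW with per-day provenance flags.

    ``day_flags`` entries are ``"kept"`` for days backed by at least one
    retained scale record and ``"imputed"`` for interpolated or
    edge-filled days.
    """

    animal_id: object
    daily_bw: np.ndarray
    day_flags: np.ndarray

    def __post_init__(self) -> None:
        self.daily_bw = np.asarray(self.daily_bw, dtype=float)
        self.day_flags = np.asarray(self.day_flags, dtype=object)
        if self.daily_bw.shape != self.day_flags.shape:
            raise ValueError("daily_bw and day_flags must have equal length")
        if np.any(~np.isfinite(self.daily_bw)) or np.any(self.daily_bw <= 0):
            raise ValueError("cleaned daily BW must be finite and positive")


def read_weight_records(path) -> pd.DataFrame:
    """Read a long CSV of scale records into a tidy DataFrame.

    Expected columns: ``animal_id``, ``weight_kg`` and either ``day``
    (integer, 0-based) or ``date`` (parsed, converted to 0-based offsets
    from the earliest date in the file).  An optional ``pasture_id``
    column is carried through.  Rows with non-positive or non-numeric
    weights are dropped with a logged warning; row order is preserved.
    """
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "weight_kg" not in df.columns:
        raise WeightFormatError(
            f"{path}: need columns animal_id, weight_kg and day (or date); "
            f"found {list(df.columns)}"
        )
    if "day" in df.columns:
        df["day"] = pd.to_numeric(df["day"], errors="coerce")
    elif "date" in df.columns:
        dates = pd.to_datetime(df["date"], errors="coerce")
        df["day"] = (dates - dates.min()).dt.days
    else:
        raise WeightFormatError(f"{path}: need a 'day' or 'date' column")

    df["weight_kg"] = pd.to_numeric(df["weight_kg"], errors="coerce")
    bad = df["weight_kg"].isna() | (df["weight_kg"] <= 0) | df["day"].isna()
    if bad.any():
        log.warning(
            "%s: dropped %d row(s) with missing/non-positive weight or day",
            path,
            int(bad.sum()),
        )
    df = df.loc[~bad].copy()
    df["day"] = df["day"].astype(int)
    keep = RECORD_COLUMNS + (["pasture_id"] if "pasture_id" in df.columns else [])
    return df[keep].reset_index(drop=True)


def _robust_scale(residuals: np.ndarray, reference_weight: float) -> float:
    """MAD-based residual scale with a tiny floor so exact fits don't divide by zero."""
    mad = np.median(np.abs(residuals - np.median(residuals)))
    scale = 1.4826 * mad
    floor = 1e-8 * max(1.0, abs(reference_weight))
    return max(scale, floor)


def _huber_residuals(day: np.ndarray, weight: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Residuals of all records from a Huber line fitted on ``mask`` records."""
    X = sm.add_constant(day.astype(float))
    rlm = sm.RLM(weight[mask], X[mask], M=sm.robust.norms.HuberT())
    with warnings.catch_warnings():
        # a perfect fit (zero scale) is a legitimate outcome on clean data
        warnings.simplefilter("ignore")
        fit = rlm.fit()
    return weight - X @ fit.params


def filter_spurious_weights(
    records: pd.DataFrame, residual_cutoff: float = 3.0
) -> pd.DataFrame:
    """Flag spurious scale records for a single animal.

    Fits a robust linear BW-vs-day trend (Huber M-estimator, iteratively
    reweighted) and flags records whose absolute residual exceeds
    ``residual_cutoff`` times a MAD-based robust scale; the line is then
    refitted on the kept records and flags recomputed once (two-pass).
    Returns a copy of ``records`` with a ``flag`` column of ``"kept"`` /
    ``"outlier"``.  The decision is a function of the (day, weight)
    set only, so it is invariant to record order.

    Fewer than 8 records: passed through unflagged with a warning.  All
    records on one day: falls back to median/MAD on the weights alone.
    """
    out = records.copy()
    n = len(out)
    if n == 0:
        out["flag"] = pd.Series(dtype=object)
        return out
    if out["animal_id"].nunique() > 1:
        raise ValueError("filter_spurious_weights operates on one animal at a time")
    if n < MIN_RECORDS_FOR_FIT:
        warnings.warn(
            f"animal {out['animal_id'].iloc[0]}: only {n} record(s); "
            "too few for a robust trend fit, keeping all",
            DataQualityWarning,
            stacklevel=2,
        )
        out["flag"] = "kept"
        return out

    day = out["day"].to_numpy(dtype=float)
    weight = out["weight_kg"].to_numpy(dtype=float)
    ref = float(np.median(weight))

    if np.ptp(day) == 0:
        # no trend estimable; robust location/scale on the weights
        resid = weight - np.median(weight)
    else:
        resid = _huber_residuals(day, weight, np.ones(n, dtype=bool))
    keep = np.abs(resid) <= residual_cutoff * _robust_scale(resid, ref)

    # second pass: refit without first-pass outliers, reflag everything
    if keep.any() and not keep.all():
        if np.ptp(day[keep]) == 0:
            resid = weight - np.median(weight[keep])
        else:
            resid = _huber_residuals(day, weight, keep)
        keep = np.abs(resid) <= residual_cutoff * _robust_scale(resid[keep], ref)

    out["flag"] = np.where(keep, "kept", "outlier")
    return out


def smooth_weights(daily_series, window_days: int = 3) -> np.ndarray:
    """Centered rolling mean over ``window_days`` (odd), truncated at edges.

    The default 3-day window damps rumen-fill variation — gut-content
    swings of several kg that are not growth — while leaving a linear
    growth trend unchanged away from the edges.
    """
    if window_days < 1 or window_days % 2 == 0:
        raise ValueError(f"window_days must be an odd integer >= 1, got {window_days}")
    s = pd.Series(np.asarray(daily_series, dtype=float))
    return s.rolling(window_days, center=True, min_periods=1).mean().to_numpy()


def align_daily(
    flagged_records: pd.DataFrame,
    period: GrazingPeriod,
    max_gap_days: int = 3,
) -> CleanWeightSeries:
    """Collapse kept records for one animal onto a gap-free daily grid.

    Same-day kept records are averaged; interior missing days are
    linearly interpolated between neighbours; leading/trailing gaps
    carry the nearest observed value.  Any gap longer than
    ``max_gap_days`` triggers a :class:`DataQualityWarning` listing the
    affected days (the analyst may prefer to drop those days herd-wide).
    """
    if "flag" in flagged_records.columns:
        kept = flagged_records[flagged_records["flag"] == "kept"]
    else:
        kept = flagged_records
    animal = flagged_records["animal_id"].iloc[0] if len(flagged_records) else "<unknown>"
    if kept.empty:
        raise ValueError(f"animal {animal}: no kept weight records to align")
    in_period = kept[(kept["day"] >= 0) & (kept["day"] < period.n_days)]
    if in_period.empty:
        raise ValueError(f"animal {animal}: no kept records inside the grazing period")

    daily = in_period.groupby("day")["weight_kg"].mean()
    grid = pd.Series(np.nan, index=pd.RangeIndex(period.n_days, name="day"))
    grid.loc[daily.index] = daily.to_numpy()
    flags = np.where(grid.notna(), "kept", "imputed").astype(object)

    missing = grid.index[grid.isna()].to_numpy()
    if missing.size:
        runs = np.split(missing, np.where(np.diff(missing) != 1)[0] + 1)
        long_runs = [r for r in runs if len(r) > max_gap_days]
        if long_runs:
            days_txt = ", ".join(f"{r[0]}-{r[-1]}" for r in long_runs)
            warnings.warn(
                f"animal {animal}: gap(s) longer than {max_gap_days} d "
                f"imputed on days {days_txt}; consider removing those days",
                DataQualityWarning,
                stacklevel=2,
            )
    filled = grid.interpolate(method="index", limit_direction="both")
    return CleanWeightSeries(animal_id=animal, daily_bw=filled.to_numpy(), day_flags=flags)


def assemble_herd(series, period: GrazingPeriod) -> HerdWeightMatrix:
    """Stack per-animal daily series into a herd matrix, rows sorted by id."""
    series = sorted(series, key=lambda s: str(s.animal_id))
    if not series:
        raise ValueError("cannot assemble a herd from zero animals")
    for s in series:
        if s.daily_bw.shape[0] != period.n_days:
            raise ValueError(
                f"animal {s.animal_id}: series length {s.daily_bw.shape[0]} "
                f"!= period {period.n_days}"
            )
    values = np.vstack([s.daily_bw for s in series])
    return HerdWeightMatrix(values, tuple(s.animal_id for s in series), period)


def clean_herd(
    records: pd.DataFrame,
    period: GrazingPeriod,
    residual_cutoff: float = 3.0,
    smoothing_window: int = 3,
    max_gap_days: int = 3,
) -> tuple[HerdWeightMatrix, pd.DataFrame]:
    """Full raw-records-to-herd-matrix pipeline.

    Per animal: robust outlier filtering, daily alignment, then rolling
    smoothing.  Returns the herd matrix and the flagged long records
    (one row per input record with its kept/outlier flag).
    """
    flagged_parts = []
    cleaned = []
    for _, grp in records.groupby("animal_id", sort=True):
        flagged = filter_spurious_weights(grp, residual_cutoff=residual_cutoff)
        flagged_parts.append(flagged)
        series = align_daily(flagged, period, max_gap_days=max_gap_days)
        series.daily_bw = smooth_weights(series.daily_bw, smoothing_window)
        cleaned.append(series)
    herd = assemble_herd(cleaned, period)
    return herd, pd.concat(flagged_parts, ignore_index=True)
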