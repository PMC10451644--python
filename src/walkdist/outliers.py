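"""Per tracker-day z-score flagging of erroneous GPS fixes.

Each calendar day of each tracker is standardised axis-wise (easting and
northing separately); fixes with |z| above the threshold on either axis are
flagged erroneous.  Flags are computed in a single pass on the full day —
they are never recomputed after removal — which makes filtering idempotent
and order-independent.  Sample standard deviation (n-1) is the default; the
population variant is available for sensitivity checks.

A consequence of standardising within the day: with sample sd the largest
attainable |z| is (n-1)/sqrt(n), so no fix can be flagged at threshold 4.5
on a day with fewer than 23 fixes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class ContractViolation(ValueError):
    """Input does not satisfy an operation's precondition."""


def zscore_flags_1d(values: np.ndarray, threshold: float, sample_sd: bool = True) -> np.ndarray:
    """Flag |z| > threshold for one axis of one tracker-day.

    Returns all-False when n < 2 or the standard deviation is zero.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        return np.zeros(n, dtype=bool)
    sd = v.std(ddof=1 if sample_sd else 0)
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros(n, dtype=bool)
    z = (v - v.mean()) / sd
    return np.abs(z) > threshold


def zscore_flag(
    day_fixes: pd.DataFrame,
    threshold: float = 4.5,
    sample_sd: bool = True,
) -> pd.DataFrame:
    """Set outlier flags on the fixes of a single tracker-day.

    Raises :class:`ContractViolation` if the rows span several trackers or
    several calendar days (UTC).  Input order is preserved.
    """
    if day_fixes.empty:
        return day_fixes.copy()
    if day_fixes["tracker_id"].nunique() > 1:
        raise ContractViolation("zscore_flag expects a single tracker")
    days = pd.to_datetime(day_fixes["timestamp"], utc=True).dt.date
    if days.nunique() > 1:
        raise ContractViolation("zscore_flag expects a single calendar day")
    out = day_fixes.copy()
    out["outlier_easting"] = zscore_flags_1d(
        out["easting"].to_numpy(), threshold, sample_sd
    )
    out["outlier_northing"] = zscore_flags_1d(
        out["northing"].to_numpy(), threshold, sample_sd
    )
    return out


def flag_all(
    fixes: pd.DataFrame,
    threshold: float = 4.5,
    day_timezone: str = "UTC",
    sample_sd: bool = True,
) -> pd.DataFrame:
    """Apply :func:`zscore_flags_1d` to every tracker-day of a fix table.

    Adds a ``date`` column (calendar date in ``day_timezone``) used as the
    grouping key by all downstream stages, so every algorithm sees the same
    day partition.
    """
    out = fixes.copy()
    out["date"] = (
        pd.to_datetime(out["timestamp"], utc=True)
        .dt.tz_convert(day_timezone)
        .dt.date
    )
    if out.empty:
        out["outlier_easting"] = pd.Series(dtype=bool)
        out["outlier_northing"] = pd.Series(dtype=bool)
        return out
    fe = np.zeros(len(out), dtype=bool)
    fn = np.zeros(len(out), dtype=bool)
    grouped = out.groupby(["tracker_id", "date"], sort=False)
    for _, g in grouped:
        locs = out.index.get_indexer(g.index)
        fe[locs] = zscore_flags_1d(g["easting"].to_numpy(), threshold, sample_sd)
        fn[locs] = zscore_flags_1d(g["northing"].to_numpy(), threshold, sample_sd)
    out["outlier_easting"] = fe
    out["outlier_northing"] = fn
    return out


def is_outlier(fixes: pd.DataFrame) -> pd.Series:
    """Erroneous iff flagged on either axis."""
    return fixes["outlier_easting"] | fixes["outlier_northing"]


def apply_filter(
    fixes: pd.DataFrame,
    drop_motionless: bool = False,
    drop_outliers: bool = False,
) -> pd.DataFrame:
    """Remove flagged and/or motionless fixes; relative order preserved.

    The two removal sets may overlap; a fix is removed once.  Counts of each
    reason are recorded in ``df.attrs`` (``n_outlier``, ``n_motionless``).
    """
    from .motion import is_motionless

    drop = pd.Series(False, index=fixes.index)
    n_out = n_still = 0
    if drop_outliers:
        out_mask = is_outlier(fixes)
        n_out = int(out_mask.sum())
        drop |= out_mask
    if drop_motionless:
        still_mask = pd.Series(is_motionless(fixes["cum_mi"]), index=fixes.index)
        n_still = int(still_mask.sum())
        drop |= still_mask
    result = fixes.loc[~drop].copy()
    result.attrs.update(n_outlier=n_out, n_motionless=n_still)
    return result
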