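"""Fuse accelerometer motion counts onto GPS fixes.

Each successful fix is annotated with the cumulative Motion Index (MI)
accrued since the previous successful fix of the same tracker, using
half-open windows (prev, current] so every motion record is counted exactly
once.  A tracker's first fix sums same-day records up to its timestamp and
is marked missing (NaN) when none exist; missing MI is never treated as
motionless, so first fixes can only be removed by the outlier filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def cumulate_motion(fixes: pd.DataFrame, motion: pd.DataFrame) -> pd.DataFrame:
    """Annotate projected fixes with inter-fix cumulative Motion Index.

    Parameters
    ----------
    fixes : DataFrame
        Projected fixes sorted by (tracker_id, timestamp).
    motion : DataFrame
        Motion records (``tracker_id, timestamp, motion_index``), sorted.

    Returns
    -------
    DataFrame
        Copy of ``fixes`` with a float ``cum_mi`` column (NaN = missing) and
        ``outlier_easting``/``outlier_northing`` flag columns initialised to
        False.  Row count and order are preserved.
    """
    out = fixes.copy()
    out["cum_mi"] = np.nan
    out["outlier_easting"] = False
    out["outlier_northing"] = False
    if out.empty:
        return out

    known = set(out["tracker_id"].unique())
    unknown = set(motion["tracker_id"].unique()) - known
    if unknown:
        logger.warning(
            "cumulate_motion: ignoring motion records for unknown tracker(s): %s",
            sorted(unknown),
        )

    def _ts64(s: pd.Series) -> np.ndarray:
        s = pd.to_datetime(s, utc=True)
        return s.dt.tz_localize(None).to_numpy(dtype="datetime64[ns]")

    motion = motion.sort_values(["tracker_id", "timestamp"], kind="stable")
    motion_by_tracker = {tid: g for tid, g in motion.groupby("tracker_id")}

    cum = np.full(len(out), np.nan)
    for tid, g in out.groupby("tracker_id", sort=False):
        idx = g.index.to_numpy()
        ts = _ts64(g["timestamp"])
        m = motion_by_tracker.get(tid)
        row_locs = out.index.get_indexer(idx)
        if m is None or m.empty:
            # no motion stream at all: windows sum to 0, first fix missing
            cum[row_locs[1:]] = 0.0
            continue
        mts = _ts64(m["timestamp"])
        mvals = m["motion_index"].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(mvals)])
        # windows (prev, cur]: cumulative sums at right-closed boundaries
        hi = np.searchsorted(mts, ts, side="right")
        sums = csum[hi[1:]] - csum[hi[:-1]]
        cum[row_locs[1:]] = sums
        # first fix: same-day (UTC) lookback window
        day_start = pd.Timestamp(ts[0]).normalize().to_datetime64()
        lo = np.searchsorted(mts, day_start, side="left")
        if hi[0] > lo:
            cum[row_locs[0]] = csum[hi[0]] - csum[lo]
        # else: leave NaN (missing)

    out["cum_mi"] = cum
    return out


def is_motionless(cum_mi) -> np.ndarray:
    """True where the inter-fix cumulative Motion Index is exactly zero.

    Missing values (NaN, e.g. a tracker's first fix with no lookback
    coverage) are treated as *not* motionless.
    """
    arr = np.asarray(cum_mi, dtype=float)
    return np.asarray((arr == 0.0) & ~np.isnan(arr))
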