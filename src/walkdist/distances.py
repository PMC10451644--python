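"""The three daily-distance algorithms.

RawDist sums consecutive planar steps over all of a day's fixes;
CorrectedDist first removes z-flagged fixes; CorrectedDist_Act additionally
removes fixes whose inter-fix cumulative Motion Index is zero.  Steps never
span a day boundary, and all three algorithms are evaluated on the identical
day partition (flags and MI are computed on the full day before any
removal), which guarantees CorrectedDist_Act <= CorrectedDist <= RawDist.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ALGORITHMS, PipelineConfig
from .io import DAILY_COLUMNS
from .motion import cumulate_motion, is_motionless
from .outliers import ContractViolation, flag_all, is_outlier


def step_distance(a, b) -> float:
    """Euclidean distance in metres between two projected fixes.

    ``a`` and ``b`` expose ``easting``/``northing`` attributes or items.
    """
    def _xy(p):
        try:
            return float(p["easting"]), float(p["northing"])
        except (TypeError, KeyError, IndexError):
            return float(p.easting), float(p.northing)

    xa, ya = _xy(a)
    xb, yb = _xy(b)
    return float(np.hypot(xa - xb, ya - yb))


def path_length(easting: np.ndarray, northing: np.ndarray) -> float:
    """Sum of consecutive Euclidean steps; 0.0 for fewer than 2 points."""
    e = np.asarray(easting, dtype=float)
    n = np.asarray(northing, dtype=float)
    if e.size < 2:
        return 0.0
    return float(np.sum(np.hypot(np.diff(e), np.diff(n))))


def daily_distance(day_fixes: pd.DataFrame) -> float:
    """Daily distance (m) for one time-ordered tracker-day of fixes."""
    if day_fixes.empty:
        return 0.0
    ts = pd.to_datetime(day_fixes["timestamp"], utc=True).dt.tz_localize(None).to_numpy(
        dtype="datetime64[ns]"
    )
    if np.any(np.diff(ts) < np.timedelta64(0, "ns")):
        raise ContractViolation("daily_distance requires time-ordered fixes")
    if day_fixes["tracker_id"].nunique() > 1:
        raise ContractViolation("daily_distance expects a single tracker")
    return path_length(day_fixes["easting"].to_numpy(), day_fixes["northing"].to_numpy())


def annotate(
    fixes_projected: pd.DataFrame,
    motion: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Motion fusion + per-day outlier flagging in one pass."""
    annotated = cumulate_motion(fixes_projected, motion)
    return flag_all(
        annotated,
        threshold=config.z_threshold,
        day_timezone=config.day_timezone,
        sample_sd=config.use_sample_sd,
    )


def compute_all(
    fixes_projected: pd.DataFrame,
    motion: pd.DataFrame,
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Compute the three algorithms for every tracker-day.

    Returns a DataFrame with one row per (tracker, date, algorithm).  Days
    with fewer than 2 surviving fixes report distance 0 (or NaN when
    ``config.degenerate_day_as_zero`` is False) with the bookkeeping counts
    preserved.
    """
    config = config or PipelineConfig()
    placements = dict(zip(manifest["tracker_id"], manifest["placement"]))
    missing = set(fixes_projected["tracker_id"].unique()) - set(placements)
    if missing:
        raise ValueError(f"tracker(s) missing from manifest: {sorted(missing)}")

    annotated = annotate(fixes_projected, motion, config)
    outlier = is_outlier(annotated).to_numpy()
    motionless = is_motionless(annotated["cum_mi"])

    keep = {
        "RawDist": np.ones(len(annotated), dtype=bool),
        "CorrectedDist": ~outlier,
        "CorrectedDist_Act": ~outlier & ~motionless,
    }

    rows = []
    for (tid, date), g in annotated.groupby(["tracker_id", "date"], sort=True):
        locs = annotated.index.get_indexer(g.index)
        e = g["easting"].to_numpy()
        n = g["northing"].to_numpy()
        n_total = len(g)
        for algo in ALGORITHMS:
            mask = keep[algo][locs]
            n_used = int(mask.sum())
            if n_used < max(2, config.min_fixes_per_day):
                dist = 0.0 if config.degenerate_day_as_zero else np.nan
                n_used_eff = n_used
            else:
                dist = path_length(e[mask], n[mask])
                n_used_eff = n_used
            rows.append(
                (tid, date, placements[tid], algo, dist, n_total, n_used_eff)
            )
    return pd.DataFrame(rows, columns=DAILY_COLUMNS)
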