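"""Delimited-text readers and writers for fixes, motion, manifests and results.

All tables are UTF-8 CSV (configurable delimiter), timestamps ISO-8601 and
parsed to UTC.  Readers are tolerant of malformed rows (rejected with a
warning and counted); writers serialize floats with 12 significant digits so
read-back round-trips within representation accuracy.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_DIALECT, PLACEMENTS

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["tracker_id", "timestamp", "lat", "lon"]
MOTION_COLUMNS = ["tracker_id", "timestamp", "motion_index"]
DAILY_COLUMNS = [
    "tracker_id", "date", "placement", "algorithm",
    "distance_m", "n_fixes_total", "n_fixes_used",
]

FLOAT_FORMAT = "%.17g"


class DialectError(ValueError):
    """A required column is missing from an input file."""


def _rename(df: pd.DataFrame, canonical: list[str], dialect: dict | None) -> pd.DataFrame:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    mapping = {dialect[c]: c for c in canonical}
    missing = [dialect[c] for c in canonical if dialect[c] not in df.columns]
    if missing:
        raise DialectError(f"missing required column(s): {missing}")
    return df.rename(columns=mapping)[canonical]


def read_fixes(path, dialect: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read GPS fix records.

    Returns a DataFrame with columns ``tracker_id, timestamp, lat, lon``
    sorted by (tracker_id, timestamp), exact duplicates dropped, rows with
    unparseable or out-of-range coordinates/timestamps rejected with a
    warning.  The number of dropped rows is stored in ``df.attrs``.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    df = _rename(raw, FIX_COLUMNS, dialect)
    n_in = len(df)

    df = df.drop_duplicates()
    n_dup = n_in - len(df)

    df = df.assign(
        timestamp=pd.to_datetime(df["timestamp"], errors="coerce", utc=True),
        lat=pd.to_numeric(df["lat"], errors="coerce"),
        lon=pd.to_numeric(df["lon"], errors="coerce"),
    )
    bad = (
        df["timestamp"].isna()
        | df["lat"].isna() | df["lon"].isna()
        | (df["lat"].abs() > 90.0) | (df["lon"].abs() > 180.0)
        | df["tracker_id"].isna()
    )
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_fixes(%s): rejected %d malformed row(s)", path, n_bad)
    if n_dup:
        logger.warning("read_fixes(%s): dropped %d exact duplicate row(s)", path, n_dup)
    df = df.loc[~bad]

    df = df.sort_values(["tracker_id", "timestamp"], kind="stable")
    # duplicate timestamps for one tracker: keep first, warn
    dup_ts = df.duplicated(["tracker_id", "timestamp"])
    if dup_ts.any():
        logger.warning(
            "read_fixes(%s): %d fix(es) share a tracker/timestamp; keeping first",
            path, int(dup_ts.sum()),
        )
        df = df.loc[~dup_ts]
    df = df.reset_index(drop=True)
    df.attrs.update(n_rejected=n_bad, n_duplicates=n_dup)
    return df


def read_motion(path, dialect: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read motion-index records (``tracker_id, timestamp, motion_index``)."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    df = _rename(raw, MOTION_COLUMNS, dialect)
    n_in = len(df)
    df = df.drop_duplicates()
    df = df.assign(
        timestamp=pd.to_datetime(df["timestamp"], errors="coerce", utc=True),
        motion_index=pd.to_numeric(df["motion_index"], errors="coerce"),
    )
    bad = df["timestamp"].isna() | df["motion_index"].isna() | (df["motion_index"] < 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("read_motion(%s): rejected %d malformed row(s)", path, n_bad)
    df = df.loc[~bad]
    df = df.assign(motion_index=df["motion_index"].astype(int))
    df = df.sort_values(["tracker_id", "timestamp"], kind="stable").reset_index(drop=True)
    df.attrs.update(n_rejected=n_bad, n_duplicates=n_in - len(df) - n_bad)
    return df


def read_manifest(path, dialect: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read the tracker placement manifest; validates the placement vocabulary."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    df = _rename(raw, ["tracker_id", "placement"], dialect)
    bad = ~df["placement"].isin(PLACEMENTS)
    if bad.any():
        raise ValueError(
            f"manifest contains unknown placement(s): {sorted(df.loc[bad, 'placement'].unique())}"
        )
    if df["tracker_id"].duplicated().any():
        dups = df.loc[df["tracker_id"].duplicated(), "tracker_id"].tolist()
        raise ValueError(f"manifest assigns multiple placements to: {dups}")
    return df.reset_index(drop=True)


def write_fixes(df: pd.DataFrame, path, sep: str = ",") -> None:
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, sep=sep, index=False, float_format="%.10f")


def write_motion(df: pd.DataFrame, path, sep: str = ",") -> None:
    out = df.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, sep=sep, index=False)


def write_manifest(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def write_daily_distances(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write the daily-distance table; header is emitted even when empty."""
    if df.empty:
        pd.DataFrame(columns=DAILY_COLUMNS).to_csv(path, sep=sep, index=False)
        return
    out = df[DAILY_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_daily_distances(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"tracker_id": str})
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"daily-distance table missing column(s): {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["n_fixes_total"] = df["n_fixes_total"].astype(int)
    df["n_fixes_used"] = df["n_fixes_used"].astype(int)
    return df


def file_digest(path) -> str:
    """SHA-256 of a file, for the run manifest."""
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def project_fixes(fixes: pd.DataFrame, zone: int, northern: bool = True) -> pd.DataFrame:
    """Attach UTM ``easting``/``northing`` columns (order and count preserved)."""
    from .projection import geographic_to_utm

    easting, northing = geographic_to_utm(
        fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), zone, northern
    )
    out = fixes.copy()
    out["easting"] = np.asarray(easting)
    out["northing"] = np.asarray(northing)
    out["utm_zone"] = zone
    out["hemisphere"] = "N" if northern else "S"
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
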