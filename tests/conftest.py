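import numpy as np
import pandas as pd
import pytest

from walkdist import PipelineConfig, compute_all
from walkdist.io import project_fixes
from walkdist.simulate import MovementModel, Schedule, SimScenario, simulate_study

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_scenario() -> SimScenario:
    return SimScenario(rng_seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_study(default_scenario):
    return simulate_study(default_scenario)


@pytest.fixture(scope="session")
def default_daily(default_study):
    cfg = PipelineConfig()
    proj = project_fixes(default_study["fixes"], cfg.utm_zone)
    return compute_all(proj, default_study["motion"], default_study["manifest"], cfg)


@pytest.fixture
def tiny_scenario() -> SimScenario:
    """Small, fast deployment for CLI / IO round-trip tests."""
    return SimScenario(
        n_animal=2,
        n_indoor=1,
        n_outdoor=1,
        schedule=Schedule(days=2, gps_interval_min=60, fix_dropout_prob=0.0),
        rng_seed=7,
    )


def fixes_frame(rows):
    """Build a projected-fix frame from (tracker_id, iso_ts, easting, northing)."""
    df = pd.DataFrame(rows, columns=["tracker_id", "timestamp", "easting", "northing"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def empty_motion():
    return pd.DataFrame(
        {
            "tracker_id": pd.Series(dtype=str),
            "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
            "motion_index": pd.Series(dtype=int),
        }
    )


def motion_frame(rows):
    df = pd.DataFrame(rows, columns=["tracker_id", "timestamp", "motion_index"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def steady_fixes(tracker="T1", day="2021-01-01", n=96, interval_min=15,
                 easting=500_000.0, northing=4_000_000.0, jitter=None, rng=None):
    """n fixes on a regular schedule at a fixed location (optional jitter sd)."""
    ts = pd.Timestamp(day, tz="UTC") + pd.to_timedelta(
        np.arange(n) * interval_min, unit="m"
    )
    e = np.full(n, easting)
    no = np.full(n, northing)
    if jitter:
        rng = rng or np.random.default_rng(0)
        e = e + rng.normal(0, jitter, n)
        no = no + rng.normal(0, jitter, n)
    return pd.DataFrame(
        {"tracker_id": tracker, "timestamp": ts, "easting": e, "northing": no}
    )
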