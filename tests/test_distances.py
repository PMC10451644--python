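"""Distance-algorithm tests: closed forms, brute-force oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from walkdist import PipelineConfig, compute_all
from walkdist.distances import daily_distance, path_length, step_distance
from walkdist.outliers import ContractViolation

from conftest import empty_motion, fixes_frame, motion_frame, steady_fixes


class TestStepDistance:
    def test_3_4_5_triangle(self):
        a = {"easting": 0.0, "northing": 0.0}
        b = {"easting": 3.0, "northing": 4.0}
        assert step_distance(a, b) == 5.0

    def test_identical_points(self):
        a = {"easting": 12.0, "northing": -7.0}
        assert step_distance(a, a) == 0.0

    def test_translation_invariance(self):
        assert step_distance(
            {"easting": 10.0, "northing": 10.0}, {"easting": 13.0, "northing": 14.0}
        ) == step_distance({"easting": 0.0, "northing": 0.0}, {"easting": 3.0, "northing": 4.0})

    def test_symmetry(self):
        a = {"easting": 1.0, "northing": 2.0}
        b = {"easting": -5.0, "northing": 9.0}
        assert step_distance(a, b) == step_distance(b, a)


class TestDailyDistance:
    def _day(self, coords):
        ts = pd.Timestamp("2021-01-01", tz="UTC") + pd.to_timedelta(
            np.arange(len(coords)) * 15, unit="m"
        )
        e, n = zip(*coords) if coords else ((), ())
        return pd.DataFrame(
            {"tracker_id": "T1", "timestamp": ts, "easting": e, "northing": n}
        )

    def test_repeated_endpoint(self):
        assert daily_distance(self._day([(0, 0), (3, 4), (3, 4)])) == 5.0

    def test_out_and_back(self):
        assert daily_distance(self._day([(0, 0), (0, 100), (0, 0)])) == 200.0

    def test_97_collinear_fixes_closed_form(self):
        coords = [(10.0 * i, 0.0) for i in range(97)]
        assert daily_distance(self._day(coords)) == pytest.approx(960.0)

    def test_fewer_than_two_fixes_is_zero(self):
        assert daily_distance(self._day([(5, 5)])) == 0.0
        assert daily_distance(self._day([])) == 0.0

    def test_unordered_input_raises(self):
        df = self._day([(0, 0), (1, 1), (2, 2)])
        df = df.iloc[[2, 0, 1]].reset_index(drop=True)
        with pytest.raises(ContractViolation):
            daily_distance(df)


def _manifest(*trackers):
    return pd.DataFrame(trackers, columns=["tracker_id", "placement"])


class TestComputeAll:
    def test_static_all_motionless(self):
        """No flags, MI=0 everywhere: Raw == Corrected > 0, Act == 0."""
        rng = np.random.default_rng(5)
        fixes = steady_fixes(n=30, jitter=3.0, rng=rng)
        motion = pd.DataFrame(
            {"tracker_id": "T1", "timestamp": fixes["timestamp"], "motion_index": 0}
        )
        daily = compute_all(fixes, motion, _manifest(("T1", "Indoor")))
        d = daily.set_index("algorithm")["distance_m"]
        assert d["RawDist"] == d["CorrectedDist"] > 0
        assert d["CorrectedDist_Act"] == 0.0

    def test_spike_day_brute_force(self):
        """RawDist exceeds CorrectedDist by the spike's detour, exactly."""
        rng = np.random.default_rng(6)
        fixes = steady_fixes(n=96, jitter=2.0, rng=rng)
        i = 40
        fixes.loc[fixes.index[i], "easting"] += 10_000.0
        motion = pd.DataFrame(
            {"tracker_id": "T1", "timestamp": fixes["timestamp"], "motion_index": 1}
        )
        daily = compute_all(fixes, motion, _manifest(("T1", "Animal")))
        d = daily.set_index("algorithm")["distance_m"]
        e, n = fixes["easting"].to_numpy(), fixes["northing"].to_numpy()
        with_spike = path_length(e, n)
        mask = np.ones(96, bool)
        mask[i] = False
        without_spike = path_length(e[mask], n[mask])
        assert d["RawDist"] == pytest.approx(with_spike)
        assert d["CorrectedDist"] == pytest.approx(without_spike)
        detour = with_spike - without_spike
        assert detour == pytest.approx(2 * 10_000.0, rel=0.01)

    def test_noiseless_always_moving_walker_all_equal(self):
        coords = [(4.0 * i, 3.0 * i) for i in range(20)]
        ts = pd.Timestamp("2021-01-01", tz="UTC") + pd.to_timedelta(
            np.arange(20) * 15, unit="m"
        )
        fixes = pd.DataFrame(
            {
                "tracker_id": "T1",
                "timestamp": ts,
                "easting": [c[0] for c in coords],
                "northing": [c[1] for c in coords],
            }
        )
        motion = pd.DataFrame(
            {"tracker_id": "T1", "timestamp": ts, "motion_index": 2}
        )
        daily = compute_all(fixes, motion, _manifest(("T1", "Animal")))
        d = daily.set_index("algorithm")["distance_m"]
        assert d["RawDist"] == d["CorrectedDist"] == d["CorrectedDist_Act"]
        assert d["RawDist"] == pytest.approx(19 * 5.0)

    def test_zero_case_identical_coordinates(self):
        fixes = steady_fixes(n=40)
        motion = pd.DataFrame(
            {"tracker_id": "T1", "timestamp": fixes["timestamp"], "motion_index": 1}
        )
        daily = compute_all(fixes, motion, _manifest(("T1", "Outdoor")))
        assert (daily["distance_m"] == 0.0).all()

    def test_missing_manifest_entry_fatal(self):
        fixes = steady_fixes(n=3)
        with pytest.raises(ValueError, match="T1"):
            compute_all(fixes, empty_motion(), _manifest(("T9", "Animal")))

    def test_cross_midnight_step_discarded(self):
        """Within-day sums exclude the step spanning the day boundary."""
        rows = [
            ("T1", "2021-01-01T23:30:00Z", 0.0, 0.0),
            ("T1", "2021-01-01T23:45:00Z", 0.0, 100.0),
            ("T1", "2021-01-02T00:00:00Z", 0.0, 10_100.0),
            ("T1", "2021-01-02T00:15:00Z", 0.0, 10_200.0),
        ]
        fixes = fixes_frame(rows)
        daily = compute_all(fixes, empty_motion(), _manifest(("T1", "Animal")))
        raw = daily[daily["algorithm"] == "RawDist"].set_index("date")["distance_m"]
        assert raw.loc[pd.Timestamp("2021-01-01").date()] == 100.0
        assert raw.loc[pd.Timestamp("2021-01-02").date()] == 100.0

    def test_degenerate_day_reports_zero_with_counts(self):
        fixes = steady_fixes(n=1)
        daily = compute_all(fixes, empty_motion(), _manifest(("T1", "Indoor")))
        assert (daily["distance_m"] == 0.0).all()
        assert (daily["n_fixes_total"] == 1).all()

    def test_degenerate_day_nan_option(self):
        fixes = steady_fixes(n=1)
        cfg = PipelineConfig(degenerate_day_as_zero=False)
        daily = compute_all(fixes, empty_motion(), _manifest(("T1", "Indoor")), cfg)
        assert daily["distance_m"].isna().all()

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 60),
        spikes=st.integers(0, 3),
    )
    def test_monotonicity_chain_property(self, seed, n, spikes):
        """CorrectedDist_Act <= CorrectedDist <= RawDist on random days."""
        rng = np.random.default_rng(seed)
        fixes = steady_fixes(n=n, jitter=rng.uniform(0.1, 20), rng=rng)
        for _ in range(spikes):
            j = int(rng.integers(0, n))
            fixes.loc[fixes.index[j], "easting"] += rng.uniform(1e3, 1e6)
        motion = pd.DataFrame(
            {
                "tracker_id": "T1",
                "timestamp": fixes["timestamp"],
                "motion_index": rng.integers(0, 3, n),
            }
        )
        daily = compute_all(fixes, motion, _manifest(("T1", "Animal")))
        d = daily.set_index("algorithm")["distance_m"]
        eps = 1e-9
        assert d["CorrectedDist_Act"] <= d["CorrectedDist"] + eps
        assert d["CorrectedDist"] <= d["RawDist"] + eps


class TestStationaryNoiseClosedForm:
    def test_expected_rawdist_matches_sigma_sqrt_pi(self):
        """E[RawDist] = (n-1) * sigma * sqrt(pi) for pure isotropic noise."""
        sigma, n_fix, n_days = 5.0, 96, 120
        rng = np.random.default_rng(11)
        dists = []
        for _ in range(n_days):
            e = rng.normal(0, sigma, n_fix)
            no = rng.normal(0, sigma, n_fix)
            dists.append(path_length(e, no))
        dists = np.asarray(dists)
        expected = (n_fix - 1) * sigma * np.sqrt(np.pi)
        se = dists.std(ddof=1) / np.sqrt(n_days)
        assert abs(dists.mean() - expected) < 3 * se
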