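"""Trajectory ingestion, speed computation and hysteresis bout filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoallo.trajectory import (FilterConfig, SpeedSeries, Trajectory,
                                   build_records, compute_speeds,
                                   exploratory_speed, process_trajectory,
                                   read_metadata_csv, read_trajectory_csv,
                                   segment_bouts)


def _series(speeds, dt=1.0):
    speeds = np.asarray(speeds, dtype=float)
    n = speeds.size
    return SpeedSeries(t_mid=(np.arange(n) + 0.5) * dt, speed=speeds,
                       dt=np.full(n, dt))


def _traj(t, x, y):
    return Trajectory("test", np.asarray(t), np.asarray(x), np.asarray(y))


class TestComputeSpeeds:
    def test_three_four_five_triangle(self):
        s = compute_speeds(_traj([0.0, 1.0], [0.0, 3.0], [0.0, 4.0]))
        assert len(s) == 1
        assert s.speed[0] == pytest.approx(5.0)

    def test_single_point_gives_empty_series(self):
        s = compute_speeds(_traj([0.0], [1.0], [2.0]))
        assert len(s) == 0

    def test_constant_speed_on_circle(self):
        # chord of a 10 mm circle stepped by 0.1 rad every 1/38 s
        dt = 1.0 / 38.0
        ang = np.arange(50) * 0.1
        traj = _traj(np.arange(50) * dt, 10 * np.cos(ang), 10 * np.sin(ang))
        s = compute_speeds(traj)
        expected = 2.0 * 10.0 * np.sin(0.05) * 38.0
        assert np.allclose(s.speed, expected, rtol=1e-12)

    def test_duplicate_timestamp_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 2"):
            _traj([0.0, 1.0, 1.0, 2.0], np.zeros(4), np.zeros(4))

    def test_length_is_points_minus_one(self, rng):
        t = np.cumsum(rng.uniform(0.01, 0.1, 20))
        s = compute_speeds(_traj(t, rng.normal(size=20),
                                 rng.normal(size=20)))
        assert len(s) == 19
        assert np.all(s.speed >= 0)

    def test_doubling_coordinates_doubles_speeds(self, rng):
        t = np.cumsum(rng.uniform(0.01, 0.1, 30))
        x, y = rng.normal(size=30), rng.normal(size=30)
        s1 = compute_speeds(_traj(t, x, y))
        s2 = compute_speeds(_traj(t, 2 * x, 2 * y))
        np.testing.assert_allclose(s2.speed, 2 * s1.speed, rtol=1e-15)

    def test_doubling_time_intervals_halves_speeds(self, rng):
        t = np.cumsum(rng.uniform(0.01, 0.1, 30))
        x, y = rng.normal(size=30), rng.normal(size=30)
        s1 = compute_speeds(_traj(t, x, y))
        s2 = compute_speeds(_traj(2 * t, x, y))
        np.testing.assert_allclose(s2.speed, s1.speed / 2, rtol=1e-15)


class TestSegmentBouts:
    def test_hand_enumerated_hysteresis(self):
        bouts = segment_bouts(_series([0.7, 0.5, 0.4, 0.2, 0.7, 0.1]),
                              FilterConfig())
        assert [(b.start_index, b.stop_index) for b in bouts] == \
            [(0, 3), (4, 5)]

    def test_never_reaching_start_threshold_gives_no_bouts(self):
        assert segment_bouts(_series([0.5] * 10), FilterConfig()) == []

    def test_never_dropping_below_stop_gives_one_full_bout(self):
        bouts = segment_bouts(_series([1.0] * 10), FilterConfig())
        assert [(b.start_index, b.stop_index) for b in bouts] == [(0, 10)]

    def test_intermediate_speeds_keep_open_bout_alive(self):
        # 0.4 is between stop and start: continues a bout, cannot open one
        bouts = segment_bouts(_series([0.4, 0.8, 0.4, 0.4, 0.1]),
                              FilterConfig())
        assert [(b.start_index, b.stop_index) for b in bouts] == [(1, 4)]

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(v_start=0.3, v_stop=0.6)

    def test_bout_duration_and_distance(self):
        bouts = segment_bouts(_series([2.0, 3.0, 0.1], dt=0.5),
                              FilterConfig())
        (b,) = bouts
        assert b.duration == pytest.approx(1.0)
        assert b.distance == pytest.approx(2.0 * 0.5 + 3.0 * 0.5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 2.0, allow_nan=False), min_size=2,
                    max_size=40),
           st.integers(min_value=1, max_value=39))
    def test_concatenation_when_cut_outside_a_bout(self, speeds, cut):
        """Segmenting halves equals segmenting the whole when the cut
        does not fall inside a bout of the full segmentation."""
        cut = min(cut, len(speeds) - 1)
        cfg = FilterConfig()
        whole = segment_bouts(_series(speeds), cfg)
        if any(b.start_index < cut < b.stop_index for b in whole):
            return
        left = segment_bouts(_series(speeds[:cut]), cfg)
        right = segment_bouts(_series(speeds[cut:]), cfg)
        merged = [(b.start_index, b.stop_index) for b in left] + \
            [(b.start_index + cut, b.stop_index + cut) for b in right]
        assert merged == [(b.start_index, b.stop_index) for b in whole]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 2.0, allow_nan=False), min_size=1,
                    max_size=50))
    def test_bouts_ordered_and_non_overlapping(self, speeds):
        bouts = segment_bouts(_series(speeds), FilterConfig())
        for a, b in zip(bouts, bouts[1:]):
            assert a.stop_index <= b.start_index


class TestExploratorySpeed:
    def test_constant_speed_bout(self):
        # 2 mm/s held for 10 s -> 0.002 m/s
        n = 11
        traj = _traj(np.arange(n, dtype=float), 2.0 * np.arange(n),
                     np.zeros(n))
        speeds = compute_speeds(traj)
        bouts = segment_bouts(speeds, FilterConfig())
        assert exploratory_speed(traj, bouts) == pytest.approx(0.002)

    def test_time_weighted_pooling_across_bouts(self):
        # 10 mm in 2 s and 30 mm in 3 s -> 40/5 mm/s = 0.008 m/s
        speeds = _series([5.0, 5.0, 0.1, 10.0, 10.0, 10.0, 0.1])
        bouts = segment_bouts(speeds, FilterConfig())
        traj = _traj(np.arange(8, dtype=float), np.zeros(8), np.zeros(8))
        assert exploratory_speed(traj, bouts) == pytest.approx(0.008)

    def test_no_bouts_flagged_missing_not_zero(self):
        traj = _traj([0.0, 1.0, 2.0], [0.0, 1e-4, 2e-4], np.zeros(3))
        speed = process_trajectory(traj)
        assert np.isnan(speed)

    def test_only_within_bout_frames_contribute(self):
        """Frames outside bouts are excluded from the aggregate."""
        speeds = _series([5.0, 5.0, 0.1, 0.2, 0.25])
        bouts = segment_bouts(speeds, FilterConfig())
        traj = _traj(np.arange(6, dtype=float), np.zeros(6), np.zeros(6))
        # aggregate must equal the bout-only mean, untouched by frames 2-4
        assert exploratory_speed(traj, bouts) == pytest.approx(0.005)


class TestIO:
    def test_round_trip_and_record_building(self, tmp_path):
        t = np.arange(20) / 38.0
        df_traj = {"id": ["b1"] * 20, "t": t, "x": 2.0 * np.arange(20.0),
                   "y": np.zeros(20)}
        import pandas as pd
        pd.DataFrame(df_traj).to_csv(tmp_path / "traj.csv", index=False)
        pd.DataFrame({
            "id": ["b1"], "species": ["species_01"],
            "habitat_group": ["forest"], "mass_mg": [105.0],
            "temperature_C": [20.0],
        }).to_csv(tmp_path / "meta.csv", index=False)

        trajs = read_trajectory_csv(tmp_path / "traj.csv")
        meta = read_metadata_csv(tmp_path / "meta.csv")
        records = build_records(trajs, meta)
        assert len(records) == 1
        # 2 mm per frame at 38 fps = 76 mm/s = 0.076 m/s
        assert records["speed_m_s"].iloc[0] == pytest.approx(0.076)

    def test_missing_columns_rejected(self, tmp_path):
        import pandas as pd
        pd.DataFrame({"a": [1]}).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="columns"):
            read_trajectory_csv(tmp_path / "bad.csv")
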