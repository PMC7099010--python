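import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from penguinpipe.errors import ConfigError, ValidationError
from penguinpipe.kraken import build_kraken
from penguinpipe.narwhal import (compute_narwhal, fahrenheit_to_celsius,
                                 mean_frame_movement, mean_kth_nn,
                                 moving_average)

from conftest import make_consensus, make_manifest


def brute_kth_nn(pts, k):
    pts = np.asarray(pts, float)
    n = len(pts)
    if n < k + 1:
        return (math.nan, math.nan)
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    kth = np.sort(d, axis=1)[:, k]  # column 0 is self-distance 0
    return (kth.mean(), kth.std(ddof=1))


def brute_movement(cur, prev):
    cur, prev = np.asarray(cur, float), np.asarray(prev, float)
    if len(cur) == 0 or len(prev) == 0:
        return math.nan
    d = np.linalg.norm(cur[:, None] - prev[None], axis=2)
    return d.min(axis=1).mean()


class TestMeanKthNN:
    def test_single_pair_345(self):
        assert mean_kth_nn(np.array([[0, 0], [3, 4]]), 1) == (5.0, 0.0)

    def test_lone_point_has_no_neighbour(self):
        mean, sd = mean_kth_nn(np.array([[0.0, 0.0]]), 1)
        assert math.isnan(mean) and math.isnan(sd)

    def test_collinear_second_neighbour(self):
        mean, sd = mean_kth_nn(np.array([[0, 0], [1, 0], [3, 0]]), 2)
        assert mean == pytest.approx(8 / 3, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 2])
    def test_matches_all_pairs_oracle(self, k, rng):
        for _ in range(20):
            pts = rng.random((int(rng.integers(2, 50)), 2)) * 1000
            mean, sd = mean_kth_nn(pts, k)
            emean, esd = brute_kth_nn(pts, k)
            if math.isnan(emean):
                assert math.isnan(mean)
            else:
                assert mean == pytest.approx(emean, abs=1e-9)
                assert sd == pytest.approx(esd, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(arrays(float, (12, 2), elements=st.floats(0, 1000)),
           st.floats(-500, 500), st.floats(-500, 500),
           st.floats(0, 2 * math.pi), st.floats(0.1, 10))
    def test_rigid_motion_invariance_and_scaling(self, pts, dx, dy, theta, scale):
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        base, _ = mean_kth_nn(pts, 1)
        moved, _ = mean_kth_nn(pts @ rot.T + [dx, dy], 1)
        scaled, _ = mean_kth_nn(pts * scale, 1)
        assert moved == pytest.approx(base, rel=1e-9, abs=1e-6)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-6)

    def test_kth_distance_nondecreasing_in_k(self, rng):
        pts = rng.random((30, 2)) * 500
        m1, _ = mean_kth_nn(pts, 1)
        m2, _ = mean_kth_nn(pts, 2)
        assert m2 >= m1


class TestMeanFrameMovement:
    def test_identical_frames_move_zero(self, rng):
        pts = rng.random((17, 2)) * 400
        assert mean_frame_movement(pts, pts) == 0.0

    def test_single_translated_point(self):
        assert mean_frame_movement(np.array([[6.0, 8.0]]), np.array([[0.0, 0.0]])) == 10.0

    def test_empty_previous_is_missing(self):
        assert math.isnan(mean_frame_movement(np.array([[1.0, 1.0]]), np.empty((0, 2))))

    def test_matches_all_pairs_minimum_oracle(self, rng):
        for _ in range(20):
            cur = rng.random((int(rng.integers(1, 100)), 2)) * 800
            prev = rng.random((int(rng.integers(1, 100)), 2)) * 800
            assert mean_frame_movement(cur, prev) == pytest.approx(
                brute_movement(cur, prev), abs=1e-9)

    def test_non_negative(self, rng):
        cur, prev = rng.random((9, 2)), rng.random((5, 2))
        assert mean_frame_movement(cur, prev) >= 0


@pytest.mark.parametrize("f,c", [(32.0, 0.0), (-40.0, -40.0), (212.0, 100.0)])
def test_fahrenheit_to_celsius(f, c):
    assert fahrenheit_to_celsius(f) == pytest.approx(c, abs=1e-12)


def test_fahrenheit_missing_propagates():
    assert math.isnan(fahrenheit_to_celsius(float("nan")))


class TestMovingAverage:
    def test_constant_series(self):
        out = moving_average([4.2] * 30, 20)
        assert np.allclose(out, 4.2)

    def test_unit_window_is_identity_on_observed(self):
        series = [1.0, math.nan, 3.0]
        out = moving_average(series, 1)
        assert out[0] == 1.0 and out[1] == 1.0 and out[2] == 3.0

    def test_missing_prefix_stays_missing(self):
        out = moving_average([math.nan, math.nan, 5.0], 3)
        assert math.isnan(out[0]) and math.isnan(out[1]) and out[2] == 5.0

    def test_matches_brute_force_window(self, rng):
        vals = rng.random(200)
        vals[rng.random(200) < 0.2] = math.nan
        out = moving_average(vals, 20)
        for i in range(len(vals)):
            obs = [v for v in vals[: i + 1] if not math.isnan(v)][-20:]
            if obs:
                assert out[i] == pytest.approx(np.mean(obs), abs=1e-12)
            else:
                assert math.isnan(out[i])

    def test_invalid_window(self):
        with pytest.raises(ConfigError):
            moving_average([1.0], 0)


def series_fixture(frame_points, classes="adult"):
    """Build a merged click table from per-frame point lists."""
    names, rows_names, cls, xs, ys, marks = [], [], [], [], [], []
    for i, pts in enumerate(frame_points, start=1):
        name = f"DAMOa2014a_{i:06d}"
        names.append(name)
        for (x, y) in pts:
            rows_names.append(name)
            cls.append(classes)
            xs.append(x)
            ys.append(y)
            marks.append(8)
    consensus = make_consensus(rows_names, cls, marks, x=xs, y=ys)
    manifest = make_manifest(names)
    return build_kraken(consensus, manifest)


class TestComputeNarwhal:
    def test_empty_frame_has_zero_counts_missing_distances(self):
        kraken = series_fixture([[(10, 10), (50, 50)], []])
        out = compute_narwhal(kraken)
        empty = out.iloc[1]
        assert (empty["nadults"], empty["nchicks"], empty["neggs"]) == (0, 0, 0)
        assert math.isnan(empty["adultndout"]) and math.isnan(empty["meanchangeadult"])

    def test_static_positions_give_zero_movement(self):
        pts = [(100, 100), (300, 200), (500, 400)]
        out = compute_narwhal(series_fixture([pts] * 5))
        assert np.allclose(out["meanchangeadult"].iloc[1:], 0.0)
        assert math.isnan(out["meanchangeadult"].iloc[0])

    def test_uniform_displacement_recovered_exactly(self, rng):
        """Shifting every adult by delta < half the minimal spacing makes each
        individual its own previous-frame nearest neighbour."""
        base = np.array([[100.0, 100.0], [220.0, 100.0], [100.0, 260.0], [400.0, 400.0]])
        delta = np.array([3.0, 4.0])  # |delta| = 5
        frames = [base + i * delta for i in range(6)]
        out = compute_narwhal(series_fixture([list(map(tuple, f)) for f in frames]))
        assert np.allclose(out["meanchangeadult"].iloc[1:], 5.0, atol=1e-9)

    def test_chick_metrics_and_temperature(self):
        kraken = series_fixture([[(0, 0), (3, 4), (10, 0)]], classes="chick")
        out = compute_narwhal(kraken)
        row = out.iloc[0]
        assert row["nchicks"] == 3 and row["nadults"] == 0
        expected1, _ = brute_kth_nn(np.array([[0, 0], [3, 4], [10, 0]]), 1)
        expected2, _ = brute_kth_nn(np.array([[0, 0], [3, 4], [10, 0]]), 2)
        assert row["chickndout"] == pytest.approx(expected1, abs=1e-9)
        assert row["chick2ndout"] == pytest.approx(expected2, abs=1e-9)
        assert row["chick2ndout"] >= row["chickndout"]
        assert row["tempc"] == pytest.approx((35 - 32) * 5 / 9, abs=1e-5)

    def test_row_count_matches_manifest_and_order_is_temporal(self):
        kraken = series_fixture([[(1, 1)], [(2, 2)], [(3, 3)]])
        out = compute_narwhal(kraken)
        assert len(out) == 3
        assert list(out["imageid"]) == sorted(out["imageid"])

    def test_series_without_strict_order_rejected(self):
        """Two images sharing datetime and frame number admit no strict order."""
        consensus = make_consensus(["DAMOa2014a_000001", "GEORa2013b_000001"],
                                   ["adult", "adult"], [8, 8])
        manifest = make_manifest(["DAMOa2014a_000001", "GEORa2013b_000001"],
                                 datetimes=["2014:01:01 07:00:00"] * 2)
        with pytest.raises(ValidationError):
            compute_narwhal(build_kraken(consensus, manifest))
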