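"""Trajectory cleaning: outlier replacement, block interpolation, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motionval import (
    NoiseConfig,
    OutlierPolicy,
    ScalarSeries,
    SeriesTooShortError,
    SmoothingConfig,
    interpolate_blocks,
    moving_average,
    preprocess_sequence,
    remove_outliers,
    static_pose,
)

finite_series = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
    min_size=3,
    max_size=100,
).map(np.asarray)


class TestRemoveOutliers:
    def test_constant_series_untouched(self):
        for source in ("neighbors-only", "literal-3-point", "global-series"):
            out, windows = remove_outliers(
                np.full(5, 5.0), OutlierPolicy(sigma_source=source)
            )
            assert np.array_equal(out, np.full(5, 5.0))
            assert windows == []

    def test_spike_replaced_by_neighbor_mean_under_default_policy(self):
        out, windows = remove_outliers(np.array([0.0, 0, 10, 0, 0]))
        assert np.array_equal(out, np.zeros(5))
        assert len(windows) == 1
        (w,) = windows
        assert (w.center_index, w.mean, w.sigma) == (2, 0.0, 0.0)
        assert w.lower == w.upper == 0.0

    def test_literal_three_point_policy_cannot_flag_the_spike(self):
        # with the candidate inside the window, |x - mean| <= sqrt(2) sigma < 1.96 sigma
        x = np.array([0.0, 0, 10, 0, 0])
        out, windows = remove_outliers(x, OutlierPolicy(sigma_source="literal-3-point"))
        assert np.array_equal(out, x)
        assert windows == []

    def test_global_series_policy_flags_gross_spike(self, rng):
        x = rng.normal(0.0, 1.0, size=60)
        x[30] += 50.0
        out, windows = remove_outliers(x, OutlierPolicy(sigma_source="global-series"))
        assert [w.center_index for w in windows] == [30]
        assert out[30] == pytest.approx(0.5 * (x[29] + x[31]))

    def test_endpoints_never_replaced(self):
        x = np.array([100.0, 0, 0, 0, -100.0])
        out, _ = remove_outliers(x)
        assert out[0] == 100.0 and out[-1] == -100.0

    def test_too_short_series_rejected(self):
        with pytest.raises(SeriesTooShortError, match="too short"):
            remove_outliers(np.array([1.0, 2.0]))

    def test_idempotent_on_isolated_spike_fixtures(self):
        x = np.array([0.0, 0, 10, 0, 0, 5, 0, 0, -7, 0, 0])
        once, w1 = remove_outliers(x)
        twice, w2 = remove_outliers(once)
        assert len(w1) == 3 and w2 == []
        assert np.array_equal(once, twice)

    def test_scalar_series_wrapper_round_trips_unit(self):
        series = ScalarSeries(np.array([0.0, 0, 10, 0, 0]), unit="deg")
        out, _ = remove_outliers(series)
        assert isinstance(out, ScalarSeries) and out.unit == "deg"

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="sigma_source"):
            OutlierPolicy(sigma_source="psychic")


class TestInterpolateBlocks:
    def test_linear_ramp_is_fixed_point(self):
        x = np.arange(10.0)
        assert np.allclose(interpolate_blocks(x), x)

    def test_interior_replaced_by_endpoint_line(self):
        x = np.array([0.0, 5, -5, 2, 8, 1, 7, -3, 4, 9])
        assert np.allclose(interpolate_blocks(x), np.arange(10.0))

    def test_partial_block_passes_through(self, rng):
        x = rng.normal(size=7)
        assert np.array_equal(interpolate_blocks(x), x)

    def test_trailing_partial_block_untouched(self, rng):
        x = rng.normal(size=23)
        out = interpolate_blocks(x)
        assert np.array_equal(out[20:], x[20:])
        assert np.allclose(out[[0, 9, 10, 19]], x[[0, 9, 10, 19]])

    @given(finite_series)
    @settings(max_examples=50, deadline=None)
    def test_projection_property(self, x):
        once = interpolate_blocks(x)
        assert np.allclose(interpolate_blocks(once), once, atol=1e-9)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(9, 3.14)
        assert np.allclose(moving_average(x, SmoothingConfig(window_n=5)), x)

    @pytest.mark.parametrize(
        "x,expected",
        [
            ([1, 2, 3, 4, 5], [1.5, 2, 3, 4, 4.5]),
            ([0, 0, 3, 0, 0], [0, 1, 1, 1, 0]),
        ],
    )
    def test_clipped_window_means(self, x, expected):
        out = moving_average(np.asarray(x, float), SmoothingConfig(window_n=3))
        assert np.allclose(out, expected)

    @pytest.mark.parametrize("bad", [0, -3, 4, 2.5])
    def test_invalid_window_rejected(self, bad):
        with pytest.raises(ValueError):
            SmoothingConfig(window_n=bad)

    @given(finite_series, st.sampled_from([1, 3, 5, 9]))
    @settings(max_examples=50, deadline=None)
    def test_output_bounded_by_input_range(self, x, n):
        out = moving_average(x, SmoothingConfig(window_n=n))
        assert out.size == x.size
        assert np.all(out >= x.min() - 1e-9) and np.all(out <= x.max() + 1e-9)


class TestLengthPreservation:
    @given(finite_series)
    @settings(max_examples=50, deadline=None)
    def test_every_stage_preserves_length(self, x):
        out1, _ = remove_outliers(x)
        out2 = interpolate_blocks(x)
        out3 = moving_average(x)
        assert out1.size == out2.size == out3.size == x.size
        assert np.all(np.isfinite(out1) & np.isfinite(out2) & np.isfinite(out3))


class TestPreprocessSequence:
    def test_clean_input_is_near_fixed_point(self, quiet_noise):
        seq = static_pose(45.0, "coronal", noise=quiet_noise, n_frames=40)
        out = preprocess_sequence(seq)
        for joint in seq.joints:
            assert np.allclose(out.positions[joint], seq.positions[joint], atol=1e-9)
        assert np.array_equal(out.t, seq.t)

    def test_single_spike_removal_is_local_to_the_joint(self, quiet_noise):
        seq = static_pose(45.0, "coronal", noise=quiet_noise, n_frames=40)
        spiked_positions = {j: p.copy() for j, p in seq.positions.items()}
        spiked_positions["wrist_right"][20, 1] += 0.5
        spiked = seq.with_positions(spiked_positions)
        clean_run = preprocess_sequence(seq, return_stages=True)
        spiked_run = preprocess_sequence(spiked, return_stages=True)
        assert spiked_run.flag_counts["wrist_right"] >= 1
        # all other joints bit-identical to the spike-free run
        for joint in seq.joints:
            if joint == "wrist_right":
                continue
            assert np.array_equal(
                spiked_run.sequence.positions[joint],
                clean_run.sequence.positions[joint],
            )
        # the spike itself is gone
        assert np.allclose(
            spiked_run.sequence.positions["wrist_right"],
            clean_run.sequence.positions["wrist_right"],
            atol=1e-6,
        )

    def test_stage_retrieval(self, quiet_noise):
        seq = static_pose(30.0, "coronal", noise=quiet_noise)
        result = preprocess_sequence(seq, return_stages=True)
        assert set(result.stages) == {"raw", "deoutliered", "interpolated", "smoothed"}
        assert result.stages["raw"] == seq
        assert result.stages["smoothed"] == result.sequence

    def test_too_short_sequence_rejected(self, quiet_noise):
        seq = static_pose(30.0, "coronal", noise=quiet_noise, n_frames=2)
        with pytest.raises(SeriesTooShortError):
            preprocess_sequence(seq)
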