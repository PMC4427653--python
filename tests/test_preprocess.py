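"""Eye combination, gap interpolation, and median filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srtkit.preprocess import (
    combine_eyes,
    combine_eyes_arrays,
    interpolate_gaps,
    median_filter,
    window_ms_from_samples,
    window_samples_from_ms,
)
from srtkit.types import ConfigurationError, GazeSample

from conftest import build_trace


def sample(xl, yl, xr, yr, vl, vr, t=0):
    return GazeSample(t, xl, yl, xr, yr, vl, vr)


class TestCombineEyes:
    @pytest.mark.parametrize("s,expected", [
        (sample(0.40, 0.50, 0.44, 0.50, 0, 0), (0.42, 0.50, True)),
        (sample(None, None, 0.44, 0.50, 4, 1), (0.44, 0.50, True)),
        (sample(0.3, 0.3, 0.44, 0.50, 4, 4), (None, None, False)),
        # validity 2+ is interpolation fodder even when coordinates exist
        (sample(0.40, 0.50, 0.44, 0.50, 2, 3), (None, None, False)),
        # valid code but missing coordinates falls back to the other eye
        (sample(None, 0.5, 0.44, 0.50, 0, 0), (0.44, 0.50, True)),
    ])
    def test_combination_rules(self, s, expected):
        point = combine_eyes(s)
        assert point.is_valid is expected[2]
        if expected[2]:
            assert point.x == pytest.approx(expected[0])
            assert point.y == pytest.approx(expected[1])
        else:
            assert point.x is None and point.y is None

    def test_empty_valid_codes_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_eyes(sample(0.4, 0.5, 0.4, 0.5, 0, 0), frozenset())

    def test_array_version_matches_scalar(self):
        rng = np.random.default_rng(0)
        n = 200
        xl, yl, xr, yr = rng.random((4, n))
        xl[rng.random(n) < 0.2] = np.nan
        vl = rng.integers(0, 5, n)
        vr = rng.integers(0, 5, n)
        x, y, valid = combine_eyes_arrays(xl, yl, xr, yr, vl, vr)
        for i in range(n):
            pt = combine_eyes(sample(
                None if np.isnan(xl[i]) else xl[i], yl[i], xr[i], yr[i],
                int(vl[i]), int(vr[i])))
            assert valid[i] == pt.is_valid
            if pt.is_valid:
                assert x[i] == pytest.approx(pt.x)
            else:
                assert np.isnan(x[i])


class TestInterpolateGaps:
    def test_forward_fill_and_record_duration(self):
        trace = build_trace([0.50, 0.6, 0.6, 0.6, 0.52],
                            valid=[True, False, False, False, True])
        out, records = interpolate_gaps(trace)
        assert out.x[1:4] == pytest.approx([0.50] * 3)
        assert list(out.interpolated) == [False, True, True, True, False]
        assert len(records) == 1
        assert (records[0].start_index, records[0].end_index) == (1, 3)
        # 3 missing samples at 300 Hz count 10 ms
        assert records[0].duration_ms == pytest.approx(10.0, abs=0.01)

    def test_fully_valid_trace_is_identity(self):
        trace = build_trace(np.linspace(0.4, 0.6, 20))
        out, records = interpolate_gaps(trace)
        assert records == []
        np.testing.assert_array_equal(out.x, trace.x)
        assert not out.interpolated.any()

    def test_leading_missing_stays_missing(self):
        trace = build_trace([0.5, 0.5, 0.5, 0.51],
                            valid=[False, False, True, True])
        out, records = interpolate_gaps(trace)
        assert np.isnan(out.x[:2]).all()
        assert records == []
        assert not out.interpolated[:2].any()

    def test_all_invalid_trace_returned_unchanged(self):
        trace = build_trace([0.5] * 10, valid=[False] * 10)
        out, records = interpolate_gaps(trace)
        assert records == []
        assert not out.has_valid_data
        assert np.isnan(out.x).all()

    def test_valid_samples_never_altered(self):
        rng = np.random.default_rng(1)
        trace = build_trace(rng.random(100), valid=rng.random(100) > 0.3)
        out, _ = interpolate_gaps(trace)
        np.testing.assert_array_equal(out.x[trace.valid_raw],
                                      trace.x[trace.valid_raw])
        np.testing.assert_array_equal(out.time_us, trace.time_us)


def oracle_median(x: np.ndarray, window: int) -> np.ndarray:
    """Naive per-index median with edge-replication padding."""
    half = window // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    return np.array([np.median(padded[i:i + window]) for i in range(x.size)])


class TestMedianFilter:
    def test_constant_signal_unchanged(self):
        trace = build_trace([0.5] * 50)
        out = median_filter(trace, 7)
        np.testing.assert_array_equal(out.x, trace.x)

    def test_spike_removed(self):
        trace = build_trace([0.5, 0.5, 0.5, 0.0, 0.5, 0.5, 0.5])
        out = median_filter(trace, 5)
        assert out.x == pytest.approx([0.5] * 7)

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ConfigurationError):
            median_filter(build_trace([0.5] * 10), window)

    def test_overlong_window_rejected(self):
        with pytest.raises(ConfigurationError):
            median_filter(build_trace([0.5] * 10), 21)

    def test_flags_and_timestamps_untouched(self):
        rng = np.random.default_rng(2)
        trace = build_trace(rng.random(60), valid=rng.random(60) > 0.2)
        filled, _ = interpolate_gaps(trace)
        out = median_filter(filled, 9)
        np.testing.assert_array_equal(out.time_us, filled.time_us)
        np.testing.assert_array_equal(out.valid_raw, filled.valid_raw)
        np.testing.assert_array_equal(out.interpolated, filled.interpolated)

    def test_matches_oracle_on_random_traces(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(5, 200))
            window = int(rng.choice([1, 3, 5, 7, 37]))
            if window > 2 * n:
                continue
            x = rng.random(n)
            out = median_filter(build_trace(x), window)
            np.testing.assert_allclose(out.x, oracle_median(x, window))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10), st.integers(0, 30))
    def test_short_artifact_runs_removed_in_constant_segment(self, half, pos):
        """Any artifact run shorter than (window+1)/2 inside a constant
        segment is erased completely."""
        window = 2 * half + 1
        run = max(1, half)  # strictly shorter than (window+1)/2 = half+1? run <= half
        n = 80
        x = np.full(n, 0.5)
        start = min(pos + window, n - run - window)  # keep away from edges
        x[start:start + run] = 0.0
        out = median_filter(build_trace(x), window)
        assert out.x == pytest.approx([0.5] * n)

    def test_step_survives_with_bounded_displacement(self):
        """A clean position step passes a median filter with its midpoint
        displaced at most (window-1)/2 samples (here: not at all, since a
        monotone sequence is a fixed point of the median)."""
        for window in (3, 5, 37):
            x = np.concatenate([np.full(60, 0.5), np.full(60, 0.9)])
            out = median_filter(build_trace(x), window)
            step_in = int(np.argmax(x > 0.7))
            step_out = int(np.argmax(out.x > 0.7))
            assert abs(step_out - step_in) <= (window - 1) // 2


class TestWindowConversion:
    def test_samples_to_ms_at_300hz(self):
        assert round(window_ms_from_samples(37, 300.0)) == 123

    @pytest.mark.parametrize("ms,rate,expected", [
        (123, 300.0, 37),
        (123.33, 300.0, 37),
        (10, 300.0, 3),
        (1, 300.0, 1),
    ])
    def test_ms_to_nearest_odd_samples(self, ms, rate, expected):
        assert window_samples_from_ms(ms, rate) == expected
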