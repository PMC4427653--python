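"""Post-analysis verification checks and their composition."""

import numpy as np
import pytest

from srtkit.detect import AnalysisParams, detect_srt
from srtkit.preprocess import InterpolationRecord, interpolate_gaps, median_filter
from srtkit.types import TrialStatus
from srtkit.verify import (
    check_border_violation,
    check_durations,
    check_interpolation,
    check_min_fixation,
    records_in_analysis_period,
    verify_trial,
)

from conftest import build_trace


def nominal_trace(x=None, n_ms=2000.0, rate=300.0, **kwargs):
    n = int(round(n_ms * rate / 1e3)) + 1
    xs = np.full(n, 0.5) if x is None else x
    return build_trace(xs, rate_hz=rate, **kwargs)


class TestDurations:
    def test_nominal_phases_pass(self, params):
        assert check_durations(nominal_trace(n_ms=2200.0), params).passed

    def test_short_first_phase_fails(self, params):
        # recorded rows stop at 850 ms, resume at the second stimulus
        trace = nominal_trace(n_ms=2200.0)
        keep = (trace.time_us < 850_000) | (trace.time_us >= 1_000_000)
        assert not check_durations(trace.slice(keep), params).passed

    def test_short_second_phase_fails(self, params):
        trace = nominal_trace(n_ms=1800.0)  # second phase spans only 800 ms
        assert not check_durations(trace, params).passed

    def test_empty_trace_fails(self, params):
        trace = nominal_trace().slice(np.zeros(601, dtype=bool))
        assert not check_durations(trace, params).passed


class TestInterpolationCap:
    def test_gap_below_cap_passes(self, params):
        assert check_interpolation([InterpolationRecord(0, 56, 190.0)], params).passed

    def test_gap_above_cap_fails(self, params):
        assert not check_interpolation([InterpolationRecord(0, 68, 230.0)], params).passed

    def test_gap_entirely_after_srt_window_ignored(self, params):
        # 230-ms gap at 2,100 ms, well past second_onset + srt_max = 2,000 ms
        trace = nominal_trace(n_ms=2500.0)
        gap = (trace.time_us >= 2_100_000) & (trace.time_us <= 2_330_000)
        trace.valid_raw[gap] = False
        trace.x[gap] = np.nan
        filled, records = interpolate_gaps(trace)
        assert len(records) == 1
        assert records[0].duration_ms > params.max_gap_ms
        relevant = records_in_analysis_period(filled, records, params)
        assert relevant == []
        result = verify_trial(filled, records, detect_srt(filled, params), params)
        assert result.status is not TrialStatus.REJECTED_INTERPOLATION


def gapped_trace(x_before, x_after, gap_ms=100.0, gap_at_ms=1200.0, n_ms=2200.0):
    """Constant trace with one dropout; flanks take the given x values."""
    trace = nominal_trace(n_ms=n_ms)
    t = trace.time_us
    gap = (t >= gap_at_ms * 1e3) & (t < (gap_at_ms + gap_ms) * 1e3)
    trace.x[t < gap_at_ms * 1e3] = x_before
    trace.raw_x[t < gap_at_ms * 1e3] = x_before
    trace.x[t >= (gap_at_ms + gap_ms) * 1e3] = x_after
    trace.raw_x[t >= (gap_at_ms + gap_ms) * 1e3] = x_after
    trace.valid_raw[gap] = False
    trace.x[gap] = np.nan
    trace.raw_x[gap] = np.nan
    return trace


class TestBorderViolation:
    def test_same_region_flanks_pass(self, params):
        trace = gapped_trace(0.5, 0.52)
        filled, records = interpolate_gaps(trace)
        assert check_border_violation(filled, records, params.aoi).passed

    def test_region_change_across_gap_fails(self, params):
        trace = gapped_trace(0.5, 0.9)
        filled, records = interpolate_gaps(trace)
        assert not check_border_violation(filled, records, params.aoi).passed

    def test_second_of_two_gaps_violating_is_reported(self, params):
        trace = gapped_trace(0.5, 0.9, gap_at_ms=1500.0)
        extra = (trace.time_us >= 1_100_000) & (trace.time_us < 1_150_000)
        trace.valid_raw[extra] = False
        trace.x[extra] = np.nan
        trace.raw_x[extra] = np.nan
        filled, records = interpolate_gaps(trace)
        assert len(records) == 2
        result = check_border_violation(filled, records, params.aoi)
        assert not result.passed
        assert "gap 1" in result.detail

    def test_trailing_gap_cannot_violate(self, params):
        trace = nominal_trace(n_ms=2200.0)
        tail = trace.time_us >= 2_000_000
        trace.valid_raw[tail] = False
        trace.x[tail] = np.nan
        trace.raw_x[tail] = np.nan
        filled, records = interpolate_gaps(trace)
        assert check_border_violation(filled, records, params.aoi).passed


class TestMinFixation:
    def _trace_with_inside(self, n_inside, n_total=300):
        x = np.full(601, 0.5)
        x[n_inside:n_total] = 0.9  # push part of the first phase off-center
        return nominal_trace(x=x)

    @pytest.mark.parametrize("n_inside,expected_prop,passes", [
        (300, 1.0, True),
        (210, 0.70, True),   # inclusive bound
        (207, 0.69, False),
    ])
    def test_proportion_and_inclusive_threshold(self, params, n_inside,
                                                expected_prop, passes):
        result, prop = check_min_fixation(self._trace_with_inside(n_inside),
                                          params.aoi, params)
        assert prop == pytest.approx(expected_prop)
        assert result.passed is passes

    def test_no_samples_in_window_fails(self, params):
        trace = nominal_trace()
        late = trace.slice(trace.time_us >= 1_000_000)
        result, prop = check_min_fixation(late, params.aoi, params)
        assert not result.passed and prop is None


class TestVerifyTrial:
    def test_clean_trial_passes_through(self, params):
        x = np.full(661, 0.5)
        trace = nominal_trace(x=np.where(
            np.round(np.arange(661) * 1e6 / 300) <= 1_350_000, 0.5, 0.9),
            n_ms=2200.0)
        filled, records = interpolate_gaps(trace)
        detection = detect_srt(filled, params)
        result = verify_trial(filled, records, detection, params)
        assert result.status is TrialStatus.VALID_SHIFT
        assert result.srt_ms == pytest.approx(350.0)
        assert result.fixation_proportion == pytest.approx(1.0)

    def test_first_failed_check_sets_the_reason(self, params):
        # fails duration (first phase 850 ms) AND fixation (off-center)
        trace = nominal_trace(x=np.full(661, 0.9), n_ms=2200.0)
        keep = (trace.time_us < 850_000) | (trace.time_us >= 1_000_000)
        trace = trace.slice(keep)
        filled, records = interpolate_gaps(trace)
        result = verify_trial(filled, records, detect_srt(filled, params), params)
        assert result.status is TrialStatus.REJECTED_DURATION
        assert result.srt_ms is None

    def test_no_shift_trial_retained_with_window_max(self, params):
        trace = nominal_trace(n_ms=2200.0)
        filled, records = interpolate_gaps(trace)
        result = verify_trial(filled, records, detect_srt(filled, params), params)
        assert result.status is TrialStatus.NO_SHIFT
        assert result.srt_ms == 1000.0

    def test_idempotent(self, params):
        trace = gapped_trace(0.5, 0.9)
        filled, records = interpolate_gaps(trace)
        once = verify_trial(filled, records, detect_srt(filled, params), params)
        twice = verify_trial(filled, records, once, params)
        assert once == twice

    def test_tightening_thresholds_never_unrejects(self, params):
        """Monotone strictness: any rejected trial stays rejected under
        uniformly stricter thresholds."""
        rng = np.random.default_rng(6)
        tighter = AnalysisParams(
            max_gap_ms=120.0, min_first_ms=950.0, max_first_ms=1050.0,
            min_second_ms=1100.0, min_fixation_prop=0.85,
        )
        rejected_seen = 0
        for _ in range(60):
            x = 0.5 + rng.normal(0, 0.12, 700)
            valid = rng.random(700) > 0.15
            trace = build_trace(x, valid=valid)
            filled, records = interpolate_gaps(trace)
            loose = verify_trial(filled, records, detect_srt(filled, params), params)
            strict = verify_trial(filled, records, detect_srt(filled, tighter), tighter)
            if not loose.scorable:
                rejected_seen += 1
                assert not strict.scorable
        assert rejected_seen > 0
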