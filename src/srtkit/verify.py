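"""Post-analysis verification checks.

Four checks convert raw detections into accepted or rejected trials; the
stance throughout is rejection, not inference — a trial whose SRT cannot be
trusted is dropped with a single machine-readable reason rather than
repaired.  The fixed order (durations → interpolation → border → fixation)
runs cheap structural checks first and guarantees exactly one reason per
trial.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .detect import AnalysisParams, AOISpec, aoi_region
from .preprocess import InterpolationRecord
from .types import GazeTrace, TrialResult, TrialStatus

logger = logging.getLogger(__name__)


class CheckResult(NamedTuple):
    passed: bool
    detail: Optional[str] = None


def _phase_duration_ms(trace: GazeTrace, start_us: int, end_us: int,
                       closed_end: bool) -> float:
    """Recorded-data span within a phase, in ms.

    Counts recorded rows regardless of validity (a row with validity 4 is
    still evidence the tracker was running); span of timestamps plus one
    nominal sample period, so an uninterrupted nominal phase measures its
    nominal duration.
    """
    mask = trace.window_mask(start_us, end_us, closed_end=closed_end)
    if not mask.any():
        return 0.0
    t = trace.time_us[mask]
    return float(t[-1] - t[0]) / 1e3 + trace.period_ms


def check_durations(trace: GazeTrace, params: AnalysisParams) -> CheckResult:
    """Reject trials whose recorded data deviates from the set trial timing.

    The first-stimulus phase must span [min_first_ms, max_first_ms] and the
    second-stimulus phase at least min_second_ms of recorded samples;
    shorter spans mean the tracker or the stimulus software failed partway
    through the trial.
    """
    first_ms = _phase_duration_ms(trace, trace.first_onset, trace.second_onset,
                                  closed_end=False)
    if trace.n_samples:
        second_ms = _phase_duration_ms(trace, trace.second_onset,
                                       int(trace.time_us[-1]), closed_end=True)
    else:
        second_ms = 0.0
    if not params.min_first_ms <= first_ms <= params.max_first_ms:
        return CheckResult(False, f"first phase spans {first_ms:.1f} ms")
    if second_ms < params.min_second_ms:
        return CheckResult(False, f"second phase spans {second_ms:.1f} ms")
    return CheckResult(True)


def longest_gap_ms(records: Sequence[InterpolationRecord]) -> float:
    return max((r.duration_ms for r in records), default=0.0)


def records_in_analysis_period(trace: GazeTrace,
                               records: Sequence[InterpolationRecord],
                               params: AnalysisParams) -> List[InterpolationRecord]:
    """Gaps overlapping [first_onset, second_onset + srt_max].

    A gap entirely outside the analysis period cannot corrupt the SRT and
    is ignored by the interpolation-cap and border checks.
    """
    start = trace.first_onset
    end = trace.second_onset + int(round(params.srt_max_ms * 1e3))
    return [
        r for r in records
        if trace.time_us[r.end_index] >= start and trace.time_us[r.start_index] <= end
    ]


def check_interpolation(records: Sequence[InterpolationRecord],
                        params: AnalysisParams) -> CheckResult:
    """Reject trials containing an over-long forward-filled gap.

    ``records`` must already be restricted to gaps overlapping the analysis
    period (they are, when produced on a segmented trace).  A gap longer
    than the cap could hide a complete central–lateral–central excursion,
    turning a real shift into an apparent fixation.
    """
    worst = longest_gap_ms(records)
    if worst > params.max_gap_ms:
        return CheckResult(False, f"longest interpolated gap {worst:.1f} ms")
    return CheckResult(True)


def check_border_violation(trace: GazeTrace,
                           records: Sequence[InterpolationRecord],
                           spec: AOISpec) -> CheckResult:
    """Detect AOI transitions hidden inside interpolated segments.

    For each filled gap, the AOI region of the last valid raw sample before
    the gap is compared with that of the first valid raw sample after it;
    interpolation is only acceptable if gaze stayed in the same region
    throughout, otherwise a shift happened at an unknowable time and the
    trial is rejected.  Raw (pre-interpolation) samples are used on both
    flanks — comparing interpolated values would make a violation
    undetectable by construction.  A gap running to the end of the trace
    has no trailing flank and cannot violate.
    """
    valid_idx = np.nonzero(trace.valid_raw)[0]
    for k, rec in enumerate(records):
        before_candidates = valid_idx[valid_idx < rec.start_index]
        after_candidates = valid_idx[valid_idx > rec.end_index]
        if before_candidates.size == 0 or after_candidates.size == 0:
            logger.debug("gap %d has no flanking valid sample; cannot violate", k)
            continue
        rb = aoi_region(trace.raw_x[before_candidates[-1]], spec)
        ra = aoi_region(trace.raw_x[after_candidates[0]], spec)
        if rb != ra:
            return CheckResult(False, f"gap {k} crosses AOI border")
    return CheckResult(True)


def check_min_fixation(trace: GazeTrace, spec: AOISpec,
                       params: AnalysisParams) -> Tuple[CheckResult, Optional[float]]:
    """Require sufficient fixation of the first stimulus before the saccade.

    The fixation proportion is the fraction of samples inside the central
    AOI during the first-stimulus window [first_onset, second_onset),
    counting interpolated samples, over all samples in that window.  The
    comparison is inclusive: exactly the threshold passes.
    """
    mask = trace.window_mask(trace.first_onset, trace.second_onset,
                             closed_end=False)
    n = int(mask.sum())
    if n == 0:
        return CheckResult(False, "no samples in first-stimulus window"), None
    x = trace.x[mask]
    inside = np.isfinite(x) & (x >= spec.edge_threshold) & (x <= 1.0 - spec.edge_threshold)
    prop = float(inside.sum()) / n
    if prop < params.min_fixation_prop:
        return CheckResult(False, f"fixation proportion {prop:.3f}"), prop
    return CheckResult(True), prop


def verify_trial(trace: GazeTrace,
                 records: Sequence[InterpolationRecord],
                 detection: TrialResult,
                 params: AnalysisParams) -> TrialResult:
    """Apply the four checks in fixed order to a detection result.

    The first failing check sets the trial status and clears the SRT; when
    all pass, the detection's own status (scorable or detection-level
    rejection) stands.  Idempotent: re-verifying a verified result changes
    nothing, because the checks depend only on the trace and records.
    """
    spec = params.aoi
    fixation_check, fixation_prop = check_min_fixation(trace, spec, params)
    relevant = records_in_analysis_period(trace, records, params)
    worst_gap = longest_gap_ms(relevant)

    status: Optional[TrialStatus] = None
    if not check_durations(trace, params).passed:
        status = TrialStatus.REJECTED_DURATION
    elif not check_interpolation(relevant, params).passed:
        status = TrialStatus.REJECTED_INTERPOLATION
    elif not check_border_violation(trace, relevant, spec).passed:
        status = TrialStatus.REJECTED_BORDER
    elif not fixation_check.passed:
        status = TrialStatus.REJECTED_FIXATION

    if status is None:
        status = detection.status
        srt_ms = detection.srt_ms
    else:
        srt_ms = None
    return dataclasses.replace(
        detection,
        srt_ms=srt_ms,
        status=status,
        longest_gap_ms=worst_gap,
        fixation_proportion=fixation_prop,
    )
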