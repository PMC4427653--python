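"""Trial-level data-quality metrics and the median-split sensitivity experiment.

Two quality indices are computed per trial, on the raw (pre-interpolation)
stream:

* **precision** — sample-to-sample consistency of the reported gaze
  position during fixation, measured as the root-mean-square Euclidean
  distance between consecutive valid raw samples (pairs never span a
  dropout).  Under white positional noise of sd σ per axis the expected
  RMS is 2σ.  A degree conversion is available via a linear small-angle
  mapping: degrees = normalized units x display span (default 46°).
* **robustness** — continuity of tracking, operationalized as the
  proportion of unavailable samples per trial.

The sensitivity experiment asks whether SRT accuracy depends on these
indices: trials are median-split into high/low quality on each metric and
the count of large SRT errors (detected vs. reference latency differing by
more than 100 ms) is compared across halves with Pearson's chi-square.
Run with the full pipeline, accuracy should be independent of quality; run
the "typical" way — no interpolation, no filtering, no verification
checks, narrower AOI margins — low-quality trials show significantly more
large errors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .detect import AnalysisParams, detect_srt
from .preprocess import interpolate_gaps, median_filter, _runs
from .types import SCORABLE, GazeTrace, TrialResult, TrialStatus
from .verify import verify_trial

DEFAULT_DISPLAY_SPAN_DEG = 46.0
LARGE_ERROR_MS = 100.0
#: symmetric widening of the edge threshold in "typical" mode: the AOI
#: margin around the central image shrinks from 2.7° to 1°, i.e. the
#: central band loses 1.7° of slack on each side of a 46°-wide display.
TYPICAL_MARGIN_REDUCTION_DEG = 2.7 - 1.0


@dataclass
class QualityReport:
    """Per-trial data-quality metrics."""

    precision_rms: Optional[float]
    robustness_missing_prop: float
    segment_durations_ms: List[float]

    def precision_deg(self, display_span_deg: float = DEFAULT_DISPLAY_SPAN_DEG
                      ) -> Optional[float]:
        if self.precision_rms is None:
            return None
        return self.precision_rms * display_span_deg


def excerpt_quality_segment(trace: GazeTrace, result: TrialResult) -> GazeTrace:
    """Samples from trial start to the detected saccade, else the first 2 s.

    Quality is judged on the pre-saccadic fixation period; when no shift
    was detected (or the trial was rejected) the first 2,000 ms stand in,
    clipped to the trace.
    """
    if result.status is TrialStatus.VALID_SHIFT and result.srt_ms is not None:
        end = trace.second_onset + int(round(result.srt_ms * 1e3))
    else:
        end = trace.first_onset + 2_000_000
    return trace.slice(trace.window_mask(trace.first_onset, end))


def precision_rms(segment: GazeTrace) -> Optional[float]:
    """RMS Euclidean distance between consecutive valid raw samples.

    Pairs are consecutive in recording order; pairs spanning a dropout are
    excluded.  Fewer than two usable pairs → absent.
    """
    v = segment.valid_raw
    if v.size < 2:
        return None
    pair = v[:-1] & v[1:]
    if int(pair.sum()) < 2:
        return None
    dx = np.diff(segment.raw_x)[pair]
    dy = np.diff(segment.raw_y)[pair]
    return float(np.sqrt(np.mean(dx ** 2 + dy ** 2)))


def robustness(segment: GazeTrace) -> float:
    """Proportion of unavailable (not valid-raw) samples in the segment."""
    if segment.n_samples == 0:
        raise ValueError("robustness is undefined for an empty segment")
    return float((~segment.valid_raw).mean())


def segment_durations(trace: GazeTrace) -> List[float]:
    """Durations (ms) of maximal runs of valid raw samples.

    Each run counts one nominal sample period per sample, so 300 uninterrupted
    samples at 300 Hz make one 1,000-ms segment.
    """
    return [
        (end - start + 1) * trace.period_ms
        for start, end in _runs(trace.valid_raw)
    ]


def quality_report(trace: GazeTrace, result: TrialResult) -> QualityReport:
    segment = excerpt_quality_segment(trace, result)
    return QualityReport(
        precision_rms=precision_rms(segment),
        robustness_missing_prop=robustness(segment) if segment.n_samples else 1.0,
        segment_durations_ms=segment_durations(trace),
    )


# ---------------------------------------------------------------------------
# median-split sensitivity experiment


@dataclass
class SplitResult:
    """2x2 association of one quality metric with large SRT errors."""

    metric: str
    mode: str
    table: Optional[np.ndarray]  # rows: low/high quality; cols: large/small error
    chi2: Optional[float]
    p_value: Optional[float]
    reason: Optional[str] = None

    @property
    def large_error_rate_low(self) -> Optional[float]:
        return self._rate(0)

    @property
    def large_error_rate_high(self) -> Optional[float]:
        return self._rate(1)

    def _rate(self, row: int) -> Optional[float]:
        if self.table is None or self.table[row].sum() == 0:
            return None
        return float(self.table[row, 0] / self.table[row].sum())


def pearson_chi2(table: np.ndarray) -> Tuple[Optional[float], Optional[float], Optional[str]]:
    """Pearson chi-square without continuity correction; degenerate → absent."""
    table = np.asarray(table, dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return None, None, "degenerate table (empty row or column)"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), None


def median_split(values: np.ndarray) -> np.ndarray:
    """True where a trial falls in the low-quality half.

    Both metrics are "higher is worse"; ties at the median go to the
    low-quality group — a fixed rule for reproducibility.
    """
    values = np.asarray(values, dtype=float)
    return values >= np.median(values)


def analyze_trial_in_mode(trace: GazeTrace, params: AnalysisParams,
                          mode: str) -> TrialResult:
    """Run one trial through the pipeline in ``full`` or ``typical`` mode.

    ``full`` applies interpolation, median filtering and all four
    verification checks.  ``typical`` emulates a naive analysis: raw
    combined gaze, no preprocessing, no checks, and an AOI narrowed by
    :data:`TYPICAL_MARGIN_REDUCTION_DEG` on each side.
    """
    if mode == "full":
        filled, records = interpolate_gaps(trace)
        filtered = median_filter(filled, params.filter_window_samples)
        detection = detect_srt(filtered, params)
        return verify_trial(filtered, records, detection, params)
    if mode == "typical":
        narrowed = params.replace(
            edge_threshold=params.edge_threshold
            + TYPICAL_MARGIN_REDUCTION_DEG / DEFAULT_DISPLAY_SPAN_DEG
        )
        return detect_srt(trace, narrowed)
    raise ValueError(f"unknown mode {mode!r}")


def quality_split_experiment(dataset: Sequence[Tuple[GazeTrace, "object"]],
                             params: AnalysisParams,
                             mode: str) -> Dict[str, SplitResult]:
    """Median-split large-error comparison over a ground-truthed dataset.

    ``dataset`` pairs each raw trace with its ground truth (any object with
    ``true_srt_ms``; None means a programmed no-shift trial, referenced at
    the window maximum).  Returns one :class:`SplitResult` per quality
    metric.  Trials whose analysis yields no SRT (rejections) carry no
    error and drop out of the comparison — exactly what the verification
    checks are for in ``full`` mode.
    """
    errors: List[float] = []
    precisions: List[float] = []
    robustnesses: List[float] = []
    for trace, truth in dataset:
        result = analyze_trial_in_mode(trace, params, mode)
        if result.status not in SCORABLE or result.srt_ms is None:
            continue
        reference = truth.true_srt_ms
        if reference is None:
            reference = params.srt_max_ms
        report = quality_report(trace, result)
        if report.precision_rms is None:
            continue
        errors.append(abs(result.srt_ms - reference))
        precisions.append(report.precision_rms)
        robustnesses.append(report.robustness_missing_prop)

    large = np.asarray(errors) > LARGE_ERROR_MS
    out: Dict[str, SplitResult] = {}
    for metric, values in (("precision", precisions), ("robustness", robustnesses)):
        if not errors:
            out[metric] = SplitResult(metric, mode, None, None, None,
                                      reason="no scorable trials")
            continue
        low = median_split(np.asarray(values))
        table = np.array([
            [int((large & low).sum()), int((~large & low).sum())],
            [int((large & ~low).sum()), int((~large & ~low).sum())],
        ])
        chi2, p, reason = pearson_chi2(table)
        out[metric] = SplitResult(metric, mode, table, chi2, p, reason)
    return out


def write_experiment(results: Dict[str, Dict[str, SplitResult]],
                     path: Union[str, Path]) -> None:
    """Write split-experiment results (one row per metric x mode) as CSV."""
    rows = []
    for mode, per_metric in results.items():
        for metric, r in per_metric.items():
            cells = (r.table.ravel().tolist() if r.table is not None
                     else [None] * 4)
            rows.append({
                "metric": metric, "mode": mode,
                "low_large": cells[0], "low_small": cells[1],
                "high_large": cells[2], "high_small": cells[3],
                "chi2": r.chi2, "p_value": r.p_value, "reason": r.reason,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
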