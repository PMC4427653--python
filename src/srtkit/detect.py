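"""Area-of-interest definition and saccadic reaction time detection.

The SRT is measured in a two-stimulus paradigm: a central stimulus, then a
lateral target with a fixed onset asynchrony.  Detection operates on the
preprocessed (interpolated + median-filtered) horizontal coordinate only —
in these paradigms both stimuli sit on the horizontal midline, so the
vertical coordinate carries no information about the shift and is retained
only for quality metrics.

The SRT is the time of the last sample inside the central AOI before the
first boundary crossing within the analysis window, relative to the lateral
stimulus onset.  A trial on which gaze never leaves the central AOI within
the window is scored at the window maximum and flagged ``no_shift`` — a
missing saccade, still a scorable outcome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import FrozenSet

import numpy as np

from .preprocess import DEFAULT_VALID_CODES
from .types import (
    ConfigurationError,
    GazeTrace,
    Side,
    TrialResult,
    TrialStatus,
)

__all__ = [
    "AOISpec",
    "AnalysisParams",
    "in_central_aoi",
    "aoi_region",
    "detect_srt",
]


@dataclass(frozen=True)
class AOISpec:
    """Central area of interest: x within ``edge_threshold`` of neither edge.

    ``edge_threshold`` is a fraction of the normalized horizontal extent
    (default 0.30, i.e. the central band x in [0.30, 0.70]).  Boundary
    samples count as inside; one convention applied everywhere.
    """

    edge_threshold: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_threshold < 0.5:
            raise ConfigurationError(
                f"edge_threshold must lie strictly between 0 and 0.5, got {self.edge_threshold}"
            )


def in_central_aoi(x, spec: AOISpec):
    """True where x lies in the central AOI (closed boundaries). NaN → False."""
    x = np.asarray(x, dtype=float)
    result = (x >= spec.edge_threshold) & (x <= 1.0 - spec.edge_threshold)
    if result.ndim == 0:
        return bool(result)
    return result


def aoi_region(x, spec: AOISpec):
    """Classify x into -1 (left of center), 0 (central), +1 (right). NaN → NaN."""
    x = np.asarray(x, dtype=float)
    region = np.where(x < spec.edge_threshold, -1.0,
                      np.where(x > 1.0 - spec.edge_threshold, 1.0, 0.0))
    region = np.where(np.isnan(x), np.nan, region)
    if region.ndim == 0:
        return float(region)
    return region


@dataclass(frozen=True)
class AnalysisParams:
    """All user-defined thresholds for the SRT analysis.

    Durations are milliseconds throughout.  The defaults are the settings
    for a 300-Hz overlap/gap paradigm with a 1,000-ms stimulus onset
    asynchrony:

    valid_codes
        tracker validity codes accepted as reliable gaze (0 and 1).
    filter_window_samples
        moving-median length in samples; 37 samples span 123 ms at 300 Hz,
        long enough to remove spike artifacts but shorter than a saccade's
        programming time, so real shifts survive.
    max_gap_ms
        longest forward-filled gap tolerated inside the analysis period.
    min_first_ms / max_first_ms
        accepted recorded duration of the first-stimulus phase.
    min_second_ms
        minimum recorded duration of the second-stimulus phase.
    min_fixation_prop
        minimum fraction of first-phase samples (interpolated included)
        inside the central AOI; inclusive comparison.
    srt_min_ms / srt_max_ms
        the acceptance window for disengagement times; shifts faster than
        srt_min_ms are anticipatory, and srt_max_ms is both the scan limit
        and the latency assigned to no-shift trials.
    edge_threshold
        central-AOI margin from either screen edge (fraction of width).
    min_scorable_trials
        per subject x condition, summaries with fewer scorable trials are
        flagged insufficient.
    """

    valid_codes: FrozenSet[int] = DEFAULT_VALID_CODES
    filter_window_samples: int = 37
    max_gap_ms: float = 200.0
    min_first_ms: float = 900.0
    max_first_ms: float = 1100.0
    min_second_ms: float = 1000.0
    min_fixation_prop: float = 0.70
    srt_min_ms: float = 150.0
    srt_max_ms: float = 1000.0
    edge_threshold: float = 0.30
    min_scorable_trials: int = 3

    def __post_init__(self) -> None:
        if not self.srt_min_ms < self.srt_max_ms:
            raise ConfigurationError("srt_min_ms must be below srt_max_ms")
        if not 0.0 < self.min_fixation_prop <= 1.0:
            raise ConfigurationError("min_fixation_prop must lie in (0, 1]")
        if self.min_first_ms > self.max_first_ms:
            raise ConfigurationError("min_first_ms must not exceed max_first_ms")
        AOISpec(self.edge_threshold)  # validates the threshold range
        object.__setattr__(self, "valid_codes", frozenset(self.valid_codes))

    @property
    def aoi(self) -> AOISpec:
        return AOISpec(self.edge_threshold)

    def replace(self, **kwargs) -> "AnalysisParams":
        return dataclasses.replace(self, **kwargs)


def detect_srt(trace: GazeTrace, params: AnalysisParams) -> TrialResult:
    """Detect the SRT on a preprocessed trace.

    Scans the analysis window [second_onset, second_onset + srt_max_ms] for
    the first sample outside the central AOI.  The SRT is the latency of
    the last in-AOI sample preceding that departure (which may precede the
    window, in which case the shift is anticipatory).  Departures on the
    non-target side are rejected rather than scored.  Samples that are
    still missing (no coordinates even after interpolation) can neither
    depart nor serve as the in-AOI reference.

    Only the detection-level statuses are assigned here; the post-analysis
    verification checks run later and may override a scorable status.
    """
    spec = params.aoi
    t = trace.time_us
    onset = trace.second_onset
    window_end = onset + int(round(params.srt_max_ms * 1e3))
    in_window = (t >= onset) & (t <= window_end)
    base = dict(
        subject_id=trace.subject_id,
        trial_number=trace.trial_number,
        condition=trace.condition,
        target_side=trace.target_side,
    )
    if not in_window.any():
        return TrialResult(srt_ms=None, status=TrialStatus.REJECTED_DURATION, **base)

    x = trace.x
    thr = spec.edge_threshold
    window_idx = np.nonzero(in_window)[0]
    xw = x[window_idx]
    outside = np.isfinite(xw) & ((xw < thr) | (xw > 1.0 - thr))
    if not outside.any():
        return TrialResult(srt_ms=params.srt_max_ms, status=TrialStatus.NO_SHIFT, **base)

    departure = int(window_idx[np.argmax(outside)])
    exit_side = Side.LEFT if x[departure] < thr else Side.RIGHT

    # last in-AOI sample anywhere before the departure
    before = x[:departure]
    inside_before = np.isfinite(before) & (before >= thr) & (before <= 1.0 - thr)
    if not inside_before.any():
        # gaze was never observed in the central AOI before leaving it
        return TrialResult(srt_ms=None, status=TrialStatus.REJECTED_ANTICIPATORY, **base)
    last_inside = int(np.nonzero(inside_before)[0][-1])
    srt_ms = float(t[last_inside] - onset) / 1e3

    if srt_ms < params.srt_min_ms:
        return TrialResult(srt_ms=None, status=TrialStatus.REJECTED_ANTICIPATORY, **base)
    if exit_side != trace.target_side:
        return TrialResult(srt_ms=None, status=TrialStatus.REJECTED_WRONG_DIRECTION, **base)
    return TrialResult(srt_ms=srt_ms, status=TrialStatus.VALID_SHIFT, **base)
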