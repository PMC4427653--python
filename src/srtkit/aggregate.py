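"""Per-condition mean SRTs and the dwell-time SRT index.

Two subject x condition summaries are computed.  The mean SRT uses valid
gaze shifts only, which discards no-shift trials — a problem in demanding
conditions where missing saccades are common and informative.  The SRT
index therefore folds shift and no-shift trials onto one 0–1 scale: the
mean proportion of the acceptance window [srt_min, srt_max] during which
gaze dwelt on the first stimulus,

    index = (1/n) * sum_i (1 - (srt_max - x_i) / (srt_max - srt_min))
          = mean_i (x_i - srt_min) / (srt_max - srt_min),

where x_i is trial i's latency (a no-shift trial contributes srt_max) and
n counts scorable trials.  With the default 150–1,000-ms window, a set of
all-minimum latencies scores 0 and a set of all-missing saccades scores 1.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .detect import AnalysisParams
from .types import SCORABLE, TrialResult, TrialStatus

logger = logging.getLogger(__name__)


@dataclass
class ConditionSummary:
    """Aggregated results for one subject in one stimulus condition."""

    subject_id: str
    condition: str
    n_valid_shift: int
    n_no_shift: int
    n_rejected: int
    rejected_by_reason: Dict[str, int] = field(default_factory=dict)
    mean_srt_ms: Optional[float] = None
    srt_index: Optional[float] = None
    insufficient: bool = False

    @property
    def n_scorable(self) -> int:
        return self.n_valid_shift + self.n_no_shift

    @property
    def n_analyzed(self) -> int:
        return self.n_scorable + self.n_rejected


def mean_srt(results: Sequence[TrialResult]) -> Optional[float]:
    """Mean latency over valid gaze shifts; no-shift and rejected excluded."""
    latencies = [r.srt_ms for r in results if r.status is TrialStatus.VALID_SHIFT]
    if not latencies:
        return None
    return sum(latencies) / len(latencies)


def srt_index(results: Sequence[TrialResult],
              params: AnalysisParams) -> Optional[float]:
    """Dwell-time index over scorable trials, in [0, 1].

    Rejected trials are ignored; anticipatory shifts are rejected upstream,
    so every scorable latency is at least srt_min and the index cannot go
    negative — asserted, never clamped.
    """
    span = params.srt_max_ms - params.srt_min_ms
    total = 0.0
    n = 0
    for r in results:
        if r.status not in SCORABLE:
            continue
        x_i = r.srt_ms
        assert x_i is not None and x_i >= params.srt_min_ms, (
            f"scorable latency {x_i} below window minimum {params.srt_min_ms}"
        )
        total += 1.0 - (params.srt_max_ms - x_i) / span
        n += 1
    if n == 0:
        logger.info("srt_index undefined: no scorable trials")
        return None
    return total / n


def summarize(results: Sequence[TrialResult],
              params: AnalysisParams) -> List[ConditionSummary]:
    """One summary per subject x condition, in first-appearance order.

    Groups with fewer scorable trials than ``params.min_scorable_trials``
    are flagged insufficient (their numbers are still reported).
    """
    groups: Dict[Tuple[str, str], List[TrialResult]] = {}
    for r in results:
        groups.setdefault((r.subject_id, r.condition), []).append(r)
    summaries: List[ConditionSummary] = []
    for (subject, condition), rs in groups.items():
        reasons = Counter(
            r.status.value for r in rs if r.status not in SCORABLE
        )
        summary = ConditionSummary(
            subject_id=subject,
            condition=condition,
            n_valid_shift=sum(r.status is TrialStatus.VALID_SHIFT for r in rs),
            n_no_shift=sum(r.status is TrialStatus.NO_SHIFT for r in rs),
            n_rejected=sum(r.status not in SCORABLE for r in rs),
            rejected_by_reason=dict(reasons),
            mean_srt_ms=mean_srt(rs),
            srt_index=srt_index(rs, params),
        )
        summary.insufficient = summary.n_scorable < params.min_scorable_trials
        summaries.append(summary)
    return summaries
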