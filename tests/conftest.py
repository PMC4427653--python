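"""Shared fixtures and trace-construction helpers."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pytest

from srtkit.detect import AnalysisParams
from srtkit.types import GazeTrace, Side, TrialResult, TrialStatus


def build_trace(x: Sequence[float], *,
                rate_hz: float = 300.0,
                first_onset: int = 0,
                second_onset: int = 1_000_000,
                target_side: str = "right",
                valid: Optional[Sequence[bool]] = None,
                y: Optional[Sequence[float]] = None,
                subject_id: str = "s01",
                trial_number: int = 1,
                condition: str = "overlap") -> GazeTrace:
    """Trace on a nominal sample grid with x given and y constant by default.

    Invalid samples get NaN coordinates regardless of the supplied x so the
    trace satisfies the raw-data invariant (missing means absent).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t = np.round(np.arange(n) * 1e6 / rate_hz).astype(np.int64) + first_onset
    valid = (np.ones(n, dtype=bool) if valid is None
             else np.asarray(valid, dtype=bool))
    x = np.where(valid, x, np.nan)
    y = (np.full(n, 0.5) if y is None else np.asarray(y, dtype=float))
    y = np.where(valid, y, np.nan)
    return GazeTrace(
        subject_id=subject_id, trial_number=trial_number, condition=condition,
        target_side=Side(target_side), first_onset=first_onset,
        second_onset=second_onset, rate_hz=rate_hz,
        time_us=t, x=x.copy(), y=y.copy(), valid_raw=valid,
        interpolated=np.zeros(n, dtype=bool),
        raw_x=x.copy(), raw_y=y.copy(),
    )


def make_result(srt_ms=None, status=TrialStatus.VALID_SHIFT, **kwargs) -> TrialResult:
    defaults = dict(subject_id="s01", trial_number=1, condition="overlap",
                    target_side=Side.RIGHT)
    defaults.update(kwargs)
    return TrialResult(srt_ms=srt_ms, status=status, **defaults)


@pytest.fixture
def params() -> AnalysisParams:
    return AnalysisParams()
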