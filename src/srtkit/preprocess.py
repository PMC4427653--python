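"""Eye combination, gap interpolation, and median filtering.

Raw corneal-reflection data from poorly cooperating participants (infants,
clinical groups) shows two stereotyped pathologies: short dropouts where the
tracker loses both eyes, and brief large-amplitude spike artifacts where the
reported gaze jumps across the screen for a few milliseconds.  The remedies
implemented here are deliberately simple and fully book-kept:

* missing samples are continued forward from the last recorded position,
  whatever the gap duration — a post-analysis check later rejects trials
  whose longest filled gap exceeds a user cap;
* a moving median filter of user-chosen odd length removes spikes without
  displacing the abrupt coordinate step that marks a saccade (the median of
  a monotone window is its central element, so steps pass through intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, NamedTuple, Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import ConfigurationError, GazeSample, GazeTrace

DEFAULT_VALID_CODES: FrozenSet[int] = frozenset({0, 1})


class CombinedPoint(NamedTuple):
    x: Optional[float]
    y: Optional[float]
    is_valid: bool


@dataclass(frozen=True)
class InterpolationRecord:
    """One maximal forward-filled gap, as inclusive sample indices.

    ``duration_ms`` counts one nominal sample period per missing sample
    (span of timestamps plus one period), so a 3-sample gap at 300 Hz is
    10 ms regardless of timestamp jitter.
    """

    start_index: int
    end_index: int
    duration_ms: float


def _eye_ok(x: Optional[float], y: Optional[float], validity: int,
            valid_codes: FrozenSet[int]) -> bool:
    if validity not in valid_codes:
        return False
    if x is None or y is None:
        return False
    return bool(np.isfinite(x) and np.isfinite(y))


def combine_eyes(sample: GazeSample,
                 valid_codes: FrozenSet[int] = DEFAULT_VALID_CODES) -> CombinedPoint:
    """Combine the two eyes of one raw sample into a single gaze point.

    Both eyes valid: arithmetic mean of the coordinates.  Exactly one eye
    valid: that eye's coordinates.  Neither: an invalid point with absent
    coordinates.  Total function — never raises.
    """
    if not valid_codes:
        raise ConfigurationError("valid_codes must be nonempty")
    left = _eye_ok(sample.x_left, sample.y_left, sample.validity_left, valid_codes)
    right = _eye_ok(sample.x_right, sample.y_right, sample.validity_right, valid_codes)
    if left and right:
        return CombinedPoint((sample.x_left + sample.x_right) / 2.0,
                             (sample.y_left + sample.y_right) / 2.0, True)
    if left:
        return CombinedPoint(sample.x_left, sample.y_left, True)
    if right:
        return CombinedPoint(sample.x_right, sample.y_right, True)
    return CombinedPoint(None, None, False)


def combine_eyes_arrays(x_left, y_left, x_right, y_right,
                        validity_left, validity_right,
                        valid_codes: FrozenSet[int] = DEFAULT_VALID_CODES
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`combine_eyes` over parallel per-eye arrays.

    Missing coordinates are NaN on input and output.
    """
    if not valid_codes:
        raise ConfigurationError("valid_codes must be nonempty")
    xl = np.asarray(x_left, dtype=float)
    yl = np.asarray(y_left, dtype=float)
    xr = np.asarray(x_right, dtype=float)
    yr = np.asarray(y_right, dtype=float)
    vl = np.isin(np.asarray(validity_left), list(valid_codes))
    vr = np.isin(np.asarray(validity_right), list(valid_codes))
    left_ok = vl & np.isfinite(xl) & np.isfinite(yl)
    right_ok = vr & np.isfinite(xr) & np.isfinite(yr)
    both = left_ok & right_ok
    x = np.full(xl.shape, np.nan)
    y = np.full(yl.shape, np.nan)
    x[left_ok] = xl[left_ok]
    y[left_ok] = yl[left_ok]
    x[right_ok & ~left_ok] = xr[right_ok & ~left_ok]
    y[right_ok & ~left_ok] = yr[right_ok & ~left_ok]
    x[both] = (xl[both] + xr[both]) / 2.0
    y[both] = (yl[both] + yr[both]) / 2.0
    return x, y, left_ok | right_ok


def interpolate_gaps(trace: GazeTrace) -> Tuple[GazeTrace, List[InterpolationRecord]]:
    """Fill missing samples by continuing the last recorded gaze forward.

    Applied to all periods of missing data regardless of their duration;
    the per-gap records allow a later check to reject trials whose longest
    gap exceeds the user cap.  A leading run with no valid predecessor is
    left missing (there is nothing to continue) and produces no record.

    A trace with no valid samples at all is returned unchanged with an
    empty record list; ``trace.has_valid_data`` is False in that case and
    every downstream check rejects it.
    """
    out = trace.copy()
    valid = out.valid_raw
    n = out.n_samples
    if n == 0 or not valid.any():
        return out, []
    idx = np.where(valid, np.arange(n), -1)
    last_valid = np.maximum.accumulate(idx)
    fill = (~valid) & (last_valid >= 0)
    out.x[fill] = out.x[last_valid[fill]]
    out.y[fill] = out.y[last_valid[fill]]
    out.interpolated = fill
    records: List[InterpolationRecord] = []
    for start, end in _runs(fill):
        span_us = float(out.time_us[end] - out.time_us[start])
        duration_ms = span_us / 1e3 + out.period_ms
        records.append(InterpolationRecord(start, end, duration_ms))
    return out, records


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    diff = np.diff(m.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0])
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size - 1)
    return list(zip(starts, ends))


def median_filter(trace: GazeTrace, window_samples: int) -> GazeTrace:
    """Moving median filter of odd length, in samples.

    Both ends of the analysis period are virtually extended by replicating
    the first/last available sample, so the filter covers the whole period.
    x and y are filtered independently; timestamps and validity flags are
    untouched.  The trace must already be gap-free in its interior (run
    :func:`interpolate_gaps` first); a leading run of still-missing samples
    is left missing and the filter starts at the first available one.
    """
    window_samples = int(window_samples)
    if window_samples < 1 or window_samples % 2 == 0:
        raise ConfigurationError(
            f"median filter window must be a positive odd sample count, got {window_samples}"
        )
    if trace.n_samples and window_samples > 2 * trace.n_samples:
        raise ConfigurationError(
            f"median filter window ({window_samples}) longer than twice the "
            f"trace ({trace.n_samples} samples)"
        )
    out = trace.copy()
    finite = np.isfinite(out.x)
    if not finite.any():
        return out
    start = int(np.argmax(finite))
    for arr in (out.x, out.y):
        arr[start:] = ndimage.median_filter(
            arr[start:], size=window_samples, mode="nearest"
        )
    return out


def window_samples_from_ms(window_ms: float, rate_hz: float) -> int:
    """Convert a filter length in milliseconds to the nearest odd sample count."""
    n = max(1, round(window_ms * rate_hz / 1e3))
    if n % 2 == 0:
        # choose the nearer odd neighbour
        lo, hi = n - 1, n + 1
        n = lo if abs(lo * 1e3 / rate_hz - window_ms) <= abs(hi * 1e3 / rate_hz - window_ms) else hi
    return int(n)


def window_ms_from_samples(window_samples: int, rate_hz: float) -> float:
    """Duration in milliseconds spanned by a filter window in samples."""
    return window_samples * 1e3 / rate_hz
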