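"""Core data containers shared across the pipeline.

Time is stored internally in integer microseconds; every user-facing
threshold is expressed in milliseconds and converted once at the module
boundary.  Gaze coordinates are normalized screen fractions with the origin
at the top-left edge (0 = left/top, 1 = right/bottom); trackers may report
estimates slightly outside [0, 1] for off-screen gaze, so no clamping is
applied anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

US_PER_MS = 1000


class ConfigurationError(ValueError):
    """A user parameter or column mapping is invalid."""


class GazeLogError(ValueError):
    """A raw gaze log violates a structural requirement (e.g. time order)."""


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class TrialStatus(str, Enum):
    """Outcome of the SRT analysis for one trial.

    ``VALID_SHIFT`` and ``NO_SHIFT`` are the two scorable outcomes; every
    ``REJECTED_*`` status names the first failed verification (or detection)
    check, so each trial carries exactly one rejection reason.
    """

    VALID_SHIFT = "valid_shift"
    NO_SHIFT = "no_shift"
    REJECTED_DURATION = "rejected_duration"
    REJECTED_INTERPOLATION = "rejected_interpolation"
    REJECTED_BORDER = "rejected_border"
    REJECTED_FIXATION = "rejected_fixation"
    REJECTED_ANTICIPATORY = "rejected_anticipatory"
    REJECTED_WRONG_DIRECTION = "rejected_wrong_direction"


#: statuses for which an SRT value is defined
SCORABLE = frozenset({TrialStatus.VALID_SHIFT, TrialStatus.NO_SHIFT})


@dataclass(frozen=True)
class GazeSample:
    """One time-stamped raw sample with per-eye coordinates and validity.

    ``time`` is microseconds since recording start.  Missing coordinates are
    ``None`` (never 0).  Validity codes follow the Tobii convention: 0 is
    certainly tracked, 4 is untracked.
    """

    time: int
    x_left: Optional[float]
    y_left: Optional[float]
    x_right: Optional[float]
    y_right: Optional[float]
    validity_left: int
    validity_right: int
    marker: str = ""


@dataclass
class GazeTrace:
    """One trial's combined-gaze sample sequence plus stimulus timing.

    The per-sample arrays are parallel and sorted by time:

    ``x``, ``y``
        working coordinates; raw after segmentation, then gap-filled by
        interpolation, then median-filtered.  NaN where missing.
    ``raw_x``, ``raw_y``
        the combined but otherwise untouched coordinates, kept for the
        border-violation check and the data-quality metrics.
    ``valid_raw``
        True where the tracker delivered an accepted validity code for at
        least one eye.
    ``interpolated``
        True where a missing sample was filled by forward continuation.

    Each sample is therefore in exactly one of three states: valid-raw,
    interpolated, or missing.
    """

    subject_id: str
    trial_number: int
    condition: str
    target_side: Side
    first_onset: int
    second_onset: int
    rate_hz: float
    time_us: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid_raw: np.ndarray
    interpolated: np.ndarray
    raw_x: np.ndarray
    raw_y: np.ndarray

    def __post_init__(self) -> None:
        self.target_side = Side(self.target_side)
        self.time_us = np.asarray(self.time_us, dtype=np.int64)
        for name in ("x", "y", "raw_x", "raw_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("valid_raw", "interpolated"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if self.second_onset <= self.first_onset:
            raise ConfigurationError(
                "second_onset must be later than first_onset"
            )
        if self.n_samples > 1 and np.any(np.diff(self.time_us) <= 0):
            raise GazeLogError("trace timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.time_us.shape[0])

    @property
    def period_us(self) -> float:
        """Nominal sample period in microseconds."""
        return 1e6 / self.rate_hz

    @property
    def period_ms(self) -> float:
        return 1e3 / self.rate_hz

    @property
    def has_valid_data(self) -> bool:
        return bool(self.valid_raw.any())

    def copy(self) -> "GazeTrace":
        return dataclasses.replace(
            self,
            time_us=self.time_us.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid_raw=self.valid_raw.copy(),
            interpolated=self.interpolated.copy(),
            raw_x=self.raw_x.copy(),
            raw_y=self.raw_y.copy(),
        )

    def slice(self, mask_or_slice) -> "GazeTrace":
        """Return a new trace restricted to the given samples."""
        sel = mask_or_slice
        return dataclasses.replace(
            self,
            time_us=self.time_us[sel].copy(),
            x=self.x[sel].copy(),
            y=self.y[sel].copy(),
            valid_raw=self.valid_raw[sel].copy(),
            interpolated=self.interpolated[sel].copy(),
            raw_x=self.raw_x[sel].copy(),
            raw_y=self.raw_y[sel].copy(),
        )

    def window_mask(self, start_us: int, end_us: int, *, closed_end: bool = True) -> np.ndarray:
        """Boolean mask of samples with time in [start, end] (or [start, end))."""
        if closed_end:
            return (self.time_us >= start_us) & (self.time_us <= end_us)
        return (self.time_us >= start_us) & (self.time_us < end_us)


@dataclass
class TrialResult:
    """One trial's SRT, or its rejection status with a single reason code.

    ``srt_ms`` is present exactly for the scorable statuses; a no-shift
    trial carries the analysis-window maximum as its latency.
    """

    subject_id: str
    trial_number: int
    condition: str
    target_side: Side
    srt_ms: Optional[float]
    status: TrialStatus
    longest_gap_ms: Optional[float] = None
    fixation_proportion: Optional[float] = None

    def __post_init__(self) -> None:
        self.target_side = Side(self.target_side)
        self.status = TrialStatus(self.status)
        if (self.srt_ms is not None) != (self.status in SCORABLE):
            raise ValueError(
                "srt_ms must be present exactly for scorable statuses, "
                f"got srt_ms={self.srt_ms!r} with status={self.status.value}"
            )

    @property
    def scorable(self) -> bool:
        return self.status in SCORABLE
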