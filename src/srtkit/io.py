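"""Reading raw gaze logs and trial tables; writing the two result files.

Input dialect: delimited text with a header row, delimiter auto-detected
among comma, tab and semicolon, decimal point only — this covers the usual
Tobii-style exports without any binary SDK dependency.  Timestamps are
converted to integer microseconds at parse time; missing coordinate cells
become NaN/None, never zeros, so no sentinel numerics can contaminate a
downstream mean.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .aggregate import ConditionSummary
from .detect import AnalysisParams
from .preprocess import combine_eyes_arrays
from .types import (
    ConfigurationError,
    GazeLogError,
    GazeSample,
    GazeTrace,
    Side,
    TrialResult,
    TrialStatus,
)

logger = logging.getLogger(__name__)

#: canonical logical column names for a raw gaze log
MANDATORY_COLUMNS = (
    "time",
    "x_left", "y_left", "x_right", "y_right",
    "validity_left", "validity_right",
)

_TIME_UNIT_US = {"us": 1.0, "ms": 1e3, "s": 1e6}


@dataclass(frozen=True)
class ColumnMap:
    """Maps logical gaze-log fields to file column names.

    ``columns`` maps each logical name in :data:`MANDATORY_COLUMNS` (plus
    the optional ``marker``) to the header name used in the file.
    ``time_unit`` is one of us/ms/s and is applied once at parse time.
    The default is the identity mapping with microsecond times.
    """

    columns: Dict[str, str] = field(
        default_factory=lambda: {c: c for c in MANDATORY_COLUMNS + ("marker",)}
    )
    time_unit: str = "us"

    def __post_init__(self) -> None:
        missing = [c for c in MANDATORY_COLUMNS if c not in self.columns]
        if missing:
            raise ConfigurationError(f"column_map lacks mandatory columns: {missing}")
        if self.time_unit not in _TIME_UNIT_US:
            raise ConfigurationError(f"unknown time unit {self.time_unit!r}")


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    counts = {d: head.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get)


def read_gaze_log(path: Union[str, Path],
                  column_map: Optional[ColumnMap] = None) -> List[GazeSample]:
    """Parse a raw gaze log into samples, in file order.

    Rows whose timestamp does not parse are dropped with a logged count;
    a non-monotone timestamp sequence is a structural error naming the
    first offending row (1-based data-row index).
    """
    path = Path(path)
    column_map = column_map or ColumnMap()
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for logical, name in column_map.columns.items():
        if logical in MANDATORY_COLUMNS and name not in df.columns:
            raise ConfigurationError(
                f"gaze log {path} has no column {name!r} (mapped from {logical!r})"
            )

    def col(logical: str) -> pd.Series:
        return df[column_map.columns[logical]]

    time_raw = pd.to_numeric(col("time"), errors="coerce")
    bad = time_raw.isna()
    if bad.any():
        logger.warning("dropped %d rows with unparseable timestamps from %s",
                       int(bad.sum()), path)
        df = df[~bad.values]
        time_raw = time_raw[~bad.values]
    time_us = np.round(time_raw.to_numpy(dtype=float)
                       * _TIME_UNIT_US[column_map.time_unit]).astype(np.int64)
    if time_us.size > 1:
        steps = np.diff(time_us)
        if (steps <= 0).any():
            row = int(np.argmax(steps <= 0)) + 2  # +1 for 0-base, +1 for the successor
            raise GazeLogError(
                f"timestamps not strictly increasing at data row {row} of {path}"
            )

    def floats(logical: str) -> np.ndarray:
        # Python's float() is round-trip exact; pandas' fast parser is not
        def conv(v: str) -> float:
            v = v.strip()
            if not v:
                return np.nan
            try:
                return float(v)
            except ValueError:
                return np.nan
        return col(logical).map(conv).to_numpy(dtype=float)

    def ints(logical: str) -> np.ndarray:
        return pd.to_numeric(col(logical), errors="coerce").fillna(4).astype(int).to_numpy()

    xl, yl = floats("x_left"), floats("y_left")
    xr, yr = floats("x_right"), floats("y_right")
    vl, vr = ints("validity_left"), ints("validity_right")
    marker_name = column_map.columns.get("marker")
    markers = (df[marker_name].astype(str).to_numpy()
               if marker_name in df.columns else np.full(len(df), "", dtype=object))

    def opt(v: float) -> Optional[float]:
        return None if np.isnan(v) else float(v)

    return [
        GazeSample(int(time_us[i]), opt(xl[i]), opt(yl[i]), opt(xr[i]), opt(yr[i]),
                   int(vl[i]), int(vr[i]), str(markers[i]))
        for i in range(len(df))
    ]


def read_trial_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial table CSV (one row per trial: keys, onsets or markers)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = {"subject_id", "trial_number", "condition", "target_side"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"trial table {path} lacks columns: {sorted(missing)}")
    has_onsets = {"first_onset_us", "second_onset_us"} <= set(df.columns)
    has_markers = {"first_marker", "second_marker"} <= set(df.columns)
    if not (has_onsets or has_markers):
        raise ConfigurationError(
            "trial table must provide first/second_onset_us or first/second_marker columns"
        )
    return df


def _marker_onset(samples: Sequence[GazeSample], marker: str) -> Optional[int]:
    for s in samples:
        if s.marker == marker:
            return s.time
    return None


def segment_trials(samples: Sequence[GazeSample],
                   trial_table: pd.DataFrame,
                   params: Optional[AnalysisParams] = None,
                   rate_hz: float = 300.0) -> List[GazeTrace]:
    """Cut a recording into per-trial traces with combined gaze points.

    Each trace spans [first_onset, second_onset + srt_max]; data beyond
    that window is irrelevant to every downstream check.  Onsets come
    either from absolute ``*_onset_us`` columns or from the first sample
    carrying the trial's marker value; a trial whose second-stimulus
    marker never appears is skipped with a log entry.  Traces with zero
    samples in the window are still emitted (downstream checks reject
    them).
    """
    params = params or AnalysisParams()
    time_us = np.array([s.time for s in samples], dtype=np.int64)
    x, y, valid = combine_eyes_arrays(
        np.array([np.nan if s.x_left is None else s.x_left for s in samples]),
        np.array([np.nan if s.y_left is None else s.y_left for s in samples]),
        np.array([np.nan if s.x_right is None else s.x_right for s in samples]),
        np.array([np.nan if s.y_right is None else s.y_right for s in samples]),
        np.array([s.validity_left for s in samples], dtype=int),
        np.array([s.validity_right for s in samples], dtype=int),
        params.valid_codes,
    ) if samples else (np.empty(0), np.empty(0), np.empty(0, dtype=bool))

    traces: List[GazeTrace] = []
    for row in trial_table.itertuples(index=False):
        d = row._asdict()
        if "first_onset_us" in d and not pd.isna(d.get("first_onset_us")):
            first = int(d["first_onset_us"])
            second = int(d["second_onset_us"])
        else:
            first = _marker_onset(samples, str(d["first_marker"]))
            second = _marker_onset(samples, str(d["second_marker"]))
            if first is None or second is None:
                logger.warning(
                    "trial %s/%s unsegmentable: stimulus marker not found; skipped",
                    d["subject_id"], d["trial_number"])
                continue
        # the duration check needs recorded data through min_second_ms,
        # so the window covers the longer of the two horizons
        end = second + int(round(max(params.srt_max_ms, params.min_second_ms) * 1e3))
        mask = (time_us >= first) & (time_us <= end)
        traces.append(GazeTrace(
            subject_id=str(d["subject_id"]),
            trial_number=int(d["trial_number"]),
            condition=str(d["condition"]),
            target_side=Side(str(d["target_side"])),
            first_onset=first,
            second_onset=second,
            rate_hz=rate_hz,
            time_us=time_us[mask],
            x=x[mask].copy(),
            y=y[mask].copy(),
            valid_raw=valid[mask].copy(),
            interpolated=np.zeros(int(mask.sum()), dtype=bool),
            raw_x=x[mask].copy(),
            raw_y=y[mask].copy(),
        ))
    return traces


TRIAL_COLUMNS = [
    "subject_id", "trial_number", "condition", "target_side",
    "srt_ms", "status", "longest_gap_ms", "fixation_proportion",
]


def write_trial_results(results: Sequence[TrialResult],
                        path: Union[str, Path]) -> None:
    """Write the trial-by-trial result file.

    One row per trial in the fixed column order :data:`TRIAL_COLUMNS`;
    rejected trials have an empty SRT cell and a status naming the failed
    check.  Missing values are empty cells.
    """
    rows = [{
        "subject_id": r.subject_id,
        "trial_number": r.trial_number,
        "condition": r.condition,
        "target_side": r.target_side.value,
        "srt_ms": r.srt_ms,
        "status": r.status.value,
        "longest_gap_ms": r.longest_gap_ms,
        "fixation_proportion": r.fixation_proportion,
    } for r in results]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


SUMMARY_FIELDS = [
    "n_valid_shift", "n_no_shift", "n_rejected",
    "mean_srt_ms", "srt_index", "insufficient",
]


def write_summary(summaries: Sequence[ConditionSummary],
                  path: Union[str, Path]) -> None:
    """Write the aggregated summary file: one row per participant.

    Condition-specific fields appear as column groups named
    ``<condition>_<field>`` so the file loads directly into any stats
    package.  Duplicate subject x condition pairs are a validation error.
    """
    seen = set()
    for s in summaries:
        key = (s.subject_id, s.condition)
        if key in seen:
            raise ValueError(f"duplicate summary for subject/condition {key}")
        seen.add(key)
    conditions = sorted({s.condition for s in summaries})
    by_subject: Dict[str, Dict[str, ConditionSummary]] = {}
    for s in summaries:
        by_subject.setdefault(s.subject_id, {})[s.condition] = s
    rows = []
    for subject, per_cond in by_subject.items():
        row: Dict[str, object] = {"subject_id": subject}
        for cond in conditions:
            s = per_cond.get(cond)
            for f in SUMMARY_FIELDS:
                row[f"{cond}_{f}"] = getattr(s, f) if s is not None else None
        rows.append(row)
    columns = ["subject_id"] + [f"{c}_{f}" for c in conditions for f in SUMMARY_FIELDS]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def write_gaze_log(samples: Sequence[GazeSample], path: Union[str, Path]) -> None:
    """Serialize samples back to the canonical gaze-log CSV dialect."""
    def cell(v: Optional[float]) -> str:
        return "" if v is None else repr(float(v))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(MANDATORY_COLUMNS) + ["marker"])
        for s in samples:
            w.writerow([s.time, cell(s.x_left), cell(s.y_left),
                        cell(s.x_right), cell(s.y_right),
                        s.validity_left, s.validity_right, s.marker])
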