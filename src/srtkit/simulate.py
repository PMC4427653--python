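"""Synthetic gaze-trace generator with known ground truth.

Emulates the stereotyped raw-data pathology of infant corneal-reflection
recordings so every pipeline stage can be validated without hardware:

* fixational jitter — white positional noise around the central stimulus;
* missing-data gaps — a Poisson process of dropouts with log-normal
  durations, during which validity goes to 4 and coordinates disappear;
* spike artifacts — brief excursions of the reported coordinates to a
  fixed off-center position (a few samples) while validity stays 0;
* the saccade — an abrupt x step from the central fixation to the lateral
  target, modelled as a linear ramp over ~30 ms.  A linear ramp is a
  deliberate simplification (no main-sequence velocity profile); it is
  sufficient for AOI-crossing detection, which only needs the crossing
  time.

The ground truth records, per trial, the time of the last sample inside
the central AOI on the noise-free trajectory — exactly the quantity the
detector estimates — plus every injected gap and spike interval.  All
randomness flows from one seed; identical seeds give bit-identical traces
and files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .detect import AnalysisParams
from .preprocess import _runs, combine_eyes_arrays
from .types import GazeSample, GazeTrace, Side

DEFAULT_CONDITIONS = ("baseline", "gap", "overlap")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults emulate a 300-Hz infant paradigm.

    Trial layout: the central stimulus appears at t = 0 and the lateral
    target 1,000 ms later, remaining on screen for 3,000 ms.  Degradation
    defaults: positional noise sd 0.01 normalized units per axis, spike
    artifacts at 0.5/s, and dropouts at 2.1/s with log-normal lengths
    (median 80 ms, sigma 0.6) — a coverage fraction of about 0.18 of all
    samples missing, matching tracking losses typical of cooperative
    infant recordings.  True latencies are truncated-normal, mean 400 ms,
    sd 150 ms on [150, 1000], populating the whole acceptance window.
    """

    rate_hz: float = 300.0
    first_stim_duration_ms: float = 1000.0
    second_stim_duration_ms: float = 3000.0
    fixation_x: float = 0.5
    fixation_y: float = 0.5
    target_x_right: float = 0.9
    target_x_left: float = 0.1
    noise_sd: float = 0.01
    eye_offset_sd: float = 0.002
    gap_rate_hz: float = 2.1
    gap_length_median_ms: float = 80.0
    gap_length_sigma: float = 0.6
    spike_rate_hz: float = 0.5
    spike_duration_samples: int = 2
    spike_x: float = 0.0
    latency_mean_ms: float = 400.0
    latency_sd_ms: float = 150.0
    latency_min_ms: float = 150.0
    latency_max_ms: float = 1000.0
    p_no_shift: float = 0.10
    p_wrong_direction: float = 0.05
    saccade_duration_ms: float = 30.0
    aoi_edge_threshold: float = 0.30

    def __post_init__(self) -> None:
        for name in ("gap_rate_hz", "spike_rate_hz", "noise_sd", "eye_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("p_no_shift", "p_wrong_direction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def second_onset_us(self) -> int:
        return int(round(self.first_stim_duration_ms * 1e3))

    @property
    def trial_duration_ms(self) -> float:
        return self.first_stim_duration_ms + self.second_stim_duration_ms

    @property
    def expected_missing_prop(self) -> float:
        """Expected covered fraction of a Poisson dropout process."""
        mean_len_s = (self.gap_length_median_ms / 1e3
                      * math.exp(self.gap_length_sigma ** 2 / 2.0))
        return 1.0 - math.exp(-self.gap_rate_hz * mean_len_s)

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-trial ground truth consistent with the emitted trace.

    ``true_srt_ms`` is the latency of the last in-AOI sample on the
    noise-free trajectory (None for programmed no-shift and
    wrong-direction trials, which carry no scorable latency);
    ``saccade_onset_ms`` is the programmed ramp start.  Gap and spike runs
    are inclusive sample-index intervals.
    """

    subject_id: str
    trial_number: int
    target_side: Side
    shift_type: str  # shift | no_shift | wrong_direction
    saccade_onset_ms: Optional[float]
    true_srt_ms: Optional[float]
    gap_runs: List[Tuple[int, int]] = field(default_factory=list)
    spike_runs: List[Tuple[int, int]] = field(default_factory=list)


def _draw_latency(config: SynthConfig, rng: np.random.Generator) -> float:
    """Truncated-normal latency by bounded rejection sampling (max 100 draws)."""
    for _ in range(100):
        v = rng.normal(config.latency_mean_ms, config.latency_sd_ms)
        if config.latency_min_ms <= v <= config.latency_max_ms:
            return float(v)
    return float(np.clip(v, config.latency_min_ms, config.latency_max_ms))


def _time_grid(config: SynthConfig) -> np.ndarray:
    n = int(round(config.trial_duration_ms * config.rate_hz / 1e3)) + 1
    return np.round(np.arange(n) * 1e6 / config.rate_hz).astype(np.int64)


def _truth_srt_ms(t_us: np.ndarray, x_base: np.ndarray, second_onset_us: int,
                  thr: float, srt_max_ms: float) -> Optional[float]:
    """Last-in-AOI latency of the noise-free trajectory within the window."""
    window_end = second_onset_us + int(round(srt_max_ms * 1e3))
    in_window = (t_us >= second_onset_us) & (t_us <= window_end)
    outside = in_window & ((x_base < thr) | (x_base > 1.0 - thr))
    if not outside.any():
        return None
    departure = int(np.argmax(outside))
    inside_before = (x_base[:departure] >= thr) & (x_base[:departure] <= 1.0 - thr)
    if not inside_before.any():
        return None
    last_inside = int(np.nonzero(inside_before)[0][-1])
    return float(t_us[last_inside] - second_onset_us) / 1e3


def generate_trial(config: SynthConfig, subject_id: str, trial_number: int,
                   seed: Union[int, np.random.Generator],
                   target_side: Optional[Side] = None,
                   condition: str = "overlap",
                   time_offset_us: int = 0,
                   ) -> Tuple[GazeTrace, GroundTruth]:
    """Generate one raw two-eye trial and its ground truth.

    The returned trace is the *raw* combined stream (no interpolation, no
    filtering) exactly as segmentation of a recorded log would produce it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_us = _time_grid(config)
    n = t_us.size
    period_ms = 1e3 / config.rate_hz
    second_onset = config.second_onset_us

    if target_side is None:
        target_side = Side.RIGHT if rng.random() < 0.5 else Side.LEFT
    target_side = Side(target_side)

    u = rng.random()
    if u < config.p_no_shift:
        shift_type = "no_shift"
    elif u < config.p_no_shift + config.p_wrong_direction:
        shift_type = "wrong_direction"
    else:
        shift_type = "shift"

    x_base = np.full(n, config.fixation_x)
    saccade_onset_ms: Optional[float] = None
    if shift_type != "no_shift":
        latency_ms = _draw_latency(config, rng)
        saccade_onset_ms = latency_ms
        landing_side = target_side if shift_type == "shift" else (
            Side.LEFT if target_side is Side.RIGHT else Side.RIGHT)
        target_x = (config.target_x_right if landing_side is Side.RIGHT
                    else config.target_x_left)
        ts = second_onset + latency_ms * 1e3
        te = ts + config.saccade_duration_ms * 1e3
        x_base = np.interp(t_us.astype(float), [ts, te],
                           [config.fixation_x, target_x])
    y_base = np.full(n, config.fixation_y)

    true_srt = (_truth_srt_ms(t_us, x_base, second_onset,
                              config.aoi_edge_threshold, config.latency_max_ms)
                if shift_type == "shift" else None)

    x_signal = x_base + rng.normal(0.0, config.noise_sd, n)
    y_signal = y_base + rng.normal(0.0, config.noise_sd, n)

    # spike artifacts: brief jumps of the reported coordinates, validity intact
    duration_s = config.trial_duration_ms / 1e3
    spike_mask = np.zeros(n, dtype=bool)
    for _ in range(rng.poisson(config.spike_rate_hz * duration_s)):
        start = int(rng.integers(0, n))
        spike_mask[start:start + config.spike_duration_samples] = True
    x_signal[spike_mask] = config.spike_x
    y_signal[spike_mask] = config.fixation_y

    # dropouts: validity 4, coordinates gone
    gap_mask = np.zeros(n, dtype=bool)
    for _ in range(rng.poisson(config.gap_rate_hz * duration_s)):
        start = int(rng.integers(0, n))
        length_ms = rng.lognormal(math.log(config.gap_length_median_ms),
                                  config.gap_length_sigma)
        gap_mask[start:start + max(1, int(round(length_ms / period_ms)))] = True

    x_left = x_signal + rng.normal(0.0, config.eye_offset_sd, n)
    y_left = y_signal + rng.normal(0.0, config.eye_offset_sd, n)
    x_right = x_signal + rng.normal(0.0, config.eye_offset_sd, n)
    y_right = y_signal + rng.normal(0.0, config.eye_offset_sd, n)
    validity = np.zeros(n, dtype=int)
    for arr in (x_left, y_left, x_right, y_right):
        arr[gap_mask] = np.nan
    validity[gap_mask] = 4

    x, y, valid = combine_eyes_arrays(x_left, y_left, x_right, y_right,
                                      validity, validity)
    trace = GazeTrace(
        subject_id=subject_id,
        trial_number=trial_number,
        condition=condition,
        target_side=target_side,
        first_onset=time_offset_us,
        second_onset=time_offset_us + second_onset,
        rate_hz=config.rate_hz,
        time_us=t_us + time_offset_us,
        x=x.copy(), y=y.copy(),
        valid_raw=valid,
        interpolated=np.zeros(n, dtype=bool),
        raw_x=x.copy(), raw_y=y.copy(),
    )
    truth = GroundTruth(
        subject_id=subject_id,
        trial_number=trial_number,
        target_side=target_side,
        shift_type=shift_type,
        saccade_onset_ms=saccade_onset_ms,
        true_srt_ms=true_srt,
        gap_runs=_runs(gap_mask),
        spike_runs=_runs(spike_mask & ~gap_mask),
    )
    # stash the per-eye arrays for lossless file export
    trace._eyes = (x_left, y_left, x_right, y_right, validity)  # type: ignore[attr-defined]
    return trace, truth


@dataclass(frozen=True)
class QualityRanges:
    """Per-trial quality spread driven by one latent tracking-quality factor.

    Poor tracking manifests jointly: a fussy or badly calibrated recording
    shows more positional jitter, more spike artifacts and more dropouts
    at once, which is what makes trial-level precision and robustness
    indices informative in real data.  Each trial draws a latent quality
    u ~ U(0, 1) (0 = worst) and every degradation parameter interpolates
    linearly from its best (at u = 1) to its worst (at u = 0) value.
    """

    noise_sd: Tuple[float, float] = (0.004, 0.02)
    gap_rate_hz: Tuple[float, float] = (0.2, 3.0)
    gap_length_median_ms: Tuple[float, float] = (40.0, 160.0)
    spike_rate_hz: Tuple[float, float] = (0.0, 1.0)

    def draw(self, config: "SynthConfig", rng: np.random.Generator) -> "SynthConfig":
        badness = rng.random()
        pick = lambda lo_hi: lo_hi[0] + badness * (lo_hi[1] - lo_hi[0])
        return config.replace(
            noise_sd=float(pick(self.noise_sd)),
            gap_rate_hz=float(pick(self.gap_rate_hz)),
            gap_length_median_ms=float(pick(self.gap_length_median_ms)),
            spike_rate_hz=float(pick(self.spike_rate_hz)),
        )


def generate_trials(config: SynthConfig, n_trials: int, seed: int,
                    subject_id: str = "s01",
                    quality_ranges: Optional[QualityRanges] = None,
                    conditions: Sequence[str] = DEFAULT_CONDITIONS,
                    ) -> List[Tuple[GazeTrace, GroundTruth]]:
    """Generate ``n_trials`` in-memory trials from a single seed."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_trials):
        cfg = config if quality_ranges is None else quality_ranges.draw(config, rng)
        out.append(generate_trial(cfg, subject_id, k + 1, rng,
                                  condition=conditions[k % len(conditions)]))
    return out


def generate_dataset(config: SynthConfig, n_subjects: int, n_trials: int,
                     seed: int, out_dir: Union[str, Path],
                     quality_ranges: Optional[QualityRanges] = None,
                     conditions: Sequence[str] = DEFAULT_CONDITIONS,
                     ) -> Dict[str, Path]:
    """Write a full synthetic dataset in the dialects the reader consumes.

    Produces ``gaze_log.csv`` (one recording, trials separated by 5-s
    offsets), ``trial_table.csv`` (absolute onsets) and ``truth.csv``.
    Deterministic down to file bytes for a fixed seed.
    """
    from .io import write_gaze_log  # local import to avoid a cycle

    if n_subjects < 1 or n_trials < 1:
        raise ValueError("n_subjects and n_trials must be at least 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    samples: List[GazeSample] = []
    trial_rows = []
    truth_rows = []
    spacing_us = 5_000_000
    offset = 0
    for s in range(n_subjects):
        subject = f"s{s + 1:02d}"
        for k in range(n_trials):
            cfg = config if quality_ranges is None else quality_ranges.draw(config, rng)
            condition = conditions[k % len(conditions)]
            trace, truth = generate_trial(cfg, subject, k + 1, rng,
                                          condition=condition,
                                          time_offset_us=offset)
            xl, yl, xr, yr, validity = trace._eyes  # type: ignore[attr-defined]

            def opt(v: float) -> Optional[float]:
                return None if np.isnan(v) else float(v)

            for i in range(trace.n_samples):
                samples.append(GazeSample(
                    int(trace.time_us[i]), opt(xl[i]), opt(yl[i]),
                    opt(xr[i]), opt(yr[i]), int(validity[i]), int(validity[i]),
                    marker=f"{subject}_t{k + 1:03d}",
                ))
            trial_rows.append({
                "subject_id": subject, "trial_number": k + 1,
                "condition": condition, "target_side": truth.target_side.value,
                "first_onset_us": trace.first_onset,
                "second_onset_us": trace.second_onset,
            })
            truth_rows.append({
                "subject_id": subject, "trial_number": k + 1,
                "shift_type": truth.shift_type,
                "target_side": truth.target_side.value,
                "saccade_onset_ms": truth.saccade_onset_ms,
                "true_srt_ms": truth.true_srt_ms,
            })
            offset += spacing_us

    paths = {
        "gaze_log": out_dir / "gaze_log.csv",
        "trial_table": out_dir / "trial_table.csv",
        "truth": out_dir / "truth.csv",
    }
    write_gaze_log(samples, paths["gaze_log"])
    pd.DataFrame(trial_rows).to_csv(paths["trial_table"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return paths
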