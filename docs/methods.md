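# Methods

## The measurement problem

In a two-stimulus orienting paradigm the dependent variable is the
saccadic reaction time: how long after the lateral target's onset the
point of gaze leaves the central stimulus. Corneal-reflection trackers
report gaze at 60–300 Hz with per-eye validity codes, but with poorly
cooperating participants the raw stream is fragmented (dropouts whenever
the tracker loses the eyes) and noisy (fixational jitter, plus brief
spike artifacts where the reported position jumps across the screen for a
few milliseconds). A naive "first sample outside the AOI" rule then
produces false SRTs from spikes, misses shifts hidden inside dropouts,
and inherits a systematic dependence on per-trial data quality. The
pipeline here removes the artifacts it can remove and *rejects* — never
repairs — the trials it cannot trust.

## Pipeline

**Eye combination.** A sample is valid if at least one eye carries an
accepted validity code (default {0, 1}) with finite coordinates; both
valid → coordinate mean, one valid → that eye. Averaging with single-eye
fallback maximizes retained data and is standard practice; the choice is
open because trackers report the eyes separately without a canonical
combination.

**Gap interpolation.** Every missing sample with at least one valid
predecessor takes the most recent valid (x, y) — forward continuation,
applied to all gaps regardless of duration. The counterpart is strict
bookkeeping: one record per maximal filled gap, whose duration counts one
nominal sample period per missing sample (a 3-sample gap at 300 Hz is
10 ms), making the downstream 200-ms cap independent of the sampling
rate. A leading run with no valid predecessor stays missing: there is
nothing to continue, and back-filling would manufacture fixation evidence.
Interpolation precedes filtering, because the median filter requires
gap-free input; the combined preprocessed trace is what detection sees.

**Median filtering.** A moving median of user-chosen odd length (default
37 samples = 123.3 ms at 300 Hz), with both ends virtually extended by
replicating the first/last available sample so the whole period is
covered. The median of a monotone window is its central element, so the
saccade's step passes through undisplaced, while any artifact run
strictly shorter than (window+1)/2 samples inside a constant segment is
erased — both properties are asserted against a brute-force per-index
median in the tests. The default length sits below the ~100–130 ms it
takes to program a saccade, so no real shift can be filtered away.

**Detection.** The scan covers [onset, onset + srt_max] of the lateral
stimulus. The SRT is the time of the last in-AOI sample preceding the
first sample outside the central band (x within `edge_threshold` = 0.30
of neither edge; boundary samples count as inside, one convention
everywhere). Only the horizontal coordinate participates: both stimuli
sit on the horizontal midline, so y carries no shift information and is
kept for quality metrics only. Departures on the non-target side are
rejected (`rejected_wrong_direction`) rather than scored; a latency below
srt_min is `rejected_anticipatory` (anticipatory shifts are detected and
rejected, not silently skipped — the scan starts at onset, not at
srt_min). When both apply, the anticipatory rejection wins: a latency
outside the window is uninterpretable regardless of direction. No
departure in the window is `no_shift`, scored at srt_max — a scorable
outcome, since a missing saccade is informative.

**Verification.** Four checks run in fixed order — durations →
interpolation cap → border violation → minimum fixation — cheap
structural checks first, and exactly one reason per rejected trial:

1. *Durations*: recorded rows (any validity) must span
   [min_first, max_first] in the first phase and ≥ min_second in the
   second; failures mean the tracker or stimulus software died mid-trial.
2. *Interpolation cap*: no forward-filled gap overlapping the analysis
   period may exceed max_gap (200 ms); a longer gap could hide a full
   central–lateral–central excursion. Gaps entirely outside the analysis
   period are ignored.
3. *Border violation*: for each gap, the AOI region (left / central /
   right) of the last valid raw sample before it is compared with the
   first valid raw sample after it; a change means a shift happened at an
   unknowable time. Raw flanks are essential — interpolated values would
   make violation undetectable by construction. A gap with no trailing
   valid sample cannot violate.
4. *Minimum fixation*: the fraction of first-phase samples inside the
   central AOI (interpolated samples count — they assert continued
   fixation) must reach min_fixation_prop; the comparison is inclusive,
   so exactly 0.70 passes.

The checks are monotone: tightening any threshold never converts a
rejected trial into an accepted one, and verification is idempotent.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| valid_codes | {0, 1} | — | codes reported as certainly-tracked |
| filter_window_samples | 37 | samples | 123 ms at 300 Hz; shorter than a saccade's programming time |
| max_gap_ms | 200 | ms | longest gap that cannot hide a there-and-back shift |
| min_first_ms / max_first_ms | 900 / 1100 | ms | tolerance around the nominal 1,000-ms first phase |
| min_second_ms | 1000 | ms | second phase must cover the analysis window |
| min_fixation_prop | 0.70 | — | evidence the central stimulus was actually fixated |
| srt_min_ms / srt_max_ms | 150 / 1000 | ms | acceptance window for disengagement times |
| edge_threshold | 0.30 | screen fraction | central band [0.30, 0.70]; a margin wide enough to ignore jitter, narrow enough to catch every real shift |
| min_scorable_trials | 3 | trials | below this a subject × condition summary is flagged insufficient |

All durations are milliseconds at the interface and integer microseconds
internally (converted once). The filter length may also be given in ms
and is rounded to the nearest odd sample count.

## Aggregation

Mean SRT averages valid shifts only. The SRT index folds shift and
no-shift trials onto [0, 1] as the mean of
1 − (srt_max − x_i)/(srt_max − srt_min), algebraically the rescaled mean
(x_i − srt_min)/(srt_max − srt_min). Anticipatory shifts are rejected
upstream, so no scorable latency is below srt_min and the index cannot go
negative — this is asserted, not clamped. The configured window
generalizes the conventional 150/1000/850 constants.

## Data-quality metrics and the sensitivity experiment

Quality is judged on the raw stream of the pre-saccadic segment (trial
start to the detected saccade; the first 2,000 ms when no shift was
detected). *Precision* is the RMS Euclidean distance between consecutive
valid raw samples, pairs never spanning a dropout; under white noise of
sd σ per axis its expectation is 2σ. This consecutive-pair formulation is
this package's own operationalization, pinned by its tests. A linear
small-angle conversion to degrees (× display span, default 46°) is
provided. *Robustness* is the proportion of unavailable samples. Usable
segment durations (maximal valid runs, one nominal period per sample)
summarize fragmentation.

The median-split experiment generates ground-truthed trials, splits them
at the median of each quality metric (ties to the low-quality half, a
fixed rule), counts trials whose detected SRT errs by more than 100 ms
against the programmed truth, and tests the 2×2 association with
Pearson's chi-square (no continuity correction; a table with an empty row
or column yields no statistic, reported with a reason). Two modes run on
identical traces: `full` (the entire pipeline) and `typical` (no
interpolation, no filtering, no checks, and the AOI margin narrowed from
2.7° to 1° per side, i.e. edge_threshold + 1.7/46 ≈ +0.037 applied
symmetrically; the stimulus geometry does not pin the narrowing to one
side). Rejected trials carry no error and drop out — in full mode that
is the mechanism under study, not a confound.

## The synthetic generator

Each trial is a 4,000-ms two-eye recording at 300 Hz: central stimulus at
t = 0, lateral target at 1,000 ms for 3,000 ms. The clean trajectory
holds x at 0.5 with the saccade as a linear 30-ms ramp to the target
(0.9 / 0.1) — a deliberate simplification (no main-sequence velocity
profile), sufficient for AOI-crossing detection, which needs only the
crossing time. Degradation layers, all seeded and recorded in the ground
truth:

* white positional noise, sd 0.01 per axis (each eye additionally
  jittered by sd 0.002 around the shared signal);
* spike artifacts at 0.5/s: 2 samples at x = 0, validity intact —
  the classic large-amplitude transient;
* dropouts as a Poisson process at 2.1/s with log-normal lengths
  (median 80 ms, σ = 0.6): coverage fraction 1 − exp(−rate·E[L]) ≈ 0.18
  of samples missing, the level typical of cooperative infant recordings;
* trial types: p(no shift) = 0.10, p(wrong direction) = 0.05, latencies
  truncated-normal (mean 400 ms, sd 150 ms, bounded by the acceptance
  window, rejection sampling capped at 100 draws).

The recorded true SRT is the last in-AOI sample of the *noise-free*
trajectory — the exact quantity the detector estimates — so noise-free
recovery can be asserted to the sample.

For the sensitivity experiment, per-trial quality is drawn from one
latent tracking-quality factor u ~ U(0, 1) that degrades every channel
together: noise sd 0.004–0.02, gap rate 0.2–3/s, gap median length
40–160 ms, spike rate 0–1/s, each interpolated linearly in u. The joint
loading is the point: in real recordings a fussy participant or a poor
calibration degrades precision and robustness at once, which is what
makes trial-level quality indices predictive. Independent draws would
decorrelate the pathologies and dissolve the contrast the experiment
exists to demonstrate.

What the generator does **not** emulate: calibration drift and systematic
offsets, head-movement transients, pupil-size crosstalk, binocular
vergence differences, two-phase (hypometric) saccades, and temporally
correlated (1/f) jitter. Passing tests therefore demonstrate correctness
of the algorithms under the stated noise model, not robustness to every
failure mode of real hardware; the verification checks, not the
simulation, are the defense against the unmodeled cases.

## Numerical choices and degenerate inputs

* Time is int64 microseconds; sample grids are rounded per index, so the
  nominal period (10/3 ms at 300 Hz) never accumulates drift.
* Phase durations count recorded rows of any validity (a validity-4 row
  still proves the tracker was running) as last − first + one period.
* A trace with zero valid samples passes through interpolation unchanged
  and is rejected by the duration/fixation checks; an empty analysis
  window is `rejected_duration`.
* A departure with no preceding in-AOI observation anywhere in the trace
  folds into the anticipatory rejection (the latency is undefined or
  ≤ 0).
* Precision requires at least two consecutive-sample pairs; otherwise it
  is absent, never zero.
* Coordinate parsing uses round-trip-exact float conversion; missing
  values are empty cells in every output, never sentinels.
* Median filtering with an even window, or a window longer than twice
  the trace, is a configuration error.

## Problem sizes

The test suite validates the filter and the detector against brute-force
oracles on 1,000 randomized traces each; parameter recovery on 500
noise-free trials (sample-exact); degraded-data recovery on 400 trials at
the default degradation (≥ 95 % of accepted trials within 100 ms of
truth); and the sensitivity experiment on 2,000 trials (full mode: large
errors < 5 % in both halves of either split and no significant
association; typical mode: p < 0.001 for both splits). These sizes give
stable statistics while keeping the default run fast on one core.

## Known limitations

* The AOI-exit rule is the only detector; velocity-based (I-VT) detection
  and target-entry variants are out of scope.
* Forward continuation is the only imputation; the package's stance on
  long gaps is rejection, not inference.
* The degree conversions are linear small-angle approximations; at ±23°
  eccentricity the tangent correction is ignored.
* Test–retest and growth analyses over sessions are downstream of the
  summary files and not implemented here.
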