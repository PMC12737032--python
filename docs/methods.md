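# Methods

This note documents the models, parameters and numerical choices behind
`actipipe`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Signal model and units

All acceleration is handled in units of g (standard gravity, fixed at
exactly 1; no local-gravity correction). Timestamps are integer
milliseconds since the Unix epoch; a recording is *regular* when its
timestamps sit on the exact 1000/rate ms grid anchored at the first
sample. Regularization snaps each grid slot to the nearest input sample
(earliest wins on ties), fills gaps by repeating the last sample, and
reports gap events — repetition rather than deletion keeps the epoch
grid contiguous, which downstream epoching assumes.

## Preprocessing

Gravity is removed either arithmetically from the magnitude
(UFNM = |UFM − 1| keeps the size of sub-1 g deviations, ENMO truncates
them to zero) or by filtering: a 3rd-order Butterworth band-pass with
0.25 and 2.5 Hz cutoffs applied per axis before the Euclidean norm
(FX/FY/FZ → FMpre) or to the magnitude after it (FMpost), and a
4th-order 0.2 Hz high-pass per axis for HFMpre. Norm and filtering do
not commute, so FMpre ≠ FMpost on posture changes — this is the
mechanism that separates preprocessing families in the comparisons.

Filters are causal single-pass by default, emulating the real-time
processing of commercial actigraphs; `zero_phase=True` switches to
forward–backward filtering (whether field pipelines filter causally is
generally unreported, so both are supported). Causal filters are
initialized at their step steady state (`sosfilt_zi` scaled by the first
sample): otherwise the DC level present at switch-on rings through the
band-pass for several seconds and produces spurious counts in the first
epochs of threshold-bearing pipelines. No transient trimming is applied
beyond that.

## Activity metrics

Epochs are 60 s by default, anchored on clock boundaries that are whole
multiples of the epoch length; partial leading/trailing epochs are
dropped. PIM is Σ|v|·Δt in g·s (the Δt factor cancels under the mean
normalization used in comparisons). ZCM counts upward crossings
(v[i−1] − θ ≤ 0 < v[i] − θ) with no hysteresis — the SD-rule threshold
already sits above the noise floor. TAT is strict time above θ. MAD is
the mean absolute deviation about the epoch mean (the definition behind
the name, even though it is sometimes loosely described as a standard
deviation). AI is √(mean over axes of max(var − σ₀², 0)) with the device
noise variance σ₀² defaulting to 0 (no calibrated value is assumed;
estimable from the stillest epoch if needed). HFEN is the epoch mean of
HFMpre and is defined only on that scheme.

The intersection threshold is the standard deviation of all preprocessed
samples — pooled across the cohort by default (streamed moments, so no
cohort-wide signal is ever held in memory), per recording on request —
with 1 g added for UFM, whose mean carries the gravity component.

The 35-method roster ({PIM, ZCM, TAT, MAD} × {UFM, UFNM, ENMO, FMpre,
FMpost, FX, FY, FZ} ∪ {AI(UFXYZ), AI(FXYZ), HFEN(HFMpre)}) is kept as a
single table constant with a preprocessing-family tag per method, so it
can be corrected in one place if an authoritative roster differs.

## Device emulations

MW (MotionWatch-style): per-axis band-pass, Euclidean norm, per-clock-
second maxima, and the per-epoch sum of maxima exceeding 0.1 g. The
native 3–11 Hz device band cannot exist below a 20 Hz sampling rate, so
the generalized 0.25–2.5 Hz filter stands in; at 10 Hz input this is the
defensible approximation.

AC (activity counts): per axis, linear-interpolation resampling to
30 Hz, an order-3 Butterworth band-pass at 0.29–1.63 Hz, rectification,
clipping at 2.13 g, a 0.068 g deadband, quantization to 1/128 g count
units, decimation back to 10 Hz and per-epoch summation; the three axis
sums combine as their Euclidean norm. The constants live in one
parameter block (`AC_PARAMS`) and follow the openly documented counts
pipeline; the implementation is an emulation of the stage structure, not
a bit-exact clone of any particular vendor release. Every stage is
monotone in movement amplitude, which is property-tested.

The device suite pairs these with PIM/ZCM/TAT on FMpre and PIM on ENMO
at 60 s epochs, the determinations used by the corresponding commercial
and open-source pipelines.

## Circadian indicators

The 24 h mean profile averages each time-of-day bin across complete
midnight-to-midnight days only (incomplete days would bias bins
unevenly); 60 s bins for activity series, 1 s bins for acceleration.
L5/M10 windows slide in 60 s onset steps for both resolutions
(configurable), wrap midnight via circular indexing, and resolve ties to
the earliest onset. IS and IV operate on clock-aligned hourly means over
the same complete days; a zero-variance series makes both undefined and
raises. Series can be normalized by their grand mean before L5/M10 so
value-range differences between determination methods cancel; RA, IS and
IV are scale-invariant regardless (property-tested).

Acceleration-based indicators require a non-constant mean: FMpre,
HFMpre, UFNM, ENMO qualify directly; FX, FY, FZ, FMpost are
near-symmetric about zero and must be rectified first (`rectify`, which
refuses nonnegative schemes to prevent silent double-processing); UFM is
rejected outright because window averages of it converge to 1 g.

## Sleep–wake scoring

The trend-threshold scorer classifies an epoch as provisional sleep when
its activity is below `threshold_frac` (default 0.25, the recommended
upper end of the published 15–25% range) of a centered 24 h moving
average (edge windows truncated, never below 12 h). Rescoring then runs
stage 1 (wake runs < 30 min flanked by sleep become sleep) before
stage 2 (sleep runs < 30 min become wake); the pair is idempotent. The
30 min constants follow the published defaults; all parameters are
recorded in every returned score.

The z-angle scorer computes atan2(z̃, √(x̃² + ỹ²)) on per-axis 5 s rolling
medians, averaged per consecutive 5 s block. Sustained inactivity bouts
are runs of successive block-angle changes < 5° lasting ≥ 5 min. The
sleep period time window is found per noon-to-noon day from the 5 min
rolling median of absolute angle changes: blocks below the fixed
threshold 0.4° seed candidates, runs ≥ 30 min are kept, gaps < 60 min
bridged, and the longest merged run is that day's single contiguous SPT
(0.4 is interpreted as this fixed angle-change threshold; the published
tuning parameter it maps onto is ambiguous). Sleep is SIB ∩ SPT, emitted
on the 60 s epoch grid (an epoch is sleep when at least half its blocks
are) so interval comparisons with the activity-based scorer are well
defined. Neither scorer is validated against polysomnography here; they
serve to compare pipelines, not to measure scoring accuracy.

## Comparison and clustering

SMAPE (Σ-normalized absolute difference, 0–200%), circular window
overlap (0–100%) and interval IoU (0–100%) are averaged over subjects
into symmetric matrices; zero-denominator cells abort with an error
naming the subject and pipeline pair rather than being silently skipped.
For clustering, matrices convert to dissimilarities (SMAPE/200,
1 − overlap/100), are min–max rescaled to [0, 1] over the off-diagonal
range, and each pipeline's feature vector is its row of the rescaled
matrix under the Euclidean metric with complete linkage (the default
behavior of the reference clustering stack when handed a square matrix).
Each matrix is rescaled independently. Trees export to Newick with
single-quoted labels (they contain parentheses) and branch lengths equal
to merge-height differences.

## Auto-calibration

A sphere-fit substitute for the published wrist auto-calibration:
still windows (10 s, per-axis SD < 0.013 g — the convention of the
wrist-accelerometer calibration literature) provide mean vectors whose
norms should be 1 g; per-axis offsets and scales are fitted by least
squares on `‖(v − o)/s‖ − 1`. The step is a flagged no-op when fewer
than 10 still windows exist or their orientations span < 15°, and the
fit is discarded if it would increase the RMS deviation of still norms
from 1 g. Cross-axis (orthogonality) and temperature corrections are out
of scope; the step is pluggable.

## Synthetic recordings

The generator emulates the statistical structure the analyses rely on,
with the acquisition constants of the emulated device as defaults
(10 days, 10 Hz, ±8 g range, 16 mg quantization):

- a unit-norm gravity vector, piecewise constant, re-drawn at nocturnal
  posture changes (Poisson, 4/night) and at waking movement bouts;
- sleep windows 23:30–07:00 with 15 min per-day jitter (per-subject
  schedule shifts of ~30 min in cohorts);
- waking movement as Poisson bouts (10/min, mean 2 s, 0.3 g) of 0.3–3 Hz
  band-limited Gaussian noise — inside the band the activity filters
  target, so filtered and unfiltered pipelines diverge realistically —
  over a continuous 0.05 g wake baseline. The baseline and bout density
  encode the observation that waking wrists are essentially never still
  for whole minutes; without them, trend-threshold rescoring amplifies
  scattered sub-threshold minutes into spurious sleep, a failure mode
  real data does not exhibit;
- 4 mg wide-band sensor noise, then quantization and clipping.

Ground truth (sleep windows, posture events, nominal schedule)
accompanies every recording. The generator is deterministic and
bit-exact under a fixed seed; cohort seeds derive from one parent seed.

What it does *not* emulate: tremor or heart-rate artifacts, napping,
wear breaks and non-wear, slow postural drift during sleep, temperature
effects, or between-device sensor differences. A green recovery test
therefore establishes that the pipeline recovers the structure the
generator encodes — consolidated nocturnal rest with near-continuous
waking movement — not clinical scoring performance on real data.

## Numerical choices and degenerate inputs

- Internal generator arithmetic is float32 (post-quantization values are
  exact at far lower precision), upcast to float64 at the container
  boundary; determinism is bit-exact either way.
- Flat daily profiles return onset 00:00 for both windows with equal
  means (degenerate but defined).
- Epoch/second/block grids all anchor on ceil-to-boundary of the first
  timestamp, so differently derived series land on comparable clocks.
- CSV round trips are lossless: writes use 17-significant-digit floats
  and reads use round-trip float parsing.
- Per-recording failures inside a study run are logged and excluded; the
  manifest records them and the remaining cohort proceeds.

## Limitations

- AC and MW are documented approximations; absolute count magnitudes
  should not be compared against real device output, only their relative
  behavior across pipelines.
- The scaled-down synthetic cohort (defaults 10 days; tests use 4-day,
  10-subject cohorts) supports mechanism-level conclusions — threshold
  vs. integration splits, preprocessing-family clusters — not effect
  sizes on any real population.
- IS/IV hourly series may concatenate non-adjacent complete days when a
  middle day is incomplete; one successive-difference term per junction
  is then between non-consecutive hours.
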