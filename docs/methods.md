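# Methods

## The problem

During vigilance and working-memory tasks, performance fluctuates from
trial to trial, and part of that fluctuation is thought to reflect slow
(tens of seconds) drifts in tonic alertness that are visible in pupil
diameter.  The difficulty is that the pupil also reacts quickly and
strongly to stimulus luminance and to event-locked (phasic) arousal, so
any index of slow "tonic" change must be constructed to be insensitive
to those fast components.  `pupiltrend` implements a family of such
indices — *pupil trends*: signed diameter changes over a window centered
on a task event — together with the preprocessing, trial bookkeeping and
paired statistics needed to relate them to behaviour.

## Preprocessing

Recordings are binocular diameter samples at a fixed rate (nominally
1,000 Hz, arbitrary pixel units).  Blink handling:

1. **Core blink** — any run of samples flagged invalid by the tracker or
   with non-positive/missing diameter.
2. **Noise flanks** — the run is grown outward while the absolute
   sample-to-sample difference exceeds `k` times the MAD of first
   differences over the whole eye trace (`k = 5` by default).  This
   captures the partial-occlusion ramps on either side of a closure
   without needing a tracker-specific event stream.  The comparison is
   always made between samples *outside* the invalid run, since steps
   into a zeroed run are uninformative.
3. **Margins and merging** — 200 ms (configurable) is added on both
   sides, segments are clamped to the recording and merged.
4. **Interpolation** — samples inside segments are replaced by the
   straight line between the nearest retained samples; gaps touching a
   recording edge are filled with the nearest retained value.  Constant
   extension avoids extrapolation artefacts in edge windows, which are
   dropped from analysis anyway.

No further despiking is applied: samples with valid flags and plausible
amplitudes are taken at face value.

## Trend indices

All indices are computed per eye on the interpolated series and then
averaged across eyes per trial (index-level averaging; if only one eye
yields a complete value it is used and flagged monocular).

**Smoothed trend** (windows w = 5, 10, 15 s): the centered moving
average evaluated at `t0 + w/2` minus its value at `t0 − w/2`, which is
identical to `mean[t0, t0+w] − mean[t0−w, t0]`.  Implementation uses
inclusive sample-index windows (`round(t·rate)` endpoints, both ends
included); the oracle tests use the same convention.  Window means are
computed by direct summation over the slice rather than differences of a
running cumulative sum: this keeps the index *exactly* invariant to
samples outside its windows, at round-off level, which matters for the
guard-interval guarantee below.

**Conservative trend**: `mean[t0+2 s, t0+12 s] − mean[t0−12 s, t0−2 s]`
(a 14 s span with 10 s windows).  Any signal confined to ±2 s of the
event — in particular the phasic, luminance-driven response to the
target — contributes exactly zero.

**Decomposed trend**: the series is decomposed with a shift-invariant
(stationary / maximal-overlap) wavelet transform using the Symlet-4
filter pair, and per-level time-aligned reconstruction yields an
additive multiresolution analysis: approximation + Σ details = input
(verified to 1e−6 relative error; in practice ~1e−12).  A decimated DWT
is deliberately not used: it is not translation invariant, which
corrupts per-event two-point readouts.  Levels are dyadic in samples and
labelled in milliseconds (level j ↔ 2^j·dt ms; at 1 kHz: 2 ms … 32,768 ms
details with the approximation at 65,536 ms).  The trend at scale s is
`detail_s(t0 + s/2) − detail_s(t0 − s/2)`.  The level-j component's
passband spans fluctuation periods of roughly 2^j to 2^(j+1) samples; a
sinusoid with period exactly 2^j sits on a band edge and splits its
energy evenly between adjacent levels, which the tests acknowledge
explicitly.

Boundary handling: the series is mirror-padded to a multiple of 2^J for
the transform and trimmed afterwards; decomposed readouts within one
scale length of a boundary, and window readouts extending past the
recording, are flagged `incomplete`.  A trend is `rejected` when more
than half (configurable) of either flanking window was interpolated.

**Calibration**: pixel values can be mapped to millimetres linearly via
a single correspondence point (default 3,300 px ↔ 4.5 mm, the
conventional dark-adapted pupil size for this tracker geometry).

## Trial bookkeeping and contrasts

Exclusions are *flags with reasons*, never deletions: misses, responses
at or below 150 ms (anticipations / false alarms; boundary inclusive),
incorrect responses where correctness applies, and the first
round-half-up(5% · N) trials per participant (116 → 6, 158 → 8).
Round-half-up is the only rounding rule consistent with both of those
counts.  For a 96-trial attention-network session the same rule gives 5;
published per-condition arithmetic for that design is ambiguous (5% of
96 is 4.8 yet "three trials" is sometimes quoted), so the fraction is
exposed as a parameter rather than special-cased.

Groups: per-participant mean split (short = RT strictly below the mean;
ties to long, since "below average" is strict), quartile split (below
Q25 vs above Q75, linear-interpolation percentiles — membership near the
cut depends on the definition, so it is fixed and documented),
correct-vs-incorrect (incorrect trials re-admitted for this scheme
only), and the attention-network contrasts (alerting: center vs no cue;
executive: congruent vs incongruent).

Statistics: the participant is the experimental unit.  Trial trends are
averaged per participant × group, then compared with a paired one-tailed
t test (expected direction: better-performance group lower).  Effect
size is paired Cohen's d = mean(diff)/SD(diff) (so |d| = |t|/√n); the
pooled-SD variant is reported alongside since published effect sizes use
either.  Within a contrast the smoothing-window family is
Benjamini–Hochberg corrected; conservative and decomposed p values are
reported uncorrected.  Zero-variance differences are flagged degenerate
(p forced to 0/1 by sign).

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
not a physiological pupil model:

| parameter | default | meaning |
|---|---|---|
| θ | 0.05 s⁻¹ | latent-state mean reversion (autocorrelation time 20 s) |
| state SD | 1 | stationary SD of the latent suboptimality s(t) |
| α | 6 px/s | tonic pupil drift per unit state (pupil integrates α·s) |
| β | 10 ms | RT shift per unit state (positive: high state → slow) |
| σ_rt | 85 ms | trial-level RT noise |
| rt_base | 370 ms | mean RT, floored at 180 ms |
| phasic | −60 px, Γ(3, 150 ms) | event-locked constriction, support < 2 s |
| σ_m | 12 px | white measurement noise per sample |
| blinks | 12 min⁻¹, lognormal ~150 ms | zeroed runs, binocular |

The latent state is an exact-discretisation Ornstein–Uhlenbeck process.
Because the tonic pupil integrates the state, a window-differenced trend
tracks the state itself: holding s ≡ +1 gives a 10 s smoothed trend of
α·10 px.  β was fixed once so that the default 17-participant cohort
yields a paired d ≈ −0.8 on the 10 s smoothed short-vs-long contrast
(measured −0.77 ± 0.24 over development cohorts); α and the noise scales
give trend differences of tens of pixels, the order of magnitude
reported for this class of task.  Task schedules reproduce the three
designs (29 × 4 vigilance latencies of 1–8 s in 250 ms steps; 158
two-back trials of 3.5 s with the two-back position-reuse rule; 96
attention-network trials with balanced cues and targets), and the
attention-network config adds cue/target main effects with no-cue and
incongruent slower.

What the generator does **not** emulate: luminance-dependent gain,
pupil foreshortening, gaze-dependent geometry, asymmetric or monocular
blinks, non-stationary fatigue trends, or any specific neural impulse
response.  Passing recovery tests therefore shows that the *pipeline*
detects couplings of the assumed form at realistic noise levels — not
that real recordings satisfy those assumptions.

## Parameter recovery and problem sizes

`recovery_experiment` simulates replicate cohorts, runs the full
pipeline (blink handling → binocular trends → exclusions → RT split →
paired contrast) and reports rejection rates.  Replicates are generated
at 250 Hz: trend indices are window means, invariant to sampling
density, and a 4 ms sample period keeps the dyadic wavelet scales
exactly on their millisecond labels while letting hundreds of replicate
cohorts run on one CPU.  The acceptance surface is 100 coupled
replicates (expected: ≥70% rejections, short-RT group lower) and 200
null replicates with β = 0 (expected: rejection near the 5% nominal
level).  Development null runs totalling over a thousand replicate
cohorts put the observed type-I rate at ≈4–5.5%, consistent with the
nominal level; individual 200-replicate measurements scatter by a
couple of percentage points, as the binomial sampling error implies.

## Numerical conventions

- Times in ms, diameters in px throughout; window lengths accepted in
  seconds at the API surface and converted internally.
- Sample-index mapping `round(t · rate)`; inclusive window endpoints.
- Moving-average positions whose window leaves the recording are NaN —
  never partially averaged.
- Degenerate inputs (zero-variance differences, empty groups, eyes with
  no valid samples) raise or flag explicitly; nothing is silently
  dropped except where a rule says so (and then it is logged).
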