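# Methods

This note documents the measurement model implemented by `facegaze`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that matter
for reproducing its outputs.

## Geometry and units

All positions live in screen/stimulus pixel space (origin top-left, y
downward, 0-based). Angular conversion uses the small-angle per-pixel
subtense `atan(pixel_size_cm / viewing_distance_cm)` per axis, so
horizontal and vertical factors differ for non-square pixels. The
default rig is a 1680×1050 display of 47.4×29.6 cm viewed from 80 cm
(≈0.020°/px both axes), with a centred face box subtending 8.8°×11.6°
— the stimulus size for which the default analysis parameters are
calibrated.

Regions of interest are simple polygons with closed boundaries (a point
on an edge belongs to the region). The default layout places three
non-overlapping rectangular bands inside the face box — eyes/brow
(22–45% of face height), nose/cheek (45–66%), mouth (68–88%) — leaving
the forehead and chin uncovered; fixations outside all regions are
labelled `other`. The published region shapes are not available as
coordinates, so the layout is parameterised by band fractions and fully
configurable; if misconfigured regions overlap, membership is resolved
by the fixed priority eyes > mouth > nose. Morph-clip timing follows
the frame-accumulation rule `total = round(n_frames · 1000/fps)` ms,
giving 1,033 ms for the canonical 31-frame, 30-fps clip.

## Event detection (I-VT)

Instantaneous angular speed at sample *i* is the central difference
over its two neighbours, `|θ(i+1) − θ(i−1)| / (t(i+1) − t(i−1))`, with
one-sided differences at stream ends and next to invalid samples, and
undefined speed where no valid neighbour exists (such samples are
treated as stationary). No smoothing is applied by default — the
published recording pipeline's internal filtering is not documented, so
the package states its own convention and exposes a configurable
moving-average window instead of guessing.

Samples at or above the 40°/s peak-velocity threshold form saccades;
below-threshold runs are fixation candidates; candidates shorter than
the 80-ms minimum (boundary inclusive: 40 samples at 500 Hz) are
discarded. Invalid-sample runs are blinks when ≥75 ms (a conventional
criterion; the source procedure states none) and dropouts otherwise;
either way they are excluded from net gaze. Fixations are not merged
across short saccades by default (merge parameters exist but are off,
again because the source states no rule). A fixation ongoing at display
offset is truncated there.

Time accounting is sample-exact: a sample at *t* owns `[t, t+dt)`, so
fixation + saccade + invalid + discarded-candidate time equals
`n_samples · dt` identically. At 500 Hz the 1,033-ms display is covered
by 517 samples (1,034 ms of sample time, within one sample of the
nominal duration); the conservation identity is the pipeline's primary
self-check and is asserted exactly in the tests.

## Scanpath measures and by-items aggregation

A fixation belongs to the region containing its centroid. Centroid
attribution keeps gaze duration consistent with fixation counts
(`gaze ≥ 80 ms × count` per region); per-sample attribution is
available as an option for gaze duration since the published definition
does not disambiguate the two.

The carried-over central fixation — gaze still parked on the nose-area
fixation-cross location when the clip starts — is identified as the
leading fixation(s) whose centroid lies within 1.0° of the cross, and
is discarded for the first-fixation and entry measures only. This
implements "the first fixation on the nose was removed as
uninformative" as removal of the *carried-over central* fixation, not
of every nose-landing first fixation: genuine later arrivals on the
nose count, which is what allows nonzero nose first-fixation
probabilities. Gaze duration and fixation counts keep the central
fixation (it is real nose-region viewing time).

First-fixation probabilities are shares among trials with a defined
(non-`none`) first fixation, and trials whose first fixation lands
outside all regions stay in the denominator, so regional probabilities
need not sum to 1. Entry times average over entrant trials only. Item
norms are per-stimulus means and sample SDs (ddof = 1) across
observers; all inference is by items, with stimuli as the random units.

## Time course, threshold and amplitude

Net gaze is binned into ten consecutive 100-ms intervals,
`[(k−1)·100, k·100)` on the sample grid; samples at ≥1,000 ms (the
final ~33 ms of the display) are excluded. The bin proportion
denominator is the bin length, not the fixated time within the bin, so
saccade/blink time dilutes all regions equally, regional proportions
within a bin sum to ≤1, and bins are comparable across the trial.

For an expression × region pair, each bin is tested with a one-way
by-items ANOVA across expressions; only in omnibus-significant bins
(α = 0.05) are single-step Bonferroni pairwise contrasts computed,
pooled on the omnibus error term. The expression *holds the advantage*
in a bin when its mean exceeds, and differs significantly from, every
expression in the comparison set (all others by default; a subset
probes partial advantages, e.g. excluding a co-leading expression).
The threshold is the earliest advantage bin and the amplitude the
length of the consecutive run starting there; isolated later advantage
bins are reported but not merged into the run, since an "advantage that
remains until …" is consecutive by meaning. Shrinking the comparison
set can only move the threshold earlier — a property the tests verify.

## Inferential statistics

One-way and split-plot (between-items × within-region) sums of squares
are computed explicitly; the split-plot tests the between effect
against items-within-groups and the within/interaction effects against
the item×region residual, each with its own error term for
`η_p² = SS_effect/(SS_effect + SS_error)`. No sphericity correction is
applied (three within levels, by-items, matching uncorrected reporting
conventions). These decompositions are cross-checked in the test suite
against `scipy.stats.f_oneway` and `pingouin.mixed_anova` to float
precision, and against independent explicit-loop oracles to 1e-9.

Post-hoc contrasts are pooled-variance *t* tests on the omnibus MS
error (classical practice after an omnibus ANOVA; the source does not
name its statistic), with the single-step Bonferroni adjustment
`p_adj = min(1, m·p)` over all `m` pairs (15 for six expressions).
Letter displays use insert-and-absorb assignment with letters ordered
so "a" attaches to the highest mean; the sharing-iff-non-significant
property is verified exhaustively for every produced display.

## The synthetic generator

The generator exists to give every pipeline stage programmed ground
truth, emulating the *statistical* structure the analysis assumes — not
oculomotor physiology. Per trial it holds the carried-over central
fixation for a U(150, 450)-ms residual, then alternates saccades and
fixations until display offset. The first post-centre target is drawn
from an expression-specific first-target bias (defaults: the published
normative first-fixation shares, remainder off-region); later targets
are drawn from dwell weights, optionally per 100-ms segment. Default
dwell weights encode the qualitative diagnostic-region pattern —
eyes-dominant anger (0.51) and sadness (0.48), nose/cheek-dominant
disgust (0.42), a mouth advantage for happiness (0.33), balanced
surprise and fear, and 3% off-region dwell so regional coverage comes
out near the empirical ~97% — with cross-expression separations of at
least 0.02 per region so the programmed ordering is statistically
recoverable at study size (40 items × 20 observers).

Fixation durations are log-normal (median 250 ms, σ = 0.4, clipped to
60–800 ms), a conventional empirical shape; saccades are straight
constant-velocity ramps at 300°/s (no main-sequence dynamics — velocity
just needs to cross the 40°/s threshold cleanly); targets are uniform
points within the region at least 0.5° away from the current position;
fixation noise is Gaussian with 0.015° SD hard-clipped at 0.05° per
axis, which guarantees plateau sample-to-sample velocity stays below
the detection threshold at 500 Hz. Blinks are Poisson per trial
(default rate 0.2) with log-normal durations, realised as invalid
samples with blank coordinates. Binocular recording is emulated as a
single averaged stream. Responses are multinomial draws from a
row-stochastic confusion model (default: the shipped norms) with
log-normal RTs measured from clip offset (median = the expression's
normative RT).

Per-trial generators are seeded from (master seed, participant, trial
index), so any trial is reproducible in isolation and identical seeds
give bitwise-identical streams.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: calibration error and drift, smooth
pursuit of the morphing features, main-sequence saccade kinematics,
pupillometry, within-observer correlations beyond the shared profile,
and any coupling between where people look and what they answer
(responses are drawn independently of the scanpath). Results on real
recordings additionally depend on the recorder's filtering, which the
detector deliberately does not replicate.

One timing property follows from the renewal structure of scanpaths
and matters when interpreting time-course recovery: fixation cycles are
synchronised at trial start, and a fixation drawn before a programmed
attention shift persists on its old target for about one cycle
(~270 ms). A dwell-weight step at 400 ms therefore surfaces in *gaze*
with a lag of roughly one fixation: the statistical localiser recovers
a divergence programmed directly into by-items bin data within ±1 bin,
while in whole-scanpath simulations the detected threshold sits one to
two bins after the programmed shift. Both properties are asserted in
the acceptance tests at their own tolerances.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run entirely on synthetic
data: the recovery study uses 240 stimuli × 20 simulated observers
(tests) or × 12 (script), oracle-equivalence checks use 1,000 and 200
random streams respectively, and Monte-Carlo recovery examples use
200–2,000 trials — sizes at which every programmed contrast the design
resolves is ≥3 standard errors. All randomness flows through explicit
seeds; reruns are bit-identical, and the file pipeline is deterministic
given its inputs and configuration.

## Known limitations

Region layouts default to rectangular bands rather than the (
unpublished) hand-drawn shapes of typical stimulus sets; the omnibus
three-way expression × region × interval decomposition is not provided
(the per-bin one-way route carries the threshold/amplitude analysis);
no mixed-effects (crossed observer × item) models, no unbiased-hit-rate
or d′ sensitivity analyses, and no dispersion-based or adaptive event
detectors. Action-unit tables from automated facial-expression scoring
can be joined to the item norms by stimulus id, but no scorer is
bundled.
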