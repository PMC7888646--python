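# Methods

## Signal model and preprocessing

Recordings are synchronized tri-axial acceleration streams (m/s²) from up to
six body sites — left/right foot, left/right wrist, lumbar, sternum — on one
implicit clock (`t = i / sample_rate`, nominally 128 Hz). All analysis runs on
band-passed signals: a 2nd-order Butterworth band-pass with 1 Hz and 10 Hz
corners, applied forward–backward (zero phase). Zero-phase application keeps
step-onset timing unshifted; its cost is a doubled effective order, so the
effective gain is the squared magnitude response of the design
(`butterworth_gain` evaluates it in closed form). Velocity is obtained per
epoch by cumulative trapezoidal integration from a zero initial condition; no
drift correction is applied because epochs last only 1.25 s and the input is
already high-passed at 1 Hz, which bounds the accumulated drift.

The forward–backward filter has a boundary transient: with a 1 Hz high-pass
corner it decays below 1e-3 about 1.4 s from a recording edge and below 1e-6
about 3 s from it. The pipeline therefore keeps epochs a configurable
`guard_s` (default 0.5 s) away from the edges, beyond the window-fit
requirement. Analyses that need exact waveform equality (e.g. the noise-free
symmetry check in the test suite) widen the guard to 2 s.

## Step detection

A step onset is the first sample where the foot's sagittal-plane magnitude
√(a_AP² + a_vert²) crosses 2 m/s² upward — operationalizing "start of heel
lift" as a plane magnitude rather than a single axis (configurable). Detection
parameters:

* `threshold` = 2 m/s² (applied to the filtered signal, since detection
  follows preprocessing);
* `min_duration_s` = 0.625 s: a step's duration is the interval to the next
  same-foot onset; onsets with duration ≤ 625 ms are flagged `too_short`.
  The last onset of a bout has undefined duration and is kept if its window
  fits;
* `refractory_s` = 0.3 s suppresses secondary threshold crossings inside a
  single burst (a foot burst oscillates through the threshold several times
  within ~0.2 s). The refractory is deliberately shorter than the minimum
  step duration: a spurious crossing 0.4 s after a true onset must still be
  *seen* so the duration rule can flag it, rather than silently absorbed;
* epochs run from 250 ms before to 1000 ms after the onset, half-open in
  samples: `[onset − round(0.25·rate), onset + round(1.0·rate))`, 160 samples
  (480 per row after axis concatenation) at 128 Hz.

Rotational (turning) steps are removed per foot: PCA on that foot's per-step
sagittal profiles, discarding steps whose first-PC score falls below
mean − 1 SD. Read literally, the opposite rule ("greater than") would discard
the majority of steps, so the outlier reading is the default and the
direction is a config switch (`direction="above"` preserves the literal
form). The first component's sign is fixed (largest-magnitude coefficient
positive) so "below" is well defined. A step rejected on its trigger foot is
dropped from every sensor's epochs — steps are whole-body events.

## Templates and the reduced dimensionality space

A template is the pair (μ, C): the column mean of the reference epoch rows
and the top principal components of their sample covariance (computed by SVD
of the centered matrix; eigenvalues are singular values squared over n − 1).
Component signs are fixed by the largest-magnitude-coefficient-positive rule
so templates are reproducible across eigensolvers. Projection is
z = C(x − μ); reconstruction is x̂ = μ + Cᵀz. External data (PD participants
on a healthy-cohort template) are centered with the *reference* mean — the
coordinates measure divergence from healthy movement, which is the point of
the construction. Coordinates are raw PC scores; no whitening.

Scopes: cohort templates use 3 components and pool every valid step of every
reference participant (one row per step; a `rows="participant_means"` option
uses per-participant average steps instead). Personalized templates use 2
components fitted on the pooled ON + OFF steps of one participant.

## Symmetry

Left and right movements are made directionally comparable by negating the
mediolateral axis block: for lateral sensors, of left-side sensors; for
midline sensors (lumbar, sternum), of the left-*triggered* epochs — the
mirrored mediolateral sway must project in the same direction for the
left-step and right-step responses to be comparable. One shared template per
combination is fitted on the pooled, sign-adjusted reference steps of both
members. Each side's step cloud is summarized by its mean coordinate vector,
and the similarity is the cosine of the two means (a raw dot product is
available via `normalized=False`; cosine is the default because a raw dot
product conflates movement amplitude with symmetry). The four combinations:
feet (right foot @ right steps vs left foot @ left steps), wrists
cross-phase (right wrist @ left steps vs left wrist @ right steps), lumbar
and sternum (each @ right steps vs @ left steps). ON and OFF sessions enter
severity regressions as independent observations.

A caveat the simulator makes explicit: the cosine of two *small* mean
vectors is noise-dominated, so symmetry scores are only stable when a
participant's mean projections sit well away from the reference mean. For
healthy participants close to the cohort average, individual scores can be
erratic even at zero asymmetry and realistic noise.

## Statistical layer

* HV vs PD: two-sided Mann–Whitney U per PC coordinate, Bonferroni-corrected
  (default m = 12: 6 sensors × 2 trigger sides; m = 24 when acceleration and
  velocity are both tested). The unit of analysis is chosen by the caller;
  the shipped pipeline compares per-participant-session mean coordinates.
* Severity: OLS of the UPDRS part-3 total on per-session mean RDS coordinates
  (3-D, or 6-D when acceleration and velocity projections are concatenated);
  reported as r² with the overall-F p-value.
* Classification: logistic regression (standardized inputs), decision tree,
  random forest, Gaussian naive Bayes — scikit-learn defaults, explicit seed.
  Cross-validation is participant-grouped 10-fold by default so no
  participant appears in both train and test of a fold; an ungrouped
  stratified mode mirrors a literal 10-fold reading. Metrics (accuracy, AUC,
  precision, F1; PD positive) are computed on pooled out-of-fold predictions.
* ON/OFF: per participant/sensor/trigger, a personalized 2-PC template on the
  pooled steps, then a two-sided U test per coordinate; significant if
  min p < 0.05/2. At least 3 steps per state are required, otherwise the
  participant is reported not-assessable. (A permutation test on the 2-D
  centroid distance would be a reasonable alternative; the per-PC U test was
  chosen for symmetry with the cohort-level analysis.)
* Random-event control: one uniformly random trigger series per recording,
  shared across sensors, with windows fully inside the recording; templates
  and projections are built by the identical code path. Random alignment
  destroys step-locked structure, so HV/PD separation and severity
  correlation should vanish — and do, on the simulator.

## The synthetic gait simulator

Every site's waveform is a sum of Gaussian-windowed sinusoid bursts locked to
step onsets: feet to their own steps, wrists to the contralateral foot's
steps (arm swing is anti-phase), lumbar and sternum to both feet. The foot's
main burst is a sine/cosine quadrature pair on the AP and vertical axes, so
the clean sagittal magnitude equals the Gaussian envelope and the 2 m/s²
crossing time is analytic — that crossing is the ground-truth onset.
Mediolateral sway at the core flips sign with the stepping foot; left-side
sensors mirror the right. With zero timing jitter the half-stride is locked
to the sample grid so both feet sample the waveform at identical sub-sample
phases, preserving exact mirror symmetry through epoch extraction; bursts are
rendered slightly past both recording edges so every retained epoch has full
neighbour context.

Variability model (per-parameter defaults in `SimConfig`):

* stride period 1.1 s per foot with 20 ms SD; per-step, per-burst amplitude
  jitter 5% (independent per burst, so the healthy PCA spans one direction
  per burst rather than a single overall-amplitude axis);
* per-participant amplitude factors, shared between mirrored left/right
  bursts: SD 12% on bursts that severity does not touch, 3% on
  severity-sensitive bursts — participants differ most in traits the disease
  does not alter, which keeps the severity signal identifiable while giving
  each participant a stable signature in the RDS;
* additive sensor noise 0.3 m/s² per axis.

Disease effects: severity (integer 10–70 for PD, 0 for HV) scales down the
severity-sensitive burst amplitudes (wrist swing, core bob/AP) by
`severity_morph_gain` = 0.006 per UPDRS unit — a bradykinesia-like loss lying
inside the span of natural amplitude variation, which is what lets a
healthy-cohort template see it. Asymmetry δ = `asymmetry_gain` × effective
severity (0.005/unit) scales the *secondary* bursts of left-side or
left-triggered responses and applies a mild width/delay morph; the main foot
burst keeps its amplitude (it is detection-critical) and expresses asymmetry
through shape only. Keeping the asymmetry direction distinct from both the
dominant participant-variation axis and the common severity morph is what
makes the cosine score fall monotonically with δ. The ON state restores a
fraction `med_effect` = 0.25 of the healthy waveform (effective severity =
0.75 × severity); the recorded per-session UPDRS is the effective severity
plus integer-rounded rater noise (SD 4). Optional short-interval doublet
bursts (0.42 s before a true onset) stress the 625 ms duration rule.

`planted_effect_oracle` computes reference statistics directly from the
planted parameters — the regression of recorded UPDRS on effective severity
and on δ, and the planted ON/OFF effect — bypassing the pipeline entirely, so
recovered statistics have an independent ceiling to be compared against.

What the simulator does **not** emulate: tremor and freezing episodes, gait
timing changes with severity or medication (a timing-effect switch exists for
robustness tests but effects act on waveform shape by default), turning
geometry, sensor orientation drift, and physiological coupling between burst
parameters. Passing tests on this generator therefore demonstrate that the
pipeline recovers step-locked waveform effects under realistic noise — not
that it handles every artifact of clinical recordings.

## Problem sizes and numerics

The shipped demo study is 30 HV + 30 PD × 2 sessions of 30 s walks — about
4,500 analyzed steps — which the full pipeline processes in well under a
minute; these sizes were chosen as the smallest cohort at which all the
statistical layers (grouped 10-fold CV, Bonferroni over 12 sensors,
permutation nulls) operate in their intended regime. Degenerate inputs are
errors, not warnings: zero-variance references, fewer than n_pc + 1 rows,
fewer than 3 steps for the rotational filter or per medication state,
zero vectors under cosine similarity, rank-deficient regression designs.
Numerical tolerances in the tests are 1e-8 to 1e-12 for linear-algebra
identities and 2% for filter-gain and resampling-amplitude checks.
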