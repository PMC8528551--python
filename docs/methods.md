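# Methods

This note documents the models, parameter choices and known limitations of
`dlsalience`. It states nothing the test suite and `scripts/acceptance.py`
do not themselves compute.

## The behavioral salience model

A dichotic trial presents two scenes, one per ear; the listener's cursor
position (LEFT/CENTER/RIGHT, logged at 10 Hz) is mapped per scene to a binary
"listening to this scene" indicator: 1 on the scene's side, 0 for the center
and the opposite side alike. The **average behavioral salience** of a scene
is the mean of these indicators over all subjects and opposing scenes, on a
common 10 Hz grid.

**Quality control.** A trial's switching rate is the number of label changes
divided by trial duration. Trials outside [0.025, 1] switches/s are flagged;
a subject with more than half their trials flagged is excluded entirely.
Boundary rates are kept (the interval is closed).

**Salient events.** The curve is smoothed with three equally weighted 1.5 s
moving averages (centered windows, edge-truncated with renormalized weights,
so a constant curve stays constant and the [0, 1] range is preserved). Events
are strict local maxima of the first-order difference of the smoothed curve;
plateau runs resolve to their left edge, a 0.5 s minimum separation keeps the
tallest peak of a cluster, and a 1e-12 positivity floor suppresses spurious
round-off peaks on exactly flat stretches. Onsets are peak times minus a 1 s
nominal reaction time (clipped at zero): event times live in *stimulus time*.
The strength of an event is

    strength = slope_peak + max{ s(t) : onset < t < onset + 4 s } × P75

where P75 is the 75th percentile of the scene's positive smoothed-slope
values ("scaled by" is implemented as multiplication, which gives both
addends slope units; it is exposed as a parameter). The top 50 % of events by
strength survive pruning.

**Pruning scope.** For a single curve the cut applies within that curve. For
a scene *set* the default is a pooled cut: strengths (always per-scene
quantities, because P75 is per scene) are ranked across all scenes and the
top 50 % of the pooled list is kept. The pooled cut is what lets a scene with
no genuine behavioral structure end up with *zero* events — its residual
noise peaks are orders of magnitude weaker than event-scene peaks — whereas a
per-scene cut necessarily keeps the top half of whatever noise a flat scene
has. Per-scene pruning remains available via `pruning="per_scene"`.

**Reaction times and F-scores.** A subject responded to an event if their
first toward-scene switch falls 0.5–1.5 s after its onset; the difference is
the reaction time. Subject-wise F-scores compare a subject's toward-scene
switch times (shifted into stimulus time by the same 1 s offset) against
events extracted from the remaining subjects' average (leave-one-out), with
greedy nearest-first one-to-one matching at 1 s tolerance and precision and
recall floored at 1e-6 before the harmonic mean.

**Interobserver agreement.** Scenes are divided into 1 s segments with 75 %
overlap (477 segments for a 120 s scene); a segment is positive when an event
onset falls in [start, start+1). The detection signal is the percentage of
subjects with a toward-scene switch in the segment, with switch times shifted
back by the same 1 s reaction offset — events are defined in stimulus time,
so detections must be too, otherwise the signal is systematically one segment
late. The ROC is swept over 201 thresholds and integrated by the trapezoid
rule (ties are traversed diagonally, equivalent to half-credit).

**Chance benchmark.** For each subsample size and repetition, every scene
receives that many mapped responses drawn without replacement from the pooled
responses of all subjects and scenes, a chance event set is extracted from
the shuffled average (pooled pruning), and the detection analysis is run with
the scene's own responses against those events. Two desk-scale corrections
matter at 16 scenes and would be negligible at corpus scale: (i) a scene's
own responses are excluded from its shuffle pool (otherwise 1/16 of each draw
carries the scene's real event structure and tilts the benchmark upward);
(ii) "flat in subject count" is tested as an equivalence claim — the
confidence interval of the chance curve's total fitted change across the
whole 5–60 subject range must lie within ±0.02 AUROC — because a point-null
test on hundreds of replicates will detect physically meaningless drifts of a
few thousandths. Measured at these settings the chance floor sits at ≈ 0.50
while the structured curve rises by ≈ 0.08 over the same range.

## Acoustic features

The front end is a constant-Q magnitude envelope spectrogram: an STFT
(Hann window, one frame per 8 ms hop) pooled into 128 log-spaced channels,
24 per octave from 90 Hz, at a 125 Hz frame rate. This replaces the cochlear
hair-cell/lateral-inhibition stages of biomimetic models with a linear
filterbank envelope — a documented approximation; every feature consumes the
spectrogram generically.

- **LD** — mean of 28 bark-spaced band envelopes on [250 Hz, min(12 kHz,
  Nyquist)], linear averaging (log compression available).
- **P, H** — each unit-norm spectral slice is correlated with unit-norm
  harmonic templates (f0 grid 50–800 Hz at 48 steps/octave, harmonics 1–8
  with 1/h amplitude decay, Gaussian spread of 1/24 octave matched to the
  channel spacing). Pitch is the argmax f0, harmonicity the maximized
  correlation ∈ [0, 1]. The 1/h decay is the standard optimum-processor
  weighting; with equal-amplitude templates every f0 sharing a harmonic with
  a pure tone would tie after normalization. Silent frames carry the previous
  pitch forward and get harmonicity 0. Octave confusions for pure tones are
  inherent to template matching and acknowledged.
- **BR, BW, IR, FL** — brightness is the power-weighted (y²) spectral
  centroid in Hz; bandwidth the magnitude-weighted mean |f − BR|;
  irregularity Σ(Δy)²/Σy² across channels; flatness the geometric/arithmetic
  mean ratio. All-zero frames propagate the previous BR/BW, take IR = 0 and
  FL = 1 by convention, and are flagged in a validity mask.
- **LR, HR, RC, SC** — temporal modulations come from a parallel 500 Hz
  envelope stream (5.8 ms window), needed because 100 Hz modulations exceed
  the 62.5 Hz Nyquist of the 125 Hz spectrogram. The channel-averaged
  envelope is filtered by octave-spaced log-Gabor magnitude filters centered
  at {1, 2, 4, 8, 16, 32, 64, 100} Hz (σ = 0.55 oct) via the analytic signal;
  averaging the complex envelope across channels *before* taking energy
  suppresses channel-incoherent stochastic envelope fluctuations (which
  otherwise bury low-rate modulations of noise carriers under a broadband
  floor) while preserving scene-coherent modulations. LR and HR are mean band
  energies over 1–20 and 20–100 Hz; RC is the energy-weighted centroid over
  1–32 Hz, defaulting to the lowest center when there is no passband energy.
  SC applies log-Gabor filters at {0.25, 0.5, 1, 2, 4, 8} cyc/oct along the
  log-frequency axis of each 125 Hz frame and takes the energy-weighted
  centroid.

All series are pooled to a 64 ms hop by window means (floor convention:
a 120 s scene gives 1875 frames) and z-scored per scene per feature (scope
configurable). Event-aligned change is the mean over [onset+0.5, onset+1)
minus the mean over [onset−1, onset−0.5); onsets within 1 s of a scene edge
are flagged missing.

## Event prediction

Each z-scored feature series is smoothed with the same triple 1.5 s boxcar,
differentiated, and slope peaks above a 0.1 z/s prominence floor (0.5 s
minimum separation) become that feature's candidate onsets; the floor was
chosen so white-noise features nominate fewer than 0.05 onsets/s and is
configurable. Scenes are segmented (1 s, 0.25 s hop, half-open membership
everywhere), labels come from the behavioral events, and the 11 binary
predictions feed a closed-form Fisher discriminant with ridge ε = 1e-6 on the
pooled covariance (binary inputs are routinely rank-deficient). Inputs are
binary by default; continuous change magnitudes are a possible extension, off
by default.

Cross-validation folds partition whole scenes so overlapping segments never
leak. The learning-curve resampler draws whole scenes in a random order until
the minute budget is met (last scene truncated); within one resample the
training set at each size is a *prefix* of the next — incremental
augmentation extends, never replaces, the smaller budget, which is also what
makes paired size comparisons well-behaved. Normalized curves divide each
fold by its mean first-step value, so they start at 1 by construction. A
learning-curve "draw" in the acceptance sense is one full replicate of the
resample-averaged estimate (20 resamples × 8 folds), mirroring how such
curves are actually reported; individual (fold, resample) pairs are dominated
by which five scenes land in a 10-minute training set. Cross-cohort grids
train the LDA on one cohort's labels and test on the other's held-out scenes
with a shared fold partition.

## The synthetic-data generator

The generator is the package's study-condition definition, not a fixture.

**Scenes.** 22 kHz mono; two-minute default duration. Backgrounds: pink
(1/f) Gaussian noise, or "AM babble" — pink noise with 3–7 Hz band-limited
random amplitude modulation (depth 0.5), giving the nonzero low-rate
modulation energy of speech-bearing scenes. Planted events are mixed at an
RMS of `magnitude × background RMS` with 10 ms raised-cosine ramps:
tone pips (300–3000 Hz), harmonic complexes (f0 90–400 Hz, harmonics 1–8 at
1/h, with 4–7 Hz tremolo and 40–80 Hz roughness AM at 0.3 depth — the
voiced/alarm-like structure that gives real LR and HR signatures), white
noise bursts, and 30–80 Hz AM noise bursts. Random scenes place onsets
uniformly under a minimum gap (default 8 s, keeping salience peaks distinct
after 3 × 1.5 s smoothing) via the order-statistics construction; uniform
placement also avoids aligning event times across scenes, an artifact regular
grids introduce and natural recordings lack.

**Subjects.** Defaults: reaction latency ~ N(1.0 s, 0.25 s²) truncated to
(0.2, 3) s — 1 s being the typical behavioral lag the event extraction also
assumes; detection probability p(m) = min(1, 0.15 m), the simplest monotone
link; spontaneous exploratory moves as a 0.1/s Poisson process toward a
uniformly random other region; return to CENTER after an exponential hold of
mean 5 s unless re-captured (the return dynamic is a stand-in — real
return-to-center behavior is undocumented — and is exposed as `hold_mean`).
The detection slope and spontaneous rate were calibrated so a simulated
cohort reproduces the behavioral statistics reported for real dichotic
listeners: median switching rates of ~0.2–0.3/s, leave-one-out F-scores well
below 1, and an interobserver AUROC clearly above a ~0.5 chance floor. With
near-deterministic subjects (p ≈ 1, few exploratory moves) the chance
benchmark becomes self-consistent and collapses against the structured
curve — simulated data can be *too* clean to exhibit the phenomena of
interest. Presets: `hyperactive` (spontaneous 1.5/s, switching > 1/s) and
`inactive` (no detection, 0.01/s) exist to exercise the QC filter.

**Schedules.** Each subject hears an independent random permutation of the
scene block, two scenes per trial, so no scene repeats within a subject;
opponent diversity accumulates across subjects (~15 distinct opponents per
scene in a 16-scene block by 200 subjects).

**What passing tests do and do not show.** The generator produces stationary
backgrounds, sharply defined events and statistically homogeneous,
memory-less subjects. Passing the suite shows the *analysis machinery* is
correct and that the pipeline's qualitative phenomenology (onset recovery,
agreement growth with subject count, feature-change directions, learning
curves, cohort portability) emerges under controlled conditions. It does not
show that real listeners behave like the model — no semantics, no attention
inertia or fatigue, no loudness calibration, no headphone variability — nor
that the feature set is sufficient for natural soundscapes.

## Problem sizes

Simulated studies are sized for single-CPU desk runs: 6–16 two-minute scenes
and 80 subjects for the behavioral analyses; 32 scenes and 60 subjects for
the prediction analyses (the regime where held-out AUROC ≈ 0.75–0.9 and added
training data yields percent-level gains); 50 repetitions per subsample size
for the agreement curves; 20 replicates × 20 resamples for the learning
curve. The full acceptance run completes in a few minutes.

## Numerical conventions

Times are seconds from scene start, 0-based; all interval membership is
half-open [start, stop). Smoothing windows are forced to odd sample counts so
they are exactly centered. The slope at index i is stamped at the time of
sample i+1. ROC sweeps use 201 thresholds padded past the score range so the
curve always spans (0,0)–(1,1). All randomness flows through
`numpy.random.default_rng` seeds; a master seed spawns independent per-stage
substreams, so any pipeline stage can be re-run alone with identical output.
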