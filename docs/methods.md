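# Methods

`fogbench` implements an end-to-end benchmark for detecting freezing of
gait (FoG) in Parkinson's disease from a single waist-worn triaxial
accelerometer.  This note records the models, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic cohort does and does not establish.

## Signal conditioning

Raw acceleration (200 Hz, in g) is decimated to 40 Hz by polyphase
resampling (`scipy.signal.resample_poly`, `padtype="line"`), whose built-in
FIR low-pass suppresses content above the 20 Hz output Nyquist.  The signal
is then filtered with a causal 2nd-order Butterworth low-pass at 15 Hz.
Causal (forward-only) filtering is deliberate: the detector is meant to run
in real time on the sensor node, which cannot filter backwards.  The filter
state is initialised to the steady state for the first sample
(`scipy.signal.sosfilt_zi`); with a zero state the constant ~1 g gravity
offset becomes a switch-on step whose broadband transient reliably turns
the first window of every recording into a false positive, which is an
artefact of the filter implementation rather than of the signal.

Windows are 128 samples (3.2 s) with 50% overlap (1.6 s stride); trailing
samples that do not fill a window are dropped.  Intervals are half-open
`[start, end)` in seconds.  Because classification is per window and runs
of positive windows are merged, detections have a minimum length of 3.2 s
and a temporal resolution of 1.6 s.

## Features (55 per window)

Twelve groups; counts in parentheses.  The DFT is taken without a taper;
bands select bins whose centre frequency (bin width 0.3125 Hz) lies in the
closed interval.  Named bands: postural 0.1–0.68 Hz, walking (WB) 0.5–3 Hz,
freezing (FB) 3–8 Hz, full 0.1–8 Hz (bins 1–25).

1. per-axis window means (3) — posture relative to gravity;
2. increments of consecutive windows' means (3) — the immediately
   preceding overlapped window supplies the reference, zeros for the first
   window of a recording;
3. pairwise differences of those increments (3);
4. per-axis standard deviations (3);
5. pairwise Pearson correlations between axes (3); a zero-variance axis
   yields correlation 0 by convention (constant windows occur at rest);
6. standard deviation of spectral magnitudes of the modulus channel in the
   postural, walking and freezing bands (3);
7. highest and second-highest harmonic magnitude of the modulus in the
   postural and freezing bands (4) plus per-axis maxima in the postural
   band (3);
8. spectral centre of mass Σf·|X| / Σ|X| over 0.1–8 Hz per axis and for the
   modulus (4);
9. spectral skewness and kurtosis per axis and modulus (8), computed by
   treating normalised harmonic magnitudes over bins 1–25 as a probability
   weight on frequency (kurtosis is the plain standardised fourth moment,
   not excess);
10. three PCA projections (3), below;
11. per-axis integrals, Σ samples / fs (3);
12. Yule–Walker autoregressive coefficients of order 4 per axis (12),
    via `statsmodels`; constant axes yield zeros with a logged warning.

The exact published per-group allocation is not fully recoverable from the
available description; the allocation above is a documented default that
sums to 55 and is enforced by an invariant.  AR order 4 completes the
budget and is standard for 3.2 s gait windows.

**PCA basis.**  For each window, `S^W` stacks the cross-axis harmonic sums
|X_h|+|Y_h|+|Z_h| over bins 1–25.  A random 10% of windows per training
subject is drawn (seeded), column-centred and decomposed by SVD; the first
three right-singular directions form the orthonormal change of basis `V`.
Projections are `V·(S − mean)`.  The basis is fitted once per training set
and ships inside the model bundle; prediction never refits.  In
leave-one-patient-out runs the basis is fitted on the 20 training subjects
only — also in the personalised mode, where the held-out subject's half
adds a negligible window count to the fit.  Row signs are fixed
(largest-magnitude loading positive) for determinism.

## Freeze-index baseline

Per window, the PSD (squared DFT magnitudes) of the modulus channel is
summed over WB and FB; the freeze index FI = FB/(WB + ε) with ε = 1e−12
(guards rest windows, where both bands are near zero), and the power index
PI = WB + FB.  A window is flagged when FI > FTH and PI > PTH.  The
modulus channel is the default because it is orientation-invariant at the
waist; per-axis selection is available.  The thresholds are optimised on
the 9×9 grid {0, 0.5, …, 4}² by maximising pooled sensitivity × specificity
subject to both exceeding 70%; if no grid point is feasible the
unconstrained argmax is used (logged).  Ties resolve to the smallest FTH,
then the smallest PTH (favouring sensitivity).  Grid points where either
metric is undefined (zero denominator) are skipped and logged.

The personalised variant blends the pooled leave-one-out surface with the
surface of one of the test subject's own episode-halves:
`Sens(PM) = Sens(LOO)·w_t + Sens(half)·w_20` (likewise specificity), with
the weight attachment exactly as published — w_t, the large cohort-side
weight, multiplies the pooled term.  Because this is arguably the reverse
of the weighting intent described for the SVM, a configuration switch
`personalization_weight_convention ∈ {as_printed, swapped}` exposes both
readings without arbitrating.

## SVM classifiers

Windows are labelled +1 when at least 50% of their 3.2 s span overlaps a
ground-truth episode (configurable, `label_overlap_min`).  Features are
z-scored with training-set statistics stored in the model bundle — an
implementation addition: mixed-unit features are scale-pathological under
an RBF kernel.  The classifier is the standard soft-margin RBF SVM dual
(the published objective prints "minimize" over the standard maximisation
form; the standard dual is implemented, via `sklearn.svm.SVC`).

**Generic mode** is leave-one-patient-out: for each held-out subject,
C and γ are selected from {10⁻², …, 10²}² by stratified 10-fold
cross-validation on the other subjects' windows, maximising mean
sensitivity × specificity under the 70%/70% constraint, with the same
unconstrained fallback and smallest-C-then-γ tie-break.  CV metrics are
window-level: folds destroy temporal contiguity, so episode-level scoring
is reserved for the final evaluation.  If a class is too scarce for ten
folds the fold count is reduced and logged.

**Personalised mode** splits the held-out subject's episodes
chronologically: half 1 holds the first ⌈E/2⌉ episodes and all signal
before the split time (the midpoint of the gap between the two middle
episodes); half 2 the rest.  Training uses the 20 other subjects plus one
half, with per-pattern cost caps C·w_t on the subject's own patterns and
C·w_20 on the cohort's, where w_t = n20/(n20+n_half) and
w_20 = n_half/(n20+n_half) — the two groups then carry equal total
influence (n_half·w_t = n20·w_20).  The caps are realised through
per-sample weights, which scale the box constraint exactly.
Hyperparameters are re-selected on the weighted training set.  The model
is evaluated on the complementary half only; the procedure runs twice with
halves swapped and the episode-level counts are pooled.

## Episode-based evaluation

Window scoring inflates both TP (long episodes) and TN (long quiet
stretches).  Instead: each ground-truth episode counts once as TP (some
detection overlaps it) or FN; each detection overlapping no episode is one
FP (a detection spanning two episodes marks both detected; several
detections inside one episode still make one TP).  The parts of a session
free of both episodes and detections are split into maximal clean spans;
a span of length L contributes floor(L/30) TN plus one more if the
remainder strictly exceeds 5 s — so 40 s ⇒ 2 TN, 30 s ⇒ 1, 4 s ⇒ 0.  The
30 s cap and 5 s floor mirror the original protocol's false-positive task
duration and the mean episode length (5.14 s).  Boundary contact is not
overlap under half-open intervals.  Detections extending up to one window
past a session or split boundary (a windowing/resampling artefact) are
clipped to the span; the complementary evaluation covers the remainder.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), GM = √(Sens·Spec).
Undefined metrics (zero denominators) are reported as missing, never as 0.
Cohort cells are pooled by summing counts; per-subject tables are also
emitted because published per-patient summaries average per-subject
metrics instead — both conventions are available.

## Synthetic cohort

The clinical recordings are not deposited, so the generator synthesises a
stand-in cohort realising exactly the properties the methods exploit, and
is labelled as such:

* **walk**: step-frequency sinusoid (0.9–1.4 Hz) plus a second harmonic
  and a small lateral component, along the gravity axis so the modulus
  carries it; rest is gravity plus white noise; segments get 0.25 s
  raised-cosine amplitude ramps to limit boundary splatter.
* **fog**: tremor sinusoid (freezing band) along a subject's tremor
  direction with the walking-band content attenuated tenfold.  Tremor
  amplitude is ~4× the walk amplitude so a clean fog window's freeze index
  reaches the 10³ range.
* **fp_activity** (ON sessions only): freezing-band oscillation in a
  *leaning* posture with per-axis phases 120° apart, giving pairwise
  cross-axis correlations of ±½ where a linear tremor gives ±1 — the band
  ratio cannot tell it from FoG, but posture and correlation features can.
  Axis signs are chosen to keep the oscillation visible on the modulus.
* Amplitudes are calibrated so the power index of default walking sits
  near 2 grid units, making the printed 0–4 threshold grid meaningful;
  walk 0.022 g, tremor 0.09 g, noise SD 0.004 g.  The SVM path z-scores
  features, so the absolute scale does not matter to it.
* Episode durations are log-normal (σ_log = 0.45, mean 5.14 s, floor 1 s).
  Each subject has an OFF-like session (more, longer FoG) and an ON-like
  session (fewer episodes plus the false-positive block) on one time axis,
  60 s apart; session spans are scored separately so detections and clean
  spans never bridge the gap.
* Two cohort flavours: `separable` uses cohort-consistent body-frame fog
  and fp signatures, the regime where one generic model suffices;
  `heterogeneous` draws subject-specific fog and fp postures and tremor
  directions from one common distribution, leaving no cohort-level cue —
  only within-subject structure, which is the regime where personalised
  training pays off.
* Randomness: one master seed; per-subject child seeds via
  `numpy.random.SeedSequence.spawn`.

What passing tests show: the pipeline recovers planted, physically
motivated structure (band energies, postures, correlations) through the
full train/evaluate protocol.  What they do not show: performance on real
patients — real FoG is nonstationary, episodes have gradual onsets, sensor
placement varies within a session, and activities of daily living are far
richer than four segment kinds.  The published per-cell accuracies are
properties of the original cohort and are not reproduced here; only the
printed arithmetic identities among them are checked.

## Problem sizes in the test suite

The default protocol template approximates two ~20-minute sessions per
subject.  The test suite exercises the full 21-subject pipeline on a
reduced template (`ProtocolTemplate.reduced(0.12)`: 2 OFF / 1 ON episodes
per subject, 5 s walk and 4 s rest bouts, one 10 s false-positive block,
~1250 windows cohort-wide), which keeps the complete grid searches —
25 (C, γ) pairs × 10 folds per held-out subject and the 81-point threshold
grid — intact while a full four-cell run remains a desk-scale computation.
Hyperparameter search shares one squared-distance matrix per CV fold
across all 25 grid pairs and materialises the RBF kernel once per γ.

## Known limitations

* The per-group feature allocation is a documented stand-in (the 55 total
  is enforced); a corrected allocation can be dropped in via the feature
  module's constants.
* Spectral skew/kurtosis band choices (bins 1–25) and the AR order are
  package decisions, stated above.
* The published weighting of the personalised threshold blend is
  implemented as printed; the `swapped` convention is available but
  nothing arbitrates between them.
* The generator plants stationary sinusoidal structure; it cannot support
  claims about gradual freeze onset, turning-related freezes, or gait
  asymmetry.
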