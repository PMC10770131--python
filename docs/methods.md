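# Methods

This note documents the models, parameters, and design choices behind
`tremorkit`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort generator

The generator produces per-participant assessment sessions with the
statistical structure the downstream analysis assumes. Each subject draws a
latent phenotype from class-conditional ranges:

| parameter | PD | DD | HC |
|---|---|---|---|
| tremor frequency (Hz) | U(4, 6) | U(5, 8) | — |
| tremor amplitude (g) | U(0.05, 0.25) | U(0.05, 0.25) | 0 |
| active contexts | rest | postural, kinetic | none |
| side-dominance fraction | U(0.70, 0.95) | U(0.50, 0.70) | — |

Rest tremor in the 4–6 Hz band with strong side dominance is the classic PD
presentation; the differential-diagnosis group is modelled as a single
configurable action/postural-tremor family (its clinical sub-groups —
essential tremor, atypical parkinsonism, multiple sclerosis — are not
simulated separately). Amplitudes sit far above the ~0.001–0.005 g
resolution of consumer smartwatch accelerometers, i.e. these are overt
rather than sub-clinical tremors.

A recording for one (step, wrist, sensor) is the sum of

* a gravitational component (acceleration only): a random unit orientation
  vector plus a piecewise-linear random walk (knots every 2 s, step SD
  `gravity_drift_scale` = 0.02 g/s), matching the piecewise-linear trend
  model the corrector assumes;
* a gated tremor sinusoid: active only when the step's task category is in
  the subject's tremor contexts, scaled per wrist by the side-dominance
  fraction, modulated by a slow (≤ 1 Hz) multiplicative log-normal envelope
  (σ = 0.2) so the spectral peak stays sharp, and projected onto a random
  3-axis loading; rotation-rate tremor uses the same carrier scaled by
  `rotation_scale` = 2 rad/s per g;
* a 0.5-s 25-Hz vibration burst at the start of every recording (the watch's
  start-of-step notification), amplitude 0.3 g, so the onset-trim stage has
  an observable effect;
* white Gaussian sensor noise, SD 0.01 g.

Questionnaire answers are independent Bernoulli draws from 30 per-class
probabilities; the defaults give PD elevated rates concentrated in the
sleep/fatigue and gastrointestinal domains, HC low rates, and DD
intermediate, less PD-specific rates. Demographics echo the study cohort's
marginals: class sizes 276 PD / 79 HC / 114 DD by default, male fractions
195/276, 29/79, and 57/114, and Gaussian ages (65.4 ± 9.6, 62.9 ± 12.5,
62.4 ± 11.5 years, clipped to 30–95). A single seeded generator drives all
draws; identical configs are bit-identical.

What the generator does **not** emulate: rigidity, bradykinesia, gait or
balance phenomena, medication on/off states, biomechanical coupling between
axes, non-stationary tremor frequency, or realistic questionnaire item
correlations. Passing recovery tests therefore shows the pipeline detects
oscillatory class signal placed where the protocol expects it — not that it
would reach the same accuracy on clinical recordings.

## Preprocessing

Order: drop excluded steps → trim 0.5 s → split 20-s recordings into two
halves → truncate all segments to the shortest common length (950 samples:
10 s minus the trim at 100 Hz) → degravitate acceleration. Trimming before
splitting reflects that the notification buzz occurs once per recording; the
two ~9.75-s halves of a 20-s step are then equalised with the 9.5-s short
steps by tail truncation.

l1 trend filtering minimises ½Σ(xₜ−zₜ)² + λΣ|zₜ₋₁−2zₜ+zₜ₊₁|. The solver is
a primal-dual interior-point method on the dual box-constrained QP with
banded Newton systems (O(n) per iteration); it terminates at a relative
duality gap of 1e-6 (default) and the recovered primal is optimal to better
than 1e-4 relative objective error across the λ range used here — the test
suite checks the solution's objective against the raw input and the
least-squares line at that slack. λ = 0 returns the input; an exact linear
ramp is a fixed point for any λ.

Default λ = 10⁴ on g-scaled 950-sample segments: at this weight the trend
tracks orientation drift below ~1 Hz while leaving the 4–8 Hz tremor band
untouched (verified spectrally in the tests). Rotation channels are not
degravitated — rotation rate carries no gravity offset. The residual is
computed by subtraction, so residual + trend reconstructs the input exactly.

## Features

**Manual (option A).** Welch PSD with 1-s (100-sample) Hann windows and 50%
overlap — the window length is what makes the 1-Hz bin spacing exact at
100 Hz. Bins 1–19 Hz are kept (DC and >19 Hz discarded) and mapped through
`log(p + 1e-12)`; the floor handles zero-power bins and makes the choice of
natural log a pure scale decision. Segment statistics use four equal-length
segments (tail remainder dropped); "absolute energy" is Σx² with Σ|x|
available behind a config switch. 19 + 12 = 31 features per channel,
concatenated channel-major.

**BOSS (option B).** Per channel and window length (20, 40, 80 samples),
sliding windows at stride 1 are z-normalised (guarding zero variance), DFT'd,
and the first 4 coefficient components (real/imaginary interleaved, DC
dropped when normalising since it is identically zero, kept otherwise)
are quantised into 4 symbols by equi-depth bins fitted **on training data
only**. A value equal to a bin edge falls in the lower bin. Words are counted
with numerosity reduction (runs of identical consecutive words count once)
into dense 4⁴ = 256-bin histograms, concatenated channel-major,
window-minor, so feature positions are stable across subjects. Word length,
alphabet size, binning, and normalisation are standard BOSS defaults,
exposed in the config.

## Modelling

* **CV plan:** stratified subject-level assignment (scikit-learn
  StratifiedKFold, shuffled, seeded). All of a subject's segments share one
  fold, precluding identity confounding.
* **Sample weights:** for gender×class group g, w_g = N/(G·n_g) over
  non-empty groups of the current task pair — every group carries equal
  total weight. Weights enter the SVM and gradient-boosted-tree losses; the
  feed-forward network is fitted unweighted (its loss has no per-sample
  weighting hook), a deliberate simplification documented here.
* **Registry:** RBF-kernel SVM (sigmoid-calibrated for probabilities, C in
  the grid) behind a train-fold standard scaler; histogram gradient-boosted
  trees (min_samples_leaf = 5 so trees can split at cohort sizes in the tens,
  otherwise library defaults); two-hidden-layer ReLU MLP (64, 32) behind a
  scaler. Standardisation matters because PSD/energy features span decades.
* **Grid search:** mean inner-fold balanced accuracy; ties break by
  enumeration order (documented, stable). Failing grid points are skipped
  with a warning; all-failing raises. Option-A features are stateless per
  subject, so they are precomputed once and sliced by fold — leakage-free by
  construction; option-B bins are refitted inside every training split.
* **Gender matching:** within each gender, every class cell is randomly
  under-sampled to the smallest class's cell size, equalising the gender mix
  across classes. Folds whose cells are empty record no matched score (the
  direct API raises, naming the cell).
* **Stacking:** meta-features are each sub-model's positive-class (PD)
  probability — for two classes the full probability vector adds nothing.
  The meta logistic regression is unpenalised (two features, intercept on)
  and trained on out-of-fold predictions: each training subject's
  meta-feature comes from a sub-model that never saw that subject; the
  per-row inner fold is retained for auditability. Sub-models are refit on
  the full training fold for test-time prediction. The questionnaire
  sub-model uses the 30 raw answers only — no demographics.
* **Importance:** one shared permutation per group per repeat (preserving
  within-group joint structure — the standard grouped-importance
  definition); importance is the mean balanced-accuracy drop over 50 repeats
  by default, averaged over test folds when run per fold. The 30 items map
  onto nine conventional non-motor-symptom domains by default; the mapping
  is configurable because item order varies between questionnaire releases.

## Calibration studies and problem sizes

The acceptance script and test suite run four statistical studies, sized so
the whole battery completes in minutes on one CPU while keeping the
conclusions stable across seeds:

* **Recovery:** default phenotypes, 100 subjects per class, full protocol,
  option A with a two-point grid — mean outer balanced accuracy ≥ 0.90
  expected (observed ≈ 1.0).
* **Null calibration:** both labels drawn from the HC phenotype, 24 per
  class on a reduced 3-step protocol (one step per task category), 20 seeds
  — the mean must lie within 3 standard errors of 0.5.
* **Stacking dominance:** a constructed cohort where half the PD subjects
  carry only sensor signal and half only questionnaire signal (40 per class,
  3 seeds) — either modality alone tops out near 75%, the stack must exceed
  the better single modality by ≥ 5 balanced-accuracy points.
* **Importance sanity:** cohorts whose only class signal is rest tremor with
  identical questionnaire rates (16 per class, 10 seeds) — the Resting task
  group must rank first in ≥ 9/10 runs, and provably ignored groups score
  exactly zero.

The reduced protocol and cohort sizes are the package's own choices for
repeated-seed studies; all of them are parameters, and the full 11-step
protocol at the study's cohort size runs through exactly the same code path.

## Known limitations

* The DD phenotype is a single family; sub-group-specific signatures are out
  of scope.
* The session reader targets this package's documented JSON layout; an
  adapter for externally produced session files would need its key
  vocabulary confirmed against that release's documentation.
* Calibrated SVM probabilities at very small inner folds (cv = 3 inside the
  calibrator) are coarse; stacking results at n ≲ 20 per class are
  correspondingly noisy.
* Deep-learning feature extraction and time-series augmentation are
  deliberately out of scope.
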