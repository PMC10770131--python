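# tremorkit

Smartwatch-based classification of Parkinson's disease (PD) against healthy
controls (HC) and against clinically similar differential diagnoses (DD,
e.g. essential tremor, atypical parkinsonism, multiple sclerosis), from an
interactive dual-wrist assessment plus a 30-item non-motor-symptom
questionnaire.

The package is aimed at researchers in digital movement-disorder biomarkers
who want a tested, fully reproducible reference pipeline: every stage — from
raw 100-Hz accelerometer/gyroscope JSON recordings to cross-validated
classification reports and feature-importance tables — is a library function
with a synthetic cohort generator standing in for clinical data, so the
whole analysis runs and is testable without any data download.

## The analysis

**Assessment structure.** Each participant performs an 11-step protocol
(three 20-s steps, eight 10-s steps) while wearing a smartwatch on each
wrist; each step is recorded as 3-axis acceleration (g) and 3-axis rotation
rate (rad/s) at 100 Hz. Steps are categorised as *Resting*, *Postural*, or
*Kinetic* by the tremor regime they provoke. After splitting 20-s steps in
half this yields 14 ten-second task segments and 168 single-axis channels
per participant (14 × 2 arms × 2 sensors × 3 axes); three steps are dropped
by default before modelling, leaving 132.

**Preprocessing.** The first 0.5 s of every recording (watch notification
buzz) is trimmed. Gravitational orientation drift is removed from the
acceleration channels by l1 trend filtering: the piecewise-linear trend

$$\hat z = \arg\min_z \tfrac12\sum_t (x_t - z_t)^2 + \lambda \sum_t |z_{t-1} - 2z_t + z_{t+1}|$$

is estimated (primal-dual interior-point solver on the dual box-constrained
QP) and subtracted, leaving the physiological signal.

**Features.** Option A: per channel, Welch power spectral density at 1-Hz
resolution (bins 1–19 Hz, log-scaled) plus the standard deviation, maximum
absolute amplitude, and absolute energy of four equal segments — 31 features
per channel. Option B: Bag-of-SFA-Symbols (BOSS) histograms; each channel's
sliding windows (20, 40, 80 samples) are Fourier-transformed, the leading
coefficients quantised into 4-symbol words with bins fitted on training
folds only, and word counts (with numerosity reduction) concatenated.

**Modelling.** Subject-level stratified 5×5 nested cross-validation: the
inner folds drive a grid search over input source (acceleration, rotation,
both), feature option, and classifier (RBF-kernel SVM, gradient-boosted
trees, feed-forward network), maximising balanced accuracy (the mean of
per-class recalls). Gender×class sample weights
$w_g = N/(G\,n_g)$ balance the loss across the four demographic cells, and
test folds are additionally scored on a gender-matched random under-sample.
A logistic meta-classifier stacks the best sensor model with a
gradient-boosted questionnaire model using out-of-fold probability
predictions. Grouped permutation importance (shared within-group
permutations, balanced-accuracy drop) attributes the final model's skill to
questionnaire symptom domains and assessment-step task categories.

## Worked example

```python
from tremorkit.synth import GeneratorConfig, generate_cohort
from tremorkit.preprocess import PreprocessConfig
from tremorkit.modeling import build_cohort_data, make_cv_plan, default_grid
from tremorkit.stacking import evaluate_stacked

config = GeneratorConfig(n_pd=20, n_hc=20, n_dd=0, seed=42)
sessions = generate_cohort(config)                  # 40 synthetic assessments
data = build_cohort_data(sessions, PreprocessConfig())
plan = make_cv_plan(data.subject_ids, data.labels, outer_k=5, inner_k=3, seed=42)
grid = default_grid(options=("A",), classifiers=("svm", "gbdt"), svm_C=(1.0,))
reports = evaluate_stacked(data, plan, grid, seed=42)
for name, report in reports.items():
    mean, sd = report.summary()["balanced_accuracy"]
    print(f"{name:>13}: balanced accuracy {100 * mean:.2f}% (SD {100 * sd:.2f}%)")
```

prints

```
      stacked: balanced accuracy 95.00% (SD 6.12%)
       sensor: balanced accuracy 95.00% (SD 6.12%)
questionnaire: balanced accuracy 97.50% (SD 5.00%)
```

With the default synthetic phenotypes (4–6 Hz rest tremor for PD, none for
HC, class-conditional questionnaire rates) both modalities separate the
classes well at n = 20 per class; the per-fold reports also record the best
sensor setup chosen by the inner grid search (here
`acceleration/option-A/svm(C=1.0)`) and the gender-matched scores.

The same workflow is available from the shell:

```bash
tremorkit simulate --n-pd 20 --n-hc 20 --seed 42 --out runs/cohort
tremorkit validate runs/cohort/*
tremorkit run-all --config examples/run.yaml
```

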