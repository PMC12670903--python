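# Methods

## Scope and model of the data

The package analyses first-pass perfusion at the ROI-curve level: each
patient contributes one signal-intensity (SI) time course per tissue
(spleen, remote myocardium, LV blood pool) and condition (adenosine stress,
rest), in arbitrary units on a common frame grid. Image acquisition, ROI
drawing, slice selection within 3D stacks and the visual ischemia read are
upstream of this package; the visual read enters only as a per-patient
positive/negative label. The reference standard is a per-patient CAD flag
(functionally significant stenosis in any vessel, FFR < 0.8); per-vessel
FFR values are deliberately reduced to this flag before the analysis, with
the CSV schema leaving room for a per-vessel extension.

## Enhancement curve model

Measured first-pass curves are summarized by a normalized gamma-variate:

    SI(t) = b                                   for t <= t0
    SI(t) = b + A (x)^a exp(a (1 - x)),  x = (t - t0) / (a s),  for t > t0

with baseline `b` (a.u.), amplitude `A` (a.u.), onset `t0` (s), shape `a`
(dimensionless) and scale `s` (s). The normalization makes the curve's
maximum exactly `b + A`, at `t0 + a s`. The gamma-variate is the standard
empirical shape for a first-pass contrast bolus; the normalized form is
chosen so that peak amplitude is an explicit, recoverable parameter — the
property the simulator's generative-identity checks rest on. No curve
*fitting* is performed anywhere: the model generates synthetic data, and
measurement operates directly on the sampled frames, as it would on real
ROI curves.

## Synthetic cohort generator

Each patient is drawn from an independent random substream spawned from the
root seed and the patient counter, so cohorts are reproducible and
insensitive to iteration order. Per patient:

- **Labels.** CAD ~ Bernoulli(0.58); stress adequacy ~ Bernoulli(0.73).
  Both prevalences follow the printed statistics of a multicenter
  FFR-referenced perfusion cohort (104/179 pathological FFR; switch-off in
  73%).
- **Splenic switch-off.** The splenic stress amplitude is
  `gamma * rest amplitude`, with `gamma` uniform on [0.05, 0.30] under
  adequate stress and [0.50, 1.10] under inadequate stress. No published
  distribution exists for these fractions; the ranges are calibration
  choices that place the two classes on either side of the clinically
  reported cutoffs (0.25–0.38) with a clear gap, and they are fully
  config-exposed.
- **Kinetics.** Blood pool arrives first (onset uniform 4–7 s), then spleen
  (+1–3 s), then myocardium (+2–4 s); shapes uniform 2–4, scales 1.5–2.5 s
  (blood pool 1–2 s), baselines and amplitudes uniform in tissue-typical
  ranges (e.g. splenic rest amplitude 50–90 a.u.). Within a tissue, stress
  and rest share onset/shape/scale and differ only in amplitude
  (myocardial stress amplitude is the rest amplitude times a hyperemia
  factor 1.3–2.0). Sharing the timing is a deliberate idealization: it
  makes the measured stress/rest ratio equal `gamma` exactly in the
  noise-free limit, giving the pipeline an exact end-to-end oracle. Real
  stress shortens transit times; that shift is not modelled, and tests
  passing on these data say nothing about robustness to stress-dependent
  bolus timing.
- **Noise.** Additive white Gaussian noise, default sd 2 a.u., on every
  frame of every series. Rician bias, drift, motion and arrhythmia
  artifacts are not modelled.
- **Reads.** The CMR read is negative for all non-CAD patients (a
  false-positive probability exists as a config hook, default 0, as the
  handful of false positives in real cohorts is immaterial to an analysis
  conditioned on negative reads). CAD patients are read negative with
  probability 0.05 under adequate stress and 0.50 under inadequate stress —
  the enrichment of false negatives under failed vasodilation that the
  markers are supposed to detect. The visual switch-off read is the
  indicator `gamma <= 0.70` (midpoint of the two ranges' upper ends),
  flipped with probability 0.05; the stress-only visual read uses the same
  indicator with a higher flip probability (0.15), reflecting that judging
  splenic enhancement against the myocardium on stress images alone is the
  harder read. These error rates were fixed once as generator defaults.
- **Hemodynamics.** Rest HR ~ N(66, 12²) bpm with a stress increment of
  N(16, 8²) (adequate) or N(4, 4²) (inadequate), anchored to printed
  cohort means of 66 rest / 82 stress. Rest systolic BP ~ N(129, 21²) mmHg
  with stress increments N(−4, 10²) / N(+3, 8²), consistent with the
  printed 129→127 cohort means; diastolic analogues N(73, 10²) and
  N(−2, 5²).

## Measurement

Baseline SI is the mean of the first `n_baseline_frames` frames (default
3; the count is rarely reported in practice and is configurable). The peak
myocardial frame is the argmax of the myocardial SI, earliest frame on
ties. Both ratios subtract each curve's own baseline and are evaluated at
the peak myocardial frame; the rest-condition anchor defaults to the rest
acquisition's own myocardial peak (`rest_anchor="independent_peak"`),
with `"same_frame_index"` available to reuse the stress frame index.
Time-to-peak is measured from the series start (injection timing is not
modelled), and "upslope" is implemented as the max-minus-min SI range —
the name is kept from measurement practice even though the quantity is a
range, not a slope.

Denominators with |enhancement| ≤ 1e−6 a.u. raise a degenerate-enhancement
error; such patients are excluded with a per-patient logged reason, never
silently dropped.

## Evaluation statistics

- **2×2 summaries.** Full precision internally; percentages are rounded to
  one decimal and likelihood ratios to two only at report time. Both
  conditioning conventions are computed; `marker_conditional` reproduces
  published SSO predictive-performance tables, whose printed values
  condition on marker status rather than on the reference outcome. The two
  conventions are transpose-duals of each other, which the tests assert.
- **ROC.** The sweep visits every distinct score (plus a call-nothing
  sentinel), ordered from no positive calls to all; for the splenic ratios
  the default direction is `lower_is_positive` (a low ratio means adequate
  stress). AUC is the trapezoidal area, identical to tie-corrected pairwise
  concordance. The Youden-optimal cutoff maximizes tpr − fpr, breaking ties
  toward fewer positive calls; the reported value is the midpoint between
  the optimal threshold score and the next distinct score, so it separates
  observed values while inducing the identical classification.
- **Cross-validated AUC.** Stratified k-fold (default 5) by seeded
  permutation within each class; the estimate is the unweighted mean of
  held-out-fold AUCs. The 95% CI uses the pooled influence-function
  variance estimator: each observation's influence value is evaluated at
  its own fold's AUC, and se² = mean(IC²)/n. The CI method is recorded in
  the result object and report.
- **Agreement.** Cohen's kappa with marginal-product expected agreement;
  undefined when both raters are constant. ICC is the two-way
  random-effects, absolute-agreement, single-measurement form ICC(2,1) via
  the mean-squares formula — chosen because repeated readings of the same
  subjects by interchangeable observers is the matching design — with
  categories poor (<0.5), moderate (0.5–<0.75), good (0.75–0.9), excellent
  (≥0.9).

## Pipeline and determinism

`run_pipeline` chains simulate → measure → classify → evaluate and writes
the cohort CSVs, `metrics.csv`, `calls.csv`, a schema-versioned
`report.json` (embedding the config hash and seed) and a structured
`run.log` of `(stage, patient_id, event)` lines. Log lines deliberately
carry no wall-clock timestamps so that a fixed configuration yields
byte-identical output trees; floats are serialized with 17 significant
digits and re-parsed with round-trip precision, making write/read an exact
identity.

## Problem sizes in tests

The test suite exercises cohorts of 179–200 patients for end-to-end
checks, 2000 for prevalence-calibration and rate-ordering checks (exact
binomial 99% intervals), 4000 scores for the binormal cvAUC closed form
Φ(Δ/√2), and 1000 subjects for variance-component ICC recovery — sizes at
which the stochastic checks have comfortable margins while the whole suite
runs in well under a minute.

## Known limitations

- The simulator's idealizations (shared stress/rest timing, Gaussian
  noise, uniform parameter ranges, a single adequacy-driven mechanism for
  false negatives) make it a test harness for the analysis logic, not a
  physiological model; cohort-level agreement statistics it produces (e.g.
  kappa between the two visual reads) depend on invented error rates and
  should not be read as estimates of anything clinical.
- Only per-patient reference labels are supported; per-vessel FFR is out
  of scope.
- No DeLong CI or AUC-comparison tests; no multiple-testing correction.
- Published cohort-level cvAUCs and kappa values for the real patient data
  are not reproducible from counts alone and are therefore not asserted
  anywhere; only internally consistent printed tables are shipped as
  executable worked examples.
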