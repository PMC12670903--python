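# ssokit

Splenic switch-off (SSO) stress-adequacy analysis for adenosine stress
perfusion cardiovascular MR (CMR).

## The problem

A negative adenosine stress perfusion CMR is only reassuring if the
adenosine actually worked. The spleen provides a built-in control:
adequate vasodilator stress visibly reduces splenic enhancement during
first-pass perfusion compared to rest — splenic switch-off. A negative
scan *without* switch-off may be a false negative caused by inadequate
stress rather than absent coronary disease.

`ssokit` is for researchers evaluating quantitative SSO biomarkers. It
implements the full analysis chain:

1. **Simulation** — synthetic cohorts of per-patient first-pass
   signal-intensity (SI) curves (spleen, remote myocardium, LV blood pool;
   stress and rest), hemodynamics, visual reads, and ground-truth labels
   (any-vessel FFR-significant CAD; stress adequacy). Enhancement curves
   follow a normalized gamma-variate whose peak amplitude is an explicit
   parameter; the splenic stress amplitude is a fraction `gamma` of the
   rest amplitude, small under adequate stress.
2. **Measurement** — baseline (pre-contrast) normalization and the two
   ratio biomarkers, both read at the time frame of peak myocardial SI:

   - SI_stress/rest = (SI_spleen,stress − SI_spleen,pre) / (SI_spleen,rest − SI_spleen,pre)
   - SI_spleen/myocardium = (SI_spleen,stress − SI_spleen,pre) / (SI_myo,stress − SI_myo,pre)

   plus time-to-peak and the SI range ("upslope") of the stress splenic curve.
3. **Classification** — FFR-referenced adjudication of each study
   (true/false positive/negative), inclusive cutoffs on the ratios
   (SSO prediction at ≤0.25 / ≤0.28; true-negative support at ≤0.32 / ≤0.38),
   and hemodynamic adequacy (HR rise ≥10 bpm, systolic BP drop ≥10 mmHg).
4. **Evaluation** — sensitivity/specificity/accuracy and likelihood ratios
   (LR+ = sens/(1−spec), LR− = (1−sens)/spec) from 2×2 tables, ROC curves
   with Youden-optimal cutoffs, stratified 5-fold cross-validated AUC with
   an influence-function 95% CI, Cohen's kappa, and two-way random-effects
   ICC(2,1) with Koo–Li categories.

The central API is statsmodels-style: build a `StressAdequacyModel` from a
cohort (or a DataFrame of your own measurements), call `.fit()`, inspect the
`StressAdequacyResults`.

Two sensitivity/specificity conventions are supported, because published
predictive-performance tables for SSO condition on *marker* status
(sens = a/(a+b), spec = d/(c+d)) rather than the textbook outcome margins;
`convention="marker_conditional"` reproduces such tables, and
`"outcome_conditional"` gives the textbook definitions. Both are always in
the report.

## Worked example

The classic predictive-performance column for visual SSO among 86 negative
CMR studies (54/67 true negatives and 7/19 false negatives with SSO):

```sh
$ ssokit worked-example sso
[PASS] sso  counts={'a': 54, 'b': 7, 'c': 13, 'd': 12}
    sensitivity_pct: computed 88.5 expected 88.5
    specificity_pct: computed 48.0 expected 48.0
    accuracy_pct: computed 76.7 expected 76.7
    lr_pos: computed 1.7 expected 1.7
    lr_neg: computed 0.24 expected 0.24
```

Read: when SSO is present, 88.5% of studies are true negatives; LR+ 1.70
means SSO presence modestly raises the odds of a true negative, while
LR− 0.24 means absent SSO substantially raises suspicion of a false
negative.

A simulated cohort end to end:

```python
from ssokit import SimulationConfig, StressAdequacyModel, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=179, seed=1))
results = StressAdequacyModel.from_cohort(cohort).fit(seed=1)
print(results.summary())
```

prints (abridged):

```
Stress-adequacy marker evaluation (reference: FFR-based adjudication)
  patients analyzed: 179   negative CMR studies: 84
...
        marker  sensitivity_pct  specificity_pct  accuracy_pct  lr_pos  lr_neg  a  b  c  d
           sso             83.3             38.9          73.8    1.36    0.43 55 11 11  7
...
  predict_adequacy         si_stress_rest_spleen          cvAUC 0.992 (95% CI 0.977-1.000)
...
Visual read agreement (stress-rest vs stress-only): kappa = 0.45
```

The marker rows evaluate each adequacy marker against the FFR-based
true-negative reference among negative studies; the cvAUC block shows how
well the continuous ratios recover visual switch-off, true-negative status
and the generative adequacy label; the Youden cutoffs are the
ROC-optimal thresholds.

The same pipeline is available from the shell
(`ssokit run --seed 1 --out out/`), writing `patients.csv`, `curves.csv`,
`config.json`, `metrics.csv`, `calls.csv`, `report.json` and a structured
`run.log`, byte-identical on reruns with the same seed.

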