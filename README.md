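# hjortheeg

Band-wise Hjorth-parameter EEG classification with leave-one-subject-out
evaluation, mRMR feature selection, channel-wise rank-sum statistics and
LIME channel attribution.

## What this is for

Resting-state EEG screening studies contrast a patient group with healthy
controls and ask three questions: *can the groups be told apart from the
signal alone*, *which frequency bands and channels carry the difference*,
and *is the classifier's evidence statistically meaningful per subject*.
`hjortheeg` implements that whole workflow for two-group cohorts recorded
with the 19-channel 10–20 montage, and ships a synthetic-cohort generator
with known ground truth so every stage can be exercised and validated
without any clinical data.

The features are the three Hjorth descriptors of each four-second epoch,
computed per channel in each of the five conventional sub-bands
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz):

- **activity** `= Var(x)` — the band power of the epoch;
- **mobility** `= sqrt(Var(Δx) / Var(x))` — a dominant-frequency proxy
  (for a sampled sinusoid of frequency *f*, mobility `= 2 sin(πf/fs)`);
- **complexity** `= mobility(Δx) / mobility(x)` — deviation from a pure
  sinusoid (≈ 1 for a sine).

With 19 channels this yields 285 features per epoch. Greedy mRMR
(maximum relevance, minimum redundancy — plug-in mutual information on
equal-frequency-binned features) reduces them to 12 before
classification. Evaluation is leave-one-subject-out: every fold trains
on N−1 subjects — feature standardization and mRMR are refitted inside
each training fold — and predicts all epochs of the held-out subject, so
no subject identity ever leaks into training. Pooled accuracy,
sensitivity, specificity, ROC/AUC, per-subject exact binomial tests
against 50 % chance, channel-wise Wilcoxon rank-sum z-maps and
LIME-based channel importance maps complete the picture.

## Worked example

A scaled-down synthetic cohort — 8 patients + 8 controls, 12 epochs
each — where the patient group's beta/gamma amplitude is elevated ×1.5
in the frontal channels F3, F4, Fz and Fp2 (so beta/gamma *activity* is
elevated ×2.25, variance being amplitude squared):

```python
from hjortheeg.bands import band_by_name
from hjortheeg.synthetic import SimulationConfig, generate_cohort
from hjortheeg.preprocess import preprocess_recording
from hjortheeg.features import extract_features, cohort_feature_table
from hjortheeg.mrmr import SelectionConfig
from hjortheeg.evaluate import run_loso, ClassifierSpec
from hjortheeg.explain import wilcoxon_map

cfg = SimulationConfig(n_per_group=8, epochs_per_subject=12, seed=11)
bands = (band_by_name("beta"), band_by_name("gamma"))
table = cohort_feature_table(
    extract_features(preprocess_recording(rec, bands))
    for rec in generate_cohort(cfg)
)

report = run_loso(table, ClassifierSpec("linear_svm"), SelectionConfig(k=12))
print(f"accuracy    {report.accuracy:.2f}%")
print(f"AUC         {report.auc:.4f}")
print("selected (fold 1):", report.folds[0].selection.ordered[:4], "...")
worst = max(report.per_subject, key=lambda s: s.p_value)
print(f"least significant subject: {worst.subject} "
      f"({worst.n_correct}/{worst.n_epochs} correct, p = {worst.p_value:.3g})")
top = max(wilcoxon_map(table, "activity", "beta"), key=lambda s: abs(s.z))
print(f"max |z| channel: {top.channel} (z = {top.z:.2f}, p = {top.p:.3g})")
```

prints

```
accuracy    100.00%
AUC         1.0000
selected (fold 1): ['beta.activity.Fp2', 'gamma.activity.F4', 'gamma.activity.Fz', 'beta.activity.F3'] ...
least significant subject: P01 (12/12 correct, p = 0.000244)
max |z| channel: Fp2 (z = 3.36, p = 0.000155)
```

Every piece of the injected ground truth is recovered: mRMR picks
frontal beta/gamma activity features, the classifier separates the
groups (the generator has no between-subject variability beyond epoch
noise, so separation is essentially perfect — see `docs/methods.md` for
what this does and does not show about real data), each held-out
subject individually beats chance (12/12 correct epochs has one-sided
binomial tail `0.5¹² ≈ 2.4 × 10⁻⁴`), and the strongest channel-wise
group difference sits in the injected frontal set.

## Command line

The same pipeline is driven by a YAML config with five composable
stages (`simulate`, `features`, `evaluate`, `explain`, `report`) or
end-to-end:

```sh
hjortheeg run --config config.yaml
```

The config declares the cohort (simulated, or EDF files to load), the
preprocessing (downsample to 250 Hz, 0.5–45 Hz zero-phase band-pass,
common average reference, 4-s epochs), the bands, and an experiment
grid — band subsets × Hjorth-parameter subsets × classifiers
(`linear_svm`, `rf`, `lda`, `knn`) — whose pooled metrics are written
as a grid summary table (CSV and aligned text). All stages are
deterministic under the configured master seed.

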