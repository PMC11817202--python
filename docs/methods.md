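# Methods

This note documents the models, conventions and numerical choices behind
`hjortheeg`, in the order data flows through the pipeline.

## Synthetic cohort model

Each subject's continuous signal per channel is a sum of independent
band-limited Gaussian processes plus an optional 1/f background:

    x(t) = Σ_b  a(g, ch, b) · n_b(t)  +  a_pink · p(t)

where `n_b` is white Gaussian noise passed through the canonical
band-pass filter for band `b` and rescaled to unit sample variance, and
`p` is unit-variance pink noise (amplitude spectrum ∝ f^-1/2). The
amplitude `a(g, ch, b)` is a per-band RMS scale, multiplied by the
effect factor for the patient group in the configured channel/band
subset. Because Hjorth activity of a band-filtered epoch is the band
variance, an amplitude factor `f` appears downstream as an activity
ratio of `f²` — a directly verifiable ground truth.

Defaults (units µV, chosen once as a plausible resting eyes-closed
spectrum — strong slow activity, weak gamma; the defaults are
assumptions of the simulation, not estimates of any particular
recording):

| parameter | default |
|---|---|
| band RMS (delta, theta, alpha, beta, gamma) | 20, 10, 15, 5, 2 |
| pink background RMS | 2 |
| patient effect | ×1.5 on {F3, F4, Fz, Fp2} × {beta, gamma} |
| cohort | 20 patients + 20 controls |
| epochs × length × fs | 50 × 4 s × 250 Hz |

The pink background is kept small so that in-band background power
dilutes the nominal activity ratio (2.25 at the default effect) by only
a few percent; the common average reference mixes a further ~1/19 of
the other channels in, leaving the observed ratio ≈ 2.17 at F3 —
still within 10 % of the nominal value.

Signals are generated with 2 s of padding per side, filtered, then
trimmed, so filter edges never reach the epochs. Each subject's
generator is seeded from `SeedSequence([master_seed, subject_index])`
(patients first, then controls), making cohorts byte-identical under a
fixed config and each subject's data a function of its index only.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: no between-subject variability of
amplitudes (every patient shares one spectrum, so classification of the
synthetic cohort is far easier than of a clinical one and accuracies
here say nothing about clinically attainable accuracy), no artifacts
(blinks, EMG, line noise), no non-stationarity within a recording, no
volume-conduction correlation between channels, no non-Gaussianity.
The cohort validates the *machinery* — bookkeeping, leakage guards,
calibration, attribution recovery — not clinical effect sizes.

## Preprocessing

Fixed order: resample → broadband filter (0.5–45 Hz) → common average
reference → sub-band filter → epoch. CAR and filtering are both linear,
so their order cannot change results (asserted in tests); sub-band
filtering runs on the continuous signal *before* epoching so per-epoch
filter transients never arise.

Filters are zero-phase windowed-sinc FIR (Hamming window). The number
of taps follows the Hamming transition-width rule `N ≈ 3.3·fs/Δf` with
`Δf = min(2 Hz, low/2)` by default, ~53 dB single-pass stopband
attenuation (doubled by the forward–backward application). The
forward–backward operator is applied as a single FFT-domain convolution
with the symmetric kernel `h * reverse(h)` plus odd-reflection edge
padding. This is the same linear operator as textbook forward–backward
filtering away from the edges, and it remains fast for the ~3300-tap
delta-band kernel where a direct-form implementation would dominate the
cohort runtime. Resampling is polyphase (`scipy.signal.resample_poly`);
only downsampling is supported, and `target_fs == fs` is a bitwise
identity. Epochs are consecutive, non-overlapping, exactly
`fs × length` samples; a trailing remainder is dropped.

The gamma band's upper edge (45 Hz) coincides with the broadband
cutoff; the gamma sub-band filter is still applied so all bands share
the same spectral shaping. Artifact handling (ICA, bad-channel
interpolation, manual rejection) is out of scope: the pipeline assumes
clean or synthetic input.

## Hjorth conventions

Variance uses the 1/N normalization. The derivative is the first-order
finite difference *without* division by the sampling interval —
Hjorth's classic discrete convention — so mobility is in per-sample
units and equals `2 sin(πf/fs)` for a sampled sinusoid; difference
signals have lengths N−1 and N−2, with no padding and no re-centering
beyond what variance implies. Degenerate inputs stay total rather than
NaN: `Var(x) = 0` yields `(0, 0, 0)` with a warning; `Var(Δx) = 0` with
`Var(x) > 0` (a linear ramp) yields mobility 0 and complexity 0.

## Feature naming and formats

Features are named `<band>.<parameter>.<channel>` (e.g.
`beta.activity.F3`), totally ordered band-major (delta→gamma), then
parameter (activity, mobility, complexity), then channel in the
canonical montage order

    Fp1 Fp2 F7 F3 Fz F4 F8 T3 C3 Cz C4 T4 T5 P3 Pz P4 T6 O1 O2

which is asserted as canonical for this package (the 10–20 literature
fixes no ordering). Feature tables are CSV with `subject_id, group,
epoch` metadata columns; writing uses shortest-round-trip float
formatting and reading uses round-trip parsing, so CSV round-trips are
bit-exact.

**Epoch container** (binary cache, extension `.epk`): magic `EPK1`,
a 4-byte little-endian unsigned header length, a JSON header
(`fs`, `epoch_length`, `subject_id`, `group`, `band` as
`[name, low, high]` or null, `channels`, `shape`, `dtype`), then the
(epoch, channel, sample) tensor as little-endian 32-bit floats in C
order.

**EDF**: reading goes through `mne`; labels are normalized
case-insensitively after stripping an `EEG ` prefix and trailing
reference suffixes (`-REF`, `-LE`, …) and reordered to the canonical
montage, with unknown/missing channels reported by name. Writing is a
minimal 16-bit EDF exporter (one-second records, physical units µV,
per-channel physical range from the data), adequate for round-tripping
cohorts into EDF-consuming tools; round-trip error is bounded by the
16-bit quantization step.

**Montage positions** are the standard polar projection of 10–20
angles onto the unit disc (nose up, +x right): the outer ring at
radius 1 and multiples of 18° (Fp1/Fp2 at ±18°, F7/F8 ±54°, T3/T4 ±90°,
T5/T6 ±126°, O1/O2 ±162°), Fz/Cz/Pz on the midline at 0.5/0/−0.5, and
F3/F4, C3/C4, P3/P4 on the half-radius ring. They are exported with
channel scores for topographic rendering; no inference depends on them.

## mRMR

Features are discretized into equal-frequency bins (5 by default;
ties on a bin edge go to the lower bin, a constant column is a single
code), and mutual information is the discrete plug-in estimator in
nats (terms summed in sorted order, making MI exactly symmetric in
floating point). Greedy forward selection scores candidates by
relevance/redundancy (MIQ, the common toolbox default; redundancy
floored at 10⁻¹²) or relevance − redundancy (MID), with redundancy the
mean MI against the already-selected set; ties break toward the earlier
column in canonical order, so selection is fully deterministic. The
`class_prior` option (`empirical` default) weights the label marginal
by observed class frequencies; `uniform` reweights rows so each class
carries equal mass — with a balanced cohort the two coincide (tested).
Whether selection should see all 285 features once (globally) or be
refitted per training fold is a genuine design fork; the default is
per-fold (no test information can reach selection), with the global
mode retained for comparison.

## LOSO evaluation

One fold per subject; the leakage guard (held-out subject absent from
training rows) is asserted, not assumed. Standardization (train-fold
z-scoring) is applied for the margin/distance learners (linear SVM,
LDA, KNN); RF consumes raw features. Defaults: SVM C = 1.0, KNN
k = 5, RF 500 trees with a fixed seed, LDA without shrinkage — all
exposed in the classifier spec.

LOSO training folds are inherently imbalanced (the held-out subject's
class is one short), which biases prior-sensitive learners toward the
over-represented class — on null data this systematically *depresses*
accuracy below chance. The package therefore uses balanced class
weights for SVM/RF and uniform priors for LDA, so the chance-level
control sits at 50 % as it should.

Metrics are pooled over all epoch-level predictions (patient =
positive); subject-level majority-vote accuracy is reported alongside,
since printed accuracies in this literature are sometimes epoch-pooled
and sometimes subject-averaged. ROC points come from the standard
threshold sweep; AUC is computed independently as the Mann–Whitney
statistic `U/(n₊·n₋)` with rank-averaged ties (the two agree with a
pair-counting oracle in tests). The per-subject binomial test is the
exact one-sided upper tail `P(X ≥ n_correct)` under chance 0.5 —
one-sided because the question is "better than chance"; a perfect
50-epoch subject has `p = 0.5⁵⁰ ≈ 8.88 × 10⁻¹⁶`.

## LIME

Tabular LIME with the widely used defaults, all configurable:
perturbations are Gaussian around the instance with per-feature train
SDs; proximity is `exp(−D²/w²)` with `D` the standardized Euclidean
distance and `w = 0.75·√d`; the surrogate is a weighted ridge
regression (α = 1) of the model's *continuous decision score* (smoother
local fits than hard labels) on standardized features, optionally
restricted to the `top_k` features with the largest weighted univariate
association. A constant prediction function yields zero weights with a
warning flag. Explanations are deterministic under a fixed seed; the
per-instance seed is derived from the master seed plus the row index.

Channel importance aggregates mean |weight| per (band, channel) over
all explained held-out epochs of all folds, rescaled to max 1 —
channels never selected score 0. Which instances to explain is a free
choice; the default is all held-out epochs (optionally capped per fold
for speed), which is order-invariant by construction.

## Channel-wise statistics

Per channel, a two-sample Wilcoxon rank-sum test between patients and
controls, by default on *subject means* — 50 epochs of one subject are
not independent replicates, and using them as such (the `epoch` unit,
also provided) inflates |z|. The z-value is the tie-corrected normal
approximation without continuity correction, signed positive when
patients are stochastically larger; the p-value uses the exact null
distribution for small untied samples and the tie-corrected asymptotic
otherwise. Significance is flagged at α = 0.05 with no multiple-testing
correction, matching common reporting practice in this literature
(a Benjamini–Hochberg correction can be applied downstream; raw
p-values are always exported).

## Pipeline and seeds

The master seed fans out as: simulation = seed, classifiers = seed + 1,
LIME = seed + 2 (+ row index per instance). Stages communicate through
serialized artifacts (epoch containers, feature CSV, report JSONs), are
idempotent, and log one structured line each (input sizes, config
digest, wall time — informational only).

## Problem sizes

The test suite exercises scaled-down cohorts (8 + 8 subjects × 12
epochs for recovery and null checks, 200 label permutations for the
false-positive-rate calibration) chosen to keep the suite fast while
leaving the binomial chance bands narrow enough to be informative; the
full 20 + 20 × 50 cohort is used for the structural bookkeeping checks
and throughout `scripts/acceptance.py`.

## Known limitations

* The synthetic cohort's lack of subject-level variability makes
  classification nearly perfect; effect-size realism was traded for a
  verifiable ground truth.
* The EDF writer covers the subset of EDF needed here (integer fs,
  16-bit, one-second records); it is not a general-purpose exporter.
* Mobility is reported in per-sample units; a per-second variant is
  deliberately not provided.
* No artifact simulation or removal; recordings are assumed clean.
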