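# Methods

## Problem and data model

The package grades muscle spasticity on the Modified Ashworth Scale
(MAS) from 3-channel surface EMG recorded while a clinician passively
flexes and extends a patient's elbow. A recording is a
`(3, n_samples)` millivolt matrix (channels LB, SB, BR in fixed order)
at a sampling rate of 1,024 Hz, labelled with one MAS grade from
{0, 1, 1+, 2, 3}. Labels map bijectively onto ordinals 0–4 ("1+" → 2),
which serve both as the ordinal variable in rank correlations and as
class labels. Grade 4 (limb rigid in flexion/extension) yields no
usable passive-movement sEMG and is rejected as a label.

The examination timeline is: 2 min rest, then three loops of three
consecutive 30-s flexion–extension cycles (each cycle containing three
~10-s movements), 30-s breaks between loops, then 2 min rest — about
7 minutes. The *active span* of a trial is the half-open sample
interval from the start of the first loop to the end of the last; it
includes the two inter-loop breaks, because segmentation requires a
contiguous interval. Splitting the active span into three equal
segments (A, B, C) therefore aligns each segment with one 90-s loop of
three cycles plus ≤ 20 s of adjacent break; the low-amplitude break
samples dilute all grades equally and do not affect rank correlations.
The resting minutes are excluded from analysis: features are meant to
quantify the stretch-reflex response, which exists only during
movement. Segmentation uses 0-based half-open `[start, end)`
intervals; a non-divisible span gives its remainder samples to the
earliest segments.

## Denoising

A Butterworth band-pass (prototype order 4, 20–450 Hz) removes drift,
motion artefact and out-of-band noise; a second-order IIR notch
centred at 50 Hz with a 48–52 Hz −3 dB band removes mains
interference. Both are applied forward–backward (`sosfiltfilt` /
`filtfilt`, with their default edge padding), so the chain is
zero-phase and burst timing is preserved for the envelope feature.
Measured on 5-s unit tones, the chain passes 100 Hz within ±1 %,
attenuates 50 Hz by far more than 40 dB and 500 Hz below 1 % — the
guarantees asserted in the test suite. The band edges require
`rate > 900 Hz`; configurations violating this are rejected rather
than silently redesigned.

## Features

Per preprocessed segment and channel:

* **RMS** `sqrt(mean(x²))` and **iEMG** `Σ|x|` — amplitude measures.
  iEMG is a plain sum, not scaled by 1/rate: any fixed scale cancels
  under max–min normalization.
* **EA (envelope area)** — strict local maxima and minima are located
  by sign changes of the first difference; the first and last samples
  anchor both lists so the envelopes never extrapolate. Natural cubic
  splines through the maxima and minima give the upper and lower
  envelopes L(t), l(t), evaluated at every sample index, and
  `EA = |∫L| + |∫l|` with trapezoidal integration over sample indices
  (dt = 1 sample; again, the unit cancels under normalization). The
  absolute value wraps the *signed* integral of each envelope — for an
  envelope that changes sign this differs from integrating |L|, and
  the signed-integral form is implemented deliberately. Natural end
  conditions cause a boundary ripple that decays within roughly two
  inter-extremum intervals; envelope accuracy is therefore asserted on
  the interior of test signals.
* **MPF and MF** — from a Welch power spectral density (1-s Hann
  windows, 50 % overlap, constant detrend). MPF is the spectral
  centroid Σf·P/ΣP; MF is the smallest frequency where cumulative
  power reaches half the total. Both are undefined (an error, not a
  zero) for a zero-power segment.

Feature columns are max–min normalized per (channel, feature) over the
retained sample population, after balanced sampling and before any
correlation or classification. A constant column raises an error —
it signals a broken extraction, not a valid state. A fold-safe
variant (parameters from training folds only) is available in the
model-comparison API; the default follows the global convention under
which the reference correlation tables were produced. Rank
correlations are invariant to this monotone scaling either way.

## Screening and fusion

Spearman correlation (tie-corrected, via `scipy.stats.spearmanr`)
between each normalized feature and the MAS ordinal is computed per
channel over the balanced population. A feature is retained iff
|r| ≥ 0.7 on **all** three channels. The magnitude rule is
deliberate: amplitude features correlate positively, frequency
features negatively, and with the clinical reference coefficients the
rule retains exactly {RMS, iEMG, EA} and drops {MPF, MF}.

For each retained feature with channel correlations (r₁, r₂, r₃), the
channel weights are ωᵢ = rᵢ/(r₁+r₂+r₃) — signed correlations, no
absolute value — and the fused sample value is the weighted sum of
its channel values, e = ω₁e₁ + ω₂e₂ + ω₃e₃, a convex combination
whenever the correlations share one sign. A mixed-sign triple has no
coherent weighting and raises an error in the core operation; the
model-comparison routine, which must remain evaluable on
structureless data (e.g. permutation baselines where correlations
straddle zero), falls back to equal weights 1/3 in that case. Reported
weight and metric tables round half away from zero to two decimals.

## Classification and evaluation

The classifier is Euclidean k-NN with majority voting, written
in-package because its determinism contract is part of the method:
vote ties go to the class of the nearest neighbour among tied classes,
then to the lowest MAS ordinal on exact distance ties; distance ties
at the K boundary resolve by stable sort order. The implementation is
verified against a pure-Python exhaustive-enumeration oracle and
against scikit-learn where votes are unambiguous.

The balanced design keeps 40 sample datasets per grade (seeded uniform
sampling without replacement within grade). Stratified 10-fold
cross-validation deals each grade's samples round-robin into folds, so
every fold holds 4 samples per grade; fold confusion matrices are
summed, predicting each of the 200 samples exactly once (row sums 40).
K is selected from the odd grid 1–13 by mean fold accuracy, smallest
K on ties. A 9:1 stratified holdout split (36 train + 4 test per
grade) is also provided. Per-class precision TP/(TP+FP), recall
TP/(TP+FN) and F1 come from the aggregated matrix; a class never
predicted has undefined precision, reported as 0.0 with an explicit
flag rather than silently as 1.0.

Seven models are compared under one fold assignment (asserted via a
digest of the assignment): three single-channel baselines (that
channel's RMS/iEMG/EA), three single-feature baselines (one amplitude
feature across the channels) and the fused model (fused RMS/iEMG/EA).
The fused classifier is fixed to the three amplitude features; on
synthetic cohorts whose frequency features also clear the screen, the
screening outcome is reported but does not enlarge the fused vector,
keeping the comparison aligned across cohorts.

## Synthetic cohorts

The generator emulates the examination, not muscle physiology: no
motor-unit action potentials, no stretch-reflex threshold dynamics, no
electrode-contact or movement artefacts beyond a white baseline floor.
It produces exactly the statistical structure the analysis assumes,
so passing tests demonstrate that the pipeline recovers planted
structure — not that clinical accuracy is reproduced.

Movement epochs carry band-limited Gaussian noise bursts
(Tukey-tapered, unit RMS before scaling). Defaults, chosen as
plausible surface-EMG scales:

| parameter | default | meaning |
|---|---|---|
| `baseline_sigma` | 0.01 mV | white noise floor everywhere |
| `burst_gain_per_grade` | 0.05–0.20 mV (×~1.4/grade) | movement-burst RMS, strictly increasing with grade |
| `burst_band` | 30–250 Hz | grade-0 burst band |
| `spectral_shift_per_grade` | 15 Hz | downward shift of the band centre per grade step (upper edge −30 Hz/step) |
| `powerline_amp` | 0.02 mV | 50 Hz tone, random phase |
| `patient_sigma` | 0.25 | log-normal between-patient reflex-intensity spread, shared across a patient's trials |
| `channel_gain_jitter` | 10 % | per-(recording, channel) multiplicative jitter |
| `epoch_jitter` | 15 % | per-movement amplitude jitter |

The between-grade gain step (~40 %) against the within-grade spread
makes grades strongly ordered but not separable — fused
cross-validated accuracy on the default cohort lands in the 70–80 %
range with adjacent-grade confusions dominating, qualitatively like
clinical reports, though the correspondence is incidental to the free
noise parameters. The channel jitter is what gives fusion its
advantage: averaging three imperfectly correlated channels reduces
amplitude noise. The default cohort is 8 patients per grade × 2
trials (80 recordings, 240 segments, 40 × 5 retained samples),
mirroring the balanced 200-sample design; at the full 570-s protocol
this generates and featurizes in about a minute on one core, which is
also the problem size used by the end-to-end tests. All randomness
descends from one integer seed: a root generator derives per-patient
generators, so any recording is reproducible from (config, seed).

## Numerical and design notes

* Sample intervals everywhere are 0-based half-open; remainders go to
  the earliest segments — deterministic tie-breaks throughout.
* Signal files are plain CSV (header `LB,SB,BR`, one sample per row,
  `%.9g` floats); cohort manifests are CSV with per-trial active-span
  boundaries. Vendor formats, EDF/BDF and streaming are out of scope.
* The spectrum window is capped at the signal length, so segments
  shorter than 1 s still yield a (coarser) spectrum; fewer than 64
  samples is an error.
* `select_k` evaluates all grid members on one fold assignment, making
  the K choice a pure function of (data, seed).
* The Welch PSD satisfies Parseval within ~1 % on long noise signals;
  the test suite asserts 5 %.

## Limitations

* Synthetic validation only: the generator realizes the assumed
  correlation structure, so structure-recovery results say nothing
  about electrode placement, crosstalk, fatigue or other clinical
  confounds, and synthetic accuracies are not clinical accuracies.
* The global normalization/weighting convention leaks label
  information into cross-validation; the fold-safe mode exists
  precisely because of this, and its accuracies are the honest ones
  for generalization claims.
* MAS is treated as five unordered classes by the classifier; the
  ordinal structure is used only in screening/weighting, not in the
  vote.
* Adjacent grades (1 / 1+ / 2) are intrinsically hard to separate on
  amplitude features alone; the confusion matrices concentrate errors
  there by construction of the problem, not by fixable implementation
  choices.
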