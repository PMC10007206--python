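# Methods

## The question the simulation answers

BCG-based heartbeat detection recovers beat times with a random offset
relative to the ECG R peak. Because HRV features are computed from interval
differences, a *constant* offset is invisible; what matters is the
beat-to-beat *jitter*. The pipeline asks: as that jitter grows, how quickly
do HRV features lose the information that sleep-stage classifiers rely on?
The design is a controlled dose-response experiment: jitter of known
standard deviation is injected into otherwise clean beat streams, features
are recomputed at every severity level, and classifier error is traced
against the realized interval error.

## Jitter model and the MAE ladder

Each beat time receives an independent Normal(0, σ²) offset. An interval is
a difference of two beat times, so its error is Normal(0, 2σ²) and the mean
absolute interval error follows the half-normal mean:

    E[MAE] = √(2σ²) · √(2/π) = 2σ/√π.

The ladder places 97 linearly spaced σ levels. σ_max starts at the
closed-form inverse of the 60 ms terminal target (≈ 53.2 ms) and is rescaled
once by the ratio of target to realized pooled MAE, so the terminal level
lands on the target up to the (tiny) nonlinearity introduced by re-sorting.
Jitter draws are independent across levels (levels are exchangeable; nothing
in the analysis requires nested noise), and seeded per participant × level so
cohort composition never perturbs individual realizations.

Design notes:

* Perturbed beat times are re-sorted. At σ ≤ 55 ms and ~1 s intervals,
  order inversions are ~10σ events — essentially absent — but sorting
  guarantees the strictly-increasing invariant and beat-count conservation
  that the MAE pairing depends on.
* The MAE target is interpreted as *pooled* over the cohort's intervals;
  per-participant MAEs are recorded at every level so a per-participant
  reading can be recovered from the ladder object.
* Interval timestamps use the trailing beat. The convention only affects
  window membership at window borders.

## Synthetic cohort

The generator emulates the statistical shape of a polysomnography archive;
it does not synthesize waveforms.

**Hypnograms.** Nights are Normal(8.43 h, 0.5 h), truncated at 6 h, scored
in 30-s epochs. Stages are emitted in blocks: a block's stage is drawn with
probability ∝ target_occupancy(s) / mean_dwell(s) and its dwell is geometric
with the stage's mean dwell (W 8, S1 5, S2 14, S3 8, REM 10 epochs). By the
renewal-reward theorem the long-run occupancy of each stage equals its
target (Wake 30.0 %, S1 2.6 %, S2 41.1 %, S3 11.6 %, REM 14.7 %); the dwell
means are package choices giving plausible bout structure while keeping runs
mostly above the 4-epoch cleaning threshold. A toggle (`s4_prob`) relabels a
fraction of S3 epochs as the non-standard S4 to exercise the cleaning rules.

**Beat streams.** Beat times grow iteratively, t_{k+1} = t_k + RR(t_k), with

    RR(t) = mean_rr(stage) + lf_amp·sin(2π f_LF t + φ) + hf_amp·sin(2π f_HF t + ψ)
            + Σ_d a_d·sin(2π f_d t + χ_d) + ε,   ε ~ Normal(0, noise_sd²),

phases drawn once per night. Deterministic sinusoids plus white noise is the
simplest process with controllable band power, which is all the analysis
consumes; no autoregressive or integral-pulse-frequency-modulation structure
is claimed.

**Stage parameter defaults.** The per-stage table is a package default, not
a claim about any cohort. It is built on two principles. First, the dominant
stage signal sits in the LF/HF balance: Wake and REM carry strong LF and
weak HF modulation, deep sleep the reverse (respiratory sinus arrhythmia),
light sleep in between. Second, mean intervals are compressed (0.86–0.98 s
across stages) and a stage-independent VLF drift (amplitudes 0.04 / 0.03 s
at periods ≈ 45 / 18 min, below the LF band edge) makes windowed mean heart
rate wander by more than the between-stage gaps — as circadian and
thermoregulatory drift does in real nights. The consequence is the regime
the study design needs: at baseline, classifiers must lean on the spectral
features; as jitter floods the spectrum, that information disappears while
windowed means survive, so error degrades smoothly with MAE and the
mean-interval feature is the least sensitive. Wake and REM are deliberately
similar (their HRV signatures genuinely overlap), keeping baseline error
realistic rather than near zero. Total interval variances are kept
comparable across stages so that the added jitter variance cannot itself
become a class cue.

**Beat-pair tables.** Each of 27 participants contributes 100 rows of
(R-to-true-J interval, detection error): RGI ~ Normal(μ, σ_RGI) truncated
positive, e_p ~ Normal(0, σ_ep). The defaults σ_RGI = 8.97 ms and
σ_ep = 11.0 ms are *inferred* via the half-normal relation from published
mean absolute values of 7.16 ms and 8.77 ms for the corresponding
quantities; the distributional means themselves are not published, and
μ = 250 ms is a typical R-J latency. These are stand-in values, labelled as
such.

**What the generator does not emulate.** Arrhythmia and ectopy, missed or
false beat detections (the error model is timing-only by design),
respiratory modulation of amplitude, inter-participant differences beyond
seeded phases and night lengths, and scorer disagreement in the hypnograms.
Passing tests therefore demonstrate the pipeline's behaviour under the
stated statistical assumptions, not performance on real polysomnography.

## Label cleaning

S4 is merged into S3 first; then any stage run shorter than 4 epochs
(configurable) is relabelled — one run at a time, scanning left to right —
to the preceding run's stage, a short leading run taking the following
run's stage instead, rescanning until no short run remains. One-at-a-time
processing resolves the cascade ambiguity (a merge can create a new short
or confusable run) deterministically; each relabel removes at least one
run, so termination is guaranteed. A whole night shorter than the threshold
is returned unchanged with a warning. The S4-first order is fixed by this
pipeline; cleaning is length-preserving and idempotent.

## HRV features

Per epoch, a 300-s window centred on the epoch midpoint (90 % overlap on
the 30-s grid, clipped at record edges) supplies the intervals. HR is the
windowed mean *interval* (s) — the convention follows "mean of the
intervals", not mean rate — and SDNN the sample SD. LF and HF are mean
normalized Lomb–Scargle ordinates over 0.04–0.15 Hz and 0.15–0.4 Hz on a
fixed grid (0.005–0.5 Hz, step 0.0025 Hz), evaluating the tachogram at
trailing-beat times — the conventional Lomb–Scargle HRV treatment for
unevenly sampled series. LFHF is their ratio; MedFiltLFHF a 5-epoch
centred, edge-truncated running median of the LFHF column. Windows holding
fewer than 60 intervals are flagged invalid and excluded from
classification (pairwise across levels, keeping per-level sample sizes
equal).

Numerical notes:

* Band power is the *mean* ordinate over in-band grid points. Units are
  arbitrary but identical across levels; only relative changes drive the
  analysis.
* The normalization is the floating-mean (generalized) form; with
  per-window mean subtraction the classical and floating-mean variants
  differ negligibly, and the floating-mean form is what both computation
  paths implement exactly.
* Because adjacent windows share 90 % of their samples, production feature
  extraction uses a prefix-sum formulation: every window statistic the
  periodogram needs (Σcos, Σsin, Σy·cos, …) is a difference of whole-night
  cumulative sums, so the trigonometric work is done once per night. A
  per-window scipy.signal.lombscargle path is kept as the reference; the
  two agree to ~1e-12 and the test suite asserts it.
* Degenerate windows (zero variance) get zero band power; LFHF is undefined
  (NaN) where HF = 0.

## Classification and sensitivity

Per participant and per level, features are z-scored with train-fold
statistics and classified by a Gaussian-kernel SVM (scikit-learn `SVC`,
backend-default C and γ, native one-vs-one voting) under stratified 10-fold
CV with a seeded shuffle; a kNN backend (k = 10 by default; k is exposed
because the Bayes bounds depend on it) serves the Bayes-error analysis.
Per-participant models follow the study design (one error curve per
participant); pooled cross-participant training is out of scope. A
participant/level whose rarest class has fewer members than folds is
flagged, never silently dropped. Stratified random folds ignore temporal
autocorrelation between neighbouring epochs — a documented optimism caveat
for absolute error levels, though not for the *trend* against MAE, which is
the study's object.

Bayes bounds for an L-class problem from the kNN error follow
(L−1)/L·(1−√(1−L/(L−1)·E_kNN)) ≤ E_bayes ≤ E_kNN, with the domain check
E_kNN ≤ (L−1)/L enforced.

Sensitivity slopes are ordinary least squares of error (%) on MAE (s),
fitted per participant and averaged; units are percentage points per second
of HBI MAE. Ensemble curves report mean and mean ± 1.96 SD across
participants per level.

Pooled confusion matrices exclude participants whose matrix has an all-zero
predicted-class column (a class never predicted), reporting the exclusion
count.

## Timing-error bound

For each participant the per-beat |RGI| is the absolute deviation of that
beat's R-to-true-J interval from the participant's own mean (mean offsets
are invisible to HRV, so only the deviation is error); centering is never
pooled. The per-beat sum |RGI| + |e_p| bounds the total error by the
triangle inequality. Summaries (mean, median, min, max) pool over beats,
not participant means; the sum's median/min/max are computed from per-beat
sums because medians are not additive, while its mean is exactly the sum of
the component means. The mean bound projects onto the ensemble error curves
by linear interpolation in MAE.

## Problem sizes and determinism

Cohort-level empirical checks run on 10 participants with a 20-level ladder
(the full 97-level ladder is exercised where only interval arithmetic is
needed); single-feature sensitivity slopes use a six-level subsample
spanning the full MAE range (a slope needs ≥ 3 points; six evenly spaced
levels preserve the estimate while keeping the per-feature × per-scheme
classifier sweep proportionate). Generator statistics use the full
50-night cohort. All randomness flows from a master seed through
`numpy.random.SeedSequence` spawn keys per participant, stream kind, and
jitter level, so outputs are bitwise reproducible and adding participants
or levels never perturbs existing draws.

## Known limitations

* Synthetic dynamics are stationary within stage up to deterministic
  sinusoids; real HRV is nonstationary within stages as well.
* The jitter model is Gaussian and independent across beats; heavy-tailed
  or autocorrelated detector errors are out of scope.
* Absolute classification errors depend on the synthetic separability and
  transfer to real cohorts only qualitatively; the meaningful outputs are
  trends against MAE, orderings between features and schemes, and the
  bound arithmetic.
* The S4-merge-first ordering and the leading-run-forward rule are fixed
  conventions where the cleaning procedure is otherwise underdetermined.
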