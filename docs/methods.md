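# Methods

`emodecode` re-creates, as a tested library, an offline EEG decoding
pipeline for emotions *expressed* during music performance: ten
region-of-interest (ROI) signals per 30 s performance segment, three
feature families (band power, magnitude-squared coherence, binarized
pairwise Granger causality), two statistical feature-selection regimes
(baseline-aware "normalized" and ANOVA-only "non-normalized"), and
one-vs-one RBF-SVM evaluation under arousal / valence / emotion
labelings. Because the motivating study's recordings are not public, the
package ships a synthetic-cohort generator with *known* planted condition
effects, so that every stage can be validated end to end against ground
truth.

## Synthetic cohort model

The generator emulates the study design: 10 participants × 4 sessions ×
50 trials (configurable), five conditions (distressed, excited,
depressed, relaxed, neutral) balanced and shuffled within each session,
and per trial a 30 s neutral-baseline segment followed by a 30 s
emotional segment, sampled at 500 Hz over 10 ROIs.

Each ROI signal is a sum over the five EEG bands (δ 1–4, θ 4–8, α 8–12,
β 12–30, γ 30–45 Hz) of unit-variance band-limited Gaussian noise
(seeded white noise passed through the same zero-phase FIR filters the
analysis uses, normalized by the ideal-filter variance), plus broadband
white observation noise (sd 0.2). Condition effects enter through three
orthogonal mechanisms:

* **Band-power gains** g(c, b, r): amplitude multipliers per condition,
  band, ROI.
* **Shared-source couplings**: a latent band-limited source u mixed into
  an ROI pair as `sqrt(1-s)·own + sqrt(s)·u`. Mixing preserves variance,
  so coherence is decoupled from power; band MSC ≈ s² (slightly diluted
  by the white-noise floor).
* **Directed couplings**: the target is remixed as
  `sqrt(1-c²)·own + c·source(t-lag)` using the pre-coupling source
  signal. This creates Granger causality from source to target, is
  feed-forward (hence unconditionally stable; an explicit
  companion-matrix spectral-radius check additionally rejects explosive
  coefficient sets), and again roughly preserves variance so that
  directionality does not confound the power features.

Trial-to-trial physiological variability is emulated by log-normal
jitter on band amplitudes (sd 0.30 — EEG band power fluctuates by tens
of percent between repetitions of the same task) and small Gaussian
jitter on coupling strengths (sd 0.05) and directed coefficients
(sd 0.02). Baseline segments always use the neutral parameter set. One
global seed expands into per-trial `SeedSequence` keys, so any trial is
individually reproducible.

`planted_truth` enumerates every (family, band, ROI/pair) whose
parameters differ from neutral, as ground truth for selection-recovery
tests.

### The shipped preset

`default_spec()` plants contrasts of deliberately different strength so
the family ordering reported for real performance EEG (connectivity
above power, MSC on top) is reproduced by construction:

* **Coherence** (strong): four band-specific ROI pairs — α(1,2),
  β(5,6), θ(3,7), γ(9,10) — with strengths 0.10–0.20 at baseline and
  0.25–0.90 across conditions in permuted orders.
* **Directed** (moderate): three edges — 3→4 (lag 2), 7→9 (lag 3),
  2→6 (lag 1) — with coefficients 0.35–0.90 permuted across the four
  emotional conditions, none at baseline. The coefficient range was
  placed in the empirically sensitive region of the binarized estimator
  (see "GC saturation" below).
* **Power** (weak): ±8% alpha gains over parieto-occipital ROIs and ±8%
  beta gains over frontal ROIs, swamped by the 0.30 log-normal jitter;
  plus a theta gain at the fronto-central ROI (1.20–1.35) shared by all
  four emotional conditions. The shared theta effect models a generic
  "emotional engagement" contrast against mechanical baseline playing
  and is what gives the power family (and the GC/power families via
  their edges) features that survive the normalized regime's
  all-conditions intersection test.

What the generator does **not** emulate: artifacts (blinks, EMG),
electrode dropout, volume conduction / common reference leakage, 1/f
spectral shape, non-stationarity within segments, or subject-specific
spectra. Passing the end-to-end tests therefore demonstrates the
*pipeline's* correctness and sensitivity, not expected accuracy levels
on real EEG.

## Preprocessing

The real-data path re-references to the mean of T7/T8 and averages
channels into ten ROIs (a 32-channel 10–20 montage grouping is shipped;
ROIs with no surviving channel are flagged, and any trial with a missing
ROI in either segment is excluded and logged). Artifact rejection, ICA
and component labeling are assumed done upstream by standard toolboxes
and are out of scope.

Filtering uses windowed-sinc (Hamming) linear-phase FIR filters applied
once with the group delay compensated — zero-phase, as in standard M/EEG
practice. The number of taps follows `3.3·fs/transition`; the transition
width defaults to `min(2 Hz, low edge)`. All five sub-band filters share
one transition width, which makes adjacent filters complementary at the
shared −6 dB edges: on white noise the five sub-band signals reconstruct
the 1–45 Hz broadband signal to well within 15% relative RMS. (A
forward-backward application would square the responses, breaking this
partition and over-attenuating the 1 Hz delta edge, which is why the
single-pass form was chosen.)

Each segment is broadband filtered (0.5–45 Hz), sub-band filtered from
the broadband signal, and cut into eight non-overlapping 3 s windows
covering [3, 27) s (window k spans samples [(3+3k)·fs, (6+3k)·fs),
0-based, half-open). The per-band tensors are stored as float32
(observations × 10 ROIs × 8 × 1500); emotional and baseline tensors are
row-aligned by construction.

## Features

All spectral estimation uses Hann-tapered periodograms of the eight 3 s
windows (frequency resolution 1/3 Hz) with across-window (Welch
ensemble) averaging.

**Band power** (100 columns): absolute power = mean per-bin periodogram
power inside the band, computed from the band-filtered windows and
averaged over windows; relative power = absolute power divided by the
mean per-bin 1–45 Hz power of the broadband windows (zero denominator →
relative power 0). Scaling a signal by c multiplies absolute powers by
c² and leaves relative powers unchanged.

**MSC** (45 columns per band): γxy = |⟨Sxy⟩|² / (⟨Sxx⟩⟨Syy⟩) per
frequency bin, averaged over the band's bins. Spectra are estimated once
from the broadband windows; restricting to a band's bins is equivalent
to coherence of the band-filtered signals because the filter gain
cancels. With L = 8 windows the estimator's null expectation is ≈ 1/L =
0.125, not 0 — the tests pin this bias. Self-coherence is exactly 1; the
10×10 matrix is symmetric and its upper triangle is unrolled row-major.

**Granger causality** (100 columns per band): for each ordered ROI pair
and each window of the band-filtered signals, two nested least-squares
autoregressions of the target are fit on the same sample range (order
p = 5, first p samples dropped, inputs demeaned): own lags only, and own
plus source lags. The literal decision rule — "full-model residual
variance smaller than restricted" — is degenerate in-sample: adding
regressors almost never increases the raw residual variance, so it fires
on essentially every pair (the tests demonstrate ≈100% on independent
noise). The default rule therefore compares degrees-of-freedom-adjusted
variances (RSS/(n−k)), which is calibrated to ≈50% on white-noise nulls;
a nested-model F-test at α = 0.05 and the literal raw rule are available
as options. The per-window binary verdicts are averaged into an entry in
[0, 1]; the diagonal is fixed at 0 (its constant columns are removed by
selection). The batched implementation solves all 90 ordered pairs per
window from precomputed lag cross-products with a tiny relative ridge
(1e-9 of the mean diagonal) that leaves generic fits unchanged and makes
degenerate (constant) inputs collapse to "no causality".

**GC saturation on narrowband signals.** An AR(5) model cannot whiten a
band-limited signal, so on band-filtered data the DoF-adjusted null rate
rises from 0.50 to ≈0.9 (band-dependent; the alpha band retains the
widest dynamic range). This is a property of binarized per-band GC, not
of the implementation — the oracle tests therefore use white-driven VAR
plants (where direction recovery exceeds 90%), and the shipped preset
places its directed coefficients in the range where per-window detection
probabilities still vary (≈0.6–1.0).

## Feature selection

*Normalized* (baseline-aware), phase 1: per column and per non-neutral
condition, a two-sided pooled-variance two-sample Student t-test between
that condition's emotional rows and their aligned baseline rows; a
column survives only if p < 0.05 for **all four** conditions (the
intersection reading of "shared across conditions"). Neutral rows are
not tested. Phase 2: one-way ANOVA across the five conditions over all
rows (neutral included), retaining p < 0.01. *Non-normalized*: phase 2
only. No multiple-testing correction in either regime, matching the
procedure being reproduced. Columns with undefined p-values (zero
variance) are dropped and logged. Despite the name, "normalized" does
not subtract the baseline arithmetically; an optional subtract-baseline
transform exists behind a flag (off by default). Because both phases are
per-column tests, the normalized retained set is a subset of the
non-normalized one on identical inputs.

## Classification

Rows are globally shuffled with a seeded generator and split into k = 5
contiguous equal folds (no subject blocking, matching the protocol being
reproduced; a stratified option exists). Per fold, columns are
standardized on the training rows, one binary RBF SVM (C = 1,
γ = 1/(d·Var(X)), i.e. scikit-learn's "scale") is trained per class pair
— C(5,2) = 10 for five classes — and test rows are assigned by majority
vote with ties broken toward the lowest class index in scheme order.
Reported: per-fold train/test accuracies (mean ± sd across folds) and
the pooled row-normalized confusion matrix in percent. Labelings:
arousal (high/low/neutral), valence (positive/negative/neutral), emotion
(five classes). Per-fold standardization was added (the RBF kernel is
scale-sensitive and raw power features span orders of magnitude);
C and γ are fixed rather than tuned so runs stay deterministic.

## Problem sizes

Unit and oracle tests run on windows of 1 500 samples (or 256 for the
coherence-bias Monte Carlo) and cohorts of 5–50 trials. The end-to-end
preset evaluation uses 100 segments per condition (10 participants × 1
session × 50 trials, seed 42) — large enough for the selection tests to
operate at their nominal levels while keeping a full three-family run in
the few-minute range; the full 2000-trial cohort layout is validated at
the schedule level. Observation tensors are stored as float32, and all
heavy loops (filtering, spectra, GC solves) are chunked over
observations to bound peak memory.

## Known limitations

* Pairwise (bivariate) GC only; no conditional/multivariate GC, DTF or
  PDC, time-varying connectivity, or phase-based measures.
* The binarized GC verdict discards effect magnitude; on narrowband
  signals its null rate is inflated (see above), which real per-band GC
  analyses share.
* Global shuffling mixes subjects across train and test folds; accuracy
  estimates are therefore optimistic relative to leave-subject-out
  evaluation (available as the stricter option).
* Synthetic effect sizes are illustrative; the motivating study reports
  no numeric power/connectivity effect sizes to calibrate against.
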