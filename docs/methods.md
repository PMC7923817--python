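# Methods

`hrvdoa` classifies the three clinical anaesthesia states — induction (I),
maintenance (II), recovery (III) — from four heart-rate-variability features
of a single-lead ECG, referenced against an expert assessment of
consciousness level (EACL, 0–100). Because intra-operative ECG with expert
annotations is not publicly available, the package ships a fully specified
synthetic cohort generator; every downstream claim the test suite makes is a
claim about recovery of that generator's known ground truth, not about
clinical data.

## The synthetic cohort

A case is generated in four layers, all driven by one seed.

**Timeline.** Six events (induction start, LOC, maintenance start, recovery
start, ROC, end). Phase durations are truncated Gaussians around the
configured means — defaults 600 s induction, 6470 s maintenance, 900 s
recovery (≈133 min total, a typical general-surgery duration), SD fraction
0.20 clipped at ±2 SD. With a 64 s window and 4 s stride this yields roughly
2000 analysis windows per case and ~46,000 for the default 23-case cohort.

**EACL.** A smooth base trajectory: cosine descent from 95 to a plateau of
50 during induction, a ±3-point slow wander on the plateau, cosine ascent to
90 during recovery. Five simulated raters each observe the base plus
independent smooth noise (white Gaussian, Gaussian-smoothed over 10 s,
rescaled to SD 5 points, clipped to [0, 100]); the reported score is their
arithmetic mean, mirroring the five-anaesthesiologist protocol. The rater
noise is smooth so that averaging across raters is a meaningful variance
reduction rather than a per-sample triviality.

**RR intervals.** Direct sinusoidal modulation:

    RR(t) = RR̄(phase) + a_LF(phase)·sin(2π·0.10·t) + a_HF(phase)·sin(2π·0.25·t) + ε,

ε ~ N(0, 15 ms). A tone of amplitude *a* contributes exactly *a*²/2 to the
band variance, so the generator's band powers are analytically known — the
reason this model was chosen over an integral-pulse-frequency-modulation
model. Beat k+1 is placed RR(t_k) after beat k. Defaults (ms):

| phase | RR̄ | a_LF | a_HF |
|---|---|---|---|
| I (induction) | 850 | 40 | 20 |
| II (maintenance) | 1000 | 25 | 8 |
| III (recovery) | 800 | 12 | 35 |

The amplitude orderings (HF: III > I > II; LF: I > II > III) encode the
clinically reported directions of the state-wise feature distributions. A
drawn RR ≤ 250 ms raises a configuration error rather than producing a
non-physiological beat. The per-phase white-noise SD is a single scalar, so
the generator does not reproduce a state-dependent SampEn gradient; SampEn is
exercised for correctness, not for state separation.

**ECG.** Each beat renders a sum-of-Gaussians PQRST complex (R amplitude
1.2 mV, width 12 ms) with the R apex at the true beat time, on a record that
starts 0.5 s before the first beat so no template is clipped. Additive
baseline wander (0.1 mV at 0.25 Hz), 50 Hz mains (0.05 mV), white noise
(0.02 mV), and Poisson-timed 0.5 s noise bursts (default 0.5/min, 1.5 mV).
Morphology realism is a non-goal; the waveform exists to exercise the
detector.

## Preprocessing

Zero-phase 4th-order Butterworth band-pass 0.5–40 Hz plus a Q=30 notch at
50 Hz, both via forward-backward filtering (no R-peak timing shift; verified
by a zero-lag impulse test). R peaks: band-pass 5–15 Hz, derivative, square,
150 ms moving-window integration, threshold at 35% of the segment-wise 95th
percentile (10 s segments), 250 ms refractory, detection refined to the
argmax of the band-passed ECG within ±100 ms. RR artifact filter: reject
intervals outside 333–2000 ms or deviating more than 20% from an 11-sample
running median taken over the raw interval sequence — computing the median
over the raw (not accepted-only) sequence makes the filter idempotent.
Rejected intervals keep their place (time order preserved) and are excluded
from features. All thresholds live in `PreprocessConfig`.

On clean synthetic ECG the chain recovers 100% of beats within ±10 ms and RR
within ~0.8 ms RMS (one sample at 500 Hz is 2 ms).

## Features

Per 64 s window (4 s stride): accepted intervals are cubic-spline resampled
at **2.5 Hz** (160 samples; grid times outside the beat span are clamped to
avoid spline extrapolation), mean-removed, **mirror-extended** (the window
concatenated with its reverse), and decomposed to 5 levels with the discrete
Meyer wavelet (periodized). Band powers are sums of squared detail
coefficients divided by the extended length, in ms²:

* HF = D2 + D3 → 0.156–0.625 Hz
* LF = D4 + D5 → 0.039–0.156 Hz

2.5 Hz was chosen because its dyadic edges (0.039, 0.078, 0.156, 0.3125 Hz)
fall almost exactly on the Task-Force band boundaries (LF 0.04–0.15, HF
0.15–0.40 Hz), and because neither canonical HRV peak (0.10, 0.25 Hz) then
sits on a dyadic edge — at a 4 Hz resample rate the 0.25 Hz respiratory peak
lies exactly on a band edge and part of its energy structurally cascades
into the LF levels. The mirror extension removes the wrap-around step a
periodized transform would otherwise see (the extension preserves the sample
multiset, so total band power still equals the window variance; measured
Parseval error < 1% for the near-orthogonal Meyer FIR approximation).
Residual cross-band leakage is ~2% of the dominant band's power. The HF/LF
ratio is reported as HF divided by LF (an `invert_ratio` toggle gives LF/HF)
and is marked missing when LF = 0.

Sample entropy uses the raw accepted RR intervals of the window (not the
tachogram): m = 2, r = 0.2 × window SD (absolute-r mode available),
Chebyshev distance, self-matches excluded, N−m templates for both lengths.
SampEn = −ln(A/B); if either count is zero the window's entropy is undefined
and the window is skipped with a logged reason — never reported as infinity.
The implementation is vectorised but exactly matches an independent O(N²)
loop-based counter (tested on random series up to N = 200, m ∈ {1,2,3}).

Each window row carries the mean EACL over the window and the state label at
the window centre (half-open boundaries: a centre exactly on a transition
belongs to the later state).

## Models

Rows with any missing feature are dropped before modelling. Features are
z-scored with training-partition statistics only. The default split is
record-level 80/20 (|train| = round(0.8·n) exactly — at the study scale of
46,000 records this is 36,800/9,200), stratified by state; a case-grouped
split is available and recommended when within-case correlation matters,
because record-level splitting leaks correlated windows across partitions.

Three reference classifiers are scikit-learn fits: multinomial logistic
regression, one-vs-rest RBF SVM, and a Gini decision tree capped at depth 8.
The deep network is implemented directly: fully connected 4-10-17-1, ReLU
hidden layers, linear scalar output, trained by mini-batch Adam (lr 0.01,
batch 256, 200 epochs, seeded He initialisation) on mean-squared error
against ordinal class codes {0, 0.5, 1}. Its output decodes to the nearest
code, ties toward the lower state. The architecture has
4·10+10 + 10·17+17 + 17·1+1 = 255 trainable parameters. An alternative head
trains the same network on EACL/100 and decodes through the per-state mean
scores seen in training; the ordinal-code head is the default because a
scalar EACL threshold cannot by itself distinguish induction from recovery
(both traverse the same score range in opposite directions).

Cross-validation is stratified 5-fold with a shared fold assignment across
models, so model comparisons are paired. The chi-square comparison between
classifiers is pairwise 2×2 (correct/incorrect × model) without continuity
correction by default (Yates and Bonferroni toggles available); expected
cells below 5 are annotated, not rejected.

## Metric conventions

Precision is column-wise, recall row-wise, accuracy trace-wise on the 3×3
confusion matrix; accuracy therefore equals class-share-weighted recall
exactly. A state never predicted has undefined (NaN) precision — reported
missing with a warning, not forced to zero.

## Problem sizes and what passing tests show

The test suite and `scripts/acceptance.py` use: the full 23-case default
cohort for the feature-ordering and correlation checks (~43,000 windows,
built directly from the generator's RR series); three ~11-minute cases for
end-to-end ECG rendering, detection and pipeline smoke runs; 200 two-tone
tachograms for the band-power oracle; 100 random series for the SampEn
oracle. These sizes keep a full run to a few minutes while leaving every
statistical margin wide (the ordering gaps are factors of 2–5, not
percent-level).

On the synthetic cohort all four classifiers reach ~99% test accuracy —
far above the 86–90% reported for clinical data — because the generator's
state-conditional feature distributions are separated far more cleanly than
real autonomic physiology. Passing tests therefore demonstrate that the
pipeline recovers known ground truth (beats, band powers, orderings, labels)
and that the statistical machinery is correct; they do not validate clinical
performance. Known limitations: no respiratory coupling or drug
pharmacokinetics in the RR model, piecewise-constant phase parameters (no
gradual transitions), a single artifact model, no ectopic beats, and no
state-dependent SampEn structure.
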