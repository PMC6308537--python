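# Methods

This note documents the models and procedures implemented in
`pulsebp`, the numerical choices behind them, what the synthetic data
generator does and does not emulate, and the package's known
limitations.

## Signal preprocessing

* **Low-pass filtering.** A 4th-order Butterworth with 50 Hz cutoff,
  applied forward–backward (`filtfilt`), so the effective response is
  8th-order with exactly zero phase: fiducial timing is never skewed by
  filter delay. Passband gain is within 0.5% of unity below 25 Hz.
  Requires `fs > 2 × cutoff`.
* **Baseline removal.** Discrete wavelet decomposition (db8) to the
  level L at which the approximation band `[0, fs/2^(L+1)]` falls below
  0.5 Hz; the reconstructed approximation (the respiratory/motion
  wander) is subtracted. At fs = 500 Hz this is level 9 and needs
  ≥ 7680 samples (≈ 15 s); at 2500 Hz level 12 and ≈ 25 s. Deep-level
  reconstruction has boundary transients over roughly the first/last
  second of a record; the beat segmenter therefore ignores a 1 s guard
  zone at each record edge.
* **Differentiation.** First and second derivatives are computed by
  cubic Savitzky–Golay differentiation with an 80 ms window (odd sample
  count, minimum 5). The smoother is zero-phase and exact for cubic
  polynomials, including at segment edges. The window was chosen so the
  small dicrotic excursion of the first derivative — on which the
  dicrotic foot/peak detection rests — remains stable under 20 dB
  additive noise, while noiseless landmark displacement stays below
  one sample at 500 Hz. A plain finite-difference stencil leaves far
  too much noise in the derivative for reliable zero-crossing logic at
  realistic SNRs.

## Beat segmentation and R-peaks

Upstroke candidates are peaks of the smoothed first derivative above
40% of its robust (98th-percentile) positive level. A first pass at a
higher threshold (60%) estimates the cardiac period; the final pass
uses a refractory distance of 0.55 periods so that steep secondary
rises (the dicrotic wave of a compliant, low-pressure pulse can reach
~half the systolic slope) are never counted as beats. Each beat's foot
is the last non-positive sample of the smoothed derivative walking back
from the upstroke peak — equivalent to the local waveform minimum
opening the systolic rise, but immune to the argmin jitter a flat
diastolic tail exhibits under noise or residual baseline ripple. Beats
outside 0.3–2 s, or without exactly one dominant peak, are dropped and
counted.

R-peaks are detected on the filtered ECG by an energy threshold (20% of
the 99.5th percentile of the squared, median-centred signal) with a
0.3 s refractory period. This is deliberately simple; the synthetic ECG
is spike-like, and any clinical-grade detector could be substituted
behind the same interface.

## Landmarks

Per beat: A (foot), B (waveform point at the first-derivative maximum),
C (systolic peak = global argmax, ties to the first index), then the
dicrotic pair. The dicrotic search runs in a window from
`C + 0.15·T` to `C + 0.60·T` (T = beat duration; both fractions are
configuration): D is the first upward zero-crossing of the first
derivative after the post-systolic descent, E the subsequent downward
zero-crossing (or, failing that, the in-window waveform argmax after
D). When no crossing pair exists — a monotone post-peak decay — the
fallback assigns the in-window maximum of the first derivative to both
D and E and flags the beat `degenerate_dicrotic`; such beats are valid
and carry TmCD = RtTP = 0.

On the derivative traces, G and M are the in-systole argmax of d1 and
d2; F and N are 10%-of-peak rising crossings walked back from them
(the onset convention; the fraction is configuration); H and L are the
*feet* of the derivative waveforms, i.e. their deepest negative
excursion after the peak. The foot-as-trough reading is what makes the
derivative features self-consistent: the second derivative's "total
amplitude" d2[M] − d2[L] is a true peak-to-trough span, its "foot
amplitude" d2[L] a real (negative) signal value, and the descending
slopes |d1 trough|/(t(H)−t(G)) and d2[M]/(t(L)−t(M)) have the natural
amplitude-over-time form. A derivative with no negative excursion after
its peak (e.g. a pure ramp) makes the beat unusable.

The ECG R-peak paired with a beat is the latest one preceding the
beat's G point by 50–600 ms (a physiologic transit-time gate).

## Features

Twenty-one features per beat (see the table in
`pulsebp/features.py`), averaged over a record's accepted beats
(≥ 5 required; a feature missing in some beats is averaged over the
beats that have it). Conventions worth noting:

* **K-values.** Pm is the trapezoid-rule mean of the beat over its full
  span; K1 restricts the mean to `[0, t1]` and K2 to `[t1, T]`, with t1
  the dicrotic-foot time. Both sub-interval quantities are *interval
  means* — this is what makes K2 vanish exactly for a diastole resting
  at the foot pressure, and keeps all three indices inside [0, 1] for
  any valid beat.
* **Discrete areas.** AS, d1_AA and d2_AA are printed sample sums; the
  package reports the raw sums (`*_raw`) alongside fs-normalised
  values (sum/fs, a rectangle-rule area), and the models consume the
  normalised form so results do not depend on the sampling rate.
* **PIR.** The peak/foot intensity ratio is computed in the
  filtered-but-not-baseline-removed frame, where the sensor's DC level
  is preserved; after baseline removal the foot hovers near zero and
  the ratio is meaningless. A non-positive raw foot marks PIR missing
  for that beat (not an error).
* **PTT** is t(G) − t(R-peak), in seconds, present only when an ECG
  channel exists.

## Calibration models

Each of the 21 features is calibrated per subject by univariate
ordinary least squares against the cuff reference (separately for SBP
and DBP); a constant feature is a hard error naming the feature. The
fusion rule is

    MPF = trimmed_mean(F, g) − std(F, ddof=1),   g = floor(γ·N), N = 21

with the standard deviation taken over the *untrimmed* ensemble and the
sample (n−1) convention, matching the convention used for the error
statistics. γ defaults to 0.1 (g = 2) and must lie in [0, 0.5);
γ = 0 reduces exactly to mean − sd. The trimmed mean gives the fusion
its robustness: for γ = 0.1, up to two arbitrarily wild single-model
estimates on each side leave the location term untouched.

A property worth knowing, measured by this package's own test suite:
the subtracted dispersion term has sampling variance of its own, which
adds in quadrature to the trimmed mean's error. At error scales of
several mmHg (a desk-scale synthetic cohort with ~2 mmHg reference
noise) this penalty is a few percent of the total SD and can leave the
MPF estimate marginally behind the single best feature model, even when
the trimmed mean alone is ahead of it; at the ~8 mmHg error scale
typical of field studies the penalty is negligible. The fusion's MD is
also biased negative by the mean dispersion — per-subject calibration
absorbs none of this because the term is computed at prediction time.

PTT baselines: `linear_PTT` (BP ~ PTT), `inverse_PTT` (BP ~ 1/PTT) and
`log_inv_sq` (BP ~ ln(1/PTT) + 1/PTT², two regressors plus intercept),
all ordinary least squares.

Models serialise to a JSON document keyed by subject, target and
feature; persistence is round-trip tested.

## Evaluation

Errors are estimate − reference. MD is their mean; SD their sample
standard deviation (ddof = 1). Cumulative percentages count
|error| ≤ 5/10/15 mmHg with closed intervals (an error of exactly
5.0 mmHg is within ±5). BHS grades require all three CP thresholds to
be *strictly* exceeded — A: 60/85/95, B: 50/75/90, C: 40/65/85, else
D. The AAMI verdict is |MD| ≤ 5 and SD ≤ 8 mmHg, inclusive.
Bland–Altman limits are MD ± 1.96·SD, bit-consistent with MD/SD from
the same inputs. Model comparison uses a two-sample t-test, Welch
(unequal-variance) by default with a pooled-variance option.

## The synthetic generator

**Beat model.** A continuous periodic template: three Gaussian bumps
(systolic, reflected, dicrotic) in normalised time, wrapped across beat
boundaries, plus an exponential diastolic decay launched smoothly from
the dicrotic wave (amplitude 0.22 of the systolic peak, time constant
0.16 periods). The decay gives the diastolic tail a definite slope so
the foot is localisable under noise — a flat tail makes the foot
position ill-posed for any detector. Landmark times (foot, peak,
dicrotic foot/peak, steepest-upstroke time) and the fullness index K
are computed from the template on a dense grid (≈ 0.1 ms resolution)
and returned as ground truth. Setting the dicrotic amplitude to zero
produces the degenerate monotone-decay case.

**BP coupling.** Template parameters are affine in SBP (and the raw
DC offset in DBP): the upstroke narrows, the reflected wave grows, the
dicrotic wave shrinks and arrives earlier, the diastolic runoff slows
(τ = RC rising with peripheral resistance), heart rate rises, and the
amplitude scale follows pulse pressure. PTT follows
`a + b/√SBP` (a = 50 ms, b = 2.2 s·mmHg^0.5 ≈ 250 ms at 120 mmHg).
Coefficients are balanced so that no feature's response is cancelled by
opposing couplings and each of the 21 features carries a comparable
share of blood-pressure information — mirroring the homogeneous
single-feature performance that motivates fusing them in the first
place.

**Nuisance variability.** Three layers: additive white noise at a
stated SNR (power ratio against the mean-removed signal), 0.2 Hz
sinusoidal baseline drift, and morphology jitter. Jitter perturbs the
template at the record level (sensor placement, vasomotor state;
master fraction 0.05) and optionally per beat (respiration, RR
variability; 0.02), with per-parameter weights balanced so that each
physiologic axis contributes comparably and no single axis mimics a
coherent pseudo-BP shift across all features.

**Trajectories and protocol.** Per subject, true SBP follows a
circadian sinusoid (amplitude 8 mmHg) plus Gaussian day-to-day drift
(σ = 3 mmHg) and within-day variability (σ = 3 mmHg); DBP tracks SBP
with slope 0.6. Subject means are drawn around 120/75 mmHg (σ = 10),
or from explicit strata (e.g. a hypertensive group). The default
protocol is the multi-day calibration study: 16 training records
spread over 09:00–17:00 on day T, then 4 records on each of days
T+1, T+3, T+6, T+8. Cuff-reference noise (σ = 2 mmHg) is optional and
off in exact-recovery settings. The resulting per-subject dynamic
ranges land near 25 mmHg SBP / 17 mmHg DBP, the scale of daytime
ambulatory variation.

**Modes.** `waveform` synthesises signals and pushes them through the
package's own extraction pipeline — every stage is exercised.
`analytic` emits feature tables whose 21 features are exactly linear in
SBP (with DBP exactly affine in SBP and no noise anywhere when so
configured); in that setting every univariate calibration, and hence
the MPF fusion, must recover BP to machine precision, which pins down
the correctness of the model layer independently of signal processing.

**What the generator does not emulate.** Real sensor nonlinearity and
contact-pressure artefacts; motion artefacts; arrhythmia and ectopic
beats; inter-subject morphology classes (age/stiffness phenotypes);
any physiological feedback between heart rate and pressure beyond the
fixed couplings. Passing tests on this generator therefore demonstrate
correctness of the algorithms under controlled, physiologically-shaped
conditions — not clinical accuracy on human data.

## Problem sizes and tolerances in the test suite

Waveform cohorts in tests use 5 subjects × (16 train + 16 test)
records of 20–60 s at fs = 500 Hz — sizes chosen so the whole suite
runs in a few minutes while every stage still operates well inside its
validity envelope (the 500 Hz rate keeps the level-9 baseline
decomposition valid for ≥ 15 s records). Landmark-recovery checks run
at the study rate of 2500 Hz. Exact-recovery assertions use 1e-6 mmHg;
landmark tolerances are ±15 ms noiseless and ±25 ms at 20 dB SNR;
closed-form feature checks use 0.5% or better.

## Known limitations

* The dicrotic search window (0.15–0.60 of the beat) and the 10% onset
  fraction are conventions, exposed as configuration; pathological
  morphologies outside those windows are flagged rather than recovered.
* Wavelet baseline removal needs a minimum record length that grows
  with the sampling rate (≈ 15 s at 500 Hz, ≈ 25 s at 2500 Hz); very
  short strips cannot be processed.
* Calibration is linear and strictly per subject; no pooling across
  subjects, and no nonlinear models.
* The R-peak detector targets clean or moderately noisy single-lead
  ECG; it is not artefact-hardened.
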