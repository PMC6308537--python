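# pulsebp

Cuffless blood-pressure estimation from single-site pressure pulse wave
(PPW) signals — the arterial pulsation waveform recorded by a
skin-contact piezoelectric sensor at the radial artery.

Continuous, cuff-free blood-pressure monitoring is a long-standing goal
in ambulatory and home health care. The classical cuffless approach —
pulse transit time (PTT), the delay from the ECG R-peak to the arrival
of the pulse at a peripheral site — needs two simultaneous channels.
`pulsebp` implements an alternative that works from the morphology of a
single PPW channel: per-subject calibration of many simple waveform
features, fused into one robust estimate.

## Method

For each heartbeat the pipeline locates eleven landmark points on the
waveform and its first/second derivatives (foot A, systolic peak C,
dicrotic foot D and peak E, the derivative onset/peak/foot triplets
F G H and N M L, and the opening ECG R-peak when available), and
computes 21 features: amplitude ratios (e.g. RtAmCE = (P_E−P_A)/(P_C−P_A),
PIR), timing spans (TmAE, TmBE, TmCD, RtTP), waveform-fullness indices

    K = (P_m − P_d) / (P_s − P_d),        P_m = (1/T) ∫₀ᵀ P(t) dt

with systolic/diastolic restrictions K1 and K2, and slope/area
descriptors of the derivative traces (d1_PAm, d2_TAm, …). Beat-level
values are averaged over each ~1-minute record.

Calibration is strictly per subject: each feature x_j gets its own
ordinary-least-squares model BP ≈ a_j·x_j + b_j against cuff reference
readings. At prediction time the 21 single-feature estimates
F₁ … F₂₁ are fused by the multiparameter-fusion (MPF) rule

    MPF = ( F₍g+1₎ + ⋯ + F₍N−g₎ ) / (N − 2g)  −  STD(F₁…F₂₁)

— a g-trimmed mean (g = ⌊γN⌋, default γ = 0.1) minus the sample
standard deviation of the untrimmed ensemble. Three conventional PTT
baselines (BP ~ PTT, BP ~ 1/PTT, BP ~ ln(1/PTT) + 1/PTT²) are provided
for comparison, and estimators are scored with the standard
cuffless-BP toolkit: MD/SD error statistics, cumulative percentages
within ±5/±10/±15 mmHg, BHS letter grades, the AAMI 5 ± 8 mmHg rule,
Pearson correlation and Bland–Altman limits of agreement.

Because no public PPW/BP corpus with this protocol exists, the package
ships a first-class synthetic generator: three-Gaussian beat templates
with analytic landmark ground truth, BP-coupled morphology and transit
time, additive noise, baseline drift, morphology jitter, and a
multi-day calibration/test protocol (a training day with 16 records,
then four records on each of days +1, +3, +6, +8). Every stage of the
pipeline is validated against this generator's ground truth.

## Worked example

Simulate a 3-subject cohort, calibrate each subject on day T, and
evaluate on days T+1 … T+8:

```bash
$ printf '{"n_subjects": 3, "duration": 20.0}' > spec.json
$ pulsebp run --spec spec.json --seed 42 --out report.json
MPF sbp: MD -2.76 SD 3.25 mmHg, CP5 75.0%, BHS A, AAMI pass
MPF dbp: MD -0.92 SD 2.47 mmHg, CP5 95.8%, BHS A, AAMI pass
```

MD/SD are the mean and standard deviation of estimation errors over the
48 test records (estimate − cuff reference, mmHg); CP5 is the fraction
of absolute errors within 5 mmHg; the BHS grade and AAMI verdict follow
from those. `report.json` also contains the per-feature single models,
the PTT baselines, a per-day breakdown (calibration-interval
robustness), and Welch t-tests comparing MPF with the best PTT
baseline.

The same pipeline is available as library calls
(`pulsebp.pipeline.run_experiment`, `pulsebp.models.MPFRegressor`,
`pulsebp.features.record_features`, …) and as separate CLI stages
(`simulate`, `extract`, `fit`, `predict`, `evaluate`).

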