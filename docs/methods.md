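# Methods

## Overview

`gaitphase` implements a pressure-insole gait-phase detector as a pure
software pipeline: a synthetic signal generator stands in for the
hardware (five force-sensing resistors sampled at 100 Hz), and every
downstream stage — framing, calibration, scaling, classification,
streaming, evaluation — operates identically on synthetic or recorded
CSV data. This note documents the model, the generator's assumptions,
the numerical conventions, and what the synthetic results do and do not
say about real recordings.

## The gait model

Seven phases: quiet **stand** plus the six-phase walking cycle
**heel strike → foot flat → midstance → heel off → toe-off → swing**,
wrapping cyclically. Heel strike, midstance and toe-off are *primary*
postures with distinctive load patterns; foot flat and heel off are
short *junction* phases in which load is migrating between primary
postures.

A `GaitTemplate` holds the study conditions:

| parameter | default | meaning |
|---|---|---|
| `amplitudes` | 7×5 matrix in [0, 1] | target force per phase × sensor |
| `phase_fractions` | HS .10, FF .15, MS .20, HO .15, TO .10, SW .30 | share of one cycle per walking phase |
| `ramp_time_s` | 0.05 s | absolute width of the raised-cosine load transfer at each boundary |
| `sensor_lag_s` | 0.02 s | first-order low-pass time constant of the FSR stack |

The default amplitudes encode the qualitative morphology of an insole:
swing ≤ 0.05 on all channels; heel strike S5-dominant; toe-off
S1-dominant; stand *identical* to midstance (both are full-foot loading,
which deliberately makes them the hard pair); the junction rows sit
between their neighbours but lean towards the phase being *entered*
(foot flat towards midstance, heel off towards toe-off), since a junction
posture is defined by the load transfer it performs. No published
amplitude values exist for this sensor layout; the matrix is a design
choice constrained by those orderings and is fully configurable.

## Signal synthesis

The cycle period is `stride_length × 3.6 / speed_kmh` (stride 1.4 m), so
walking speed compresses the cycle while `ramp_time_s` and
`sensor_lag_s` stay fixed in absolute time — at 8 km/h the 50 ms ramp
covers most of a 95 ms junction phase, at 1 km/h almost none of it.
This single assumption produces the two speed phenomena the package is
built to study: accuracy degrades with speed, and the degradation hits
junction phases first.

Construction, per sample (midpoint convention: a sample represents
`[t, t + dt)`):

1. piecewise-constant target from the amplitude row of the current
   phase, **advanced by one ramp width**: phase labels follow
   foot-posture events, which trail the pressure redistribution, so the
   sensed load transfer (ramp plus sensor lag) completes roughly at the
   labelled boundary. The tail of each labelled phase therefore already
   shows the next phase's pattern — the physical origin of the forward
   "cross-phase" error mode;
2. raised-cosine boundary blending, implemented as convolution with a
   normalized Hann kernel of width `ramp_time_s` (handles overlapping
   ramps at high speed; width 0 is an exact pass-through);
3. first-order lag `y' = (x − y)/τ`, initialised at steady state;
4. linear weight scaling by `weight_kg / 53` (53 kg is the reference
   wearer at which the template amplitudes apply unscaled);
5. additive Gaussian noise, truncated at zero (FSR readings are
   non-negative).

`noise_sd` defaults to 0.05 of full scale, representing step-to-step
repeatability of an FSR insole (sensor migration, shoe fit, placement),
not electrical noise, which is far smaller. This level matters: it is
large enough that the small boundary-contamination shifts which would
otherwise let the classifier tell fast-walking midstance frames from
standing frames are buried, while the large junction-blend excursions
survive — i.e. it keeps the stand/midstance pair honestly ambiguous at
every speed and leaves speed degradation driven by the junction
mechanism above.

Determinism: every stochastic operation takes an explicit seed and
derives any internal streams from it; identical arguments give
bit-identical output. There is no global random state.

## Preprocessing

- **Framing**: non-overlapping blocks of `sample_rate / frame_rate`
  samples (100/20 → 5) reduced to per-sensor means; a trailing partial
  block is dropped. The frame label is the majority label of its source
  samples, ties going to the earliest sample's label.
- **Calibration**: per-sensor baselines are the mean forces of a ≥ 1 s
  quiet-standing recording; frames are divided by them, so 1.0 means
  "standing load on this sensor". Because the generator is linear in
  weight, this cancels wearer weight exactly; a near-zero baseline
  raises an error naming the dead sensor.
- **Scaling**: per-attribute min–max fitted on training data only;
  a zero-range attribute maps to 0; out-of-sample values are not
  clipped.

## Classification

Brute-force kNN over the stored training set (a few hundred points; no
spatial index), Euclidean distance, odd k. Voting is uniform or
Dudani-weighted, `w_i = (d_k − d_i)/(d_k − d_1)` on ascending distances
(`w = 1` for k = 1). Distance weighting is the default mode.

Degenerate and tie cases are fixed deterministically:

- all k distances equal (the weight formula degenerates to 0/0): every
  weight is 1, reducing to uniform voting among indistinguishable
  neighbors;
- neighbor-rank ties at the k-th distance: training-set insertion order
  (stable argsort), earlier wins;
- vote-score ties: smaller summed neighbor distance, then phase
  enumeration order. (An odd k prevents two-class vote ties but not
  seven-class ones.)

Model selection sweeps odd k over 1–15 and keeps the candidate with the
best validation accuracy, ties to the smaller k.

## Evaluation protocol

Balanced datasets (`n` frames per phase) are split stratified per class:
`floor(0.7 · n)` to train, the rest to test, shuffled per class by seed
— 100 per class gives the 490/210 protocol sizes exactly. Reports
derive from the 7×7 confusion matrix:

- precision, recall, F1 per class (F1 = 0 when P + R = 0);
- per-class **accuracy (%) = recall × 100** — this report-table
  convention is worth emphasising because "accuracy" usually means
  something else; the macro accuracy is the unweighted mean of the seven
  per-class accuracies, and the overall accuracy is trace/total;
- the **cross-phase rate**: among misclassified frames whose true phase
  is a walking phase (stand has no successor and is excluded), the
  fraction predicted as the cycle-successor of the truth — the
  classifier running one phase ahead. `cross_phase_rate_from_cm` can
  restrict the true phases to the junction or primary group.

Internal values are unrounded; display rounds P/R/F1 to 3 decimals and
percentages to 2.

The speed sweep trains one model at a reference speed (4 km/h) after
standing calibration and evaluates fresh labelled test sets per speed.
With the defaults, accuracy is higher in the slow band (1–2 km/h) than
in the fast band (6–8 km/h) on average over seeds, and fast-band
junction-phase errors are predominantly cross-phase while primary-phase
errors are not — the mechanism section above explains why.

## The streaming loop

`stream_classify` buffers samples into frames and classifies each
completed frame with the identical calibration → scaling → classify
chain, so batch and stream outputs match exactly and no future sample
can influence a label (verified by prefix-equivalence tests). Phase
events fire on label changes; `emitted_t = t + delay_s` models the
wireless link to the prosthesis as a constant injected delay (default
15 ms) — transmission timing is configuration, not simulation. No
temporal smoothing or transition-legality filter is applied by default:
cross-phase errors are a phenomenon under study, not something to
suppress (a smoothing hook exists for users who want one).

## Problem sizes

The test suite and `scripts/acceptance.py` use the protocol sizes where
they are the point (700 frames, 490/210 split, 70 training frames per
class for sweeps) and smaller balanced sets (8–25 per class) elsewhere;
the speed-band comparison averages ten seeds with 30 test frames per
class per speed. The full suite runs in a few seconds.

## Limitations

- The generator emulates signal *morphology*, not biomechanics: no
  ground-reaction-force physics, no left/right asymmetry, no gait
  variability beyond i.i.d. amplitude noise, no sensor drift or
  hysteresis. Absolute accuracies on synthetic data therefore say
  nothing about absolute performance on human subjects; only the
  protocol arithmetic and the qualitative phenomena (weight invariance,
  speed degradation, junction-first cross-phase errors) transfer.
- Stand and midstance share one amplitude row by construction, so in
  the noiseless limit they are a single point mass and their frames are
  assigned by the deterministic tie rules; with noise they approach a
  coin flip. Their per-class accuracies are floor-limited by design.
- Force units are normalized (1.0 ≈ standing load at the 53 kg
  reference); no ADC model is included.
- "Mean force per frame" is the implemented reading of 20 Hz frame
  reduction; a max–min range reduction would be an alternative and is
  not implemented.
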