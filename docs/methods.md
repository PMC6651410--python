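# Methods

## Overview

`comcop` implements a complete in-silico version of a wearable-sensor balance
study: estimate the COM-COP inclination angle (IA) during walking from a
single 9-channel IMU on the lower back, with the ground truth defined by
laboratory kinematics and force-plate data. The package has five stages —
synthetic gait generation, biomechanical ground truth, preprocessing, neural
estimation, and subject-wise evaluation — each usable on its own.

## Ground-truth model

**Whole-body COM.** The kinematic method: COM(t) = Σᵢ fᵢ·segᵢ(t) over 15 body
segments. The default mass-fraction table (head+neck 0.081, torso 0.355,
pelvis 0.142, paired upper arms 0.028, forearms 0.016, hands 0.006, thighs
0.100, shanks 0.0465, feet 0.0145; sum = 1) follows standard cadaver-based
segment-parameter tables; it is config-swappable because published tables
differ by a few percent.

**Net COP.** Vertical-force weighted combination of the two plate COPs.
Frames where both plates are unloaded have no defined COP; they are flagged
invalid, logged, and excluded from cycle analysis.

**Inclination angle.** With P the COP→COM vector (COP lifted to the ground
plane) and Z = (0,0,1), `v = (P × Z)/‖P‖` and IA = asin(v). We report the
anterior-lean component asin(Pₓ/‖P‖) as the sagittal angle and the
lateral-lean component asin(P_y/‖P‖) as the frontal angle, in degrees.
Sign convention (an open choice; no universal standard exists): sagittal
positive = COM anterior of the COP; frontal positive = COM toward the
subject's left. Both components are invariant to the length of P, and the
asin-composed total equals the direct angle between P and Z (verified to
1e-9° in the tests).

**Cycle definition.** The default `paper_modified` policy takes each window
from a toe-off to the next heel contact of the *same* foot — the swing of
that foot, i.e. the single-support interval of the opposite limb during the
two-plate crossing. The conventional heel-strike-to-heel-strike `standard`
policy is also implemented; the wording of the modified definition is
ambiguous in parts of the literature, so both are exposed and the selection
is logged. Each trial's analysis window is the middle one of the available
windows.

**Time normalization.** Cubic-spline resampling to 100 frames over the cycle
window (linear available); window endpoints are evaluated exactly. Inputs
and outputs share the same interpolator so they stay frame-aligned.

## Synthetic gait generator

The generator stands in for the motion-capture / force-plate / IMU
experiment. It is a prescribed-kinematics (inverted-pendulum-flavoured
harmonic) model, not multibody dynamics: sufficient to give every downstream
stage physically consistent, morphologically realistic signals with an
exactly known ground truth.

**Cohort.** Height ~ N(171.2, 4.3) cm, mass ~ N(67.3, 7.1) kg (clipped at
±3 SD) — a young adult male population. Leg length 0.53 H, standing COM
height 0.575 H, foot length 0.152 H, preferred cadence ~ N(112, 4) steps/min.
Each subject carries a gait-style vector: step length ratio ~ N(0.41, 0.012)
of height, COM bounce ~ N(16, 1.5) mm, trunk pitch/yaw amplitudes, a
heel-strike impact amplitude ~ N(5.5, 0.6) m/s², and a latent frontal-plane
factor φ ~ N(1, 0.12) that jointly scales mediolateral sway (42·φ mm), step
width ((0.050 + 0.012 φ) H) and trunk roll (2.5·φ°). The φ coupling encodes
the physiological fact that subjects who sway more also walk with a wider
base and roll the trunk more — which is what makes a subject's frontal
offset observable from the inertial signals at all.

**Speeds.** Classes slow/normal/fast multiply speed by 0.8/1.0/1.2, split
between cadence (∝ s⁰·⁴) and step length (∝ s⁰·⁶), matching the empirical
pattern that humans modulate both.

**Timeline.** Stride period T from cadence; stance = 0.62 T; each double
support = 0.12 T. Right heel strikes at t₀ + kT, left at t₀ + (k+½)T; three
strides per trial with a half-stride lead-in. Footfalls advance one step
length; each landing is half a step length ahead of the mean COM position.

**COM.** Forward drift at the class speed plus a small 2-per-stride
oscillation; vertical bounce at 2 per stride plus a 3 mm second harmonic;
mediolateral sway at 1 per stride, phase-locked so the COM is rightmost at
right mid-stance. Sway and trunk-roll amplitudes receive smooth
stride-to-stride multiplicative modulation (sd 5%, linear between stride
boundaries) — real walking never repeats a cycle exactly, and the roll
shares the sway's modulation because pelvis obliquity is mechanically
coupled to the mediolateral COM excursion.

**GRF and COP.** Total vertical force is m·(g + z̈_com), so the
impulse–momentum balance over any full cycle is exact by construction; it
is shared between the feet by cosine load-transfer ramps across each double
support (the shares sum to one identically). Per-foot COP advances linearly
heel→toe (−0.20 to +0.75 foot lengths about the ankle) and rolls
mediolaterally from a slightly lateral heel contact to the medial forefoot
(−12 mm to +38 mm toward the midline). Plate 1 records all right-foot
stances and plate 2 all left-foot stances (split-belt convention); this
keeps the two-plate sum equal to the whole-body force at every sample and
gives a defined net COP on every analysis frame, while the analyzed crossing
is still one right-stance/left-stance pair.

**IMU.** The sensor sits 10 cm posterior / 2 cm above the COM in the trunk
frame. Trunk orientation = stride-locked roll/pitch/yaw sinusoids plus
heel-strike rotational jolts; sensor position = COM + R·offset + impact
displacement. Heel-strike transients are damped ~14 Hz oscillations with
per-event amplitude, frequency, direction and roll/pitch-mix jitter; they are
stored as displacements/rotations so that the accelerometer output remains
the exact specific force of the sensor's rigid-body motion: accel =
Rᵀ(p̈ + g·ẑ), gyro from the skew part of Ṙ Rᵀ, magnetometer = Rᵀ·B with
B = (20, 0, −44) µT. Derivatives are taken by central differences on the
dense 1080 Hz master clock, then resampled to 100 Hz. Noise: white Gaussian
(accel 0.15 m/s², gyro 1.0 deg/s, mag 1.0 µT) plus a random walk with
per-sample step 0.05 σ — the slow bias wander of consumer MEMS parts, which
no low-pass filter removes. Channels are clipped to ±16 g, ±2000 deg/s,
±4800 µT.

**What the generator does *not* emulate.** Marker-level kinematics and
soft-tissue artifact; anteroposterior/mediolateral GRF components; arm
swing as a separate oscillator; magnetic disturbance fields beyond white
noise + drift; pathological gait. Consequently, passing tests demonstrate
that the pipeline recovers the IA under realistic signal morphology and
subject-wise generalization pressure — not that the trained weights would
transfer to real recordings.

## Preprocessing

4th-order Butterworth low-pass, zero-phase by default (forward–backward pass
with odd-reflection padding of 3× the filter order; single-pass causal mode
available). Mocap and force streams are filtered at 7 Hz before the ground
truth is computed; IMU channels at the experimental cutoff (2, 10 or 25 Hz).
The zero-phase double pass has |H(f_c)|² = ½ at the cutoff — the tests pin
this value.

Columns are scaled linearly to [−1, 1] from per-column extremes. The default
`paper` mode computes extremes over the whole matrix, which leaks test-set
statistics into training; the leakage-safe `train_only` mode is provided and
recommended for any methodological reuse. The learning matrices stack one
100-frame cycle per trial with full subject/trial/speed/frame provenance per
row (24 × 5 × 3 × 100 = 36,000 rows at full scale).

## Estimators

Both estimators are implemented in numpy and are pure functions of
(data, spec, seed); gradients are verified against central finite
differences in the tests.

**FFANN.** 9 → 10 log-sigmoid → 2 linear. A log-sigmoid *output* cannot
reach targets in [−1, 1], so the output layer is linear (a sigmoid-output
variant with rescaled targets is available). Trained full-batch with
Møller's scaled conjugate gradient (the classical trainer for small
feed-forward networks: finite-difference Hessian-vector products with
Levenberg–Marquardt scaling, no line search), at most 1000 epochs, early
stopping when the validation MSE fails to improve for 6 consecutive
weight-changing iterations (SCG iterations that reject the step leave the
weights unchanged and carry no stopping evidence); a gradient-norm stopping
mode is available. The best-validation weights are returned.

**LSTM.** Two stacked layers (512 cells at full scale; the desk profile uses
64), standard gates with tanh state activation, linear readout; each
100-frame cycle is one independent sequence (state reset between cycles).
Adam, learning rate 0.001, minibatches of 10 sequences, seeded shuffling, an
L2 weight penalty of 0.0025 applied as decoupled decay on the weight
matrices, fixed epoch budget (100 full scale / 30 desk). Three
implementation choices make the fixed budget sufficient: orthogonal
initialization of the recurrent kernels (healthy gradient propagation
through 100 steps), an echo-state-style initialization of the readout —
ridge regression of the targets on the *untrained* recurrent features — so
no epochs are spent learning the output map from scratch, and stochastic
weight averaging over the last 5 epochs, which removes the minibatch jitter
of the final iterate. Each choice was adopted for its effect on convergence
at the fixed budget; none alters the stated architecture or optimizer
hyperparameters.

## Evaluation

Splits are by subject, 75/12.5/12.5 (18/3/3 of 24; for other cohort sizes
the training share is rounded and the remainder split val/test with test
taking the larger half). Ten disjoint 3-subject test sets cannot partition
24 subjects, so "10-fold" is realized as 10 repeated random subject-wise
splits; every fold's composition is logged.

Per fold, test cycles are concatenated and scored per plane: Pearson r,
RMSE in degrees, and rRMSE = 100·RMSE / range(y_true) (range normalization
is the convention in this literature; a mean-normalized variant is
configurable). Cell values are means of fold values. The estimator contrast
is a one-way ANOVA on rRMSE pooled over cutoffs (df (1, 2·3·n_folds − 2));
the cutoff contrast is per estimator across the three cutoffs
(df (2, 3·n_folds − 3)). Significance thresholds 0.05/0.01, no
multiple-testing correction.

## Problem sizes

The desk-scale profile used by the test suite and the acceptance script is
12 subjects × 3 trials × 3 speeds (10,800 frames), 3 folds, LSTM 2 × 64
cells / 30 epochs — chosen as the smallest configuration at which the
study's qualitative findings are stable across master seeds. The full-scale
profile (24 × 5 × 3, 10 folds, LSTM 2 × 512 / 100 epochs) is a documented
flag; its LSTM is roughly two orders of magnitude more expensive and was
sized for GPU hardware.

## Known limitations

* The generator's harmonic gait model has no feedback control; perturbation
  responses and pathological patterns are out of reach.
* Frontal-plane IA excursions (~3–5° over a cycle) sit at the lower end of
  published envelopes; the latent-factor coupling that makes frontal offsets
  observable is a modelling assumption, not a measured quantity.
* The `paper` scaling mode leaks extremes across the subject split by
  design fidelity; use `train_only` for honest deployment estimates.
* Determinism is guaranteed per platform/BLAS build; bit-level results may
  differ across numpy/BLAS versions while remaining statistically
  equivalent.
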