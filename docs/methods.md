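# Methods

This note documents the models, numerical choices and limitations behind
`stepredict`, in the package's own terms.

## Problem setting

A standing subject receives a forward pelvis push (a rectangular force
pulse, 0.2 s, with magnitude expressed as a fraction of body weight
`m·g`).  The outcome is binary: the subject recovers feet-in-place or
takes a reactive step.  The analysis asks whether the step can be
predicted from force-plate and kinematic measurements *before* it
happens, using only the subject's state (no information about the
perturbation itself), and which features carry the prediction.

Because the package ships no experimental recordings, a synthetic-data
generator is a first-class module: it defines the study conditions under
which every downstream result in the test suite and the acceptance
script is computed.

## Synthetic balance responses

**Dynamics.**  The anteroposterior CoM is a single-link inverted
pendulum about the ankles, linearized about upright:

    ẍ = (g/h_com)·(x − p) + F(t)/M + η(t)

where `p` is the centre of pressure commanded by an ankle controller
`p = x₀ + k_p (x − x₀) + k_d ẋ` (defaults `k_p = 3`, `k_d = 0.45`,
reference `x₀` = the trial's baseline lean) and **saturated to the foot
extents** — the ankle is placed 25% of the foot length from the heel, so
`p ∈ [−0.25, +0.75]·l_foot` relative to the ankle.  `F(t)` is the pulse,
`η(t)` white acceleration noise (0.7 m/s² by default) that produces
postural sway of a few millimetres RMS.  Integration is explicit
fixed-step at 1000 Hz, matching the force-plate rate; kinematic channels
are decimated to 100 Hz, matching a camera system.

A hip/trunk degree of freedom responds to the pulse as a damped
second-order system (natural frequency 6 rad/s, damping 0.7).  Its angle
`φ` adds a flexion term to the cervical-joint-centre position
`x_CJC = (0.85·H/h_com)·x + 0.30·H·sin φ` and defines the hip angle.
The trunk gain varies per trial (15% sd) and is 1.3x larger on stepping
trials, so the CJC carries class information beyond the CoM — this is
what makes feature-selection experiments meaningful.  Other joint
centres (hip 0.53·H, knee 0.285·H) ride on the pendulum.  Whole-body
angular momentum about the CoM is synthesized as
`0.35·M·h_com²·(ẋ/h_com) + 0.05·M·H²·φ̇`.

**Ground reaction channels.**  Total vertical force is `M·g`; a load
share splits it between the feet.  Non-stepping trials keep the share at
0.5 plus slow sway noise.  Stepping trials superimpose: an anticipatory
loading peak (+0.08 of body weight over 0.08 s, peaking exactly at SLU),
a cosine-shaped monotone decline to zero between SLU and TO, an unloaded
swing, and smooth reloading after landing.  Plate moments are back-
computed from the commanded CoP (`M_y = −p_x·F_z`, `M_x = p_y·F_z` per
foot, feet at ±w_stance/2), so the CoP module must exactly invert the
synthesis — a tested identity.  The anticipatory peak makes SLU an
identifiable corner of the force trace even after 8 Hz low-pass
filtering; its amplitude and width were chosen so the filtered peak
stays within one or two samples of the true event.

**Event timing.**  Perturbation-to-TO is drawn from N(0.56, 0.20²) s
(clipped to [0.30, 1.90]), SLU-to-TO from N(0.16, 0.03²) s.  The
unloading duration is additionally capped at `(t_TO − 0.05)/1.5` so that
the earliest of the seven prediction time steps, `TO − 1.5·(TO − SLU)`,
always falls after perturbation onset — fast responses unload fast.
Swing duration ~ N(0.18, 0.03²) s and step length ~ N(0.30, 0.05²) m.

**Stepping decision.**  Each subject has a latent force threshold drawn
from N(0.11, 0.029²) in units of `m·g`.  A trial steps when its pulse
fraction exceeds the threshold plus logistic noise (scale 0.01 `m·g`),
which makes stepping probability rise monotonically with force and
produces the class overlap the protocol aims for.  With the threshold sd
and the noise set to zero the labels are a deterministic function of the
force level — the degenerate case used in tests.  An alternative rule
(`label_rule="xcom_margin"`) thresholds the peak extrapolated-CoM margin
of a noise-free probe simulation instead; it is used when the true
decision rule must be a known function of the mechanical state, e.g. for
parameter-recovery experiments.  Its default threshold (−0.155 m
relative to the toe) sits mid-range of the margins spanned by the
default force levels, so both classes occur for every subject.

**What the generator does not emulate.**  Marker-level noise and
occlusion, the perturbation device's imperfect force tracking, vertical
CoM motion, backward perturbations, second steps, inter-trial learning
or fatigue, and the full anthropometric regression (segment parameters
are fixed height fractions).  Passing tests therefore demonstrate that
the pipeline's machinery is correct under controlled conditions, not
that the reported accuracies transfer to real motion-capture data.

## Preprocessing

Force channels are resampled 1000 → 100 Hz by polyphase filtering with
linear-extension padding, then filtered; motion and force channels use a
4th-order Butterworth applied forward and backward (zero phase,
reflective padding), cut off at 5 Hz and 8 Hz respectively, so the
effective magnitude response is 8th-order.  CoP is computed per sample
from the summed plate moments and vertical forces and masked invalid
wherever `F_z ≤ 20 N` (the quotient is ill-conditioned near zero force;
the floor reuses the step-detection threshold).  Derivatives are central
differences with one-sided differences at the edges; positions are
re-expressed relative to the mean ankle position over the 2 s baseline;
CoM velocity and acceleration are recomputed as derivatives of the
filtered position.  Clock offsets between force and motion systems are
estimated as the lag maximizing the cross-correlation of a shared
pseudo-random synchronization signal, at one-sample resolution.

## Labeling

Step detection and screening follow fixed rules: a step requires the
vertical force under one foot to drop below 20 N within 2 s of onset
with a step length of at least 20% of foot length (anteroposterior ankle
displacement from baseline to first ground contact after TO); a sub-20 N
event failing the other two conditions excludes the trial.  TO is
refined from the first sub-20 N sample to the zero-force onset (≤ 1 N).
SLU is found by scanning the stepping-foot force backward from TO while
it keeps rising, absorbing dips of up to 2 N, and taking the latest
sample still within 2 N of the running peak — the latest admissible
onset of the final monotone decline.  If the decline extends to the
first sample the trial is flagged with a warning.

Screening thresholds operationalize otherwise qualitative rules:
baseline lean beyond 0.03 m, baseline CoM-velocity RMS above 0.02 m/s,
either foot under 40% of body weight at onset, or (without a step) CoP
dwelling in the front 20% of the foot for more than 0.5 s (a heel-lift
proxy).  All are configurable (`ScreenConfig`).

The seven prediction time steps are `SLU − 2Δ, SLU − Δ, SLU, SLU + Δ,
…, TO` with `Δ = (TO − SLU)/4`, snapped to the 100 Hz grid by
round-half-away-from-zero.  Per-response time steps are averaged before
any reporting, so mean pre-SLU steps need not equal the rounded mean SLU
minus multiples of the rounded mean spacing.

Splits are stratified per subject and class: 15% test first, then 70/30
train/validation of the remainder, deterministic under a seed.

## Features and standardization

Fifteen features per 100 Hz observation; positions normalized per
subject (CoM by `h_com`, CoP by `l_foot` / `w_stance`, joint centres by
`H`, angular momentum by `M·h_com²`), accelerations and joint angles in
physical units.  The kinematics set removes all six CoP-derived columns,
leaving nine.  Standardization `x' = (x − mean)/sd` uses the sample
standard deviation of the *training split only*; validation and test
tables are transformed with the training statistics.

Training observation sets pair every 100 Hz observation of a
non-stepping response from onset to onset + 4 s (401 observations) with
a single observation per stepping response taken at the chosen
prediction time step, giving the strong class imbalance the classifier
settings respond to.

## Classifiers and evaluation

LDA and QDA use empirical priors (class imbalance is compensated at the
threshold, not the prior); QDA carries a 10⁻⁶ covariance regularizer.
The linear SVM minimizes hinge loss with L2 regularization (C = 1) and a
35x weight on stepping observations.  The neural network has one hidden
layer of 5–8 sigmoid units with a softmax-normalized output, trained by
cross-entropy (L-BFGS, at most 500 iterations, seeded initialization).
A weight decay of 0.1 is applied: without it the heavily imbalanced
observation sets drive the hidden units into saturation, which collapses
distinct observations onto identical scores and makes single fits
erratic.  Prediction scores are the stepping posterior (LDA/QDA/NN) or
the signed decision value (LSVM; the threshold sweep is scale-free, so
the canonical-margin question is moot).

Stepping responses are scored on all observations from onset to the
prediction time step, non-stepping responses on onset to onset + 4 s.  A
response is predicted stepping when at least one observation exceeds the
score threshold (single hit ⇔ window maximum above threshold).  The
threshold is chosen on the validation set by exhaustive search over
midpoints of the sorted per-response maxima (with open sentinels),
maximizing accuracy and breaking ties by the larger
sensitivity + specificity, then the larger threshold; test metrics reuse
the validation threshold.

Conventional predictors trigger per sample and aggregate with the same
single-hit rule.  The pendulum length for the XCoM defaults to `h_com`;
the base-of-support scale is chosen on the validation set from
{1.0, 0.9, …, 0.5}; the time-to-boundary threshold is optimized on the
training + validation responses by midpoint search over per-response
minimum τ, with the same tie-break.

## Recursive feature elimination

At each stage all leave-one-out subsets are retrained and scored by
threshold-swept response-level validation accuracy; NN subsets average
over `n_repeats` seeded restarts (10 by default) with a
stage-and-subset-indexed seed schedule, so reruns reproduce exactly.
The feature absent from the best subset is eliminated.  Ties go to the
larger sensitivity + specificity sum, then fixed feature order.  Both
the full 15-feature set and the 9-feature kinematics set are supported
entry points.

## Problem sizes

The test suite and the acceptance script run on synthetic cohorts of
120–200 responses (4–8 subjects, 20–40 trials each) — about a third of a
full experimental session per subject — with classifier comparisons
repeated over 10 generator seeds where an ordering is asserted.  These
sizes keep each fit well-conditioned (the largest observation sets are
a few tens of thousands of rows) while exercising every pipeline stage.

## Known limitations

- The simulator's non-stepping trials never lose balance; very large
  forces labeled non-stepping by the noisy threshold produce unusually
  large excursions rather than falls.
- Mediolateral dynamics are synthesized (load-share profile plus sway
  noise), not simulated from frontal-plane mechanics.
- The stability-boundary and XCoM baselines use the linearized sagittal
  state only, as designed; no angular-momentum-augmented capture point
  is provided.
- Classifier hyperparameters are fixed defaults, not searched.
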