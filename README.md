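# stepredict

Predicting **natural reactive stepping** from perturbed-standing balance
responses with a classification approach.

When a standing person is pushed forward at the pelvis, they either
recover in place (ankle and hip strategies) or take a reactive step.
`stepredict` implements a full analysis pipeline for asking *whether the
step can be predicted before it happens*, and *which biomechanical
features carry that prediction*:

1. **Synthetic data** — a seeded simulator of perturbed standing
   (sagittal inverted pendulum with saturated ankle-torque feedback plus
   a trunk degree of freedom) produces per-foot force-plate channels at
   1000 Hz and kinematic channels at 100 Hz, with stepping and
   non-stepping outcomes that overlap near a per-subject force
   threshold.
2. **Preprocessing** — zero-lag 4th-order Butterworth filtering (5 Hz
   motion / 8 Hz force), polyphase resampling of force data to the
   100 Hz kinematic clock, cross-correlation clock synchronization, and
   centre-of-pressure computation from the plate moments,
   `p_x = -M_y / F_z`, `p_y = M_x / F_z`.
3. **Labeling** — step detection (vertical force on one foot below
   20 N, within 2 s of perturbation onset, step length at least 20% of
   foot length), toe-off (TO) and step-leg-unloading (SLU) detection,
   seven prediction time steps spaced by `(t_TO - t_SLU)/4`, screening
   of unnatural trials, and a stratified 15% / 70% / 30%
   test / train / validation split.
4. **Features** — the 15-feature set (CoM position/velocity/acceleration,
   whole-body angular momentum, CoP positions and derivatives, hip and
   knee angles, cervical-joint-centre / hip / knee positions), normalized
   per subject and standardized with training-set statistics
   (`x' = (x - mean)/sd`).
5. **Classifiers** — LDA, QDA, a linear SVM (hinge loss, stepping
   observations weighted x35) and one-hidden-layer neural networks
   (5–8 sigmoid units).  A response is predicted *stepping* if any
   observation in its window scores above a threshold chosen on the
   validation set to maximize response-level accuracy.
6. **Conventional baselines** — the CoM-state stability boundary
   (velocity limit falling from 0.45 s⁻¹ over the heel to 0 over the
   toe), the extrapolated centre of mass
   `ξ = x_com + ẋ_com / sqrt(g/l)` against the base-of-support limit,
   and the CoM time-to-boundary
   `τ = (x_bos - x_com)/ẋ_com` (infinite for non-forward motion) with an
   accuracy-optimized threshold.
7. **Recursive feature elimination** — leave-one-out retraining with
   10-run averaging for neural networks, eliminating the feature whose
   absence yields the best validation accuracy, down to one survivor.

## Worked example

```python
from stepredict import PipelineConfig, GeneratorConfig, run_pipeline

config = PipelineConfig(
    generator=GeneratorConfig(n_subjects=4, trials_per_subject=20, random_seed=7),
    timesteps=["SLU-2", "SLU", "TO"],
)
results = run_pipeline(config, "scratch/demo_run")
print(results["comparison"]
      .query("split == 'validation' and timestep == 'SLU'")
      [["method", "accuracy", "sensitivity", "specificity"]]
      .to_string(index=False))
```

prints (seed 7):

```
method  accuracy  sensitivity  specificity
   LDA      1.00          1.0          1.0
   QDA      1.00          1.0          1.0
  LSVM      1.00          1.0          1.0
  NN-8      1.00          1.0          1.0
    SB      0.50          0.0          1.0
  XCoM      0.75          0.5          1.0
   TTB      0.85          0.7          1.0
```

Read this as: at the moment of step-leg unloading the trained
classifiers identify essentially every stepping and non-stepping
response of this synthetic cohort, while the conventional
inverted-pendulum predictors are conservative — near-perfect
specificity but low sensitivity, so lower accuracy.  Accuracy drops for
earlier prediction time steps and rises toward toe-off; the same
qualitative pattern reported for the motion-capture experiments this
pipeline emulates.

The same analysis is available from the shell:

```bash
stepredict report --out scratch/demo_run
stepredict rfe --feature-set kinematics --n-repeats 10 --out scratch/demo_rfe
```

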