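# graspadapt

Analysis tools for **trial-by-trial sensorimotor adaptation and perturbation
detection in reach-to-grasp experiments** with visuo-haptic size mismatches.

In mirror-setup grasping experiments, the size of the object a participant
*sees* (v, mm) and the size of the object they *feel* (h, mm) can be
dissociated. The mismatch h − v can be switched on abruptly (constant over a
block) or swept as a sine over trials. Two questions follow: how does the
grip adapt trial by trial, and how does that adaptation change the
participant's ability to *detect* the mismatch in a two-alternative
forced-choice (2AFC) judgment?

`graspadapt` implements the full chain for both questions:

- **schedules** — abrupt (24 trials, 4 unperturbed baselines at each end) and
  sinusoidal (36 trials, 3 cycles, first trial unperturbed) perturbation
  schedules, with felt sizes quantised to the 0.5 mm grid of physical objects
  in [28, 60] mm.
- **simulate** — a complete synthetic-experiment generator: maximum grip
  apertures (MGAs) from the state-space model below, 3-D marker trajectories
  realising those apertures, and 2AFC responses from a noisy-comparison
  observer whose internal reference may be shifted by the adaptation state.
- **kinematics** — cubic-spline interpolation of missing motion-capture
  frames, 200 ms Savitzky–Golay smoothing, velocity/position segmentation of
  the grasp, MGA extraction, and the four standard per-trial exclusion rules.
- **adaptation** — the core model and its block-wise RMSE fit.
- **psychometrics** — correctness scoring, per-trial accuracy traces,
  participant-wise detection trends, half-cycle folding for sinusoidal
  blocks, and cumulative-normal psychometric fits yielding PSE and JND.
- **stats** — two-way repeated-measures ANOVA, paired t with Cohen's
  d = t/√n, JZS Bayes factors for t-tests (Cauchy prior) and correlations
  (stretched-beta prior), Deming regression, percentile bootstrap.
- **pipeline** — end-to-end runs (simulate/import → preprocess → fit →
  detect → stats → report) with manifests; a thin `graspadapt` CLI.

## The model

Grip apertures scale linearly with object size,
`MGA(v) = int + slope·v`. Adaptation is a latent visuomotor-mapping state
`x_t` (mm) added to the seen size at planning time:

    MGA_mod(t) = int + slope·(v_t + x_t)
    E_t        = MGA_t − (int + slope·h_t)
    x_{t+1}    = A·x_t − b·E_t ,  x_1 = 0

with retention `A ∈ [0,1]` and error-correction rate `b ∈ [0,1]`. The error
signal `E_t` is the deviation of the executed aperture from the comfortable
grasp of the *felt* object; a too-large grasp (E > 0) drives the state down.
For a constant mismatch Δ the noise-free loop converges to
`x* = b·slope·Δ / (1 − A + b·slope)`; for a sinusoidal mismatch the state is
the output of a first-order linear filter — attenuated and phase-lagged.
Block-wise fits minimise the RMSE between observed and modelled apertures
over (A, b, int) with the slope held fixed at the cohort's response-function
slope.

Detection is analysed from the 2AFC judgments: a response is correct when it
matches the sign of the mismatch, and per-participant JNDs come from
maximum-likelihood cumulative-normal fits of P(felt larger) against the
mismatch.

## Worked example

Simulate one abrupt block at the reference parameter point and fit it back
(`examples/02_fit_adaptation_model.py`):

```text
generating: A = 0.95, b = 0.2, int = 23.0 mm
recovered : A = 0.971, b = 0.232, int = 22.3 mm
fit RMSE  : 2.29 mm (motor noise was 2.0 mm)

noise-free asymptotic state for a constant 12 mm mismatch, slope 1: 9.6 mm
```

A single noisy 24-trial block recovers the generating parameters to within a
few hundredths (noise-free blocks recover them to 1e-3), and the fitted RMSE
sits at the injected motor-noise level. The 9.6 mm asymptote means the grip
silently absorbs ~80% of a sustained 12 mm perturbation — which is exactly
why the mismatch becomes hard to detect: an adaptation-coupled observer
cohort (`examples/04_detection_analysis.py`) shows

```text
mean accuracy trend (% correct per trial):
  abrupt    : -1.59
  sinusoidal: -0.01

mean JND (mm):
  abrupt    : 11.8
  sinusoidal: 5.0
```

declining accuracy and a larger JND only where the schedule allows full
adaptation. The other examples cover schedule construction, MGA extraction
from synthetic recordings (sub-0.1 mm on clean data), the inferential
toolbox, and the one-shot pipeline.

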