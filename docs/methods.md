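# Methods

This note documents the models, algorithms and design choices behind
`graspadapt`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Perturbation schedules

A schedule is an ordered list of (seen size v, felt size h) pairs. Two
shapes are implemented.

**Abrupt.** n = 24 trials: 4 unperturbed baseline trials, 16 trials at a
constant signed mismatch M ∈ ±{3, 6, 12} mm (main experiment) or
±{4, 8, 12} mm (pilot), and 4 unperturbed washout trials.

**Sinusoidal.** n = 36 trials, 3 cycles of period P = 12:
`mismatch(t) = s·M·sin(2π(t−1)/P)` with start sign s = ±1. The phase
convention anchors trial 1 at exactly zero; quarter-cycle trials sit at the
peak ±M. In the main experiment half the sinusoidal blocks start negative;
in the pilot all start positive.

Felt objects exist physically from 28 to 60 mm in 0.5 mm steps, so
mismatches are quantised to the nearest multiple of 0.5 mm, ties away from
zero (only the step size is physically constrained; the tie rule is a
package convention, and it is immaterial on the printed designs, whose only
ties are at ±M/2·√3 etc. nowhere near a tie point). `quantum=None` yields
the ideal continuous schedule used for the linear-systems checks. Whether
quantisation applies to the mismatch or to the felt size is moot for the
printed integer seen sizes; the package quantises the mismatch.

Seen sizes are {40, 44, 48} mm re-drawn uniformly per trial (main) or fixed
per block at {40, 45} mm (pilot). The uniform per-trial draw is a package
choice; the original randomisation scheme is not specified. Block order is
caller-provided (the original Latin-square counterbalancing is out of
scope), and the 12-trial practice block is generable but excluded from all
analyses.

## 2. State-space adaptation model

The response function maps object size to a comfortable aperture,
`MGA(v) = int + slope·v` (both in mm; slope dimensionless). Adaptation adds
a latent state x_t (mm of object size) to the seen size at planning time.
After each grasp the haptic channel defines the error signal — the deviation
of the executed aperture from the comfortable aperture for the felt size —
and the state is carried over and corrected:

    MGA_mod(t) = int + slope·(v_t + x_t)
    E_t        = MGA_t − (int + slope·h_t)
    x_{t+1}    = A·x_t − b·E_t ,  x_1 = 0 at each block start.

**Sign convention.** Some write-ups state the error as comfortable-minus-
observed; combined with the `A·x − b·E` update that convention is a positive
feedback loop (a too-large grasp makes the next grasp larger still), which
contradicts the behaviour the model is meant to describe — errors corrected
*downwards* when the grasp was too large, exponential convergence to an
asymptote. The package therefore defaults to observed-minus-comfortable
(`error_sign="stable"`), with the opposite convention selectable
(`"as_printed"`) for audit.

**Closed-loop algebra.** With E substituted, the noise-free loop on a
constant mismatch Δ is `x' = (A − b·slope)·x + b·slope·Δ`, a contraction for
the parameter box of interest, with fixed point
`x* = b·slope·Δ/(1 − A + b·slope)` (9.6 mm at A = 0.95, b = 0.2, slope = 1,
Δ = 12). For a sinusoidal mismatch the loop is a first-order linear filter
with pole `c = A − b·slope`; `closed_loop_frequency_response` returns its
gain and phase at 2π/P, against which simulated steady states are verified
to 1e−6.

**Fitting.** Per block, (A, b, int) minimise the RMSE between observed and
modelled apertures, with A and b box-constrained to [0, 1] and the slope
frozen at the across-participant mean of per-participant OLS slopes of mean
MGA on seen size (slope and b both encode a responsiveness and trade off if
freed jointly). The error term uses the *observed* aperture, so random
motor errors propagate into correction — matching how the model is taken to
the data. The optimiser is deterministic: a 9 × 10 grid over
A ∈ {0.1…0.9}, b ∈ {0.05…0.5} (intercept seeded from de-sloped apertures on
zero-mismatch trials, where the state is near zero) ranks starts, and the
best three are polished by bounded trust-region least squares to 1e−12
tolerances. Earlier builds used a bounded direction-set (Powell) polish; on
this objective it stalls on ridges that the least-squares step resolves, so
the least-squares polish is the shipped choice. Noise-free synthetic blocks
are recovered to 1e−3 in A and b with RMSE < 1e−6 mm.

**Excluded trials** keep the state propagating with the model's own
prediction as the error carrier, and their residuals are dropped from the
objective; `excluded_policy="freeze_state"` is available as the alternative
reading. Blocks whose objective is insensitive to b (e.g. constant
apertures on an unperturbed block) are flagged `flat_ridge` rather than
reported as sharp estimates.

## 3. Synthetic data generator

The generator exists so that every downstream stage is testable without any
external download; its defaults are the study conditions where those are
stated, and conventional grasp parameters where not.

- **Participant parameters**: A = 0.95, b = 0.2 (the reference simulation
  point for this class of experiment), intercept 23 mm and slope 0.93 —
  the slope matches the strong size scaling seen in simple mirror setups,
  and the intercept then puts baseline apertures ≈ 20 mm above the object,
  a typical grasp safety margin (both documented as conventional choices);
  motor noise 2 mm SD added to each MGA, with the noisy value feeding the
  state update.
- **Observer**: the 2AFC decision variable is
  `d = h − (v + κ·x) − bias + η`, η ~ N(0, σ), response "felt larger" iff
  d > 0, with σ = 4 mm by default. κ ∈ [0, 1] couples the internal size
  reference to the adaptation state: κ = 0 is a stationary observer whose
  accuracy is Φ(|mismatch|/σ) regardless of schedule; κ = 1 fully couples
  perception to the adapted mapping, so the *sensed* mismatch on adapted
  trials shrinks towards (1 − gain)·Δ. This operationalises the hypothesis
  that adaptation masks perturbations; it is a simulation device, not an
  empirical claim, and κ = 1 produces a stronger masking than real cohorts
  show.
- **Trajectories**: thumb/index midpoints follow a minimum-jerk transport
  (300 mm reach main, 600 mm pilot — the pilot's touch-proximity radius is
  300 mm, so the reach must exceed it) over 1 s inside a 3 s @ 500 Hz (main)
  or 5 s @ 200 Hz (pilot) recording; the inter-digit aperture opens from
  20 mm to exactly the programmed MGA with cosine easing, then closes onto
  the object. The peak is placed at 45% of movement time, *before* the
  midpoint crosses the touch-detection radius (which happens at half the
  reach under minimum jerk): this guarantees the [onset, touch) extraction
  window brackets the true peak, making the generator a construction oracle
  for the kinematic chain (clean recordings re-extract the programmed MGA
  to < 0.1 mm). Real aperture profiles peak later (~60–75% of movement
  time); only the extracted MGA, not the profile shape, carries information
  downstream. Gaussian marker noise and per-frame dropouts are applied
  last.
- **Determinism**: a session is reproducible bit-for-bit from the
  participant seeds; per-block RNG streams are spawned from a seed
  sequence so stages can be regenerated independently.

## 4. Kinematic processing

Interior gaps in each marker coordinate are filled by cubic spline (exact on
cubic trajectories); leading/trailing gaps are never extrapolated and count
as missing. Smoothing is Savitzky–Golay with a 200 ms window (forced odd in
frames) and polynomial order 3 — the standard order for position data, given
that only the window is conventionally reported. Velocities are central
differences on smoothed positions.

Movement onset is the first frame where thumb *and* index speed exceed
0.05 m/s and stay there for 25 ms (the sustain window suppresses single-
frame noise; the bare thresholds alone are the field convention). The touch
event is the first post-onset frame where |d(aperture)/dt| falls below
0.075 m/s (main; 0.1 pilot) *and* the thumb–index midpoint is within 150 mm
(main; 300 pilot) of the object centre, again sustained 25 ms. The MGA is
the maximum thumb–index distance on [onset, touch), earliest frame on ties.

Exclusion rules, per participant: (i) the MGA frame's thumb or index sample
was interpolated; (ii) more than 20% of frames between onset and touch are
missing (missing = either digit marker absent; the per-marker alternative
is a stricter reading the package does not take); (iii) the MGA is smaller
than the grasped (felt) object; (iv) the MGA deviates more than 3 IQRs from
the participant's median for the same (seen, felt) cell — skipped with a
warning for cells of fewer than 2 trials.

## 5. Detection analyses

Correctness is the agreement of the response with the sign of the mismatch;
zero-mismatch trials have no correct answer and are excluded from accuracy
denominators. Detection trends are participant-wise OLS of binary
correctness (scored 0/100) on trial index, per schedule × magnitude; for
balanced data this equals OLS on per-trial means, and the binary form is
used. Half-cycle folding maps sinusoidal trials to positions 1…P/2 via
(t − 1) mod P/2, collapsing the two half-cycles so that position and
momentary magnitude are unconfounded; the zero-crossing position stays
undefined.

Psychometric functions are maximum-likelihood cumulative normals,
`P(felt larger | m) = Φ((m − PSE)/σ)`, fitted by Nelder–Mead on (PSE,
log σ) with a Bernoulli likelihood and no lapse parameters (a lapse/guess
extension is deliberately omitted as it is not part of the analysis being
mirrored). Perfect separation drives σ to a bound and sets a flag instead
of raising. The JND is σ (the PSE-to-84.1% distance) by default;
`half_interquartile` (0.674·σ, half the 25–75% spread) is selectable because
absolute JND magnitudes depend on the convention.

## 6. Inferential statistics

The two-way fully-within-subject ANOVA uses the classical decomposition with
each effect tested against its participant interaction; replicates are
averaged per cell first and incomplete designs are refused. No sphericity
correction is applied by default, matching the uncorrected degrees of
freedom this literature reports; Greenhouse–Geisser is available. Cohen's d
for paired designs is t/√n.

The JZS t-test Bayes factor integrates the noncentral-t likelihood over a
Cauchy(0, r) prior on the standardised effect (default r = 0.707) by
adaptive quadrature; the test suite cross-checks it against the equivalent
g-prior-mixture integral. The correlation Bayes factor places a symmetric
stretched-beta prior of width r = 0.333 on ρ — density ∝ (1 − ρ²)^(1/r − 1) —
and integrates the exact Hotelling sampling density of r. Identical paired
samples return t = 0, d = 0 by convention; constant *non-zero* differences
are refused as degenerate.

Deming regression uses the closed-form errors-in-variables slope with the
error-variance ratio fixed at 1 (orthogonal regression) since no ratio is
conventionally reported for this use. Bootstrap intervals are percentile,
10,000 replicates by default, deterministic under a seed.

## 7. Pipeline

`run_pipeline` composes the stages and writes tidy CSVs plus a
`manifest.json` (full config, its hash, the seed, the realised exclusion
fraction), so any output is reproducible from the manifest alone. Without
marker recordings the simulated apertures are analysed directly and only
exclusion rules (iii)/(iv) can bind; with `include_trajectories=True` the
kinematic chain re-derives every aperture. `import_external` maps a
deposited trial table onto the canonical columns under a caller-supplied
column map with unit sanity checks (sizes 10–100 mm, apertures 10–200 mm),
since the deposited layout is not part of this package's contract.

## 8. Problem sizes in the shipped checks

The shipped acceptance checks use 200 synthetic blocks per schedule for the
noisy recovery study, 40 blocks per noise level for the noise-curve, a
48-participant cohort for the detection findings, and 8 clean recordings for
the kinematics oracle — sizes chosen to make the Monte-Carlo means stable at
the asserted tolerances. What passing shows, and what it does not: the
synthetic generator realises the model's own assumptions (linear response
function, single-rate state, Gaussian noises, a κ-coupled observer), so
green tests demonstrate the correctness and calibration of the *analysis
chain*, not the adequacy of the model for real grasping data. Features of
real data the generator does not emulate include response-switching
tendencies over long constant-answer stretches, fatigue, anticipation of
the sinusoidal schedule, force/lift dynamics, and two-rate (fast/slow)
adaptation, which needs longer blocks than these designs contain.
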