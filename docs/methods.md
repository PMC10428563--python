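# Methods

## Problem and measurement model

Cerebral edema after ischemic stroke progresses through two stages that need
opposite treatment: cytotoxic edema (CE), where water moves from the
extracellular to the intracellular space and tissue electrical conductivity
*falls*, and vasogenic edema (VE), where blood–brain-barrier breakdown raises
extracellular water and conductivity *rises*. Near-field coupling phase shift
(NFCPS) monitoring senses these conductivity changes non-invasively: an
excitation coil induces eddy currents in the head, and the phase of the
transmission coefficient between excitation and receiving coils shifts with
tissue conductivity. With one receiving coil over each hemisphere, the
lesion-minus-healthy difference (symmetric cancellation) isolates the
unilateral lesion signal, because early unilateral edema does not affect the
healthy hemisphere and the two hemispheres are approximately symmetric.

The package implements the analysis chain for such recordings:

1. **Symmetric cancellation** — element-wise `lesion(t) − healthy(t)` per
   frequency point.
2. **Time-difference offset** — subtraction of the cancelled pre-modeling
   (anesthetized, t = −1 h) reference sweep from every post-modeling sweep.
3. **MPFB** — the arithmetic mean of the offset phase over the 83–87 MHz
   feature band (41 grid points on the default 70–90 MHz / 201-point grid).
4. **Window features** over the hourly MPFB series, for window start t0:
   α = MPFB(t0), β = MPFB(t0+1) − MPFB(t0), γ = MPFB(t0+2) − MPFB(t0+1),
   δ = (MPFB(t0+2) − MPFB(t0)) / 2 (degrees per hour). γ at t0 equals β at
   t0 + 1 exactly.
5. **Classification** — a soft-margin linear SVM (CE = −1, VE = +1)
   separately per feature combination (α, β, αβ, αδ, αβγ).
6. **Evaluation** — test accuracy, confusion/specificity (VE positive),
   ROC/AUC by threshold sweep and trapezoid rule, learning curves with an
   over/underfitting diagnosis, and t-based group statistics.

Both processing stages are element-wise subtractions, so cancel-then-offset
equals offset-then-cancel; the implementation uses the cancelled baseline as
the offset reference. The sign convention (lesion minus healthy) makes the
CE stage appear as a negative MPFB deviation. No unwrapping, filtering or
denoising beyond band averaging is applied.

## Synthetic cohort generator

Real dual-hemisphere recordings are not redistributable, so the package ships
a generator whose defaults encode the study conditions the analysis assumes:
13 subjects (8 experimental with a thrombin-model-style unilateral lesion,
5 controls), one baseline plus 25 hourly sweeps per hemisphere, 201 points
over 70–90 MHz.

**Forward map.** The conductivity deviation Δσ(t) of the lesion hemisphere
enters the phase additively, `phase = baseline(f) + k(f)·Δσ + ε`, with a
Gaussian-bump sensitivity k(f) peaking at 85 MHz (inside the feature band,
where the observed change is largest) and normalised to band-mean one, so
Δσ is expressed directly in cancelled band-mean degrees. ε is i.i.d.
Gaussian per frequency point (default sd 1.0°); per-subject baselines are
low-order polynomials with small static left–right asymmetry. The full
circuit/impedance physics is intentionally absorbed into these calibration
constants.

**Trajectory.** For experimental subjects Δσ(t) is zero up to modeling at
t = 0, falls as a half-cosine to the nadir at the transition time
η ~ U[5, 7] h, and recovers monotonically to `(1 − recovery_fraction)` of the
nadir by 24 h. The recovery is a mixture (weight 0.5) of a *fast* half-cosine
with an 8-h characteristic time and a *slow* half-cosine over the whole
remaining span. The mixture matters: with a single slow half-cosine the
rebound starts with zero slope, subjects transitioning early have barely
recovered by hour 7, and the seed-averaged group-mean curve becomes
flat-bottomed with its minimum drifting to hour 7; the fast component gives
the early visible rebound that keeps the group-mean nadir at hour 6 while
the slow component keeps the curve rising through 24 h. Controls follow a
single smooth half-cosine drift reaching their net 24-h deviation
(−0.12 ± 0.05°).

**Default amplitudes.** Nadir depth −36 ± 6° and recovery fraction
0.7 ± 0.08 place the group-mean minimum near −35° at hour 6 with a 24-h
residual near −11°, the levels the analysis is designed around. The noise sd
of 1.0° per frequency point propagates to ≈ 0.3° on an MPFB value (41-point
band average, four sweeps per value), leaving the control group fluctuating
visibly around zero without masking its small drift.

**Labels.** Windows are labeled CE for t0 < η and VE for t0 ≥ η (the trend
turns upward at the transition, so the boundary window is VE). The η used
for labeling is the *hourly* transition time — the hour at which the
noise-free sampled trajectory attains its minimum — not the underlying
continuous draw: with 1-h sampling the transition is observable only at that
resolution, no interpolation between hours is attempted, and this labeling
makes the noise-free cohort exactly linearly separable in (α, β), as the
design intends. Window starts t0 = 0..22 are pooled across the 8
experimental subjects (184 rows; all four features defined at every row);
controls have no transition and are excluded.

What the generator does **not** emulate: instrument drift and temperature
effects, non-Gaussian or frequency-correlated noise, inter-subject
variability in the *shape* (rather than amplitude and timing) of the
trajectory, partial or bilateral lesions, and any amplitude (τ) information.
Passing tests therefore show that the analysis chain is correct and that the
protocol behaves as designed under these idealised conditions — not that the
reported accuracies transfer to real recordings.

## Classification protocol

The SVM is the standard soft-margin primal with linear kernel; any solver
meeting the KKT invariants is acceptable and the implementation delegates
the quadratic program to `sklearn.svm.SVC(kernel="linear", tol=1e-8)` behind
`SoftMarginLinearSVM`, which re-exposes the dual multipliers λᵢ for every
training row and verifies 0 ≤ λᵢ ≤ C, Σλᵢyᵢ = 0 and w = Σλᵢyᵢxᵢ to 1e−6
after every fit. Features are used unscaled by default (all are degrees on
comparable scales); a `standardize` flag applies training-set-only
standardisation.

Protocol, per feature combination:

1. 6:2:2 train/validation/test split by seeded shuffle (floor for the two
   smaller splits, remainder to training: 184 rows → 112/36/36).
2. Penalty grid C ∈ {0.1, 0.2, …, 10.0} (100 values); tenfold stratified CV
   **on the training split only** of the first candidate state; the smallest
   C attaining the highest mean accuracy wins. Fewer rows than folds reduces
   the fold count with a logged warning.
3. Random states 1–5 are evaluated by validation accuracy with the tuned C;
   the state attaining the median of the five accuracies is kept (ties to
   the lowest state index).
4. Final fit on train ∪ validation of the chosen split; the test split is
   touched only by the final evaluation.

Prediction is `VE if w·x + b ≥ 0 else CE`; exact boundary ties go to VE (a
borderline window is treated as already transitioning). Learning curves
refit on the first n shuffled training rows; the diagnosis thresholds are
"much lower" = error gap > 0.1 (overfitting) and "high" = both errors > 0.2
(underfitting).

## Group statistics

Confidence intervals are two-sided 95% t-intervals of the group mean. The
independent comparison (experimental vs control at the transition hour) uses
Welch's t-test by default — group sizes 8 vs 5 and visibly unequal variances
— with a pooled-variance option. The paired comparison (experimental at η vs
24 h) uses the paired t-test and additionally reports the paired-difference
interval; a zero-variance nonzero-mean difference vector is rejected with an
explicit error rather than returning a degenerate p-value.

## Numerical choices and edge cases

- Band membership uses a 1e−6 MHz tolerance at the closed endpoints.
- The C grid tie-break is "smallest C", implemented by strict-improvement
  scanning in ascending order.
- `np.median` of the five validation accuracies is always an attained value
  (odd count); `pick_median_state` still handles even counts by nearest
  value, lowest index.
- Degenerate ROC input (all scores equal) yields the chance diagonal,
  AUC 0.5.
- Model serialization is JSON text with full float precision (round-trip
  lossless to 1e−12).
- All randomness flows from explicit integer seeds; two runs with the same
  configuration and master seed produce byte-identical tables (output files
  carry no timestamps).

## Problem sizes used in the shipped checks

The calibration checks average 20 cohorts; the classification check runs the
full protocol on 50 cohort replicates for αβ, αδ and αβγ; the learning-curve
check uses 10 cohorts. These sizes give stable medians for quantities
quantised at 1/36 (the test-split size) while keeping a full run of the
suite and the acceptance script in the minutes range.

## Known limitations

- The σ→φ forward map is linear and additive; real coil physics is
  nonlinear in geometry and loading, and τ (amplitude) information is
  discarded by design.
- The trajectory family is smooth and unimodal; real MPFB curves show
  plateaus, secondary dips and inter-subject shape variability that the
  generator does not model, so real-data accuracy is expected to be lower
  than on the synthetic default (the published real-rabbit figures are in
  the low-to-high 90s rather than ≈100%).
- With continuous transition times and hourly sampling, windows that
  straddle the true transition are intrinsically ambiguous; the hourly
  labeling convention resolves them consistently for 1-h windows but a small
  fraction of 2-h windows (αδ) remain borderline by construction.
- Only the linear kernel and this one classifier are implemented; feature
  learning, PCA selection and other classifiers are out of scope.
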