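# nfcps — cerebral edema typing from near-field coupling phase-shift monitoring

Point-of-care discrimination of **cytotoxic** (CE) vs **vasogenic** (VE)
cerebral edema from dual-hemisphere near-field coupling phase shift (NFCPS)
monitoring. NFCPS is the phase of the transmission coefficient between an
excitation coil and a receiving coil over the head; it tracks tissue
electrical conductivity, which falls during CE (water moves into cells) and
rises during VE (extracellular water increases after blood–brain-barrier
breakdown). Distinguishing the two at the bedside matters because they call
for different dehydration therapy.

The package is aimed at biomedical-signal researchers working with
magnetic-induction / bioimpedance monitoring. It provides the complete
analysis chain plus a synthetic cohort simulator so every stage is testable
without animal data:

- **simulate** — dual-hemisphere phase-vs-frequency sweeps (201 points,
  70–90 MHz, hourly for 24 h plus an anesthetized baseline) for an
  experimental group (n = 8, unilateral ischemic lesion, conductivity
  falls to a nadir at the CE→VE transition η ∈ [5, 7] h then recovers) and
  a control group (n = 5, small drift only).
- **process** — symmetric cancellation (lesion − healthy), time-difference
  offset against the baseline sweep, and the mean phase in the 83–87 MHz
  feature band:  MPFB = Σᵢ NFCPS(fᵢ) / n  over the 41 band points.
- **extract** — sliding-window features over the hourly MPFB series:
  α = MPFB(t₀), β = MPFB(t₁) − MPFB(t₀), γ = MPFB(t₂) − MPFB(t₁),
  δ = (MPFB(t₂) − MPFB(t₀))/2, labeled CE before the subject's transition
  hour and VE from it onward.
- **classify** — a soft-margin linear SVM
  (min ½‖ω‖² + C Σξᵢ s.t. yᵢ(ωᵀxᵢ + b) ≥ 1 − ξᵢ, CE = −1, VE = +1) with the
  full selection protocol: C grid 0.1…10.0 by tenfold cross-validation
  (lowest C at the best mean accuracy), shuffle states 1–5 chosen by median
  validation accuracy on a 6:2:2 split, final fit on train + validation.
- **evaluate** — accuracy per feature combination (α, β, αβ, αδ, αβγ),
  confusion/specificity (VE positive), ROC/AUC, learning curves with an
  over/underfitting diagnosis, and Welch/paired t-tests with t-based
  confidence intervals for the group comparison.

See `docs/methods.md` for the model, the generator's assumptions and the
design decisions.

## Worked example

```python
import numpy as np
from nfcps import (generate_cohort, process_cohort, window_features,
                   run_protocol, evaluate_model, group_mean_curve)
from nfcps.pipeline import transition_hours

cohort = generate_cohort(master_seed=7)           # 13 subjects, 2 hemispheres
series = process_cohort(cohort.sweeps, cohort.config.grid)
times, curve = group_mean_curve(series, "experimental")
print(f"group-mean nadir: {curve.min():.2f} deg at hour {int(times[np.argmin(curve)])}")

feats = window_features(series, transition_hours(cohort))   # 184 labeled windows
result = run_protocol(feats, "ab", fold_seed=7)             # full SVM protocol
report = evaluate_model(result)
print(f"C* = {result.c_star:.1f}, state* = {result.state_star}")
print(f"alpha-beta test accuracy: {report.test_accuracy_rounded:.2f} %")
print(f"specificity: {report.specificity:.3f}, AUC: {report.auc:.3f}")
```

prints

```
group-mean nadir: -37.71 deg at hour 6
C* = 0.4, state* = 2
alpha-beta test accuracy: 100.00 %
specificity: 1.000, AUC: 1.000
```

The group-mean MPFB trajectory falls to its nadir at hour 6 (the CE stage —
conductivity, and with it the cancelled phase, drops) and recovers afterwards
(the VE stage). On this synthetic cohort the tuned αβ model separates the
held-out test windows perfectly; on real recordings, with their shape
variability and artefacts, accuracies in the low-to-high 90s are the
realistic expectation.

The same pipeline is scriptable from the shell:

```bash
nfcps all --seed 7 --out runs/demo          # sweeps -> ... -> report.json
nfcps simulate --seed 7 --out runs/demo     # or stage by stage
nfcps process --sweeps runs/demo/sweeps.csv --out runs/demo/mpfb.csv
nfcps extract --mpfb runs/demo/mpfb.csv --subjects runs/demo/subjects.csv \
              --out runs/demo/features.csv
nfcps train --features runs/demo/features.csv --combination ab \
            --out runs/demo/model_ab.json
```

Externally supplied feature tables (comma- or tab-separated, Greek or Latin
column names) can be trained on directly with
`nfcps train --external --features ... --combination αβ`.

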