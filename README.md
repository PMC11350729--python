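# hisfkin

Kinetic-mechanism analysis for enzymes whose substrate binding is coupled to
an active-site conformational change — written around the transient and
steady-state kinetics of the HisF cyclase and its loop1 (beta1-alpha1 loop)
variants, but applicable to any one-substrate system with the same
experiment types. It is aimed at enzymologists who run stopped-flow,
spectrophotometric turnover and fluorescence-titration experiments and want
the complete analysis chain — from raw transients to a mechanistic verdict —
as reproducible, tested code.

## What it computes

**Binding mechanism from stopped-flow transients.** Transients are fitted
with one or two exponentials (`y = Amp1*exp(-kobs1*t) + Amp2*exp(-kobs2*t)
+ c`), the phase count chosen by AICc. The concentration dependence of
kobs discriminates mechanisms: one-step binding `E + S = ES` gives
`kobs = k1[S] + k-1` (linear), while binding followed by loop closure
(induced fit, `E + S = ES = E*S`) gives the saturating

    kobs = k-conf + kconf * [S] / (KD1 + [S]),      KD1 = k-1/k1

`classify_mechanism` fits both and reports `two-state`,
`conformational-step` or `ambiguous` (nonlinearity alone cannot separate
induced fit from conformational selection, and the package never claims to).

**Global fitting of multi-trace datasets.** `global_fit` fits shared rate
constants to whole datasets by direct numerical integration of a mass-action
scheme, with per-trace offsets and response coefficients solved exactly at
every iteration and syringe contents pre-equilibrated before simulated
mixing. The built-in `TERNARY` scheme describes both reaction products
binding independently (`k2/k-2` for ImGP, `k3/k-3` for AICAR) with loop
closure stabilizing the ternary complex (`k4/k-4`). Residual-resampling
bootstrap gives confidence intervals; structurally unidentifiable
parameters (e.g. binding steps that complete within the ~2 ms instrument
dead time) are flagged, not printed as precise numbers.

**Steady-state vs single turnover.** Progress curves at 300 nm are reduced
to velocities (`v = slope / (1 cm x 0.005637 uM^-1 cm^-1)`), burst artifacts
excluded, and fitted to `v = kcat*E*[S]/(KM+[S])`; `kcat/KM` is derived with
Gaussian error propagation. Single-turnover decays (enzyme excess) isolate
the chemical step; comparing their rate with kcat locates the rate-limiting
step.

**Equilibrium titrations.** Hyperbolic (or tight-binding quadratic)
isotherms with dilution/background corrections, plus model-based apparent-KD
predictions: at saturating co-ligand the apparent KD of the second product
drops to `KD/(1+K4)` — the quantitative form of ternary-complex synergy.

**Synthetic data.** Every experiment type can be generated with known
ground truth (scheme, rate constants, responses, noise, seed), at the
reference designs, so each fitter is validated by parameter recovery.

## Worked example

```python
import numpy as np
from hisfkin import classify_mechanism, fit_michaelis_menten, propagate_kcat_over_km
from hisfkin.synthetic import gen_secondary_plot

# mechanism from a kobs-vs-[S] secondary plot (5% noise, 0.5-40 uM design)
pts, truth = gen_secondary_plot("INDUCED_FIT", noise_frac=0.05, seed=1)
v = classify_mechanism(pts)
print(v.classification, round(v.delta_aicc, 1))
print({k: round(x, 2) for k, x in v.selected.params.items()})

# steady-state table arithmetic: wild-type kcat = 2.4 /s, KM = 4.5 uM
val, se = propagate_kcat_over_km(2.4, 0.2, 4.5, 0.5)
print(f"kcat/KM = ({val:.3g} +/- {se:.2g}) /M/s")
```

prints

```
conformational-step 13.1
{'KD1': 14.22, 'kconf': 43.84, 'k-conf': 1.42}
kcat/KM = (5.33e+05 +/- 7.4e+04) /M/s
```

i.e. the noisy induced-fit series is recognized as conformational-step
binding with KD1/kconf/k-conf recovered near their true values
(10 uM, 40 s^-1, 2 s^-1), and the specificity constant reproduces the
printed 5.3 +/- 0.7 x 10^5 M^-1 s^-1.

`docs/methods.md` documents the models, numerical choices and the
synthetic-data assumptions. A command-line interface (`hisfkin gen /
fit-exp / fit-secondary / fit-global / fit-mm / fit-st / fit-titration /
classify / report`) wraps the same functions for shell use.

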