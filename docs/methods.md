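# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `hisfkin`, in the spirit of the model documentation that
packages like msprime or statsmodels ship: what is computed, under which
assumptions, and what the validation does and does not demonstrate.

## Kinetic schemes and units

All concentrations are micromolar and time is in seconds; bimolecular rate
constants therefore carry uM^-1 s^-1 (multiply by 1e6 for M^-1 s^-1, the
unit used in reports). Keeping the internal unit near 1 avoids the poor
conditioning that M-based units (1e-7 .. 1e-3) produce in least-squares
Jacobians.

A scheme is a list of species, each annotated with conserved-moiety counts
(enzyme E; substrate S; the two products ImGP = I and AICAR = A), and a list
of reversible elementary reactions referencing named rate constants. Moiety
balance is validated at construction, which makes conservation of each total
an exact structural property of the equations rather than something the
integrator must be trusted with. Built-ins:

* `ONE_STEP` - E + S = ES (k1, k-1). Pseudo-first-order (PFO) relaxation
  rate kobs = k1[S] + k-1, linear in [S].
* `INDUCED_FIT` - E + S = ES = E*S: binding first, then the active-site
  loop closes (kconf, k-conf). The PFO system has two relaxations; in the
  rapid-binding limit the slow one follows
  kobs = k-conf + kconf [S]/(KD1 + [S]), with KD1 = k-1/k1.
* `CONF_SELECTION` - the conformational change precedes binding. Included
  because kobs([S]) curvature alone cannot distinguish it from induced fit;
  the classifier deliberately reports only "conformational-step".
* `TERNARY` - product binding with loop closure over the ternary complex:
  E+I = EI and EA+I = EIA share k2/k-2, E+A = EA and EI+A = EIA share
  k3/k-3, and EIA = EIA* is the loop-closing step (k4/k-4, K4 = k4/k-4).
  Sharing the binding constants is the simplest model in which the two
  product sites are independent until the loop closes, and it makes the
  thermodynamic cycle exactly consistent. `tied=False` introduces separate
  constants for binding to the binary complexes; note that arbitrary untied
  values can violate detailed balance around the cycle, which
  `equilibrium_state` detects and rejects.

The closed ternary complex is assumed not to exchange ligands directly
(no EIA* + ligand reactions): ligands can only leave after the loop reopens.

## Integration and equilibria

`integrate_scheme` uses `scipy.integrate.solve_ivp` (LSODA by default, BDF
for stiff ligand-excess problems) with an analytic mass-action Jacobian and
defaults rtol = 1e-8, atol = 1e-12 uM. Conserved totals stay constant to
better than 1e-8 relative over the time spans used here (property-tested).
Selected species can be *clamped* (held constant), which turns the one-step
scheme into the textbook PFO ODE; that mode is what is compared against the
closed-form solution to 1e-6 of amplitude. The full ODE can only match the
closed form to the ligand-depletion scale E0/S0, and a separate test checks
exactly that.

`equilibrium_state` solves the mass-action equilibrium algebraically:
species concentrations are written as exp(sum_m n_sm lam_m - G_s), with
formation potentials G obtained from the reaction equilibrium constants
(least squares with one gauge reference per moiety; a residual flags
detailed-balance violations), and the moiety potentials lam solved by a
damped fixed-point iteration followed by Newton (scipy `root`). Convergence
is judged on the conservation residual (<= 1e-8 relative). A forward rate
of exactly zero marks an irreversible direction: as a reactant-side zero it
simply empties the product complex; a zero *reverse* rate means no finite
equilibrium and raises. Single-moiety species can be clamped as a bath,
which is how apparent-KD predictions scan free ligand at fixed co-ligand.

In ligand excess (ratio >= 10, the PFO threshold used throughout), the
enzyme-state subsystem is linear and is propagated exactly by
eigendecomposition of the fixed-free-ligand rate matrix. States unreachable
from the initial condition (e.g. complexes of an absent ligand) are pruned
first - their inclusion makes the eigenproblem defective and numerically
poisons the solution. Below 10x excess the full ODE is used automatically.

## Dead time and the "obscured" flag

Simulated observation starts at the instrument dead time (default 2.0 ms);
the time origin is not shifted. A trace is flagged dead-time-obscured when
>= 86% of its total signal change (1 - e^-2, i.e. a 1000 s^-1 relaxation
over 2 ms) is lost before the first recorded point; the threshold is a
configurable operationalization of "association complete within the dead
time". The corollary bound used in the analyses: a transient at 1 mM ligand
whose kobs must exceed 1000 s^-1 to be invisible implies an association
rate constant >= 1e6 M^-1 s^-1.

## Transient fitting and mechanism classification

Exponential fits optimize the rates in log space over a multistart grid
spanning the observable window, with amplitudes and offset solved exactly
by linear least squares at every step (variable projection), then polish
all parameters jointly for the covariance. Amplitudes are referenced to the
first recorded point. Phase-number selection uses AICc (with the n log(SSR/n)
Gaussian form and small-sample correction); a biphasic fit is discarded as
degenerate when its rates differ by < 10% or the minor amplitude is below 3x
the residual noise. Secondary plots are fitted weighted (1/se^2) when SEs
are given. Mechanism classification compares the linear and hyperbolic
models by AICc with an ambiguity band |dAICc| < 2; with fewer than five
concentrations the hyperbola is not fittable and the verdict defaults to
two-state. The classifier never claims to separate induced fit from
conformational selection.

## Global fitting

The global fitter follows the structure of numerical-integration global
analysis programs: shared rate constants are optimized nonlinearly (log10
space, bound-constrained trust-region least squares, 5 seeded log-uniform
multistarts by default), while all linear observable parameters are solved
exactly per iteration. Each trace is described by its two syringe
compositions; syringes are pre-equilibrated under the candidate parameters,
mixed 1:1 (or per the stated fractions), and the relaxation to the new
equilibrium is simulated.

Observable model: per-trace offsets plus one response coefficient per
complex species. By default the responses are **shared across the dataset**
(one fluorophore, one instrument gain); a per-trace-response option exists.
This choice matters for identifiability: with fully per-trace responses each
trace contributes only a relaxation rate and an amplitude of arbitrary
gain, and the loop-closure equilibrium K4 trades off against the response
ratio of EIA and EIA*, leaving k-4 nearly unconstrained. AICc counts the
shared rate constants plus every linear coefficient.

Standard errors come from the full Jacobian (finite differences over the
log-rates, analytic blocks for the linear parameters). Two flags mark weak
parameters: SE/value > 10, and a large component in the near-null space of
the Jacobian (the pseudo-inverse otherwise reports deceptively small SEs
for structurally unidentifiable directions). For the printed ternary design
the product-binding steps complete within the dead time, so k2, k3, k-2,
k-3 are identified only through their ratios and second-order corrections -
their fitted magnitudes should not be taken at face value, which is exactly
the behavior the flags communicate.

Error analysis is a residual-resampling bootstrap (within-trace resampling,
refit from the point estimate, percentile intervals, seeded). A 40-replicate
calibration at the 1%-noise desk scale gives ~91-95% observed coverage for
nominal 95% intervals on the loop-closure rates.

## Steady-state and single-turnover analysis

Velocities come from A300 slopes via v = |slope|/(path x 0.005637 uM^-1
cm^-1), with d-eps300(substrate - product) = 5637 M^-1 cm^-1. The
steady-state window of a progress curve starts where a fitted
burst-exponential (the stopped-flow mixing artifact) has decayed below 5%
of its amplitude and ends at 20% substrate depletion; the fitted burst is
subtracted before the window's linear fit so its tail cannot bias
small-amplitude curves, the burst rate is constrained above 20/span so slow
depletion cannot masquerade as the artifact, and the depletion threshold is
evaluated on a lightly smoothed signal so point noise cannot trigger it.
Michaelis-Menten fits v = kcat E [S]/(KM+[S]) in log space with optional
SEM weights; kcat/KM is always recomputed from the fitted pair with
quadrature (Gaussian) error propagation, never fitted independently. An
assay with no detectable turnover yields the bound kcat < v_detect/E_tot.

Single-turnover curves (enzyme >= 2x substrate) are fitted with one
exponential. The rate-limiting diagnosis compares mean single-turnover kobs
with kcat: a ratio within [1/3, 3] ("same order of magnitude") means the
chemical step limits turnover; above 3, a post-chemistry step (product
release / loop opening) does; a ratio below 1/3 is not physically expected
(kcat cannot exceed the chemistry rate) and is reported inconclusive.

## Titrations

Fluorescence titrations are corrected once each for dilution
(x (V0+Vadd)/V0) and a linear intrinsic ligand background, then fitted to
dF = dFmax [L]/(KD_app + [L]) + c. When the receptor concentration exceeds
KD/5 the free-ligand approximation biases KD and the tight-binding
quadratic replaces it automatically (the hyperbola remains the default
presentation for parity with common practice; the switch is recorded).
Model-predicted apparent KDs scan the scheme equilibrium over clamped free
ligand and locate half-saturation of total bound enzyme; at saturating
co-ligand this reduces analytically to KD/(1+K4), the quantitative form of
the observed product-binding synergy. A synergy report is "synergistic"
when KD(binary)/KD(+co-ligand) exceeds 1 beyond its propagated SE.

## Synthetic data: what it emulates and what it does not

Generators reproduce the reference experimental designs: PrFAR-binding transients (0.5-40 uM
ligand over 0.1 uM enzyme, dead time 2 ms), the 16-trace product-binding
set (free enzyme vs one or both products at 100-250 uM ImGP / 250-1000 uM
AICAR, and each preformed binary complex vs the second product),
multiple-turnover progress curves (0.1 uM enzyme, 1-40 uM substrate, with
an additive mixing-artifact burst of 0.05 A at 30 s^-1 that also appears in
ammonia-free controls), single-turnover decays (20 uM enzyme over 2.5-10 uM
substrate) and equilibrium titrations computed from the scheme equilibrium
at total-ligand concentrations (receptor depletion is therefore present in
the data).

Default true parameters: induced-fit binding k1 = 10 uM^-1 s^-1 (1e7
M^-1 s^-1), KD1 = 10 uM, kconf = 40 s^-1, k-conf = 2 s^-1; one-step
variant k1 = 0.05 uM^-1 s^-1, k-1 = 4 s^-1; ternary k2 = 100, k-2 = 5000,
k3 = 100, k-3 = 20000, k4 = 50, k-4 = 12 (KD(ImGP) = 50 uM, KD(AICAR) =
200 uM, loop closure ~50 s^-1 and 4:1 toward closed); turnover cycle
kon = 10 uM^-1 s^-1, koff = 20 s^-1, kchem = 2.64 s^-1, krel = 26.4 s^-1
(kcat = 2.4 s^-1, chemistry 10x slower than all other steps).

Noise is additive i.i.d. Gaussian on the signal; averaging n shots scales
the per-shot sigma by 1/sqrt(n) (the instrument protocol averages >= 5).
For the ternary dataset the noise SD is a single instrument-level value
(a fraction of the median trace amplitude) shared by all 16 traces,
including the flat binary-only ones. Ternary traces default to 1000
log-spaced points over 0.15 s, the density a stopped-flow record actually
has; this matters because the identifiability of k-4 degrades roughly as
1/sqrt(points) (Fisher SE ~6% at 1000 points vs ~12% at 200). The
bootstrap-coverage simulation uses the 200-point desk scale with 20
replicates x 100 bootstrap draws to stay within a practical runtime.

Not emulated: photon-shot noise, lamp drift, flow artifacts beyond the
single burst term, pipetting error in the titrations, and the lower
signal-to-noise of weakly fluorescent variants. Passing recovery tests on
these data therefore demonstrates correctness of the estimators under the
stated noise model, not robustness to every instrument pathology.

## Known limitations

* kobs-vs-[S] curvature identifies *a* conformational step, not its order
  relative to binding; distinguishing induced fit from conformational
  selection needs enzyme-excess vs ligand-excess asymmetry experiments that
  are out of scope.
* The ternary global fit cannot resolve the absolute magnitudes of binding
  steps that complete within the dead time; they are reported with
  unidentifiability flags rather than suppressed.
* The equilibrium solver requires a detailed-balanced network; untied
  ternary binding constants that break cycle consistency are rejected
  rather than silently relaxed to a steady state.
* AICc model discrimination assumes Gaussian i.i.d. residuals; correlated
  instrument noise would overstate discrimination confidence.
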