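# Methods

## Model

The package models the LuxR-dependent promoter pR as a two-input promoter
logic function (PLF) at clamped cell density ρ (OD600). Steady-state AHL is
proportional to density times the LuxI level, `A = c·ρ·I`; AHL binds LuxR
in rapid equilibrium with Hill cooperativity `m`, giving active LuxR
`R* = R·A^m/(K_A^m + A^m)`; active LuxR activates pR with Hill
cooperativity `n` over a basal floor:

    f = (ε·K_R^n + R*^n) / (K_R^n + R*^n).

The maximal transcription rate is normalized to 1, so `f ∈ [ε, 1]`. This
composition is one of several algebraic forms consistent with the two named
cooperativities and the basal/saturating limits; the parameter-file schema
and every consumer of the PLF go through `plf_eval`, so a substituted
functional form can sit behind the same interface.

Assumptions worth stating explicitly: AHL equilibrates fast relative to
growth (so A depends only on the instantaneous ρ and I); LuxR folding,
dimerization and AHL export are not modelled mechanistically — they are
absorbed into the phenomenological Hill constants; all protein levels are
expressed in fluorescence units, with production scales λ (level at full pR
activity) and response rates γ (1/time) per protein.

Feedback circuits obey `dX/dt = γ(λ·f(...) − X)` with the appropriate
argument of `f` closed over the state: LuxR-feedback `f(Ī, R)`,
LuxI-feedback `f(I, R̄)`, dual-positive both. Because density enters only
through the product `c·ρ·I`, rescaling ρ by k is identical to stretching
the LuxI axis by k (`density_rescale`), and scaling `c` by k shifts every
fold density by exactly 1/k — both used as exact invariants in the tests.

## Parameters and defaults

The study's real fluorescence scales are not tabulated, so defaults are in
arbitrary units, chosen once to reproduce the qualitative design conditions
and then frozen:

| parameter | default | meaning |
|---|---|---|
| ε | 0.008 | basal pR activity (fraction of max) |
| K_A | 100 | AHL half-saturation for AHL–LuxR binding (a.u.) |
| K_R | 40 | active-LuxR half-saturation for pR (a.u.) |
| m | 2 | AHL–LuxR Hill coefficient (held fixed when fitting) |
| n | 1.45 | LuxR–DNA Hill coefficient |
| c | 20 | AHL per (OD600 × LuxI a.u.); protocol-specific |
| ρ | 0.1 | nominal sender–receiver measurement density (OD600) |
| λ_R, λ_I | 60, 600 | feedback production scales (a.u.) |
| ρ_T | 0.05 / 0.1 | terminal density: autonomous / sender–receiver |

Induction curves (Hill form `V0 + Vmax·x^h/(K^h + x^h)`): aTc→LuxI::CFP
with (10, 1000, 10 ng/ml, 2); IPTG→LuxR::YFP with (10, 600, 60 µM, 1.5).
Default inducer grids are 6 aTc levels (0–50 ng/ml) × 7 IPTG levels
(0–1000 µM), i.e. 42 combinations.

Two defaults are deliberate design points rather than arbitrary numbers.
First, λ_R/K_R = 1.5 lies below the analytic bistability window of the
scalar LuxR loop — for the Hill floor/ceiling above, tangency requires
`w² + w(1+ε−n(1−ε)) + ε = 0` to have real roots, giving a window
θ·λ_R/K_R ∈ (1.82, 2.45) at n = 1.45, ε = 0.008 — so the LuxR-feedback
loop is monostable for every regulator level and density. Second,
λ_I = 600 puts the LuxI-feedback loop inside that effective window at
intermediate regulator levels, producing the B−/B±/B+ progression across
the seven IPTG-induced LuxR levels at ρ_T = 0.05. The noise-free default
grid spans a factor ≈ 107 (2.03 orders of magnitude) in output.

## Synthetic data

`generate_plf_grid` emulates replicated single-cell imaging measurements:
each measured channel (LuxI::CFP, LuxR::YFP, output CFP) is multiplied by
an independent unit-mean log-normal factor with coefficient of variation
`cv` (default 0.15, replicates default 3), reflecting the approximately
log-normal single-cell fluorescence distributions summarized by geometric
means. `generate_equivalence_table` adds channel backgrounds and noise on
the output channel only (so the affine fit's regressor is exogenous);
`generate_feedback_dataset` integrates the feedback ODE from basal (OFF) or
saturated (ON) initial conditions to steady state and reports noisy
terminal levels, flagging non-convergent integrations.

What the generator does **not** emulate: cell-to-cell variability structure
(noise factors are i.i.d. across replicates, not across cells), plasmid
loss, growth-phase effects, instrument cross-calibration, or any spatial
AHL gradient. Passing tests therefore demonstrate correctness of the
analysis chain under the stated noise model, not robustness to every
artifact of real imaging data.

## Fitting

Residuals are computed on log-transformed replicate geometric means
(measurement noise is multiplicative), weighted by the replicate standard
errors of the log-output (uniform weights when those vanish). `m` is never
fitted freely: an unconstrained fit drifts to ever larger `m` as chi-square
decreases monotonically, so the protocol is a sweep over fixed `m` with
m = 2 the default. A single-density grid cannot separate K_A from c; the
fit estimates the identifiable combination κ = K_A/(c·ρ) — the LuxI level
at half-saturating AHL — and `c` can be rescaled independently afterward
for cross-protocol prediction. Five log-spaced multi-starts of κ guard
against local minima (lowest chi-square kept, ties to the first index).
The five free parameters are (ε, κ, K_R, n, amplitude).

Goodness of fit is a parametric bootstrap: synthetic grids from the fitted
model with per-channel replicate-level noise estimated from the data,
refit single-start, Q = fraction of synthetic chi-squares above the
observed one. Resampling the *input* channels matters — the fit regresses
on noisy replicate-averaged inputs, and omitting that error source makes
the observed chi-square look systematically worse than the synthetic ones.

## Model-independent prediction

IOCs are background-subtracted, replicate-averaged slices of the grid
(vertical cuts at fixed aTc for LuxR-feedback, horizontal cuts at fixed
IPTG for LuxI-feedback). Interpolation is power-law (linear in log-log),
with conservative flat extrapolation outside the measured range; values at
or below the background floor are clamped to `1e-6` of the channel maximum
before the log transform. In log-log coordinates the line of equivalence is
also linear (`Y = u + log s`), so every intersection is solved exactly
segment by segment — no iterative root-finding. Stability follows the 1-D
alternation convention (IOC crossing the line from above = stable),
cross-checked against ODE integration; crossings closer than 1e-9 log
units are merged as tangencies with stability `unknown`. Monte-Carlo
uncertainty propagation perturbs node log-outputs with Gaussian noise at
the replicate standard errors and re-runs the analysis per trial.

When predictions at measured regulator levels must be interpolated to an
unmeasured level, stable branches are interpolated branch-wise (lower with
lower, upper with upper); if the branch count changes between flanking
levels only the persisting outer branches are interpolated and a warning
is issued — the correct treatment inside a fold is genuinely ambiguous and
is flagged rather than guessed.

## Density-dependent responses

Steady states at each density are roots of `λ·f(x) − x`, bracketed on a
512-point log-spaced scan over `[λε/10, 10λ]` (all roots lie in `[λε, λ]`)
and refined by Brent's method to 1e-10 relative. The density grid is 400
log-spaced points over `[1e-4, 1]` OD600 (carrying capacity ≈ 1); fold
densities are localized by bisection on the root count to 1e-3 relative.
The generic 1-or-3 root structure is asserted, not patched: any other
count flags the curve as degenerate. Classification against ρ_T:
no bistable interval → M; ρ_T above the upper fold → B+; inside → B±;
below → B−. Bifurcation maps classify each (n, regulator) cell on a
coarser 200-point density grid, which resolves class boundaries to cell
resolution. `dynamic_response` co-integrates logistic growth with the
feedback ODE and overlays the history-connected quasi-static branch,
exposing the lag and critical slowing near thresholds.

## Oscillator

The dual positive/negative-feedback system keeps LuxR in positive feedback
(λ_R = 104, i.e. λ_R/K_R = 2.6, above the bistability window) and represses
LuxI production through LacI expressed from pR: with LacI at quasi-steady
state `L = λ_L·f`, LuxI obeys `dI/dt = γ_I(β_I/(1+(L/K_L)^{h_L}) − I)`.
Density is clamped at the chemostat operating point OD600 = 0.185 and
enters only through `A = c·ρ·I`. Defaults: β_I = 150, λ_L = 100, K_L = 10,
h_L = 2 (a LacI-cooperativity convention, not a measured value), γ_R = 1;
γ_I is the free dynamical parameter. Slow LuxI (small γ_I) drags the
bistable LuxR subsystem around its hysteresis loop (relaxation
oscillation); fast LuxI slaves to LacI and the fixed point is stable. The
fixed point's location is rate-independent, so the Hopf boundary is found
by bisection on the leading eigenvalue real part (central-difference
Jacobian, relative step 1e-6, boundary to 1e-4 relative); with the
defaults it sits at γ_I ≈ 0.097. An explicit three-variable LacI variant
is provided because the exact quasi-steady-state reduction is a modelling
choice; with fast LacI it reproduces the two-variable behavior. Time is in
arbitrary units throughout — the experimental period is not a target.
Oscillation detection: peaks on the LuxR trace after discarding the first
half of the run; a period is reported only when the last three inter-peak
intervals agree within 5%.

## Numerical choices and edge cases

- ODE integration: LSODA with rtol 1e-8..1e-9; settling declared when the
  relative rate falls below 1e-8 (non-convergence is flagged per record).
- Equivalence-line fits weight residuals by 1/x² (constant relative
  error); weights depend only on the regressor, so the slope estimate is
  unbiased under multiplicative output noise. The intercept split into
  channel backgrounds is not identifiable from the pairs alone; an
  independent zero-inducer x reading resolves it when supplied, else the
  x background is taken as zero (documented, configurable).
- Saturated Hill powers (`R*^n` overflowing) return the exact limit 1.
- Zero replicate scatter (noise-free grids) falls back to uniform fit
  weights.
- Fits, Monte-Carlo ensembles and synthetic datasets are bit-reproducible
  given their seeds; every stochastic CLI artifact records its seed and a
  configuration digest.

## Problem sizes

Defaults used by the test suite and the acceptance script: 42-combination
grids with 2–3 replicates; 100-seed noisy-recovery ensembles; 200-trial
goodness-of-fit bootstraps; 1000-trial intersection Monte Carlo; 200
randomized instances per oracle-equivalence check; 12-point γ_I sweeps with
simulations of 3000 time units. These sizes keep every stage deterministic
and fast on a single CPU while leaving the statistical conclusions stable
across seeds.

## Known limitations

- The PLF's algebraic form is phenomenological; data generated by a
  promoter with, e.g., additive basal activity entering after LuxR
  saturation would bias ε and n estimates.
- Stability labels from the intersection analysis rely on the 1-D
  monotone-response convention; they are not a substitute for the full
  monotone-systems machinery, and the package cross-checks them by ODE
  integration rather than proving them.
- κ and c are only identifiable jointly from single-density data;
  cross-protocol predictions inherit the uncertainty of the rescaled c.
- The bifurcation-map boundaries are resolved to cell resolution only;
  classes within one cell of a boundary can flip with the density grid.
- Near a fold, ON/OFF-history integration can disagree with the static
  classification for densities within the numerical tolerance of the fold
  (slow transients); concordance checks therefore exclude a ±2% band.
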