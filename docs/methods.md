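# Methods

## The model

The observable in a multiplexed protease activity assay is the fraction
of each peptide substrate that remains uncleaved, `S ∈ [0, 1]`, starting
at `S(0) = 1`. A single protease at concentration `α` cleaves one
substrate according to a saturating Michaelis–Menten rate law

    dS/dt = −α · V · (S − β)^n / ((S − β)^n + K^n)

with four kinetic parameters per protease–substrate pair:

| parameter | meaning | units | default sampling range |
|---|---|---|---|
| `V` | maximal cleavage rate | fraction · min⁻¹ | uniform [0.005, 0.05] |
| `K` | half-saturation level | fraction-uncleaved | uniform [0.1, 0.9] |
| `n` | reaction order (positive real) | — | uniform [0.5, 3] |
| `β` | saturation floor | fraction-uncleaved | uniform [0, 0.4] |

`β` captures the empirical observation that cleavage stalls at a
pair-specific nonzero level of intact substrate: the rate vanishes
exactly at `S = β`. For a mixture of `N` proteases acting on substrate
`i`, the per-protease rates add (no synergistic or antagonistic
interactions), each term carrying its own `(V_ij, K_ij, n_ij, β_ij)`.
A mixture term is set to zero whenever `S_i ≤ β_ij`: each protease
deactivates at its own floor, which keeps every term's sign physical
and prevents substrate regeneration. Rows of a mixture trajectory
therefore stay at or above the smallest applicable floor.

The `(S − β)` form is used in both the numerator and the denominator of
every rate expression, in the single-protease and the mixture law alike,
so that the simulated forward model and the fitted estimator are the
same function.

## Numerical integration

Trajectories are solved with an embedded Dormand–Prince 5(4) adaptive
Runge–Kutta method, JIT-compiled (numba), at `rtol = 1e-8`,
`atol = 1e-10`, with states clipped to `[0, 1]` after each accepted
step. An explicit method was chosen deliberately: at the parameter
ranges above the system is non-stiff (rates ≤ 0.05 min⁻¹ over a 400 min
window), and the estimation loops nest tens of thousands of trajectory
solves, so per-solve cost — microseconds here — dominates the design.
The solver is audited in the test suite against an independent
fixed-step explicit Euler reference (step 1e-4 min), agreeing to
~1e-6 absolute, well inside the 1e-4 audit tolerance. For `n < 1` the
rate is non-Lipschitz at the floor; a minimum step-size guard accepts
the step there, where rate magnitudes are negligible.

## Study design emulated by the generator

The generator emulates a mass-barcoded substrate-library assay:
M ≈ 7 substrates, fraction-uncleaved traces starting at 1, decaying
monotonically toward pair-specific floors over a 0–400 min window.
Two time grids play different roles:

* **Calibration grid** (`calibration_times`, default
  {10, 30, 60, 120, 240, 400} min): single-protease–single-substrate
  assays at unit concentration, the data from which kinetic parameters
  are fitted. Six points across the window mirror the sampling of real
  recombinant-protease traces and are necessary for the four-parameter
  rate law to be identified — two points are not enough, and kinetics
  mis-fitted from under-sampled calibration transfer systematic bias
  into every downstream mixture estimate. The early 10-min point pins
  the transient of the fastest pairs.
* **Mixture grid** (`times`, default {0, 60} min, Q = 2): the read-out
  of library-versus-mixture assays. The first point is the known
  baseline (all substrates intact); the 60-min point is the informative
  one. Each substrate therefore contributes one effective equation per
  mixture, so a library of M substrates can resolve at most M proteases
  — the identifiability threshold that the substrate-selection
  experiments probe. Because `S(t; α) = S(αt; 1)`, a 60-min read-out at
  concentrations in [0.2, 2] probes effective single-protease times of
  12–120 min, inside the calibrated range; a later read-out would
  extrapolate beyond it at high concentrations.

Mixing coefficients are drawn uniformly from [0.2, 2] by default.
Observation noise is additive Gaussian on fraction-uncleaved, clipped
to [0, 1], default `noise_sd = 0`: the default experiments are
deterministic given the random draws, and variability across a
condition comes from repeated parameter/coefficient draws.

What the generator does **not** emulate: mass-spectrometry measurement
physics (barcode collisions, ionisation efficiency), particle-handling
artifacts, cross-substrate competition for enzyme, or temperature/pH
dependence. Passing tests on synthetic panels therefore demonstrate the
estimator and design logic under the model's own assumptions, not
robustness to real-assay systematics.

## Estimation

Both fitting problems are bound-constrained nonlinear least squares
solved with a trust-region-reflective method, with every residual
evaluation re-integrating the rate law.

* **Kinetics** `(V, K, n, β)` per pair: objective is the sum of squared
  differences between observed and predicted fraction-uncleaved at the
  calibration times. Bounds: `V ≤ max(10 × steepest observed rate,
  range top)`, `K ≤ 10`, `n ∈ [0.05, 5]`, `β ∈ [0, 1)`. The objective
  is nonconvex in `(K, n)`, so 5 seeded random restarts are drawn from
  the generator's parameter ranges and the best residual kept (first
  encountered wins ties).
* **Mixing coefficients** `α ≥ 0`: objective is the double sum over
  substrates and times of squared residuals between the mixture data
  and the re-integrated mixture model. Starts: the all-ones vector,
  then 1 + N(0, 0.5) perturbations clipped into bounds; `α ≤ 100`.

Gradients are finite differences with a relative step of `1e-4`. This
step size matters: the integrator's error floor is ~1e-8, and a
square-root-of-epsilon step (the library default) sits at that floor,
producing gradients dominated by integration noise and stalling the
optimizer far from the optimum. With the 1e-4 step, noiseless
recovery of both kinetics and coefficients is exact to optimizer
tolerance. Integration tolerances (1e-8/1e-10) sit below the optimizer
tolerances (1e-8) throughout.

Family-level kinetics pool the member proteases' calibration assays as
replicates of one representative protease and minimise the pooled sum
of squares with a single parameter set.

## Experiment drivers

**Panel evaluation** runs the full two-step pipeline the way a real
study would: simulate calibration assays, fit kinetics *from them*
(true kinetics are never available in practice), simulate `P` mixtures
with random coefficients, estimate the coefficients with the fitted
kinetics, and score with RMSE — per protease
`R_j = sqrt(mean_k (α̂_jk − α_jk)²)` over `P` repetitions, overall the
mean of the `R_j`. Kinetics are fitted once per condition and
re-restricted to substrate subsets (fits are per-cell, so no re-fit is
needed).

**Greedy substrate reduction** starts from the full library and
repeatedly removes the substrate whose removal yields the lowest RMSE,
down to two substrates. Within one round, all leave-one-out candidates
are evaluated on a shared draw of true coefficients (common random
numbers), so comparisons are paired; ties go to the lowest substrate
index.

**λ-difficulty sweep**: a correlated protease is constructed as a
convex combination `p3 = λ·p1 + (1−λ)·p2` of two independently drawn
parameter columns, and mixtures of `p1` and `p3` are deconvolved for a
grid of λ and library sizes. The sweep experiments run at
`noise_sd = 0.01`: in the exact noiseless limit the two-step pipeline
recovers coefficients to numerical precision at every λ < 1, so the
difficulty ordering needs a realistic error source for the
ill-conditioning at high λ to amplify. 0.01 fraction units is a modest
level for quantitative MS read-outs.

**Families**: each protease is represented by the concatenation of all
its calibration observations (substrate-major, time-ascending, no
rescaling — values are already on [0, 1]) and clustered by
agglomerative single-linkage with Euclidean distance; flat families are
the connected components below a cutoff (default 0.6). Simulated family
panels build 3 members per family as `p1`, `λp1+(1−λ)p2`,
`λp1+(1−λ)p3` from independent bases, giving the exact distance
identity `d(p1, p4) = (1−λ)·d(p1, p2)` in concatenated parameter space.
Family deconvolution experiments draw per-protease concentrations from
[0.2, 2] scaled by `3/N`: a 9-protease cocktail at the unscaled range
would carry three times the total cleavage activity of the 3-protease
experiments, saturating substrates past their floors by the read-out
time and leaving the family coefficients in a flat, runaway direction
of the objective. Real multi-enzyme panels are assayed at comparable
total load for the same reason.

## Problem sizes

Simulation experiments run at `P = 50` repeated mixtures per condition
(the package default for `SimConfig.P` is 200; experiment drivers and
the reproduction script pass 50 explicitly), 7 substrates, and 3–9
proteases. Aggregate comparisons (difficulty ordering, family quality)
pool three independent panel draws, since a single random panel spans a
broad quality range.

## Known limitations

* With one informative mixture time point, coefficient identifiability
  is limited to `N ≤ M` even for independent proteases; richer mixture
  time courses would relax this but change the design question.
* Family-level estimates carry an irreducible representative-model
  error that grows as within-family correlation (λ) falls; at λ ≲ 0.6
  the "replicates of one protease" approximation visibly degrades.
* The greedy search is not guaranteed optimal among substrate subsets;
  it matches the intended experimental protocol, not an exhaustive
  design search.
* Fitted kinetic parameters from realistic calibration grids are
  well-identified as a *curve* but individual parameters (especially
  `K` vs `n`) remain correlated; downstream analyses only ever use the
  fitted curves.
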