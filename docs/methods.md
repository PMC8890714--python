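# Methods

## Model and assumptions

IL2 mass balance in two well-mixed, constant-volume compartments — the IP
fluid (`V1`) and systemic blood (`V2`) — with production only from the
implanted capsules, exchange across the peritoneal wall as a single
first-order rate, and elimination only by renal clearance:

```
dN/dt  = -λ N                                    capsules
dC1/dt = k_prod N / V1 - k_trans (C1 - C2)       IP, pg/ml/day
dC2/dt = k_trans (V1/V2)(C1 - C2) - k_clr C2/V2  blood, pg/ml/day
```

Assumptions worth stating explicitly:

- **Constant volumes.** The ~50 ml carrier bolus used at administration is
  neglected: isosmotic fluid is absorbed from the peritoneum at roughly
  30 ml/h, so the bolus is gone within two hours of a 30-day simulation.
  A time-varying `V1` is out of scope.
- **Exponential capsule decay.** Pericapsular fibrotic overgrowth is
  summarized by a single rate `λ`; no lag phase, no heterogeneity between
  capsules.
- **No endogenous IL2, no binding/consumption by immune cells.** The model
  is purely pharmacokinetic; pharmacodynamics enter only as fixed
  concentration thresholds (effector activation, systemic toxicity)
  supplied by configuration — the package deliberately ships no default
  thresholds because they are literature judgments, not model outputs.
- **Linearity.** Everything is first-order, so trajectories scale exactly
  with dose (`N0`) and with `k_prod·N0`; multi-dose responses superpose.

## Numerics

- The augmented state `(N, C1, C2)` follows `x' = A x` with constant `A`,
  so the exact solution is `x(t) = e^{At} x0`. `closed_form_solution`
  evaluates it by eigendecomposition, falling back to scaling-and-squaring
  `expm` when eigenvalues come within 1e-9 relative distance (e.g. `λ`
  colliding with an elimination eigenvalue).
- `simulate` integrates the same system with a stiff implicit solver (BDF,
  rtol 1e-8, atol 1e-10 pg/ml, analytic Jacobian). Stiffness is real: the
  printed mouse clearance bounds put the blood eigenvalue near 1e6/day.
  The two routes are mutually validating; tests hold them to 1e-6
  relative error over randomized parameter draws.
- Model predictions inside the fitting objective use the exact linear
  propagator by default (`predictor="analytic"`): for a linear model this
  is not an approximation, and it makes a 60-particle swarm over hundreds
  of iterations cheap. `predictor="ode"` runs the stiff integrator
  instead, and the tests confirm both give the same objective.
- Peaks and troughs reported from a grid are refined by local quadratic
  interpolation, with two guards: refinement is skipped when neighboring
  abscissae nearly coincide (a dose event adjacent to a grid point makes
  the quadratic ill-conditioned) and at dose events themselves, where C1
  is continuous but kinked and the event grid point is already the exact
  extremum. Threshold crossings for the therapeutic window are located by
  linear interpolation between grid points.
- Failed or non-finite simulations inside a search return a large finite
  penalty (1e12) so the swarm can route around pathological corners of
  parameter space.

## Fitting

The objective is the normalized MSE `Σ_ij (μij − Pij)²/(μij² + μ0²)` over
mean concentrations per compartment and time point, with `μ0 = 1 pg/ml`
keeping censored points (recorded as 0) at finite weight. The
limit-of-detection rule: a point below the 30 pg/ml assay LOD contributes
nothing when the prediction is also ≤ LOD, and the full penalty otherwise.
Replicates are averaged into `μij` before scoring; raw replicates exist
only inside the synthetic generator.

Particle swarm optimization is implemented in-package (global best
topology; inertia 0.729, cognitive/social 1.49; uniform initialization in
bounds; reflective boundaries; deterministic given a seed) and searches
log10-transformed parameters because the literature bounds span 4–6
decades. A bounded Nelder–Mead polish runs from the swarm optimum by
default. Species bounds are stored exactly as printed in the source
literature; the mouse renal-clearance bounds (250–750 ml/min against a
1.2 ml blood volume) are physiologically implausible as printed, so the
package emits a `UnitPlausibilityWarning` and exposes
`MOUSE_CLEARANCE_PLAUSIBLE_BOUNDS` (the µl/min reading, 360–1080 ml/day)
as a documented override — used by the recovery tests, since under the
printed bounds blood never rises above the LOD and clearance is
unidentifiable.

Identifiability caveat: on the IP curve the decay/transport pair
(λ, k_trans) is exactly exchangeable (a two-exponential flip-flop), and a
censored blood compartment leaves `k_clr` free. Fit quality is therefore
judged on the observable trajectories — `trajectory_sup_error` computes
the per-compartment sup-norm relative error restricted to times where the
true curve is at or above the LOD, since a fit cannot be validated below
what the assay can measure — rather than on individual parameter values.

## Redosing and interval optimization

Multi-dose regimens integrate block-by-block between events; at each event
the full dose is added to the surviving capsules (`N` jumps, `C1`/`C2`
continuous). With a horizon `T` and interval `I` this yields
`floor(T/I)` whole blocks plus a final partial block. An independent
superposition oracle (sum of shifted single-dose responses, valid by
linearity and time-invariance) checks the block integrator in tests.

The trough `C1,min` is the minimum IP concentration after the initial
transient, defined as the first local maximum of `C1` after the first
dose; the search window ends at (last event + I) for uniform schedules.
If all doses land inside the rise phase the whole window is transient and
the level at the window's end is reported, flagged. The interval optimizer
minimizes `S(I) = (C_tgt − C1,min)²`. S(I) proved non-convex and locally
jagged — the binding trough hops between dose cycles as `I` varies — so
restarted scalar minimization was unreliable; the implementation scans the
feasible range `(0.25, T/n_doses]` at 0.05-day resolution and polishes the
best bracket with bounded Brent, and is validated against an exhaustive
grid in tests.

## Synthetic data

The generator reproduces the structure of the study designs, not any real
measurements: the mouse design (200 capsules at t=0; IP and blood sampled
at days 1, 4, 7, 14, 21, 30; five animals per point), an NHP single-dose
design (one animal, ~two weeks of sampling), and a human constant-infusion
design (0.33 mg/m²/day over a 1.75 m² peritoneum ≈ 0.57 mg/day). Noise is
mean-preserving lognormal with CV 0.20 by default — concentrations are
positive and immunoassay error is multiplicative; the source data publish
no noise model, so this is the package's choice. Replicate means below the
LOD are recorded as 0 and flagged. What passing tests show is therefore
internal consistency — the pipeline recovers what generated its input
under realistic sparsity, noise, and censoring — not agreement with any
animal's measurements.

Two per-capsule production constants are exposed because they genuinely
disagree: the in-vitro supernatant estimate
(`PER_CAPSULE_RATE_INVITRO_PG_PER_DAY`, 1e4 pg/day) and the value implied
by in-vivo dose labels (`PER_CAPSULE_RATE_DOSE_LABEL_PG_PER_DAY`,
1.31e5 pg/day, e.g. 200 capsules labelled 26.2 µg/day). The ~13× gap is
unexplained upstream; scenarios must pick one explicitly, and the stock
designs use the in-vitro value so that generating parameters sit inside
the fitting bounds.

The mouse generating parameters (`MOUSE_TRUE_PARAMS`) place production and
decay inside the literature fitting bounds and use a clearance of
720 ml/day (0.5 ml/min), which reproduces the measurable ng/ml-scale blood
concentrations characteristic of mouse PK data; under the printed ml/min
bounds the blood compartment would censor entirely.

## Species parameter files

`configs/*_synthetic_s6.yaml` are **synthetic reconstructions** of the
species simulation tables, not published values. Printed constants are
used where they exist — human `V1 = 20 ml`, `V2 = 5320 ml`,
`k_clr = 1.68e5 ml/day`, transport rate 0.7/day from the infusion-trial
fit; NHP volumes from `V2 = 65·m` (4 kg assumed, mass is a required input
elsewhere) with the human `V1:V2` ratio, clearance from linear mass
scaling. The never-published entries (per-capsule production, decay rate,
effector threshold) were reconstructed once from the documented
constraints: production at the in-vitro estimate, mouse/human decay at
0.45/day, NHP decay ~50 % faster (0.70/day, matching the reported
direction of the NHP fit), and the effector threshold (21 000 pg/ml)
placed so a 5000-capsule human dose sustains the reported ~13-day
therapeutic window. These files exist to drive the scenario simulations
and are clearly labelled; replace them with real values where available.

## Problem sizes

Default test and acceptance runs use 100 random parameter draws for the
oracle comparison, 20 seeded noisy-fit replicates with a 40-particle,
120-iteration swarm (the polish step makes larger swarms unnecessary on
this 4-parameter problem), 0.05-day interval scans, and ~2000-point
simulation grids. All are arguments, not constants.

## Known limitations

- No pharmacodynamics: thresholds are inputs, immune feedback on capsule
  decay (plausible for an immunostimulatory payload) is not modelled.
- No uncertainty quantification beyond seeded re-runs; no hierarchical
  fitting across animals or dose levels.
- `λ`/`k_trans` exchangeability means single-compartment datasets cannot
  pin individual rates; report trajectories or fit richer designs.
- The constant-`V1` assumption is wrong for regimens with large repeated
  fluid instillations (e.g. continuous infusion trials at high volume),
  where the IP:blood gradient it predicts will overestimate reality.
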