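# Methods

This note documents the model and procedure implemented by `fluxcourse`, the
parameters that matter, the numerical choices, and what the synthetic test
fixtures do and do not establish about real data.

## The procedure

The analysis answers: *under the substrate consumption and growth the strain
actually exhibited, how much product could its metabolic network have made?*
It replaces the kinetic rate laws of classical dynamic FBA with direct
polynomial approximations of the measured time courses.

### Time-course approximation

Measured concentrations are normalised to mM (metabolites; g/L divided by
the molar mass, ×1000) and g DCW/L (biomass; OD600 × 0.33 g DCW/OD for
*E. coli*), then fitted by unweighted least squares on **raw, uncentred
time**, so the coefficients are directly comparable to published fit
equations. The fit order defaults to 5, matching the fifth-order fits used
for the bundled case-study coefficients; the residual recorded with every
fit is the RMS deviation at the sample times. Raw-time Vandermonde matrices
become ill-conditioned for high orders or long horizons; the fitter warns
when that happens rather than silently rescaling, because rescaled
coefficients would no longer be comparable.

Data may be split at user-chosen breakpoints ("segments"); each segment is
fitted independently with **no continuity constraint**, so the derived rates
may jump at breakpoints. This is deliberate — enforcing smoothness would be
a different approximation model (splines), which is out of scope and noted
only as an extension point.

### Specific-rate constraints

With fitted `Glc(t)` and `X(t)`,

- specific uptake: `v_uptake(t) = max(0, −Glc′(t) / X(t))` (mmol/g DCW/h),
- specific growth: `μ(t) = max(0, X′(t) / X(t))` (1/h).

The clamp at zero is part of the method's contract: a polynomial
wiggle must not be interpreted as glucose secretion or biomass decay. Its
important side effect: wherever the fitted glucose curve still *rises*
(as it does near t = 0 for the bundled case-study fit, where
Glc′(0) = +1.89582 mM/h), the uptake target is exactly 0.

Uptake rates are stored as nonnegative consumption magnitudes; the mapping
onto the constraint-based sign convention (exchange flux negative = uptake)
happens only when bounds are written into the LP: uptake in `[lo, hi]`
becomes exchange flux in `[−hi, −lo]`.

### Sequential two-step FBA with relaxation

On a uniform grid `t_start, t_start+h, …, t_end` (default h = 0.01 h over
0–27 h), targets are evaluated at the **left endpoint** of each step — the
simplest consistent reading of sequential static optimisation. Each node:

1. **Step 1 — growth.** For n = 1, 2, …, bound both uptake and growth to
   `target·{1 − d(n−1)} … target·{1 + d(n−1)}` with d = 0.01 and the lower
   bound floored at 0, and maximise growth. Stop at the first n with an
   optimal solver status. At n = 1 the band is an equality constraint; a
   target of exactly 0 keeps the degenerate band {0} at every n, as the
   multiplicative formula dictates. `n_max` defaults to 101 (a ±100 % band);
   beyond that the step fails loudly with the solver status attached. The
   value 101 is not arbitrary: when the clamped uptake target is 0 but the
   growth target is positive, the step only becomes feasible once the growth
   lower bound reaches 0, i.e. exactly at n = 101.
2. **Step 2 — product.** Fix growth at the step-1 optimum with a relative
   slack of 1e-6 on both bounds (an exact equality is numerically brittle),
   keep the uptake band of the feasible n, and maximise the product exchange
   flux. Before `induction_end` (default 2 h) the product exchange upper
   bound is 0 in both steps, so no product forms during induction.

Only the objective value and the constrained fluxes are contractual:
alternate optima may distribute the remaining fluxes differently, and no
flux-variability resolution is attempted.

Supplemented medium species (case-study defaults: phenylalanine and
tyrosine 0.7 g/L, tryptophan 0.35 g/L, converted with molar masses 165.19,
181.19 and 204.23 g/mol) may be imported up to a configurable magnitude
(default 1000 mmol/g DCW/h, i.e. demand-limited). Depletion is checked
against the running integral at the start of each step; the step at which a
pool first reaches ≤ 0 is the last step allowed to import it, and the uptake
bound is 0 from the next step *permanently*. Consequently the raw integral
can undershoot zero by at most that one step's consumption; reported
concentrations are floored at 0 and the raw series is kept for diagnostics.
Oxygen keeps the model's default aerobic bounds — no oxygen time course is
imposed.

### Integration

Fluxes are converted to concentrations by
`C_m(t) = C_m(0) + ∫ v_m(τ)·X(τ) dτ` with a **running** composite Simpson
rule: each new node gets a provisional trapezoid value, and every completed
pair of intervals is finalised with Simpson's rule, so depletion checks see
up-to-date pools while retaining fourth-order accuracy at pair boundaries.
A post-hoc pass over the full grid (`simpson_cumulative`,
`fluxes_to_concentrations`) applies the identical rule and reproduces the
running series to rounding.

Biomass appears inside its own integrand (`dX/dt = μX`) and is advanced by a
self-consistent implicit sweep: implicit trapezoid at the newest node, then,
at pair completion, two corrector iterations that refine the pair midpoint
with the three-node rule `h/12 (5g_{k−2} + 8g_{k−1} − g_k)` (exact for
quadratic integrands) and the endpoint with implicit Simpson. The corrector
makes the sweep fourth-order in the step; with a plain trapezoid midpoint it
would be third-order. Midpoint refinements are propagated into the
metabolite integrands so running and post-hoc integration stay identical.
Stability requires `μh < 2`, which any sensible grid satisfies by orders of
magnitude.

### Performance evaluation

The integrated product concentration at the final grid time is taken as the
simulated maximum — under a product-maximising second objective the product
can only accumulate, so the final value is the maximum. Attainment is
`100 × experimental_final / simulated_max` with units harmonised to mM;
headroom is its complement. One run yields one ratio; sensitivity to
relaxation or medium settings is explored by re-running with changed
configuration rather than by hidden defaults.

## Synthetic fixtures: what they show and what they don't

`fixtures.make_synthetic_timecourse` evaluates the bundled fifth-order
case-study concentration fits (glucose, biomass) on 0–27 h and optionally
adds seeded additive Gaussian noise — the natural noise model for
least-squares fitting. `fixtures.make_toy_model` builds three LP-transparent
networks (3, 6 and 10 reactions) whose optima are exact small rationals; the
10-reaction "shikimate toy" mirrors the case study's *structure* — glucose
uptake, growth requiring the three supplemented aromatic amino acids 1:1:1
per unit flux, a costly tryptophan-synthesis bypass, a respiration overflow
for surplus carbon, and a product export route.

Passing tests on these fixtures establish that the machinery is correct:
unit handling, fit recovery, LP agreement with an exhaustive
vertex-enumeration oracle, minimal relaxation counts, induction and
depletion switching, and integration accuracy. They do **not** establish
biological accuracy: the toy yields are arbitrary integers, real
measurements carry non-Gaussian and autocorrelated errors, real models have
thousands of reactions with degenerate optima, and a polynomial that fits
poorly (oscillation at the ends of the horizon, segmentation artefacts)
propagates directly into the constraints. Attainment figures computed on toy
networks characterise the pipeline, not any strain.

## Default problem sizes

The default grid (0–27 h at 0.01 h; 2701 nodes, ≥ 2 LPs each) reflects the
step size the method was designed around. The test suite and the worked
example use the toy networks, where the full fine grid solves in seconds;
coarser grids (0.1–0.5 h) are used in tests whose point is behavioural
rather than numerical, after checking that the attainment ratio moves by
well under one percentage point between 0.1 h and 0.01 h on the toy. With a
genome-scale model such as iJO1366 the same run is minutes-to-hours; the
grid, horizon and `n_max` are all configurable.

## Known limitations

- The method interpolates the measured behaviour; it cannot predict outside
  the measured feeding/growth envelope, nor simulate parameter changes or
  co-cultures (no kinetic uptake laws by construction).
- Intracellular accumulation and regulatory limitation are invisible to the
  steady-state LP inside each step; only the export flux is constrained
  during induction.
- Where the clamped targets are infeasible for the network, the relaxation
  loop substitutes the nearest band — heavy relaxation (n near `n_max`) is
  reported per node and should be inspected, not ignored.
- Segmented fits can produce rate discontinuities at breakpoints; the
  trajectory is then only piecewise smooth.
- Alternate LP optima make non-objective fluxes non-unique; downstream users
  should rely only on the constrained and objective fluxes.
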