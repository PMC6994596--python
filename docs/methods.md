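# Methods

## Model

One cell is described by two dimensionless states: intact proteins
P ∈ [0, 1] and damaged proteins D ∈ [0, 1], each a fraction of its
threshold.  Between events they obey

    dP/dτ = P (g − D) − k₁ P + k₂ Q D
    dD/dτ = (k₁/Q) P − k₂ D

where g > 1 is the growth factor (growth slows as damage accumulates),
k₁ ≥ 0 and k₂ ≥ 0 are the damage formation and repair rates as fractions of
the growth rate μ, and Q > 0 is the damage resilience, the ratio of death
to division thresholds.  The factor Q enters asymmetrically because the two
states are normalised by different thresholds: one unit of P converted to
damage adds only 1/Q units of D, and repairing one unit of D returns Q
units of P.  Division at P = 1 applies the mother/daughter map given in the
README; death at D = 1 ends the lineage.  The dimensional system (rates in
1/h, thresholds in concentration units) is supported only as an input to
`nondimensionalise`; simulations always run in dimensionless form.  The
substrate enters solely through the Monod expression μ = μ_max·S/(S + K_S)
when evaluating μ, and through the minimal-substrate formula
S_min = (k₁+k₂)/(μ_max·g − (k₁+k₂))·K_S; S is never a dynamic state.

Two published-constant conventions deserve note.  The constraint printed
alongside the dimensionless system in the source analysis restricts
Q ∈ (0, 1], which contradicts the values Q ≈ 2.5–3.0 used throughout;
validation here requires only Q > 0.  Likewise the second line of the
dimensionless system is treated as the damage equation dD/dτ (dividing the
dimensional damage balance k₁P − k₂D by μ·D_death yields exactly
(k₁/Q)P − k₂D).

## Event-driven integration

The stepper is an adaptive Runge–Kutta–Fehlberg 4(5) pair with max-norm
error control (default rtol 1e−8, atol 1e−10), compiled with numba.  After
each accepted step, upward crossings of P = 1 and D = 1 are detected by
sign change and localised by bisection **on the step size**: each trial is
a genuine error-controlled RKF45 step from the last accepted state, so the
event time inherits the integrator's accuracy rather than an interpolant's.
If both thresholds are crossed within one accepted step the earlier
crossing wins; exact ties resolve to death (the stricter reading).  The
crossing component is clipped to exactly 1 in the reported event state, so
trajectories never leave the unit box.  Tightening both tolerances tenfold
moves the reference-lineage event times by less than 1e−5, below the
four-decimal reporting precision; the suite asserts this.  The
implementation is cross-checked against two independent integrations of the
same system — scipy `solve_ivp` (RK45, terminal events) in the test suite,
and R deSolve's `lsodar` root-finding during development — which agree with
it to six decimals on the reference lineages.

## Lineage simulation and fate classification

A lineage starts from a damage-free daughter (1 − s, 0) unless another
initial state is given, and follows the mother: at each division the mother
map is applied and integration continues.  Stopping rules
(`SimulationCaps`): death (D = 1); immortality, declared when successive
post-division birth states agree within 1e−8 in max-norm (the operational
form of convergence to the division-return-map fixed point), with caps of
1000 divisions and τ = 10⁴; anything cap-limited is labelled *censored*,
never silently assigned.  Fates: *starvation* is assigned analytically from
k₁ + k₂ ≥ g without simulation (the ODE itself can still divide there, but
the bound marks where sustained growth is impossible on substrate grounds);
k₁ = 0 is immortal by construction; death before the first division is
*clonal senescence*; death after at least one division is *ageing*.

Generation times are inter-division intervals, the first measured from
birth.  The *maximum generation time* includes, by default, the terminal
interval from the last division to death: growth stalls as D → 1 (the
death crossing is nearly tangential), so the unfinished last generation is
always the longest in the ageing region.  A flag excludes it.

Replicative lifespan is extremely sensitive near the immortality boundary:
on the reference line (g = 1.1, k₂ = 0.1, Q = 3.0) moving k₁ from 0.50 to
0.49 changes the RLS from 14 to 24.  Quantities computed near that boundary
(including two of the three reference lifespans) should be read with this
amplification in mind; the package reports converged values.

## Parameter-plane scans

`scan` classifies the N×N grid kᵢ = i·g/N, i = 0…N−1 (spacing Δ = g/N,
axes included).  Default N = 50 for analysis (2 500 cells, a few seconds);
N = 200 is practical for figures.  Cells with k₁ + k₂ ≥ g and the k₁ = 0
column are assigned analytically to avoid needless or infinite runs.
`strategy_comparison` perturbs each ageing cell multiplicatively
(δ = 0.05, i.e. 5% less formation vs 5% more repair — an absolute-step mode
exists behind a flag), simulates both perturbed lifespans, and labels the
cell by the larger integer gain; equality is exact integer equality, so no
floating tolerance is involved.  Perturbations landing on immortality or a
censoring cap count as infinite gain and are tallied in the metadata.
Scans are deterministic and bit-identical across runs.

Two views of "which division strategy lives longer" must be kept apart.
Per common grid cell, a symmetric mother (s = ½) weakly outlives an
asymmetric one (s = 0.64, re = 0): she keeps 50% of the damage instead of
64%.  At the landscape level the ordering reverses: asymmetry shifts the
ageing region toward the immortality boundary, where far higher lifespans
are attainable (at N = 50, Q = 2.6: maximum RLS 70 vs 28, mean 6.1 vs 3.6).
`compare_landscapes` reports both the per-cell counts and the per-region
summaries so either claim can be tested explicitly.

## Synthetic cell-area data and fitting

The generator emulates time-lapse cohorts: n_young damage-free daughters
starting at (1 − s, 0) and n_old mothers starting at the birth states one
to n_old divisions before death in a simulated lineage, giving staggered
elevated damage loads (defaults 3 and 5).  Each cell is sampled on a common
grid, by default τ ∈ [0, 2] in steps of 0.05 — roughly one full generation,
mirroring imaging through at least one division at ~5-minute frames — and
truncated (and flagged) at its first division or death event.  Areas are
scale·(P + Q·D) plus i.i.d. Gaussian noise, either absolute or relative to
the signal; all randomness flows through one seeded generator.  The
generator reproduces the sampling design and noise character of real
cell-area series but none of their biology beyond the model itself — no
segmentation error structure, no cell-to-cell parameter variability, no
drift — so recovery results certify the estimation machinery under the
model, not robustness to model misspecification.

Fitting estimates θ = (g, k₁, k₂) by multistart bounded least squares
(scipy trust-region-reflective; uniform seeded starts within the bounds,
default 8).  Q is fixed (default from the measured old/young volume ratio,
2.5–2.6) because it is structurally confounded with the area scale; the
scale is likewise fixed, shared across cohorts (one proportionality
constant per imaging setup).  Each trajectory's initial state is carried in
the data table and treated as known — for young cells it is the design
point (1 − s, 0); for old cells an unknown D₀ would otherwise be confounded
with θ on a single window.  Parameter sets under which the model cell dies
inside the observation window incur a large finite penalty (10³ per
residual) instead of an exception so optimisers can traverse the region.
The information criterion uses the Gaussian-residual form
AIC = n·ln(LS/n) + 2p; an exact LS = 0 has no likelihood scale and is
rejected rather than scored.

## Problem sizes and determinism

The test suite runs coarse scans at N = 20–25 and the acceptance checks at
N = 50; parameter recovery uses 20 seeded replicates of 8 trajectories at
2% relative noise.  Everything except the declared noise and multistart
draws is deterministic; every stochastic path takes an explicit seed.

## Known limitations

- Single mother lineages only: no daughter subtrees, populations or
  lineage trees, and no stochasticity in division timing or partitioning.
- The starvation label is an analytic proxy; substrate is never simulated.
- Immortality is decided by an operational convergence rule, not the
  analytic stability boundary of the division return map; near that
  boundary cells may be censored, and censored counts are reported.
- Fits treat initial states as known and Q as fixed; relaxing either
  requires richer data than one observation window per cell.
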