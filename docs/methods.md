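# Methods

## Model

`m` territorial species compete for `p` nutrients on a ring of circumference
`L`.  The state is the vector of segment lengths `n` (populations), ordered
by ring adjacency and summing to `L`.  Nutrient `i` obeys, inside the
territory of species σ,

    ∂c/∂t = S_i − α_σi c + D c'' ,

with spatially uniform supply `S_i`, linear (nutrient-limited) uptake and a
common diffusivity `D`.  Two assumptions define the regime:

1. **Separation of timescales.**  Nutrient relaxation is fast compared to
   population change, so the concentration field is always at its
   quasi-steady profile for the current `n` (`∂c/∂t = 0`).  No
   time-dependent nutrient PDE is ever integrated.
2. **Fixed total territory.**  Populations never overlap and fill the ring,
   which forces the death rate `δ = v S_total`; the dynamics conserve
   `Σ n_σ = L` exactly.

Units default to `v = 1`, `S_total = 1`, `E = 1`, `L = 1`, so `δ = 1` and
time is measured in death-rate units; all APIs accept general units.  The
single control parameter is the dimensionless mixing time `τ_D = L²E/D`;
`τ_D = 0` (`D = ∞`) takes the explicit well-mixed path with
`c_i = S_i L / Σ_σ n_σ α_σi`.

## Quasi-steady nutrient solve

Within each occupied segment the profile is
`c = S_i/α + A e^{−k(n−x)} + B e^{−kx}` with `k = √(α/D)` — the decaying
two-sided basis keeps every matrix entry in `[0, 1]` even when `k n ≫ 1`
(raw `e^{±kx}` overflows already at moderate `τ_D`).  Segments with
`α_σi = 0` carry the parabolic particular solution `−S_i x²/(2D) + Ax + B`.
Continuity and differentiability at all boundaries with periodic closure
give a `2m′ × 2m′` linear system per nutrient (`m′` = occupied segments),
assembled batched over nutrients and solved densely; at the community sizes
this package targets (`m ≤ ~20`) the dense batched solve is faster than
sparse machinery.  The hot path (all allocations positive, the almost-sure
case for sampled strategies) is JIT-compiled with numba; the generic
numpy path handles zero allocations and the two paths are cross-checked in
the tests.  Degenerate inputs are rejected explicitly: a supplied nutrient
consumed by no occupied species has no steady state (`NoSteadyStateError`);
an unsupplied, unconsumed nutrient is pinned to `c ≡ 0`.

Per-territory uptake integrals are evaluated in closed form (no
quadrature).  Validation is against an independent cell-centered
finite-difference discretization of the same boundary-value problem
(N = 16384 periodic cells, direct sparse solve): maximum relative deviation
over random communities (`m ≤ 5`, `p ≤ 3`, `τ_D ∈ [1, 1000]`) is ~3×10⁻⁷,
asserted at 10⁻⁴.

## Population dynamics and steady states

`dn_σ/dt = v Σ_i α_σi ∫_σ c_i dx − δ n_σ`.  Integration uses LSODA (the
slow-manifold dynamics are stiff: fast modes relax at rate ~δ while slow
modes relax at ~τ_D·const) in geometrically growing time windows.  After
each window the conserved total is renormalized to `L` (drift over 10⁷-time
integrations is otherwise ~10⁻⁸) and steadiness is declared when
`max_σ |dn_σ/dt| / L < rate_tol` (library default 10⁻¹⁰).

**Extinction.**  The only threshold the model prints is the classification
rule `n_σ/L < 10⁻⁶`.  By default the integrator reuses it as a dynamic
floor: a crossing species (detected by a terminal event) is clamped to zero
and removed from the matching chain, its neighbors becoming adjacent.  A
`remove_extinct=False` mode only classifies post hoc; segments below
`10⁻¹² L` are then dropped from the chain (whose conditioning degrades as
`k n → 0`) and decay freely.  Both modes give indistinguishable steady-state
diversity in head-to-head runs; the default is faster.  Extinction is
absorbing: `n_σ = 0` implies `dn_σ/dt = 0`.

**Horizons.**  Near `τ_D → 0` the degenerate manifold of well-mixed fixed
points becomes a slow manifold and full convergence requires `t ~ 10⁷–10⁸`
(in δ-units) at `τ_D = 0.01`.  The experiment drivers therefore default to
`t_max = 10⁹` and rely on the rate criterion to stop; the library default
`t_max = 10⁵/δ` suits moderate `τ_D`.  Non-converged runs are always
flagged, never dropped.  Note that *any* finite rate tolerance defines the
reported steady state: at large `τ_D` interactions are exponentially weak in
`k n`, so looser stopping rules freeze visibly more diverse communities
(e.g. `M ≈ 2.1` at `t ≈ 1.5×10³` vs `M ≈ 1.05` converged, for one
`τ_D = 1600` community).  Diversity statistics quoted by this package are
at the stated `rate_tol`, which the drivers record.

**Stability analysis.**  The Jacobian at a fixed point is built by central
finite differences along an orthonormal basis of the conservation
hyperplane `Σ δn = 0` restricted to survivors, so its `m′ − 1` eigenvalues
exclude the trivial conservation direction.  Defaults: step
`max(10⁻⁷L, 10⁻⁹)`, numerical-zero threshold `10⁻³ δ` (suitable for
counting the `m − p` degenerate well-mixed modes).  Resolving the slow-mode
scaling `t_slow ∼ 1/τ_D` requires a larger step (10⁻⁴, since slow-mode rate
differences approach solver noise) and a smaller zero threshold (10⁻⁸);
both are parameters.  The inverse scaling is an asymptotic small-`τ_D` law:
measured slopes of `log t_slow` vs `log τ_D` are ≈ −0.95 on
`τ_D ∈ {0.1, 0.4, 1.6, 6.4}`, with saturation above `τ_D ~ 10` where the
slow eigenvalue approaches the boundary-layer modes.

## Demographic noise

Territory is granular at the quantum `ℓ` (one individual; enforced
`ℓ ≤ L/100`).  Per step `Δt`, species σ gains `Poisson(b_σ Δt/ℓ)·ℓ` and
loses `Poisson(δ n_σ Δt/ℓ)·ℓ`, with `b_σ` the deterministic birth flux, so
the scheme's mean increment is exactly the deterministic flow and `ℓ` sets
the noise amplitude.  The total is renormalized to `L` each step; zero is
absorbing.  Steps whose gross proposed change exceeds
`max(0.1 n_σ, 10ℓ)` are rejected and retried with a halved `Δt` (recovering
geometrically).  This birth–death scheme is this package's own concrete
interpretation of demographic noise for territorial populations; claims
tested against it are qualitative orderings (fluctuations concentrate on
slow modes; unrestored well-mixed drift loses species far more often than
spatial communities at equal quantum), not quantitative noise spectra.

## Random communities (the generator)

`sample_strategies` draws each strategy row uniformly on the
`(p−1)`-simplex via normalized i.i.d. exponentials (flat Dirichlet), scaled
by the species budget.  Budget noise draws `E_σ ~ Normal(E, δ_E)` and
redraws nonpositive values (negligible mass at the studied `δ_E`);
oligotroph exclusion rejects rows with `R_σ < p` (capped, since the
admissible region can have negligible measure under skewed supplies).  The
ring ordering of generated species is generation order; a seeded shuffle is
available.  The generator emulates the study conditions — communities with
exact (or noisily inexact) trade-offs, no correlations between strategies,
uniform supply — and none of the structure of real communities (phylogenetic
correlation, uptake saturation, variable diffusivities), so passing tests
demonstrate properties of the model, not of any dataset.

## Experiment defaults (problem sizes)

Drivers are exactly reproducible from `(config, master seed)`; per-replicate
streams derive from `SeedSequence((master_seed, context, replicate))`.
Desk-scale defaults, chosen once: 100 replicates for the `τ_D` sweep and 200
for the oligotroph and budget scans (the historical counts, 400 and 2000,
sit behind `--full`); `m = 10` for sweeps, `m = 20` with `τ_D = 10` for
oligotroph/budget scans; supplies `s = (0.4, 0.6)` and, for the two-species
attractor scans, `s = (0.3, 0.7)` with `τ_D = 400`.  The bistability
driver's default `α_21` window (0.40–0.46, step 0.004, with `α_11 = 0.29`)
brackets the fold: two coexistence attractors appear for
`α_21 ≈ 0.434–0.438`, and with `α_11 = 0.31` (an oligotroph, `R = 1.98`)
an Allee window appears at `α_21 ≈ 0.38–0.41` where species 2 survives only
if it starts large enough.  Attractors are distinguished by clustering final
`n_1` values at absolute tolerance 10⁻³ L.

## Known limitations

* One spatial dimension with periodic closure only; no 2-D extension.
* All nutrients share one diffusivity; no evolution or regulation of
  strategies.
* The `τ_D = 0` limit is implemented directly (no perturbative expansion
  around it); consistency with the spatial model is verified numerically at
  `τ_D = 10⁻⁴` (rates within 1%).
* Steady-state diversity at extreme `τ_D` depends on the declared stopping
  tolerance (see *Horizons* above); comparisons across studies require
  matching that convention.
* The noise model is a per-step Poisson birth–death scheme on segment
  lengths; individuals have no identity or spatial position beyond their
  species' segment.
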