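# territorysim

Simulator for **territorial resource competition on a ring** — a mechanistic
model of surface-bound communities (biofilms, vegetation, coral, mussel beds)
in which populations compete simultaneously for diffusing nutrients and for a
share of a fixed total territory.

## The model

`m` species compete for `p` nutrients on a one-dimensional ring of
circumference `L`.  Species σ is defined by its metabolic strategy
`α_σ = (α_σ1 … α_σp)`, the enzyme allocation it devotes to each nutrient,
constrained by a budget `Σ_i α_σi = E` (the metabolic trade-off).  Each
species occupies an exclusive segment of length `n_σ` — its population — so
`Σ_σ n_σ = L` and the community state lives on a simplex.

Nutrients are supplied uniformly at rates `S_i` (`Σ_i S_i = S`), are consumed
locally at rate `α_σi c_i`, and diffuse with coefficient `D`.  Nutrient
processing is fast compared to growth, so concentrations take their
quasi-steady profile at every population state: inside a segment,

    c_σi(x) = S_i/α_σi + A_σi exp(−k x) + B_σi exp(+k x),   k = √(α_σi / D),

with the integration constants fixed by continuity and differentiability of
`c_i` at every territory boundary and periodic closure around the ring — a
`2m × 2m` linear system per nutrient that `territorysim` assembles and solves
exactly (in an overflow-safe decaying basis).  Populations then grow by the
nutrient flux integrated over their own territory,

    dn_σ/dt = Σ_i α_σi v ∫_σ c_i(x) dx − δ n_σ,

with `δ = v S` enforced by conservation of total territory.  A single
dimensionless group, the nutrient mixing time `τ_D = L²E/D`, controls the
physics: `τ_D = 0` is the classic well-mixed trade-off model (implemented as
an explicit limit), large `τ_D` means nutrients barely outrun their
consumers.

Phenomena the package reproduces and quantifies:

* coexistence far beyond the competitive-exclusion limit, and its *loss* as
  spatial structure sharpens competitive differences;
* the **oligotroph criterion**: a species with
  `R_σ = Σ_i S_i/α_σi < p` maintains, and survives on, the minimum total
  nutrient concentration and crashes community diversity;
* the degenerate manifold of well-mixed fixed points, its collapse into a
  **slow manifold** with relaxation time `t_slow ∼ 1/τ_D`, and demographic
  drift confined to that manifold;
* **multistability and the Allee effect** in two-species competitions;
* the asymmetric response to *inexact* trade-offs: budget noise
  `E_σ ~ N(1, δ_E)` collapses well-mixed diversity while spatial diversity
  increases.

## Worked example

```python
import numpy as np
from territorysim import (CommunityState, ModelParams, NutrientSupply,
                          integrate_to_steady_state, sample_strategies, summarize)

supply = NutrientSupply.from_fractions((0.4, 0.6))     # two nutrients, 40/60
strategies = sample_strategies(m=10, p=2, seed=42)     # uniform on the simplex
initial = CommunityState.equal(10)                     # equal initial populations

for tau_D in (0.0, 10.0):
    params = ModelParams.from_tau_D(tau_D)
    traj = integrate_to_steady_state(initial, strategies, supply, params,
                                     rate_tol=1e-10, t_max=1e9)
    stats = summarize(traj.steady_state)
    print(f"tau_D = {tau_D:>4}: converged at t = {traj.times[-1]:9.1f}, "
          f"survivors = {int(10 * stats.survival_fraction)}/10, M = {stats.M:.2f}")
```

Output:

```
tau_D =  0.0: converged at t =     100.0, survivors = 10/10, M = 9.88
tau_D = 10.0: converged at t =  121280.5, survivors = 7/10, M = 3.21
```

The same ten species all coexist in comparable proportions when nutrients mix
instantaneously (effective species number `M = exp(H) ≈ 9.9`), but in a
spatial environment three of them go extinct (`n_σ/L < 10⁻⁶`) and one
species dominates, leaving an effective diversity of ≈ 3.2 — reached four
orders of magnitude more slowly.

## Command line

The experiment drivers behind the library are exposed as a CLI:

```bash
territorysim simulate --community community.json --out results/
territorysim sweep-tauD --replicates 100 --seed 0 --out results/
territorysim oligotrophs --exclude-oligotrophs --seed 0 --out results/
territorysim bistability --alpha11 0.31 --out results/
territorysim budgets --replicates 50 --seed 0 --out results/
```

Each command accepts a YAML/JSON config (`--config`), writes a per-replicate
CSV, a summary JSON and a run log, and is exactly reproducible from the
config plus master seed.  `--full` switches to the historical large replicate
counts.

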