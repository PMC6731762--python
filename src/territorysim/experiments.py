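"""Seeded experiment drivers.

Four experiment families, each exactly reproducible from a configuration and
a master seed:

* a diversity sweep over the nutrient mixing time tau_D (survival fraction
  and effective species number of random communities),
* random-community scans probing the oligotroph condition R_sigma < p,
* a two-species bistability / Allee-effect scan over strategy space and
  initial conditions,
* an unequal-enzyme-budget comparison of the well-mixed and spatial models.

Per-replicate rows are emitted as pandas DataFrames; summary statistics are
always recomputable from the rows (no hidden state).  Replicate seeds derive
deterministically from the master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import effective_species, survival_fraction
from .dynamics import integrate_to_steady_state
from .model import (
    CommunityState,
    ModelParams,
    NutrientSupply,
    StrategySet,
    is_oligotroph,
    oligotroph_index,
    sample_strategies,
)

__all__ = [
    "ExperimentConfig",
    "OligotrophResult",
    "run_diversity_sweep",
    "diversity_sweep_summary",
    "run_oligotroph_experiment",
    "top_decile_strategies",
    "oligotroph_region_occupancy",
    "run_bistability_scan",
    "bistability_summary",
    "run_budget_experiment",
    "budget_experiment_summary",
]

#: Large-scale replicate counts used when ``full=True``.
FULL_REPLICATES = {
    "diversity_sweep": 400,
    "oligotrophs": 2000,
    "budgets": 2000,
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for the experiment drivers.

    Only the fields relevant to a given driver are consulted; unused fields
    are ignored.  ``replicates`` is the desk-scale count; with ``full=True``
    the driver substitutes the historical large-scale count for its family.
    """

    name: str = ""
    replicates: int = 100
    m: int = 10
    p: int = 2
    supply_fractions: Sequence[float] = (0.4, 0.6)
    supplies: Sequence[Sequence[float]] | None = None
    tau_D_grid: Sequence[float] = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1600.0)
    tau_D: float = 10.0
    delta_E_grid: Sequence[float] = (0.0, 0.05)
    exclude_oligotrophs: bool = False
    alpha11: float = 0.29
    alpha21_grid: Sequence[float] = tuple(
        np.round(np.arange(0.40, 0.4601, 0.004), 3)
    )
    init_n1_grid: Sequence[float] = (0.05, 0.2, 0.5, 0.8, 0.95)
    initial_populations: str = "equal"       # "equal" or "random"
    master_seed: int = 0
    L: float = 1.0
    extinction_threshold: float = 1e-6
    rate_tol: float = 1e-9
    # The slow-manifold crawl at small tau_D takes ~1/tau_D times longer than
    # the demographic timescale, so experiments allow very long horizons and
    # rely on the rate criterion to stop.
    t_max: float | None = 1e9
    full: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        for grid_name in ("tau_D_grid", "delta_E_grid", "alpha21_grid",
                          "init_n1_grid"):
            if len(getattr(self, grid_name)) == 0:
                raise ValueError(f"{grid_name} must be non-empty")
        if self.initial_populations not in ("equal", "random"):
            raise ValueError("initial_populations must be 'equal' or 'random'")

    def n_replicates(self, family: str) -> int:
        return FULL_REPLICATES.get(family, self.replicates) if self.full \
            else self.replicates

    def replicate_rng(self, replicate: int, *context: int) -> np.random.Generator:
        """Independent stream derived from the master seed and replicate index."""
        return np.random.default_rng(
            np.random.SeedSequence((self.master_seed, *context, replicate))
        )

    def with_overrides(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


def _initial_state(config: ExperimentConfig, rng: np.random.Generator):
    if config.initial_populations == "random":
        return CommunityState(
            rng.dirichlet(np.ones(config.m)) * config.L, config.L
        )
    return CommunityState.equal(config.m, config.L)


def _integrate(initial, strategies, supply, params, config):
    return integrate_to_steady_state(
        initial,
        strategies,
        supply,
        params,
        rate_tol=config.rate_tol,
        t_max=config.t_max,
        extinction_threshold=config.extinction_threshold,
        record=False,
    )


def run_diversity_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Survival fraction and diversity M over the tau_D grid.

    Each replicate draws one random strategy set and integrates it from the
    configured initial populations (equal by default, seeded-random
    optionally) at every tau_D in the grid (tau_D = 0 takes the well-mixed
    path), so points along the grid are paired.  Non-convergent runs are
    flagged in the ``converged`` column, never dropped.
    """
    supply = NutrientSupply.from_fractions(config.supply_fractions)
    reps = config.n_replicates("diversity_sweep")
    rows = []
    for r in range(reps):
        rng = config.replicate_rng(r)
        strategies = sample_strategies(config.m, config.p, seed=rng)
        initial = _initial_state(config, rng)
        for tau in config.tau_D_grid:
            params = ModelParams.from_tau_D(tau, L=config.L)
            traj = _integrate(initial, strategies, supply, params, config)
            final = traj.steady_state
            rows.append(
                {
                    "tau_D": tau,
                    "replicate": r,
                    "survival_fraction": survival_fraction(
                        final, config.extinction_threshold
                    ),
                    "M": effective_species(final),
                    "converged": traj.converged,
                }
            )
    return pd.DataFrame(rows)


def diversity_sweep_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of survival fraction and M per tau_D."""
    return (
        table.groupby("tau_D")
        .agg(
            survival_mean=("survival_fraction", "mean"),
            survival_sd=("survival_fraction", "std"),
            M_mean=("M", "mean"),
            M_sd=("M", "std"),
            n_converged=("converged", "sum"),
            n=("replicate", "count"),
        )
        .reset_index()
    )


@dataclass
class OligotrophResult:
    """Per-replicate table plus the strategies and final states behind it."""

    table: pd.DataFrame
    strategies: dict            # (s1, replicate) -> alpha matrix (m x p)
    final_states: dict          # (s1, replicate) -> final n vector


def run_oligotroph_experiment(config: ExperimentConfig) -> OligotrophResult:
    """Distribution of steady-state diversity M for random communities.

    Runs one scan per supply in ``config.supplies`` (default: the
    ``supply_fractions``) at fixed ``config.tau_D``.  With
    ``exclude_oligotrophs`` strategies in the oligotroph region
    ``R_sigma < p`` are rejected at sampling time.
    """
    supplies = config.supplies or [config.supply_fractions]
    reps = config.n_replicates("oligotrophs")
    params = ModelParams.from_tau_D(config.tau_D, L=config.L)
    rows = []
    strategies_store: dict = {}
    finals: dict = {}
    for s_idx, fractions in enumerate(supplies):
        supply = NutrientSupply.from_fractions(fractions)
        key_s1 = float(fractions[0])
        for r in range(reps):
            rng = config.replicate_rng(r, s_idx)
            strategies = sample_strategies(
                config.m,
                config.p,
                seed=rng,
                exclude_oligotrophs=config.exclude_oligotrophs,
                supply=supply,
            )
            n_olig = sum(
                is_oligotroph(row, supply) for row in strategies.alpha
            )
            initial = _initial_state(config, rng)
            traj = _integrate(initial, strategies, supply, params, config)
            final = traj.steady_state
            rows.append(
                {
                    "s1": key_s1,
                    "replicate": r,
                    "M": effective_species(final),
                    "survival_fraction": survival_fraction(
                        final, config.extinction_threshold
                    ),
                    "n_oligotrophs": int(n_olig),
                    "converged": traj.converged,
                }
            )
            strategies_store[(key_s1, r)] = strategies.alpha
            finals[(key_s1, r)] = final.n
    return OligotrophResult(pd.DataFrame(rows), strategies_store, finals)


def top_decile_strategies(
    result: OligotrophResult,
    s1: float,
    decile: float = 0.9,
    surviving_only: bool = True,
    extinction_threshold: float = 1e-6,
) -> np.ndarray:
    """Strategies appearing in the most diverse communities for one supply.

    Communities at or above the ``decile`` quantile of M are selected; by
    default only strategies that survived there are returned (stacked as an
    array of allocation rows).
    """
    sub = result.table[result.table["s1"] == s1]
    if sub.empty:
        raise ValueError(f"no replicates recorded for s1 = {s1}")
    cutoff = sub["M"].quantile(decile)
    rows = []
    for _, rec in sub[sub["M"] >= cutoff].iterrows():
        key = (s1, int(rec["replicate"]))
        alpha = result.strategies[key]
        if surviving_only:
            n = result.final_states[key]
            alpha = alpha[n / n.sum() >= extinction_threshold]
        rows.append(alpha)
    return np.vstack(rows)


def oligotroph_region_occupancy(
    result: OligotrophResult,
    s1: float,
    supply: NutrientSupply,
    decile: float = 0.9,
    **kwargs,
) -> float:
    """Fraction of top-decile strategies lying in the oligotroph region."""
    alpha = top_decile_strategies(result, s1, decile=decile, **kwargs)
    flags = [is_oligotroph(row, supply) for row in alpha]
    return float(np.mean(flags))


def run_bistability_scan(config: ExperimentConfig) -> pd.DataFrame:
    """Attractor map of the two-species competition.

    Species 1 has fixed allocation ``alpha11`` to nutrient 1 (the trade-off
    fixes the rest); ``alpha21`` and the initial share of species 1 are
    scanned on grids.  Each cell is integrated to steady state and the
    attractor classified as coexistence or exclusion; non-converged cells
    are flagged unresolved.  Defaults target the documented regime
    s = (0.3, 0.7), tau_D = 400.
    """
    if config.p != 2:
        raise ValueError("the bistability scan is a 2-species, 2-nutrient setup")
    supply = NutrientSupply.from_fractions(config.supply_fractions)
    params = ModelParams.from_tau_D(config.tau_D, L=config.L)
    a11 = config.alpha11
    rows = []
    for a21 in config.alpha21_grid:
        strategies = StrategySet(np.array([[a11, 1.0 - a11], [a21, 1.0 - a21]]))
        for f1 in config.init_n1_grid:
            initial = CommunityState(
                np.array([f1, 1.0 - f1]) * config.L, config.L
            )
            traj = _integrate(initial, strategies, supply, params, config)
            final = traj.steady_state
            frac = final.fractions
            thr = config.extinction_threshold
            if frac[1] < thr:
                outcome = "exclusion_of_2"
            elif frac[0] < thr:
                outcome = "exclusion_of_1"
            else:
                outcome = "coexistence"
            rows.append(
                {
                    "alpha11": a11,
                    "alpha21": float(a21),
                    "n1_init": float(f1) * config.L,
                    "n1_final": final.n[0],
                    "n2_final": final.n[1],
                    "outcome": outcome,
                    "converged": traj.converged,
                }
            )
    return pd.DataFrame(rows)


def bistability_summary(table: pd.DataFrame, atol: float = 1e-3) -> pd.DataFrame:
    """Distinct attractors per ``alpha21``.

    Converged cells are clustered on the final ``n1`` (tolerance ``atol`` in
    absolute length); the count of clusters is the number of attractors
    reached from the scanned initial conditions.
    """
    rows = []
    for a21, grp in table.groupby("alpha21"):
        ok = grp[grp["converged"]]
        finals = np.sort(ok["n1_final"].to_numpy())
        n_attr = 0
        if finals.size:
            n_attr = 1 + int((np.diff(finals) > atol).sum())
        rows.append(
            {
                "alpha21": a21,
                "n_attractors": n_attr,
                "outcomes": ",".join(sorted(ok["outcome"].unique())),
                "n_unresolved": int((~grp["converged"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def run_budget_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Diversity under unequal enzyme budgets, well-mixed vs spatial.

    For every delta_E in the grid and both dynamics modes, draws communities
    whose budgets are N(1, delta_E) (redrawing nonpositive values) and
    records steady-state M.  The same replicate seed is reused across modes
    and delta_E values share no draws (budgets scale the whole strategy row),
    so mode comparisons are paired on the random strategy directions only
    through the seed derivation.
    """
    supply = NutrientSupply.from_fractions(config.supply_fractions)
    reps = config.n_replicates("budgets")
    rows = []
    for e_idx, delta_E in enumerate(config.delta_E_grid):
        for mode_idx, mode in enumerate(("well_mixed", "spatial")):
            tau = 0.0 if mode == "well_mixed" else config.tau_D
            params = ModelParams.from_tau_D(tau, L=config.L)
            for r in range(reps):
                rng = config.replicate_rng(r, e_idx)
                strategies = sample_strategies(
                    config.m, config.p, seed=rng, budget_sd=float(delta_E)
                )
                initial = _initial_state(config, rng)
                traj = _integrate(initial, strategies, supply, params, config)
                final = traj.steady_state
                rows.append(
                    {
                        "mode": mode,
                        "delta_E": float(delta_E),
                        "replicate": r,
                        "M": effective_species(final),
                        "survival_fraction": survival_fraction(
                            final, config.extinction_threshold
                        ),
                        "converged": traj.converged,
                    }
                )
    return pd.DataFrame(rows)


def budget_experiment_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of M per (mode, delta_E)."""
    return (
        table.groupby(["mode", "delta_E"])
        .agg(M_mean=("M", "mean"), M_sd=("M", "std"), n=("replicate", "count"))
        .reset_index()
    )
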