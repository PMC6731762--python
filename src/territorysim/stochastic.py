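"""Demographic noise: random births and deaths on the ring.

Territory is treated as granular at the scale of one individual, the
``quantum`` length ``l``.  Over a step ``dt`` species ``sigma`` gains
``Poisson(b_sigma dt / l) * l`` of territory and loses
``Poisson(delta n_sigma dt / l) * l``, where
``b_sigma = v sum_i alpha_sigma_i int c_i dx`` is the deterministic birth
flux over its segment.  The expected increment therefore equals the
deterministic growth rate times ``dt``, and the quantum sets the noise
amplitude.  Total territory is renormalized to ``L`` after every step
(competition for a fixed total), and a species that reaches zero is
permanently extinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, _spatial_rates_active, _well_mixed_rates_active
from .model import CommunityState, ModelParams, NutrientSupply, StrategySet

__all__ = ["StochasticConfig", "simulate_demographic", "write_trajectory"]


@dataclass(frozen=True)
class StochasticConfig:
    """Parameters of the birth-death simulation.

    ``quantum`` is the territory length of one individual (must be small
    compared to the ring: at most ``L / 100`` is enforced at run time);
    ``dt`` is the base time step (halved on rejection when a proposed
    increment exceeds 10% of a population, and grown back afterwards).
    """

    quantum: float
    seed: int
    t_max: float
    record_interval: float
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.quantum <= 0:
            raise ValueError("quantum must be positive")
        if self.t_max <= 0 or self.record_interval <= 0:
            raise ValueError("t_max and record_interval must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


def _birth_flux(
    n: np.ndarray,
    alpha: np.ndarray,
    S: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Deterministic birth flux b_sigma for the currently occupied species."""
    act = n > 0
    b = np.zeros_like(n)
    if not act.any():
        return b
    if params.well_mixed:
        # growth rate + delta*n recovers the gross birth term
        rates = _well_mixed_rates_active(
            n[act], alpha[act], S, params.L, params.v, params.delta
        )
        b[act] = rates + params.delta * n[act]
    else:
        rates = _spatial_rates_active(
            n[act], alpha[act], S, params.D, params.v, params.delta
        )
        b[act] = rates + params.delta * n[act]
    return b


def simulate_demographic(
    initial: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
    config: StochasticConfig,
) -> Trajectory:
    """Simulate territory dynamics with demographic (birth-death) noise.

    Deterministic given ``config.seed``.  Snapshots are recorded every
    ``record_interval`` (plus the initial and final states); the trajectory's
    ``converged`` flag is always False (a stochastic run has no steady-state
    criterion).
    """
    L = params.L
    ell = config.quantum
    if ell > L / 100.0:
        raise ValueError("quantum must be at most L/100")
    rng = np.random.default_rng(config.seed)
    S = supply.S
    alpha = strategies.alpha
    delta = params.delta

    n = initial.n.astype(float).copy()
    dt0 = config.dt if config.dt is not None else min(
        config.record_interval, 0.05 / delta
    )
    dt = dt0
    min_dt = dt0 * 2.0**-20

    times = [0.0]
    snaps = [n.copy()]
    t = 0.0
    next_record = config.record_interval
    while t < config.t_max:
        step = min(dt, config.t_max - t)
        b = _birth_flux(n, alpha, S, params)
        d = delta * n
        births = rng.poisson(b * step / ell) * ell
        deaths = rng.poisson(d * step / ell) * ell
        gross = births + deaths
        # A step whose proposed change is large relative to any population is
        # rejected and retried with a smaller dt (the random draws are not
        # reused, keeping increments Poisson at the accepted step size).
        limit = np.maximum(0.1 * n, 10.0 * ell)
        if np.any(gross[n > 0] > limit[n > 0]) and step > min_dt:
            dt = max(step / 2.0, min_dt)
            continue
        n = np.maximum(n + births - deaths, 0.0)
        total = n.sum()
        if total <= 0:
            raise RuntimeError("entire community went extinct in one step")
        n *= L / total
        t += step
        dt = min(dt * 1.05, dt0)
        if t >= next_record - 1e-12 * config.record_interval:
            times.append(t)
            snaps.append(n.copy())
            next_record += config.record_interval
    if times[-1] < t:
        times.append(t)
        snaps.append(n.copy())

    extinct = n / L < 1e-6
    return Trajectory(
        times=np.asarray(times),
        populations=np.asarray(snaps),
        L=L,
        converged=False,
        extinct_mask=extinct,
    )


def write_trajectory(
    traj: Trajectory,
    csv_path,
    config: StochasticConfig | None = None,
) -> None:
    """Export a trajectory as CSV (time, n_1..n_m) with a JSON sidecar.

    When ``config`` is given, the sidecar (``<csv_path>.json``) records the
    seed, quantum and stepping parameters needed to reproduce the run.
    """
    import dataclasses
    import json
    from pathlib import Path

    path = Path(csv_path)
    traj.to_frame().to_csv(path, index=False)
    if config is not None:
        sidecar = dataclasses.asdict(config)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )
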