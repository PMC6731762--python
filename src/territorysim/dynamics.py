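"""Deterministic population dynamics and steady-state analysis.

Territory growth: each species gains territory at rate
``v * sum_i alpha_sigma_i * int c_i dx`` (the integral over its own segment
of the quasi-steady nutrient field) and loses it at the death rate ``delta``.
Because ``delta = v * S_total``, the total territory is exactly conserved and
the population vector moves on the simplex ``sum n_sigma = L``.

The well-mixed limit (``tau_D = 0``, instantaneous diffusion) replaces the
spatial field by the uniform concentrations
``c_i = S_i L / sum_sigma n_sigma alpha_sigma_i``; any community whose
aggregate consumption produces ``c_i = S_total / E`` for every nutrient is a
fixed point, giving an (m - p)-dimensional degenerate manifold.  For small
positive ``tau_D`` that manifold becomes a slow manifold with relaxation time
scaling like ``1 / tau_D``, which this module quantifies via a finite
difference Jacobian restricted to the conservation hyperplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .model import CommunityState, ModelParams, NutrientSupply, StrategySet
from .nutrients import (
    _HAVE_NUMBA,
    _segment_integrals_arrays,
    _solve_field_arrays,
    _uptake_exp_kernel,
)

__all__ = [
    "Trajectory",
    "StabilityResult",
    "growth_rates",
    "well_mixed_rates",
    "integrate_to_steady_state",
    "relaxation_time",
]


@dataclass
class Trajectory:
    """Time series of a community integration.

    ``populations`` has one row per recorded time; ``extinct_mask`` flags
    species below the extinction threshold at the final time.
    """

    times: np.ndarray                    # (T,)
    populations: np.ndarray              # (T, m)
    L: float
    converged: bool
    extinct_mask: np.ndarray             # (m,) bool
    extinction_threshold: float = 1e-6
    rate_tol: float = field(default=np.nan, repr=False)

    @property
    def steady_state(self) -> CommunityState:
        """Final community state (steady if ``converged`` is True)."""
        return CommunityState(self.populations[-1], self.L)

    @property
    def states(self) -> list[CommunityState]:
        return [CommunityState(row, self.L) for row in self.populations]

    def to_frame(self):
        """Trajectory as a pandas DataFrame with columns ``time, n_1..n_m``."""
        import pandas as pd

        m = self.populations.shape[1]
        data = {"time": self.times}
        for j in range(m):
            data[f"n_{j + 1}"] = self.populations[:, j]
        return pd.DataFrame(data)


def _spatial_rates_active(
    n_act: np.ndarray,
    alpha_act: np.ndarray,
    S: np.ndarray,
    D: float,
    v: float,
    delta: float,
) -> np.ndarray:
    """Growth rates of the occupied segments (hot path, array in/out)."""
    if _HAVE_NUMBA and alpha_act.min() > 0.0:
        integrals = _uptake_exp_kernel(n_act, alpha_act, S, D)
    else:
        pieces = _solve_field_arrays(n_act, alpha_act, S, D)
        integrals = _segment_integrals_arrays(n_act, S, D, *pieces)
    return v * (alpha_act * integrals).sum(axis=1) - delta * n_act


def _well_mixed_rates_active(
    n_act: np.ndarray,
    alpha_act: np.ndarray,
    S: np.ndarray,
    L: float,
    v: float,
    delta: float,
) -> np.ndarray:
    consumption = n_act @ alpha_act                    # (p,)
    missing = (consumption <= 0) & (S > 0)
    if np.any(missing):
        bad = np.flatnonzero(missing)
        raise ValueError(
            f"nutrient(s) {bad.tolist()} are supplied but have no consumer "
            "with positive population"
        )
    c = np.zeros_like(S)
    np.divide(S * L, consumption, out=c, where=consumption > 0)
    return n_act * (v * (alpha_act @ c) - delta)


def growth_rates(
    state: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
) -> np.ndarray:
    """Per-species territory growth rates ``dn_sigma/dt`` (spatial model).

    Unoccupied species (``n_sigma = 0``) have zero rate: extinction is
    absorbing.  The returned vector sums to zero analytically (territory
    conservation); numerically to ~1e-10 of ``v * S_total * L``.
    """
    if params.well_mixed:
        return well_mixed_rates(state, strategies, supply, params)
    rates = np.zeros(state.m)
    act = state.n > 0
    rates[act] = _spatial_rates_active(
        state.n[act], strategies.alpha[act], supply.S, params.D, params.v,
        params.delta,
    )
    return rates


def well_mixed_rates(
    state: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
) -> np.ndarray:
    """Growth rates in the instantaneous-diffusion (``tau_D = 0``) limit.

    Uses uniform concentrations ``c_i = S_i L / sum_sigma n_sigma alpha_sigma_i``
    and ``dn_sigma/dt = n_sigma (v sum_i alpha_sigma_i c_i - delta)``.
    """
    return _well_mixed_rates_active(
        state.n, strategies.alpha, supply.S, state.L, params.v, params.delta
    )


def integrate_to_steady_state(
    initial: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
    rate_tol: float = 1e-10,
    t_max: float | None = None,
    extinction_threshold: float = 1e-6,
    remove_extinct: bool = True,
    rtol: float = 1e-8,
    atol: float | None = None,
    record: bool = True,
) -> Trajectory:
    """Integrate the population dynamics until steady state (or ``t_max``).

    The stiff-capable adaptive integrator (LSODA) is run in geometrically
    growing time windows; after each window the total territory is
    renormalized to ``L`` (guarding against slow drift of the conserved sum)
    and steadiness is declared when ``max_sigma |dn_sigma/dt| / L < rate_tol``.
    With ``remove_extinct`` (default) a species crossing
    ``extinction_threshold * L`` from above is clamped to zero and removed
    from the boundary-matching chain, its neighbors becoming adjacent;
    otherwise species are only classified post hoc.  The well-mixed path is
    taken automatically when ``params.tau_D == 0``.
    """
    if rate_tol <= 0:
        raise ValueError("rate_tol must be positive")
    if not 0 < extinction_threshold < 1:
        raise ValueError("extinction_threshold must lie in (0, 1)")
    L, v, delta = params.L, params.v, params.delta
    if t_max is None:
        t_max = 1e5 / delta
    if atol is None:
        atol = 1e-12 * L
    S = supply.S
    alpha_full = strategies.alpha
    well_mixed = params.well_mixed
    floor = extinction_threshold * L

    n = initial.n.astype(float).copy()
    alive = n > 0
    times = [0.0]
    snaps = [n.copy()]

    def rates_for(idx: np.ndarray):
        alpha_sub = alpha_full[idx]

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            y = np.maximum(y, 0.0)
            if well_mixed:
                return _well_mixed_rates_active(y, alpha_sub, S, L, v, delta)
            # Segments far below the extinction threshold are dropped from
            # the boundary-matching chain (which would otherwise become
            # ill-conditioned as k*n -> 0) and decay without uptake.
            act = y > 1e-12 * L
            if act.all():
                return _spatial_rates_active(y, alpha_sub, S, params.D, v, delta)
            out = -delta * y
            out[act] = _spatial_rates_active(
                y[act], alpha_sub[act], S, params.D, v, delta
            )
            return out

        return rhs

    def extinction_event(t: float, y: np.ndarray) -> float:
        return y.min() - floor

    extinction_event.terminal = True
    extinction_event.direction = -1.0

    t = 0.0
    window = 20.0 / delta
    converged = False
    while True:
        idx = np.flatnonzero(alive)
        rhs = rates_for(idx)
        r = rhs(t, n[idx])
        if not np.all(np.isfinite(r)):
            raise RuntimeError("non-finite growth rates encountered")
        if np.max(np.abs(r)) / L < rate_tol:
            converged = True
            break
        if t >= t_max:
            break
        t_end = min(t + window, t_max)
        events = extinction_event if (remove_extinct and idx.size > 1) else None
        sol = solve_ivp(
            rhs,
            (t, t_end),
            n[idx],
            method="LSODA",
            rtol=rtol,
            atol=atol,
            events=events,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed at t={t}: {sol.message}")
        if record and sol.t.size > 1:
            block = np.tile(n, (sol.t.size - 1, 1))
            block[:, idx] = sol.y[:, 1:].T
            times.extend(sol.t[1:].tolist())
            snaps.extend(block)
        t = float(sol.t[-1])
        y = sol.y[:, -1].copy()
        if remove_extinct:
            dead = y <= floor * (1.0 + 1e-9)
            if dead.any() and not dead.all():
                y[dead] = 0.0
                alive[idx[dead]] = False
        y = np.maximum(y, 0.0)
        total = y.sum()
        if total <= 0:
            raise RuntimeError("all populations vanished; conservation violated")
        y *= L / total
        n[idx] = y
        n[~alive] = 0.0
        if sol.status != 1:                 # no event: window completed
            window = min(window * 4.0, t_max)

    if times[-1] < t or not record:
        times.append(t)
        snaps.append(n.copy())
    else:
        snaps[-1] = n.copy()                # final row: renormalized state
    populations = np.asarray(snaps)
    times_arr = np.asarray(times)
    if not record:
        times_arr = times_arr[[0, -1]]
        populations = populations[[0, -1]]
    extinct = n / L < extinction_threshold
    return Trajectory(
        times=times_arr,
        populations=populations,
        L=L,
        converged=converged,
        extinct_mask=extinct,
        extinction_threshold=extinction_threshold,
        rate_tol=rate_tol,
    )


@dataclass(frozen=True)
class StabilityResult:
    """Linear stability of a fixed point on the conservation hyperplane.

    ``eigenvalues`` are those of the Jacobian restricted to perturbations of
    the surviving species with ``sum delta_n = 0`` (so there are
    ``m_survivors - 1`` of them).  Modes with ``|lambda|`` below
    ``zero_threshold`` are counted as numerically zero (the degenerate
    manifold of the well-mixed model); ``tslow = -1 / max Re(lambda)`` over
    the nonzero modes (negative if the fixed point is unstable, ``inf`` if
    every mode is numerically zero).
    """

    tslow: float
    eigenvalues: np.ndarray
    n_zero_modes: int
    zero_threshold: float


def relaxation_time(
    steady: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
    fixed_point_tol: float = 1e-6,
    step: float | None = None,
    zero_threshold: float | None = None,
) -> StabilityResult:
    """Eigenvalue spectrum and slow relaxation time at a fixed point.

    The Jacobian of the growth rates is built by central finite differences
    along an orthonormal basis of the conservation hyperplane
    ``sum delta_n = 0`` restricted to the surviving (``n > 0``) species.
    Raises if ``steady`` is not a fixed point to within ``fixed_point_tol``
    (units of ``delta * L``).
    """
    L, delta = params.L, params.delta
    idx = np.flatnonzero(steady.n > 0)
    y0 = steady.n[idx]
    alpha_sub = strategies.alpha[idx]
    S = supply.S

    def rates(y: np.ndarray) -> np.ndarray:
        if params.well_mixed:
            return _well_mixed_rates_active(y, alpha_sub, S, L, params.v, delta)
        return _spatial_rates_active(y, alpha_sub, S, params.D, params.v, delta)

    r0 = rates(y0)
    if np.max(np.abs(r0)) / L > fixed_point_tol * delta:
        raise ValueError(
            f"input is not a fixed point: max |dn/dt|/L = "
            f"{np.max(np.abs(r0)) / L:.3e}"
        )
    if idx.size < 2:
        return StabilityResult(np.inf, np.empty(0, dtype=complex), 0,
                               zero_threshold or 1e-3 * delta)

    h = step if step is not None else max(1e-7 * L, 1e-9)
    Q = null_space(np.ones((1, idx.size)))            # (ms, ms-1) orthonormal
    J = np.empty((idx.size - 1, idx.size - 1))
    for b in range(Q.shape[1]):
        dr = rates(y0 + h * Q[:, b]) - rates(y0 - h * Q[:, b])
        J[:, b] = Q.T @ dr / (2.0 * h)
    eig = np.linalg.eigvals(J)
    zt = zero_threshold if zero_threshold is not None else 1e-3 * delta
    nonzero = np.abs(eig) >= zt
    n_zero = int((~nonzero).sum())
    if nonzero.any():
        max_re = float(eig[nonzero].real.max())
        tslow = np.inf if max_re == 0 else -1.0 / max_re
    else:
        tslow = np.inf
    return StabilityResult(tslow, eig, n_zero, zt)
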