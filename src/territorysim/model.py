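"""Core domain types and random community generation.

The model describes ``m`` territorial species competing for ``p`` diffusing
nutrients on a ring of circumference ``L``.  Each species is defined by a
metabolic strategy: the row of enzyme allocations it devotes to the uptake of
each nutrient, constrained by a total enzyme budget (the metabolic trade-off).
Species occupy non-overlapping segments of the ring whose lengths are the
population sizes, so the community state is an ordered vector of segment
lengths summing to ``L``.

Conventions follow the dimensionless units used throughout the package:
``v = 1`` (nutrient-to-territory conversion), ``S_total = 1`` (total supply
rate) and ``E = 1`` (reference enzyme budget), which force the death rate
``delta = v * S_total = 1``.  All types accept general units; the experiment
drivers use the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "NutrientSupply",
    "StrategySet",
    "CommunityState",
    "sample_strategies",
    "oligotroph_index",
    "is_oligotroph",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical and geometric parameters of the ring ecosystem.

    Parameters
    ----------
    L : float
        Ring circumference (total territory, length units).
    D : float
        Nutrient diffusivity (length^2 / time).  ``np.inf`` denotes the
        well-mixed limit ``tau_D = 0``.
    v : float
        Conversion from nutrient uptake to territory growth
        (length per concentration * time).
    S_total : float
        Total nutrient supply rate (concentration / time).
    E : float
        Reference enzyme budget.

    Notes
    -----
    The death rate is not free: conservation of total territory requires
    ``delta = v * S_total`` exactly, so ``delta`` is a derived property.
    The dimensionless nutrient mixing time is ``tau_D = L**2 * E / D``;
    ``tau_D = 0`` (``D = inf``) is the well-mixed limit.
    """

    L: float = 1.0
    D: float = 1.0
    v: float = 1.0
    S_total: float = 1.0
    E: float = 1.0

    def __post_init__(self) -> None:
        for name in ("L", "v", "S_total", "E"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.D > 0:
            raise ValueError(f"D must be strictly positive (inf allowed), got {self.D!r}")

    @property
    def delta(self) -> float:
        """Death rate; pinned to ``v * S_total`` by territory conservation."""
        return self.v * self.S_total

    @property
    def tau_D(self) -> float:
        """Dimensionless diffusion time ``L**2 * E / D`` (0 when well mixed)."""
        if np.isinf(self.D):
            return 0.0
        return self.L**2 * self.E / self.D

    @property
    def well_mixed(self) -> bool:
        return np.isinf(self.D)

    @classmethod
    def from_tau_D(
        cls,
        tau_D: float,
        L: float = 1.0,
        v: float = 1.0,
        S_total: float = 1.0,
        E: float = 1.0,
    ) -> "ModelParams":
        """Construct parameters from the dimensionless mixing time.

        ``tau_D = 0`` yields ``D = inf`` (instantaneous diffusion).
        """
        if tau_D < 0:
            raise ValueError(f"tau_D must be nonnegative, got {tau_D!r}")
        D = np.inf if tau_D == 0 else L**2 * E / tau_D
        return cls(L=L, D=D, v=v, S_total=S_total, E=E)


@dataclass(frozen=True)
class NutrientSupply:
    """Spatially uniform nutrient supply rates ``S_i`` (concentration/time)."""

    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.atleast_1d(np.asarray(self.S, dtype=float))
        if S.ndim != 1 or S.size == 0:
            raise ValueError("supply must be a nonempty 1-d vector")
        if np.any(S < 0) or not np.all(np.isfinite(S)):
            raise ValueError("supply rates must be finite and nonnegative")
        if S.sum() <= 0:
            raise ValueError("total supply must be positive")
        object.__setattr__(self, "S", S)
        self.S.setflags(write=False)

    @property
    def p(self) -> int:
        return self.S.size

    @property
    def total(self) -> float:
        return float(self.S.sum())

    def normalized(self, E: float = 1.0) -> np.ndarray:
        """Normalized supply ``s = (E / S_total) * S``; sums to ``E``.

        On the same simplex as the strategies, so supply and strategies can
        be compared directly.
        """
        return (E / self.total) * self.S

    @property
    def s(self) -> np.ndarray:
        """Normalized supply in the standard units ``E = 1``."""
        return self.normalized(1.0)

    @classmethod
    def from_fractions(
        cls, s: Sequence[float], S_total: float = 1.0, E: float = 1.0
    ) -> "NutrientSupply":
        """Build a supply from its normalized representation ``s`` (sums to E)."""
        s = np.asarray(s, dtype=float)
        return cls(S=s * S_total / E)


@dataclass(frozen=True)
class StrategySet:
    """Metabolic strategies: an ``m x p`` enzyme-allocation matrix.

    Row ``sigma`` gives the allocation of species ``sigma`` across the ``p``
    nutrients; with exact trade-offs each row sums to the common budget ``E``.
    ``budgets`` holds the per-species totals (relevant when trade-offs are
    inexact).
    """

    alpha: np.ndarray
    budgets: np.ndarray | None = None

    def __post_init__(self) -> None:
        alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if alpha.ndim != 2 or alpha.size == 0:
            raise ValueError("alpha must be a nonempty m x p matrix")
        if np.any(alpha < 0) or not np.all(np.isfinite(alpha)):
            raise ValueError("allocations must be finite and nonnegative")
        row_sums = alpha.sum(axis=1)
        if self.budgets is None:
            budgets = row_sums
        else:
            budgets = np.asarray(self.budgets, dtype=float)
            if budgets.shape != (alpha.shape[0],):
                raise ValueError("budgets must have one entry per species")
            if not np.allclose(row_sums, budgets, rtol=1e-12, atol=0):
                raise ValueError("row sums of alpha must equal the stated budgets")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "budgets", budgets)
        self.alpha.setflags(write=False)
        self.budgets.setflags(write=False)

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def p(self) -> int:
        return self.alpha.shape[1]

    def subset(self, index: np.ndarray) -> "StrategySet":
        """Strategies of the species selected by ``index`` (mask or indices)."""
        return StrategySet(self.alpha[index], self.budgets[index])


@dataclass(frozen=True)
class CommunityState:
    """Ordered segment lengths ``n_sigma`` on the ring.

    Index order is spatial adjacency: species ``sigma`` occupies the segment
    starting at the prefix sum of the preceding lengths, and species ``m``
    neighbors species 1 (periodic wrap).  Lengths are populations, so the
    state doubles as the abundance vector; the total is conserved at ``L``.
    """

    n: np.ndarray
    L: float
    rtol: float = field(default=1e-8, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = np.atleast_1d(np.asarray(self.n, dtype=float))
        if n.ndim != 1 or n.size == 0:
            raise ValueError("n must be a nonempty 1-d vector")
        if np.any(n < 0):
            raise ValueError("segment lengths must be nonnegative")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if abs(n.sum() - self.L) > self.rtol * self.L:
            raise ValueError(
                f"segment lengths sum to {n.sum()!r}, expected L = {self.L!r}"
            )
        object.__setattr__(self, "n", n)
        self.n.setflags(write=False)

    @property
    def m(self) -> int:
        return self.n.size

    @property
    def fractions(self) -> np.ndarray:
        """Relative abundances ``p_sigma = n_sigma / L``."""
        return self.n / self.L

    @property
    def boundaries(self) -> np.ndarray:
        """Ring coordinates of the m segment endpoints (prefix sums)."""
        return np.cumsum(self.n)

    @classmethod
    def equal(cls, m: int, L: float = 1.0) -> "CommunityState":
        """Equal initial populations ``n_sigma = L / m``."""
        return cls(np.full(m, L / m), L)


def _sample_simplex(rng: np.random.Generator, p: int) -> np.ndarray:
    # Normalized i.i.d. exponentials == flat Dirichlet on the (p-1)-simplex.
    g = rng.exponential(size=p)
    return g / g.sum()


def sample_strategies(
    m: int,
    p: int,
    seed: int | np.random.Generator | None = None,
    budget_sd: float = 0.0,
    exclude_oligotrophs: bool = False,
    supply: NutrientSupply | None = None,
    E: float = 1.0,
    max_redraws: int = 100_000,
    shuffle: bool = False,
) -> StrategySet:
    """Draw a random community of ``m`` strategies over ``p`` nutrients.

    Each row is an independent uniform draw from the ``(p-1)``-simplex scaled
    by the species budget.  With ``budget_sd > 0`` the budgets are drawn from
    ``Normal(E, budget_sd)``, redrawing nonpositive values.  With
    ``exclude_oligotrophs`` rows satisfying the oligotroph condition
    ``R_sigma < p`` (see :func:`oligotroph_index`) are rejected and redrawn,
    which requires ``supply``.

    Species are placed on the ring in generation order; ``shuffle`` applies
    a seeded random permutation instead (ring ordering matters to the
    spatial dynamics, not to the well-mixed limit).

    Deterministic given an integer ``seed``; a ``numpy.random.Generator`` may
    be passed instead to share a stream.
    """
    if m < 1 or p < 1:
        raise ValueError("m and p must be positive")
    if budget_sd < 0:
        raise ValueError("budget_sd must be nonnegative")
    if exclude_oligotrophs and supply is None:
        raise ValueError("excluding oligotrophs requires a supply")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    alpha = np.empty((m, p))
    budgets = np.empty(m)
    for sigma in range(m):
        for attempt in range(max_redraws):
            budget = E
            if budget_sd > 0:
                budget = rng.normal(E, budget_sd)
                if budget <= 0:
                    continue
            row = budget * _sample_simplex(rng, p)
            if exclude_oligotrophs and is_oligotroph(row, supply):
                continue
            alpha[sigma] = row
            budgets[sigma] = budget
            break
        else:
            raise RuntimeError(
                f"rejection sampling exceeded {max_redraws} draws for species "
                f"{sigma}; the admissible strategy region has negligible measure"
            )
    if shuffle:
        order = rng.permutation(m)
        alpha, budgets = alpha[order], budgets[order]
    return StrategySet(alpha, budgets)


def oligotroph_index(
    strategy: np.ndarray, supply: NutrientSupply
) -> float:
    """Total steady-state nutrient concentration sustained by an isolated species.

    ``R_sigma = sum_i S_i / alpha_sigma_i`` where ``S_i / alpha_sigma_i`` is
    the uniform concentration of nutrient ``i`` an isolated population with
    uptake ``alpha_sigma_i`` would maintain under supply ``S_i``.  Returns
    ``+inf`` for specialists (``alpha_sigma_i = 0`` with ``S_i > 0``).
    Nutrients with zero supply and zero allocation contribute nothing.

    In the standard units ``S_total = E = 1`` a perfect generalist and a
    supply-matched strategy both give ``R_sigma = p``; strategies with
    ``R_sigma < p`` are oligotrophs.
    """
    strategy = np.atleast_1d(np.asarray(strategy, dtype=float))
    if strategy.shape != supply.S.shape:
        raise ValueError(
            f"strategy has {strategy.size} entries but supply has {supply.p}"
        )
    if np.any(strategy < 0):
        raise ValueError("allocations must be nonnegative")
    S = supply.S
    zero = strategy == 0
    if np.any(zero & (S > 0)):
        return float("inf")
    terms = np.zeros_like(S)
    np.divide(S, strategy, out=terms, where=~zero)
    return float(terms.sum())


def is_oligotroph(strategy: np.ndarray, supply: NutrientSupply) -> bool:
    """True iff ``R_sigma < p`` strictly (units ``S_total = E = 1``).

    Oligotrophs create, and survive on, less than the generalist's total
    nutrient concentration, which lets them drive competitors extinct.
    """
    return oligotroph_index(strategy, supply) < supply.p
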