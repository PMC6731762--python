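"""Shared fixtures and independent numerical oracles.

The finite-difference oracle discretizes the steady-state nutrient equation
directly on a periodic grid and solves the sparse linear system; it shares
no code with the piecewise-analytic solver under test.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from territorysim import (
    CommunityState,
    ModelParams,
    NutrientSupply,
    StrategySet,
)


def fd_steady_state(
    n: np.ndarray,
    alpha: np.ndarray,
    S: np.ndarray,
    D: float,
    N: int = 16384,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference steady state of D c'' - alpha(x) c + S = 0, periodic.

    Cell-centered grid of N points; returns (x, C) with C of shape (N, p).
    Segment boundaries should be aligned to grid edges (lengths that are
    multiples of L/N) for clean convergence.
    """
    L = float(n.sum())
    h = L / N
    x = (np.arange(N) + 0.5) * h
    bounds = np.cumsum(n)
    seg = np.clip(np.searchsorted(bounds, x, side="right"), 0, len(n) - 1)
    p = len(S)
    C = np.empty((N, p))
    lap = D / h**2
    for i in range(p):
        a = alpha[seg, i]
        A = sp.lil_matrix((N, N))
        A.setdiag(-2.0 * lap - a)
        A.setdiag(lap, 1)
        A.setdiag(lap, -1)
        A[0, -1] = lap
        A[-1, 0] = lap
        C[:, i] = spla.spsolve(sp.csc_matrix(A), -np.full(N, S[i]))
    return x, C


def grid_aligned_lengths(
    rng: np.random.Generator, m: int, L: float = 1.0, cells: int = 1024
) -> np.ndarray:
    """Random positive segment lengths that are multiples of L/cells."""
    while True:
        counts = rng.multinomial(cells, rng.dirichlet(np.ones(m)))
        if np.all(counts > 0):
            return counts * (L / cells)


def random_instance(
    rng: np.random.Generator,
    m: int | None = None,
    p: int | None = None,
    tau_range: tuple[float, float] = (1.0, 1000.0),
):
    """A random small community (grid-aligned lengths) for oracle checks."""
    m = int(rng.integers(2, 6)) if m is None else m
    p = int(rng.integers(1, 4)) if p is None else p
    tau = float(10 ** rng.uniform(*np.log10(tau_range)))
    n = grid_aligned_lengths(rng, m)
    alpha = rng.dirichlet(np.ones(p), size=m)
    S = rng.dirichlet(np.ones(p))
    params = ModelParams.from_tau_D(tau)
    return (
        CommunityState(n, 1.0),
        StrategySet(alpha),
        NutrientSupply(S),
        params,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture
def supply_46() -> NutrientSupply:
    """The standard two-nutrient supply s = (0.4, 0.6)."""
    return NutrientSupply.from_fractions((0.4, 0.6))
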