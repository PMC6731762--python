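"""Quasi-steady-state nutrient profiles on the ring.

Nutrient processing is fast compared to population growth, so concentrations
are taken to equilibrate at every population state.  Within the territory of
species ``sigma``, nutrient ``i`` with allocation ``a = alpha[sigma, i] > 0``
then satisfies ``D c'' - a c + S_i = 0``, whose solution in segment-local
coordinates ``x in [0, n_sigma]`` is

    c(x) = S_i / a + A * exp(-k (n_sigma - x)) + B * exp(-k x),   k = sqrt(a / D).

The decaying-exponential basis is used instead of ``exp(+-k x)`` so that all
matrix entries stay in [0, 1] even when ``k n`` is large.  Segments that do
not consume nutrient ``i`` (``a = 0``) carry the parabolic particular solution
``c(x) = -S_i x^2 / (2 D) + A x + B``.  The coefficients are fixed by
continuity and differentiability of ``c`` at every population boundary, with
periodic closure around the ring — a 2m' x 2m' linear system per nutrient
(m' = number of occupied segments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityState, ModelParams, NutrientSupply, StrategySet

try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap

__all__ = [
    "NutrientField",
    "NoSteadyStateError",
    "SingularFieldError",
    "solve_quasistatic_field",
    "field_at",
    "uptake_integrals",
    "profile_frame",
]


class NoSteadyStateError(ValueError):
    """A supplied nutrient is consumed by no occupied species: it accumulates
    without bound and the quasi-steady-state problem is ill posed."""


class SingularFieldError(RuntimeError):
    """The boundary-matching linear system is singular (degenerate geometry)."""


@dataclass(frozen=True)
class NutrientField:
    """Piecewise-analytic steady-state concentration profile.

    All arrays run over the ``m'`` occupied segments (in ring order) and the
    ``p`` nutrients.  ``active`` maps occupied-segment rows back to the
    original species indices of the community state the field was solved for.
    """

    n: np.ndarray            # (m',) occupied segment lengths
    active: np.ndarray       # (m',) original species indices
    m_total: int             # number of species in the solved community state
    starts: np.ndarray       # (m'+1,) prefix sums, starts[-1] == L
    L: float
    D: float
    S: np.ndarray            # (p,) supply rates
    exp_piece: np.ndarray    # (m', p) bool: exponential (True) or parabolic piece
    k: np.ndarray            # (m', p) decay rates sqrt(alpha/D), 0 on parabolic pieces
    part: np.ndarray         # (m', p) uniform particular value S_i/alpha, 0 on parabolic
    coef1: np.ndarray        # (m', p) A (exp) or linear coefficient (parabolic)
    coef2: np.ndarray        # (m', p) B (exp) or constant coefficient (parabolic)

    @property
    def m_active(self) -> int:
        return self.n.size

    @property
    def p(self) -> int:
        return self.S.size

    def concentrations(self, x) -> np.ndarray:
        """Concentration vector(s) at ring coordinate(s) ``x``.

        ``x`` is wrapped onto ``[0, L)``; boundary points belong to the
        segment on their right.  Returns shape ``(p,)`` for scalar ``x`` and
        ``(len(x), p)`` for a 1-d array.
        """
        scalar = np.isscalar(x) or np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float)) % self.L
        seg = np.searchsorted(self.starts[1:], x, side="right")
        seg = np.clip(seg, 0, self.m_active - 1)
        t = x - self.starts[seg]                       # local coordinate
        n = self.n[seg][:, None]
        t = t[:, None]
        k, A, B, P = (arr[seg] for arr in (self.k, self.coef1, self.coef2, self.part))
        exp_piece = self.exp_piece[seg]
        with np.errstate(over="ignore"):
            c_exp = P + A * np.exp(-k * (n - t)) + B * np.exp(-k * t)
        Srow = self.S[None, :]
        c_par = -Srow * t**2 / (2.0 * self.D) + A * t + B
        c = np.where(exp_piece, c_exp, c_par)
        return c[0] if scalar else c

    def segment_integrals(self) -> np.ndarray:
        """Exact per-segment uptake integrals ``int_0^{n} c_i(x) dx``, shape (m', p)."""
        return _segment_integrals_arrays(
            self.n, self.S, self.D, self.exp_piece, self.k, self.part,
            self.coef1, self.coef2,
        )


def _segment_integrals_arrays(
    n: np.ndarray,
    S: np.ndarray,
    D: float,
    exp_piece: np.ndarray,
    k: np.ndarray,
    part: np.ndarray,
    coef1: np.ndarray,
    coef2: np.ndarray,
) -> np.ndarray:
    """Closed-form per-segment integrals of the piecewise solution."""
    ncol = n[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        decay = np.exp(-k * ncol)
        basis_int = np.where(exp_piece, (1.0 - decay) / k, 0.0)
    I_exp = part * ncol + (coef1 + coef2) * basis_int
    I_par = (
        -S[None, :] * ncol**3 / (6.0 * D)
        + coef1 * ncol**2 / 2.0
        + coef2 * ncol
    )
    return np.where(exp_piece, I_exp, I_par)


@_njit(cache=True)
def _uptake_exp_kernel(
    n: np.ndarray, alpha: np.ndarray, S: np.ndarray, D: float
) -> np.ndarray:
    """Per-segment uptake integrals when every allocation is positive.

    Same boundary-matching solve as :func:`_solve_field_arrays`, specialized
    (and JIT-compiled) for the all-exponential case that dominates the
    population-dynamics hot path.
    """
    m, p = alpha.shape
    out = np.empty((m, p))
    if m == 1:
        for i in range(p):
            out[0, i] = S[i] / alpha[0, i] * n[0]
        return out
    M = np.empty((2 * m, 2 * m))
    b = np.empty(2 * m)
    k = np.empty(m)
    E = np.empty(m)
    P = np.empty(m)
    for i in range(p):
        for s in range(m):
            k[s] = np.sqrt(alpha[s, i] / D)
            E[s] = np.exp(-k[s] * n[s])
            P[s] = S[i] / alpha[s, i]
        M[:] = 0.0
        for s in range(m):
            nx = s + 1 if s + 1 < m else 0
            rv = 2 * s
            rd = 2 * s + 1
            M[rv, 2 * s] = 1.0
            M[rv, 2 * s + 1] = E[s]
            M[rv, 2 * nx] = -E[nx]
            M[rv, 2 * nx + 1] = -1.0
            b[rv] = P[nx] - P[s]
            M[rd, 2 * s] = k[s]
            M[rd, 2 * s + 1] = -k[s] * E[s]
            M[rd, 2 * nx] = -k[nx] * E[nx]
            M[rd, 2 * nx + 1] = k[nx]
            b[rd] = 0.0
        sol = np.linalg.solve(M, b)
        for s in range(m):
            A = sol[2 * s]
            B = sol[2 * s + 1]
            out[s, i] = P[s] * n[s] + (A + B) * (1.0 - E[s]) / k[s]
    return out


def _solve_field_arrays(
    n: np.ndarray, alpha: np.ndarray, S: np.ndarray, D: float
) -> tuple[np.ndarray, ...]:
    """Boundary-matching solve over occupied segments only (hot path).

    Returns ``(exp_piece, k, part, coef1, coef2)`` with shapes ``(m', p)``.
    """
    mp, p = alpha.shape
    exp_piece = alpha > 0
    # Nutrients nobody consumes: supplied -> no steady state; unsupplied ->
    # identically-zero concentration (decoupled, coefficient rows left zero).
    consumed = exp_piece.any(axis=0)
    if np.any(~consumed & (S > 0)):
        bad = np.flatnonzero(~consumed & (S > 0))
        raise NoSteadyStateError(
            f"nutrient(s) {bad.tolist()} are supplied but consumed by no "
            "occupied species; concentrations grow without bound"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(exp_piece, np.sqrt(alpha / D), 0.0)
        part = np.where(exp_piece, S[None, :] / alpha, 0.0)
    ncol = n[:, None]
    decay = np.where(exp_piece, np.exp(-k * ncol), 0.0)

    # Basis values/derivatives at the segment ends.  Exponential piece:
    # f1 = exp(-k(n-x)), f2 = exp(-k x).  Parabolic piece: f1 = x, f2 = 1,
    # particular q = -S x^2 / (2D).
    f1r = np.where(exp_piece, 1.0, ncol)
    f1l = decay                                   # 0 on parabolic pieces
    f2r = np.where(exp_piece, decay, 1.0)
    f2l = np.ones_like(f1r)
    g1r = np.where(exp_piece, k, 1.0)
    g1l = np.where(exp_piece, k * decay, 1.0)
    g2r = np.where(exp_piece, -k * decay, 0.0)
    g2l = np.where(exp_piece, -k, 0.0)
    q_r = np.where(exp_piece, part, -S[None, :] * ncol**2 / (2.0 * D))
    q_l = np.where(exp_piece, part, 0.0)
    qd_r = np.where(exp_piece, 0.0, -S[None, :] * ncol / D)

    if mp == 1:
        # Periodic closure of a single segment forces A = B = 0: the field is
        # the uniform particular solution (the parabolic case cannot occur
        # for a supplied nutrient past the consumption check above).
        coef = np.zeros((1, p))
        return exp_piece, k, part, coef, coef.copy()

    sig = np.arange(mp)
    nxt = (sig + 1) % mp
    M = np.zeros((p, 2 * mp, 2 * mp))
    rhs = np.zeros((p, 2 * mp))
    rows_v = 2 * sig
    rows_d = 2 * sig + 1
    # Value matching  c_sig(n_sig) = c_nxt(0)  and derivative matching.
    M[:, rows_v, 2 * sig] = f1r.T
    M[:, rows_v, 2 * sig + 1] = f2r.T
    M[:, rows_v, 2 * nxt] = -f1l[nxt].T
    M[:, rows_v, 2 * nxt + 1] = -f2l[nxt].T
    rhs[:, rows_v] = (q_l[nxt] - q_r[sig]).T
    M[:, rows_d, 2 * sig] = g1r.T
    M[:, rows_d, 2 * sig + 1] = g2r.T
    M[:, rows_d, 2 * nxt] = -g1l[nxt].T
    M[:, rows_d, 2 * nxt + 1] = -g2l[nxt].T
    rhs[:, rows_d] = (-qd_r[sig]).T

    # Unconsumed, unsupplied nutrients have an all-parabolic, singular system
    # with zero RHS; pin their solution to c = 0 via the identity block.
    if not consumed.all():
        idx = np.flatnonzero(~consumed)
        M[idx] = np.eye(2 * mp)[None]
        rhs[idx] = 0.0

    try:
        coef = np.linalg.solve(M, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError as exc:
        raise SingularFieldError(
            "boundary-matching system is singular for this geometry"
        ) from exc
    if not np.all(np.isfinite(coef)):
        raise SingularFieldError("boundary-matching solve produced non-finite values")
    coef1 = coef[:, 0::2].T.copy()
    coef2 = coef[:, 1::2].T.copy()
    return exp_piece, k, part, coef1, coef2


def solve_quasistatic_field(
    state: CommunityState,
    strategies: StrategySet,
    supply: NutrientSupply,
    params: ModelParams,
) -> NutrientField:
    """Solve the steady-state nutrient profile for a community state.

    Zero-length segments are excluded from the matching chain (their
    neighbors become adjacent); at least one segment must be occupied.
    Raises :class:`NoSteadyStateError` when a supplied nutrient has no
    consumer among the occupied segments, and :class:`SingularFieldError` on
    a degenerate matching system.
    """
    if strategies.m != state.m:
        raise ValueError("state and strategies disagree on the number of species")
    if strategies.p != supply.p:
        raise ValueError("strategies and supply disagree on the number of nutrients")
    if not np.isfinite(params.D):
        raise ValueError(
            "the spatial field requires finite D; use the well-mixed dynamics "
            "for tau_D = 0"
        )
    active = np.flatnonzero(state.n > 0)
    if active.size == 0:
        raise ValueError("at least one segment must have positive length")
    n = state.n[active]
    alpha = strategies.alpha[active]
    exp_piece, k, part, coef1, coef2 = _solve_field_arrays(n, alpha, supply.S, params.D)
    starts = np.concatenate([[0.0], np.cumsum(n)])
    return NutrientField(
        n=n,
        active=active,
        m_total=state.m,
        starts=starts,
        L=state.L,
        D=params.D,
        S=supply.S,
        exp_piece=exp_piece,
        k=k,
        part=part,
        coef1=coef1,
        coef2=coef2,
    )


def field_at(field: NutrientField, x) -> np.ndarray:
    """Evaluate the concentration vector at ring coordinate ``x`` (wrapped)."""
    return field.concentrations(x)


def uptake_integrals(
    field: NutrientField,
    state: CommunityState | None = None,
    strategies: StrategySet | None = None,
) -> np.ndarray:
    """Per-species, per-nutrient territory integrals ``int_0^{n_sigma} c_i dx``.

    Closed-form integration of the exponential/parabolic pieces (no
    quadrature).  Returns an ``m x p`` matrix aligned with the community
    state the field was solved for; rows of unoccupied species are zero.
    ``state``/``strategies`` are accepted for interface symmetry and, when
    given, validated against the field.
    """
    if state is not None and state.n[field.active].shape != field.n.shape:
        raise ValueError("state does not match the field's occupied segments")
    if state is not None and not np.allclose(
        state.n[field.active], field.n, rtol=1e-12, atol=0
    ):
        raise ValueError("field was solved for a different community state")
    out = np.zeros((field.m_total, field.p))
    out[field.active] = field.segment_integrals()
    return out


def profile_frame(field: NutrientField, num: int = 512):
    """Sampled concentration profile as a pandas DataFrame.

    Columns: ``x``, ``c_1`` ... ``c_p`` and ``species_index`` (the original
    species occupying each sample point), suitable for CSV export and
    plotting of the spatial nutrient environment.
    """
    import pandas as pd

    x = np.linspace(0.0, field.L, num, endpoint=False)
    c = field.concentrations(x)
    seg = np.clip(
        np.searchsorted(field.starts[1:], x, side="right"), 0, field.m_active - 1
    )
    data = {"x": x}
    for i in range(field.p):
        data[f"c_{i + 1}"] = c[:, i]
    data["species_index"] = field.active[seg]
    return pd.DataFrame(data)
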