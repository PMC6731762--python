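"""Diversity and survival statistics.

Abundances are territory fractions ``p_sigma = n_sigma / L``.  Diversity is
reported as the effective number of species ``M = exp(H)`` with ``H`` the
Shannon entropy in nats — the number of equally abundant species that would
produce the same entropy (the Hill number of order 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CommunityState

__all__ = [
    "DiversitySummary",
    "effective_species",
    "survival_fraction",
    "rank_abundance",
    "summarize",
]


def _fractions(populations) -> np.ndarray:
    if isinstance(populations, CommunityState):
        n = populations.n
    else:
        n = np.atleast_1d(np.asarray(populations, dtype=float))
    if np.any(n < 0):
        raise ValueError("abundances must be nonnegative")
    total = n.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    return n / total


@dataclass(frozen=True)
class DiversitySummary:
    """Shannon entropy H (nats), effective species number M = exp(H),
    survival fraction at the extinction threshold, and the descending
    rank-abundance vector."""

    H: float
    M: float
    survival_fraction: float
    rank_abundance: np.ndarray


def effective_species(populations) -> float:
    """Effective number of species ``M = exp(H)``, ``H = -sum p log p``.

    Zero abundances contribute nothing (the ``0 log 0 = 0`` convention).
    ``M`` ranges from 1 (a single survivor) to ``m`` (all equal).
    """
    p = _fractions(populations)
    p = p[p > 0]
    H = float(-(p * np.log(p)).sum())
    return float(np.exp(H))


def survival_fraction(populations, threshold: float = 1e-6) -> float:
    """Fraction of species with ``n_sigma / L >= threshold``.

    A population below the threshold fraction of the total territory is
    classified extinct.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(populations, CommunityState):
        frac = populations.fractions
    else:
        n = np.atleast_1d(np.asarray(populations, dtype=float))
        frac = n / n.sum()
    return float(np.mean(frac >= threshold))


def rank_abundance(populations) -> np.ndarray:
    """Relative abundances sorted in descending order (sums to 1)."""
    return np.sort(_fractions(populations))[::-1]


def summarize(populations, threshold: float = 1e-6) -> DiversitySummary:
    """All diversity statistics of a community in one pass."""
    M = effective_species(populations)
    return DiversitySummary(
        H=float(np.log(M)),
        M=M,
        survival_fraction=survival_fraction(populations, threshold),
        rank_abundance=rank_abundance(populations),
    )
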