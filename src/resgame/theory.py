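"""Analytic references: neutral expected richness and pairwise game structure.

The neutral benchmark is the expected species count of the infinite-alleles
Wright-Fisher community (unified neutral theory of biodiversity), governed by
the fundamental biodiversity number ``theta = 2 * N * nu``:

    S = sum_{k=0}^{N-1} theta / (theta + k),   with the k = 0 term == 1.

The game census classifies each unordered species pair by its 2x2 payoff
submatrix using the invasion conditions: a pair is a *coexistence* game when
each species can invade the other as a rare mutant (``a21 > a11`` and
``a12 > a22``), a *bistability* (coordination) game when each resident
resists invasion, and *dominance* when exactly one invasion succeeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PayoffMatrix
from .errors import InvalidParameterError

__all__ = [
    "GameCensus",
    "neutral_expected_diversity",
    "classify_pair_game",
    "is_prisoners_dilemma",
    "game_census",
    "GAME_LABELS",
]

GAME_LABELS = ("coexistence", "bistability", "dominance", "degenerate")


@dataclass(frozen=True)
class GameCensus:
    """Fractions of each 2x2 game type among all unordered species pairs."""

    n_pairs: int
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_pairs > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidParameterError("census fractions must sum to 1")


def neutral_expected_diversity(community_size: int, mutation_prob: float) -> float:
    """Expected neutral species richness for a community of size N.

    Direct summation of ``theta/(theta+k)`` over ``k = 0..N-1`` with
    ``theta = 2*N*nu``; the k = 0 term is 1 (its ``theta -> 0`` limit), so
    S = 1 when mutation is absent.
    """
    if community_size < 1:
        raise InvalidParameterError("community_size must be >= 1")
    if mutation_prob < 0:
        raise InvalidParameterError("mutation_prob must be >= 0")
    theta = 2.0 * community_size * mutation_prob
    if theta == 0.0 or community_size == 1:
        return 1.0
    k = np.arange(1, community_size)
    return 1.0 + float(np.sum(theta / (theta + k)))


def classify_pair_game(a11: float, a12: float, a21: float, a22: float) -> str:
    """Classify a 2x2 payoff submatrix by its invasion structure.

    Species 2 invades a resident species-1 population iff ``a21 > a11``;
    species 1 invades resident 2 iff ``a12 > a22``.  Exact ties in either
    comparison are reported as ``degenerate`` (probability zero under
    continuous traits) rather than silently assigned.
    """
    inv2 = a21 - a11  # can 2 invade 1?
    inv1 = a12 - a22  # can 1 invade 2?
    if inv2 == 0.0 or inv1 == 0.0:
        return "degenerate"
    if inv2 > 0.0 and inv1 > 0.0:
        return "coexistence"
    if inv2 < 0.0 and inv1 < 0.0:
        return "bistability"
    return "dominance"


def is_prisoners_dilemma(a11: float, a12: float, a21: float, a22: float) -> bool:
    """Dominance subtype with the conventional ordering a21 > a11 > a22 > a12."""
    return a21 > a11 > a22 > a12


def game_census(matrix: PayoffMatrix | np.ndarray) -> GameCensus:
    """Census of the 2x2 subgames over all unordered species pairs.

    With fewer than two species there are no pairs and the census is empty.
    """
    entries = matrix.entries if isinstance(matrix, PayoffMatrix) else np.asarray(matrix)
    n = entries.shape[0]
    if n < 2:
        return GameCensus(n_pairs=0, fractions={})
    iu, ju = np.triu_indices(n, k=1)
    inv_j = entries[ju, iu] - entries[iu, iu]  # j invades resident i
    inv_i = entries[iu, ju] - entries[ju, ju]  # i invades resident j
    tie = (inv_j == 0.0) | (inv_i == 0.0)
    coex = ~tie & (inv_j > 0.0) & (inv_i > 0.0)
    bist = ~tie & (inv_j < 0.0) & (inv_i < 0.0)
    dom = ~(tie | coex | bist)
    n_pairs = iu.size
    fractions = {
        "coexistence": float(coex.sum()) / n_pairs,
        "bistability": float(bist.sum()) / n_pairs,
        "dominance": float(dom.sum()) / n_pairs,
        "degenerate": float(tie.sum()) / n_pairs,
    }
    return GameCensus(n_pairs=int(n_pairs), fractions=fractions)
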