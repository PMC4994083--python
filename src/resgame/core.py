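"""Deterministic per-generation mathematics of the resource-competition game.

A community of ``n`` species (``N`` individuals in total) competes for ``M``
substitutable-in-supply but individually essential resources.  Each species
consumes a fixed subset of ``M_cons`` resources with half-saturation constants
``K_{m,i}`` constrained by the trade-off ``sum_m K_{m,i} = M_cons / 2``.  The
per-generation pipeline implemented here is:

1. per-capita availability ``R_m = R'_m / N_m`` from the current consumer
   counts ``N_m``;
2. capability ``mu_i = min_m R_m / (R_m + K_{m,i})`` (law of the minimum over
   Monod terms), a number in (0, 1);
3. payoff matrix ``a_ij = -1 / (1 + exp(mu_i - mu_j))`` off-diagonal,
   ``a_ii = mu_i - 1`` on the diagonal, all entries in (-1, 0);
4. mean payoff ``pi_i`` of a focal individual against its N-1 partners;
5. fitness ``f_i = exp(w * pi_i)``.

Everything here is pure and deterministic given its inputs; the stochastic
reproduction step lives in :mod:`resgame.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import InternalConsistencyError, InvalidParameterError

__all__ = [
    "ResourceEnvironment",
    "SpeciesTraits",
    "CommunityState",
    "PayoffMatrix",
    "ModelParams",
    "sample_environment",
    "spawn_species",
    "consumer_counts",
    "capability",
    "capabilities",
    "payoff_matrix",
    "average_payoffs",
    "fitness",
]

#: absolute tolerance on the half-saturation trade-off sum
TRADEOFF_ATOL = 1e-9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResourceEnvironment:
    """The fixed resource supplies of a run.

    Parameters
    ----------
    supplies
        Total supply ``R'_m`` of each of the ``M`` resources.  Drawn once at
        run initialisation and held constant (homogeneous constant
        environment).
    r_max
        Upper bound of the uniform supply distribution.
    """

    supplies: np.ndarray
    r_max: float

    def __post_init__(self) -> None:
        supplies = np.asarray(self.supplies, dtype=float)
        if supplies.ndim != 1 or supplies.size < 1:
            raise InvalidParameterError("supplies must be a non-empty 1-D array")
        if self.r_max <= 0:
            raise InvalidParameterError(f"r_max must be positive, got {self.r_max}")
        if not (np.all(supplies > 0) and np.all(supplies < self.r_max)):
            raise InvalidParameterError(
                "every supply must lie strictly inside (0, r_max)"
            )
        supplies.setflags(write=False)
        object.__setattr__(self, "supplies", supplies)

    @property
    def num_resources(self) -> int:
        return int(self.supplies.size)


@dataclass(frozen=True)
class SpeciesTraits:
    """Identity and resource-use traits of one species.

    ``consumed`` lists the M_cons resource indices the species depends on;
    ``k_values`` holds the matching half-saturation constants, which satisfy
    the efficiency trade-off ``sum(k_values) == M_cons / 2``.
    """

    species_id: int
    consumed: tuple[int, ...]
    k_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.consumed) != len(self.k_values):
            raise InvalidParameterError("consumed and k_values length mismatch")
        if len(set(self.consumed)) != len(self.consumed):
            raise InvalidParameterError("consumed resource indices must be distinct")
        if any(k <= 0 for k in self.k_values):
            raise InvalidParameterError("half-saturation constants must be positive")
        target = len(self.consumed) / 2.0
        if abs(sum(self.k_values) - target) > TRADEOFF_ATOL:
            raise InvalidParameterError(
                f"half-saturation constants must sum to {target} "
                f"(trade-off constraint), got {sum(self.k_values)}"
            )

    @property
    def half_saturation(self) -> Mapping[int, float]:
        """Map from consumed resource index to its K value."""
        return dict(zip(self.consumed, self.k_values))


@dataclass(frozen=True)
class ModelParams:
    """All model-level parameters of a run (excluding schedule and seed)."""

    community_size: int  # N
    num_resources: int  # M
    num_consumed: int  # M_cons
    r_max: float  # R_Max
    selection_intensity: float  # w
    mutation_prob: float  # nu
    frequency_dependent: bool = True

    def __post_init__(self) -> None:
        if self.community_size < 2:
            raise InvalidParameterError("community_size must be >= 2")
        if not (1 <= self.num_consumed <= self.num_resources):
            raise InvalidParameterError(
                f"need 1 <= num_consumed <= num_resources, got "
                f"M_cons={self.num_consumed}, M={self.num_resources}"
            )
        if self.r_max <= 0:
            raise InvalidParameterError("r_max must be positive")
        if self.selection_intensity < 0:
            raise InvalidParameterError("selection_intensity must be >= 0")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise InvalidParameterError("mutation_prob must lie in [0, 1]")


class CommunityState:
    """The current community: species traits and integer abundances.

    Internally array-backed for speed: row ``i`` of ``consumed`` /
    ``half_sat`` holds the traits of the species with label ``ids[i]`` and
    abundance ``abundance[i]``.  Abundances always sum to the fixed community
    size ``N``; extinct species carry no row.  The :attr:`members` property
    exposes the (SpeciesTraits, abundance) view.
    """

    __slots__ = (
        "ids",
        "consumed",
        "half_sat",
        "abundance",
        "community_size",
        "generation",
        "next_species_id",
    )

    def __init__(
        self,
        ids: np.ndarray,
        consumed: np.ndarray,
        half_sat: np.ndarray,
        abundance: np.ndarray,
        community_size: int,
        generation: int = 0,
        next_species_id: int | None = None,
    ) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.consumed = np.asarray(consumed, dtype=np.int64)
        self.half_sat = np.asarray(half_sat, dtype=float)
        self.abundance = np.asarray(abundance, dtype=np.int64)
        self.community_size = int(community_size)
        self.generation = int(generation)
        self.next_species_id = (
            int(self.ids.max()) + 1 if next_species_id is None else int(next_species_id)
        )

    @classmethod
    def from_members(
        cls,
        members: list[tuple[SpeciesTraits, int]],
        community_size: int,
        generation: int = 0,
        next_species_id: int | None = None,
    ) -> "CommunityState":
        ids = np.array([t.species_id for t, _ in members], dtype=np.int64)
        consumed = np.array([t.consumed for t, _ in members], dtype=np.int64)
        half_sat = np.array([t.k_values for t, _ in members], dtype=float)
        abundance = np.array([a for _, a in members], dtype=np.int64)
        state = cls(
            ids, consumed, half_sat, abundance, community_size, generation,
            next_species_id,
        )
        state.validate()
        return state

    def __len__(self) -> int:
        return int(self.ids.size)

    @property
    def num_species(self) -> int:
        return len(self)

    @property
    def members(self) -> list[tuple[SpeciesTraits, int]]:
        return [
            (
                SpeciesTraits(
                    int(self.ids[i]),
                    tuple(int(m) for m in self.consumed[i]),
                    tuple(float(k) for k in self.half_sat[i]),
                ),
                int(self.abundance[i]),
            )
            for i in range(len(self))
        ]

    def __iter__(self) -> Iterator[tuple[SpeciesTraits, int]]:
        return iter(self.members)

    def validate(self) -> None:
        """Check the state invariants; raise on violation."""
        if int(self.abundance.sum()) != self.community_size:
            raise InternalConsistencyError(
                f"abundances sum to {int(self.abundance.sum())}, "
                f"expected N={self.community_size}"
            )
        if np.any(self.abundance < 1):
            raise InternalConsistencyError("extinct species present in state")
        if np.unique(self.ids).size != self.ids.size:
            raise InternalConsistencyError("duplicate species ids")


@dataclass(frozen=True)
class PayoffMatrix:
    """The n-by-n competition matrix rebuilt each generation.

    ``entries[i, j]`` is the average gain of a species-``i`` individual in a
    pairwise competition with a species-``j`` individual; rows follow the
    order of the community state the capabilities came from.
    """

    entries: np.ndarray
    capabilities: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return int(self.entries.shape[0])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _open_uniform(rng: np.random.Generator, low: float, high: float, size) -> np.ndarray:
    """Uniform draws on the open interval (low, high): redraw exact endpoints."""
    out = rng.uniform(low, high, size)
    bad = out <= low  # numpy's uniform is closed at low, open at high
    while np.any(bad):
        out[bad] = rng.uniform(low, high, int(bad.sum()))
        bad = out <= low
    return out


def sample_environment(
    num_resources: int, r_max: float, rng: np.random.Generator
) -> ResourceEnvironment:
    """Draw the M fixed resource supplies, each uniform on (0, r_max)."""
    if num_resources < 1:
        raise InvalidParameterError("num_resources must be >= 1")
    if r_max <= 0:
        raise InvalidParameterError("r_max must be positive")
    supplies = _open_uniform(rng, 0.0, r_max, num_resources)
    return ResourceEnvironment(supplies=supplies, r_max=float(r_max))


def _draw_traits_arrays(
    num_resources: int, num_consumed: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Raw trait draw: (consumed indices, K values) as arrays.

    K values are M_cons independent U(0,1) draws normalised to sum to
    M_cons/2: symmetric across resources and strictly positive.
    """
    consumed = rng.choice(num_resources, size=num_consumed, replace=False)
    u = _open_uniform(rng, 0.0, 1.0, num_consumed)
    k = u * (num_consumed / 2.0 / u.sum())
    return consumed, k


def spawn_species(
    num_resources: int,
    num_consumed: int,
    species_id: int,
    rng: np.random.Generator,
) -> SpeciesTraits:
    """Create a brand-new species with random resource-use traits.

    The consumed subset is a uniform random ``num_consumed``-subset of the
    ``num_resources`` resource indices; half-saturation constants are strictly
    positive and sum to ``num_consumed / 2`` (efficiency trade-off).
    """
    if not (1 <= num_consumed <= num_resources):
        raise InvalidParameterError(
            f"need 1 <= num_consumed <= num_resources, got "
            f"M_cons={num_consumed}, M={num_resources}"
        )
    consumed, k = _draw_traits_arrays(num_resources, num_consumed, rng)
    # re-balance the last element so the sum is exact to float precision
    k[-1] = num_consumed / 2.0 - k[:-1].sum()
    return SpeciesTraits(
        species_id=int(species_id),
        consumed=tuple(int(m) for m in consumed),
        k_values=tuple(float(v) for v in k),
    )


def consumer_counts(state: CommunityState, num_resources: int) -> np.ndarray:
    """Number of individuals consuming each resource, ``N_m``.

    Entry ``m`` sums the abundances of all species whose consumed subset
    contains resource ``m``.
    """
    counts = np.zeros(num_resources, dtype=np.int64)
    np.add.at(
        counts,
        state.consumed.ravel(),
        np.repeat(state.abundance, state.consumed.shape[1]),
    )
    return counts


def capability(
    traits: SpeciesTraits, env: ResourceEnvironment, counts: np.ndarray
) -> float:
    """Capability mu of one species: min over consumed resources of the
    Monod term ``R_m / (R_m + K)`` at per-capita availability
    ``R_m = R'_m / N_m``."""
    idx = np.asarray(traits.consumed, dtype=np.int64)
    n_m = np.asarray(counts)[idx]
    if np.any(n_m < 1):
        raise InternalConsistencyError(
            "a live species consumes a resource with zero consumers"
        )
    r = env.supplies[idx] / n_m
    k = np.asarray(traits.k_values, dtype=float)
    return float(np.min(r / (r + k)))


def capabilities(state: CommunityState, env: ResourceEnvironment) -> np.ndarray:
    """Vector of capabilities mu_i for every species in the state."""
    counts = consumer_counts(state, env.num_resources)
    n_m = counts[state.consumed]  # (n, M_cons)
    if np.any(n_m < 1):
        raise InternalConsistencyError(
            "a live species consumes a resource with zero consumers"
        )
    r = env.supplies[state.consumed] / n_m
    return np.min(r / (r + state.half_sat), axis=1)


def payoff_matrix(capabilities: np.ndarray) -> PayoffMatrix:
    """Build the dynamical payoff matrix from the capability vector.

    Off-diagonal: ``a_ij = -1 / (1 + exp(mu_i - mu_j))`` — the better
    competitor's entry is closer to 0, the worse one's closer to -1, and the
    pair always satisfies ``a_ij + a_ji = -1``.  Diagonal:
    ``a_ii = mu_i - 1`` — intraspecific competition softens as resources
    become plentiful for the species.
    """
    mu = np.asarray(capabilities, dtype=float)
    if mu.ndim != 1 or np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise InvalidParameterError("capabilities must be a 1-D vector in (0, 1)")
    entries = -1.0 / (1.0 + np.exp(mu[:, None] - mu[None, :]))
    np.fill_diagonal(entries, mu - 1.0)
    return PayoffMatrix(entries=entries, capabilities=mu)


def average_payoffs(matrix: PayoffMatrix, state: CommunityState) -> np.ndarray:
    """Mean payoff pi_i of a focal individual of each species.

    A focal individual interacts with the other N-1 individuals, so its own
    self-interaction is removed from the abundance-weighted row sum:
    ``pi_i = (sum_j a_ij N_j - a_ii) / (N - 1)``.
    """
    if state.community_size < 2:
        raise InvalidParameterError("community_size must be >= 2")
    if matrix.n != len(state):
        raise InvalidParameterError("matrix size does not match community state")
    return _average_payoffs_raw(
        matrix.entries, state.abundance, state.community_size
    )


def _average_payoffs_raw(
    entries: np.ndarray, abundance: np.ndarray, community_size: int
) -> np.ndarray:
    diag = np.diagonal(entries)
    return (entries @ abundance - diag) / (community_size - 1)


def fitness(payoffs: np.ndarray, selection_intensity: float) -> np.ndarray:
    """Exponential payoff-to-fitness map ``f_i = exp(w * pi_i)``.

    Strictly positive for any payoff; ``w = 0`` gives the neutral model.
    """
    if selection_intensity < 0:
        raise InvalidParameterError("selection_intensity must be >= 0")
    return np.exp(selection_intensity * np.asarray(payoffs, dtype=float))
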