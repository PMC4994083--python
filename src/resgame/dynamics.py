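"""Stochastic engine: Wright-Fisher reproduction with speciation mutations.

Each generation the whole community is replaced: capabilities, the payoff
matrix, mean payoffs and fitness are recomputed from the current state, N
offspring are drawn from a multinomial with probabilities proportional to
``f_i * N_i``, and each offspring independently founds a brand-new species
with probability ``nu`` (traits drawn fresh, not inherited).  Species left
with zero individuals are removed.  The community size N is strictly
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import core
from .core import CommunityState, ModelParams, ResourceEnvironment
from .errors import ConfigurationError, InvalidParameterError, NumericalDegeneracyError

__all__ = [
    "GenerationEvent",
    "Trajectory",
    "RunResult",
    "wright_fisher_step",
    "frequency_independent_step",
    "initial_state",
    "run",
]


@dataclass(frozen=True)
class GenerationEvent:
    """Mutations and extinctions that occurred in one generation."""

    generation: int
    mutation_count: int
    extinctions: tuple[int, ...] = ()


@dataclass
class Trajectory:
    """Recorded output of a run.

    ``richness`` is always recorded (one entry per sampled generation);
    full abundance ``records`` and per-sample capability vectors are
    optional.  ``events`` lists only generations in which at least one
    mutation or extinction happened.
    """

    sampling_interval: int
    burn_in: int
    sampled_generations: list[int] = field(default_factory=list)
    richness: list[int] = field(default_factory=list)
    records: list[tuple[int, int, int]] | None = None
    capability_samples: list[np.ndarray] | None = None
    events: list[GenerationEvent] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sampled_generations)

    @property
    def total_mutations(self) -> int:
        return sum(e.mutation_count for e in self.events)

    def richness_array(self) -> np.ndarray:
        return np.asarray(self.richness, dtype=np.int64)

    def _sample(self, state: CommunityState, mu: np.ndarray | None) -> None:
        self.sampled_generations.append(state.generation)
        self.richness.append(len(state))
        if self.records is not None:
            g = state.generation
            self.records.extend(
                (g, int(s), int(a)) for s, a in zip(state.ids, state.abundance)
            )
        if self.capability_samples is not None:
            self.capability_samples.append(np.asarray(mu, dtype=float))


@dataclass
class RunResult:
    """Trajectory plus everything needed to interpret or reproduce it."""

    trajectory: Trajectory
    final_state: CommunityState
    env: ResourceEnvironment
    params: ModelParams
    seed: int | None


def _step_arrays(
    state: CommunityState,
    env: ResourceEnvironment,
    params: ModelParams,
    rng: np.random.Generator,
    mutants: np.ndarray | None = None,
) -> tuple[CommunityState, GenerationEvent]:
    """One generation. Shared by the public step functions and `run`.

    ``mutants`` lets a caller that already flipped the per-offspring mutation
    coins (the monomorphic fast path in :func:`run`) inject the counts so the
    coins are not flipped twice.
    """
    n = len(state)
    big_n = params.community_size

    if n == 1:
        # single-category multinomial: every offspring descends from the one
        # species regardless of fitness, so the payoff pipeline is skipped
        offspring = np.array([big_n], dtype=np.int64)
    else:
        mu = core.capabilities(state, env)
        if params.frequency_dependent:
            entries = -1.0 / (1.0 + np.exp(mu[:, None] - mu[None, :]))
            np.fill_diagonal(entries, mu - 1.0)
            payoffs = core._average_payoffs_raw(
                entries, state.abundance, big_n
            )
        else:
            # frequency-independent control: only the self-interaction term
            payoffs = mu - 1.0
        weights = np.exp(params.selection_intensity * payoffs) * state.abundance
        total = weights.sum()
        if not np.isfinite(total) or total <= 0.0:
            raise NumericalDegeneracyError(
                "all fitness weights vanished or overflowed; rescale payoffs "
                "(reduce selection_intensity)"
            )
        offspring = rng.multinomial(big_n, weights / total)

    # speciation: each offspring independently founds a new species w.p. nu
    if mutants is None:
        if params.mutation_prob > 0.0:
            mutants = rng.binomial(offspring, params.mutation_prob)
        else:
            mutants = np.zeros_like(offspring)
    n_mut = int(mutants.sum())
    offspring = offspring - mutants

    gen = state.generation + 1
    extinct_mask = offspring == 0
    extinctions = tuple(int(s) for s in state.ids[extinct_mask])

    keep = ~extinct_mask
    next_id = state.next_species_id
    if n_mut == 0:
        new_state = CommunityState(
            state.ids[keep],
            state.consumed[keep],
            state.half_sat[keep],
            offspring[keep],
            big_n,
            gen,
            next_id,
        )
    else:
        mut_consumed = np.empty((n_mut, params.num_consumed), dtype=np.int64)
        mut_k = np.empty((n_mut, params.num_consumed), dtype=float)
        for r in range(n_mut):
            c, k = core._draw_traits_arrays(
                params.num_resources, params.num_consumed, rng
            )
            mut_consumed[r] = c
            mut_k[r] = k
        new_state = CommunityState(
            np.concatenate([state.ids[keep], np.arange(next_id, next_id + n_mut)]),
            np.concatenate([state.consumed[keep], mut_consumed]),
            np.concatenate([state.half_sat[keep], mut_k]),
            np.concatenate([offspring[keep], np.ones(n_mut, dtype=np.int64)]),
            big_n,
            gen,
            next_id + n_mut,
        )
    event = GenerationEvent(gen, n_mut, extinctions)
    return new_state, event


def wright_fisher_step(
    state: CommunityState,
    env: ResourceEnvironment,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[CommunityState, GenerationEvent]:
    """Advance the community by one Wright-Fisher generation.

    Fitness is evaluated from the pre-reproduction state; mutation coins are
    flipped per offspring after sampling; zero-offspring species are pruned.
    Returns the new state (input state is not modified) and the generation's
    event record.
    """
    if int(state.abundance.sum()) != params.community_size:
        raise InvalidParameterError(
            "state abundances do not sum to params.community_size"
        )
    return _step_arrays(state, env, params, rng)


def frequency_independent_step(
    state: CommunityState,
    env: ResourceEnvironment,
    params: ModelParams,
    rng: np.random.Generator,
) -> tuple[CommunityState, GenerationEvent]:
    """One generation of the frequency-independent control model.

    Identical to :func:`wright_fisher_step` except that the payoff of species
    i is its self-interaction term alone, ``pi_i = a_ii = mu_i - 1``, so
    fitness does not depend on the other species' abundances (capabilities
    still respond to consumer counts through the per-capita availability).
    """
    if params.frequency_dependent:
        params = replace(params, frequency_dependent=False)
    return wright_fisher_step(state, env, params, rng)


def initial_state(
    params: ModelParams,
    rng: np.random.Generator,
    init_mode: str = "single",
    init_species: int = 10,
) -> CommunityState:
    """Build the generation-0 community.

    ``single`` starts isogenic: one random species holding all N individuals.
    ``k_species`` starts with ``init_species`` random species at near-equal
    abundances (remainder spread over the first few).
    """
    if init_mode == "single":
        k = 1
    elif init_mode == "k_species":
        k = int(init_species)
        if not (1 <= k <= params.community_size):
            raise ConfigurationError(
                "init_species must lie in [1, community_size]"
            )
    else:
        raise ConfigurationError(f"unknown init_mode: {init_mode!r}")

    consumed = np.empty((k, params.num_consumed), dtype=np.int64)
    half_sat = np.empty((k, params.num_consumed), dtype=float)
    for i in range(k):
        c, kv = core._draw_traits_arrays(
            params.num_resources, params.num_consumed, rng
        )
        consumed[i] = c
        half_sat[i] = kv
    base, rem = divmod(params.community_size, k)
    abundance = np.full(k, base, dtype=np.int64)
    abundance[:rem] += 1
    return CommunityState(
        np.arange(k), consumed, half_sat, abundance, params.community_size,
        generation=0, next_species_id=k,
    )


def run(
    params: ModelParams,
    generations: int,
    *,
    burn_in: int = 0,
    sampling_interval: int = 1,
    init_mode: str = "single",
    init_species: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    env: ResourceEnvironment | None = None,
    record_abundances: bool = True,
    record_capabilities: bool = False,
) -> RunResult:
    """Simulate a community for a fixed number of generations.

    The environment is sampled once (unless supplied) and held fixed.  The
    community is recorded at every ``sampling_interval``-th generation from
    ``burn_in`` onwards.  Fully reproducible from ``seed``.

    Parameters
    ----------
    params
        Model parameters (N, M, M_cons, R_Max, w, nu, frequency flag).
    generations
        Number of Wright-Fisher generations to simulate (>= 0).
    burn_in
        Generations discarded before sampling starts.
    sampling_interval
        Record every this-many generations after burn-in.
    record_abundances
        Keep full (generation, species_id, abundance) records; disable for
        long diversity runs where only richness is needed.
    record_capabilities
        Additionally store the capability vector at each sample (needed for
        the pairwise game census).
    """
    if generations < 0:
        raise InvalidParameterError("generations must be >= 0")
    if sampling_interval < 1:
        raise InvalidParameterError("sampling_interval must be >= 1")
    if burn_in < 0:
        raise InvalidParameterError("burn_in must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if env is None:
        env = core.sample_environment(params.num_resources, params.r_max, rng)

    state = initial_state(params, rng, init_mode, init_species)

    traj = Trajectory(
        sampling_interval=sampling_interval,
        burn_in=burn_in,
        records=[] if record_abundances else None,
        capability_samples=[] if record_capabilities else None,
    )

    def mu_of(s: CommunityState) -> np.ndarray | None:
        if traj.capability_samples is None:
            return None
        return core.capabilities(s, env)

    if burn_in == 0:
        traj._sample(state, mu_of(state))

    nu = params.mutation_prob
    for g in range(1, generations + 1):
        if len(state) == 1:
            # fast path: fitness cannot matter; only the mutation coins do
            n_mut = rng.binomial(params.community_size, nu) if nu > 0 else 0
            if n_mut == 0:
                state.generation = g
            else:
                state, event = _step_arrays(
                    state, env, params, rng,
                    mutants=np.array([n_mut], dtype=np.int64),
                )
                traj.events.append(event)
        else:
            state, event = _step_arrays(state, env, params, rng)
            if event.mutation_count or event.extinctions:
                traj.events.append(event)
        if g >= burn_in and (g - burn_in) % sampling_interval == 0:
            traj._sample(state, mu_of(state))

    return RunResult(
        trajectory=traj, final_state=state, env=env, params=params, seed=seed
    )
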