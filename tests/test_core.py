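"""Unit tests for the deterministic per-generation model mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resgame as rg
from resgame.errors import InternalConsistencyError, InvalidParameterError


# ---------------------------------------------------------------------------
# resource environment
# ---------------------------------------------------------------------------


def test_environment_supplies_strictly_inside_open_interval():
    rng = np.random.default_rng(0)
    env = rg.sample_environment(3, 30.0, rng)
    assert env.num_resources == 3
    assert np.all(env.supplies > 0.0) and np.all(env.supplies < 30.0)


def test_environment_deterministic_under_fixed_seed():
    a = rg.sample_environment(5, 10.0, np.random.default_rng(42))
    b = rg.sample_environment(5, 10.0, np.random.default_rng(42))
    np.testing.assert_array_equal(a.supplies, b.supplies)


def test_environment_shrinks_with_r_max():
    # degenerate bound: as r_max -> 0+ all supplies -> 0
    env = rg.sample_environment(4, 1e-12, np.random.default_rng(1))
    assert np.all(env.supplies < 1e-12)


@pytest.mark.parametrize("m,r_max", [(0, 1.0), (-1, 1.0), (3, 0.0), (3, -2.0)])
def test_environment_invalid_parameters(m, r_max):
    with pytest.raises(InvalidParameterError):
        rg.sample_environment(m, r_max, np.random.default_rng(0))


def test_environment_supplies_immutable(env3):
    with pytest.raises(ValueError):
        env3.supplies[0] = 1.0


# ---------------------------------------------------------------------------
# species traits and the efficiency trade-off
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("m,m_cons", [(7, 5), (3, 3), (5, 1), (2, 2)])
def test_spawned_species_satisfy_tradeoff(m, m_cons, rng):
    for sid in range(200):
        tr = rg.spawn_species(m, m_cons, sid, rng)
        assert len(tr.consumed) == m_cons
        assert len(set(tr.consumed)) == m_cons
        assert all(0 <= c < m for c in tr.consumed)
        assert all(k > 0 for k in tr.k_values)
        assert sum(tr.k_values) == pytest.approx(m_cons / 2.0, abs=1e-9)


def test_single_resource_consumer_has_forced_k(rng):
    tr = rg.spawn_species(5, 1, 0, rng)
    assert tr.k_values == (0.5,)


def test_full_overlap_consumes_every_resource(rng):
    tr = rg.spawn_species(4, 4, 0, rng)
    assert sorted(tr.consumed) == [0, 1, 2, 3]


def test_spawn_rejects_oversized_subset(rng):
    with pytest.raises(InvalidParameterError):
        rg.spawn_species(3, 4, 0, rng)


def test_traits_constructor_enforces_tradeoff():
    with pytest.raises(InvalidParameterError):
        rg.SpeciesTraits(0, (0, 1), (0.3, 0.3))  # sums to 0.6, not 1.0


# ---------------------------------------------------------------------------
# consumer counts
# ---------------------------------------------------------------------------


def _state_of(members, community_size):
    return rg.CommunityState.from_members(members, community_size)


def _traits(sid, consumed, k_values):
    return rg.SpeciesTraits(sid, consumed, k_values)


def test_consumer_counts_single_species():
    st_ = _state_of([(_traits(0, (0, 1), (0.4, 0.6)), 10)], 10)
    np.testing.assert_array_equal(rg.consumer_counts(st_, 3), [10, 10, 0])


def test_consumer_counts_disjoint_subsets():
    st_ = _state_of(
        [
            (_traits(0, (0, 1), (0.4, 0.6)), 3),
            (_traits(1, (2, 3), (0.5, 0.5)), 7),
        ],
        10,
    )
    np.testing.assert_array_equal(rg.consumer_counts(st_, 4), [3, 3, 7, 7])


def test_consumer_counts_shared_resource_sums_to_capacity():
    st_ = _state_of(
        [
            (_traits(0, (1, 0), (0.4, 0.6)), 4),
            (_traits(1, (1, 2), (0.5, 0.5)), 6),
        ],
        10,
    )
    counts = rg.consumer_counts(st_, 3)
    assert counts[1] == 10  # everyone consumes resource 1


# ---------------------------------------------------------------------------
# capability (law of the minimum over Monod terms)
# ---------------------------------------------------------------------------


def test_capability_half_saturation_point():
    # per-capita availability equal to K gives exactly 1/2
    tr = _traits(0, (0,), (0.5,))
    env = rg.ResourceEnvironment(supplies=np.array([5.0]), r_max=100.0)
    counts = np.array([10])  # R_m = 0.5 = K
    assert rg.capability(tr, env, counts) == pytest.approx(0.5)


def test_capability_takes_minimum_over_consumed():
    # availabilities (0.75, 0.75), K = (0.25, 0.75):
    # Monod terms (0.75, 0.5) -> the minimum rule gives mu = 0.5
    tr = _traits(0, (0, 1), (0.25, 0.75))
    env = rg.ResourceEnvironment(supplies=np.array([0.75, 0.75]), r_max=100.0)
    counts = np.array([1, 1])
    assert rg.capability(tr, env, counts) == pytest.approx(0.5)


def test_capability_saturates_to_one():
    tr = _traits(0, (0, 1), (0.3, 0.7))
    env = rg.ResourceEnvironment(supplies=np.array([1e12, 1e12]), r_max=1e13)
    counts = np.array([1, 1])
    assert rg.capability(tr, env, counts) == pytest.approx(1.0, abs=1e-9)


def test_capability_zero_consumer_count_is_internal_error():
    tr = _traits(0, (0,), (0.5,))
    env = rg.ResourceEnvironment(supplies=np.array([5.0]), r_max=100.0)
    with pytest.raises(InternalConsistencyError):
        rg.capability(tr, env, np.array([0]))


def test_capability_monotone_in_k_and_supply(rng):
    """mu is non-increasing in every K and non-decreasing in every supply."""
    env = rg.sample_environment(3, 30.0, rng)
    st_ = _state_of([(_traits(0, (0, 1), (0.4, 0.6)), 5)], 5)
    counts = rg.consumer_counts(st_, 3)
    base_tr = _traits(0, (0, 1), (0.4, 0.6))
    mu0 = rg.capability(base_tr, env, counts)
    # bump each K upwards (renormalisation dropped: direct perturbation)
    for kv in [(0.5, 0.6), (0.4, 0.7)]:
        worse = rg.SpeciesTraits.__new__(rg.SpeciesTraits)
        object.__setattr__(worse, "species_id", 0)
        object.__setattr__(worse, "consumed", (0, 1))
        object.__setattr__(worse, "k_values", kv)
        assert rg.capability(worse, env, counts) <= mu0
    # raise every supply: capability cannot drop
    bigger = rg.ResourceEnvironment(supplies=env.supplies * 2.0, r_max=60.0)
    assert rg.capability(base_tr, bigger, counts) >= mu0


def test_vectorised_capabilities_match_scalar(rng):
    env = rg.sample_environment(4, 20.0, rng)
    members = [
        (rg.spawn_species(4, 2, i, rng), a) for i, a in enumerate([5, 3, 2])
    ]
    st_ = _state_of(members, 10)
    counts = rg.consumer_counts(st_, 4)
    vec = rg.capabilities(st_, env)
    for i, (tr, _) in enumerate(members):
        assert vec[i] == pytest.approx(rg.capability(tr, env, counts), abs=1e-14)


# ---------------------------------------------------------------------------
# payoff matrix
# ---------------------------------------------------------------------------


def test_payoff_matrix_hand_example():
    m = rg.payoff_matrix(np.array([0.2, 0.7]))
    assert m.entries[0, 1] == pytest.approx(-1.0 / (1.0 + np.exp(-0.5)))
    assert m.entries[0, 1] == pytest.approx(-0.6225, abs=5e-5)
    assert m.entries[1, 0] == pytest.approx(-0.3775, abs=5e-5)
    assert m.entries[0, 1] + m.entries[1, 0] == pytest.approx(-1.0, abs=1e-12)
    assert m.entries[0, 0] == pytest.approx(0.2 - 1.0)
    assert m.entries[1, 1] == pytest.approx(0.7 - 1.0)


def test_payoff_matrix_equal_capabilities_give_symmetric_midpoint():
    m = rg.payoff_matrix(np.array([0.4, 0.4, 0.4]))
    off = m.entries[~np.eye(3, dtype=bool)]
    np.testing.assert_allclose(off, -0.5)


def test_payoff_matrix_rejects_capabilities_outside_unit_interval():
    for bad in ([0.0, 0.5], [0.5, 1.0], [-0.1, 0.5], [1.2, 0.5]):
        with pytest.raises(InvalidParameterError):
            rg.payoff_matrix(np.array(bad))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mu=st.lists(
        st.floats(min_value=1e-6, max_value=1.0 - 1e-6),
        min_size=2,
        max_size=12,
    )
)
def test_payoff_matrix_invariants(mu):
    """All entries in (-1, 0); complement identity; advantage antisymmetry."""
    mu = np.asarray(mu)
    m = rg.payoff_matrix(mu)
    assert np.all(m.entries > -1.0) and np.all(m.entries < 0.0)
    off_sum = m.entries + m.entries.T
    np.fill_diagonal(off_sum, -1.0)
    np.testing.assert_allclose(off_sum, -1.0, atol=1e-12)
    np.testing.assert_allclose(np.diagonal(m.entries), mu - 1.0, atol=1e-15)
    for i in range(len(mu)):
        for j in range(len(mu)):
            if mu[i] < mu[j]:
                assert m.entries[i, j] < m.entries[j, i]


# ---------------------------------------------------------------------------
# mean payoff and fitness
# ---------------------------------------------------------------------------


def test_average_payoff_single_species_reduces_to_self_interaction():
    st_ = _state_of([(_traits(0, (0,), (0.5,)), 10)], 10)
    m = rg.payoff_matrix(np.array([0.3]))
    pi = rg.average_payoffs(m, st_)
    assert pi[0] == pytest.approx(m.entries[0, 0], abs=1e-14)


def test_average_payoff_two_singletons_meet_only_each_other():
    st_ = _state_of(
        [(_traits(0, (0,), (0.5,)), 1), (_traits(1, (0,), (0.5,)), 1)], 2
    )
    m = rg.payoff_matrix(np.array([0.3, 0.8]))
    pi = rg.average_payoffs(m, st_)
    assert pi[0] == pytest.approx(m.entries[0, 1], abs=1e-14)
    assert pi[1] == pytest.approx(m.entries[1, 0], abs=1e-14)


def test_average_payoff_hand_example():
    # n=2, N=4, abundances (3,1), a11=-0.4, a12=-0.3 -> pi_1 = -1.1/3
    st_ = _state_of(
        [(_traits(0, (0,), (0.5,)), 3), (_traits(1, (0,), (0.5,)), 1)], 4
    )
    entries = np.array([[-0.4, -0.3], [-0.7, -0.2]])
    m = rg.PayoffMatrix(entries=entries, capabilities=np.array([0.6, 0.8]))
    pi = rg.average_payoffs(m, st_)
    assert pi[0] == pytest.approx(-1.1 / 3.0, abs=1e-12)


def test_average_payoff_matches_individual_level_brute_force(rng):
    """Mean payoff equals the explicit average over the N-1 partners."""
    for _ in range(20):
        n = int(rng.integers(2, 5))
        big_n = int(rng.integers(n, 21))
        ab = rng.multinomial(big_n - n, np.full(n, 1.0 / n)) + 1
        mu = rng.uniform(0.05, 0.95, n)
        m = rg.payoff_matrix(mu)
        members = [
            (_traits(i, (0,), (0.5,)), int(a)) for i, a in enumerate(ab)
        ]
        st_ = _state_of(members, big_n)
        pi = rg.average_payoffs(m, st_)
        # brute force: enumerate individuals, average a[s_f, s_o] over others
        individuals = np.repeat(np.arange(n), ab)
        for i in range(n):
            focal = np.where(individuals == i)[0][0]
            others = np.delete(individuals, focal)
            expected = m.entries[i, others].mean()
            assert pi[i] == pytest.approx(expected, abs=1e-12)


def test_fitness_neutral_and_exponential_values():
    pi = np.array([-0.5, 0.0, -0.2])
    np.testing.assert_allclose(rg.fitness(pi, 0.0), 1.0)
    assert rg.fitness(np.array([0.0]), 7.0)[0] == pytest.approx(1.0)
    assert rg.fitness(np.array([-0.5]), 10.0)[0] == pytest.approx(
        np.exp(-5.0)
    )
    with pytest.raises(InvalidParameterError):
        rg.fitness(pi, -1.0)
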