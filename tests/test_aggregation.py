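import numpy as np
import pytest
from scipy.linalg import expm

from aggphylo import (
    Alignment,
    M0Params,
    RateMatrix,
    aggregate_probability_matrix,
    aggregate_rate_matrix,
    aggregation_scheme,
    build_m0_rate_matrix,
    eigendecompose,
    is_lumpable,
    observed_states,
    transition_matrix,
)
from aggphylo.aggregation import ObservedSet, Partition, identity_partition, site_partitions


def obs(*codon_indices):
    return ObservedSet(site_index=0, codons=frozenset(codon_indices))


class TestObservedStates:
    def test_conserved_column(self, space):
        aln = Alignment(names=("a", "b", "c"), sequences=("TTT", "TTT", "TTT"))
        got = observed_states(aln, 0, space)
        assert got.codons == frozenset({space.index["TTT"]})

    def test_variable_column(self, space):
        aln = Alignment(names=("a", "b", "c"), sequences=("TTT", "TTC", "CTT"))
        assert len(observed_states(aln, 0, space)) == 3

    def test_gap_column_is_empty(self, space):
        aln = Alignment(names=("a", "b"), sequences=("---", "NNN"))
        assert len(observed_states(aln, 0, space)) == 0

    def test_out_of_range_site(self, space):
        aln = Alignment(names=("a",), sequences=("TTT",))
        with pytest.raises(IndexError):
            observed_states(aln, 1, space)


class TestAggregationScheme:
    def test_conserved_site_reduces_to_two_states(self, space):
        part = aggregation_scheme(obs(5), "conserved_only", space)
        assert part.M == 2
        assert part.m == 60  # meta-state holds the 60 other sense codons
        assert part.groups[0] == (5,)

    def test_conserved_strategy_skips_variable_sites(self, space):
        part = aggregation_scheme(obs(5, 6), "conserved_only", space)
        assert part.is_identity

    def test_full_with_everything_observed_is_identity(self, space):
        part = aggregation_scheme(obs(*range(61)), "full", space)
        assert part.is_identity and part.M == 61

    def test_full_keeps_observed_singletons(self, space):
        part = aggregation_scheme(obs(3, 10, 20), "full", space)
        assert part.M == 4
        assert part.groups[:3] == ((3,), (10,), (20,))
        assert len(part.groups[part.aggregated_group]) == 58

    def test_amino_acid_keeps_synonymous_codons(self, space):
        idx = space.index["TTT"]  # Phe; TTC is the only synonym
        part = aggregation_scheme(obs(idx), "amino_acid", space)
        singles = {g[0] for g in part.groups[:-1]}
        assert singles == {space.index["TTT"], space.index["TTC"]}

    def test_random_split_preserves_state_count(self, space):
        full = aggregation_scheme(obs(3, 10, 20), "full", space)
        rand = aggregation_scheme(obs(3, 10, 20), "random_split", space, rng_seed=9)
        assert rand.M == full.M
        assert rand.aggregated_group is None

    def test_unknown_strategy(self, space):
        with pytest.raises(ValueError):
            aggregation_scheme(obs(1), "bogus", space)

    def test_shuffled_partitions_permute_sites(self, space):
        aln = Alignment(names=("a", "b"), sequences=("TTTAAACCC", "TTTAAAGGG"))
        full = site_partitions(aln, "full", space)
        shuf = site_partitions(aln, "random_shuffled", space, seed=1)
        assert sorted(p.groups for p in shuf) == sorted(p.groups for p in full)


class TestLumping:
    @pytest.fixture(scope="class")
    def toy_chain(self):
        """A seeded 4-state reversible chain (P, pi)."""
        rng = np.random.default_rng(1234)
        pi = rng.dirichlet(np.ones(4))
        S = rng.random((4, 4))
        Q = (S + S.T) * pi[None, :]  # detailed balance by construction
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        P = expm(Q * 0.9)
        return P, pi

    def test_single_state_group_is_identity(self, toy_chain):
        P, pi = toy_chain
        part = Partition(groups=((0,), (1,), (2,), (3,)), n_states=4, aggregated_group=3)
        ac = aggregate_probability_matrix(P, pi, part)
        assert np.abs(ac.P_tilde - P).max() < 1e-12

    def test_total_lumping(self, toy_chain):
        P, pi = toy_chain
        part = Partition(groups=((0, 1, 2, 3),), n_states=4, aggregated_group=0)
        ac = aggregate_probability_matrix(P, pi, part)
        assert ac.P_tilde.shape == (1, 1)
        assert abs(ac.P_tilde[0, 0] - 1.0) < 1e-12
        assert abs(ac.pi_tilde[0] - 1.0) < 1e-12

    def test_mass_conservation_and_stationarity(self, toy_chain):
        P, pi = toy_chain
        part = Partition(groups=((0,), (1,), (2, 3)), n_states=4, aggregated_group=2)
        ac = aggregate_probability_matrix(P, pi, part)
        assert np.abs(ac.P_tilde.sum(axis=1) - 1.0).max() < 1e-10
        assert abs(ac.pi_tilde.sum() - 1.0) < 1e-12
        assert np.abs(ac.pi_tilde @ ac.P_tilde - ac.pi_tilde).max() < 1e-8
        # non-aggregated frequencies are untouched
        assert np.allclose(ac.pi_tilde[:2], pi[:2])

    def test_matches_monte_carlo_lumped_frequencies(self, toy_chain):
        """P-tilde equals empirical lumped transition frequencies of a long
        simulation of the original chain at stationarity."""
        P, pi = toy_chain
        part = Partition(groups=((0,), (1,), (2, 3)), n_states=4, aggregated_group=2)
        ac = aggregate_probability_matrix(P, pi, part)
        rng = np.random.default_rng(77)
        n_steps = 1_000_000
        cum = P.cumsum(axis=1)
        states = np.empty(n_steps, dtype=np.int8)
        s = int(rng.choice(4, p=pi))
        u = rng.random(n_steps)
        for i in range(n_steps):
            s = int(np.searchsorted(cum[s], u[i]))
            states[i] = s
        lab = np.array([0, 1, 2, 2])
        lumped = lab[states]
        counts = np.zeros((3, 3))
        np.add.at(counts, (lumped[:-1], lumped[1:]), 1)
        row_tot = counts.sum(axis=1, keepdims=True)
        emp = counts / row_tot
        se = np.sqrt(ac.P_tilde * (1 - ac.P_tilde) / row_tot)
        assert np.all(np.abs(emp - ac.P_tilde) <= 3 * se + 1e-12)

    def test_rate_matrix_lumping_identity_and_row_sums(self, space, equal_pi):
        rm = build_m0_rate_matrix(M0Params(omega=0.3, kappa=2.0, pi=equal_pi), space)
        ident = identity_partition(61)
        assert np.abs(aggregate_rate_matrix(rm, equal_pi, ident).Q - rm.Q).max() < 1e-12
        part = aggregation_scheme(obs(1, 2, 3), "full", space)
        Qt = aggregate_rate_matrix(rm, equal_pi, part)
        assert np.abs(Qt.Q.sum(axis=1)).max() < 1e-10

    def test_q_and_p_lumping_commute_for_lumpable_generator(self):
        """For a generator with equal rates into the aggregated set from
        every outside state (and equal outflow rows inside it), lumping
        commutes with exponentiation."""
        Q = np.array(
            [
                [-1.0, 0.4, 0.3, 0.3],
                [0.5, -1.1, 0.3, 0.3],
                [0.2, 0.3, -1.0, 0.5],
                [0.2, 0.3, 0.5, -1.0],
            ]
        )
        pi = np.ones(4) / 4
        part = Partition(groups=((0,), (1,), (2, 3)), n_states=4, aggregated_group=2)
        assert is_lumpable(expm(Q * 0.6), part, tol=1e-9)
        Qt = aggregate_rate_matrix(RateMatrix(Q=Q, pi=pi), pi, part)
        direct = expm(Qt.Q * 0.6)
        via_P = aggregate_probability_matrix(expm(Q * 0.6), pi, part).P_tilde
        assert np.abs(direct - via_P).max() < 1e-10

    def test_idempotent_under_identity_partition(self, toy_chain):
        P, pi = toy_chain
        part = Partition(groups=((0,), (1,), (2, 3)), n_states=4, aggregated_group=2)
        ac = aggregate_probability_matrix(P, pi, part)
        again = aggregate_probability_matrix(ac.P_tilde, ac.pi_tilde, identity_partition(3))
        assert np.abs(again.P_tilde - ac.P_tilde).max() < 1e-12


class TestLumpability:
    def test_identical_rows_always_lumpable(self, space, equal_pi):
        P = np.tile(equal_pi, (61, 1))
        part = aggregation_scheme(obs(1, 2), "full", space)
        assert is_lumpable(P, part)

    def test_identity_partition_vacuously_lumpable(self, toy_P=None):
        rng = np.random.default_rng(0)
        P = rng.dirichlet(np.ones(5), size=5)
        assert is_lumpable(P, identity_partition(5))

    def test_codon_model_is_not_lumpable(self, space, equal_pi):
        rm = build_m0_rate_matrix(M0Params(omega=0.3, kappa=2.0, pi=equal_pi), space)
        P = transition_matrix(eigendecompose(rm), 0.4)
        part = aggregation_scheme(obs(3, 10, 20), "full", space)
        assert not is_lumpable(P, part, tol=1e-6)
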