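import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import coaltree as ct
from coaltree.tmrca import (
    _compositions,
    allocate_mutations,
    allocate_waiting_times,
    initial_candidate_weights,
)

from conftest import make_alignment


def pipeline(aln):
    lab = ct.label_least_shared(ct.find_segregating_sites(aln))
    return ct.enumerate_rooted_trees(lab, aln)


def top_branch_of(calibrated, node_index):
    node = calibrated.node_list[node_index]
    target = node.clade_lineages()
    for child in calibrated.tree.root.children:
        if target <= child.clade_lineages():
            return frozenset(child.clade_lineages())
    return frozenset()  # merged at the root scope itself


class TestWaitingTimeAllocation:
    def test_first_step_candidate_weights_match_leaf_counts(self, nuu_tree):
        weights = initial_candidate_weights(nuu_tree.root)
        assert sorted(weights) == [3, 3, 5, 19, 24]
        assert sum(weights) == 54

    def test_subclade_weights(self, nuu_tree):
        abef = nuu_tree.find_edge_with_site(4)
        assert sum(initial_candidate_weights(abef)) == 23
        ij = nuu_tree.find_edge_with_site(16)
        assert ij.clade_multiplicity() == 12

    def test_first_event_frequencies_match_weights(self, nuu_tree):
        """Empirical branch choice of the oldest coalescence (w_55) follows
        the (3,24,5,19,3)/54 law."""
        rng = np.random.default_rng(77)
        reps = 20000
        counts: dict[frozenset, int] = {}
        for _ in range(reps):
            w = ct.sample_waiting_times(55, rng)
            cal = allocate_waiting_times(nuu_tree, w, rng)
            i, node_index, kind = cal.events[0]
            assert i == 55
            branch = top_branch_of(cal, node_index)
            counts[branch] = counts.get(branch, 0) + 1
        expected_weights = {
            frozenset("m"): 3,
            frozenset("abef"): 24,
            frozenset("k"): 5,
            frozenset("cghijl"): 19,
            frozenset("d"): 3,
        }
        assert set(counts) == set(expected_weights)
        observed = [counts[b] for b in expected_weights]
        expected = [reps * v / 54 for v in expected_weights.values()]
        assert stats.chisquare(observed, expected).pvalue > 1e-4

    def test_every_waiting_time_assigned_once(self, nuu_tree, rng):
        w = ct.sample_waiting_times(55, rng)
        cal = allocate_waiting_times(nuu_tree, w, rng)
        assert sorted(i for i, _, _ in cal.events) == list(range(2, 56))

    def test_segment_lengths_partition_waiting_times(self, nuu_tree, rng):
        """Each segment's length is a sum of whole w_i's and the spans are
        consistent with the tree: mutated segments span >= 1 interval."""
        w = ct.sample_waiting_times(55, rng)
        cal = allocate_waiting_times(nuu_tree, w, rng)
        for u, node in enumerate(cal.node_list):
            if u == 0:
                continue
            span = cal.spanned_intervals(u)
            assert len(span) >= 1
            assert cal.segment_length(u) == pytest.approx(
                sum(w.w_of(i) for i in span)
            )

    def test_two_leaves_deterministic(self, rng):
        aln = make_alignment(["x", "y"], ["A", "G"], [1, 1])
        tree = pipeline(aln)[0]
        w = ct.sample_waiting_times(2, rng)
        cal = allocate_waiting_times(tree, w, rng)
        assert len(cal.events) == 1
        assert cal.events[0][0] == 2

    def test_leaf_count_mismatch_rejected(self, nuu_tree, rng):
        w = ct.sample_waiting_times(10, rng)
        with pytest.raises(ValueError, match="n = 10"):
            allocate_waiting_times(nuu_tree, w, rng)


class TestMutationAllocation:
    def test_counts_conserve_segregating_sites(self, nuu_trees, rng):
        for tree in nuu_trees[:5]:
            w = ct.sample_waiting_times(55, rng)
            cal = allocate_waiting_times(tree, w, rng)
            k = allocate_mutations(cal, rng)
            assert k.total == 18

    def test_single_interval_segment_gets_all_mutations(self, rng):
        # two sampled copies, 7 mutations separating them: every segment
        # spans exactly the single interval [0, w_2]
        aln = make_alignment(["x", "y"], ["A" * 7, "G" * 7], [1, 1])
        tree = pipeline(aln)[0]
        w = ct.sample_waiting_times(2, rng)
        cal = allocate_waiting_times(tree, w, rng)
        k = allocate_mutations(cal, rng)
        assert k.k.tolist() == [7]

    def test_binomial_split_over_two_equal_intervals(self):
        """d=2 with equal interval lengths: the split is Binomial(m, 1/2)."""
        rng = np.random.default_rng(5)
        from coaltree.tmrca import _FlatTree, _scatter_mutations

        tree = pipeline(make_alignment(["x", "y"], ["AAAAAAAAAA", "GGGGGGGGGG"], [2, 1]))[0]
        flat = _FlatTree(tree)
        # force a two-interval span for the mutated segment
        muted = next(u for u in range(1, len(flat.nodes)) if flat.n_mut[u] == 10)
        merge_i = [0] * len(flat.nodes)
        resolve_i = [0] * len(flat.nodes)
        merge_i[muted], resolve_i[muted] = 2, 4  # spans intervals 2 and 3
        w = np.array([1.0, 1.0])
        firsts = []
        for _ in range(2000):
            k = _scatter_mutations(flat, merge_i, resolve_i, w, 3, rng)
            assert k.sum() == 10
            firsts.append(k[0])
        # mean of Binomial(10, 1/2) is 5
        assert np.mean(firsts) == pytest.approx(5.0, abs=0.15)
        assert min(firsts) >= 0 and max(firsts) <= 10


class TestPosteriorMeanGivenK:
    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("k", range(0, 11))
    def test_conjugate_posterior_oracle_n2(self, k, theta):
        """With t_2 ~ Exp(1) and k ~ Poisson(theta t_2) the posterior is
        Gamma(k+1, 1+theta); the formula must equal its mean."""
        expected = (k + 1) / (1 + theta)
        assert ct.posterior_mean_given_k([k], theta) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [2, 3, 10, 55])
    def test_no_mutations_theta0_telescopes_to_predata_mean(self, n):
        val = ct.posterior_mean_given_k([0] * (n - 1), theta=0.0)
        assert val == pytest.approx(2 * (1 - 1 / n), abs=1e-12)

    def test_n3_worked_value(self):
        assert ct.posterior_mean_given_k([0, 0], theta=1.0) == pytest.approx(13 / 18)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ct.posterior_mean_given_k([1, 2], theta=1.0, n=4)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        k=st.lists(st.integers(0, 30), min_size=1, max_size=12),
        theta=st.floats(0.0, 50.0, allow_nan=False),
    )
    def test_linear_in_counts_and_bounded_below_by_base(self, k, theta):
        """The conditional mean is the telescoped base term plus a
        positively weighted sum of the counts: adding mutations anywhere
        can only push the estimate up."""
        n = len(k) + 1
        base = ct.posterior_mean_given_k([0] * (n - 1), theta)
        val = ct.posterior_mean_given_k(k, theta)
        direct = base + 2 * sum(
            ki / (i * (i + theta - 1)) for ki, i in zip(k, range(2, n + 1))
        )
        assert val == pytest.approx(direct, rel=1e-12)
        assert val >= base


class TestPosteriorMeanGivenS:
    def test_s0_reduces_to_single_composition(self):
        n, theta = 5, 0.7
        expected = 2 * sum(1 / (i * (i + theta - 1)) for i in range(2, n + 1))
        assert ct.posterior_mean_given_s(n, 0, theta) == pytest.approx(expected)

    def test_n3_s2_matches_direct_composition_sum(self):
        # compositions of 2 into intervals (i=2, i=3): (2,0), (1,1), (0,2)
        theta = 1.0
        direct = 0.0
        for k2, k3 in [(2, 0), (1, 1), (0, 2)]:
            direct += (k2 + 1) / (2 * 2) + (k3 + 1) / (3 * 3)
        direct *= 2 / 3  # 2 / (s + 1)
        assert ct.posterior_mean_given_s(3, 2, theta) == pytest.approx(direct)

    def test_expectation_source_is_pluggable(self):
        # with E[k_i] = 0 regardless of composition, each term is the
        # telescoped base sum
        n, s, theta = 3, 2, 0.0
        n_comps = 3
        base = 2 * sum(1 / (i * (i - 1)) for i in range(2, n + 1))
        val = ct.posterior_mean_given_s(
            n, s, theta, expected_k=lambda k: [0.0] * len(k)
        )
        assert val == pytest.approx(n_comps / (s + 1) * base)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            ct.posterior_mean_given_s(40, 60, 1.0, max_terms=10_000)

    def test_composition_enumeration_is_exact(self):
        comps = list(_compositions(3, 3))
        assert len(comps) == 10  # C(3 + 2, 2)
        assert all(sum(c) == 3 for c in comps)
        assert len(set(comps)) == 10


class TestEstimator:
    def test_degenerate_star_is_exact(self):
        """s = 0, theta = 0: every replicate evaluates to 2 (1 - 1/n)."""
        aln = make_alignment(["x"], [""], [12])
        trees = pipeline(aln)
        res = ct.estimate_tmrca(
            trees, theta=0.0, M=300, rng=np.random.default_rng(0)
        )
        assert res.t_hat == pytest.approx(2 * (1 - 1 / 12), abs=1e-12)
        assert res.mc_se == pytest.approx(0.0, abs=1e-15)
        assert res.converged

    def test_replicate_average_identity(self, toy_n3):
        """t_hat is exactly the average over replicates of the per-tree
        conditional means (the Monte-Carlo form of the estimator)."""
        trees = pipeline(toy_n3)
        res = ct.estimate_tmrca(
            trees, theta=1.0, M=500, rng=np.random.default_rng(3),
            tol=0.0, keep_draws=True,
        )
        assert res.draws.shape == (res.M_used, len(trees))
        assert res.t_hat == pytest.approx(float(res.draws.mean(axis=1).mean()))
        assert res.per_tree_means == pytest.approx(
            tuple(res.draws.mean(axis=0))
        )

    def test_agrees_with_bruteforce_simulator_n3(self, toy_n3):
        import oracles

        trees = pipeline(toy_n3)
        res = ct.estimate_tmrca(
            trees, theta=1.0, M=30000, rng=np.random.default_rng(11), tol=0.0
        )
        brute, brute_se = oracles.brute_force_tmrca(
            list(toy_n3.sequences),
            list(toy_n3.multiplicities),
            theta=1.0,
            M=6000,
            rng=np.random.default_rng(12),
        )
        tol = 3 * math.hypot(res.mc_se, brute_se)
        assert abs(res.t_hat - brute) < tol

    def test_monotone_in_theta(self, toy_n4_s2):
        trees = pipeline(toy_n4_s2)
        vals = [
            ct.estimate_tmrca(
                trees, theta=th, M=4000, rng=np.random.default_rng(9), tol=0.0
            ).t_hat
            for th in (0.25, 1.0, 4.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_monotone_in_observed_s(self):
        """More observed mutations on the same two-lineage split pull the
        estimate up (fixed theta)."""
        vals = []
        for s in (0, 3, 9):
            aln = make_alignment(
                ["x", "y"], ["A" * s, "G" * s], [2, 2]
            ) if s else make_alignment(["x"], [""], [4])
            trees = pipeline(aln)
            vals.append(
                ct.estimate_tmrca(
                    trees, theta=1.0, M=4000, rng=np.random.default_rng(13), tol=0.0
                ).t_hat
            )
        assert vals[0] < vals[1] < vals[2]

    def test_requires_full_enumeration(self, nuu_trees):
        with pytest.raises(ValueError, match="s \\+ 1"):
            ct.estimate_tmrca(
                list(nuu_trees[:5]), theta=1.0, M=10, rng=np.random.default_rng(0)
            )

    def test_empty_tree_list_rejected(self):
        with pytest.raises(ValueError):
            ct.estimate_tmrca([], theta=1.0, M=10, rng=np.random.default_rng(0))

    def test_unconverged_flag_when_budget_exhausted(self, toy_n3):
        trees = pipeline(toy_n3)
        res = ct.estimate_tmrca(
            trees, theta=1.0, M=150, rng=np.random.default_rng(4), tol=0.0
        )
        assert not res.converged
        assert res.M_used == 150
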