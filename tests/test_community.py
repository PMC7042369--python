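"""Signed modularity, Louvain, participation and consensus.

Independent oracles: a literal double-loop evaluation of the signed quality
function, and exhaustive search over all set partitions for small graphs.
"""

from itertools import combinations

import numpy as np
import pytest

from sedanet.community import (
    Partition,
    agreement_matrix,
    best_partition,
    consensus,
    louvain,
    participation,
    signed_modularity,
)
from sedanet.graphs import ConnectivityMatrix, proportional_threshold
from sedanet.synthdata import generate_covariance, generate_timeseries
from sedanet.graphs import correlation_matrix

from conftest import symmetric


def brute_force_signed_q(w, assignment, gamma=1.0):
    """Literal double-loop evaluation of Q = Q+ - s-/(s+ + s-) Q-."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    total = 0.0
    for part, sign in ((wp, +1), (wn, -1)):
        s = part.sum()
        if s == 0:
            continue
        k = part.sum(axis=1)
        q = 0.0
        for i in range(n):
            for j in range(n):
                if assignment[i] == assignment[j]:
                    q += (part[i, j] - gamma * k[i] * k[j] / s) / s
        if sign > 0:
            total += q
        else:
            sp, sn = wp.sum(), wn.sum()
            total -= (sn / (sp + sn)) * q
    return total


def all_partitions(n):
    """Every set partition of range(n) as a label array (restricted growth)."""
    def rec(prefix, n_used):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for c in range(n_used + 1):
            yield from rec(prefix + [c], max(n_used, c + 1))

    yield from rec([], 0)


def exhaustive_max_q(w, gamma=1.0):
    best = -np.inf
    for p in all_partitions(w.shape[0]):
        best = max(best, signed_modularity(w, p, gamma))
    return best


def rand_index_adjusted(a, b):
    """Adjusted Rand index (chance-corrected partition agreement)."""
    n = len(a)
    from collections import Counter

    cont = Counter(zip(a, b))
    sum_comb = sum(v * (v - 1) // 2 for v in cont.values())
    sum_a = sum(v * (v - 1) // 2 for v in Counter(a).values())
    sum_b = sum(v * (v - 1) // 2 for v in Counter(b).values())
    pairs = n * (n - 1) // 2
    expected = sum_a * sum_b / pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


class TestSignedModularity:
    def test_two_cliques_q_half(self, two_cliques):
        assert signed_modularity(two_cliques, np.array([0, 0, 0, 1, 1, 1])) == (
            pytest.approx(0.5, abs=1e-12)
        )

    def test_single_community_zero_q_positive_weights(self, two_cliques):
        assert signed_modularity(two_cliques, np.zeros(6, dtype=int)) == (
            pytest.approx(0.0, abs=1e-12)
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_double_loop_oracle_signed(self, seed):
        rng = np.random.default_rng(seed)
        n = 9
        w = rng.uniform(-1, 1, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        assignment = rng.integers(0, 3, size=n)
        for mat in (w, -w):
            assert signed_modularity(mat, assignment) == pytest.approx(
                brute_force_signed_q(mat, assignment), abs=1e-10
            )

    def test_q_invariant_under_node_permutation_and_relabeling(self, two_cliques):
        rng = np.random.default_rng(1)
        perm = rng.permutation(6)
        w = two_cliques[np.ix_(perm, perm)]
        assignment = np.array([0, 0, 0, 1, 1, 1])[perm]
        relabeled = 5 - assignment  # arbitrary relabeling
        assert signed_modularity(w, relabeled) == pytest.approx(0.5, abs=1e-12)


class TestLouvain:
    @pytest.mark.parametrize("seed", range(5))
    def test_two_cliques_recovered_at_exhaustive_optimum(self, two_cliques, seed):
        p = louvain(two_cliques, seed=seed)
        assert p.q_value == pytest.approx(0.5, abs=1e-12)
        assert rand_index_adjusted(p.assignment, [0, 0, 0, 1, 1, 1]) == 1.0
        assert exhaustive_max_q(two_cliques) == pytest.approx(0.5, abs=1e-12)

    def test_two_node_positive_edge_merges(self):
        p = louvain(symmetric({(0, 1): 0.8}, 2), seed=0)
        assert p.n_communities == 1

    def test_stored_q_equals_reevaluated_q(self, two_cliques):
        p = best_partition(two_cliques, n_restarts=4, seed=2)
        assert signed_modularity(two_cliques, p) == pytest.approx(p.q_value, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_attains_exhaustive_optimum_small_signed_graphs(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 7
        w = rng.uniform(-0.5, 1, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        target = exhaustive_max_q(w)
        got = best_partition(w, n_restarts=20, seed=seed).q_value
        assert got == pytest.approx(target, abs=1e-8)

    def test_planted_four_block_recovery(self):
        model = generate_covariance(60, (15, 15, 15, 15), 0.6, 0.05)
        c = ConnectivityMatrix(
            model.cov - np.eye(60), node_labels=[f"r{i}" for i in range(60)]
        )
        thr = proportional_threshold(c, 0.2)
        hits = 0
        for seed in range(20):
            p = louvain(thr, seed=seed)
            if rand_index_adjusted(p.assignment, model.partition) == 1.0:
                hits += 1
        assert hits >= 19  # >= 95% of 20 seeds

    def test_deterministic_per_seed(self, two_cliques):
        a = louvain(two_cliques, seed=11)
        b = louvain(two_cliques, seed=11)
        assert np.array_equal(a.assignment, b.assignment) and a.q_value == b.q_value


class TestBestPartition:
    def test_single_restart_equals_louvain(self, two_cliques):
        assert best_partition(two_cliques, n_restarts=1, seed=5) == louvain(
            two_cliques, seed=5
        )

    def test_returns_max_over_restarts(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(-0.3, 1, size=(12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        qs = [louvain(w, seed=3 + k).q_value for k in range(10)]
        assert best_partition(w, n_restarts=10, seed=3).q_value == max(qs)
        assert best_partition(w, n_restarts=10, seed=3).q_value >= louvain(
            w, seed=3
        ).q_value


class TestParticipation:
    def test_all_edges_within_own_community_zero(self, two_cliques):
        p = participation(two_cliques, np.array([0, 0, 0, 1, 1, 1]))
        np.testing.assert_allclose(p, 0.0, atol=1e-14)

    def test_two_unit_edges_into_two_communities(self):
        w = symmetric({(0, 1): 1.0, (0, 2): 1.0}, 3)
        p = participation(w, np.array([0, 1, 2]))
        assert p[0] == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("m", [2, 3, 5, 8])
    def test_equal_split_closed_form(self, m):
        n = m + 1
        w = symmetric({(0, j): 1.0 for j in range(1, n)}, n)
        assignment = np.array([0] + list(range(1, n)))
        p = participation(w, assignment)
        assert p[0] == pytest.approx(1 - 1 / m, abs=1e-14)

    def test_invariant_under_positive_scaling(self, two_cliques):
        a = participation(two_cliques, np.array([0, 0, 1, 1, 2, 2]))
        b = participation(two_cliques * 7.3, np.array([0, 0, 1, 1, 2, 2]))
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_negative_weights_ignored_and_isolated_zero(self):
        w = symmetric({(0, 1): -0.5, (2, 3): 1.0}, 4)
        p = participation(w, np.array([0, 0, 1, 1]))
        assert p[0] == 0.0 and p[1] == 0.0


class TestConsensus:
    def test_identical_partitions_returned_in_one_iteration(self):
        base = Partition(np.array([0, 0, 1, 1, 2, 2]), 0.3)
        out, converged = consensus([base] * 5, seed=0)
        assert converged
        assert out == base

    def test_two_partition_families_separate(self):
        # Families agree on the coarse 2-block split, disagree inside blocks.
        rng = np.random.default_rng(0)
        parts = []
        for k in range(8):
            fine = rng.integers(0, 2, size=10)
            labels = np.where(np.arange(10) < 5, 0, 2) + fine
            parts.append(Partition(labels, 0.2))
        out, _ = consensus(parts, tau=0.4, seed=1)
        coarse = out.assignment
        assert len(set(coarse[:5])) == 1 and len(set(coarse[5:])) == 1
        assert coarse[0] != coarse[5]

    @pytest.mark.parametrize("tau", [0.0, 0.5])
    def test_noisy_four_block_partitions_converge_to_blocks(self, tau):
        model = generate_covariance(40, (10, 10, 10, 10), 0.6, 0.05)
        c = ConnectivityMatrix(model.cov - np.eye(40))
        parts = []
        for seed in range(6):
            panel = generate_timeseries(model, 120, seed=seed)
            thr = proportional_threshold(correlation_matrix(panel), 0.2)
            parts.append(best_partition(thr, n_restarts=5, seed=seed))
        out, converged = consensus(parts, tau=tau, seed=2)
        assert converged
        assert rand_index_adjusted(out.assignment, model.partition) == 1.0


class TestAgreementMatrix:
    def test_fractions_and_diagonal(self):
        p1 = Partition(np.array([0, 0, 1, 1]), 0.1)
        p2 = Partition(np.array([0, 1, 1, 1]), 0.1)
        ag = agreement_matrix([p1, p2]).matrix
        assert ag[0, 1] == 0.5 and ag[2, 3] == 1.0 and np.all(np.diag(ag) == 1.0)
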