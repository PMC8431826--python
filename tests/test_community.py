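import itertools

import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from nctpipe import (
    BoundaryRanker,
    GammaSweepConsensus,
    LouvainCommunities,
    boundary_controllability,
    consensus_partition,
    louvain_partition,
    modularity,
    sweep_and_select,
    zrand,
)
from nctpipe.community import Partition, _canonical


class TestModularity:
    def test_all_in_one_is_zero(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6))
        a = np.triu(a, 1) + np.triu(a, 1).T
        assert modularity(a, np.zeros(6, dtype=int), 1.0) == pytest.approx(0.0)

    def test_two_disconnected_cliques_half(self, two_cliques):
        a, planted = two_cliques
        assert modularity(a, planted, 1.0) == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.random((7, 7)) * (rng.random((7, 7)) > 0.4)
        a = np.triu(a, 1) + np.triu(a, 1).T
        assignment = rng.integers(0, 3, 7)
        gamma = 1.7
        two_m = a.sum()
        k = a.sum(axis=1)
        q = 0.0
        for i in range(7):
            for j in range(7):
                if assignment[i] == assignment[j]:
                    q += a[i, j] - gamma * k[i] * k[j] / two_m
        q /= two_m
        assert modularity(a, assignment, gamma) == pytest.approx(q, abs=1e-12)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((3, 3)), [0, 1, 2])


class TestLouvain:
    def test_recovers_joined_five_cliques(self, joined_five_cliques):
        a, planted = joined_five_cliques
        part = louvain_partition(a, gamma=1.0, seed=0)
        assert adjusted_rand_score(planted, part.assignment) == 1.0

    def test_complete_graph_single_module(self):
        a = nx.to_numpy_array(nx.complete_graph(8))
        assert louvain_partition(a, gamma=1.0, seed=0).n_modules == 1

    def test_high_gamma_refines(self):
        a = nx.to_numpy_array(nx.complete_graph(8))
        coarse = louvain_partition(a, gamma=1.0, seed=0).n_modules
        fine = louvain_partition(a, gamma=4.0, seed=0).n_modules
        assert fine >= coarse

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        a = rng.random((20, 20)) * (rng.random((20, 20)) > 0.6)
        a = np.triu(a, 1) + np.triu(a, 1).T
        p1 = louvain_partition(a, 1.5, seed=42)
        p2 = louvain_partition(a, 1.5, seed=42)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)

    def test_never_below_all_in_one(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            a = rng.random((15, 15)) * (rng.random((15, 15)) > 0.5)
            a = np.triu(a, 1) + np.triu(a, 1).T
            for gamma in (0.5, 1.0, 2.0):
                part = louvain_partition(a, gamma, seed=seed)
                assert part.quality >= modularity(a, np.zeros(15, int), gamma) - 1e-12

    def test_quality_recomputable(self):
        rng = np.random.default_rng(4)
        a = rng.random((12, 12)) * (rng.random((12, 12)) > 0.5)
        a = np.triu(a, 1) + np.triu(a, 1).T
        part = louvain_partition(a, 2.0, seed=7)
        assert part.quality == pytest.approx(
            modularity(a, part.assignment, 2.0), abs=1e-10
        )

    def test_estimator_interface(self, joined_five_cliques):
        a, planted = joined_five_cliques
        est = LouvainCommunities(gamma=1.0, seed=0).fit(a)
        assert adjusted_rand_score(planted, est.labels_) == 1.0
        assert est.get_params() == {"gamma": 1.0, "seed": 0}


def _all_partitions(n):
    """Every set partition of range(n), as canonical label vectors."""
    def rec(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for sub in rec(rest):
            for i in range(len(sub)):
                yield sub[:i] + [sub[i] | {first}] + sub[i + 1:]
            yield sub + [{first}]
    for blocks in rec(list(range(n))):
        labels = np.empty(n, dtype=int)
        for m, block in enumerate(blocks):
            for v in block:
                labels[v] = m
        yield _canonical(labels)


def _w_stat(a, b):
    from sklearn.metrics.cluster import contingency_matrix

    c = contingency_matrix(a, b)
    return float((c * (c - 1) // 2).sum())


class TestZRand:
    def test_symmetric(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 10)
        b = rng.integers(0, 3, 10)
        assert zrand(a, b) == pytest.approx(zrand(b, a))

    def test_self_similarity_positive(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        assert zrand(a, a) > 0

    def test_matches_permutation_enumeration(self):
        """Null mean/variance agree exactly with all 720 label permutations."""
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 1, 1])
        ws = np.array([_w_stat(a, np.array(p))
                       for p in itertools.permutations(b)])
        expected = (_w_stat(a, b) - ws.mean()) / ws.std()
        assert zrand(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_variance_warns_zero(self):
        singletons = np.arange(5)
        with pytest.warns(UserWarning, match="degenerate"):
            assert zrand(singletons, singletons) == 0.0


class TestSweepAndSelect:
    def test_singleton_grid(self, two_cliques):
        a, _ = two_cliques
        res = sweep_and_select(a, [2.0], n_opt=4, seed=0)
        assert res.selected_gamma == 2.0

    def test_tie_breaks_to_smallest_gamma(self, two_cliques):
        # every seeded run finds the same 2-clique split at both resolutions,
        # so mean z-Rand ties and the smaller gamma must win
        a, _ = two_cliques
        res = sweep_and_select(a, [1.0, 1.1], n_opt=4, seed=0)
        assert res.mean_zrand[0] == pytest.approx(res.mean_zrand[1])
        assert res.selected_gamma == 1.0

    def test_empty_grid_rejected(self, two_cliques):
        with pytest.raises(ValueError):
            sweep_and_select(two_cliques[0], [], n_opt=4, seed=0)

    def test_estimator_exposes_sweep(self, two_cliques):
        a, planted = two_cliques
        est = GammaSweepConsensus(gammas=[1.0, 2.0], n_opt=4, seed=1).fit(a)
        assert est.mean_zrand_.shape == (2,)
        assert adjusted_rand_score(planted, est.labels_) == 1.0


class TestConsensus:
    def _part(self, labels):
        return Partition(np.asarray(labels), gamma=1.0, quality=0.0)

    def test_identical_inputs_fixed_point(self):
        p = self._part([0, 0, 1, 1, 2, 2])
        out = consensus_partition([p, p, p], seed=0)
        np.testing.assert_array_equal(out.assignment, p.assignment)

    def test_majority_wins(self):
        maj = self._part([0, 0, 1, 1, 2, 2])
        noise = self._part([0, 1, 2, 0, 1, 2])
        out = consensus_partition([maj] * 9 + [noise], seed=3)
        np.testing.assert_array_equal(out.assignment, maj.assignment)

    def test_deterministic_given_seed(self):
        p1 = self._part([0, 0, 1, 1])
        p2 = self._part([0, 1, 0, 1])
        outs = [consensus_partition([p1, p2] * 2, seed=11) for _ in range(2)]
        np.testing.assert_array_equal(outs[0].assignment, outs[1].assignment)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            consensus_partition([self._part([0, 1])], seed=0)


class TestBoundary:
    def test_bridge_endpoints_rank_first(self, barbell):
        a, planted = barbell
        res = boundary_controllability(a, planted)
        assert set(np.flatnonzero(res.rank <= 2)) == {2, 3}
        assert set(res.rank) == set(range(1, 7))

    def test_disconnected_cliques_all_nonboundary(self, two_cliques):
        a, planted = two_cliques
        res = boundary_controllability(a, planted)
        assert not res.is_boundary.any()
        assert np.all(res.boundary_fraction == 0.0)

    def test_pure_cross_node_rank_one(self):
        # star center in module 0, leaves in module 1: all center strength crosses
        a = nx.to_numpy_array(nx.star_graph(4))
        res = boundary_controllability(a, [0, 1, 1, 1, 1])
        assert res.boundary_fraction[0] == 1.0
        assert res.rank[0] == 1

    def test_fraction_bounds_and_centering(self, barbell):
        a, planted = barbell
        res = boundary_controllability(a, planted)
        assert np.all((res.boundary_fraction >= 0) & (res.boundary_fraction <= 1))
        assert res.centered_rank.sum() == pytest.approx(0.0)

    def test_permutation_equivariance(self, barbell):
        a, planted = barbell
        rng = np.random.default_rng(8)
        perm = rng.permutation(6)
        res = boundary_controllability(a, planted)
        res_p = boundary_controllability(a[np.ix_(perm, perm)], planted[perm])
        np.testing.assert_allclose(res_p.boundary_fraction,
                                   res.boundary_fraction[perm], atol=1e-12)

    def test_single_module_rejected(self, two_cliques):
        with pytest.raises(ValueError, match="modules"):
            boundary_controllability(two_cliques[0], np.zeros(8, dtype=int))

    def test_ranker_transform_returns_centered(self, barbell):
        a, planted = barbell
        est = BoundaryRanker().fit(a, planted)
        np.testing.assert_array_equal(est.transform(a), est.centered_rank_)
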