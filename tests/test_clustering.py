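"""PCA/Tracy-Widom, EM admixture, K selection, run alignment and NJ trees."""

import itertools

import numpy as np
import pytest

from popgen.clustering import (
    ClusteringError,
    HardAssignment,
    MembershipMatrix,
    admixture_fit,
    agreement,
    align_runs,
    evidence_by_k,
    neighbor_joining,
    partition_evidence,
    pca,
    replicate_runs,
    select_components,
    select_k,
    tracy_widom_sf,
    ward_cluster,
)
from popgen.simulate import SimulationConfig, simulate_admixture, simulate_island

from conftest import make_matrix


class TestTracyWidom:
    def test_published_quantiles(self):
        # smartpca's tabulated GOE thresholds: 0.9793 at 5%, 2.0234 at 1%
        assert tracy_widom_sf(0.9793) == pytest.approx(0.05, abs=0.003)
        assert tracy_widom_sf(2.0234) == pytest.approx(0.01, abs=0.003)

    def test_monotone_decreasing(self):
        xs = np.linspace(-8, 6, 30)
        ps = [tracy_widom_sf(x) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestPca:
    def test_variance_fractions_sum_to_one(self, rng):
        calls = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
        g = make_matrix(calls.tolist())
        res = pca(g)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_two_demes_separated_with_significant_pc1(self):
        g, _ = simulate_island(
            SimulationConfig(seed=9, n_pops=2, samples_per_pop=15, n_loci=150, F=0.4)
        )
        res = pca(g)
        assert res.tw_pvalues[0] < 0.01
        pops = np.array(g.populations)
        pc1 = res.scores[:, 0]
        assert (pc1[pops == "pop01"].mean() > 0) != (pc1[pops == "pop02"].mean() > 0) or abs(
            pc1[pops == "pop01"].mean() - pc1[pops == "pop02"].mean()
        ) > pc1.std()

    def test_duplicating_samples_preserves_scores(self, rng):
        calls = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        g = make_matrix(calls.tolist())
        g2 = make_matrix(np.vstack([calls, calls]).tolist())
        s1 = pca(g).scores[:, 0]
        s2 = pca(g2).scores[:, 0]
        # doubled matrix repeats the leading score pattern (up to sign/scale)
        c = np.corrcoef(np.concatenate([s1, s1]), s2)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-6)

    def test_ld_correction_accepts_neighbour_counts(self, rng):
        calls = rng.integers(0, 2, size=(9, 25)).astype(np.int8)
        g = make_matrix(calls.tolist())
        for ld in (0, 1, 2):
            res = pca(g, ld_correct=ld)
            assert res.scores.shape[0] == 9
        with pytest.raises(ClusteringError):
            pca(g, ld_correct=3)


class TestSelectComponents:
    def _fake(self, fractions):
        fractions = np.asarray(fractions, dtype=float)
        n = len(fractions)
        return type(
            "P",
            (),
            {
                "variance_fractions": fractions,
                "scores": np.tile(np.arange(n, dtype=float), (6, 1)),
            },
        )()

    def test_threshold_forces_three(self):
        p = self._fake([0.10, 0.05, 0.03, 0.01])
        assert select_components(p).shape[1] == 3

    def test_clipped_to_five(self):
        p = self._fake([0.10, 0.08, 0.06, 0.05, 0.04, 0.03, 0.025])
        assert select_components(p).shape[1] == 5

    def test_fewer_than_three_eligible_pads_to_three(self):
        p = self._fake([0.5, 0.01, 0.005, 0.004])
        assert select_components(p).shape[1] == 3


class TestWard:
    def test_two_blobs_recovered(self, rng):
        a = rng.normal(0, 0.3, size=(10, 3))
        b = rng.normal(5, 0.3, size=(10, 3))
        hard, heights = ward_cluster(np.vstack([a, b]))
        assert hard.k == 2
        labels = hard.labels
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_explicit_k_one(self, rng):
        hard, _ = ward_cluster(rng.normal(size=(6, 2)), k=1)
        assert hard.k == 1

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ClusteringError):
            ward_cluster(rng.normal(size=(4, 2)), k=9)


class TestAdmixture:
    def test_k1_closed_form_likelihood(self, rng):
        calls = rng.integers(0, 2, size=(12, 30)).astype(np.int8)
        g = make_matrix(calls.tolist())
        m = admixture_fit(g, K=1)
        p = calls.mean(axis=0)
        p = np.clip(p, 1e-6, 1 - 1e-6)
        expected = float(
            (calls.sum(axis=0) * np.log(p) + (12 - calls.sum(axis=0)) * np.log(1 - p)).sum()
        )
        assert m.loglik == pytest.approx(expected, rel=1e-9)
        assert np.all(m.Q == 1.0)

    def test_likelihood_at_truth_beats_perturbation(self):
        cfg = SimulationConfig(seed=5, n_loci=120, F=0.4, admixture_Q=_block_q(20, 2))
        g, truth = simulate_admixture(cfg)
        from popgen.clustering import _admixture_loglik

        x = g.calls
        obs = x != -1
        ll_true = _admixture_loglik(x, obs, truth.Q, np.clip(truth.deme_freqs, 1e-6, 1 - 1e-6))
        rng = np.random.default_rng(0)
        for _ in range(5):
            P_pert = np.clip(
                truth.deme_freqs + rng.normal(0, 0.15, truth.deme_freqs.shape), 1e-6, 1 - 1e-6
            )
            assert ll_true >= _admixture_loglik(x, obs, truth.Q, P_pert)

    def test_recovers_simulated_q(self):
        q_true = _block_q(30, 2)
        cfg = SimulationConfig(seed=6, n_loci=200, F=0.4, admixture_Q=q_true)
        g, truth = simulate_admixture(cfg)
        maes = []
        for m in replicate_runs(g, 2, n_replicates=3, seed=50):
            best = min(
                itertools.permutations(range(2)),
                key=lambda p: np.abs(m.Q[:, p] - q_true).mean(),
            )
            maes.append(np.abs(m.Q[:, best] - q_true).mean())
        assert min(maes) < 0.1

    def test_missing_calls_tolerated(self, rng):
        calls = rng.integers(0, 2, size=(10, 40)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = -1
        g = make_matrix(calls.tolist())
        m = admixture_fit(g, K=2, seed=1)
        assert np.allclose(m.Q.sum(axis=1), 1.0)
        assert np.isfinite(m.loglik)

    def test_k_above_n_rejected(self, rng):
        g = make_matrix(rng.integers(0, 2, size=(3, 10)).astype(np.int8).tolist())
        with pytest.raises(ClusteringError):
            admixture_fit(g, K=5)


class TestPartitionEvidence:
    def test_splitting_homogeneous_cluster_lowers_evidence(self, rng):
        calls = (rng.random((20, 60)) < 0.5).astype(np.int8)
        g = make_matrix(calls.tolist())
        one = partition_evidence(g, np.zeros(20, dtype=int))
        split = partition_evidence(g, np.repeat([0, 1], 10))
        assert one > split

    def test_separating_distinct_demes_raises_evidence(self):
        g, _ = simulate_island(
            SimulationConfig(seed=11, n_pops=2, samples_per_pop=12, n_loci=80, F=0.4)
        )
        truth = np.repeat([0, 1], 12)
        assert partition_evidence(g, truth) > partition_evidence(g, np.zeros(24, dtype=int))


class TestSelectK:
    def test_panmictic_selects_one(self):
        g, _ = simulate_island(
            SimulationConfig(seed=13, n_pops=1, samples_per_pop=40, n_loci=100, F=0.0)
        )
        _, ev = evidence_by_k(g, (1, 3), n_replicates=15, seed=60, n_starts=2)
        assert select_k(ev) == 1

    def test_two_demes_select_two(self):
        g, _ = simulate_island(
            SimulationConfig(seed=14, n_pops=2, samples_per_pop=20, n_loci=100, F=0.5)
        )
        _, ev = evidence_by_k(g, (1, 3), n_replicates=15, seed=61, n_starts=2)
        assert select_k(ev) == 2

    def test_requires_contiguous_range_from_one(self):
        with pytest.raises(ClusteringError):
            select_k({2: [1.0, 2.0], 3: [1.0, 2.0]})

    def test_tied_likelihoods_give_one(self):
        ev = {1: [5.0] * 10, 2: [5.0] * 10, 3: [5.0] * 10}
        assert select_k(ev) == 1


class TestAlignRuns:
    def _hard_q(self, labels, k):
        q = np.zeros((len(labels), k))
        q[np.arange(len(labels)), labels] = 1.0
        return MembershipMatrix(Q=q, loglik=0.0)

    def test_identical_runs_h_prime_one(self, rng):
        q = rng.dirichlet(np.ones(3), size=12)
        runs = [MembershipMatrix(Q=q.copy(), loglik=0.0) for _ in range(4)]
        assert align_runs(runs).H_prime == pytest.approx(1.0)

    def test_column_permutation_recovered(self, rng):
        q = rng.dirichlet(np.ones(4), size=15)
        runs = [
            MembershipMatrix(Q=q, loglik=0.0),
            MembershipMatrix(Q=q[:, [2, 0, 3, 1]], loglik=0.0),
        ]
        ens = align_runs(runs)
        assert ens.H_prime == pytest.approx(1.0)
        np.testing.assert_allclose(ens.aligned[1], q)

    def test_half_swapped_hard_assignments_give_half(self):
        n = 20
        labels_a = np.repeat([0, 1], n // 2)
        labels_b = labels_a.copy()
        labels_b[: n // 4] = 1 - labels_b[: n // 4]  # swap half of cluster 0... no:
        # swap half of all samples: flip labels of every other sample
        labels_b = labels_a.copy()
        labels_b[::2] = 1 - labels_b[::2]
        runs = [self._hard_q(labels_a, 2), self._hard_q(labels_b, 2)]
        assert align_runs(runs).H_prime == pytest.approx(0.5)

    def test_invariant_to_any_column_permutation(self, rng):
        runs = [MembershipMatrix(Q=rng.dirichlet(np.ones(3), size=10), loglik=0.0) for _ in range(3)]
        base = align_runs(runs).H_prime
        permuted = [MembershipMatrix(Q=r.Q[:, [1, 2, 0]], loglik=0.0) for r in runs]
        assert align_runs(permuted).H_prime == pytest.approx(base)

    def test_shape_mismatch_rejected(self, rng):
        a = MembershipMatrix(Q=rng.dirichlet(np.ones(2), size=5), loglik=0.0)
        b = MembershipMatrix(Q=rng.dirichlet(np.ones(3), size=5), loglik=0.0)
        with pytest.raises(ClusteringError):
            align_runs([a, b])


class TestAgreement:
    def test_identical_is_100(self):
        a = HardAssignment(labels=np.array([0, 0, 1, 1, 2]), source="ward")
        assert agreement(a, a) == pytest.approx(100.0)

    def test_symmetric_and_relabel_invariant(self, rng):
        la = rng.integers(0, 3, size=30)
        lb = rng.integers(0, 3, size=30)
        a = HardAssignment(labels=la, source="ward")
        b = HardAssignment(labels=lb, source="admixture-majority")
        assert agreement(a, b) == pytest.approx(agreement(b, a))
        relabeled = HardAssignment(labels=(lb + 1) % 3, source="ward")
        assert agreement(a, relabeled) == pytest.approx(agreement(a, b))

    def test_known_confusion(self):
        a = HardAssignment(labels=np.array([0, 0, 0, 1, 1, 1]), source="ward")
        b = HardAssignment(labels=np.array([1, 1, 0, 0, 0, 0]), source="ward")
        # best matching: a0->b1 (2 hits), a1->b0 (3 hits) = 5/6
        assert agreement(a, b) == pytest.approx(100 * 5 / 6)

    def test_different_sample_sets_rejected(self):
        a = HardAssignment(labels=np.array([0, 1]), source="ward", sample_ids=["x", "y"])
        b = HardAssignment(labels=np.array([0, 1]), source="ward", sample_ids=["x", "z"])
        with pytest.raises(ClusteringError):
            agreement(a, b)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths(self):
        # three-point formulas: x=(dab+dac-dbc)/2 etc.
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree, _ = neighbor_joining(d, ids=["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_five_taxon_tree_recovered(self):
        # tree: ((a:2,b:3):1,(c:2,d:4):2,e:3) with additive distances
        tips = ["a", "b", "c", "d", "e"]
        paths = {
            ("a", "b"): 5, ("a", "c"): 7, ("a", "d"): 9, ("a", "e"): 6,
            ("b", "c"): 8, ("b", "d"): 10, ("b", "e"): 7,
            ("c", "d"): 6, ("c", "e"): 7, ("d", "e"): 9,
        }
        d = np.zeros((5, 5))
        for (u, v), val in paths.items():
            i, j = tips.index(u), tips.index(v)
            d[i, j] = d[j, i] = val
        tree, _ = neighbor_joining(d, ids=tips)
        # recovered tree must reproduce every pairwise path length exactly
        for (u, v), val in paths.items():
            assert tree.find(u).distance(tree.find(v)) == pytest.approx(val)
        # and contain the generating bipartitions
        from popgen.clustering import _splits

        splits = _splits(tree, frozenset(tips))
        assert frozenset({"a", "b"}) in splits
        assert frozenset({"c", "d"}) in splits

    def test_bootstrap_supports_clear_clades(self):
        g, _ = simulate_island(
            SimulationConfig(seed=17, n_pops=2, samples_per_pop=3, n_loci=150, F=0.6)
        )
        tree, support = neighbor_joining(g=g, n_boot=50, seed=1)
        # the deepest split separates the two demes with high support
        big = [v for s, v in support.items() if len(s) == 3]
        assert big and max(big) >= 80.0

    def test_missing_distance_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ClusteringError):
            neighbor_joining(d, ids=list("abc"))


def _block_q(n_per, k):
    q = np.zeros((n_per * k, k))
    for i in range(k):
        q[i * n_per : (i + 1) * n_per, i] = 1.0
    return q
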