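"""Agglomerative clustering: merge selection, trajectory scoring, pooling."""

import numpy as np
import pandas as pd
import pytest

from _oracles import set_partitions
from dielbfc import (
    NIGPrior,
    best_merge,
    init_partition,
    log_evidence,
    pooled_clustering,
    run_agglomeration,
    simulate_expression,
)
from dielbfc.cluster import partition_score, pool_assignments
from dielbfc.errors import NoMergeError
from dielbfc.matrix import ExpressionMatrix


def _matrix(values, design):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[s.sample_id for s in design],
    )
    return ExpressionMatrix(df, list(design))


def _cohort(design, n_clusters, genes_per_cluster, amplitude, noise_sd, seed):
    phases = [24.0 * c / n_clusters for c in range(n_clusters)]
    return simulate_expression(
        design, n_clusters, genes_per_cluster, phases,
        [amplitude] * n_clusters, noise_sd=noise_sd, seed=seed,
    )


class TestInitPartition:
    def test_singletons_and_score(self, default_design, default_basis, default_prior):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(0, 1, (5, 27)), default_design)
        p = init_partition(m, default_basis, default_prior)
        assert p.n_clusters == 5
        assert all(c.size == 1 for c in p.clusters)
        expected = sum(
            log_evidence(m.values.iloc[i].to_numpy(), default_basis, default_prior)
            for i in range(5)
        )
        assert p.score == pytest.approx(expected, abs=1e-8)
        assert p.score == pytest.approx(partition_score(p), abs=1e-8)

    def test_single_gene_terminates_immediately(
        self, default_design, default_basis, default_prior
    ):
        m = _matrix(np.zeros((1, 27)), default_design)
        p = run_agglomeration(m, default_basis, default_prior)
        assert p.n_clusters == 1
        assert len(p.merge_history) == 1  # only the initial score

    def test_best_merge_needs_two_clusters(
        self, default_design, default_basis, default_prior
    ):
        m = _matrix(np.zeros((1, 27)), default_design)
        with pytest.raises(NoMergeError):
            best_merge(init_partition(m, default_basis, default_prior))


class TestBestMerge:
    def _exhaustive_best(self, p):
        """Oracle: evaluate every pairwise delta via direct evidence calls."""
        best, best_d = None, -np.inf
        for i in range(p.n_clusters):
            for j in range(i + 1, p.n_clusters):
                stats = p.clusters[i].stats + p.clusters[j].stats
                from dielbfc.model import log_evidence_stats

                d = (
                    log_evidence_stats(stats, p.prior)
                    - p.clusters[i].log_evidence
                    - p.clusters[j].log_evidence
                )
                if d > best_d:
                    best, best_d = (i, j), d
        return best, best_d

    def test_identical_profiles_merge_first(
        self, default_design, default_basis, default_prior
    ):
        tod = np.array([s.tod for s in default_design])
        rows = [
            2 * np.cos(2 * np.pi * (tod - 3) / 24),
            2 * np.cos(2 * np.pi * (tod - 3) / 24),
            2 * np.cos(2 * np.pi * (tod - 12) / 24),
            2 * np.cos(2 * np.pi * (tod - 18) / 24),
        ]
        p = init_partition(_matrix(rows, default_design), default_basis, default_prior)
        pair, delta = best_merge(p)
        assert pair == (0, 1)
        oracle_pair, oracle_delta = self._exhaustive_best(p)
        assert pair == oracle_pair
        assert delta == pytest.approx(oracle_delta, abs=1e-9)

    def test_shared_generator_merges_first(
        self, default_design, default_basis, default_prior
    ):
        rng = np.random.default_rng(1)
        tod = np.array([s.tod for s in default_design])
        base = 2 * np.cos(2 * np.pi * (tod - 9) / 24)
        rows = [
            base + rng.normal(0, 0.2, 27),
            2 * np.cos(2 * np.pi * (tod - 21) / 24) + rng.normal(0, 0.2, 27),
            base + rng.normal(0, 0.2, 27),
        ]
        p = init_partition(_matrix(rows, default_design), default_basis, default_prior)
        pair, _ = best_merge(p)
        assert pair == (0, 2)
        assert pair == self._exhaustive_best(p)[0]

    def test_symmetric_tie_breaks_lexicographically(
        self, default_design, default_basis, default_prior
    ):
        tod = np.array([s.tod for s in default_design])
        a = np.cos(2 * np.pi * tod / 24)
        b = np.cos(2 * np.pi * (tod - 12) / 24)
        p = init_partition(_matrix([a, a, b, b], default_design), default_basis, default_prior)
        pair, _ = best_merge(p)
        assert pair == (0, 1)  # (2, 3) scores identically by symmetry


class TestAgglomeration:
    def test_two_identical_genes_end_merged(
        self, default_design, default_basis, default_prior
    ):
        tod = np.array([s.tod for s in default_design])
        y = 2 * np.cos(2 * np.pi * tod / 24)
        m = _matrix([y, y], default_design)
        p = run_agglomeration(m, default_basis, default_prior)
        assert p.n_clusters == 1
        joint = log_evidence(np.vstack([y, y]), default_basis, default_prior)
        singles = 2 * log_evidence(y, default_basis, default_prior)
        assert joint - singles > 0  # merge gain confirmed by the evidence itself

    def test_three_separated_clusters_recovered(self, default_design, default_basis, default_prior):
        from sklearn.metrics import adjusted_rand_score

        m, truth = simulate_expression(
            default_design, 3, 10, [3, 11, 19], [3, 3, 3], noise_sd=0.3, seed=1
        )
        p = run_agglomeration(m, default_basis, default_prior)
        assert p.n_clusters == 3
        ari = adjusted_rand_score(
            truth.true_clusters().loc[m.gene_ids].to_numpy(), p.labels_for(m.gene_ids)
        )
        assert ari == 1.0

    def test_coverage_and_incremental_scores(
        self, default_design, default_basis, default_prior
    ):
        """Trajectory scores match from-scratch rescoring at every step."""
        from dielbfc.model import gene_stats, log_evidence_stats

        rng = np.random.default_rng(2)
        m, _ = _cohort(default_design, 2, 4, 2.0, 0.5, seed=3)
        noise = rng.normal(6, 0.5, (2, 27))
        vals = np.vstack([m.values.to_numpy(), noise])
        m = _matrix(vals, default_design)
        p = run_agglomeration(m, default_basis, default_prior)

        # replay the merge trajectory independently
        per_gene = [gene_stats(vals[i], default_basis) for i in range(m.n_genes)]
        groups = {i: [i] for i in range(m.n_genes)}
        next_id = m.n_genes
        steps = {0: None}
        for step, pair, score in p.merge_history:
            if pair is not None:
                i, j = pair
                groups[next_id] = groups.pop(i) + groups.pop(j)
                next_id += 1
            covered = sorted(g for genes in groups.values() for g in genes)
            assert covered == list(range(m.n_genes))  # coverage conservation
            rescored = sum(
                log_evidence_stats(
                    sum((per_gene[g] for g in genes[1:]), per_gene[genes[0]]),
                    default_prior,
                )
                for genes in groups.values()
            )
            assert score == pytest.approx(rescored, abs=1e-8)

    def test_best_partition_score_is_trajectory_max(
        self, default_design, default_basis, default_prior
    ):
        m, _ = _cohort(default_design, 3, 5, 2.0, 0.3, seed=4)
        p = run_agglomeration(m, default_basis, default_prior)
        traj = [s for _, _, s in p.merge_history]
        assert p.score == pytest.approx(max(traj), abs=1e-10)
        assert p.score == pytest.approx(partition_score(p), abs=1e-8)

    @pytest.mark.parametrize("n_clusters", [2, 6])
    def test_parameter_recovery_across_seeds(
        self, default_design, default_basis, default_prior, n_clusters
    ):
        from sklearn.metrics import adjusted_rand_score

        good = 0
        for seed in range(1, 6):
            m, truth = _cohort(default_design, n_clusters, 40, 2.0, 0.3, seed=seed)
            p = run_agglomeration(m, default_basis, default_prior)
            ari = adjusted_rand_score(
                truth.true_clusters().loc[m.gene_ids].to_numpy(),
                p.labels_for(m.gene_ids),
            )
            good += ari >= 0.9
        assert good >= 4

    def test_greedy_matches_exhaustive_on_separated_toy(
        self, default_design, default_basis, default_prior
    ):
        from dielbfc.model import gene_stats, log_evidence_stats

        m, _ = _cohort(default_design, 2, 4, 3.0, 0.2, seed=5)
        vals = m.values.to_numpy()
        p = run_agglomeration(m, default_basis, default_prior)

        per_gene = [gene_stats(vals[i], default_basis) for i in range(8)]
        cache: dict[frozenset, float] = {}

        def cluster_ev(genes):
            key = frozenset(genes)
            if key not in cache:
                stats = per_gene[genes[0]]
                for g in genes[1:]:
                    stats = stats + per_gene[g]
                cache[key] = log_evidence_stats(stats, default_prior)
            return cache[key]

        scores = np.array(
            [
                sum(cluster_ev(block) for block in part)
                for part in set_partitions(list(range(8)))
            ]
        )
        assert len(scores) == 4140
        assert p.score == pytest.approx(scores.max(), abs=1e-8)
        assert np.mean(scores <= p.score + 1e-8) >= 0.99


class TestPooled:
    def test_three_equal_pools_at_study_scale(self):
        pools = pool_assignments(6822, 2274, seed=0)
        assert [len(c) for c in pools] == [2274, 2274, 2274]
        assert sorted(np.concatenate(pools)) == list(range(6822))

    def test_pool_assignment_deterministic(self):
        a = pool_assignments(100, 30, seed=9)
        b = pool_assignments(100, 30, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_single_pool_matches_plain_agglomeration(
        self, default_design, default_basis, default_prior
    ):
        m, _ = _cohort(default_design, 2, 4, 3.0, 0.3, seed=6)
        pooled = pooled_clustering(m, 100, 0, default_basis, default_prior)
        plain = run_agglomeration(m, default_basis, default_prior)
        assert len(pooled) == 1
        assert {frozenset(c.members) for c in pooled[0].clusters} == {
            frozenset(c.members) for c in plain.clusters
        }

    def test_pool_size_too_small_rejected(
        self, default_design, default_basis, default_prior
    ):
        m, _ = _cohort(default_design, 2, 4, 3.0, 0.3, seed=7)
        with pytest.raises(ValueError):
            pooled_clustering(m, 1, 0, default_basis, default_prior)

    def test_pools_cover_genes_disjointly(
        self, default_design, default_basis, default_prior
    ):
        m, _ = _cohort(default_design, 3, 6, 3.0, 0.3, seed=8)
        parts = pooled_clustering(m, 7, 1, default_basis, default_prior)
        seen = [g for p in parts for c in p.clusters for g in c.members]
        assert sorted(seen) == sorted(m.gene_ids)
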