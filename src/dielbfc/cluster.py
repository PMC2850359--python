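"""Agglomerative Bayesian Fourier clustering (BFC).

Every gene starts as its own cluster; at each step the two clusters whose
merge most increases the partition score (sum of member-cluster log evidences,
optionally plus a cohesion prior) are joined, until one cluster remains. The
score is recorded after every merge and the best-scoring partition along the
trajectory is returned. A pooled mode splits large gene sets into
independently clustered random pools, as was once necessary for memory.

Merging is cheap because cluster evidence depends on the data only through
additive sufficient statistics; pairwise merge gains are cached and only pairs
touching the last merge are recomputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import NoMergeError
from .fourier import FourierBasis
from .matrix import ExpressionMatrix
from .model import (
    ClusterPosterior,
    NIGPrior,
    SufficientStats,
    gene_stats,
    log_evidence_stats,
    posterior_from_stats,
)


@dataclass
class Partition:
    """A disjoint clustering of the input gene set with its score.

    ``merge_history`` holds ``(step, (i, j), score)`` for the greedy
    trajectory that produced this partition (step 0 records the all-singleton
    score with no pair). Cluster order is creation order, which is also the
    tie-break order for merges.
    """

    clusters: list[ClusterPosterior]
    score: float
    merge_history: list[tuple[int, tuple[int, int] | None, float]]
    prior: NIGPrior
    basis: FourierBasis
    partition_prior: str = "uniform"
    alpha: float = 1.0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignments(self) -> pd.Series:
        """gene_id -> 1-based cluster label, in cluster creation order."""
        pairs = [
            (g, c + 1) for c, post in enumerate(self.clusters) for g in post.members
        ]
        s = pd.Series(dict(pairs), name="cluster_id")
        s.index.name = "gene_id"
        return s

    def labels_for(self, gene_ids: list[str]) -> np.ndarray:
        a = self.assignments()
        return a.loc[gene_ids].to_numpy()


def _prior_term(partition_prior: str, alpha: float, sizes: list[int]) -> float:
    if partition_prior == "uniform":
        return 0.0
    if partition_prior == "cohesion":
        # Crowley / DP-style: alpha^{#clusters} * prod Gamma(n_c)
        return len(sizes) * math.log(alpha) + float(sum(gammaln(n) for n in sizes))
    raise ValueError(f"unknown partition prior {partition_prior!r}")


def partition_score(p: Partition) -> float:
    """Recompute the partition score from scratch (evidence sum + prior term)."""
    ev = sum(c.log_evidence for c in p.clusters)
    return ev + _prior_term(p.partition_prior, p.alpha, [c.size for c in p.clusters])


def _merge_delta(
    a: tuple[SufficientStats, float, int],
    b: tuple[SufficientStats, float, int],
    prior: NIGPrior,
    partition_prior: str,
    alpha: float,
) -> float:
    stats_a, ev_a, n_a = a
    stats_b, ev_b, n_b = b
    delta = log_evidence_stats(stats_a + stats_b, prior) - ev_a - ev_b
    if partition_prior == "cohesion":
        delta += float(gammaln(n_a + n_b) - gammaln(n_a) - gammaln(n_b)) - math.log(alpha)
    return delta


def init_partition(
    m: ExpressionMatrix,
    basis: FourierBasis,
    prior: NIGPrior,
    partition_prior: str = "uniform",
    alpha: float = 1.0,
) -> Partition:
    """One singleton cluster per gene, each with evidence and posterior."""
    if m.n_genes == 0:
        raise ValueError("cannot initialise a partition on an empty matrix")
    y = m.values.to_numpy()
    clusters = [
        posterior_from_stats((gid,), gene_stats(y[i], basis), basis, prior)
        for i, gid in enumerate(m.gene_ids)
    ]
    p = Partition(
        clusters=clusters,
        score=0.0,
        merge_history=[],
        prior=prior,
        basis=basis,
        partition_prior=partition_prior,
        alpha=alpha,
    )
    p.score = partition_score(p)
    p.merge_history = [(0, None, p.score)]
    return p


def best_merge(p: Partition) -> tuple[tuple[int, int], float]:
    """The pair of cluster indices whose merge maximises the score gain.

    Ties break to the lexicographically smallest ``(i, j)`` in cluster
    creation order.
    """
    if p.n_clusters < 2:
        raise NoMergeError("need at least 2 clusters to merge")
    entries = [(c.stats, c.log_evidence, c.size) for c in p.clusters]
    best_pair: tuple[int, int] | None = None
    best_delta = -np.inf
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            d = _merge_delta(entries[i], entries[j], p.prior, p.partition_prior, p.alpha)
            if d > best_delta or (d == best_delta and (best_pair is None or (i, j) < best_pair)):
                best_delta = d
                best_pair = (i, j)
    assert best_pair is not None
    return best_pair, float(best_delta)


@dataclass
class _Entry:
    genes: list[int]
    stats: SufficientStats
    log_ev: float

    @property
    def size(self) -> int:
        return len(self.genes)


def run_agglomeration(
    m: ExpressionMatrix,
    basis: FourierBasis,
    prior: NIGPrior,
    partition_prior: str = "uniform",
    alpha: float = 1.0,
) -> Partition:
    """Greedy agglomeration over the full merge trajectory.

    Performs ``G - 1`` merges, scoring after initialisation and after every
    merge, and returns the partition attaining the maximum recorded score
    (earliest step on ties). Cached pairwise gains are invalidated only for
    pairs touching the last merge.
    """
    if m.n_genes == 0:
        raise ValueError("cannot cluster an empty matrix")
    gene_ids = m.gene_ids
    y = m.values.to_numpy()
    per_gene = [gene_stats(y[i], basis) for i in range(m.n_genes)]

    active: dict[int, _Entry] = {
        i: _Entry([i], per_gene[i], log_evidence_stats(per_gene[i], prior))
        for i in range(m.n_genes)
    }
    next_id = m.n_genes

    def entry_tuple(e: _Entry) -> tuple[SufficientStats, float, int]:
        return e.stats, e.log_ev, e.size

    cache: dict[tuple[int, int], float] = {}
    ids = sorted(active)
    for ai in range(len(ids)):
        for aj in range(ai + 1, len(ids)):
            i, j = ids[ai], ids[aj]
            cache[(i, j)] = _merge_delta(
                entry_tuple(active[i]), entry_tuple(active[j]), prior, partition_prior, alpha
            )

    score = sum(e.log_ev for e in active.values()) + _prior_term(
        partition_prior, alpha, [e.size for e in active.values()]
    )
    scores = [score]
    merge_pairs: list[tuple[int, int, int]] = []  # (i, j, new_id)
    history: list[tuple[int, tuple[int, int] | None, float]] = [(0, None, score)]

    step = 0
    while len(active) > 1:
        best_pair: tuple[int, int] | None = None
        best_delta = -np.inf
        for pair, d in cache.items():
            if d > best_delta or (d == best_delta and (best_pair is None or pair < best_pair)):
                best_delta = d
                best_pair = pair
        assert best_pair is not None
        i, j = best_pair
        merged = _Entry(
            active[i].genes + active[j].genes,
            active[i].stats + active[j].stats,
            0.0,
        )
        merged.log_ev = log_evidence_stats(merged.stats, prior)
        del active[i], active[j]
        cache = {k: v for k, v in cache.items() if i not in k and j not in k}
        new_id = next_id
        next_id += 1
        mt = entry_tuple(merged)
        for k, e in active.items():
            key = (k, new_id) if k < new_id else (new_id, k)
            cache[key] = _merge_delta(entry_tuple(e), mt, prior, partition_prior, alpha)
        active[new_id] = merged

        step += 1
        score += best_delta
        scores.append(score)
        merge_pairs.append((i, j, new_id))
        history.append((step, (i, j), score))

    best_step = int(np.argmax(scores))

    # replay merges up to the best-scoring step to recover that partition
    groups: dict[int, list[int]] = {i: [i] for i in range(m.n_genes)}
    for i, j, new_id in merge_pairs[:best_step]:
        groups[new_id] = groups.pop(i) + groups.pop(j)
    clusters = [
        posterior_from_stats(
            tuple(gene_ids[g] for g in genes),
            sum((per_gene[g] for g in genes[1:]), per_gene[genes[0]]),
            basis,
            prior,
        )
        for _, genes in sorted(groups.items())
    ]
    p = Partition(
        clusters=clusters,
        score=scores[best_step],
        merge_history=history,
        prior=prior,
        basis=basis,
        partition_prior=partition_prior,
        alpha=alpha,
    )
    return p


def pool_assignments(n_genes: int, pool_size: int, seed: int) -> list[np.ndarray]:
    """Seed-reproducible random split into ``ceil(G / pool_size)`` near-equal pools."""
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    n_pools = max(1, math.ceil(n_genes / pool_size))
    order = np.random.default_rng(seed).permutation(n_genes)
    return list(np.array_split(order, n_pools))


def pooled_clustering(
    m: ExpressionMatrix,
    pool_size: int,
    seed: int,
    basis: FourierBasis,
    prior: NIGPrior,
    partition_prior: str = "uniform",
    alpha: float = 1.0,
) -> list[Partition]:
    """Shuffle genes, split into near-equal random pools, cluster each pool.

    The number of pools is ``ceil(G / pool_size)``; with the seed fixed the
    pool assignment (and hence every per-pool partition) is reproducible.
    """
    partitions = []
    for chunk in pool_assignments(m.n_genes, pool_size, seed):
        sub = m.subset([m.gene_ids[i] for i in chunk])
        partitions.append(
            run_agglomeration(sub, basis, prior, partition_prior, alpha)
        )
    return partitions
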