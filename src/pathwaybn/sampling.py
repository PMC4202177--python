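"""Cluster-guided candidate-gene sampling.

A seed pathway's genes identify a *pivotal* expression cluster (the one
holding most of them); additional candidate genes are then drawn with
per-cluster probabilities that decay with the cluster's distance from the
pivot, so co-expressed genes are favoured while the rest of the genome is
still reachable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .expression import ClusterModel, cluster_distance
from .knowledgebase import PathwayMap


@dataclass
class SamplingPlan:
    pivot: int
    cluster_weights: np.ndarray
    n_to_sample: int
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.cluster_weights, dtype=float)
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError("cluster weights must sum to 1")
        if w.max() > w[self.pivot] + 1e-12:
            raise ValueError("pivot must carry the maximal weight")
        if self.n_to_sample < 1:
            raise ValueError("n_to_sample must be ≥ 1")
        self.cluster_weights = w

    def to_json(self) -> str:
        return json.dumps({"pivot": self.pivot,
                           "cluster_weights": self.cluster_weights.tolist(),
                           "n_to_sample": self.n_to_sample,
                           "seed": self.seed}, indent=1)


def pivotal_cluster(model: ClusterModel, seed_genes: set[str]) -> int:
    """Cluster containing the most seed genes; ties go to the lower index."""
    if not seed_genes:
        raise ValueError("seed gene set is empty")
    missing = sorted(g for g in seed_genes if g not in model.assignments)
    if missing:
        raise KeyError(f"seed genes not assigned in the cluster model: {missing}")
    counts = [0] * model.n_clusters
    for g in seed_genes:
        counts[model.assignments[g]] += 1
    return int(np.argmax(counts))  # argmax returns the first (lowest) maximiser


def cluster_weights(model: ClusterModel, pivot: int) -> np.ndarray:
    """Per-cluster sampling probabilities ∝ 1/(1 + distance-to-pivot)."""
    if not 0 <= pivot < model.n_clusters:
        raise IndexError(f"pivot {pivot} out of range")
    raw = np.array([1.0 / (1.0 + cluster_distance(model, c, pivot))
                    for c in range(model.n_clusters)])
    return raw / raw.sum()


def target_sample_size(reference_maps: list[PathwayMap]) -> int:
    """Average enzyme-entry count over the reference maps, rounded half-up."""
    if not reference_maps:
        raise ValueError("need at least one reference map")
    mean = np.mean([len(m.enzyme_entries()) for m in reference_maps])
    return max(1, int(math.floor(mean + 0.5)))


def sample_genes(model: ClusterModel, plan: SamplingPlan,
                 exclude: set[str] = frozenset()) -> set[str]:
    """Draw ``plan.n_to_sample`` distinct genes without replacement.

    Each draw first picks a cluster by the plan's weights (exhausted clusters
    are dropped and the weights renormalised), then a uniformly random unused
    gene of that cluster.  Deterministic given ``plan.seed``; the result is
    disjoint from ``exclude``.
    """
    rng = np.random.default_rng(plan.seed)
    pools = {c: sorted(set(model.cluster_members(c)) - set(exclude))
             for c in range(model.n_clusters)}
    available = sum(len(p) for p in pools.values())
    if available < plan.n_to_sample:
        raise ValueError(f"only {available} genes available, need {plan.n_to_sample}")
    chosen: set[str] = set()
    for _ in range(plan.n_to_sample):
        live = [c for c in range(model.n_clusters) if pools[c]]
        w = plan.cluster_weights[live]
        w = w / w.sum()
        cluster = int(rng.choice(live, p=w))
        idx = int(rng.integers(len(pools[cluster])))
        chosen.add(pools[cluster].pop(idx))
    return chosen
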