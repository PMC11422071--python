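"""Core-collection selection: the two-step P+G strategy and baselines.

The two-step strategy first captures rarity from the phenotypes: every
cluster whose raw-trait centroid falls in either tail of the pooled per-trait
distribution (or whose size is at most 1% of the collection) is flagged rare
and contributes its phenotype-distance medoid.  The remaining quota is spread
over the other clusters by largest-remainder proportional allocation and
filled within each cluster by greedy maximin selection on the genotype (IOF)
distance component — the maximisation-strategy realisation that spreads the
selected accessions as far apart as possible in marker space.

Baselines: ``p_only`` / ``g_only`` run the same per-cluster maximin on the
phenotype-only / genotype-only component, ``traditional_pg`` on the full MGD,
and ``random`` draws a seeded stratified sample with the same allocation.
All strategies are deterministic given the seed; ties break by canonical
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import ClusterAssignment
from .collection import GermplasmCollection
from .distance import DistanceMatrix, mgd_matrix

__all__ = [
    "SelectionConfig",
    "CoreCollection",
    "allocate",
    "identify_rare_clusters",
    "maximin_select",
    "CoreSelector",
    "select_core",
]

STRATEGIES = ("two_step_pg", "p_only", "g_only", "traditional_pg", "random")
DEFAULT_SAMPLING_FRACTION = 22 / 207


@dataclass
class SelectionConfig:
    """Selection strategy and sizing.

    Exactly one of ``target_size`` / ``sampling_fraction`` may be given; with
    neither, the default fraction 22/207 is used.
    """

    target_size: int | None = None
    sampling_fraction: float | None = None
    strategy: str = "two_step_pg"
    rare_quantile: float = 0.05
    min_per_cluster: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.target_size is not None and self.sampling_fraction is not None:
            raise ValueError("give target_size or sampling_fraction, not both")
        if self.sampling_fraction is not None and not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")
        if not 0 < self.rare_quantile < 0.5:
            raise ValueError("rare_quantile must lie in (0, 0.5)")

    def resolve_size(self, n: int) -> int:
        if self.target_size is not None:
            return int(self.target_size)
        frac = self.sampling_fraction if self.sampling_fraction is not None else DEFAULT_SAMPLING_FRACTION
        return max(1, round(frac * n))


@dataclass
class CoreCollection:
    """A selected core: IDs, per-cluster allocation, and provenance."""

    selected_ids: list[str]
    allocation: dict[int, int]
    rare_clusters: list[int]
    strategy: SelectionConfig = field(repr=False)

    def __post_init__(self):
        if len(set(self.selected_ids)) != len(self.selected_ids):
            raise ValueError("selected accessions must be unique")


def allocate(cluster_sizes, target_size: int, min_per_cluster: int = 1) -> list[int]:
    """Largest-remainder proportional allocation with a per-cluster floor.

    Quotas are capped at the cluster sizes and floored at ``min_per_cluster``;
    they sum exactly to ``target_size``.
    """
    sizes = np.asarray(list(cluster_sizes), dtype=float)
    k = len(sizes)
    if (sizes <= 0).any():
        raise ValueError("cluster sizes must be positive")
    floors = np.minimum(min_per_cluster, sizes.astype(int))
    if target_size < floors.sum():
        offenders = [i for i in range(k)]
        raise ValueError(
            f"target_size={target_size} cannot satisfy the floor of "
            f"{min_per_cluster} for {k} clusters {offenders}"
        )
    if target_size > sizes.sum():
        raise ValueError(f"target_size={target_size} exceeds the {int(sizes.sum())} available accessions")

    ideal = target_size * sizes / sizes.sum()
    quotas = np.clip(np.floor(ideal).astype(int), floors, sizes.astype(int))
    # hand out (or retract) seats one at a time by the largest (smallest)
    # deficit relative to the ideal share; floors and caps always respected,
    # ties broken by cluster index
    guard = 0
    while quotas.sum() != target_size:
        deficit = ideal - quotas
        if quotas.sum() < target_size:
            order = sorted(range(k), key=lambda i: (-deficit[i], i))
            for i in order:
                if quotas[i] < sizes[i]:
                    quotas[i] += 1
                    break
        else:
            order = sorted(range(k), key=lambda i: (deficit[i], i))
            for i in order:
                if quotas[i] > floors[i]:
                    quotas[i] -= 1
                    break
        guard += 1
        if guard > target_size + int(sizes.sum()):
            raise RuntimeError("allocation failed to converge")
    return quotas.astype(int).tolist()


def identify_rare_clusters(
    c: GermplasmCollection,
    clusters: ClusterAssignment,
    rare_quantile: float = 0.05,
) -> list[int]:
    """Clusters whose raw-trait centroid breaches a pooled tail, or tiny ones.

    A cluster is rare iff its centroid falls below the ``rare_quantile`` or
    above the ``1 - rare_quantile`` quantile of the pooled distribution on
    any quantitative trait, or its size is at most ``max(1, ceil(0.01 n))``.
    """
    q = c.quantitative_index
    X = c.phenotypes[:, q]
    if np.isnan(X).any():
        raise ValueError("phenotypes contain missing values: impute first")
    lo = np.quantile(X, rare_quantile, axis=0)
    hi = np.quantile(X, 1.0 - rare_quantile, axis=0)
    size_cut = max(1, int(np.ceil(0.01 * c.n_accessions)))
    rare = []
    for g in range(1, clusters.k + 1):
        members = clusters.members(g)
        if members.size == 0:
            continue
        centroid = X[members].mean(axis=0)
        if members.size <= size_cut or (centroid < lo).any() or (centroid > hi).any():
            rare.append(g)
    return rare


def maximin_select(
    d: DistanceMatrix,
    candidate_ids,
    quota: int,
    preselected_ids=(),
) -> list[str]:
    """Greedy maximin (p-dispersion) selection on a distance matrix.

    With no preselected accessions the seed is the candidate pair at maximal
    distance (the medoid — minimal distance sum — for quota 1); afterwards the
    candidate maximising its minimum distance to everything already selected
    is added repeatedly.  Deterministic; ties break by candidate input order.
    """
    candidates = list(candidate_ids)
    if quota > len(candidates):
        raise ValueError(f"quota {quota} exceeds {len(candidates)} candidates")
    if quota <= 0:
        return []
    idx = {a: d.index_of(a) for a in candidates}
    pre = [d.index_of(a) for a in preselected_ids]
    chosen: list[str] = []

    if not pre:
        if quota == 1:
            sums = [d.values[idx[a], [idx[b] for b in candidates]].sum() for a in candidates]
            return [candidates[int(np.argmin(sums))]]
        best = None
        for ai in range(len(candidates)):
            for bi in range(ai + 1, len(candidates)):
                val = d.values[idx[candidates[ai]], idx[candidates[bi]]]
                if best is None or val > best[0] + 1e-15:
                    best = (val, ai, bi)
        chosen = [candidates[best[1]], candidates[best[2]]]

    anchor = pre + [idx[a] for a in chosen]
    remaining = [a for a in candidates if a not in chosen]
    while len(chosen) < quota:
        gains = [d.values[idx[a], anchor].min() for a in remaining]
        pick = int(np.argmax(gains))
        chosen.append(remaining[pick])
        anchor.append(idx[remaining[pick]])
        remaining.pop(pick)
    return chosen


class CoreSelector(BaseEstimator):
    """Estimator-style front end for core selection.

    ``fit(collection, clusters)`` computes the needed MGD components and
    stores the result in ``core_``, ``selected_ids_``, ``allocation_`` and
    ``rare_clusters_``.
    """

    def __init__(
        self,
        target_size: int | None = None,
        sampling_fraction: float | None = None,
        strategy: str = "two_step_pg",
        rare_quantile: float = 0.05,
        min_per_cluster: int = 1,
        seed: int | None = None,
    ):
        self.target_size = target_size
        self.sampling_fraction = sampling_fraction
        self.strategy = strategy
        self.rare_quantile = rare_quantile
        self.min_per_cluster = min_per_cluster
        self.seed = seed

    def fit(self, collection: GermplasmCollection, clusters: ClusterAssignment):
        cfg = SelectionConfig(
            target_size=self.target_size,
            sampling_fraction=self.sampling_fraction,
            strategy=self.strategy,
            rare_quantile=self.rare_quantile,
            min_per_cluster=self.min_per_cluster,
            seed=self.seed,
        )
        self.core_ = select_core(collection, clusters, cfg)
        self.selected_ids_ = self.core_.selected_ids
        self.allocation_ = self.core_.allocation
        self.rare_clusters_ = self.core_.rare_clusters
        return self


def select_core(
    c: GermplasmCollection,
    clusters: ClusterAssignment,
    cfg: SelectionConfig,
) -> CoreCollection:
    """Select a core collection under the configured strategy (see module docs)."""
    n = c.n_accessions
    target = cfg.resolve_size(n)
    ids = c.accession_ids
    if target > n:
        raise ValueError(f"target_size={target} exceeds the {n} available accessions")
    if target == n:
        sizes = {g: int(clusters.members(g).size) for g in range(1, clusters.k + 1)}
        return CoreCollection(list(ids), {g: s for g, s in sizes.items() if s}, [], cfg)

    groups = [g for g in range(1, clusters.k + 1) if clusters.members(g).size > 0]
    members = {g: [ids[i] for i in clusters.members(g)] for g in groups}

    if cfg.strategy == "two_step_pg":
        eul = mgd_matrix(c, "eul")
        iof = mgd_matrix(c, "iof") if c.bands.shape[1] else eul
        rare = identify_rare_clusters(c, clusters, cfg.rare_quantile)
        rare = [g for g in rare if g in groups]
        selected: list[str] = []
        allocation: dict[int, int] = {}
        # step 1: one phenotype-distance medoid per rare cluster
        for g in rare:
            medoid = maximin_select(eul.submatrix(members[g]), members[g], 1)
            selected.extend(medoid)
            allocation[g] = 1
        remaining = target - len(selected)
        non_rare = [g for g in groups if g not in rare]
        if remaining < 0 or (non_rare and remaining < len(non_rare) * cfg.min_per_cluster):
            raise ValueError(
                f"target_size={target} too small for {len(rare)} rare clusters plus "
                f"{len(non_rare)} clusters at min_per_cluster={cfg.min_per_cluster}"
            )
        if non_rare:
            quotas = allocate([len(members[g]) for g in non_rare], remaining, cfg.min_per_cluster)
            for g, quota in zip(non_rare, quotas):
                allocation[g] = quota
                selected.extend(maximin_select(iof.submatrix(members[g]), members[g], quota))
        return CoreCollection(selected, allocation, rare, cfg)

    if cfg.strategy == "random":
        rng = np.random.default_rng(cfg.seed)
        quotas = allocate([len(members[g]) for g in groups], target, cfg.min_per_cluster)
        selected = []
        allocation = {}
        for g, quota in zip(groups, quotas):
            pick = rng.choice(len(members[g]), size=quota, replace=False)
            selected.extend(members[g][i] for i in sorted(pick))
            allocation[g] = quota
        return CoreCollection(selected, allocation, [], cfg)

    component = {"p_only": "eul", "g_only": "iof", "traditional_pg": "mgd"}[cfg.strategy]
    if component in ("iof", "mgd") and not c.bands.shape[1]:
        raise ValueError(f"strategy {cfg.strategy!r} needs band data")
    d = mgd_matrix(c, component)
    quotas = allocate([len(members[g]) for g in groups], target, cfg.min_per_cluster)
    selected = []
    allocation = {}
    for g, quota in zip(groups, quotas):
        allocation[g] = quota
        selected.extend(maximin_select(d.submatrix(members[g]), members[g], quota))
    return CoreCollection(selected, allocation, [], cfg)
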