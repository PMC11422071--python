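"""Allocation, rare-cluster flagging, greedy maximin, and the selection
strategies."""

import itertools

import numpy as np
import pytest
from scipy import stats

from germcore.clustering import ClusterAssignment, cluster
from germcore.distance import DistanceMatrix, mgd_matrix
from germcore.imputation import impute
from germcore.selection import (
    SelectionConfig,
    allocate,
    identify_rare_clusters,
    maximin_select,
    select_core,
)
from germcore.simulate import simulate

from conftest import make_collection


def _assignment(labels):
    labels = np.asarray(labels)
    k = int(labels.max())
    return ClusterAssignment(labels, k, np.zeros((k, 1)), 0.0, {}, 0)


def _dmatrix(points):
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    return DistanceMatrix([f"A{i + 1}" for i in range(len(points))], d2, "eul")


class TestAllocate:
    def test_exact_proportions(self):
        assert allocate([50, 30, 20], 10) == [5, 3, 2]

    def test_all_singletons(self):
        assert allocate([1, 1, 1], 3) == [1, 1, 1]

    def test_floor_binds_against_proportionality(self):
        assert allocate([97, 1, 2], 3) == [1, 1, 1]

    def test_sums_to_target_and_respects_caps(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 8))
            sizes = rng.integers(1, 40, size=k)
            lo = k
            hi = int(sizes.sum())
            target = int(rng.integers(lo, hi + 1))
            q = allocate(sizes.tolist(), target)
            assert sum(q) == target
            assert all(1 <= qi <= s for qi, s in zip(q, sizes))

    def test_matches_brute_force_on_proportional_deviation(self, rng):
        # oracle: among feasible allocations, largest-remainder should achieve
        # the minimal max proportional deviation family; check total deviation
        for _ in range(30):
            sizes = rng.integers(1, 15, size=3)
            target = int(min(sizes.sum(), rng.integers(3, 10)))
            if target < 3:
                continue
            q = allocate(sizes.tolist(), target)
            ideal = target * sizes / sizes.sum()
            best = None
            for cand in itertools.product(*[range(1, s + 1) for s in sizes]):
                if sum(cand) != target:
                    continue
                dev = np.abs(np.array(cand) - ideal).sum()
                best = dev if best is None else min(best, dev)
            assert np.abs(np.array(q) - ideal).sum() <= best + 1e-9

    def test_infeasible_floor_raises(self):
        with pytest.raises(ValueError, match="floor"):
            allocate([5, 5, 5], 2)


class TestRareClusters:
    def test_planted_extreme_cluster_is_flagged(self, default_sim):
        _, complete, truth = default_sim
        a = _assignment(truth.labels)
        rare = identify_rare_clusters(complete, a)
        assert truth.rare_cluster in rare

    def test_median_centroid_cluster_never_flagged(self, rng):
        # the median cannot breach a 5% tail; a central cluster stays unflagged
        x = rng.normal(50, 10, size=(200, 2))
        coll = make_collection(x)
        labels = np.where(np.abs(x[:, 0] - 50) < 3, 1, 2)
        if (labels == 1).sum() < 10:
            labels[:10] = 1
        rare = identify_rare_clusters(coll, _assignment(labels))
        assert 1 not in rare

    def test_singleton_cluster_flagged_by_size(self, rng):
        x = rng.normal(50, 10, size=(60, 2))
        labels = np.ones(60, dtype=int)
        labels[0] = 2
        coll = make_collection(x)
        rare = identify_rare_clusters(coll, _assignment(labels))
        assert 2 in rare


class TestMaximin:
    def test_three_points_quota_two_takes_extremes(self):
        d = _dmatrix([0.0, 1.0, 10.0])
        assert set(maximin_select(d, d.ids, 2)) == {"A1", "A3"}

    def test_quota_equals_candidates_returns_all(self):
        d = _dmatrix([0.0, 1.0, 2.0])
        assert set(maximin_select(d, d.ids, 3)) == set(d.ids)

    def test_quota_one_returns_medoid(self):
        d = _dmatrix([0.0, 4.0, 5.0, 9.0])
        assert maximin_select(d, d.ids, 1) == ["A2"]

    def test_quota_above_candidates_raises(self):
        d = _dmatrix([0.0, 1.0])
        with pytest.raises(ValueError):
            maximin_select(d, d.ids, 3)

    def test_greedy_within_half_of_exhaustive_optimum(self, rng):
        # the classical greedy p-dispersion guarantee
        for trial in range(100):
            n = int(rng.integers(4, 12))
            quota = int(rng.integers(2, min(4, n) + 1))
            pts = rng.normal(0, 1, size=(n, 2))
            d = _dmatrix(pts)
            sel = maximin_select(d, d.ids, quota)
            idx = [d.ids.index(s) for s in sel]
            greedy_obj = min(
                d.values[a, b] for a in idx for b in idx if a != b
            )
            best = max(
                min(d.values[a, b] for a in comb for b in comb if a != b)
                for comb in itertools.combinations(range(n), quota)
            )
            # distances here are squared; the metric guarantee is on the
            # square root
            assert np.sqrt(greedy_obj) >= 0.5 * np.sqrt(best) - 1e-12

    def test_exact_on_collinear_fixture(self):
        d = _dmatrix([0.0, 1.0, 4.0, 6.0, 10.0])
        sel = maximin_select(d, d.ids, 3)
        idx = [d.ids.index(s) for s in sel]
        obj = min(d.values[a, b] for a in idx for b in idx if a != b)
        best = max(
            min(d.values[a, b] for a in comb for b in comb if a != b)
            for comb in itertools.combinations(range(5), 3)
        )
        assert obj == best


class TestSelectCore:
    def test_rare_cluster_always_represented_by_two_step(self, default_sim):
        _, complete, truth = default_sim
        a = cluster(complete, 7, seed=0)
        cfg = SelectionConfig(target_size=22, strategy="two_step_pg", seed=0)
        core = select_core(complete, a, cfg)
        assert len(core.selected_ids) == 22
        rare_ids = {
            complete.accession_ids[i]
            for i in range(complete.n_accessions)
            if truth.labels[i] == truth.rare_cluster
        }
        assert rare_ids & set(core.selected_ids)
        for g in core.rare_clusters:
            members = {complete.accession_ids[i] for i in a.members(g)}
            assert members & set(core.selected_ids)

    def test_target_size_n_returns_whole_collection(self, default_sim):
        _, complete, _ = default_sim
        a = cluster(complete, 7, seed=0)
        cfg = SelectionConfig(target_size=complete.n_accessions, strategy="two_step_pg")
        core = select_core(complete, a, cfg)
        assert set(core.selected_ids) == set(complete.accession_ids)

    @pytest.mark.parametrize("strategy", ["two_step_pg", "p_only", "g_only", "traditional_pg", "random"])
    def test_deterministic_given_seed_and_exact_size(self, default_sim, strategy):
        _, complete, _ = default_sim
        a = cluster(complete, 7, seed=0)
        cfg = SelectionConfig(target_size=22, strategy=strategy, seed=42)
        c1 = select_core(complete, a, cfg)
        c2 = select_core(complete, a, cfg)
        assert c1.selected_ids == c2.selected_ids
        assert len(c1.selected_ids) == 22
        assert len(set(c1.selected_ids)) == 22

    def test_default_fraction_matches_published_core_share(self, default_sim):
        _, complete, _ = default_sim
        a = cluster(complete, 7, seed=0)
        core = select_core(complete, a, SelectionConfig(strategy="traditional_pg", seed=0))
        assert len(core.selected_ids) == 22  # 22/207 of 207

    def test_stratified_sampling_preserves_cluster_proportions(self):
        # chi-square of core vs whole-collection cluster counts stays
        # non-significant for essentially all seeds
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            sizes = rng.integers(15, 60, size=5)
            labels = np.repeat(np.arange(1, 6), sizes)
            n = labels.size
            coll = make_collection(rng.normal(50, 10, size=(n, 2)))
            a = _assignment(labels)
            cfg = SelectionConfig(target_size=max(10, n // 8), strategy="random", seed=seed)
            core = select_core(coll, a, cfg)
            idx = [coll.index_of(i) for i in core.selected_ids]
            cc = np.bincount(labels[idx], minlength=6)[1:]
            ec = np.bincount(labels, minlength=6)[1:]
            p = stats.chi2_contingency(np.vstack([ec, cc]))[1]
            hits += p > 0.05
        assert hits >= 0.95 * reps
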