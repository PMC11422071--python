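"""Core-vs-entire evaluation statistics: published-table reproduction,
representativeness percentages, diversity and dominant-marker indices."""

import numpy as np
import pytest

from germcore.collection import PedigreeTable
from germcore.evaluation import (
    TraitComparison,
    compare_traits,
    expected_heterozygosity,
    fst,
    nei_index,
    pedigree_correlation,
    pic,
    proportions_test,
    representativeness,
    shannon_weaver,
    trait_stats,
)
from germcore.simulate import PUBLISHED_CORE_CLUSTER_COUNTS

from conftest import make_collection


class TestCompareTraits:
    def test_self_comparison_is_null(self, published_core):
        coll, _ = published_core
        for c in compare_traits(coll, coll.accession_ids, n_boot=200, seed=0):
            assert c.ec["mean"] == c.cc["mean"]
            assert c.mean_p == pytest.approx(1.0)

    def test_published_core_summary_cells(self, published_core):
        # the published per-trait summary of the 22-accession core, at the
        # printed 1-decimal rounding
        coll, _ = published_core
        comps = {c.trait: c for c in compare_traits(coll, coll.accession_ids, n_boot=100, seed=0)}
        fd, ph = comps["flower_diameter"].cc, comps["plant_height"].cc
        assert (round(fd["mean"], 1), round(fd["sd"], 1)) == (7.6, 3.3)
        assert (round(fd["cv"], 1), round(fd["range"], 1)) == (43.4, 11.1)
        assert (fd["min"], fd["max"]) == (2.9, 14.0)
        assert (round(ph["mean"], 1), round(ph["sd"], 1)) == (42.0, 20.6)
        assert (round(ph["cv"], 1), round(ph["range"], 1)) == (49.1, 77.6)
        assert (ph["min"], ph["max"]) == (2.4, 80.0)

    def test_ninefold_variance_ratio_switches_to_welch(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 3, 40)])
        coll = make_collection(np.column_stack([x, x]))
        cc_ids = coll.accession_ids[200:]
        comps = compare_traits(coll, cc_ids, n_boot=300, seed=1)
        assert all(c.levene_p < 0.05 and c.mean_test == "welch" for c in comps)


def _comparison(trait, ec, cc, mean_p=1.0):
    return TraitComparison(trait=trait, ec=ec, cc=cc, levene_p=1.0, mean_test="student", mean_p=mean_p)


def _stats_from(values):
    return trait_stats(np.asarray(values, dtype=float))


class TestRepresentativeness:
    def test_identity_core_scores_perfectly(self, rng):
        s = _stats_from(rng.normal(10, 2, 30))
        out = representativeness([_comparison("t", s, s)])
        assert (out["md_pct"], out["vd_pct"]) == (0.0, 0.0)
        assert out["cr_pct"] == pytest.approx(100.0)
        assert out["vr_pct"] == pytest.approx(100.0)

    def test_published_ranges_give_coincidence_rate_97(self):
        # CR% from the published ranges: R_c = (11.1, 77.6), R_e = (11.1, 82.6)
        cr = 100.0 * np.mean([11.1 / 11.1, 77.6 / 82.6])
        assert round(cr, 1) == 97.0
        ec1, cc1 = _stats_from([0, 11.1]), _stats_from([0, 11.1])
        ec2, cc2 = _stats_from([0, 82.6]), _stats_from([0, 77.6])
        out = representativeness([_comparison("fd", ec1, cc1), _comparison("ph", ec2, cc2)])
        assert round(out["cr_pct"], 1) == 97.0

    def test_double_variance_gives_vd_100(self, rng):
        x = rng.normal(0, 1, 50)
        ec = _stats_from(x * np.sqrt(2))
        cc = _stats_from(x)
        out = representativeness([_comparison("t", ec, cc)])
        assert out["vd_pct"] == pytest.approx(100.0, rel=1e-9)

    def test_zero_denominator_trait_excluded_with_warning(self, rng):
        good = _comparison("ok", _stats_from(rng.normal(5, 1, 20)), _stats_from(rng.normal(5, 1, 20)))
        degenerate = _comparison("flat", _stats_from(rng.normal(5, 1, 20)), _stats_from([3.0, 3.0, 3.0]))
        with pytest.warns(UserWarning, match="flat"):
            out = representativeness([good, degenerate])
        assert out["m"] == 1


class TestDiversityIndices:
    def test_shannon_maximal_at_uniform_counts(self):
        for s in (2, 5, 9):
            assert shannon_weaver([10] * s) == pytest.approx(1.0)

    def test_shannon_of_published_cluster_tally(self):
        assert round(shannon_weaver(PUBLISHED_CORE_CLUSTER_COUNTS), 3) == 0.949

    def test_shannon_degenerate_cases(self):
        assert shannon_weaver([30, 0, 0]) == 0.0
        with pytest.raises(ValueError):
            shannon_weaver([30])

    def test_nei_closed_forms(self):
        assert nei_index([7]) == 0.0
        for s in (2, 4, 10):
            assert nei_index([3] * s) == pytest.approx(1 - 1 / s)
        assert round(nei_index(PUBLISHED_CORE_CLUSTER_COUNTS), 3) == 0.831

    def test_nei_increases_when_counts_become_more_even(self):
        assert nei_index([5, 5, 2]) > nei_index([7, 4, 1])
        assert nei_index([4, 4, 4]) > nei_index([5, 5, 2])


class TestMarkerStats:
    def test_pic_maximal_at_half_presence(self):
        bands = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        coll = make_collection(np.zeros((4, 2)), bands)
        assert pic(coll)["overall"] == pytest.approx(0.5)

    def test_pic_monomorphic_primer_is_zero(self):
        bands = np.ones((5, 3), dtype=np.uint8)
        coll = make_collection(np.zeros((5, 2)), bands)
        assert pic(coll)["overall"] == 0.0

    def test_pic_hand_value_two_alleles(self):
        # q = (0.2, 0.8): mean of 1-(q^2+r^2) = 0.32
        bands = np.zeros((10, 2), dtype=np.uint8)
        bands[:2, 0] = 1
        bands[:8, 1] = 1
        coll = make_collection(np.zeros((10, 2)), bands)
        assert pic(coll)["per_primer"]["P1"] == pytest.approx(0.32)

    def test_pic_never_exceeds_dominant_maximum(self, rng):
        for _ in range(50):
            bands = (rng.random((20, 6)) < rng.uniform(0, 1, 6)).astype(np.uint8)
            coll = make_collection(np.zeros((20, 2)), bands, primer_sizes=[3, 3])
            assert max(pic(coll)["per_allele"].values()) <= 0.5 + 1e-12

    def test_hexp_closed_forms(self):
        one = make_collection(np.zeros((4, 2)), np.ones((4, 1), dtype=np.uint8))
        assert expected_heterozygosity(one)["per_primer"]["P1"] == 0.0
        # two alleles with equal band counts -> 0.5
        bands = np.array([[1, 1], [1, 1], [0, 0]], dtype=np.uint8)
        two = make_collection(np.zeros((3, 2)), bands)
        assert expected_heterozygosity(two)["per_primer"]["P1"] == pytest.approx(0.5)

    def test_hexp_hand_value_counts_10_30_60(self):
        bands = np.zeros((100, 3), dtype=np.uint8)
        bands[:10, 0] = 1
        bands[:30, 1] = 1
        bands[:60, 2] = 1
        coll = make_collection(np.zeros((100, 2)), bands)
        assert expected_heterozygosity(coll)["per_primer"]["P1"] == pytest.approx(0.54)


class TestFst:
    def test_identical_subpopulations_give_zero(self):
        bands = np.array([[1], [0], [1], [0]], dtype=np.uint8)
        coll = make_collection(np.zeros((4, 2)), bands)
        out = fst(coll, [1, 1, 2, 2])
        assert out["overall"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternative_alleles_give_one(self):
        bands = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        coll = make_collection(np.zeros((4, 2)), bands)
        assert fst(coll, [1, 1, 2, 2])["overall"] == pytest.approx(1.0)

    def test_hand_value_frequencies_02_and_06(self):
        bands = np.zeros((10, 1), dtype=np.uint8)
        bands[:1, 0] = 1  # subpop 1: presence 1/5 = 0.2
        bands[5:8, 0] = 1  # subpop 2: presence 3/5 = 0.6
        coll = make_collection(np.zeros((10, 2)), bands)
        labels = [1] * 5 + [2] * 5
        out = fst(coll, labels)
        assert out["overall"] == pytest.approx((0.48 - 0.40) / 0.48)
        assert round(out["overall"], 3) == 0.167

    def test_invariant_to_duplicating_each_subpopulation(self, rng):
        bands = (rng.random((12, 5)) < 0.5).astype(np.uint8)
        coll = make_collection(np.zeros((12, 2)), bands)
        labels = np.array([1] * 6 + [2] * 6)
        doubled = make_collection(
            np.zeros((24, 2)), np.vstack([bands, bands]), ids=[f"B{i}" for i in range(24)]
        )
        lab2 = np.concatenate([labels, labels])
        assert fst(coll, labels)["overall"] == pytest.approx(fst(doubled, lab2)["overall"])

    def test_monomorphic_everything_reports_zero_with_warning(self):
        bands = np.ones((6, 2), dtype=np.uint8)
        coll = make_collection(np.zeros((6, 2)), bands)
        with pytest.warns(UserWarning, match="monomorphic"):
            out = fst(coll, [1, 1, 1, 2, 2, 2])
        assert out["overall"] == 0.0


class TestProportions:
    def test_identical_large_counts_are_non_significant(self):
        out = proportions_test([100, 100, 100], [100, 100, 100])
        assert out["p"] > 0.99

    def test_identical_counts_give_p_one(self):
        out = proportions_test([50, 60], [50, 60])
        assert out["p"] == pytest.approx(1.0)

    def test_extreme_heterogeneity_detected_by_monte_carlo(self):
        out = proportions_test([100, 0], [0, 100], seed=0)
        assert out["p"] < 1e-3

    def test_small_expected_cells_use_monte_carlo(self):
        out = proportions_test([30, 30, 30], [3, 3, 2], seed=0)
        assert out["method"] == "monte_carlo"


class TestPedigree:
    def _table(self, rng, n_cultivars=79, n_ancestors=17):
        # a few founder species dominate the breeding background, as is
        # typical of ornamental pedigrees
        popularity = 0.65 ** np.arange(n_ancestors)
        popularity /= popularity.sum()
        raw = rng.dirichlet(20 * popularity, size=n_cultivars) * 100
        return PedigreeTable(
            [f"C{i}" for i in range(n_cultivars)],
            [f"anc{i}" for i in range(n_ancestors)],
            raw,
        )

    def test_core_equal_to_collection_gives_r_one(self, rng):
        ped = self._table(rng)
        out = pedigree_correlation(ped, ped.cultivar_ids, ped.cultivar_ids)
        assert out["r"] == pytest.approx(1.0)

    def test_proportional_subsample_correlates_strongly(self, rng):
        ped = self._table(rng)
        cc = list(rng.choice(ped.cultivar_ids, size=12, replace=False))
        out = pedigree_correlation(ped, ped.cultivar_ids, cc)
        assert out["r"] > 0.9 and out["n_ancestors"] == 17

    def test_disjoint_ancestry_blocks_decorrelate(self):
        # the core draws on a different ancestor block than the collection
        # average, so the per-ancestor profiles correlate only weakly
        contrib = np.array(
            [
                [50.0, 20.0, 10.0, 10.0, 10.0],
                [20.0, 50.0, 10.0, 10.0, 10.0],
                [10.0, 10.0, 50.0, 20.0, 10.0],
                [10.0, 10.0, 20.0, 50.0, 10.0],
            ]
        )
        ped = PedigreeTable([f"C{i}" for i in range(4)], [f"a{i}" for i in range(5)], contrib)
        out = pedigree_correlation(ped, [f"C{i}" for i in range(4)], ["C2", "C3"])
        assert abs(out["r"]) < 0.6

    def test_too_few_ancestors_rejected(self):
        ped = PedigreeTable(["C0"], ["a0", "a1"], np.array([[60.0, 40.0]]))
        with pytest.raises(ValueError):
            pedigree_correlation(ped, ["C0"], ["C0"])
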