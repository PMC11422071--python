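import numpy as np
import pytest

from germcore.collection import GermplasmCollection, PrimerGroup, TraitSpec
from germcore.simulate import SimulationConfig, simulate, published_core_fixture


@pytest.fixture(scope="session")
def published_core():
    """The published 22-accession core collection and its cluster labels."""
    return published_core_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_collection(phenotypes, bands=None, primer_sizes=None, ids=None):
    """Small helper to assemble a valid collection from raw arrays."""
    phenotypes = np.asarray(phenotypes, dtype=float)
    n, t = phenotypes.shape
    if bands is None:
        bands = np.zeros((n, 0), dtype=np.uint8)
        primers = []
    else:
        bands = np.asarray(bands)
        L = bands.shape[1]
        primer_sizes = primer_sizes or [L]
        assert sum(primer_sizes) == L
        primers, pos = [], 0
        for i, m in enumerate(primer_sizes):
            primers.append(PrimerGroup(f"P{i + 1}", tuple(f"P{i + 1}_a{j + 1}" for j in range(m))))
            pos += m
    return GermplasmCollection(
        accession_ids=ids or [f"A{i + 1}" for i in range(n)],
        phenotypes=phenotypes,
        bands=bands,
        traits=[TraitSpec(f"t{j + 1}", "quantitative", "cm") for j in range(t)],
        primers=primers,
    )


def random_collection(rng, n=None, n_traits=2, n_alleles=None):
    """Random valid collection for property tests."""
    n = n or int(rng.integers(3, 20))
    n_alleles = int(rng.integers(1, 12)) if n_alleles is None else n_alleles
    phen = rng.normal(50, 15, size=(n, n_traits))
    bands = (rng.random((n, n_alleles)) < rng.uniform(0.1, 0.9, size=n_alleles)).astype(np.uint8)
    return make_collection(phen, bands)


@pytest.fixture()
def bivariate_mar_config():
    """Single-population bivariate-normal design with 20% MAR missingness."""

    def _make(n=200, corr=0.8, missing=0.20):
        return SimulationConfig(
            n_accessions=n,
            n_clusters=1,
            cluster_sizes=[n],
            trait_means=[(50.0, 8.0)],
            trait_sds=[(10.0, 2.0)],
            trait_corr=corr,
            rare_cluster=0,
            n_primers=0,
            n_alleles_total=0,
            missing_rate=missing,
        )

    return _make


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulation, imputed once for reuse."""
    from germcore.imputation import impute

    coll, truth = simulate(seed=7)
    complete = coll.with_phenotypes(impute(coll, seed=8).pooled)
    return coll, complete, truth


def hungarian_agreement(truth_labels, pred_labels):
    """Best-matching label agreement in [0, 1]."""
    from scipy.optimize import linear_sum_assignment

    truth_labels = np.asarray(truth_labels)
    pred_labels = np.asarray(pred_labels)
    k1, k2 = truth_labels.max(), pred_labels.max()
    m = np.zeros((k1, k2))
    for a in range(1, k1 + 1):
        for b in range(1, k2 + 1):
            m[a - 1, b - 1] = np.sum((truth_labels == a) & (pred_labels == b))
    r, c = linear_sum_assignment(-m)
    return float(m[r, c].sum() / len(truth_labels))
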