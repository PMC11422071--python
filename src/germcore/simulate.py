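"""Seeded generator of germplasm collections with the study's structure.

The default configuration emulates a commercial orchid germplasm bank of 207
accessions: two positively correlated quantitative traits (plant height and
flower diameter, within-cluster Pearson r = 0.8), seven latent clusters
spanning dwarf/small-flowered to tall/large-flowered types — including one
rare eight-member dwarf cluster with the smallest flowers — eight SSR primers
totalling 65 dominant band columns whose presence frequencies are shifted
per cluster, and ~20% missing-at-random phenotypes (the missingness of each
trait depends on the observed value of the other trait).

``published_core_fixture`` returns the published 22-accession core collection
(IDs, nursery, location, cluster, plant height, flower diameter) used as a
ground-truth fixture throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collection import GermplasmCollection, PrimerGroup, TraitSpec

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "published_core_fixture", "PUBLISHED_CORE_CLUSTER_COUNTS"]

# per-cluster (size, height mean, diameter mean, height sd, diameter sd);
# cluster 7 is the rare dwarf, smallest-flower cluster
_DEFAULT_CLUSTERS = [
    (37, 20.0, 5.2, 2.2, 0.5),
    (37, 30.0, 6.0, 2.2, 0.5),
    (33, 46.0, 7.6, 2.2, 0.5),
    (34, 59.0, 9.4, 2.2, 0.5),
    (30, 72.0, 11.6, 2.6, 0.62),
    (28, 85.0, 13.8, 2.6, 0.62),
    (8, 2.5, 1.2, 0.4, 0.25),
]


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters (defaults are the study conditions)."""

    n_accessions: int = 207
    n_clusters: int = 7
    cluster_sizes: list[int] = field(default_factory=lambda: [c[0] for c in _DEFAULT_CLUSTERS])
    trait_means: list[tuple[float, float]] = field(
        default_factory=lambda: [(c[1], c[2]) for c in _DEFAULT_CLUSTERS]
    )
    trait_sds: list[tuple[float, float]] = field(
        default_factory=lambda: [(c[3], c[4]) for c in _DEFAULT_CLUSTERS]
    )
    trait_corr: float = 0.8
    rare_cluster: int = 7  # 1-based index of the planted rare cluster (0 = none)
    n_primers: int = 8
    n_alleles_total: int = 65
    allele_freq_range: tuple[float, float] = (0.15, 0.85)
    cluster_allele_shift: float = 0.15
    missing_rate: float = 0.20
    seed: int | None = None

    def __post_init__(self):
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if sum(self.cluster_sizes) != self.n_accessions:
            raise ValueError(
                f"cluster sizes sum to {sum(self.cluster_sizes)}, expected {self.n_accessions}"
            )
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if len(self.trait_means) != self.n_clusters or len(self.trait_sds) != self.n_clusters:
            raise ValueError("trait_means/trait_sds must have one entry per cluster")
        if not -1 < self.trait_corr < 1:
            raise ValueError("trait_corr must lie in (-1, 1)")
        if self.n_primers > 0 and self.n_alleles_total < self.n_primers:
            raise ValueError("need at least one allele per primer")


@dataclass
class SimulationTruth:
    """Generating state: labels, pre-masking traits, allele probabilities."""

    labels: np.ndarray  # 1..k per accession
    true_phenotypes: np.ndarray  # before masking
    allele_probs: np.ndarray  # (k, L) per-cluster presence probabilities
    rare_cluster: int


def _primer_blocks(n_primers: int, n_alleles: int) -> list[int]:
    base, extra = divmod(n_alleles, n_primers)
    return [base + (1 if i < extra else 0) for i in range(n_primers)]


def simulate(cfg: SimulationConfig | None = None, seed: int | None = None):
    """Draw a collection (and its truth record) from the configured design.

    ``seed`` overrides ``cfg.seed`` when given.  Deterministic per seed.
    Returns ``(GermplasmCollection, SimulationTruth)``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    k = cfg.n_clusters
    labels = np.repeat(np.arange(1, k + 1), cfg.cluster_sizes)
    n = cfg.n_accessions

    # traits: per-cluster bivariate normal with the configured correlation
    X = np.empty((n, 2))
    for g in range(1, k + 1):
        rows = labels == g
        mu = np.asarray(cfg.trait_means[g - 1], dtype=float)
        sd = np.asarray(cfg.trait_sds[g - 1], dtype=float)
        cov = np.array(
            [
                [sd[0] ** 2, cfg.trait_corr * sd[0] * sd[1]],
                [cfg.trait_corr * sd[0] * sd[1], sd[1] ** 2],
            ]
        )
        X[rows] = rng.multivariate_normal(mu, cov, size=int(rows.sum()), method="cholesky")
    true_phen = X.copy()

    # bands: cluster-shifted presence probabilities, clipped into (0, 1)
    L = cfg.n_alleles_total if cfg.n_primers > 0 else 0
    if L:
        lo, hi = cfg.allele_freq_range
        base = rng.uniform(lo, hi, size=L)
        shift = rng.uniform(-cfg.cluster_allele_shift, cfg.cluster_allele_shift, size=(k, L))
        probs = np.clip(base[None, :] + shift, 0.02, 0.98)
        bands = (rng.random((n, L)) < probs[labels - 1]).astype(np.uint8)
        blocks = _primer_blocks(cfg.n_primers, L)
        allele_ids = [f"SSR{p + 1}_a{a + 1}" for p, b in enumerate(blocks) for a in range(b)]
        primers, pos = [], 0
        for p, b in enumerate(blocks):
            primers.append(PrimerGroup(f"SSR{p + 1}", tuple(allele_ids[pos : pos + b])))
            pos += b
    else:
        probs = np.zeros((k, 0))
        bands = np.zeros((n, 0), dtype=np.uint8)
        primers = []

    # MAR masking: each trait is masked only where the other trait is
    # observed, with probability increasing in the other trait's value
    if cfg.missing_rate > 0:
        mask = np.zeros((n, 2), dtype=bool)
        mask[:, 1] = rng.random(n) < cfg.missing_rate  # diameter: MCAR
        donors = ~mask[:, 1]
        z = (X[donors, 1] - X[donors, 1].mean()) / X[donors, 1].std()
        logits = z.copy()
        # calibrate the intercept so the marginal height missing rate matches
        target = cfg.missing_rate * n / max(int(donors.sum()), 1)
        lo_b, hi_b = -10.0, 10.0
        for _ in range(60):
            mid = 0.5 * (lo_b + hi_b)
            if np.mean(1 / (1 + np.exp(-(logits + mid)))) < target:
                lo_b = mid
            else:
                hi_b = mid
        p_h = 1 / (1 + np.exp(-(logits + 0.5 * (lo_b + hi_b))))
        mask[donors, 0] = rng.random(int(donors.sum())) < p_h
        X = X.copy()
        X[mask] = np.nan

    nurseries = [chr(ord("A") + int(i)) for i in rng.integers(0, 10, size=n)]
    coll = GermplasmCollection(
        accession_ids=[f"ACC{i + 1:04d}" for i in range(n)],
        phenotypes=X,
        bands=bands,
        traits=[
            TraitSpec("plant_height", "quantitative", "cm"),
            TraitSpec("flower_diameter", "quantitative", "cm"),
        ],
        primers=primers,
        nursery=nurseries,
        location=None,
    )
    truth = SimulationTruth(
        labels=labels,
        true_phenotypes=true_phen,
        allele_probs=probs,
        rare_cluster=cfg.rare_cluster,
    )
    return coll, truth


# ---------------------------------------------------------------------------
# published 22-accession core collection fixture
# ---------------------------------------------------------------------------

# (variety, nursery, location, cluster, plant height cm, flower diameter cm)
_PUBLISHED_CORE_ROWS = [
    ("Phal.Equestris", "H", "Tainan", 2, 29.1, 2.9),
    ("OX1233", "E", "Tainan", 4, 80.0, 14.0),
    ("A7524", "B", "Changhua", 3, 55.0, 13.8),
    ("A9333", "B", "Changhua", 1, 20.0, 3.9),
    ("A7403", "B", "Changhua", 2, 25.0, 4.3),
    ("A8591", "B", "Changhua", 1, 20.0, 4.8),
    ("OX1701", "E", "Tainan", 4, 70.0, 12.4),
    ("A10362", "B", "Changhua", 4, 65.0, 12.3),
    ("OX1560", "E", "Tainan", 2, 32.0, 4.9),
    ("OX1408", "E", "Tainan", 4, 74.0, 11.6),
    ("K71303", "G", "Tainan", 4, 65.0, 10.5),
    ("F89320", "C", "Pingtung", 6, 38.0, 5.8),
    ("A9633", "B", "Changhua", 1, 17.0, 5.9),
    ("A5724", "B", "Changhua", 2, 28.0, 6.1),
    ("A6535", "B", "Changhua", 5, 46.0, 6.2),
    ("OX1499", "E", "Tainan", 5, 46.0, 6.4),
    ("A9302", "B", "Changhua", 6, 41.0, 6.7),
    ("A10045", "B", "Changhua", 5, 47.0, 6.8),
    ("A10731", "B", "Changhua", 2, 31.0, 7.2),
    ("VM8400", "G", "Tainan", 3, 58.0, 7.8),
    ("A8521", "B", "Changhua", 6, 34.0, 8.6),
    ("Phal.Bellina", "H", "Tainan", 7, 2.4, 5.2),
]

#: cluster tally of the published core (clusters 1..7)
PUBLISHED_CORE_CLUSTER_COUNTS = (3, 5, 2, 5, 3, 3, 1)


def published_core_fixture() -> tuple[GermplasmCollection, np.ndarray]:
    """The published 22-accession core collection and its cluster labels."""
    coll = GermplasmCollection(
        accession_ids=[r[0] for r in _PUBLISHED_CORE_ROWS],
        phenotypes=np.array([[r[4], r[5]] for r in _PUBLISHED_CORE_ROWS], dtype=float),
        bands=np.zeros((len(_PUBLISHED_CORE_ROWS), 0), dtype=np.uint8),
        traits=[
            TraitSpec("plant_height", "quantitative", "cm"),
            TraitSpec("flower_diameter", "quantitative", "cm"),
        ],
        primers=[],
        nursery=[r[1] for r in _PUBLISHED_CORE_ROWS],
        location=[r[2] for r in _PUBLISHED_CORE_ROWS],
    )
    labels = np.array([r[3] for r in _PUBLISHED_CORE_ROWS], dtype=int)
    return coll, labels
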