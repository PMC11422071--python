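"""Weighted k-means clustering of mixed quantitative + binary data.

The mixed data is mapped to a single real feature space: quantitative traits
are z-standardised and scaled by ``phenotype_weight``; binary band columns
are scaled by ``genotype_weight / sqrt(L)`` (L = total band columns) so the
two blocks enter on comparable footing at weights (1, 1).  Lloyd's algorithm
with farthest-point seeding is then run on the embedding, best of
``n_restarts`` by within-cluster sum of squares.

The number of clusters is chosen by the smallest k whose solution passes all
three of: normalised Shannon evenness of the cluster proportions > 0.90,
Nei diversity of the proportions > 0.80, and explained variance
(between-cluster SS / total SS) > 0.75.  If no k in the range passes, the k
with the smallest total threshold shortfall is returned, flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .collection import GermplasmCollection

__all__ = [
    "ClusterAssignment",
    "MixedEmbedding",
    "FarthestPointKMeans",
    "embed",
    "cluster",
    "select_k",
    "SELECT_K_THRESHOLDS",
]

SELECT_K_THRESHOLDS = {"shannon": 0.90, "nei": 0.80, "explained_variance": 0.75}


@dataclass
class ClusterAssignment:
    """A k-means solution on the embedded space.

    ``labels`` are 1..k, every cluster non-empty; ``explained_variance`` is
    between-cluster SS over total SS of the embedding.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    explained_variance: float
    weights: dict
    seed: int | None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=1) < 1 or (self.k and self.labels.max(initial=1) > self.k):
            raise ValueError("labels must lie in 1..k")
        if not (0.0 <= self.explained_variance <= 1.0 + 1e-12):
            raise ValueError("explained variance must lie in [0, 1]")

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, cluster_index: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster_index)[0]


class MixedEmbedding(BaseEstimator, TransformerMixin):
    """Embed [quantitative | binary] columns into one weighted real space.

    ``X`` is the horizontal concatenation of ``n_quantitative`` trait columns
    and the binary band columns.  Quantitative columns are z-scored (fit
    statistics) then scaled by ``phenotype_weight``; binary columns by
    ``genotype_weight / sqrt(L)``.  Zero-variance traits are dropped with a
    warning.
    """

    def __init__(self, n_quantitative: int, phenotype_weight: float = 1.0, genotype_weight: float = 1.0):
        self.n_quantitative = n_quantitative
        self.phenotype_weight = phenotype_weight
        self.genotype_weight = genotype_weight

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        q = self.n_quantitative
        if self.phenotype_weight < 0 or self.genotype_weight < 0:
            raise ValueError("weights must be nonnegative")
        Xq = X[:, :q]
        if np.isnan(Xq).any():
            raise ValueError("quantitative block contains missing values: impute first")
        mean = Xq.mean(axis=0)
        sd = Xq.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn("zero-variance quantitative trait(s) excluded from embedding")
        self.mean_, self.sd_, self.keep_ = mean, sd, keep
        self.n_binary_ = X.shape[1] - q
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        q = self.n_quantitative
        Xq = (X[:, :q][:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        blocks = [self.phenotype_weight * Xq]
        L = self.n_binary_
        if L:
            blocks.append(self.genotype_weight / np.sqrt(L) * X[:, q:])
        return np.hstack(blocks)


class FarthestPointKMeans(BaseEstimator, ClusterMixin):
    """Lloyd k-means with seeded farthest-point initialisation.

    The first centre of each restart is drawn from the seeded RNG; the rest
    are the points maximising their minimum distance to the chosen centres
    (ties to the lowest index).  Assignment ties go to the lowest cluster
    index; a cluster emptied during iteration is re-seeded at the point
    farthest from its current centroid.  Best of ``n_restarts`` by
    within-cluster SS.

    Attributes: ``labels_`` (0-based), ``cluster_centers_``, ``inertia_``,
    ``explained_variance_``.
    """

    def __init__(self, n_clusters: int = 2, n_restarts: int = 20, max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must lie in 1..n={n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            centers = self._init_centers(X, k, rng)
            labels, centers, inertia = self._lloyd(X, centers)
            if best is None or inertia < best[2] - 1e-12:
                best = (labels, centers, inertia)
        labels, centers, inertia = best
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.inertia_ = float(inertia)
        tss = float(((X - X.mean(axis=0)) ** 2).sum())
        self.explained_variance_ = 1.0 - self.inertia_ / tss if tss > 0 else 1.0
        self.explained_variance_ = float(min(max(self.explained_variance_, 0.0), 1.0))
        return self

    @staticmethod
    def _init_centers(X, k, rng):
        n = X.shape[0]
        first = int(rng.integers(n))
        idx = [first]
        d2 = ((X - X[first]) ** 2).sum(axis=1)
        for _ in range(1, k):
            nxt = int(np.argmax(d2))  # argmax ties -> lowest index
            idx.append(nxt)
            d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
        return X[idx].copy()

    def _lloyd(self, X, centers):
        n, k = X.shape[0], centers.shape[0]
        labels = np.full(n, -1)
        for _ in range(self.max_iter):
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)  # ties -> lowest cluster index
            for c in range(k):
                if not (new_labels == c).any():
                    # re-seed an emptied cluster at the farthest point
                    far = int(np.argmax(d2[np.arange(n), new_labels]))
                    centers[c] = X[far]
                    new_labels[far] = c
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for c in range(k):
                centers[c] = X[labels == c].mean(axis=0)
        d2 = ((X - centers[labels]) ** 2).sum(axis=1)
        return labels, centers, float(d2.sum())

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# collection-level wrappers
# ---------------------------------------------------------------------------

def _mixed_matrix(c: GermplasmCollection) -> tuple[np.ndarray, int]:
    q = c.quantitative_index
    X = np.hstack([c.phenotypes[:, q], c.bands.astype(float)])
    return X, len(q)


def embed(c: GermplasmCollection, phenotype_weight: float = 1.0, genotype_weight: float = 1.0) -> np.ndarray:
    """Embedded accession x feature matrix (see :class:`MixedEmbedding`)."""
    X, nq = _mixed_matrix(c)
    return MixedEmbedding(nq, phenotype_weight, genotype_weight).fit_transform(X)


def cluster(
    c: GermplasmCollection,
    k: int,
    phenotype_weight: float = 1.0,
    genotype_weight: float = 1.0,
    seed: int | None = None,
    n_restarts: int = 20,
) -> ClusterAssignment:
    """Weighted k-means of a (complete-phenotype) collection into k clusters."""
    if k < 2:
        raise ValueError("k must be >= 2")
    E = embed(c, phenotype_weight, genotype_weight)
    km = FarthestPointKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed).fit(E)
    return ClusterAssignment(
        labels=km.labels_ + 1,
        k=k,
        centroids=km.cluster_centers_,
        explained_variance=km.explained_variance_,
        weights={"phenotype_weight": phenotype_weight, "genotype_weight": genotype_weight},
        seed=seed,
    )


def _proportion_indices(labels: np.ndarray, k: int) -> tuple[float, float]:
    """Normalised Shannon evenness and Nei diversity of cluster proportions."""
    counts = np.bincount(labels, minlength=k + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    shannon = float(-(nz * np.log(nz)).sum() / np.log(k)) if k > 1 else float("nan")
    nei = float(1.0 - (p**2).sum())
    return shannon, nei


def select_k(
    c: GermplasmCollection,
    k_range=range(2, 11),
    phenotype_weight: float = 1.0,
    genotype_weight: float = 1.0,
    seed: int | None = None,
    n_restarts: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by the three diversity/variance criteria.

    For each k the solution's normalised Shannon evenness, Nei diversity of
    cluster proportions, and explained variance are tabulated; the chosen k*
    is the smallest k passing all thresholds (H' > 0.90, Nei > 0.80,
    EV > 0.75).  If none passes, the k with the smallest total shortfall is
    returned and the diagnostics table carries ``fallback=True``.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k_range")
    if min(ks) < 2 or max(ks) > c.n_accessions - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    rows = []
    for k in ks:
        a = cluster(c, k, phenotype_weight, genotype_weight, seed=seed, n_restarts=n_restarts)
        shannon, nei = _proportion_indices(a.labels, k)
        passes = (
            shannon > SELECT_K_THRESHOLDS["shannon"]
            and nei > SELECT_K_THRESHOLDS["nei"]
            and a.explained_variance > SELECT_K_THRESHOLDS["explained_variance"]
        )
        shortfall = (
            max(0.0, SELECT_K_THRESHOLDS["shannon"] - shannon)
            + max(0.0, SELECT_K_THRESHOLDS["nei"] - nei)
            + max(0.0, SELECT_K_THRESHOLDS["explained_variance"] - a.explained_variance)
        )
        rows.append(
            {
                "k": k,
                "shannon": shannon,
                "nei": nei,
                "explained_variance": a.explained_variance,
                "passes": passes,
                "shortfall": shortfall,
            }
        )
    table = pd.DataFrame(rows).set_index("k")
    passing = table.index[table["passes"]]
    if len(passing):
        k_star = int(passing.min())
        table.attrs["fallback"] = False
    else:
        k_star = int(table["shortfall"].idxmin())
        table.attrs["fallback"] = True
        warnings.warn(f"no k in {ks} meets all thresholds; falling back to k={k_star}")
    return k_star, table
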