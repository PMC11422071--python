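"""Modified genetic distance (MGD) for mixed quantitative + qualitative data.

The pairwise dissimilarity between accessions i and i* is the sum of two
components:

* ``eul`` — squared Euclidean distance over the raw (unstandardised)
  quantitative trait values, ``sum_j (x_ij - x_i*j)^2``;
* ``iof`` — inverse-occurrence-frequency weight over qualitative variables
  (here: dominant band columns, each a two-level variable).  A variable
  contributes 0 when the two accessions share its level and
  ``(ln f_i . ln f_i*)^2`` otherwise, where ``f`` are the whole-collection
  occurrence counts of each accession's level.

``mgd = eul + iof`` entry-wise.  The squared values are used directly as the
dissimilarity (no square root); MGD is symmetric and nonnegative but does not
satisfy the triangle inequality in general.  Note that with counts, a
mismatch on an evenly split variable carries the largest weight and a level
observed exactly once contributes ln(1) = 0; the latter silences a maximally
rare mismatch and is flagged with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .collection import GermplasmCollection

__all__ = [
    "DistanceMatrix",
    "LevelFrequencies",
    "level_frequencies",
    "euclidean_sq",
    "iof_sq",
    "mgd_matrix",
    "distance_summary",
]

Component = Literal["eul", "iof", "mgd"]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise dissimilarity with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    component: Component

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def index_of(self, accession_id: str) -> int:
        return self.ids.index(accession_id)

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.component)


@dataclass
class LevelFrequencies:
    """Per-variable occurrence counts of each level over the whole collection.

    For binary band columns the levels are {0, 1}; ``counts[j, v]`` is the
    number of accessions carrying level ``v`` of variable ``j``.
    """

    ids: list[str]
    levels: np.ndarray  # (n, L) integer level codes per accession
    counts: np.ndarray  # (L, n_levels) occurrence counts

    @property
    def n(self) -> int:
        return len(self.ids)


def level_frequencies(c: GermplasmCollection) -> LevelFrequencies:
    """Tabulate band-level occurrence counts over the whole collection."""
    levels = c.bands.astype(int)
    n, L = levels.shape
    counts = np.zeros((L, 2), dtype=int)
    if L:
        ones = levels.sum(axis=0)
        counts[:, 1] = ones
        counts[:, 0] = n - ones
        if ((counts == 1) & (counts.sum(axis=1, keepdims=True) > 1)).any():
            warnings.warn(
                "a band level occurs exactly once: its mismatches contribute "
                "ln(1) = 0 to the IOF component"
            )
    return LevelFrequencies(list(c.accession_ids), levels, counts)


def euclidean_sq(c: GermplasmCollection, i: str, i_star: str) -> float:
    """Squared Euclidean distance over raw quantitative trait values."""
    a, b = c.index_of(i), c.index_of(i_star)
    q = c.quantitative_index
    xa, xb = c.phenotypes[a, q], c.phenotypes[b, q]
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ValueError(
            f"missing phenotype for {i!r} or {i_star!r}: impute before computing distances"
        )
    return float(np.sum((xa - xb) ** 2))


def iof_sq(freqs: LevelFrequencies, i: str, i_star: str) -> float:
    """Inverse-occurrence-frequency mismatch weight between two accessions.

    Sum over qualitative variables of ``(ln f_i . ln f_i*)^2`` on mismatched
    levels, 0 on matches, with ``f`` the whole-collection level counts.
    """
    a, b = freqs.ids.index(i), freqs.ids.index(i_star)
    la, lb = freqs.levels[a], freqs.levels[b]
    mism = la != lb
    if not mism.any():
        return 0.0
    idx = np.nonzero(mism)[0]
    fa = freqs.counts[idx, la[idx]]
    fb = freqs.counts[idx, lb[idx]]
    return float(np.sum((np.log(fa) * np.log(fb)) ** 2))


def _iof_weights(freqs: LevelFrequencies) -> np.ndarray:
    """Per-variable mismatch weight for binary variables: (ln f0 * ln f1)^2."""
    f0 = freqs.counts[:, 0].astype(float)
    f1 = freqs.counts[:, 1].astype(float)
    with np.errstate(divide="ignore"):
        w = (np.log(np.maximum(f0, 1.0)) * np.log(np.maximum(f1, 1.0))) ** 2
    # a variable with a level count of 0 can never mismatch; weight irrelevant
    return w


def mgd_matrix(c: GermplasmCollection, component: Component = "mgd") -> DistanceMatrix:
    """All pairwise values of the chosen MGD component.

    ``component='mgd'`` equals the entry-wise sum of ``'eul'`` and ``'iof'``.
    """
    n = c.n_accessions
    if n < 2:
        raise ValueError("need at least two accessions for a distance matrix")
    if component not in ("eul", "iof", "mgd"):
        raise ValueError(f"unknown component {component!r}")

    values = np.zeros((n, n))
    if component in ("eul", "mgd"):
        q = c.quantitative_index
        X = c.phenotypes[:, q]
        if np.isnan(X).any():
            raise ValueError("phenotypes contain missing values: impute before computing distances")
        sq = np.sum(X**2, axis=1)
        eul = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.maximum(eul, 0.0, out=eul)
        values += eul
    if component in ("iof", "mgd") and c.bands.shape[1]:
        freqs = level_frequencies(c)
        w = _iof_weights(freqs)
        B = freqs.levels.astype(float)
        Bw = B * w
        # mismatch_j(i, i*) = x_ij (1 - x_i*j) + (1 - x_ij) x_i*j
        iof = Bw @ (1.0 - B).T + (1.0 - B) @ Bw.T
        values += iof
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return DistanceMatrix(list(c.accession_ids), values, component)


def distance_summary(d: DistanceMatrix, labels: np.ndarray | None = None) -> dict:
    """Off-diagonal summary, optionally broken down by cluster pair.

    With ``labels`` (one label per accession) the result includes a
    ``cluster_pair_mean`` table whose diagonal holds within-cluster means and
    off-diagonal entries between-cluster means (NaN for singleton clusters'
    empty within-pairs).
    """
    n = len(d.ids)
    off = ~np.eye(n, dtype=bool)
    vals = d.values[off]
    out: dict = {
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
    }
    if labels is not None:
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        k = len(uniq)
        pair_mean = np.full((k, k), np.nan)
        for a_i, a in enumerate(uniq):
            for b_i, b in enumerate(uniq):
                mask = np.outer(labels == a, labels == b) & off
                if mask.any():
                    pair_mean[a_i, b_i] = float(d.values[mask].mean())
        out["clusters"] = uniq.tolist()
        out["cluster_pair_mean"] = pair_mean
        within = np.diag(pair_mean)
        between = pair_mean[~np.eye(k, dtype=bool)]
        out["within_mean"] = float(np.nanmean(within)) if np.isfinite(within).any() else float("nan")
        out["between_mean"] = float(np.nanmean(between)) if between.size and np.isfinite(between).any() else float("nan")
    return out
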