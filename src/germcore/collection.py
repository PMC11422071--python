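"""Data model and on-disk formats for mixed phenotype/genotype germplasm collections.

A collection couples a quantitative phenotype matrix (missing cells allowed,
encoded as NaN) with a dominant marker band matrix (strict 0/1, no missing),
the grouping of band columns into primers, and per-accession provenance
(nursery, location).  The accession ID is the join key across all files and
the order of the phenotype file is canonical.

On-disk layout (all CSV, headers required):

* ``phenotypes.csv`` — ``accession_id,nursery,location,<trait>,...``
* ``bands.csv``      — ``accession_id,<allele>,...`` with 0/1 entries
* ``primers.csv``    — long format ``primer_id,allele_id``
* ``pedigree.csv``   — ``cultivar_id,<ancestor>,...`` contribution percentages

Empty cells and ``NA`` are both read as missing; missing is written back as
an empty cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "PrimerGroup",
    "GermplasmCollection",
    "PedigreeTable",
    "CollectionError",
    "read_collection",
    "write_collection",
    "read_pedigree",
    "summary",
]

_MISSING_MARKERS = ["", "NA"]
_META_COLUMNS = ("nursery", "location")


class CollectionError(ValueError):
    """Raised when a collection violates its invariants or cannot be loaded."""


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: its label, kind and units."""

    name: str
    kind: str = "quantitative"  # {"quantitative", "qualitative"}
    units: str = ""

    def __post_init__(self):
        if self.kind not in ("quantitative", "qualitative"):
            raise CollectionError(f"unknown trait kind {self.kind!r}")


@dataclass(frozen=True)
class PrimerGroup:
    """One SSR primer and the ordered band (allele) columns it scored."""

    primer_id: str
    allele_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.allele_ids) == 0:
            raise CollectionError(f"primer {self.primer_id!r} has no alleles")


@dataclass
class GermplasmCollection:
    """In-memory germplasm collection: accessions x (traits, bands).

    Parameters
    ----------
    accession_ids : ordered unique labels.
    phenotypes : (n, n_traits) float array; NaN marks a missing cell.
    bands : (n, n_alleles) 0/1 array; may have zero columns.
    traits : TraitSpec per phenotype column.
    primers : PrimerGroup list partitioning the band columns.
    nursery, location : optional per-accession labels (None for unknown).
    """

    accession_ids: list[str]
    phenotypes: np.ndarray
    bands: np.ndarray
    traits: list[TraitSpec]
    primers: list[PrimerGroup]
    nursery: list[str | None] | None = None
    location: list[str | None] | None = None

    def __post_init__(self):
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        self.bands = np.asarray(self.bands)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n = len(self.accession_ids)
        if n == 0:
            raise CollectionError("no accessions")
        dupes = _duplicates(self.accession_ids)
        if dupes:
            raise CollectionError(f"duplicated accession IDs: {sorted(dupes)}")
        if self.phenotypes.shape != (n, len(self.traits)):
            raise CollectionError(
                f"phenotype matrix shape {self.phenotypes.shape} does not match "
                f"{n} accessions x {len(self.traits)} traits"
            )
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise CollectionError(f"duplicated trait names: {sorted(_duplicates(names))}")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.phenotypes).any():
                raise CollectionError("phenotype values must be finite or missing")
        allele_ids = self.allele_ids
        if self.bands.shape != (n, len(allele_ids)):
            raise CollectionError(
                f"band matrix shape {self.bands.shape} does not match "
                f"{n} accessions x {len(allele_ids)} alleles"
            )
        if self.bands.size:
            bad = ~np.isin(self.bands, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise CollectionError(
                    f"non-binary band value {self.bands[i, j]!r} at accession "
                    f"{self.accession_ids[i]!r}, allele {allele_ids[j]!r}"
                )
            self.bands = self.bands.astype(np.uint8)
        else:
            self.bands = self.bands.reshape(n, 0).astype(np.uint8)
        seen: set[str] = set()
        for p in self.primers:
            overlap = seen.intersection(p.allele_ids)
            if overlap:
                raise CollectionError(f"alleles in more than one primer: {sorted(overlap)}")
            seen.update(p.allele_ids)
        for meta in _META_COLUMNS:
            vals = getattr(self, meta)
            if vals is not None and len(vals) != n:
                raise CollectionError(f"{meta} has {len(vals)} entries for {n} accessions")

    # -- derived views ----------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def allele_ids(self) -> list[str]:
        return [a for p in self.primers for a in p.allele_ids]

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def quantitative_index(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.traits) if t.kind == "quantitative"], dtype=int)

    def index_of(self, accession_id: str) -> int:
        try:
            return self.accession_ids.index(accession_id)
        except ValueError:
            raise KeyError(f"unknown accession {accession_id!r}") from None

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phenotypes, index=self.accession_ids, columns=self.trait_names)

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bands, index=self.accession_ids, columns=self.allele_ids)

    def subset(self, ids: Sequence[str]) -> "GermplasmCollection":
        """Row-subset by accession ID, preserving this collection's order metadata."""
        idx = [self.index_of(i) for i in ids]
        return GermplasmCollection(
            accession_ids=[self.accession_ids[i] for i in idx],
            phenotypes=self.phenotypes[idx],
            bands=self.bands[idx],
            traits=list(self.traits),
            primers=list(self.primers),
            nursery=None if self.nursery is None else [self.nursery[i] for i in idx],
            location=None if self.location is None else [self.location[i] for i in idx],
        )

    def with_phenotypes(self, phenotypes: np.ndarray) -> "GermplasmCollection":
        return GermplasmCollection(
            accession_ids=list(self.accession_ids),
            phenotypes=np.asarray(phenotypes, dtype=float).copy(),
            bands=self.bands.copy(),
            traits=list(self.traits),
            primers=list(self.primers),
            nursery=None if self.nursery is None else list(self.nursery),
            location=None if self.location is None else list(self.location),
        )


@dataclass
class PedigreeTable:
    """Cultivar x ancestor contribution percentages (rows need not sum to 100)."""

    cultivar_ids: list[str]
    ancestor_ids: list[str]
    contribution: np.ndarray  # (n_cultivars, n_ancestors), percentages in [0, 100]

    def __post_init__(self):
        self.contribution = np.asarray(self.contribution, dtype=float)
        n, m = len(self.cultivar_ids), len(self.ancestor_ids)
        if self.contribution.shape != (n, m):
            raise CollectionError("pedigree contribution matrix shape mismatch")
        if np.nanmin(self.contribution, initial=0.0) < 0 or np.nanmax(self.contribution, initial=0.0) > 100:
            raise CollectionError("pedigree contributions must lie in [0, 100]")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=_MISSING_MARKERS)


def read_collection(
    phenotype_path,
    bands_path=None,
    primer_map_path=None,
) -> GermplasmCollection:
    """Load and validate a collection from its CSV files.

    ``bands_path``/``primer_map_path`` may be omitted for phenotype-only
    collections (the band matrix is then empty).  Accession IDs must align
    across files; the phenotype file order is canonical.
    """
    pheno = _read_csv(phenotype_path)
    if "accession_id" not in pheno.columns:
        raise CollectionError(f"{phenotype_path}: missing 'accession_id' column")
    if len(pheno) == 0:
        raise CollectionError(f"{phenotype_path}: no accessions")
    ids = pheno["accession_id"].tolist()
    meta: dict[str, list | None] = {}
    for col in _META_COLUMNS:
        if col in pheno.columns:
            meta[col] = [None if pd.isna(v) else str(v) for v in pheno[col]]
        else:
            meta[col] = None
    trait_cols = [c for c in pheno.columns if c not in ("accession_id",) + _META_COLUMNS]
    try:
        values = pheno[trait_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise CollectionError(f"{phenotype_path}: non-numeric trait value ({exc})") from exc
    traits = [TraitSpec(name=c, kind="quantitative", units="cm") for c in trait_cols]

    if bands_path is None:
        bands = np.zeros((len(ids), 0), dtype=np.uint8)
        primers: list[PrimerGroup] = []
    else:
        bdf = _read_csv(bands_path)
        if "accession_id" not in bdf.columns:
            raise CollectionError(f"{bands_path}: missing 'accession_id' column")
        band_ids = bdf["accession_id"].tolist()
        if sorted(band_ids) != sorted(ids):
            only_p = sorted(set(ids) - set(band_ids))
            only_b = sorted(set(band_ids) - set(ids))
            raise CollectionError(
                f"accession IDs disagree between phenotype and band files "
                f"(phenotypes only: {only_p[:5]}, bands only: {only_b[:5]})"
            )
        bdf = bdf.set_index("accession_id").loc[ids]
        allele_cols = list(bdf.columns)
        raw = bdf.to_numpy()
        if pd.isna(raw).any():
            i, j = np.argwhere(pd.isna(raw))[0]
            raise CollectionError(
                f"{bands_path}: missing band value at accession {ids[i]!r}, allele {allele_cols[j]!r}"
            )
        bands = np.empty(raw.shape, dtype=np.uint8)
        for (i, j), v in np.ndenumerate(raw):
            s = str(v).strip()
            if s not in ("0", "1"):
                raise CollectionError(
                    f"{bands_path}: non-binary band value {v!r} at accession "
                    f"{ids[i]!r}, allele {allele_cols[j]!r}"
                )
            bands[i, j] = int(s)
        if primer_map_path is None:
            primers = [PrimerGroup("P1", tuple(allele_cols))] if allele_cols else []
        else:
            pmap = _read_csv(primer_map_path)
            for col in ("primer_id", "allele_id"):
                if col not in pmap.columns:
                    raise CollectionError(f"{primer_map_path}: missing '{col}' column")
            mapped = pmap["allele_id"].tolist()
            if sorted(mapped) != sorted(allele_cols):
                raise CollectionError(
                    "primer map alleles do not match band columns "
                    f"(unmapped: {sorted(set(allele_cols) - set(mapped))[:5]}, "
                    f"unknown: {sorted(set(mapped) - set(allele_cols))[:5]})"
                )
            order: dict[str, list[str]] = {}
            for pid, aid in zip(pmap["primer_id"], pmap["allele_id"]):
                order.setdefault(str(pid), []).append(str(aid))
            primers = [PrimerGroup(pid, tuple(alleles)) for pid, alleles in order.items()]
            col_order = [a for p in primers for a in p.allele_ids]
            bands = bands[:, [allele_cols.index(a) for a in col_order]]

    return GermplasmCollection(
        accession_ids=ids,
        phenotypes=values,
        bands=bands,
        traits=traits,
        primers=primers,
        nursery=meta["nursery"],
        location=meta["location"],
    )


def write_collection(c: GermplasmCollection, directory) -> dict[str, Path]:
    """Write a collection to ``directory`` so that :func:`read_collection`
    reproduces it exactly (round-trip identity, including missingness)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pheno = pd.DataFrame({"accession_id": c.accession_ids})
    if c.nursery is not None:
        pheno["nursery"] = ["" if v is None else v for v in c.nursery]
    if c.location is not None:
        pheno["location"] = ["" if v is None else v for v in c.location]
    for j, t in enumerate(c.traits):
        pheno[t.name] = [("" if np.isnan(v) else repr(float(v))) for v in c.phenotypes[:, j]]
    paths["phenotypes"] = directory / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False)

    if c.bands.shape[1]:
        bdf = pd.DataFrame(c.bands, columns=c.allele_ids)
        bdf.insert(0, "accession_id", c.accession_ids)
        paths["bands"] = directory / "bands.csv"
        bdf.to_csv(paths["bands"], index=False)
        pmap = pd.DataFrame(
            [(p.primer_id, a) for p in c.primers for a in p.allele_ids],
            columns=["primer_id", "allele_id"],
        )
        paths["primers"] = directory / "primers.csv"
        pmap.to_csv(paths["primers"], index=False)
    return paths


def read_pedigree(path) -> PedigreeTable:
    df = _read_csv(path)
    if "cultivar_id" not in df.columns:
        raise CollectionError(f"{path}: missing 'cultivar_id' column")
    ancestors = [c for c in df.columns if c != "cultivar_id"]
    contrib = df[ancestors].astype(float).fillna(0.0).to_numpy()
    return PedigreeTable(df["cultivar_id"].tolist(), ancestors, contrib)


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def summary(c: GermplasmCollection) -> dict:
    """Per-trait (and per-nursery) descriptive statistics.

    Returns a dict with ``per_trait`` and ``per_nursery`` DataFrames plus a
    ``correlations`` DataFrame of pairwise-complete Pearson r between traits.
    SD uses the sample (n-1) denominator; an all-missing trait reports NaN
    statistics with a warning.
    """
    rows = []
    for j, t in enumerate(c.traits):
        col = c.phenotypes[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            warnings.warn(f"trait {t.name!r} has no observed values; statistics reported missing")
        rows.append(_describe(t.name, col, obs))
    per_trait = pd.DataFrame(rows).set_index("trait")

    nursery_rows = []
    if c.nursery is not None:
        groups = sorted({v for v in c.nursery if v is not None})
        for g in groups:
            mask = np.array([v == g for v in c.nursery])
            for j, t in enumerate(c.traits):
                col = c.phenotypes[mask, j]
                obs = col[~np.isnan(col)]
                row = _describe(t.name, col, obs)
                row["nursery"] = g
                nursery_rows.append(row)
    per_nursery = pd.DataFrame(nursery_rows)
    if len(nursery_rows):
        per_nursery = per_nursery.set_index(["nursery", "trait"])

    names = c.trait_names
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            both = ~np.isnan(c.phenotypes[:, a]) & ~np.isnan(c.phenotypes[:, b])
            if both.sum() >= 3:
                r = float(np.corrcoef(c.phenotypes[both, a], c.phenotypes[both, b])[0, 1])
            else:
                r = float("nan")
            corr.iloc[a, b] = corr.iloc[b, a] = r
    return {"per_trait": per_trait, "per_nursery": per_nursery, "correlations": corr}


def _describe(name: str, col: np.ndarray, obs: np.ndarray) -> dict:
    return {
        "trait": name,
        "n": int(obs.size),
        "missing": int(np.isnan(col).sum()),
        "min": float(obs.min()) if obs.size else float("nan"),
        "max": float(obs.max()) if obs.size else float("nan"),
        "mean": float(obs.mean()) if obs.size else float("nan"),
        "sd": float(obs.std(ddof=1)) if obs.size > 1 else float("nan"),
    }
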