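"""Statistics comparing a core collection (CC) to the entire collection (EC).

Covers the standard germplasm evaluation suite:

* per-trait summary and difference tests — Brown-Forsythe (median-centred
  Levene) variance test with a bootstrap p-value, then Student's or Welch's
  t-test for the mean depending on the variance verdict;
* representativeness percentages MD%, VD%, CR%, VR% over the trait set;
* Shannon-Weaver evenness and Nei diversity of group proportions;
* dominant-marker statistics: PIC, expected heterozygosity, and the fixation
  index F_ST = (H_T - H_S) / H_T over subpopulations;
* a chi-square homogeneity test of CC vs EC cluster proportions (Monte-Carlo
  p when expected cells are small);
* Pearson correlation of per-ancestor mean pedigree contributions.

VD% and VR% are computed exactly as printed formulas
(``|V_e - V_c| / V_c`` and ``CV_c / CV_e``); because the opposite
denominator convention also circulates, the swapped-ratio variants are
emitted alongside (``vd_pct_alt``, ``vr_pct_alt``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .collection import GermplasmCollection, PedigreeTable

__all__ = [
    "TraitComparison",
    "compare_traits",
    "representativeness",
    "shannon_weaver",
    "nei_index",
    "pic",
    "expected_heterozygosity",
    "fst",
    "proportions_test",
    "pedigree_correlation",
    "trait_stats",
    "evaluate",
]


@dataclass
class TraitComparison:
    """Summary statistics of one trait in the EC and CC plus difference tests."""

    trait: str
    ec: dict
    cc: dict
    levene_p: float
    mean_test: str  # "student" | "welch"
    mean_p: float


def trait_stats(values: np.ndarray) -> dict:
    """n, min, max, range, mean, sample SD, variance, CV% of observed values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need >= 2 observed values")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "range": float(v.max() - v.min()),
        "mean": mean,
        "sd": sd,
        "variance": float(v.var(ddof=1)),
        "cv": float(sd / mean * 100.0) if mean != 0 else float("nan"),
    }


def _bootstrap_levene_p(groups, n_boot: int, rng) -> tuple[float, float]:
    """Brown-Forsythe statistic and bootstrap p (resampling pooled,
    median-centred groups)."""
    if all(np.allclose(g, g[0]) for g in groups):
        return 0.0, 1.0
    stat, _ = stats.levene(*groups, center="median")
    centred = [g - np.median(g) for g in groups]
    pooled = np.concatenate(centred)
    sizes = [len(g) for g in groups]
    count = 0
    for _ in range(n_boot):
        resampled = [rng.choice(pooled, size=s, replace=True) for s in sizes]
        if all(np.allclose(r, r[0]) for r in resampled):
            continue
        b, _ = stats.levene(*resampled, center="median")
        if b >= stat:
            count += 1
    return float(stat), float((count + 1) / (n_boot + 1))


def compare_traits(
    ec: GermplasmCollection,
    cc_ids,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[TraitComparison]:
    """Per-trait EC vs CC summary statistics and difference tests.

    Variance homogeneity first (bootstrap Brown-Forsythe); the mean test is
    Student's t when ``levene_p >= alpha`` and Welch's otherwise.
    """
    cc_ids = list(cc_ids)
    missing = [i for i in cc_ids if i not in ec.accession_ids]
    if missing:
        raise ValueError(f"core IDs not in the collection: {missing[:5]}")
    cc_idx = [ec.index_of(i) for i in cc_ids]
    rng = np.random.default_rng(seed)
    out = []
    for j, t in enumerate(ec.traits):
        e = ec.phenotypes[:, j]
        c = ec.phenotypes[cc_idx, j]
        e, c = e[~np.isnan(e)], c[~np.isnan(c)]
        if e.size < 2 or c.size < 2:
            raise ValueError(f"trait {t.name!r} has fewer than 2 values in a group")
        _, lev_p = _bootstrap_levene_p([e, c], n_boot, rng)
        if np.allclose(e, e[0]) and np.allclose(c, c[0]):
            mean_p = 1.0 if np.isclose(e[0], c[0]) else 0.0
            test = "student"
        elif lev_p >= alpha:
            test = "student"
            _, mean_p = stats.ttest_ind(e, c, equal_var=True)
        else:
            test = "welch"
            _, mean_p = stats.ttest_ind(e, c, equal_var=False)
        if np.isnan(mean_p):  # identical constant-ish groups
            mean_p = 1.0
        out.append(
            TraitComparison(
                trait=t.name,
                ec=trait_stats(e),
                cc=trait_stats(c),
                levene_p=float(lev_p),
                mean_test=test,
                mean_p=float(mean_p),
            )
        )
    return out


def representativeness(comparisons: list[TraitComparison], alpha: float = 0.05) -> dict:
    """MD%, VD%, CR%, VR% over the compared traits, as printed formulas.

    MD% = share of significant mean tests; VD% = mean |V_e - V_c| / V_c;
    CR% = mean R_c / R_e; VR% = mean CV_c / CV_e (all x100).  Traits with a
    zero denominator are excluded with a warning and m adjusted; the
    denominator-swapped variants are reported as ``vd_pct_alt``/``vr_pct_alt``.
    """
    if not comparisons:
        raise ValueError("need at least one trait comparison")
    md_hits = sum(1 for c in comparisons if c.mean_p < alpha)
    vd, vd_alt, cr, vr, vr_alt = [], [], [], [], []
    for c in comparisons:
        ve, vc = c.ec["variance"], c.cc["variance"]
        re_, rc = c.ec["range"], c.cc["range"]
        cve, cvc = c.ec["cv"], c.cc["cv"]
        if vc == 0 or re_ == 0 or cve == 0 or ve == 0 or cvc == 0:
            warnings.warn(f"trait {c.trait!r} excluded from ratio metrics (zero denominator)")
            continue
        vd.append(abs(ve - vc) / vc)
        vd_alt.append(abs(ve - vc) / ve)
        cr.append(rc / re_)
        vr.append(cvc / cve)
        vr_alt.append(cve / cvc)
    if not cr:
        raise ValueError("no traits with usable denominators")
    return {
        "md_pct": 100.0 * md_hits / len(comparisons),
        "vd_pct": 100.0 * float(np.mean(vd)),
        "vd_pct_alt": 100.0 * float(np.mean(vd_alt)),
        "cr_pct": 100.0 * float(np.mean(cr)),
        "vr_pct": 100.0 * float(np.mean(vr)),
        "vr_pct_alt": 100.0 * float(np.mean(vr_alt)),
        "m": len(cr),
    }


def shannon_weaver(counts) -> float:
    """Normalised Shannon evenness of group counts: -sum p ln p / ln S in [0, 1]."""
    c = np.asarray(list(counts), dtype=float)
    if c.size < 2:
        raise ValueError("need >= 2 groups (ln S = 0 otherwise)")
    if (c < 0).any() or c.sum() == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    p = c / c.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(c.size))


def nei_index(counts) -> float:
    """Nei diversity of group counts: 1 - sum p^2, in [0, 1)."""
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any() or c.sum() == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def _presence_freq(c: GermplasmCollection) -> np.ndarray:
    if not c.bands.shape[1]:
        raise ValueError("collection has no band data")
    return c.bands.mean(axis=0)


def pic(c: GermplasmCollection) -> dict:
    """Dominant-marker polymorphic information content.

    Per allele, q = presence fraction and r = 1 - q; a primer's PIC is the
    mean over its alleles of 1 - (q^2 + r^2) (so 0.5 at q = 0.5 is the
    dominant-marker maximum) and the overall value is the mean over primers.
    """
    q = _presence_freq(c)
    per_allele = 1.0 - (q**2 + (1.0 - q) ** 2)
    out = {"per_primer": {}, "per_allele": dict(zip(c.allele_ids, per_allele.tolist()))}
    pos = 0
    vals = []
    for p in c.primers:
        m = len(p.allele_ids)
        v = float(per_allele[pos : pos + m].mean())
        out["per_primer"][p.primer_id] = v
        vals.append(v)
        pos += m
    out["overall"] = float(np.mean(vals))
    return out


def expected_heterozygosity(c: GermplasmCollection) -> dict:
    """Per-primer expected heterozygosity 1 - sum p_i^2 over the primer's
    allele frequencies (band counts normalised within the primer)."""
    out = {"per_primer": {}}
    pos = 0
    vals = []
    for p in c.primers:
        m = len(p.allele_ids)
        counts = c.bands[:, pos : pos + m].sum(axis=0).astype(float)
        total = counts.sum()
        if total == 0:
            warnings.warn(f"primer {p.primer_id!r} has no bands; Hexp undefined")
            out["per_primer"][p.primer_id] = float("nan")
        else:
            freq = counts / total
            h = float(1.0 - (freq**2).sum())
            out["per_primer"][p.primer_id] = h
            vals.append(h)
        pos += m
    out["overall"] = float(np.mean(vals)) if vals else float("nan")
    return out


def fst(c: GermplasmCollection, subpop_labels) -> dict:
    """Fixation index over subpopulations, per primer and overall.

    Each band column is treated as a two-level dominant locus.  Per locus,
    H_S is the mean over subpopulations of the within-subpopulation gene
    diversity 1 - sum p^2 and H_T the diversity of the unweighted mean level
    frequencies; a primer's F_ST is (mean H_T - mean H_S) / mean H_T over its
    loci and the overall value is the mean over primers.  All-monomorphic
    primers (H_T = 0) report 0 with a warning.
    """
    labels = np.asarray(list(subpop_labels))
    if len(labels) != c.n_accessions:
        raise ValueError("one subpopulation label per accession required")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 subpopulations")
    q_by_pop = np.stack([c.bands[labels == g].mean(axis=0) for g in groups])  # (G, L)
    hs_loc = 1.0 - (q_by_pop**2 + (1.0 - q_by_pop) ** 2)  # (G, L)
    hs = hs_loc.mean(axis=0)  # (L,)
    q_bar = q_by_pop.mean(axis=0)
    ht = 1.0 - (q_bar**2 + (1.0 - q_bar) ** 2)
    out = {"per_primer": {}}
    pos = 0
    vals = []
    for p in c.primers:
        m = len(p.allele_ids)
        HT = float(ht[pos : pos + m].mean())
        HS = float(hs[pos : pos + m].mean())
        if HT == 0.0:
            warnings.warn(f"primer {p.primer_id!r} is monomorphic in all subpopulations; F_ST = 0")
            f = 0.0
        else:
            f = (HT - HS) / HT
        out["per_primer"][p.primer_id] = float(f)
        vals.append(float(f))
        pos += m
    out["overall"] = float(np.mean(vals)) if vals else float("nan")
    out["hs"] = float(hs.mean()) if hs.size else float("nan")
    out["ht"] = float(ht.mean()) if ht.size else float("nan")
    return out


def proportions_test(
    ec_counts,
    cc_counts,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Chi-square homogeneity of two cluster count vectors.

    Falls back to a seeded Monte-Carlo p-value (rows resampled from the
    pooled proportions) whenever any expected cell is below 5.
    """
    a = np.asarray(list(ec_counts), dtype=float)
    b = np.asarray(list(cc_counts), dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the cluster index set")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero totals")
    table = np.vstack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()

    def _chi2(t, e):
        return float(((t - e) ** 2 / e).sum())

    obs = _chi2(table, expected)
    if (expected >= 5).all():
        dof = table.shape[1] - 1
        p = float(stats.chi2.sf(obs, dof))
        return {"statistic": obs, "p": p, "method": "asymptotic", "dof": dof}
    rng = np.random.default_rng(seed)
    pooled = table.sum(axis=0) / table.sum()
    n1, n2 = int(row[0, 0]), int(row[1, 0])
    count = 0
    for _ in range(n_sim):
        t = np.vstack([rng.multinomial(n1, pooled), rng.multinomial(n2, pooled)]).astype(float)
        e = t.sum(axis=1, keepdims=True) @ t.sum(axis=0, keepdims=True) / t.sum()
        mask = e > 0
        stat_sim = float((((t - e) ** 2)[mask] / e[mask]).sum())
        if stat_sim >= obs - 1e-12:
            count += 1
    return {"statistic": obs, "p": float((count + 1) / (n_sim + 1)), "method": "monte_carlo", "n_sim": n_sim}


def pedigree_correlation(ped: PedigreeTable, ec_ids, cc_ids) -> dict:
    """Pearson correlation of per-ancestor mean contributions, EC vs CC.

    Uses only cultivars present in the pedigree table; requires >= 3
    ancestors with a nonzero contribution in either group.
    """
    ec_rows = [i for i, cid in enumerate(ped.cultivar_ids) if cid in set(ec_ids)]
    cc_rows = [i for i, cid in enumerate(ped.cultivar_ids) if cid in set(cc_ids)]
    if not ec_rows or not cc_rows:
        raise ValueError("no pedigree rows overlap the given collections")
    ec_mean = ped.contribution[ec_rows].mean(axis=0)
    cc_mean = ped.contribution[cc_rows].mean(axis=0)
    used = (ec_mean > 0) | (cc_mean > 0)
    if used.sum() < 3:
        raise ValueError("need >= 3 ancestors with nonzero contribution")
    r, p = stats.pearsonr(ec_mean[used], cc_mean[used])
    return {
        "r": float(r),
        "r_squared": float(r**2),
        "p": float(p),
        "n_ancestors": int(used.sum()),
        "n_ec": len(ec_rows),
        "n_cc": len(cc_rows),
    }


def evaluate(
    ec: GermplasmCollection,
    cc_ids,
    cluster_labels=None,
    pedigree: PedigreeTable | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Full evaluation report of a core against the entire collection."""
    comparisons = compare_traits(ec, cc_ids, alpha=alpha, n_boot=n_boot, seed=seed)
    report: dict = {
        "trait_comparisons": comparisons,
        "representativeness": representativeness(comparisons, alpha=alpha),
    }
    cc = ec.subset(cc_ids)
    if cluster_labels is not None:
        labels = np.asarray(cluster_labels)
        cc_idx = [ec.index_of(i) for i in cc_ids]
        uniq = np.unique(labels)
        ec_counts = [(labels == g).sum() for g in uniq]
        cc_counts = [(labels[cc_idx] == g).sum() for g in uniq]
        report["phenotype_diversity"] = {
            "ec": {"shannon": shannon_weaver(ec_counts), "nei": nei_index(ec_counts)},
            "cc": {
                "shannon": shannon_weaver(cc_counts) if len(cc_counts) > 1 else float("nan"),
                "nei": nei_index(cc_counts),
            },
        }
        report["proportions"] = proportions_test(ec_counts, cc_counts, seed=seed)
    if ec.bands.shape[1]:
        report["marker_stats"] = {
            "ec": {"pic": pic(ec), "hexp": expected_heterozygosity(ec)},
            "cc": {"pic": pic(cc), "hexp": expected_heterozygosity(cc)},
        }
        if cluster_labels is not None:
            report["fst"] = {
                "ec": fst(ec, labels),
                "cc": fst(cc, labels[cc_idx]),
            }
    if pedigree is not None:
        report["pedigree"] = pedigree_correlation(pedigree, ec.accession_ids, cc_ids)
    return report


def comparison_table(comparisons: list[TraitComparison]) -> pd.DataFrame:
    """Summary-statistics table in the usual EC/CC-per-trait layout."""
    rows = []
    for c in comparisons:
        for group, d in (("EC", c.ec), ("CC", c.cc)):
            rows.append({"trait": c.trait, "collection": group, **d,
                         "levene_p": c.levene_p, "mean_test": c.mean_test, "mean_p": c.mean_p})
    return pd.DataFrame(rows).set_index(["trait", "collection"])
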