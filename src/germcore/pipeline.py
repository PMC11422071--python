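"""End-to-end pipeline: impute -> cluster -> distance -> select -> evaluate.

Driven by a YAML config with one section per stage; unknown keys are
rejected.  Every stochastic stage receives a seed derived deterministically
from the global seed and the stage name, so a rerun with the same config is
byte-identical.  Each stage writes its artifact into the output directory and
a provenance JSON records the config echo, derived seeds and package version.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster, select_k
from .collection import GermplasmCollection, read_collection, read_pedigree, write_collection
from .distance import distance_summary, mgd_matrix
from .evaluation import comparison_table, evaluate, representativeness
from .imputation import impute
from .selection import SelectionConfig, select_core
from .simulate import SimulationConfig, simulate

log = logging.getLogger("germcore")

__all__ = ["ConfigError", "run_pipeline", "stage_seed", "load_config"]


class ConfigError(ValueError):
    """Config schema violation (unknown key, wrong type, missing input)."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "log_level", "inputs", "simulate", "impute", "cluster", "select", "evaluate"},
    "inputs": {"phenotypes", "bands", "primers", "pedigree"},
    "simulate": {
        "enabled", "n_accessions", "n_clusters", "cluster_sizes", "trait_corr",
        "n_primers", "n_alleles_total", "cluster_allele_shift", "missing_rate",
    },
    "impute": {"n_chains", "n_iter", "n_draws"},
    "cluster": {"k", "k_range", "phenotype_weight", "genotype_weight", "n_restarts"},
    "select": {"target_size", "sampling_fraction", "strategy", "rare_quantile", "min_per_cluster"},
    "evaluate": {"alpha", "n_boot"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(cfg, "")
    for section in ("inputs", "simulate", "impute", "cluster", "select", "evaluate"):
        sub = cfg.get(section)
        if sub is None:
            continue
        if not isinstance(sub, dict):
            raise ConfigError(f"{section}: must be a mapping")
        _check_keys(sub, section)
    return cfg


def _check_keys(d: dict, section: str) -> None:
    unknown = set(d) - _SCHEMA[section]
    if unknown:
        where = section or "top level"
        raise ConfigError(f"unknown config key(s) at {where}: {sorted(unknown)}")


def run_pipeline(config_path, output_dir=None) -> Path:
    """Run the full pipeline; returns the artifact directory.

    Raises :class:`ConfigError` on schema violations; stage failures
    propagate as their own exceptions.
    """
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "germcore_run"))
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg.get("log_level", "INFO")).upper(), logging.INFO))
    seeds = {s: stage_seed(seed, s) for s in ("simulate", "impute", "cluster", "select", "evaluate")}

    sim_cfg = cfg.get("simulate") or {}
    truth = None
    if sim_cfg.get("enabled"):
        params = {k: v for k, v in sim_cfg.items() if k != "enabled"}
        coll, truth = simulate(SimulationConfig(**params), seed=seeds["simulate"])
        write_collection(coll, out / "simulated")
        with open(out / "simulated" / "truth.json", "w") as fh:
            json.dump(
                {"labels": truth.labels.tolist(), "rare_cluster": truth.rare_cluster},
                fh,
            )
        log.info("simulate: n=%d seed=%d", coll.n_accessions, seeds["simulate"])
    else:
        inputs = cfg.get("inputs") or {}
        if "phenotypes" not in inputs:
            raise ConfigError("inputs.phenotypes required when simulate is disabled")
        coll = read_collection(inputs["phenotypes"], inputs.get("bands"), inputs.get("primers"))
        log.info("loaded collection: n=%d", coll.n_accessions)

    imp_cfg = cfg.get("impute") or {}
    res = impute(coll, seed=seeds["impute"], **imp_cfg)
    complete = coll.with_phenotypes(res.pooled)
    pd.DataFrame(res.pooled, index=coll.accession_ids, columns=coll.trait_names).to_csv(
        out / "phenotypes_completed.csv"
    )
    with open(out / "imputation.json", "w") as fh:
        json.dump(res.diagnostics(), fh, indent=2)
    log.info("impute: converged=%s seed=%d", res.converged, seeds["impute"])

    cl_cfg = dict(cfg.get("cluster") or {})
    weights = {
        "phenotype_weight": cl_cfg.pop("phenotype_weight", 1.0),
        "genotype_weight": cl_cfg.pop("genotype_weight", 1.0),
    }
    restarts = cl_cfg.pop("n_restarts", 20)
    if "k" in cl_cfg:
        k = int(cl_cfg["k"])
        table = None
    else:
        k_range = cl_cfg.get("k_range", [2, 10])
        k, table = select_k(
            complete, range(int(k_range[0]), int(k_range[1]) + 1),
            seed=seeds["cluster"], n_restarts=restarts, **weights,
        )
        table.to_csv(out / "select_k.csv")
    assign = cluster(complete, k, seed=seeds["cluster"], n_restarts=restarts, **weights)
    pd.DataFrame({"accession_id": coll.accession_ids, "cluster": assign.labels}).to_csv(
        out / "clusters.csv", index=False
    )
    log.info("cluster: k=%d ev=%.3f seed=%d", k, assign.explained_variance, seeds["cluster"])

    d = mgd_matrix(complete, "mgd")
    pd.DataFrame(d.values, index=d.ids, columns=d.ids).to_csv(out / "distance_mgd.tsv", sep="\t")
    dsum = distance_summary(d, assign.labels)
    with open(out / "distance_summary.json", "w") as fh:
        json.dump({k_: v for k_, v in dsum.items() if not isinstance(v, np.ndarray)}, fh, indent=2, default=str)

    sel_cfg = dict(cfg.get("select") or {})
    sel = SelectionConfig(seed=seeds["select"], **sel_cfg)
    core = select_core(complete, assign, sel)
    core_labels = [int(assign.labels[complete.index_of(i)]) for i in core.selected_ids]
    pd.DataFrame(
        {"accession_id": core.selected_ids, "cluster": core_labels, "strategy": sel.strategy}
    ).to_csv(out / "core.csv", index=False)
    log.info("select: %d accessions, rare clusters %s", len(core.selected_ids), core.rare_clusters)

    ev_cfg = cfg.get("evaluate") or {}
    pedigree = None
    inputs = cfg.get("inputs") or {}
    if inputs.get("pedigree"):
        pedigree = read_pedigree(inputs["pedigree"])
    report = evaluate(
        complete, core.selected_ids, cluster_labels=assign.labels, pedigree=pedigree,
        seed=seeds["evaluate"], **ev_cfg,
    )
    comparison_table(report["trait_comparisons"]).to_csv(out / "trait_comparison.csv")
    serialisable = {
        "representativeness": report["representativeness"],
        "phenotype_diversity": report.get("phenotype_diversity"),
        "proportions": report.get("proportions"),
        "marker_stats": report.get("marker_stats"),
        "fst": report.get("fst"),
        "pedigree": report.get("pedigree"),
    }
    with open(out / "evaluation.json", "w") as fh:
        json.dump(serialisable, fh, indent=2, default=float)

    provenance = {
        "config": cfg,
        "global_seed": seed,
        "stage_seeds": seeds,
        "version": __version__,
        "core_size": len(core.selected_ids),
        "k": k,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return out
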