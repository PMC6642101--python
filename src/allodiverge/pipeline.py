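"""End-to-end orchestration: simulate → assign → rates → expression →
stoichiometry → enrichment, driven by one config and one seed.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stage subsets can be re-run when the upstream files already
exist.  A manifest records the config hash, seed and SHA-256 digests of
every file a stage produced; re-running with identical config and seed
reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_model import (
    load_expression,
    load_gene_table,
    load_interactions,
    load_substitutions,
    load_tfbs,
    log_average_replicates,
)
from .enrichment_stats import tfbs_sharing_test
from .expression_analysis import (
    expression_divergence_call,
    rate_expression_concordance,
    silent_copy_scan,
    spearman_correlation_matrix,
    subgenome_bias_test,
    suppressed_region_scan,
)
from .rate_divergence import test_rate_divergence
from .stoichiometry_network import (
    loss_expression_preference,
    loss_position_test,
    mode_comparison,
    stoichiometry_table,
)
from .subgenome_assignment import HomeologLink, assign_subgenomes
from .synthetic_hybrid import HYBRID, REFERENCE, SimulationConfig, generate_dataset

__all__ = ["STAGES", "load_config", "run_pipeline"]

log = logging.getLogger("allodiverge")

STAGES = ("simulate", "assign", "rates", "expression", "stoich", "enrich")

_REQUIRES = {
    "simulate": (),
    "assign": ("genes.bed", "links.tsv"),
    "rates": ("substitutions.tsv", "pairs.tsv"),
    "expression": ("counts.hyb.tsv", "fpkm.hyb.tsv", "fpkm.ref.tsv",
                   "pairs.tsv", "genes.bed"),
    "stoich": ("interactome.tsv", "group_expression.tsv"),
    "enrich": ("tfbs.tsv", "rates.tsv", "expression_divergence.tsv"),
}
_PRODUCER = {
    "genes.bed": "simulate", "links.tsv": "simulate", "pairs.tsv": "simulate",
    "substitutions.tsv": "simulate", "counts.hyb.tsv": "simulate",
    "fpkm.hyb.tsv": "simulate", "fpkm.ref.tsv": "simulate",
    "interactome.tsv": "simulate", "group_expression.tsv": "simulate",
    "tfbs.tsv": "simulate", "rates.tsv": "rates",
    "expression_divergence.tsv": "expression",
}


def load_config(path: str | Path | None, seed: int | None = None) -> dict:
    """Read the YAML/JSON run config; every threshold is named and
    overridable.  ``seed`` (CLI) overrides the file's seed."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("simulation", {})
    cfg.setdefault("assignment", {})
    cfg.setdefault("rates", {})
    cfg.setdefault("expression", {})
    if seed is not None:
        cfg["seed"] = seed
    cfg.setdefault("seed", cfg["simulation"].get("seed", 0))
    cfg["simulation"]["seed"] = cfg["seed"]
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_links(path: Path) -> list[HomeologLink]:
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str})
    return [
        HomeologLink(
            group_id=row["group_id"],
            gene_a_candidate=row["gene1"],
            gene_b_candidate=row["gene2"],
            identity_to_reference={
                row["gene1"]: float(row["identity1"]),
                row["gene2"]: float(row["identity2"]),
            },
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim = SimulationConfig(**cfg["simulation"])
    dataset = generate_dataset(sim)
    dataset.write(outdir)
    dataset.two_copy_pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    statuses = pd.Series(
        [g.hybrid_status.get(HYBRID, "absent") for g in dataset.groups]
    ).value_counts()
    return {
        "n_groups": len(dataset.groups),
        "n_genes": len(dataset.genes),
        "n_edges": len(dataset.edges),
        "status_counts": {k: int(v) for k, v in statuses.items()},
    }


def _stage_assign(cfg: dict, outdir: Path) -> dict:
    params = cfg["assignment"]
    genes = load_gene_table(outdir / "genes.bed")
    hybrid_genes = [
        g.with_subgenome("unassigned") for g in genes if g.species == HYBRID
    ]
    links = _load_links(outdir / "links.tsv")
    kept, table, removals = assign_subgenomes(
        hybrid_genes,
        links,
        regime=params.get("regime", "identity"),
        margin=params.get("margin", 2.0),
        min_support=params.get("min_support", 10),
        k_neighbors=params.get("k_neighbors", 20),
    )
    table.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
    removals.to_csv(outdir / "assignment_removals.tsv", sep="\t", index=False)
    summary = {
        "n_assigned_A": int((table["subgenome"] == "A").sum()),
        "n_assigned_B": int((table["subgenome"] == "B").sum()),
        "n_removed": int(len(removals)),
    }
    truth = {g.gene_id: g.subgenome for g in genes if g.species == HYBRID
             if g.subgenome in ("A", "B")}
    if truth:
        called = table[table["subgenome"].isin(["A", "B"])]
        hits = sum(
            truth.get(r.gene_id) == r.subgenome for r in called.itertuples()
        )
        summary["accuracy_vs_truth"] = hits / len(called) if len(called) else np.nan
    return summary


def _stage_rates(cfg: dict, outdir: Path) -> dict:
    params = cfg["rates"]
    subs = load_substitutions(outdir / "substitutions.tsv")
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t", dtype=str)
    results, report = test_rate_divergence(
        subs,
        pairs,
        normalize=params.get("normalize", "auto"),
        fdr=params.get("fdr", 0.01),
        fold_min=params.get("fold_min", 3.0),
        saturation_cap=params.get("saturation_cap", 2.0),
    )
    results.to_csv(outdir / "rates.tsv", sep="\t", index=False,
                   float_format="%.12g")
    return {
        "n_tested": report["n_tested"],
        "n_saturated_removed": report["n_saturated"],
        "n_divergent": int(results["divergent"].sum()) if len(results) else 0,
        "n_decelerated": int(results["decelerated"].fillna(False).sum())
        if len(results) else 0,
        "normalization_scale": report["normalization_scale"],
    }


def _stage_expression(cfg: dict, outdir: Path) -> dict:
    params = cfg["expression"]
    fdr = params.get("fdr", 0.01)
    fold_min = params.get("fold_min", 3.0)
    pseudocount = params.get("pseudocount", 0.01)
    counts = load_expression(outdir / "counts.hyb.tsv", unit="count")
    fpkm = load_expression(outdir / "fpkm.hyb.tsv", unit="fpkm")
    fpkm_ref = load_expression(outdir / "fpkm.ref.tsv", unit="fpkm")
    pairs = pd.read_csv(outdir / "pairs.tsv", sep="\t", dtype=str)
    genes = load_gene_table(outdir / "genes.bed")

    calls, report = expression_divergence_call(
        counts.values, pairs, fdr=fdr, fold_min=fold_min
    )
    calls.to_csv(outdir / "expression_divergence.tsv", sep="\t", index=False,
                 float_format="%.12g")

    log_fpkm = log_average_replicates(fpkm, pseudocount=pseudocount)[
        (HYBRID, "log")
    ]
    log_fpkm_ref = log_average_replicates(fpkm_ref, pseudocount=pseudocount)[
        (REFERENCE, "log")
    ]
    a_vals = log_fpkm.loc[pairs["gene_a"]].to_numpy()
    b_vals = log_fpkm.loc[pairs["gene_b"]].to_numpy()
    hybrid_ids = {g.gene_id for g in genes if g.species == HYBRID}
    paired_genes = set(pairs["gene_a"]) | set(pairs["gene_b"])
    assign_path = outdir / "assignment.tsv"
    single_a: list[float] = []
    single_b: list[float] = []
    if assign_path.exists():
        assignment = pd.read_csv(assign_path, sep="\t").set_index("gene_id")
        for gid, row in assignment.iterrows():
            if gid in paired_genes or gid not in hybrid_ids or gid not in log_fpkm.index:
                continue
            if row["subgenome"] == "A":
                single_a.append(float(log_fpkm.loc[gid]))
            elif row["subgenome"] == "B":
                single_b.append(float(log_fpkm.loc[gid]))
    bias = subgenome_bias_test(a_vals, b_vals, single_a, single_b)

    # cross-unit correlation over groups shared by subgenomes and reference
    grp_a = pd.Series(a_vals, index=pairs["group_id"].to_numpy())
    grp_b = pd.Series(b_vals, index=pairs["group_id"].to_numpy())
    ref_of = pd.Series(
        log_fpkm_ref.loc[pairs["gene_ref"]].to_numpy(),
        index=pairs["group_id"].to_numpy(),
    )
    corr = spearman_correlation_matrix(
        {"subgenome_A": grp_a, "subgenome_B": grp_b, "reference": ref_of}
    )
    corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t",
                float_format="%.6g")

    silent = silent_copy_scan(pairs, fpkm)
    silent.to_csv(outdir / "silent_copies.tsv", sep="\t", index=False)
    regions = suppressed_region_scan(
        [g for g in genes if g.species == HYBRID],
        log_fpkm.to_dict(),
        window_kb=params.get("window_kb", 100.0),
        step_kb=params.get("step_kb", 10.0),
        min_genes=params.get("min_genes", 10),
    )
    regions.to_csv(outdir / "suppressed_regions.bed", sep="\t", index=False,
                   header=False)
    return {
        "n_pairs_tested": report["n_pairs"],
        "n_divergent": report["n_divergent"],
        "bias": {k: v for k, v in bias.items()},
        "spearman_A_B": float(corr.loc["subgenome_A", "subgenome_B"]),
        "spearman_A_ref": float(corr.loc["subgenome_A", "reference"]),
        "spearman_B_ref": float(corr.loc["subgenome_B", "reference"]),
        "n_silent_copies": int(len(silent)),
        "n_suppressed_regions": int(len(regions)),
    }


def _stage_stoich(cfg: dict, outdir: Path) -> dict:
    edges = load_interactions(outdir / "interactome.tsv")
    group_expr = pd.read_csv(
        outdir / "group_expression.tsv", sep="\t", index_col="group_id"
    )
    records, skips = stoichiometry_table(edges, group_expr)
    records.to_csv(outdir / "stoichiometry.tsv", sep="\t", index=False,
                   float_format="%.12g")
    comparison = mode_comparison(records)
    try:
        preference = loss_expression_preference(edges, group_expr)
    except ValueError:
        preference = None
    import networkx as nx

    graph = nx.Graph((e.group_a, e.group_b) for e in edges)
    coeffs = nx.clustering(graph)
    singles_a = group_expr.index[group_expr["status"] == "single_A"].tolist()
    singles_b = group_expr.index[group_expr["status"] == "single_B"].tolist()
    try:
        position = loss_position_test(coeffs, singles_a, singles_b)
    except ValueError:
        position = None
    return {
        "n_edges": len(edges),
        "n_records": int(len(records)),
        "skips": skips,
        "verdict": comparison["verdict"],
        "per_class": comparison["per_class"],
        "loss_expression_preference": preference,
        "loss_position_test": position,
    }


def _stage_enrich(cfg: dict, outdir: Path) -> dict:
    tfbs = load_tfbs(outdir / "tfbs.tsv")
    sharing = tfbs_sharing_test(tfbs)
    rates = pd.read_csv(outdir / "rates.tsv", sep="\t")
    expr = pd.read_csv(outdir / "expression_divergence.tsv", sep="\t")
    concordance = rate_expression_concordance(rates, expr)
    return {
        "tfbs_sharing_p": sharing,
        "tfbs_max_p": max(sharing.values()) if sharing else None,
        "concordance": concordance,
    }


_RUNNERS = {
    "simulate": _stage_simulate,
    "assign": _stage_assign,
    "rates": _stage_rates,
    "expression": _stage_expression,
    "stoich": _stage_stoich,
    "enrich": _stage_enrich,
}


def run_pipeline(
    config: Mapping | str | Path | None,
    outdir: str | Path,
    stages: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the requested stages in dependency order.

    ``config`` is a path to a YAML/JSON config or an already-loaded mapping.
    Missing upstream outputs raise an error naming the stage to run first.
    Writes ``summary.json`` and ``manifest.json`` to ``outdir`` and returns
    the summary dict.
    """
    if isinstance(config, (str, Path)) or config is None:
        cfg = load_config(config, seed=seed)
    else:
        cfg = load_config(None, seed=seed)
        for key, val in config.items():
            if isinstance(val, Mapping):
                cfg.setdefault(key, {}).update(val)
            else:
                cfg[key] = val
        if seed is None and "seed" in config:
            cfg["seed"] = config["seed"]
        cfg["simulation"]["seed"] = cfg["seed"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(STAGES) if stages is None else [
        s for s in STAGES if s in set(stages)
    ]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(message)s")
    summary: dict = {"version": __version__, "seed": cfg["seed"],
                     "config": cfg, "stages": {}}
    manifest_stages = []
    before = {p.name for p in outdir.iterdir()}
    for stage in requested:
        for req in _REQUIRES[stage]:
            if not (outdir / req).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs {req}; run stage "
                    f"'{_PRODUCER[req]}' first"
                )
        t0 = time.time()
        log.info("[%s] starting", stage)
        snapshot = {p.name: p.stat().st_mtime_ns for p in outdir.iterdir()}
        summary["stages"][stage] = _RUNNERS[stage](cfg, outdir)
        produced = sorted(
            p.name
            for p in outdir.iterdir()
            if p.name not in snapshot or p.stat().st_mtime_ns != snapshot[p.name]
        )
        manifest_stages.append(
            {
                "stage": stage,
                "outputs": {
                    name: _digest(outdir / name)
                    for name in produced
                    if name not in ("summary.json", "manifest.json")
                },
                "elapsed_s": round(time.time() - t0, 3),
            }
        )
        log.info("[%s] done (%.2fs)", stage, time.time() - t0)
    manifest = {
        "tool": "allodiverge",
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash(cfg),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": manifest_stages,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
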