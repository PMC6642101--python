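"""Self-contained benchmark experiments exercising the pipeline end to end.

Each function regenerates its inputs from the synthetic-data generator (or
closed-form cases), runs the relevant analysis, and returns summary numbers:
the worked stoichiometry case, Monte-Carlo oracle agreement of the rate
test's analytic p-values, null FDR calibration, stoichiometry-mode recovery,
subgenome-assignment recovery, hypergeometric exactness against rational
enumeration, and uniformity of the rate/expression overlap test under
independent divergence channels.

All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import InteractionEdge, UNASSIGNED
from .enrichment_stats import hypergeometric_tail
from .expression_analysis import expression_divergence_call, rate_expression_concordance
from .rate_divergence import divergence_test, test_rate_divergence
from .stoichiometry_network import edge_stoichiometry, mode_comparison, stoichiometry_table
from .subgenome_assignment import assign_subgenomes
from .synthetic_hybrid import (
    HYBRID,
    SimulationConfig,
    generate_genome,
    simulate_expression,
    simulate_network,
    simulate_substitutions,
)

__all__ = [
    "worked_stoichiometry_example",
    "oracle_equivalence",
    "fdr_calibration",
    "mode_recovery",
    "assignment_recovery",
    "hypergeometric_exactness",
    "overlap_uniformity",
]


def _subseeds(master_seed: int, n: int, stream: int) -> np.ndarray:
    rng = np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(1000 + stream,))
    )
    return rng.integers(0, 2**31 - 1, size=n)


def _pair_table(genes, groups) -> pd.DataFrame:
    label = {g.gene_id: g.subgenome for g in genes}
    rows = []
    for grp in groups:
        if grp.hybrid_status.get(HYBRID) != "two_copy":
            continue
        members = grp.members[HYBRID]
        a = next(g for g in members if label[g] == "A")
        b = next(g for g in members if label[g] == "B")
        rows.append({"group_id": grp.group_id, "gene_a": a, "gene_b": b})
    return pd.DataFrame(rows, columns=["group_id", "gene_a", "gene_b"])


def worked_stoichiometry_example() -> dict:
    """Homeolog pair at 10 and 20 FPKM with a 5 FPKM subgenome-A single-copy
    partner: total stoichiometry 30/5 = 6, subgenome-specific 10/5 = 2."""
    table = pd.DataFrame(
        [
            {"group_id": "pair", "status": "two_copy", "fpkm_a": 10.0,
             "fpkm_b": 20.0, "ref_fpkm": 1.0},
            {"group_id": "single", "status": "single_A", "fpkm_a": 5.0,
             "fpkm_b": np.nan, "ref_fpkm": 1.0},
        ]
    ).set_index("group_id")
    edge = InteractionEdge("pair", "single")
    total = edge_stoichiometry(edge, table, "total").hybrid_stoichiometry
    subgenome = edge_stoichiometry(edge, table, "subgenome").hybrid_stoichiometry
    return {"total": float(total), "subgenome": float(subgenome)}


def oracle_equivalence(
    seed: int, n_draws: int = 200, n_mc: int = 100_000
) -> dict:
    """Analytic two-sided p of the rate-divergence test vs a paired-binomial
    Monte-Carlo p over random parameter draws.

    N is uniform on [200, 5000]; dS1, dS2 uniform on [0.1, 1]; omega uniform
    on the range keeping both binomial probabilities omega*dSi in
    [0.02, 0.5].  The empirical p is the exceedance probability of the
    uniformly smoothed folded statistic |D* + U|, U ~ Uniform(±h) with h half
    the finer lattice spacing — the lattice-free analogue of a mid-p, so that
    only Monte-Carlo noise separates it from an exact continuous tail.
    Agreement is measured in Monte-Carlo standard errors.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1001,)))
    deviations = []
    while len(deviations) < n_draws:
        N = int(rng.uniform(200, 5001))
        dS1, dS2 = rng.uniform(0.1, 1.0, 2)
        lo, hi = 0.02 / min(dS1, dS2), 0.5 / max(dS1, dS2)
        if lo >= hi:
            continue
        omega = rng.uniform(lo, hi)
        c1 = rng.binomial(N, dS1 * omega)
        c2 = rng.binomial(N, dS2 * omega)
        omega_hat, _, _, _, p = divergence_test(c1 / N, dS1, c2 / N, dS2, N)
        q1 = min(dS1 * omega_hat, 0.999)
        q2 = min(dS2 * omega_hat, 0.999)
        x = (rng.binomial(N, q1, n_mc) / (N * dS1)
             - rng.binomial(N, q2, n_mc) / (N * dS2))
        t = abs(c1 / (N * dS1) - c2 / (N * dS2))
        h = 0.5 * min(1 / (N * dS1), 1 / (N * dS2))
        w = np.minimum(
            np.clip((x + h - t) / (2 * h), 0.0, 1.0)
            + np.clip((h - t - x) / (2 * h), 0.0, 1.0),
            1.0,
        )
        p_emp = float(w.mean())
        se = max(np.sqrt(p_emp * (1 - p_emp) / n_mc), 1e-9)
        deviations.append((abs(p - p_emp) / se, abs(p - p_emp)))
    dev_se = np.array([d[0] for d in deviations])
    dev_abs = np.array([d[1] for d in deviations])
    return {
        "n_draws": n_draws,
        "n_within_3se": int((dev_se <= 3.0).sum()),
        "fraction_within_3se": float((dev_se <= 3.0).mean()),
        "max_dev_se": float(dev_se.max()),
        "max_abs_dp": float(dev_abs.max()),
    }


def fdr_calibration(seed: int, n_pairs: int = 5000, n_seeds: int = 20) -> dict:
    """Realized false-discovery proportion of the divergence caller on pure
    null data (no injected divergence) at nominal BH 1% with the 3-fold
    filter.  On a null every call is false, so FDP per seed is 1 if anything
    is called and 0 otherwise."""
    fdps = []
    for sub in _subseeds(seed, n_seeds, stream=2):
        cfg = SimulationConfig(
            seed=int(sub), n_groups=n_pairs, loss_rate=0.0,
            frac_rate_divergent=0.0, frac_decelerated=0.0,
        )
        genes, groups, _ = generate_genome(cfg)
        subs, _ = simulate_substitutions(groups, cfg, genes=genes)
        res, _ = test_rate_divergence(subs, _pair_table(genes, groups))
        n_called = int(res["divergent"].sum())
        fdps.append(n_called / max(1, n_called))
    fdps = np.array(fdps, dtype=float)
    return {
        "n_seeds": n_seeds,
        "n_pairs": n_pairs,
        "n_seeds_fdp_le_2pct": int((fdps <= 0.02).sum()),
        "max_fdp": float(fdps.max()),
    }


def mode_recovery(
    seed: int, n_seeds: int = 10, noise_sd: float = 0.3, n_groups: int = 1500
) -> dict:
    """Does mode_comparison recover the generating stoichiometry mode?"""
    out = {}
    min_edges = None
    for k, mode in enumerate(("total", "subgenome")):
        hits = 0
        for sub in _subseeds(seed, n_seeds, stream=3 + k):
            cfg = SimulationConfig(
                seed=int(sub), n_groups=n_groups,
                stoichiometry_mode=mode, stoich_noise_sd=noise_sd,
            )
            _, groups, _ = generate_genome(cfg)
            edges, gexpr = simulate_network(groups, cfg)
            recs, _ = stoichiometry_table(edges, gexpr)
            mixed = recs[
                recs["edge_class"].str.startswith("two_one")
                & (recs["mode"] == "total")
            ]
            min_edges = len(mixed) if min_edges is None else min(min_edges, len(mixed))
            if mode_comparison(recs)["verdict"] == mode:
                hits += 1
        out[f"recovered_{mode}"] = hits
    out["n_seeds_per_mode"] = n_seeds
    out["min_two_one_edges"] = int(min_edges)
    return out


def assignment_recovery(
    seed: int, n_groups: int = 2000, identity_gap: float = 5.0,
    loss_rate: float = 0.3,
) -> dict:
    """Label accuracy of the full assignment cascade on a synthetic genome
    with known subgenome truth."""
    cfg = SimulationConfig(
        seed=int(_subseeds(seed, 1, stream=5)[0]), n_groups=n_groups,
        loss_rate=loss_rate, identity_gap=identity_gap,
    )
    genes, groups, links = generate_genome(cfg)
    truth = {g.gene_id: g.subgenome for g in genes if g.species == HYBRID}
    stripped = [g.with_subgenome(UNASSIGNED) for g in genes if g.species == HYBRID]
    _, table, _ = assign_subgenomes(stripped, links, regime="identity")
    called = table[table["subgenome"].isin(["A", "B"])]
    hits = sum(truth[r.gene_id] == r.subgenome for r in called.itertuples())
    return {
        "n_called": int(len(called)),
        "n_genes": len(stripped),
        "accuracy": hits / len(called),
    }


def hypergeometric_exactness(max_universe: int = 12) -> dict:
    """Exhaustive comparison of the hypergeometric tail against a
    rational-arithmetic enumeration for every consistent (k, K, n, M),
    M <= max_universe."""
    max_err = 0.0
    n_cases = 0
    for M in range(1, max_universe + 1):
        total_cache = {}
        for K in range(M + 1):
            for n in range(M + 1):
                total = total_cache.setdefault(n, comb(M, n))
                for k in range(min(K, n) + 1):
                    exact = float(
                        sum(
                            Fraction(comb(K, i) * comb(M - K, n - i), total)
                            for i in range(k, min(K, n) + 1)
                        )
                    )
                    err = abs(hypergeometric_tail(k, K, n, M) - exact)
                    max_err = max(max_err, err)
                    n_cases += 1
    return {"n_cases": n_cases, "max_abs_error": max_err}


def overlap_uniformity(seed: int, n_seeds: int = 100, n_groups: int = 1000) -> dict:
    """Uniformity of the rate/expression divergent-set overlap p when the two
    divergence channels are simulated independently (the structural null of
    no concerted sequence/expression evolution)."""
    ps = []
    for sub in _subseeds(seed, n_seeds, stream=6):
        cfg = SimulationConfig(
            seed=int(sub), n_groups=n_groups, loss_rate=0.1,
            frac_rate_divergent=0.08, frac_expr_divergent=0.08,
            frac_decelerated=0.0,
        )
        genes, groups, _ = generate_genome(cfg)
        subs, _ = simulate_substitutions(groups, cfg, genes=genes)
        expr = simulate_expression(groups, genes, cfg)
        pairs = _pair_table(genes, groups)
        rates, _ = test_rate_divergence(subs, pairs)
        calls, _ = expression_divergence_call(expr.counts[HYBRID].values, pairs)
        ps.append(rate_expression_concordance(rates, calls)["overlap_p"])
    ps = np.array(ps)
    ks = stats.kstest(ps, "uniform")
    return {
        "n_seeds": n_seeds,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "fraction_p_above_01": float((ps > 0.01).mean()),
    }
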