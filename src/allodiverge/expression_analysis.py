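"""Homeolog expression analyses: cross-(sub)genome correlation, subgenome
bias, expression-divergence calling, silent-copy and suppressed-region
scans, and the concordance of rate and expression divergence.

The expression-divergence caller is a self-contained negative-binomial Wald
stage (median-of-ratios library normalization, method-of-moments dispersion
with a floor, Wald z on the log fold change, Benjamini–Hochberg adjustment),
matching the test family and thresholds of the DESeq2-style analysis it
stands in for while remaining deterministic and dependency-light.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ExpressionMatrix, GeneRecord
from .enrichment_stats import set_overlap_test
from .rate_divergence import bh_adjust, median_normalize_rates

__all__ = [
    "spearman_correlation_matrix",
    "subgenome_bias_test",
    "size_factors",
    "expression_divergence_call",
    "normalize_expression_ratios",
    "rate_expression_concordance",
    "deceleration_expression_association",
    "silent_copy_scan",
    "suppressed_region_scan",
]


def spearman_correlation_matrix(tables: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise Spearman correlations between expression vectors, restricted
    to ortholog groups present in every compared unit.

    ``tables`` maps a unit name (a genome or a subgenome) to a Series of
    expression values indexed by group id.  At least 3 shared groups are
    required; ties are mid-ranked (scipy's convention).
    """
    names = list(tables)
    shared = None
    for name in names:
        idx = tables[name].dropna().index
        shared = idx if shared is None else shared.intersection(idx)
    if shared is None or len(shared) < 3:
        raise ValueError(
            f"need >=3 shared groups across units, got {0 if shared is None else len(shared)}"
        )
    mat = np.column_stack([tables[name].loc[shared].to_numpy() for name in names])
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rho = stats.spearmanr(mat[:, i], mat[:, j]).statistic
            out.iat[i, j] = out.iat[j, i] = rho
    return out


def subgenome_bias_test(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    single_a: Sequence[float] = (),
    single_b: Sequence[float] = (),
    min_n: int = 10,
) -> dict:
    """Subgenome expression-bias tests.

    Two-copy branch: Wilcoxon signed-rank on paired (A, B) expression values
    within groups.  Single-copy branch: Mann–Whitney U on the single_A vs
    single_B gene sets (unpaired).  Two-sided p-values; medians per class
    reported.  The single-copy branch is skipped (p = None) when either side
    has fewer than ``min_n`` genes.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if a.size < min_n:
        raise ValueError(f"need >= {min_n} two-copy pairs, got {a.size}")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; signed-rank p set to 1")
        p_two = 1.0
    else:
        p_two = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    out = {
        "two_copy_p": p_two,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_pairs": int(a.size),
        "single_copy_p": None,
        "median_single_a": None,
        "median_single_b": None,
        "n_single_a": len(single_a),
        "n_single_b": len(single_b),
    }
    if len(single_a) >= min_n and len(single_b) >= min_n:
        sa = np.asarray(single_a, dtype=float)
        sb = np.asarray(single_b, dtype=float)
        out["single_copy_p"] = float(
            stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue
        )
        out["median_single_a"] = float(np.median(sa))
        out["median_single_b"] = float(np.median(sb))
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Per sample, the median ratio of its counts to the per-gene geometric mean
    across samples, over genes expressed in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.sum() == 0:
        raise ValueError("no gene expressed in every sample; size factors undefined")
    log_ref = np.log(mat[all_pos]).mean(axis=1)
    sf = np.exp(np.median(np.log(mat[all_pos]) - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def expression_divergence_call(
    counts: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr: float = 0.01,
    fold_min: float = 3.0,
    dispersion_floor: float = 0.01,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-pair negative-binomial Wald test of copy A vs copy B counts.

    ``counts`` is a raw-count genes x samples table over the hybrid's
    replicates; ``pairs`` has columns group_id, gene_a, gene_b.  After
    median-of-ratios normalization the Wald statistic is

        z = log(mean_A / mean_B) / se,
        se² = (1/mean_A + α)/m + (1/mean_B + α)/m,

    the delta-method variance of a log NB mean with dispersion α (estimated
    per pair by method of moments, floored at ``dispersion_floor``) over m
    replicates.  BH adjustment; divergent ⇔ q ≤ fdr and fold ≥ fold_min.
    A/B expression ratios (raw and median-normalized) are also reported.
    """
    if counts.shape[1] < 2:
        raise ValueError(
            "at least 2 replicate samples required; use ratio-only mode "
            "(normalize_expression_ratios) for single-replicate designs"
        )
    norm = counts / size_factors(counts)
    a = norm.loc[pairs["gene_a"]].to_numpy(dtype=float)
    b = norm.loc[pairs["gene_b"]].to_numpy(dtype=float)
    m = a.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mean_a) / mean_a**2
        alpha_b = (var_b - mean_b) / mean_b**2
    stacked = np.column_stack(
        [np.clip(alpha_a, 0, None), np.clip(alpha_b, 0, None)]
    )
    valid = np.isfinite(stacked)
    n_valid = valid.sum(axis=1)
    alpha = np.where(valid, stacked, 0.0).sum(axis=1) / np.maximum(n_valid, 1)
    alpha = np.where(n_valid == 0, dispersion_floor, alpha)
    alpha = np.maximum(alpha, dispersion_floor)

    lfc = np.log((mean_a + pseudocount) / (mean_b + pseudocount))
    se2 = ((1.0 / (mean_a + pseudocount) + alpha) +
           (1.0 / (mean_b + pseudocount) + alpha)) / m
    z = lfc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q, _ = bh_adjust(p, fdr=fdr)
    fold = np.exp(np.abs(lfc))

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_raw = np.where(mean_b > 0, mean_a / mean_b, np.inf)
    ratio_norm, scale = normalize_expression_ratios(ratio_raw)
    out = pd.DataFrame(
        {
            "group_id": pairs["group_id"].to_numpy(),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "ratio_raw": ratio_raw,
            "ratio_normalized": ratio_norm,
            "dispersion": alpha,
            "lfc": lfc,
            "z": z,
            "p": p,
            "q": q,
            "fold": fold,
        }
    )
    out["divergent"] = (out["q"] <= fdr) & (out["fold"] >= fold_min)
    report = {
        "n_pairs": int(len(out)),
        "n_divergent": int(out["divergent"].sum()),
        "ratio_normalization_scale": float(scale),
        "n_replicate_samples": int(m),
        "fdr": fdr,
        "fold_min": fold_min,
    }
    return out, report


def normalize_expression_ratios(
    ratios: Sequence[float],
) -> tuple[np.ndarray, float]:
    """Divide A/B expression ratios by their median so the median normalized
    ratio is one — the same contract as rate median normalization, removing
    intrinsic subgenome biases inherited from the parents."""
    r = np.asarray(ratios, dtype=float)
    pairs = [(x, 1.0) for x in r]
    _, scale = median_normalize_rates(pairs)
    return r / scale, scale


def rate_expression_concordance(
    rate_results: pd.DataFrame,
    expr_results: pd.DataFrame,
) -> dict:
    """Do sequence-rate divergence and expression divergence coincide?

    Both inputs are per-pair result tables (group_id, normalized measures,
    divergent flag).  Computes the Spearman correlation between the two
    normalized log divergences over the shared tested universe, the
    hypergeometric overlap p between the two divergent sets, and quadrant
    counts of the doubly divergent pairs (signs of the two log ratios).
    """
    rr = rate_results.set_index("group_id")
    er = expr_results.set_index("group_id")
    universe = rr.index.intersection(er.index)
    if len(universe) < 3:
        raise ValueError("need >=3 jointly tested pairs")
    with np.errstate(divide="ignore"):
        log_rate = np.log(rr.loc[universe, "omega_a"] / rr.loc[universe, "omega_b"])
        log_expr = np.log(er.loc[universe, "ratio_normalized"])
    finite = np.isfinite(log_rate) & np.isfinite(log_expr)
    rho = float(stats.spearmanr(log_rate[finite], log_expr[finite]).statistic)
    set_rate = set(rr.index[rr["divergent"].astype(bool)]) & set(universe)
    set_expr = set(er.index[er["divergent"].astype(bool)]) & set(universe)
    overlap_p = set_overlap_test(set_rate, set_expr, set(universe))
    both = sorted(set_rate & set_expr)
    quadrants = {"++": 0, "+-": 0, "-+": 0, "--": 0}
    for gid in both:
        key = ("+" if log_rate.loc[gid] > 0 else "-") + (
            "+" if log_expr.loc[gid] > 0 else "-"
        )
        quadrants[key] += 1
    return {
        "spearman_rho": rho,
        "overlap_p": overlap_p,
        "n_universe": int(len(universe)),
        "n_rate_divergent": len(set_rate),
        "n_expr_divergent": len(set_expr),
        "n_both": len(both),
        "quadrants": quadrants,
    }


def deceleration_expression_association(
    decelerated: Sequence[bool], pair_expression: Sequence[float]
) -> dict:
    """Are rate-decelerated homeolog pairs more highly expressed?

    ``pair_expression`` is the pair-level expression (mean of the two
    copies' log FPKM).  Two-sided Mann–Whitney U between decelerated and
    non-decelerated classes; medians reported.
    """
    dec = np.asarray(decelerated, dtype=bool)
    expr = np.asarray(pair_expression, dtype=float)
    if dec.shape != expr.shape:
        raise ValueError("flag and expression arrays must align")
    x, y = expr[dec], expr[~dec]
    if x.size == 0 or y.size == 0:
        raise ValueError("both decelerated and non-decelerated classes required")
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return {
        "p": p,
        "median_decelerated": float(np.median(x)),
        "median_other": float(np.median(y)),
        "n_decelerated": int(x.size),
        "n_other": int(y.size),
    }


def silent_copy_scan(
    pairs: pd.DataFrame,
    fpkm: ExpressionMatrix,
    low_partner_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Two-copy pairs where one copy is transcriptionally silent.

    Silent = zero FPKM in every sample of the hybrid (the strictest reading
    of "not detected").  The partner's mean FPKM is reported with a flag
    when it falls below ``low_partner_fpkm`` — such cases are plausibly a
    detection-limit artifact rather than true silencing.
    """
    rows = []
    vals = fpkm.values
    for _, pr in pairs.iterrows():
        for silent_gene, partner, copy in (
            (pr["gene_a"], pr["gene_b"], "A"),
            (pr["gene_b"], pr["gene_a"], "B"),
        ):
            if silent_gene not in vals.index or partner not in vals.index:
                continue
            if (vals.loc[silent_gene] == 0).all():
                partner_fpkm = float(vals.loc[partner].mean())
                rows.append(
                    {
                        "group_id": pr["group_id"],
                        "silent_copy": copy,
                        "silent_gene": silent_gene,
                        "partner_gene": partner,
                        "partner_mean_fpkm": partner_fpkm,
                        "low_partner": partner_fpkm < low_partner_fpkm,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "group_id", "silent_copy", "silent_gene", "partner_gene",
            "partner_mean_fpkm", "low_partner",
        ],
    )


def suppressed_region_scan(
    genes: Sequence[GeneRecord],
    expression: Mapping[str, float],
    window_kb: float = 100.0,
    step_kb: float = 10.0,
    min_genes: int = 10,
    percentile: float = 5.0,
) -> pd.DataFrame:
    """Sliding-window scan for scaffold regions with distinctively suppressed
    transcription.

    Windows of ``window_kb`` advanced by ``step_kb`` over each scaffold; a
    window's statistic is the median expression (e.g. mean log10 FPKM) of the
    genes whose midpoints it contains.  Windows with at least ``min_genes``
    genes whose median falls strictly below the genome-wide ``percentile`` of
    all qualifying window medians are candidates; overlapping candidates on a
    scaffold are merged.  Returns a BED-like table (scaffold, start, end,
    n_genes, median_expression).
    """
    window = int(window_kb * 1000)
    step = int(step_kb * 1000)
    by_scaffold: dict[str, list[tuple[int, float]]] = {}
    for g in genes:
        if g.gene_id in expression:
            mid = (g.start + g.end) // 2
            by_scaffold.setdefault(g.scaffold_id, []).append(
                (mid, float(expression[g.gene_id]))
            )
    windows = []  # (scaffold, start, end, n_genes, median)
    for scf, items in sorted(by_scaffold.items()):
        items.sort()
        pos = np.array([m for m, _ in items])
        val = np.array([v for _, v in items])
        if len(items) == 0:
            continue
        last = int(pos.max())
        for start in range(0, last + 1, step):
            mask = (pos >= start) & (pos < start + window)
            if mask.sum() >= min_genes:
                windows.append(
                    (scf, start, start + window, int(mask.sum()),
                     float(np.median(val[mask])))
                )
    if not windows:
        return pd.DataFrame(
            columns=["scaffold", "start", "end", "n_genes", "median_expression"]
        )
    medians = np.array([w[4] for w in windows])
    cutoff = float(np.percentile(medians, percentile))
    center = float(np.median(medians))
    # <= admits ties at the percentile (a wide fully-suppressed region);
    # the strict comparison against the genome-wide center keeps a flat
    # genome candidate-free
    candidates = [w for w in windows if w[4] <= cutoff and w[4] < center]
    # merge overlapping candidate windows per scaffold
    merged: list[list] = []
    for scf, start, end, ng, med in sorted(candidates):
        if merged and merged[-1][0] == scf and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
            merged[-1][3] = max(merged[-1][3], ng)
            merged[-1][4] = min(merged[-1][4], med)
        else:
            merged.append([scf, start, end, ng, med])
    return pd.DataFrame(
        merged, columns=["scaffold", "start", "end", "n_genes", "median_expression"]
    )
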