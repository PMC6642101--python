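"""Interaction-network transcript-stoichiometry conservation.

A reference interactome is lifted onto hybrid ortholog groups; each edge is
classified by the copy status of its endpoints (two-copy↔two-copy,
two-copy↔single-copy on subgenome A or B, single↔single).  The transcript
stoichiometry of an edge is the FPKM ratio of its endpoints, computed in two
modes for edges joining a two-copy pair to a single-copy partner:

* total — the two-copy side contributes the summed FPKM of both copies
  (e.g. copies at 10 and 20 FPKM against a 5 FPKM partner give 30/5 = 6);
* subgenome — only the copy sharing the single partner's subgenome counts
  (10/5 = 2 in the same example).

Conservation is the ratio of hybrid stoichiometry to the same edge's
stoichiometry between the non-hybrid reference orthologs: 1 means perfectly
conserved.  Comparing the dispersion of |log ratio| between the two modes
tells which dosage-balance regime a hybrid follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_model import InteractionEdge

__all__ = [
    "StoichiometryRecord",
    "map_interactions",
    "classify_edges",
    "edge_stoichiometry",
    "conservation_ratio",
    "stoichiometry_table",
    "mode_comparison",
    "identity_vs_conservation",
    "loss_expression_preference",
    "local_clustering_coefficient",
    "loss_position_test",
]


@dataclass(frozen=True)
class StoichiometryRecord:
    group_numerator: str
    group_denominator: str
    edge_class: str
    mode: str  # total | subgenome
    hybrid_stoichiometry: float
    reference_stoichiometry: float
    conservation_ratio: float

    @property
    def log2_ratio(self) -> float:
        return float(np.log2(self.conservation_ratio))


def map_interactions(
    reference_edges: Sequence[tuple[str, str]],
    gene_to_group: Mapping[str, str],
    present_groups: set[str] | None = None,
) -> tuple[list[InteractionEdge], dict]:
    """Lift a reference-species edge list onto ortholog groups.

    Edges with an unmapped gene are dropped (counted); lifted self-loops and
    duplicate unordered pairs are removed; edges touching groups absent from
    the hybrid (when ``present_groups`` is given) are excluded.
    """
    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str]] = set()
    dropped_unmapped = dropped_self = dropped_dup = dropped_absent = 0
    for g1, g2 in reference_edges:
        if g1 not in gene_to_group or g2 not in gene_to_group:
            dropped_unmapped += 1
            continue
        a, b = gene_to_group[g1], gene_to_group[g2]
        if a == b:
            dropped_self += 1
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            dropped_dup += 1
            continue
        if present_groups is not None and (a not in present_groups or b not in present_groups):
            dropped_absent += 1
            continue
        seen.add(key)
        edges.append(InteractionEdge(*key))
    report = {
        "n_mapped": len(edges),
        "dropped_unmapped": dropped_unmapped,
        "dropped_self_loop": dropped_self,
        "dropped_duplicate": dropped_dup,
        "dropped_absent_group": dropped_absent,
    }
    return edges, report


def classify_edges(
    edges: Sequence[InteractionEdge], status_of: Mapping[str, str]
) -> pd.DataFrame:
    """Classify each edge by its endpoints' copy status.

    two_two (both two-copy), two_one_A / two_one_B (two-copy vs single-copy,
    subdivided by the single partner's subgenome), one_one (both single).
    Edges touching an ``absent`` group are classed ``unclassified``.
    """
    rows = []
    for e in edges:
        s1 = status_of.get(e.group_a, "absent")
        s2 = status_of.get(e.group_b, "absent")
        statuses = sorted((s1, s2))
        if "absent" in statuses:
            cls = "unclassified"
        elif statuses == ["two_copy", "two_copy"]:
            cls = "two_two"
        elif "two_copy" in statuses:
            single = s1 if s1 != "two_copy" else s2
            cls = f"two_one_{single[-1]}"
        else:
            cls = "one_one"
        rows.append({"group_a": e.group_a, "group_b": e.group_b, "edge_class": cls})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "edge_class"])


def _endpoint_fpkm(row: pd.Series, mode: str, single_subgenome: str | None) -> float:
    status = row["status"]
    if status == "two_copy":
        if mode == "total":
            return float(row["fpkm_a"]) + float(row["fpkm_b"])
        assert single_subgenome in ("A", "B")
        return float(row["fpkm_a"] if single_subgenome == "A" else row["fpkm_b"])
    if status == "single_A":
        return float(row["fpkm_a"])
    if status == "single_B":
        return float(row["fpkm_b"])
    return np.nan


def edge_stoichiometry(
    edge: InteractionEdge,
    group_expr: pd.DataFrame,
    mode: str = "total",
) -> StoichiometryRecord | str:
    """Stoichiometry of one edge, or a skip-reason string.

    ``group_expr`` is indexed by group_id with columns status, fpkm_a,
    fpkm_b, ref_fpkm.  Orientation: the two-copy side is the numerator for
    mixed edges; symmetric classes use lexicographic group order.
    Subgenome mode is defined only for two-copy↔single-copy edges.
    """
    if mode not in ("total", "subgenome"):
        raise ValueError(f"unknown stoichiometry mode {mode!r}")
    for gid in (edge.group_a, edge.group_b):
        if gid not in group_expr.index:
            return f"missing_group:{gid}"
    r1, r2 = group_expr.loc[edge.group_a], group_expr.loc[edge.group_b]
    cls_df = classify_edges(
        [edge], {edge.group_a: r1["status"], edge.group_b: r2["status"]}
    )
    cls = cls_df["edge_class"].iloc[0]
    if cls == "unclassified":
        return "absent_endpoint"
    if cls.startswith("two_one"):
        if r1["status"] == "two_copy":
            num, den = (edge.group_a, r1), (edge.group_b, r2)
        else:
            num, den = (edge.group_b, r2), (edge.group_a, r1)
        single_sub = cls[-1]
    else:
        if mode == "subgenome":
            return "subgenome_mode_undefined_for_symmetric_edge"
        num, den = (edge.group_a, r1), (edge.group_b, r2)
        single_sub = None
    hyb_num = _endpoint_fpkm(num[1], mode, single_sub)
    hyb_den = _endpoint_fpkm(den[1], mode, single_sub)
    if not np.isfinite(hyb_num) or not np.isfinite(hyb_den):
        return "missing_expression"
    if hyb_den == 0 or hyb_num == 0:
        return "zero_hybrid_expression"
    ref_num, ref_den = float(num[1]["ref_fpkm"]), float(den[1]["ref_fpkm"])
    if not (np.isfinite(ref_num) and np.isfinite(ref_den)) or ref_num == 0 or ref_den == 0:
        return "zero_reference_expression"
    hybrid = hyb_num / hyb_den
    reference = ref_num / ref_den
    return StoichiometryRecord(
        group_numerator=num[0],
        group_denominator=den[0],
        edge_class=cls,
        mode=mode,
        hybrid_stoichiometry=hybrid,
        reference_stoichiometry=reference,
        conservation_ratio=hybrid / reference,
    )


def conservation_ratio(
    hybrid_stoichiometry: float, reference_stoichiometry: float
) -> tuple[float, float]:
    """(linear ratio, log2 ratio) of hybrid over reference stoichiometry."""
    if reference_stoichiometry <= 0 or hybrid_stoichiometry <= 0:
        raise ValueError("stoichiometries must be positive")
    r = hybrid_stoichiometry / reference_stoichiometry
    return r, float(np.log2(r))


def stoichiometry_table(
    edges: Sequence[InteractionEdge],
    group_expr: pd.DataFrame,
    modes: Sequence[str] = ("total", "subgenome"),
) -> tuple[pd.DataFrame, dict]:
    """Per-edge stoichiometry records across modes, plus skip counts."""
    rows, skips = [], {}
    for mode in modes:
        for e in edges:
            rec = edge_stoichiometry(e, group_expr, mode=mode)
            if isinstance(rec, str):
                skips[rec] = skips.get(rec, 0) + 1
                continue
            rows.append(
                {
                    "group_numerator": rec.group_numerator,
                    "group_denominator": rec.group_denominator,
                    "edge_class": rec.edge_class,
                    "mode": rec.mode,
                    "hybrid_stoichiometry": rec.hybrid_stoichiometry,
                    "reference_stoichiometry": rec.reference_stoichiometry,
                    "conservation_ratio": rec.conservation_ratio,
                    "log2_ratio": rec.log2_ratio,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "group_numerator", "group_denominator", "edge_class", "mode",
            "hybrid_stoichiometry", "reference_stoichiometry",
            "conservation_ratio", "log2_ratio",
        ],
    )
    return df, skips


def mode_comparison(records: pd.DataFrame) -> dict:
    """Summarize log2 conservation ratios per (edge class, mode) and decide
    which mode preserves stoichiometry more tightly on mixed edges.

    For two-copy↔single-copy edges the verdict is the mode with the smaller
    median |log2 ratio| (deviation from perfect conservation), tie-broken by
    the IQR of the log2 ratios.  The verdict is this module's stand-in for
    the total-dosage vs subgenome-specific contrast between hybrids.
    """
    summary: dict[str, dict] = {}
    for (cls, mode), sub in records.groupby(["edge_class", "mode"]):
        lr = sub["log2_ratio"].to_numpy(dtype=float)
        q75, q25 = np.percentile(lr, [75, 25]) if lr.size else (np.nan, np.nan)
        summary.setdefault(cls, {})[mode] = {
            "n": int(lr.size),
            "median": float(np.median(lr)) if lr.size else np.nan,
            "iqr": float(q75 - q25),
            "variance": float(np.var(lr, ddof=1)) if lr.size > 1 else np.nan,
            "median_abs": float(np.median(np.abs(lr))) if lr.size else np.nan,
        }
    mixed = records[records["edge_class"].str.startswith("two_one")]
    verdict = None
    if len(mixed):
        stats_by_mode = {}
        for mode, sub in mixed.groupby("mode"):
            lr = sub["log2_ratio"].to_numpy(dtype=float)
            q75, q25 = np.percentile(lr, [75, 25])
            stats_by_mode[mode] = (float(np.median(np.abs(lr))), float(q75 - q25))
        if len(stats_by_mode) == 2:
            verdict = min(stats_by_mode, key=lambda m: stats_by_mode[m])
    return {"per_class": summary, "verdict": verdict}


def identity_vs_conservation(
    records: pd.DataFrame,
    identities: Mapping[str, float],
    window: int = 51,
) -> tuple[pd.DataFrame, float]:
    """Relationship between within-pair amino-acid identity and stoichiometry
    conservation on mixed edges.

    Returns the running median of |log2 ratio| ordered by the two-copy
    group's identity (centered window) and the Spearman correlation between
    the two quantities.  A flat curve / near-zero rho says sequence
    divergence between copies does not impair stoichiometry conservation.
    """
    sub = records[records["edge_class"].str.startswith("two_one")].copy()
    sub["identity"] = sub["group_numerator"].map(identities)
    sub = sub.dropna(subset=["identity"])
    if sub["identity"].nunique() < 2:
        raise ValueError("need >=2 distinct identity values")
    sub = sub.sort_values("identity").reset_index(drop=True)
    abs_lr = sub["log2_ratio"].abs()
    curve = pd.DataFrame(
        {
            "identity": sub["identity"],
            "running_median_abs_log2": abs_lr.rolling(
                window, center=True, min_periods=1
            ).median(),
        }
    )
    rho = float(stats.spearmanr(sub["identity"], abs_lr).statistic)
    return curve, rho


def loss_expression_preference(
    edges: Sequence[InteractionEdge],
    group_expr: pd.DataFrame,
) -> dict:
    """On mixed edges, was the retained single-copy side the more highly
    expressed partner ancestrally?

    Uses reference-species ortholog expression only (hybrid expression would
    confound the question with post-hybridization regulation).  Ties count
    as half.  Binomial test of the success fraction against 0.5.
    """
    status_of = group_expr["status"].to_dict()
    cls = classify_edges(list(edges), status_of)
    mixed = cls[cls["edge_class"].str.startswith("two_one")]
    if len(mixed) == 0:
        raise ValueError("no two-copy/single-copy edges")
    wins = 0.0
    n = 0
    for _, row in mixed.iterrows():
        ga, gb = row["group_a"], row["group_b"]
        single, two = (ga, gb) if status_of[ga] != "two_copy" else (gb, ga)
        rs = group_expr.loc[single, "ref_fpkm"]
        rt = group_expr.loc[two, "ref_fpkm"]
        if not (np.isfinite(rs) and np.isfinite(rt)):
            continue
        n += 1
        if rs > rt:
            wins += 1.0
        elif rs == rt:
            wins += 0.5
    if n == 0:
        raise ValueError("no edge with reference expression on both sides")
    p = float(stats.binomtest(int(round(wins)), n, 0.5).pvalue)
    return {"fraction": wins / n, "k": wins, "n": n, "binomial_p": p}


def local_clustering_coefficient(graph: nx.Graph, node) -> float:
    """Standard local clustering coefficient; 0 for degree < 2."""
    return float(nx.clustering(graph, node))


def loss_position_test(
    coefficients: Mapping[str, float],
    single_a_groups: Sequence[str],
    single_b_groups: Sequence[str],
) -> dict:
    """Are single-copy survivors of one subgenome embedded in denser network
    neighborhoods than the other's?

    Two-sided Mann–Whitney U on the clustering-coefficient distributions of
    the two single-copy classes; the fold difference of medians is reported
    (A over B).
    """
    xa = np.array([coefficients[g] for g in single_a_groups if g in coefficients])
    xb = np.array([coefficients[g] for g in single_b_groups if g in coefficients])
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both single-copy classes must be non-empty")
    p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    med_a, med_b = float(np.median(xa)), float(np.median(xb))
    return {
        "p": p,
        "median_A": med_a,
        "median_B": med_b,
        "median_fold_A_over_B": med_a / med_b if med_b > 0 else np.inf,
        "n_A": int(xa.size),
        "n_B": int(xb.size),
    }
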