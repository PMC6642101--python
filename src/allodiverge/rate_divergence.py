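"""Homeolog evolutionary-rate divergence testing.

For a two-copy homeolog pair with site count N, observed substitution rates
(dN1, dS1) and (dN2, dS2), and a common (null) rate ω, the observed
nonsynonymous substitution count N·dNi is modelled as Binomial(N, dSi·ω).
For large N the observed rate dNi/dSi is then approximately normal with mean
ω and variance ω(1 − dSi·ω)/(N·dSi), so under the null the difference
dN1/dS1 − dN2/dS2 is approximately normal with mean 0 and variance

    ω(1 − dS1·ω)/(N·dS1) + ω(1 − dS2·ω)/(N·dS2).

ω is estimated by pooling, ω̂ = (dN1 + dN2)/(dS1 + dS2).  Two-sided normal
p-values are corrected by Benjamini–Hochberg; a pair is called divergent when
q ≤ 0.01 and the (normalized) rate ratio is at least 3-fold.  Rates on one
subgenome may first be rescaled so the median A/B rate ratio is one, removing
intrinsic rate differences inherited from the parental species.  Pairs whose
substitutions are saturated (any member with dN or dS of 2 or larger) are
removed before testing, and a pair is called decelerated when both copies'
rates are at least 3-fold below their non-hybrid ortholog's rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core_model import SubstitutionRecord

__all__ = [
    "RateTestResult",
    "saturation_filter",
    "median_normalize_rates",
    "pooled_null_rate",
    "divergence_test",
    "bh_adjust",
    "call_rate_divergent",
    "call_decelerated",
    "test_rate_divergence",
]


@dataclass(frozen=True)
class RateTestResult:
    group_id: str
    omega_a: float
    omega_b: float
    omega_hat: float
    var_a: float
    var_b: float
    z: float
    p: float
    q: float
    fold: float
    divergent: bool
    decelerated: bool | None = None


def saturation_filter(
    records_by_group: Mapping[str, Sequence[SubstitutionRecord]],
    cap: float = 2.0,
) -> tuple[dict[str, list[SubstitutionRecord]], int]:
    """Drop groups containing any gene with dN or dS of ``cap`` (default 2)
    or larger; such branch estimates are substitution-saturated and the
    binomial model no longer applies.  Boundary inclusive."""
    kept: dict[str, list[SubstitutionRecord]] = {}
    removed = 0
    for gid, recs in records_by_group.items():
        if any(r.dN >= cap or r.dS >= cap for r in recs):
            removed += 1
        else:
            kept[gid] = list(recs)
    return kept, removed


def median_normalize_rates(
    pairs: Sequence[tuple[float, float]]
) -> tuple[list[tuple[float, float]], float]:
    """Rescale subgenome-A rates by a constant so the median A/B rate ratio
    over pairs is one.

    The scale c is the (interpolated) median of omega_a/omega_b over pairs
    where both rates are finite and positive; pairs with zero denominators
    are excluded from c but still rescaled.  Returns (normalized pairs, c).
    """
    ratios = [
        a / b
        for a, b in pairs
        if b > 0 and a > 0 and np.isfinite(a) and np.isfinite(b)
    ]
    if not ratios:
        raise ValueError("no pair with positive finite rates: scale undefined")
    c = float(np.median(ratios))
    return [(a / c, b) for a, b in pairs], c


def pooled_null_rate(dN1: float, dS1: float, dN2: float, dS2: float) -> float:
    """Pooled estimate of the common rate: ω̂ = (dN1 + dN2)/(dS1 + dS2)."""
    if dS1 + dS2 <= 0:
        raise ValueError("dS1 + dS2 must be positive")
    return (dN1 + dN2) / (dS1 + dS2)


def divergence_test(
    dN1: float, dS1: float, dN2: float, dS2: float, N_effective: float
) -> tuple[float, float, float, float, float]:
    """z and two-sided p for rate divergence of one homeolog pair.

    Returns (omega_hat, var_1, var_2, z, p) with
    var_i = ω̂(1 − dSi·ω̂)/(N_effective·dSi).
    """
    if dS1 <= 0 or dS2 <= 0:
        raise ValueError("dS must be positive for both copies")
    if N_effective <= 0:
        raise ValueError("N_effective must be positive")
    omega_hat = pooled_null_rate(dN1, dS1, dN2, dS2)
    for ds in (dS1, dS2):
        if omega_hat * ds >= 1:
            raise ValueError(
                f"binomial probability out of range: omega_hat*dS = {omega_hat * ds:.4g} >= 1"
            )
    var1 = omega_hat * (1 - dS1 * omega_hat) / (N_effective * dS1)
    var2 = omega_hat * (1 - dS2 * omega_hat) / (N_effective * dS2)
    diff = dN1 / dS1 - dN2 / dS2
    var_sum = var1 + var2
    if var_sum == 0:
        if diff == 0:
            return omega_hat, var1, var2, 0.0, 1.0
        warnings.warn("zero variance with nonzero rate difference; p set to 0")
        return omega_hat, var1, var2, np.inf if diff > 0 else -np.inf, 0.0
    z = diff / np.sqrt(var_sum)
    p = 2.0 * float(norm.sf(abs(z)))
    return omega_hat, var1, var2, float(z), min(p, 1.0)


def bh_adjust(
    pvalues: Sequence[float], fdr: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (q-values, rejection mask) with the rejection set {q <= fdr}.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= fdr


def _fold(omega_a: float, omega_b: float) -> float:
    """max(a/b, b/a); infinite when exactly one rate is zero, 1 when both are."""
    if omega_a == 0 and omega_b == 0:
        return 1.0
    if omega_a == 0 or omega_b == 0:
        return np.inf
    return max(omega_a / omega_b, omega_b / omega_a)


def call_rate_divergent(
    results: pd.DataFrame, fdr: float = 0.01, fold_min: float = 3.0
) -> pd.Series:
    """divergent ⇔ q ≤ fdr AND fold ≥ fold_min (both boundaries inclusive;
    fold on normalized rates)."""
    return (results["q"] <= fdr) & (results["fold"] >= fold_min)


def call_decelerated(
    omega_a: float, omega_b: float, omega_ref: float, fold: float = 3.0
) -> bool | None:
    """Pair-level deceleration call: both copies' rates at least ``fold``
    times below the non-hybrid ortholog's rate.  Returns None (skipped) when
    the reference rate is zero."""
    if omega_ref <= 0:
        return None
    # multiplicative form with a relative tolerance keeps the inclusive
    # boundary (exactly fold-times lower counts) robust to rounding
    tol = 1.0 + 1e-9
    return bool(
        omega_a * fold <= omega_ref * tol and omega_b * fold <= omega_ref * tol
    )


def test_rate_divergence(
    substitutions: Mapping[str, SubstitutionRecord],
    pairs: pd.DataFrame,
    normalize: str = "auto",
    fdr: float = 0.01,
    fold_min: float = 3.0,
    saturation_cap: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full divergence test over two-copy homeolog pairs.

    Parameters
    ----------
    substitutions : mapping gene_id -> SubstitutionRecord.
    pairs : DataFrame with columns ``group_id``, ``gene_a``, ``gene_b`` and
        optionally ``gene_ref`` (non-hybrid ortholog, for deceleration calls).
    normalize : "on" | "off" | "auto".  Median normalization of subgenome-A
        rates; "auto" applies it (the safe default for hybrids whose parents
        differed in intrinsic rate — it is a no-op when the median ratio is
        already one).
    fdr, fold_min, saturation_cap : calling thresholds.

    Returns the per-pair results table and a report dict with skip/removal
    counts, the normalization scale, and N_effective bookkeeping.
    """
    if normalize not in ("on", "off", "auto"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    records_by_group: dict[str, list[SubstitutionRecord]] = {}
    skipped: dict[str, str] = {}
    rows = []
    for _, row in pairs.iterrows():
        gid = row["group_id"]
        members = [row["gene_a"], row["gene_b"]]
        if "gene_ref" in pairs.columns and pd.notna(row.get("gene_ref")):
            members.append(row["gene_ref"])
        recs = []
        for g in members:
            if g not in substitutions:
                skipped[gid] = f"missing_substitution_record:{g}"
                break
            recs.append(substitutions[g])
        else:
            records_by_group[gid] = recs
            rows.append(row)
    kept, n_saturated = saturation_filter(records_by_group, cap=saturation_cap)

    testable = []
    for row in rows:
        gid = row["group_id"]
        if gid not in kept:
            skipped.setdefault(gid, "saturated")
            continue
        ra, rb = kept[gid][0], kept[gid][1]
        if ra.dS <= 0 or rb.dS <= 0:
            skipped[gid] = "zero_dS"
            continue
        testable.append((row, ra, rb, kept[gid][2] if len(kept[gid]) > 2 else None))

    raw_pairs = [(ra.dN / ra.dS, rb.dN / rb.dS) for _, ra, rb, _ in testable]
    scale = 1.0
    norm_pairs = list(raw_pairs)
    if normalize in ("on", "auto") and raw_pairs:
        try:
            norm_pairs, scale = median_normalize_rates(raw_pairs)
        except ValueError:
            if normalize == "on":
                raise
            # auto mode: no positive ratios to anchor the scale; leave as-is

    results = []
    for (row, ra, rb, rref), (oa, ob) in zip(testable, norm_pairs):
        gid = row["group_id"]
        n_eff = 0.5 * (ra.N + rb.N)  # arithmetic mean when site counts differ
        dn_a = ra.dN / scale  # normalization acts on subgenome-A rates
        try:
            omega_hat, var_a, var_b, z, p = divergence_test(
                dn_a, ra.dS, rb.dN, rb.dS, n_eff
            )
        except ValueError as exc:
            skipped[gid] = str(exc)
            continue
        dec = None
        if rref is not None and rref.dS > 0:
            dec = call_decelerated(oa, ob, rref.dN / rref.dS, fold=fold_min)
        results.append(
            {
                "group_id": gid,
                "omega_a": oa,
                "omega_b": ob,
                "omega_hat": omega_hat,
                "var_a": var_a,
                "var_b": var_b,
                "z": z,
                "p": p,
                "fold": _fold(oa, ob),
                "n_effective": n_eff,
                "decelerated": dec,
            }
        )
    df = pd.DataFrame(results)
    if len(df):
        q, _ = bh_adjust(df["p"].to_numpy(), fdr=fdr)
        df["q"] = q
        df["divergent"] = call_rate_divergent(df, fdr=fdr, fold_min=fold_min)
    else:
        df = pd.DataFrame(
            columns=[
                "group_id", "omega_a", "omega_b", "omega_hat", "var_a", "var_b",
                "z", "p", "fold", "n_effective", "decelerated", "q", "divergent",
            ]
        )
    report = {
        "n_input_pairs": int(len(pairs)),
        "n_tested": int(len(df)),
        "n_saturated": int(n_saturated),
        "skipped": skipped,
        "normalization_scale": float(scale),
        "fdr": fdr,
        "fold_min": fold_min,
    }
    return df, report
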