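"""Hypergeometric enrichment machinery shared across the pipeline.

Three uses of the same exact tail: functional-term enrichment with Bonferroni
correction and term-size bounds, overlap testing between two gene sets, and
testing whether a transcription factor's binding sites are shared between the
two copies of homeolog pairs more often than independence predicts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

from scipy.stats import hypergeom

from .core_model import TFBSPresence

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "term_enrichment",
    "set_overlap_test",
    "tfbs_sharing_test",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # overlap with the query
    K: int  # term size
    n: int  # query size
    M: int  # universe size
    p: float
    p_adjusted: float
    significant: bool


def hypergeometric_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(M, K, n).

    ``M`` is the universe size, ``K`` the number of marked items, ``n`` the
    draw size and ``k`` the observed number of marked draws.  Enrichment
    only — depletion is not tested.
    """
    if not (0 <= k <= min(K, n) and K <= M and n <= M):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} M={M}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); clip tiny negative rounding to 0
    p = float(hypergeom.sf(k - 1, M, K, n))
    return min(max(p, 0.0), 1.0)


def term_enrichment(
    query: Set[str],
    annotations: Mapping[str, Set[str]],
    universe: Set[str],
    min_term: int = 10,
    max_term: int = 500,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each annotation term in ``query``, with
    Bonferroni correction over the terms actually tested.

    Terms whose (universe-restricted) size falls outside [min_term, max_term]
    are excluded before testing and before the Bonferroni divisor is fixed:
    undersized terms are too specific, oversized ones too broad to be
    informative.  Results are sorted by raw p.
    """
    query = set(query) & set(universe)
    M, n = len(universe), len(query)
    tested: list[tuple[str, int, int]] = []
    for term_id, genes in annotations.items():
        term_genes = set(genes) & set(universe)
        if min_term <= len(term_genes) <= max_term:
            tested.append((term_id, len(term_genes), len(term_genes & query)))
    divisor = len(tested)
    results = []
    for term_id, K, k in tested:
        p = hypergeometric_tail(k, K, n, M)
        p_adj = min(1.0, p * divisor)
        results.append(
            EnrichmentResult(term_id, k, K, n, M, p, p_adj, p_adj <= alpha)
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def set_overlap_test(set_a: Set[str], set_b: Set[str], universe: Set[str]) -> float:
    """Hypergeometric p for the observed overlap of two sets within a universe.

    Symmetric in its two sets; used for testing whether rate-divergent and
    expression-divergent homeolog sets coincide more than chance.
    """
    a = set(set_a) & set(universe)
    b = set(set_b) & set(universe)
    return hypergeometric_tail(len(a & b), len(a), len(b), len(universe))


def tfbs_sharing_test(rows: Sequence[TFBSPresence]) -> dict[str, float]:
    """Per-TF sharing test over all two-copy homeolog pairs.

    For each transcription factor: universe = all pairs scored for that TF,
    set A = pairs with a site upstream of the subgenome-A copy, set B =
    likewise for subgenome B; the hypergeometric tail on |A∩B| asks whether
    the same pairs carry the site on both copies more often than independent
    placement predicts (shared ancestral promoters).
    """
    by_tf: dict[str, list[TFBSPresence]] = {}
    for r in rows:
        by_tf.setdefault(r.tf_id, []).append(r)
    out: dict[str, float] = {}
    for tf_id, tf_rows in sorted(by_tf.items()):
        universe = {r.pair_id for r in tf_rows}
        set_a = {r.pair_id for r in tf_rows if r.present_a}
        set_b = {r.pair_id for r in tf_rows if r.present_b}
        out[tf_id] = set_overlap_test(set_a, set_b, universe)
    return out
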