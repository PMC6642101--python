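"""Assignment of hybrid genes to parental subgenomes A and B.

Two regimes, mirroring the two situations a recent allodiploid presents:

* identity margin — when the parents were distant enough, each copy of a
  homeolog pair is assigned directly: the copy with higher sequence identity
  to the non-hybrid reference species goes to subgenome A, provided the
  identity difference clears a margin;
* scaffold tracks — when the parents were too similar for per-gene calls,
  scaffolds are split into two tracks using homeolog-pair links as
  "must-differ" constraints (a 2-coloring of the scaffold conflict graph),
  and every pair member inherits its scaffold's track.

Single-copy genes, which have no homeolog partner, are then assigned by
majority vote of the nearest assigned homeolog-pair genes on the same
scaffold.  Whatever remains unassigned is removed, with reason codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import GeneRecord, UNASSIGNED

__all__ = [
    "HomeologLink",
    "ScaffoldTrack",
    "assign_by_identity_margin",
    "build_scaffold_tracks",
    "assign_single_copy_by_neighbors",
    "drop_unassigned",
    "assign_subgenomes",
]


@dataclass(frozen=True)
class HomeologLink:
    """A homeolog pair with percent identities of each copy to the common
    ortholog in the reference species."""

    group_id: str
    gene_a_candidate: str
    gene_b_candidate: str
    identity_to_reference: Mapping[str, float]


@dataclass
class ScaffoldTrack:
    scaffold_id: str
    track_label: str  # A | B | unassigned
    support: int = 0


def assign_by_identity_margin(
    links: Sequence[HomeologLink], margin: float = 2.0
) -> dict[str, str]:
    """Per-gene labels from the identity-margin rule.

    The copy with higher identity to the reference is subgenome A, its
    partner B, whenever the identity difference is at least ``margin``
    percentage points; smaller differences (and ties) leave both copies
    unassigned for the downstream rules.  Links missing an identity are
    skipped with a warning.
    """
    labels: dict[str, str] = {}
    for link in links:
        g1, g2 = link.gene_a_candidate, link.gene_b_candidate
        ids = link.identity_to_reference
        if g1 not in ids or g2 not in ids:
            warnings.warn(f"link {link.group_id}: missing identity, skipped")
            continue
        diff = ids[g1] - ids[g2]
        if abs(diff) < margin or diff == 0:
            continue
        if diff > 0:
            labels[g1], labels[g2] = "A", "B"
        else:
            labels[g1], labels[g2] = "B", "A"
    return labels


def build_scaffold_tracks(
    links: Sequence[HomeologLink],
    genes: Sequence[GeneRecord],
    min_support: int = 10,
    orientation: Mapping[str, str] | None = None,
) -> dict[str, ScaffoldTrack]:
    """Split scaffolds into two subgenome tracks from homeolog-pair links.

    Scaffold pairs joined by at least ``min_support`` homeolog links become
    edges of a conflict graph (linked scaffolds must lie on opposite tracks).
    Each connected component is 2-colored; non-bipartite components cannot be
    split consistently and all their scaffolds stay unassigned (warning).
    Track orientation (which color is subgenome A) is fixed per component by
    mean identity to the reference — the higher-identity color becomes A —
    unless an explicit ``orientation`` mapping scaffold→label is given.
    """
    scaffold_of = {g.gene_id: g.scaffold_id for g in genes}
    pair_links: dict[tuple[str, str], list[HomeologLink]] = {}
    for link in links:
        s1 = scaffold_of.get(link.gene_a_candidate)
        s2 = scaffold_of.get(link.gene_b_candidate)
        if s1 is None or s2 is None or s1 == s2:
            continue
        key = (min(s1, s2), max(s1, s2))
        pair_links.setdefault(key, []).append(link)

    graph = nx.Graph()
    graph.add_nodes_from(sorted({s for key in pair_links for s in key}))
    support: dict[tuple[str, str], int] = {}
    for key, ll in pair_links.items():
        if len(ll) >= min_support:
            graph.add_edge(*key)
            support[key] = len(ll)

    tracks: dict[str, ScaffoldTrack] = {}
    for comp_nodes in sorted(nx.connected_components(graph), key=min):
        comp = graph.subgraph(comp_nodes)
        scaffolds = sorted(comp_nodes)
        supp = {
            s: sum(n for k, n in support.items() if s in k) for s in scaffolds
        }
        if comp.number_of_edges() == 0:
            for s in scaffolds:
                tracks[s] = ScaffoldTrack(s, UNASSIGNED, 0)
            continue
        try:
            coloring = nx.bipartite.color(comp)
        except nx.NetworkXError:
            warnings.warn(
                f"non-bipartite scaffold component {scaffolds}: conflicting "
                "synteny, all left unassigned"
            )
            for s in scaffolds:
                tracks[s] = ScaffoldTrack(s, UNASSIGNED, supp[s])
            continue
        if orientation is not None:
            anchored = {s: orientation[s] for s in scaffolds if s in orientation}
            if not anchored:
                raise ValueError(
                    f"orientation mapping covers no scaffold of component {scaffolds}"
                )
            s0, lab0 = sorted(anchored.items())[0]
            color_to_label = {
                coloring[s0]: lab0,
                1 - coloring[s0]: "B" if lab0 == "A" else "A",
            }
        else:
            # orient by evolutionary proximity: higher mean identity -> A
            ident_sum = {0: [], 1: []}
            for key, ll in pair_links.items():
                if key not in support:
                    continue
                if key[0] not in comp_nodes:
                    continue
                for link in ll:
                    for gene in (link.gene_a_candidate, link.gene_b_candidate):
                        s = scaffold_of[gene]
                        ident = link.identity_to_reference.get(gene)
                        if ident is not None and s in coloring:
                            ident_sum[coloring[s]].append(ident)
            mean0 = float(np.mean(ident_sum[0])) if ident_sum[0] else -np.inf
            mean1 = float(np.mean(ident_sum[1])) if ident_sum[1] else -np.inf
            color_to_label = {0: "A", 1: "B"} if mean0 >= mean1 else {0: "B", 1: "A"}
        for s in scaffolds:
            tracks[s] = ScaffoldTrack(s, color_to_label[coloring[s]], supp[s])
    return tracks


def assign_single_copy_by_neighbors(
    gene: GeneRecord,
    assigned_neighbors: Sequence[tuple[GeneRecord, str]],
    k: int = 20,
) -> str:
    """Consensus label from the ``k`` nearest assigned homeolog-pair genes on
    the same scaffold (nearest by start-coordinate distance).

    A strict majority among the available neighbors (all of them when fewer
    than k exist) is required; ties or no neighbors leave the gene
    unassigned.
    """
    same = [
        (abs(n.start - gene.start), n.gene_id, lab)
        for n, lab in assigned_neighbors
        if n.scaffold_id == gene.scaffold_id and n.gene_id != gene.gene_id
    ]
    if not same:
        return UNASSIGNED
    same.sort()
    votes = [lab for _, _, lab in same[:k]]
    n_a, n_b = votes.count("A"), votes.count("B")
    if n_a > n_b:
        return "A"
    if n_b > n_a:
        return "B"
    return UNASSIGNED


def drop_unassigned(
    genes: Sequence[GeneRecord],
    reasons: Mapping[str, str] | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Remove genes still unassigned after all rules; report reasons.

    ``reasons`` may pre-record a cause per gene id (e.g. conflicting_synteny);
    anything else unassigned is reported as no_synteny_no_neighbors.
    """
    reasons = dict(reasons or {})
    kept, removed = [], []
    for g in genes:
        if g.subgenome == UNASSIGNED:
            removed.append(
                {
                    "gene_id": g.gene_id,
                    "scaffold_id": g.scaffold_id,
                    "reason": reasons.get(g.gene_id, "no_synteny_no_neighbors"),
                }
            )
        else:
            kept.append(g)
    report = pd.DataFrame(removed, columns=["gene_id", "scaffold_id", "reason"])
    return kept, report


def assign_subgenomes(
    genes: Sequence[GeneRecord],
    links: Sequence[HomeologLink],
    regime: str = "identity",
    margin: float = 2.0,
    min_support: int = 10,
    k_neighbors: int = 20,
    orientation: Mapping[str, str] | None = None,
) -> tuple[list[GeneRecord], pd.DataFrame, pd.DataFrame]:
    """Full assignment cascade for one hybrid species.

    regime="identity": per-gene identity-margin rule on homeolog pairs, then
    the neighbor-consensus rule for everything still unassigned (single-copy
    genes and below-margin pairs).  regime="scaffold": 2-colored scaffold
    tracks assign every gene on a track; the neighbor rule then covers genes
    on unassigned scaffolds.  Output is independent of input row order, and
    two-copy pairs are checked to carry complementary labels.

    Returns (assigned gene records, assignment table, removal report).
    """
    if regime not in ("identity", "scaffold"):
        raise ValueError(f"unknown regime {regime!r}")
    genes = sorted(genes, key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    labels: dict[str, str] = {}
    method: dict[str, str] = {}
    reasons: dict[str, str] = {}

    if regime == "identity":
        by_margin = assign_by_identity_margin(links, margin=margin)
        for gid, lab in by_margin.items():
            labels[gid] = lab
            method[gid] = "identity_margin"
    else:
        tracks = build_scaffold_tracks(
            links, genes, min_support=min_support, orientation=orientation
        )
        pair_genes = {
            g for link in links for g in (link.gene_a_candidate, link.gene_b_candidate)
        }
        for g in genes:
            tr = tracks.get(g.scaffold_id)
            if tr is None:
                continue
            if tr.track_label == UNASSIGNED:
                if tr.support > 0:
                    reasons[g.gene_id] = "conflicting_synteny"
                continue
            if g.gene_id in pair_genes:
                labels[g.gene_id] = tr.track_label
                method[g.gene_id] = "scaffold_track"

    # pair genes labelled so far anchor the neighbor-consensus vote
    anchor = [
        (g, labels[g.gene_id]) for g in genes if labels.get(g.gene_id) in ("A", "B")
    ]
    for g in genes:
        if g.gene_id in labels:
            continue
        lab = assign_single_copy_by_neighbors(g, anchor, k=k_neighbors)
        if lab != UNASSIGNED:
            labels[g.gene_id] = lab
            method[g.gene_id] = "neighbor_consensus"

    # complementarity within every homeolog pair: the neighbor rule can in
    # principle put both copies on the same subgenome; such pairs are
    # contradictory and both copies are unassigned with a reason
    for link in links:
        g1, g2 = link.gene_a_candidate, link.gene_b_candidate
        if labels.get(g1) in ("A", "B") and labels.get(g1) == labels.get(g2):
            for g in (g1, g2):
                labels.pop(g, None)
                method.pop(g, None)
                reasons[g] = "pair_conflict"
    for link in links:
        la, lb = labels.get(link.gene_a_candidate), labels.get(link.gene_b_candidate)
        assert not (la in ("A", "B") and la == lb), link.group_id

    assigned = [g.with_subgenome(labels.get(g.gene_id, UNASSIGNED)) for g in genes]
    kept, removal_report = drop_unassigned(assigned, reasons)
    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in assigned],
            "subgenome": [g.subgenome for g in assigned],
            "method": [method.get(g.gene_id, "none") for g in assigned],
        }
    )
    return kept, table, removal_report
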