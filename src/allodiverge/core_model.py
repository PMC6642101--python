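"""Shared data types and tabular I/O for the hybrid-genome analysis pipeline.

All coordinates are held internally as 0-based half-open intervals; BED-like
input is taken verbatim and GFF-like (1-based, closed) input is converted at
the boundary.  Every loader validates its invariants and raises
:class:`ValidationError` with the offending line where possible, so that
downstream stages can assume clean tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneRecord",
    "OrthologGroup",
    "SubstitutionRecord",
    "ExpressionMatrix",
    "InteractionEdge",
    "TFBSPresence",
    "load_gene_table",
    "write_gene_table",
    "load_ortholog_groups",
    "write_ortholog_groups",
    "load_substitutions",
    "write_substitutions",
    "load_expression",
    "write_expression",
    "load_interactions",
    "write_interactions",
    "load_tfbs",
    "write_tfbs",
    "log_average_replicates",
    "infer_hybrid_status",
]

SUBGENOMES = ("A", "B")
UNASSIGNED = "unassigned"
HYBRID_STATUSES = ("two_copy", "single_A", "single_B", "absent")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """A gene locus on a scaffold, with an optional subgenome label."""

    gene_id: str
    species: str
    scaffold_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str = "+"
    subgenome: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.gene_id}: negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"{self.gene_id}: end {self.end} must exceed start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.subgenome not in (*SUBGENOMES, UNASSIGNED):
            raise ValidationError(f"{self.gene_id}: bad subgenome {self.subgenome!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_subgenome(self, label: str) -> "GeneRecord":
        return replace(self, subgenome=label)


@dataclass
class OrthologGroup:
    """Cross-species ortholog membership with hybrid copy status.

    ``members`` maps species name to the list of member gene ids.  Non-hybrid
    species may contribute at most one gene and hybrid species at most two;
    groups violating this are rejected at load time (the distinction between
    in- and out-paralogs cannot be made downstream).
    """

    group_id: str
    members: dict[str, list[str]]
    hybrid_status: dict[str, str] = field(default_factory=dict)

    def validate(self, hybrid_species: Iterable[str]) -> None:
        hybrids = set(hybrid_species)
        for sp, genes in self.members.items():
            cap = 2 if sp in hybrids else 1
            if len(genes) > cap:
                raise ValidationError(
                    f"group {self.group_id}: {len(genes)} members for {sp} "
                    f"(max {cap})"
                )
            if len(set(genes)) != len(genes):
                raise ValidationError(f"group {self.group_id}: duplicate gene ids")


@dataclass(frozen=True)
class SubstitutionRecord:
    """Per-gene branch substitution rates and site counts (codeml-style)."""

    gene_id: str
    dN: float
    dS: float
    N: int  # nonsynonymous sites
    S: int  # synonymous sites

    def __post_init__(self) -> None:
        if self.dN < 0 or self.dS < 0:
            raise ValidationError(f"{self.gene_id}: negative substitution rate")
        if self.N < 1 or self.S < 1:
            raise ValidationError(f"{self.gene_id}: site counts must be >= 1")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample abundance table with per-sample metadata.

    ``values`` is a genes x samples DataFrame; ``sample_meta`` is indexed by
    sample name with columns ``species``, ``condition`` and ``replicate``.
    ``unit`` is ``"fpkm"`` or ``"count"``.  Undetected transcripts are stored
    as 0.0, never as missing values.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("fpkm", "count"):
            raise ValidationError(f"unknown expression unit {self.unit!r}")
        v = self.values.to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (v < 0).any():
            raise ValidationError("expression matrix contains negative values")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicated gene id {dup!r}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_for(self, species: str | None = None, condition: str | None = None) -> list[str]:
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        if species is not None:
            mask &= meta["species"] == species
        if condition is not None:
            mask &= meta["condition"] == condition
        return [s for s in self.values.columns if mask.get(s, False)]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.sample_meta.loc[list(samples)], self.unit
        )


@dataclass(frozen=True)
class InteractionEdge:
    """An undirected interaction between two ortholog groups."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValidationError(f"self-loop on group {self.group_a}")

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.group_a, self.group_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class TFBSPresence:
    """Presence of one transcription factor's binding site upstream of the
    two copies of a homeolog pair."""

    pair_id: str
    tf_id: str
    present_a: bool
    present_b: bool


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


def load_gene_table(path: str | Path, dialect: str = "bed_like") -> list[GeneRecord]:
    """Read gene coordinates from a BED-like (0-based half-open) or GFF-like
    (1-based closed) TSV.

    BED-like columns: scaffold, start, end, gene_id, score(ignored), strand,
    [species], [subgenome].  GFF-like columns are identical except start/end
    follow the 1-based closed convention.  Output is sorted by
    (scaffold, start) for determinism.
    """
    if dialect not in ("bed_like", "gff_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValidationError(f"{path}:{lineno}: expected >=6 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad coordinates") from exc
            if dialect == "gff_like":
                start -= 1  # 1-based closed -> 0-based half-open
            species = parts[6] if len(parts) > 6 else "unknown"
            subgenome = parts[7] if len(parts) > 7 else UNASSIGNED
            try:
                records.append(
                    GeneRecord(
                        gene_id=parts[3],
                        species=species,
                        scaffold_id=parts[0],
                        start=start,
                        end=end,
                        strand=parts[5],
                        subgenome=subgenome,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.scaffold_id, r.start, r.gene_id))
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as 8-column BED-like TSV (0-based half-open)."""
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda r: (r.scaffold_id, r.start, r.gene_id)):
            fh.write(
                f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}"
                f"\t{r.species}\t{r.subgenome}\n"
            )


# ---------------------------------------------------------------------------
# Ortholog groups
# ---------------------------------------------------------------------------


def load_ortholog_groups(
    path: str | Path, hybrid_species: Sequence[str]
) -> list[OrthologGroup]:
    """Read a group table: header ``group_id<TAB>speciesA<TAB>...``, one row
    per group, cells holding comma-separated gene ids ('' = absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    species = [c for c in df.columns if c != "group_id"]
    groups: list[OrthologGroup] = []
    for _, row in df.iterrows():
        members = {
            sp: [g for g in row[sp].split(",") if g] for sp in species if row[sp]
        }
        grp = OrthologGroup(group_id=row["group_id"], members=members)
        grp.validate(hybrid_species)
        groups.append(grp)
    return groups


def write_ortholog_groups(groups: Sequence[OrthologGroup], path: str | Path) -> None:
    species = sorted({sp for g in groups for sp in g.members})
    with open(path, "w") as fh:
        fh.write("group_id\t" + "\t".join(species) + "\n")
        for g in groups:
            cells = [",".join(g.members.get(sp, [])) for sp in species]
            fh.write(g.group_id + "\t" + "\t".join(cells) + "\n")


def infer_hybrid_status(
    members: Sequence[str], subgenome_of: Mapping[str, str]
) -> str:
    """Copy status of a hybrid species' members given per-gene subgenome labels.

    two_copy requires exactly one copy on each subgenome; a lone copy is
    single_A/single_B by its label; no members means absent.
    """
    labels = sorted(subgenome_of.get(g, UNASSIGNED) for g in members)
    if len(members) == 0:
        return "absent"
    if len(members) == 2 and labels == ["A", "B"]:
        return "two_copy"
    if len(members) == 1 and labels[0] in SUBGENOMES:
        return f"single_{labels[0]}"
    return "absent"  # unassignable configurations drop out of copy analyses


# ---------------------------------------------------------------------------
# Substitution records
# ---------------------------------------------------------------------------


def load_substitutions(path: str | Path) -> dict[str, SubstitutionRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"gene_id", "dN", "dS", "N", "S"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    out: dict[str, SubstitutionRecord] = {}
    for _, row in df.iterrows():
        rec = SubstitutionRecord(
            gene_id=str(row["gene_id"]),
            dN=float(row["dN"]),
            dS=float(row["dS"]),
            N=int(row["N"]),
            S=int(row["S"]),
        )
        if rec.gene_id in out:
            raise ValidationError(f"{path}: duplicated gene id {rec.gene_id}")
        out[rec.gene_id] = rec
    return out


def write_substitutions(
    records: Iterable[SubstitutionRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdN\tdS\tN\tS\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.dN:.17g}\t{r.dS:.17g}\t{r.N}\t{r.S}\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

_SAMPLE_RE = re.compile(r"^(?P<species>[^.]+)\.(?P<condition>[^.]+)\.rep(?P<rep>\d+)$")


def parse_sample_name(name: str) -> tuple[str, str, int]:
    """Parse the canonical ``species.condition.repN`` sample-name grammar."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValidationError(
            f"sample name {name!r} does not match species.condition.repN"
        )
    return m["species"], m["condition"], int(m["rep"])


def load_expression(
    path: str | Path, unit: str, sample_meta: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id, one column per sample).

    Sample metadata is parsed from the header using the
    ``species.condition.repN`` grammar unless a sidecar ``sample_meta``
    DataFrame (indexed by sample name) is supplied.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated gene id {dup!r}")
    if sample_meta is None:
        rows = {}
        for col in df.columns:
            sp, cond, rep = parse_sample_name(col)
            rows[col] = {"species": sp, "condition": cond, "replicate": rep}
        sample_meta = pd.DataFrame.from_dict(rows, orient="index")
    return ExpressionMatrix(values=df.astype(float), sample_meta=sample_meta, unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def log_average_replicates(
    expr: ExpressionMatrix, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Mean over replicates of log10(FPKM + pseudocount), one column per
    (species, condition).

    The pseudocount (default 0.01 FPKM) keeps undetected transcripts finite;
    with pseudocount 0 any zero raises.
    """
    if expr.unit != "fpkm":
        raise ValidationError("log_average_replicates requires FPKM units")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    groups = expr.sample_meta.groupby(["species", "condition"], sort=True)
    cols = {}
    for (sp, cond), meta in groups:
        samples = [s for s in expr.values.columns if s in set(meta.index)]
        if not samples:
            raise ValidationError(f"no samples for replicate group ({sp}, {cond})")
        block = expr.values[samples].to_numpy(dtype=float) + pseudocount
        if (block <= 0).any():
            raise ValidationError(
                "zero FPKM with zero pseudocount: log undefined"
            )
        cols[(sp, cond)] = np.log10(block).mean(axis=1)
    out = pd.DataFrame(cols, index=expr.values.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "condition"])
    return out


# ---------------------------------------------------------------------------
# Interactions and TFBS tables
# ---------------------------------------------------------------------------


def load_interactions(path: str | Path) -> list[InteractionEdge]:
    """Read a 2-column TSV edge list; self-loops and duplicate (unordered)
    pairs are rejected."""
    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            edge = InteractionEdge(parts[0], parts[1])
            if edge.key in seen:
                raise ValidationError(f"{path}:{lineno}: duplicated edge {edge.key}")
            seen.add(edge.key)
            edges.append(edge)
    return edges


def write_interactions(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.group_a}\t{e.group_b}\n")


def load_tfbs(path: str | Path) -> list[TFBSPresence]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "tf_id": str})
    rows: list[TFBSPresence] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["pair_id"], row["tf_id"])
        if key in seen:
            raise ValidationError(f"{path}: duplicate row for {key}")
        seen.add(key)
        rows.append(
            TFBSPresence(
                pair_id=row["pair_id"],
                tf_id=row["tf_id"],
                present_a=bool(int(row["present_a"])),
                present_b=bool(int(row["present_b"])),
            )
        )
    return rows


def write_tfbs(rows: Iterable[TFBSPresence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\ttf_id\tpresent_a\tpresent_b\n")
        for r in rows:
            fh.write(
                f"{r.pair_id}\t{r.tf_id}\t{int(r.present_a)}\t{int(r.present_b)}\n"
            )
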