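"""Synthetic allodiploid-hybrid datasets with the statistical structure the
analysis pipeline assumes.

The generator emulates a recently hybridized diploid fungus ("hyb") and a
non-hybrid reference relative ("ref"): an ortholog-group scaffold layout with
two mirrored subgenomes, biased gene loss, binomially generated substitution
counts under a shared-rate null with configurable rate-divergent and
decelerated subsets, negative-binomially distributed replicate counts with
correlated homeolog expression and an expression-divergent subset, an
interaction network whose transcript stoichiometry is conserved in either
"total" or "subgenome" mode, and transcription-factor binding-site presence
with configurable sharing between homeolog copies.

Each stage draws from its own named substream of the master seed, so any
stage can be regenerated independently and identically.  Identical config +
seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    ExpressionMatrix,
    GeneRecord,
    InteractionEdge,
    OrthologGroup,
    SubstitutionRecord,
    TFBSPresence,
    write_expression,
    write_gene_table,
    write_interactions,
    write_ortholog_groups,
    write_substitutions,
    write_tfbs,
)
from .subgenome_assignment import HomeologLink

__all__ = [
    "SimulationConfig",
    "generate_genome",
    "simulate_substitutions",
    "simulate_expression",
    "simulate_network",
    "simulate_tfbs",
    "generate_dataset",
    "SyntheticDataset",
]

HYBRID = "hyb"
REFERENCE = "ref"

_STAGES = {"genome": 0, "substitutions": 1, "expression": 2, "network": 3, "tfbs": 4}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults describe a hybrid of moderate
    parental divergence at realistic scale (two replicates, ~25% gene
    loss, mean interactome degree ~4)."""

    seed: int = 0
    # genome layout
    n_groups: int = 5000
    n_scaffolds_per_subgenome: int = 10
    loss_rate: float = 0.25
    loss_bias_B: float = 0.5  # fraction of losses taken from subgenome B
    gene_min_codons: int = 300
    gene_max_codons: int = 3000
    identity_mean: float = 90.0  # % identity of subgenome-A copies to reference
    identity_gap: float = 5.0  # identity margin between subgenomes
    identity_sd: float = 1.0
    # substitution model
    omega_log_mean: float = -2.0  # lognormal(ln-mean, ln-sd) of true omega
    omega_log_sd: float = 0.6
    frac_rate_divergent: float = 0.05
    rate_divergence_fold: float = 4.0
    frac_decelerated: float = 0.05
    deceleration_fold: float = 4.0
    site_count_N: int = 1000
    site_count_S: int = 400
    true_dS: float = 0.3
    dS_noise_sd: float = 0.05
    # expression model (log10 FPKM)
    expr_log_mean: float = 1.0
    expr_log_sd: float = 0.8
    homeolog_expr_correlation: float = 0.9
    ref_expr_correlation: float = 0.8
    frac_expr_divergent: float = 0.05
    expr_divergence_fold: float = 4.0
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    library_millions: float = 5.0  # mapped fragments per library, in millions
    # interaction network / stoichiometry
    network_mean_degree: float = 4.0
    stoichiometry_mode: str = "total"  # total | subgenome
    stoich_noise_sd: float = 0.2
    # TF binding sites
    n_tfs: int = 18
    tfbs_marginal_prob: float = 0.2
    tfbs_sharing_prob: float = 0.5

    def __post_init__(self) -> None:
        checks = [
            ("n_groups", self.n_groups >= 1),
            ("loss_rate", 0 <= self.loss_rate <= 1),
            ("loss_bias_B", 0 <= self.loss_bias_B <= 1),
            ("frac_rate_divergent", 0 <= self.frac_rate_divergent <= 1),
            ("rate_divergence_fold", self.rate_divergence_fold >= 1),
            ("frac_decelerated", 0 <= self.frac_decelerated <= 1),
            ("deceleration_fold", self.deceleration_fold >= 1),
            ("frac_expr_divergent", 0 <= self.frac_expr_divergent <= 1),
            ("expr_divergence_fold", self.expr_divergence_fold >= 1),
            ("homeolog_expr_correlation", 0 <= self.homeolog_expr_correlation <= 1),
            ("ref_expr_correlation", 0 <= self.ref_expr_correlation <= 1),
            ("true_dS", self.true_dS > 0),
            ("nb_dispersion", self.nb_dispersion >= 0),
            ("n_replicates", self.n_replicates >= 1),
            ("stoich_noise_sd", self.stoich_noise_sd >= 0),
            ("tfbs_sharing_prob", 0 <= self.tfbs_sharing_prob <= 1),
            ("tfbs_marginal_prob", 0 <= self.tfbs_marginal_prob <= 1),
            ("stoichiometry_mode", self.stoichiometry_mode in ("total", "subgenome")),
            ("site_count_N", self.site_count_N >= 1),
            ("site_count_S", self.site_count_S >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid SimulationConfig fields: {bad}")
        if self.n_replicates < 2:
            warnings.warn(
                "n_replicates < 2: replicate-based expression divergence "
                "testing will be disabled"
            )

    def rng(self, stage: str) -> np.random.Generator:
        """Named, independent substream of the master seed for one stage."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[OrthologGroup], list[HomeologLink]]:
    """Draw the gene complement: reference orthologs plus hybrid copies laid
    out in matching order on paired subgenome scaffolds, with biased loss.

    Each group has one reference gene and, before loss, one copy on each
    subgenome; with probability ``loss_rate`` a group loses one hybrid copy,
    taken from subgenome B with probability ``loss_bias_B``.  Homeolog links
    (for two-copy groups) carry percent identities to the reference: the
    subgenome-A copy is the evolutionarily closer one, drawn around
    ``identity_mean``, the B copy around ``identity_mean − identity_gap``.
    Gene records carry the true subgenome label; assignment benchmarks strip
    it.  Copy order within a link is randomized so positional shortcuts
    cannot recover the truth.
    """
    rng = config.rng("genome")
    n = config.n_groups
    n_scf = config.n_scaffolds_per_subgenome
    per_scf = -(-n // n_scf)  # ceil division

    lost = rng.random(n) < config.loss_rate
    # loss_bias_B is the probability that a loss leaves the survivor on
    # subgenome B (the expected single_B count is n_groups*loss_rate*loss_bias_B)
    survivor_on_B = rng.random(n) < config.loss_bias_B
    codons = rng.integers(config.gene_min_codons, config.gene_max_codons + 1, size=n)
    ident_a = np.clip(rng.normal(config.identity_mean, config.identity_sd, n), 0, 100)
    ident_b = np.clip(
        rng.normal(config.identity_mean - config.identity_gap, config.identity_sd, n),
        0,
        100,
    )
    swap = rng.random(n) < 0.5  # randomize which listed copy is the A copy

    genes: list[GeneRecord] = []
    groups: list[OrthologGroup] = []
    links: list[HomeologLink] = []
    cursor: dict[str, int] = {}
    for i in range(n):
        gid = f"g{i:05d}"
        scf_idx = i // per_scf
        scf_a = f"scf{scf_idx + 1}"
        scf_b = f"scf{n_scf + scf_idx + 1}"
        length = int(codons[i]) * 3
        ref_gene = f"{gid}.r"
        genes.append(
            GeneRecord(ref_gene, REFERENCE, f"ref_scf{scf_idx + 1}",
                       cursor.get("r" + scf_a, 0), cursor.get("r" + scf_a, 0) + length)
        )
        cursor["r" + scf_a] = cursor.get("r" + scf_a, 0) + length + 200

        copy_tags = ("h1", "h2") if not swap[i] else ("h2", "h1")
        name_a, name_b = f"{gid}.{copy_tags[0]}", f"{gid}.{copy_tags[1]}"
        keep_a = not (lost[i] and survivor_on_B[i])
        keep_b = not (lost[i] and not survivor_on_B[i])
        members = []
        if keep_a:
            start = cursor.get(scf_a, 0)
            genes.append(GeneRecord(name_a, HYBRID, scf_a, start, start + length,
                                    subgenome="A"))
            cursor[scf_a] = start + length + 200
            members.append(name_a)
        if keep_b:
            start = cursor.get(scf_b, 0)
            genes.append(GeneRecord(name_b, HYBRID, scf_b, start, start + length,
                                    subgenome="B"))
            cursor[scf_b] = start + length + 200
            members.append(name_b)
        status = (
            "two_copy" if keep_a and keep_b
            else "single_A" if keep_a
            else "single_B"
        )
        groups.append(
            OrthologGroup(
                group_id=gid,
                members={REFERENCE: [ref_gene], HYBRID: sorted(members)},
                hybrid_status={HYBRID: status},
            )
        )
        if keep_a and keep_b:
            first, second = sorted([name_a, name_b])
            links.append(
                HomeologLink(
                    group_id=gid,
                    gene_a_candidate=first,
                    gene_b_candidate=second,
                    identity_to_reference={
                        name_a: float(ident_a[i]),
                        name_b: float(ident_b[i]),
                    },
                )
            )
    if not links:
        warnings.warn("no two-copy pairs generated (loss_rate too high?)")
    return genes, groups, links


# ---------------------------------------------------------------------------
# substitutions
# ---------------------------------------------------------------------------


def simulate_substitutions(
    groups: list[OrthologGroup],
    config: SimulationConfig,
    genes: list[GeneRecord] | None = None,
) -> tuple[dict[str, SubstitutionRecord], pd.DataFrame]:
    """Binomially generated substitution records for every gene.

    Per group a true rate ω is drawn lognormal and shared by the reference
    ortholog and both hybrid copies (the null).  A ``frac_rate_divergent``
    subset of two-copy groups has one copy's ω multiplied by
    ``rate_divergence_fold`` (copy chosen by fair coin); a disjoint
    ``frac_decelerated`` subset has both hybrid copies' ω divided by
    ``deceleration_fold`` relative to the reference.  ω is capped at
    0.99/dS so the binomial probability stays valid (cap count reported in
    the truth table attrs).  Observed dS has small multiplicative noise
    around ``true_dS``; the observed nonsynonymous count is
    Binomial(N, dS·ω) and dN = count/N.

    Returns (records by gene_id, truth table indexed by group_id).
    """
    rng = config.rng("substitutions")
    sub = {g.gene_id: g for g in (genes or [])}
    label_of = {g.gene_id: g.subgenome for g in (genes or [])}

    two_copy = [g for g in groups if g.hybrid_status.get(HYBRID) == "two_copy"]
    perm = rng.permutation(len(two_copy))
    n_div = int(round(config.frac_rate_divergent * len(two_copy)))
    n_dec = int(round(config.frac_decelerated * len(two_copy)))
    if n_div + n_dec > len(two_copy):
        raise ValueError("frac_rate_divergent + frac_decelerated exceed 1")
    divergent_ids = {two_copy[j].group_id for j in perm[:n_div]}
    decelerated_ids = {two_copy[j].group_id for j in perm[n_div:n_div + n_dec]}
    div_copy_is_a = rng.random(len(groups)) < 0.5

    records: dict[str, SubstitutionRecord] = {}
    truth_rows = []
    n_capped = 0
    omega_cap = 0.99 / config.true_dS

    def observe(gene_id: str, omega: float) -> None:
        nonlocal n_capped
        ds = config.true_dS * float(np.exp(rng.normal(0.0, config.dS_noise_sd)))
        p = ds * omega
        if p >= 1.0:
            p = 0.99
            n_capped += 1
        count = int(rng.binomial(config.site_count_N, p))
        records[gene_id] = SubstitutionRecord(
            gene_id=gene_id,
            dN=count / config.site_count_N,
            dS=ds,
            N=config.site_count_N,
            S=config.site_count_S,
        )

    for gi, grp in enumerate(groups):
        omega_ref = float(rng.lognormal(config.omega_log_mean, config.omega_log_sd))
        omega_ref = min(omega_ref, omega_cap)
        omega_a = omega_b = omega_ref
        if grp.group_id in divergent_ids:
            if div_copy_is_a[gi]:
                omega_a = min(omega_a * config.rate_divergence_fold, omega_cap)
            else:
                omega_b = min(omega_b * config.rate_divergence_fold, omega_cap)
        elif grp.group_id in decelerated_ids:
            omega_a = omega_b = omega_ref / config.deceleration_fold

        ref_gene = grp.members[REFERENCE][0]
        observe(ref_gene, omega_ref)
        for gene_id in grp.members.get(HYBRID, []):
            lab = label_of.get(gene_id)
            if lab is None:  # fall back to tag order when no gene records given
                lab = "A" if gene_id.endswith("h1") else "B"
            observe(gene_id, omega_a if lab == "A" else omega_b)
        truth_rows.append(
            {
                "group_id": grp.group_id,
                "omega_ref": omega_ref,
                "omega_a": omega_a,
                "omega_b": omega_b,
                "rate_divergent": grp.group_id in divergent_ids,
                "decelerated": grp.group_id in decelerated_ids,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("group_id")
    truth.attrs["n_omega_capped"] = n_capped
    return records, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExpression:
    """Counts and FPKM views per species, plus the generating truth."""

    counts: dict[str, ExpressionMatrix]
    fpkm: dict[str, ExpressionMatrix]
    truth: pd.DataFrame


def _copy_labels(grp: OrthologGroup, genes_by_id: dict[str, GeneRecord]) -> dict[str, str]:
    out = {}
    for gene_id in grp.members.get(HYBRID, []):
        rec = genes_by_id.get(gene_id)
        lab = rec.subgenome if rec is not None else ("A" if gene_id.endswith("h1") else "B")
        out[gene_id] = lab
    return out


def simulate_expression(
    groups: list[OrthologGroup],
    genes: list[GeneRecord],
    config: SimulationConfig,
) -> SimulatedExpression:
    """Correlated homeolog expression with NB replicate counts.

    Per group, log10-FPKM means for (reference ortholog, copy A, copy B) are
    drawn from a trivariate normal: mean ``expr_log_mean``, sd
    ``expr_log_sd``, correlation ``homeolog_expr_correlation`` between the
    two copies and ``ref_expr_correlation`` between the reference and each
    copy (hybrid subgenomes converge transcriptionally, so their mutual
    correlation exceeds the correlation with the outgroup by default).  A
    ``frac_expr_divergent`` subset of two-copy groups has one copy (fair
    coin) shifted up by log10(``expr_divergence_fold``).  Replicate fragment
    counts are negative binomial with mean FPKM × length_kb ×
    ``library_millions`` and dispersion ``nb_dispersion``; the FPKM view is
    recomputed from the counts so both carry the same sampling noise.
    Conditions (log, stationary) share the same means: the generator models
    no condition effect.
    """
    rng = config.rng("expression")
    genes_by_id = {g.gene_id: g for g in genes}

    r_ab = config.homeolog_expr_correlation
    r_r = config.ref_expr_correlation
    cov = np.array([[1.0, r_r, r_r], [r_r, 1.0, r_ab], [r_r, r_ab, 1.0]])
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < -1e-10:
        raise ValueError(
            f"correlation structure not positive semidefinite: ref={r_r}, "
            f"homeolog={r_ab}"
        )
    chol = eigvec * np.sqrt(np.clip(eigval, 0.0, None))  # cov = chol @ chol.T

    n = len(groups)
    z = rng.standard_normal((n, 3)) @ chol.T
    log_mu = config.expr_log_mean + config.expr_log_sd * z  # ref, A, B

    two_copy_idx = [
        i for i, g in enumerate(groups) if g.hybrid_status.get(HYBRID) == "two_copy"
    ]
    n_div = int(round(config.frac_expr_divergent * len(two_copy_idx)))
    div_idx = set(np.asarray(two_copy_idx)[rng.permutation(len(two_copy_idx))[:n_div]])
    shift_a = rng.random(n) < 0.5
    shift = np.log10(config.expr_divergence_fold)
    truth_rows = []
    gene_mu_fpkm: dict[str, float] = {}
    for i, grp in enumerate(groups):
        mu_ref, mu_a, mu_b = log_mu[i]
        divergent = i in div_idx
        if divergent:
            if shift_a[i]:
                mu_a += shift
            else:
                mu_b += shift
        ref_gene = grp.members[REFERENCE][0]
        gene_mu_fpkm[ref_gene] = 10.0 ** mu_ref
        for gene_id, lab in _copy_labels(grp, genes_by_id).items():
            gene_mu_fpkm[gene_id] = 10.0 ** (mu_a if lab == "A" else mu_b)
        truth_rows.append(
            {
                "group_id": grp.group_id,
                "log_mu_ref": mu_ref,
                "log_mu_a": mu_a,
                "log_mu_b": mu_b,
                "expr_divergent": divergent,
                "shifted_copy": ("A" if shift_a[i] else "B") if divergent else "",
            }
        )

    conditions = ("log", "stationary")
    counts_mats: dict[str, ExpressionMatrix] = {}
    fpkm_mats: dict[str, ExpressionMatrix] = {}
    for species in (HYBRID, REFERENCE):
        sp_genes = [g for g in genes if g.species == species]
        ids = [g.gene_id for g in sp_genes]
        len_kb = np.array([g.length / 1000.0 for g in sp_genes])
        mu_fpkm = np.array([gene_mu_fpkm[g] for g in ids])
        mu_counts = mu_fpkm * len_kb * config.library_millions
        sample_names, meta_rows = [], {}
        blocks = []
        for cond in conditions:
            for rep in range(1, config.n_replicates + 1):
                name = f"{species}.{cond}.rep{rep}"
                sample_names.append(name)
                meta_rows[name] = {
                    "species": species, "condition": cond, "replicate": rep,
                }
                if config.nb_dispersion > 0:
                    size = 1.0 / config.nb_dispersion
                    draw = rng.negative_binomial(
                        size, size / (size + np.maximum(mu_counts, 1e-12))
                    )
                else:
                    draw = rng.poisson(mu_counts)
                blocks.append(draw.astype(float))
        counts_df = pd.DataFrame(
            np.column_stack(blocks), index=ids, columns=sample_names
        )
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")
        fpkm_df = counts_df.div(len_kb * config.library_millions, axis=0)
        counts_mats[species] = ExpressionMatrix(counts_df, meta, "count")
        fpkm_mats[species] = ExpressionMatrix(fpkm_df, meta, "fpkm")

    truth = pd.DataFrame(truth_rows).set_index("group_id")
    return SimulatedExpression(counts=counts_mats, fpkm=fpkm_mats, truth=truth)


# ---------------------------------------------------------------------------
# interaction network + stoichiometry
# ---------------------------------------------------------------------------


def simulate_network(
    groups: list[OrthologGroup],
    config: SimulationConfig,
) -> tuple[list[InteractionEdge], pd.DataFrame]:
    """Random interaction network plus group-level expression consistent with
    the configured stoichiometry-conservation mode.

    Edges form an Erdős–Rényi-style random graph (G(n, m) with
    m = n·mean_degree/2, deduplicated, no self-loops).  Reference
    expression per group is lognormal; hybrid expression is constructed so
    that under ``stoichiometry_mode="total"`` the two copies' FPKMs sum to
    the reference level (split uniformly between copies), and under
    ``"subgenome"`` each copy individually matches the reference level.
    Per-gene multiplicative lognormal noise ``stoich_noise_sd`` is applied
    to hybrid genes.  With zero noise the generating mode's conservation
    ratio is exactly 1 on every edge.

    Returns (edges, group expression table indexed by group_id with columns
    status, fpkm_a, fpkm_b, ref_fpkm, pair_identity).
    """
    rng = config.rng("network")
    n = len(groups)
    gids = [g.group_id for g in groups]
    m = int(round(n * config.network_mean_degree / 2.0))
    seen: set[tuple[int, int]] = set()
    edges: list[InteractionEdge] = []
    if n >= 2 and m > 0:
        draws = rng.integers(0, n, size=(int(m * 1.3) + 16, 2))
        for u, v in draws:
            if len(edges) >= m:
                break
            if u == v:
                continue
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            edges.append(InteractionEdge(gids[key[0]], gids[key[1]]))

    ref_fpkm = 10.0 ** rng.normal(config.expr_log_mean, config.expr_log_sd, n)
    share_a = rng.uniform(0.25, 0.75, n)
    noise = np.exp(rng.normal(0.0, config.stoich_noise_sd, (n, 2)))
    pair_identity = np.clip(rng.normal(90.0, 3.0, n), 50.0, 100.0)

    rows = []
    for i, grp in enumerate(groups):
        status = grp.hybrid_status.get(HYBRID, "absent")
        fpkm_a = fpkm_b = np.nan
        if config.stoichiometry_mode == "total":
            a_level = ref_fpkm[i] * share_a[i]
            b_level = ref_fpkm[i] * (1.0 - share_a[i])
        else:
            a_level = b_level = ref_fpkm[i]
        if status == "two_copy":
            fpkm_a = a_level * noise[i, 0]
            fpkm_b = b_level * noise[i, 1]
        elif status == "single_A":
            fpkm_a = ref_fpkm[i] * noise[i, 0]
        elif status == "single_B":
            fpkm_b = ref_fpkm[i] * noise[i, 1]
        rows.append(
            {
                "group_id": grp.group_id,
                "status": status,
                "fpkm_a": fpkm_a,
                "fpkm_b": fpkm_b,
                "ref_fpkm": ref_fpkm[i],
                "pair_identity": pair_identity[i] if status == "two_copy" else np.nan,
            }
        )
    return edges, pd.DataFrame(rows).set_index("group_id")


# ---------------------------------------------------------------------------
# TF binding sites
# ---------------------------------------------------------------------------


def simulate_tfbs(
    pair_ids: list[str], config: SimulationConfig
) -> list[TFBSPresence]:
    """Binding-site presence for each TF over all two-copy pairs.

    Marginal presence probability is ``tfbs_marginal_prob`` for each copy.
    With probability ``tfbs_sharing_prob`` a pair inherits one shared
    promoter state (both copies identical); otherwise the two copies draw
    independently.  sharing 0 ⇒ independence, sharing 1 ⇒ perfect sharing;
    the marginal is preserved either way.
    """
    rng = config.rng("tfbs")
    rows: list[TFBSPresence] = []
    q = config.tfbs_marginal_prob
    for t in range(config.n_tfs):
        tf_id = f"TF{t + 1:02d}"
        shared = rng.random(len(pair_ids)) < config.tfbs_sharing_prob
        x = rng.random(len(pair_ids)) < q
        ya = rng.random(len(pair_ids)) < q
        yb = rng.random(len(pair_ids)) < q
        for j, pid in enumerate(pair_ids):
            a = bool(x[j]) if shared[j] else bool(ya[j])
            b = bool(x[j]) if shared[j] else bool(yb[j])
            rows.append(TFBSPresence(pid, tf_id, a, b))
    return rows


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneRecord]
    groups: list[OrthologGroup]
    links: list[HomeologLink]
    substitutions: dict[str, SubstitutionRecord]
    substitution_truth: pd.DataFrame
    expression: SimulatedExpression
    edges: list[InteractionEdge]
    group_expr: pd.DataFrame
    tfbs: list[TFBSPresence]

    @property
    def two_copy_pairs(self) -> pd.DataFrame:
        """Pair table (group_id, gene_a, gene_b, gene_ref) for two-copy
        groups, with gene_a the subgenome-A copy."""
        label = {g.gene_id: g.subgenome for g in self.genes}
        rows = []
        for grp in self.groups:
            if grp.hybrid_status.get(HYBRID) != "two_copy":
                continue
            members = grp.members[HYBRID]
            a = next(g for g in members if label[g] == "A")
            b = next(g for g in members if label[g] == "B")
            rows.append(
                {
                    "group_id": grp.group_id,
                    "gene_a": a,
                    "gene_b": b,
                    "gene_ref": grp.members[REFERENCE][0],
                }
            )
        return pd.DataFrame(rows, columns=["group_id", "gene_a", "gene_b", "gene_ref"])

    def write(self, outdir: str | Path) -> None:
        """Write all tables in the pipeline's TSV dialects plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_table(self.genes, outdir / "genes.bed")
        write_ortholog_groups(self.groups, outdir / "groups.tsv")
        write_substitutions(
            sorted(self.substitutions.values(), key=lambda r: r.gene_id),
            outdir / "substitutions.tsv",
        )
        for species in (HYBRID, REFERENCE):
            write_expression(
                self.expression.counts[species], outdir / f"counts.{species}.tsv"
            )
            write_expression(
                self.expression.fpkm[species], outdir / f"fpkm.{species}.tsv"
            )
        write_interactions(self.edges, outdir / "interactome.tsv")
        self.group_expr.to_csv(outdir / "group_expression.tsv", sep="\t",
                               float_format="%.12g")
        write_tfbs(self.tfbs, outdir / "tfbs.tsv")
        with open(outdir / "links.tsv", "w") as fh:
            fh.write("group_id\tgene1\tgene2\tidentity1\tidentity2\n")
            for link in self.links:
                g1, g2 = link.gene_a_candidate, link.gene_b_candidate
                fh.write(
                    f"{link.group_id}\t{g1}\t{g2}"
                    f"\t{link.identity_to_reference[g1]:.6g}"
                    f"\t{link.identity_to_reference[g2]:.6g}\n"
                )
        manifest = {
            "config": dataclasses.asdict(self.config),
            "seed": self.config.seed,
            "n_genes": len(self.genes),
            "n_groups": len(self.groups),
            "n_edges": len(self.edges),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage with its own substream of ``config.seed``."""
    genes, groups, links = generate_genome(config)
    substitutions, sub_truth = simulate_substitutions(groups, config, genes=genes)
    expression = simulate_expression(groups, genes, config)
    edges, group_expr = simulate_network(groups, config)
    pair_ids = [
        g.group_id for g in groups if g.hybrid_status.get(HYBRID) == "two_copy"
    ]
    tfbs = simulate_tfbs(pair_ids, config)
    return SyntheticDataset(
        config=config,
        genes=genes,
        groups=groups,
        links=links,
        substitutions=substitutions,
        substitution_truth=sub_truth,
        expression=expression,
        edges=edges,
        group_expr=group_expr,
        tfbs=tfbs,
    )
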