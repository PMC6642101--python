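# Methods

This note documents the models behind `allodiverge`, the choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate about real data.

## 1. The homeolog rate-divergence test

**Model.** For a two-copy homeolog pair sharing N nonsynonymous sites and a
common evolutionary rate ω, the observed nonsynonymous substitution count of
copy *i*, N·dNᵢ, is modelled as Binomial(N, dSᵢ·ω): the synonymous rate dSᵢ
acts as the copy's exposure (elapsed substitution opportunity), ω as the
proportionality between nonsynonymous and synonymous substitution per site.
The normal approximation to the binomial gives dNᵢ/dSᵢ ~ Normal(ω,
ω(1−dSᵢω)/(N·dSᵢ)), hence a z statistic for the difference of the two
copies' observed rates with plug-in ω̂.

**Estimator of ω.** The null needs a common-rate estimate; we pool:
ω̂ = (dN₁+dN₂)/(dS₁+dS₂).  It is symmetric in the copies, consistent, and
reduces to each copy's observed rate when those agree.  (A precision-weighted
MLE differs only at second order for the dS ranges involved.)

**N when copies differ.** The variance formula assumes one N per pair; when
the copies' site counts differ we use their arithmetic mean, recorded
per pair in the results (`n_effective`).

**Median normalization.** Hybrids whose parents differed in intrinsic rate
show a global A/B rate ratio offset that would masquerade as widespread
divergence.  Before testing, subgenome-A rates (operationally, dN₁) may be
divided by c = median(ω₁/ω₂) over pairs with positive finite rates, making
the median normalized ratio exactly 1 (interpolated median for even counts).
Pairs with zero denominators are excluded from c but still rescaled.  The
default mode `auto` always applies the scaling — it is a no-op (c ≈ 1) when
no intrinsic offset exists — and `off` disables it.  Normalization is
idempotent: applying it twice yields a second scale of 1.

**Filters and calls.** Groups containing any gene with dN ≥ 2 or dS ≥ 2 are
removed before testing (substitution saturation; boundary inclusive).
P-values are BH-adjusted; *divergent* ⇔ q ≤ 0.01 and fold ≥ 3 (both
inclusive), with fold = max(ω₁/ω₂, ω₂/ω₁) on normalized rates.
*Decelerated* ⇔ both copies' ω at most ω_ref/3, compared multiplicatively
with a 1e−9 relative tolerance so an exactly-3-fold pair is included despite
floating-point rounding; the call is pair-level (both copies must pass) —
the natural reading for a mechanism protecting the pair as a dosage unit —
and reference orthologs with ω_ref = 0 are skipped.  Copies with dS = 0 are
excluded with a reason code (their rate is undefined); dN = 0 copies are
tested normally.

**Degenerate cases.** z = 0 gives p = 1.  A zero variance with a nonzero
rate difference (only possible at ω̂ = 0 with conflicting inputs) yields
p = 0 with a warning.  ω̂·dSᵢ ≥ 1 is a model violation and raises.

**Accuracy of the normal approximation.** The benchmark
(`benchmarks.oracle_equivalence`) compares the analytic two-sided p with an
empirical p from 10⁵ paired-binomial draws under the plug-in null, across
200 parameter draws with N ∈ [200, 5000] and ω̂·dS ∈ [0.02, 0.5].  Because
the paired-binomial statistic lives on a lattice, the raw empirical
exceedance differs from any continuous tail by lattice-atom effects that
dominate where the Monte-Carlo standard error vanishes (p → 1).  The
empirical p is therefore defined as P(|D* + U| ≥ |d_obs|) with U uniform on
± half the finer lattice spacing — a lattice-free generalization of the
mid-p convention.  With it, deviations are pure Monte-Carlo noise; since a
3-SE band is exceeded by chance in ~0.5 of 200 draws even for an exact
tail, the acceptance check requires ≥198/200 draws within 3 SE.

## 2. Subgenome assignment

Two regimes reflect two biological situations:

* **identity margin** (distant parents): within each homeolog pair, the
  copy with higher percent identity to the reference-species ortholog is
  assigned to subgenome A and its partner to B, provided the identity
  difference is ≥ 2 points (default; configurable).  Below-margin pairs and
  ties fall through.
* **scaffold tracks** (similar parents): scaffold pairs connected by ≥ 10
  homeolog links form "must-differ" constraints; each connected component of
  this conflict graph is 2-colored, non-bipartite components are left
  unassigned with a warning, and colors are oriented by mean identity to the
  reference (higher = A) or an explicit user mapping.  The original analyses
  oriented tracks with a maximum-likelihood phylogeny; mean identity uses
  the same information source (evolutionary proximity) without tree
  inference, and the override flag accepts an external orientation.

Genes still unassigned (single-copy genes, below-margin pairs) take the
majority label of the k = 20 nearest assigned pair-genes on the same
scaffold, nearest by start-coordinate distance; a strict majority over the
available neighbors (all of them when fewer than k exist) is required.
Pairs that end up with identical labels are contradictory and both copies
are unassigned (`pair_conflict`); everything else unassigned is removed with
a reason code.  The output is independent of input row order, and
complementarity of labels within every pair is asserted after the cascade.

## 3. Expression analyses

**Replicate averaging.** FPKM is log₁₀-transformed with a pseudocount
(default 0.01 FPKM — two decades below the common 1-FPKM detection
threshold) and averaged across replicates per (species, condition).
Undetected transcripts are stored as 0.0, never as missing.

**Correlation matrices.** Spearman, restricted to ortholog groups present
in every compared unit, ties mid-ranked.  Rank correlation makes the
log-vs-linear FPKM question moot.

**Subgenome bias.** Paired Wilcoxon signed-rank across two-copy pairs;
unpaired Mann–Whitney U between single-A and single-B gene sets (skipped
below 10 genes per side).  All-zero paired differences give p = 1 with a
warning.

**Expression-divergence calling.** A self-contained negative-binomial Wald
stage, deliberately in the same test family and at the same thresholds as a
DESeq2-style analysis without being a clone of it: median-of-ratios size
factors (over genes expressed in all samples); per-pair method-of-moments
dispersion α = (s² − m)/m² averaged over the two copies, floored at 0.01
(the floor prevents the 2-replicate variance estimate from collapsing);
Wald z = log(m_A/m_B)/se with the delta-method variance
se² = [(1/m_A + α) + (1/m_B + α)]/m over m replicates and a 0.5 pseudocount
on the means; BH adjustment; divergent ⇔ q ≤ 0.01 and fold ≥ 3.  Raw and
median-normalized A/B expression ratios are carried alongside (the same
median-scaling contract as for rates).  Single-replicate designs are
refused and directed to ratio-only mode.

**Concordance of rate and expression divergence.** Spearman correlation of
the two normalized log divergences over the jointly tested universe,
hypergeometric overlap p between the two divergent sets, and quadrant counts
of doubly divergent pairs.  Pair-level expression for the deceleration
association is the mean of the two copies' log FPKM.

**Silent copies.** Silent = 0 FPKM in *every* sample of the hybrid (the
strictest reading of "undetected"); the partner's mean FPKM is reported and
flagged when < 1 FPKM, where apparent silencing is plausibly a
detection-limit artifact.

**Suppressed regions.** Sliding windows (defaults 100 kb, 10 kb step,
≥ 10 genes) over each scaffold; candidates have a median gene expression at
or below the genome-wide 5th percentile of window medians *and* strictly
below the global median (so a perfectly flat genome yields none);
overlapping candidates merge.  No published delineation procedure exists
for this scan; the defaults are exposed in config.

## 4. Interaction stoichiometry

Edges of a reference interactome are lifted to ortholog groups (self-loops,
duplicates, unmapped genes dropped with counts) and classified by endpoint
copy status.  Stoichiometry of an edge is the FPKM ratio of its endpoints:

* **total** mode sums both copies of a two-copy endpoint
  (10 + 20 vs 5 → 6);
* **subgenome** mode counts only the copy sharing the single-copy partner's
  subgenome (10 vs 5 → 2) and is defined only for two-copy↔single-copy
  edges — the per-subgenome view of symmetric edges is descriptive (box ii/iii
  style) and excluded from the verdict.

Conservation is hybrid stoichiometry divided by the same edge's reference
stoichiometry, reported linearly and as log₂.  Orientation: two-copy side
over single-copy side for mixed edges, lexicographic group order otherwise;
|log ratio| analyses are orientation-free.  Zero FPKM on a required copy
skips the record with a reason (never imputed).

**Mode verdict.** For mixed edges, the mode with the smaller median
|log₂ conservation ratio| (tie-broken by IQR) is declared the hybrid's
conservation regime.  Median absolute deviation from perfect conservation is
the right contrast here because the wrong mode is not merely noisier — it is
*offset* (total measurement of subgenome-conserved data centers at log₂ 2).

**Network position.** Local clustering coefficients (degree < 2 → 0) are
computed on the reference network, where topology is not distorted by the
hybrid's own losses; the single-A vs single-B comparison is a two-sided
Mann–Whitney U with the fold difference of medians.  The loss-expression
preference uses reference-species expression only, to ask about the
*ancestral* state rather than post-hybridization regulation; ties count as
half an event in the binomial test against 0.5.

## 5. Enrichment statistics

Exact upper-tail hypergeometric P(X ≥ k) throughout (enrichment only).
Term enrichment excludes terms of size < 10 or > 500 *before* fixing the
Bonferroni divisor — the divisor is the number of terms actually tested,
the defensible universe after filtering.  The TFBS-sharing test treats the
pairs carrying a site on copy A and on copy B as two sets over the universe
of scored pairs; the hypergeometric on their intersection is symmetric in
which margin is treated as "draws", so the 2×2 orientation is
convention-free.  Raw and Bonferroni-adjusted p are both reported.

## 6. The synthetic generator

One master seed; each stage (genome, substitutions, expression, network,
TFBS) draws from its own named substream, so stages regenerate independently
and identical config + seed gives byte-identical files.

What it emulates, with defaults chosen to mirror a young hybrid fungus of
moderate parental divergence:

| aspect | model | default |
|---|---|---|
| gene complement | one reference ortholog + mirrored hybrid copies on paired scaffolds | 5000 groups, 10 scaffolds/subgenome |
| gene loss | per-group Bernoulli; survivor on subgenome B with prob `loss_bias_B` | rate 0.25, bias 0.5 |
| identities | A copies ~N(90, 1)%, B copies `identity_gap` lower | gap 5 points |
| true ω | lognormal | ln-mean −2.0, ln-sd 0.6 (median ω ≈ 0.14) |
| rate divergence | one copy × fold, fair coin | 5% of pairs, fold 4 |
| deceleration | both copies ÷ fold vs reference | 5% of pairs, fold 4 |
| substitutions | count ~ Binomial(N, dS·ω), dN = count/N; dS lognormal-noised around 0.3 | N = 1000 sites |
| expression | trivariate normal log₁₀ FPKM (ref, A, B); A–B correlation above ref correlation | 0.9 vs 0.8; mean 1.0, sd 0.8 |
| expression divergence | one copy shifted +log fold | 5%, fold 4 |
| counts | NB, mean = FPKM × length_kb × library size, shared across conditions | dispersion 0.05, 2 replicates, 5 M fragments |
| network | G(n, m) random graph | mean degree 4 (≈ curated-interactome edge density) |
| stoichiometry | copies sum to (total) or each equal (subgenome) the reference level, per-gene lognormal noise | mode total, noise sd 0.2 |
| TFBS | shared promoter state with prob `tfbs_sharing_prob`, else independent | 18 TFs, marginal 0.2, sharing 0.5 |

ω is capped at 0.99/dS to keep the binomial probability valid (cap count
recorded).  Gene lengths are uniform over 300–3000 codons and matter only
for the FPKM↔count conversion.

What it does **not** emulate — and hence what passing benchmarks do not
show about real data: codeml's estimation noise and branch-model artifacts
(dN, dS arrive as clean binomial summaries); condition effects, batch
effects and cross-species library composition; the curated interactome's
topology (degree heterogeneity, modularity — the random graph only matches
edge density); assembly errors and collapsed repeats behind real
unassignable genes; inherited cis-regulatory divergence beyond a single
per-copy shift; and any sequence-level signal (no FASTA anywhere).

## 7. Benchmark problem sizes

The acceptance benchmarks run, per invocation: 200 oracle draws × 10⁵ MC
replicates; 20 null seeds × 5000 pairs; 10 seeds per stoichiometry mode at
1500 groups (≥ 1100 mixed edges each); one 2000-group assignment genome;
all 3184 hypergeometric cases with M ≤ 12; and 100 seeds × 1000 groups for
overlap uniformity — about 1–2 CPU-minutes total.  These sizes give the
binomial/KS margins computed in the ledgered power analyses while staying
desk-scale; larger runs only tighten the same checks.

## 8. Known limitations

* The rate test conditions on dS as exposure and ignores estimation error
  in dS itself; with real codeml output, dS noise inflates apparent rate
  divergence slightly — the saturation filter bounds but does not remove
  this.
* The NB Wald stage is not DESeq2: no dispersion shrinkage across genes, no
  Cook's filtering, no independent filtering.  At 2 replicates its
  dispersion estimates are crude; the floor keeps it conservative.
* The mode verdict is a single binary summary; hybrids could mix regimes
  across network modules, which the per-class summaries expose but the
  verdict collapses.
* Assignment assumes homeolog links are given (from synteny/orthology
  tools); it discovers no synteny itself.
* The generator's expression model is condition-free; condition-specific
  bias analyses run but are not exercised against a true effect.
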