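# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Data model

All stages operate on an `ExpressionBundle`: a log2 intensity matrix
(genes × samples) with a binary cohort label per sample (case = 1,
control = 0), an optional clinical table (SLEDAI, anti-dsDNA [IU/mL],
C3 [mg/dL], C4 [mg/dL], CRP [mg/L]; all nonnegative) and an optional
probe→gene map. Missing values are rejected at load — the arrays this
pipeline targets have none, and silent imputation would contaminate
every downstream correlation. Duplicate gene or sample ids are load
errors naming the offending row/column.

## Preprocessing

**Low-intensity filter.** A gene is removed when its *maximum* log2
intensity falls below the cutoff (default 2.34): the "all samples
below threshold" reading. The alternative ("any sample below") removes
genes with a single dim array and was rejected as too aggressive for
n ≈ 4 per cohort; the choice is a parameter, not a constant. The IQR
mode (used before per-sample scoring) removes genes below a quantile
of the per-gene interquartile ranges. Because that cutoff is
quantile-relative, re-applying the IQR filter to its own output removes
more genes; only the absolute-threshold mode is idempotent.

**Outlier samples.** The manual practice — inspecting PC1–3 and the
UPGMA (average-linkage, Euclidean) sample dendrogram — is automated as
the conjunction of two flags, each reported separately so a reviewer
can audit the call: (i) distance from the sample's cohort centroid in
PC1–3 space exceeding k·MAD (k = 3, MAD scaled by 1.4826 over all
samples); (ii) the sample's first dendrogram merge occurring above
1.5 × the second-largest merge height (an outlier joins last, far
above the rest of the tree). The conjunction is deliberately
conservative: with n ≈ 8, a false exclusion costs more than a retained
borderline sample. The call is invariant to gene permutation and to
adding a constant to the whole matrix.

**Probe collapse.** One row per gene under a declared rule — `min_p`
(most significant probe, for differential-expression tables),
`max_mean` (for expression matrices), `max_kME` (strongest correlation
to the probe's module eigengene, for network results). Ties break
lexicographically on probe id so re-runs are identical.

## Moderated differential expression

Two-group design only (the target studies have no covariates). Per
gene, the pooled variance s²_g with d_g = n₁+n₂−2 df is shrunk toward
a prior: s²_post = (d₀·s₀² + d_g·s²_g)/(d₀+d_g); the moderated
t = LFC/(s_post·√(1/n₁+1/n₂)) is referred to t with d₀+d_g df. When no
prior is supplied, (d₀, s₀²) come from closed-form moment matching of
e_g = log s²_g under the scaled-F model: var(e) − ψ′(d_g/2) = ψ′(d₀/2)
(trigamma inverted by Newton iteration; nonpositive excess variance ⇒
d₀ = ∞) and s₀² from the mean of e_g via digamma terms. d₀ = 0
reproduces the ordinary pooled t to 1e-10 on fixtures; d₀ = ∞ gives the
z-form. Zero-variance genes with d₀ = 0 are reported as per-gene
errors, not global failures.

Benjamini–Hochberg adjustment is the step-up q-value (delegated to
statsmodels behind the `adjust_bh` surface and verified against the
"largest k with p₍k₎ ≤ kα/m" decision rule across an α grid). The
significance gate is a pre-specified FDR, default 0.2 — deliberately
liberal to avoid false negatives at these sample sizes.

**Merging two annotation definitions.** Results computed under two
probe annotations merge by union of gene symbols; a gene present in
both keeps the smaller-p entry (ties: smaller q, then first source).
The q < 0.2 gate is re-evaluated per kept entry; q-values are *not*
recomputed on the merged list (adjust-then-merge). Opposite-sign fold
changes between the two sources are kept but listed in a discordance
report. Both orderings (merge-then-adjust was the alternative) are
defensible; adjust-then-merge was chosen so each annotation's error
control stands on its own, and the choice is documented rather than
silent.

## Fisher-exact category enrichment

For list L, category C and universe U (counts a, b, c, d), the
right-sided p is the hypergeometric upper tail P(X ≥ a), computed by
direct pmf summation for accuracy in extreme tails, and the effect is
the *sample* odds ratio ad/(bc) — not the conditional MLE — because
the reporting convention for empty overlaps (OR = 0, drawn at the CI
upper bound in forest plots) requires it. The 95% CI uses the Woolf
log method; when any cell is zero, the Haldane–Anscombe 0.5 is added
to all four cells *for the CI only*. Significance = p < α (0.05) and
CI excluding 1. The universe defaults to all genes surviving the
low-intensity filter; back-solving published odds ratios (2.84 up,
0.0749 down, with 926-gene category, 2,477/4,019-gene lists) implies a
universe near 21,000 genes, and at 20,992 the package reproduces both
printed ORs — a consistency check on the convention, since the
universe size itself is never printed.

## Co-expression modules

Unsigned adjacency a_ij = |cor(x_i,x_j)|^β with β = 30 (signed
((1+cor)/2)^β available), topological overlap
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), TOM_ii = 1.

**Detection.** At β = 30 the dissimilarity 1 − TOM is compressed
against 1 (off-diagonal TOM spans many orders of magnitude), so no
single horizontal cut of the average-linkage dendrogram separates
modules, and the published dynamic-tree-cut parameters are not stated.
The replacement is deterministic and two-staged:

1. *Cores.* The dendrogram is built on −log10(TOM), where average
   linkage compares geometric-mean overlaps and module boundaries
   appear as additive jumps. A subtree is a core candidate when it has
   ≥ half the minimum module size and joins the rest of the tree
   ≥ `gap_decades` (default 0.2, i.e. a ≥ 1.6× drop in mean overlap)
   above its own root merge; smallest candidates are accepted first
   (they are purest), overlapping ones skipped.
2. *kME refinement.* Three rounds of: eigengene per module (first PC
   of standardized member expression, sign-aligned with the mean
   profile), kME for every gene, reassignment to the best module when
   |kME| ≥ 0.5 (the same "strong correlation" convention used for
   trait QC), fusion of modules whose eigengenes differ by < the merge
   height. This is the eigengene analogue of the
   partitioning-around-medoids outlier reassignment. Without
   expression data (TOM-only input), grey genes instead join the
   module with the highest mean TOM when it clears 0.01 × the module's
   median member connectivity.

Modules below the minimum size (default 100) dissolve to grey.
Labels map deterministically to the conventional color palette in
size order — the usual randomized color assignment is dropped for
reproducibility. On planted three-module data (size 120, factor noise
sd 0.5, n = 20) this recovers the partition with ARI ≥ 0.8 in ≥ 90% of
seeds; on structureless data it returns all grey.

**Merging, traits, QC.** Modules whose eigengene dissimilarity
1 − cor(ME_a, ME_b) is below the merge height (0.2) fuse
(complete-linkage, strict <, iterated to stability; eigengenes
recomputed). Eigengenes correlate with clinical traits by Pearson r
with two-sided p; missing trait values use pairwise deletion
(reported), constant traits give NA with a reason. QC reports
per-cohort eigengene summaries, the concordance between member kME and
member gene–trait correlation for the primary trait (SLEDAI), and a
strong/weak call per module–trait pair: |r| ≥ 0.5 (boundary inclusive)
and p < 0.05.

## Per-sample gene-set scoring

The expression statistic is ẑ_ij = (1/n)Σ_k Φ((x_ij − x_ik)/h_i) with
bandwidth h_i = s_i/4 — the standard kernel choice for log-intensity
data — or, with `kernel="ecdf"`, the mid-rank empirical CDF of the
gene's values, which makes everything downstream *exactly* invariant
under strictly monotone per-gene transforms. Genes are ranked per
sample by ẑ (descending, ties by row order) with symmetric weight
r_ij = |p/2 − rank_ij|. The random walk adds r^τ (normalized within
the set; τ = 1 default) on set genes and subtracts 1/(p−m) otherwise;
the score is ν_max + ν_min ("diff" mode; the walk ends at 0, so the
score lies strictly inside (−1, 1)) or the single largest-magnitude
deviation ("max"). τ and the mode are config-exposed because the
published settings are not stated. Constant genes are excluded with a
warning; the IQR pre-filter lives in the preprocessing stage.

Cohort contrasts: Welch's t (Satterthwaite df) at α = 0.05, then
Hedges' g = J·(m₁−m₂)/s_pooled with
s_pooled² = ((n₁−1)s₁²+(n₂−1)s₂²)/(n₁+n₂−2) and
J = 1 − 3/(4(n₁+n₂−2)−1); at n = 4 vs 4, J = 0.8, and Monte-Carlo
at d = 1 confirms the bias correction (mean g within 0.1 of truth over
1,000 replicates).

## Signature refinement

Pass 1 keeps gene g when its Spearman p (two-sided, ties mid-ranked)
is < α against at least ⌈f·(m−1)⌉ of the *other* original signature
genes (f = 0.25, α = 0.05); pass 2 keeps g when rho > 0 against at
least ⌈f·(m′−1)⌉ of the other pass-1 survivors. Self-correlation is
excluded from both counts and the ceiling is used for the fractional
threshold — both points were open; excluding self and rounding up is
the stricter, better-calibrated reading (fully independent size-12
"signatures" at n = 8 keep ≤ 25% of their genes in ≥ 90% of seeds).
The output is always a subset of the input; per-gene counts at both
passes are returned as an audit trail, including on failure. Ortholog
mapping consumes a user-supplied two-column table; one-to-many
mappings expand and unmapped symbols are reported, never dropped
silently.

## Connectivity summaries

Score windows are inclusive at both ends ([−100, −75] compounds/KD,
[50, 100] OE) — the published ranges are stated without strictness,
and inclusivity keeps the printed boundary compounds. Direction
consistency: a target fails when both its agonist and antagonist score
sets are non-empty and all lie on the same side of zero; single-
direction targets pass vacuously (flagged). Exclusion happens *before*
summarization. Per surviving target with ≥ 2 compounds: n, score
range, mean, SEM = sd(n−1)/√n (for n = 2 this is |x₁−x₂|/2 exactly),
and the most negative compound (ties: lexicographic id). Report
rounding is half-even at 2 decimals; raw values are preserved in the
summary objects. Regulator ranking sorts admitted KD/OE rows by
|score| (ties: target, type, id) and keeps the top 50; KD and OE
evidence for the same gene stay separate lines.

## Synthetic studies

The generator emulates the target design: ~20,000 genes, two cohorts
of about four samples, several hundred signal genes with planted log2
fold changes (magnitudes 0.5–2.5, half down-regulated by default),
five 200-gene latent-factor modules, and clinical traits that are
linear in chosen factors plus Gaussian noise, with baselines matching
the descriptive statistics of the emulated cohort (SLEDAI 8.25,
anti-dsDNA 97.6 IU/mL, C3 82.5 mg/dL, C4 13 mg/dL, CRP 12.5 mg/L).
Noise is independent Gaussian on the log2 scale — baseline sd 1.5
across genes, residual sd 0.5 within genes; module members are
baseline + loading·factor + factor noise (loadings uniform on
[0.6, 1.0]), so the configured factor-noise sd is the *total* noise on
module genes. Taxonomies default to 32 cell categories whose union is
exactly 926 genes (plus 52 function groups and 2 tissue categories);
one category's membership is biased so its odds ratio among signal
genes targets a configured value. Connectivity tables plant target
groups at published two-compound endpoints, decoys just outside the
score windows, a direction-inconsistent pair, and KD/OE regulator
rows. Everything planted is recorded in a `GroundTruth`.

What the generator does **not** emulate: probe-level hybridization,
batch effects, heavy-tailed or intensity-dependent noise, correlated
signal-and-module membership, or realistic gene-gene correlation
outside planted modules. Passing recovery tests therefore demonstrates
that the implementations detect the structure they claim to detect at
study-realistic sizes and noise — not that real synovium data would
yield any particular biological result.

## Problem sizes in tests and the acceptance script

Simulation checks run at reduced but structure-preserving sizes chosen
so the whole suite completes in a few minutes: module recovery at 500
genes × 20 samples over 20 seeds, scoring power at 200 genes over 200
seeds, differential-expression recovery at 2,000 genes over 10–50
seeds, Fisher-tail enumeration over > 10,000 tables with universes up
to 2,000. The acceptance script uses the same conditions with seeds
derived from its `--seed` argument.

## Known limitations

- The module-detection cut is a replacement for dynamic tree cutting,
  not a reimplementation; on data with strongly nested or highly
  unequal-density modules the two can differ. Structureless data can
  in principle yield a spurious module if a noise subtree passes the
  gap test; the kME bar and size dissolution make this rare.
- The moderated-variance prior uses moment matching only (no Newton
  refinement of the profile likelihood); differences are negligible at
  the gene counts involved.
- The Fisher universe is a modelling choice; all reported odds ratios
  move with it, which is why the printed-OR check is a consistency
  property rather than a reproduction.
- Connectivity scores are inputs: computing them from raw signatures
  (the signature-matching service's job) is out of scope, as are
  proprietary pathway tools, protein-interaction visualization, and
  drug-annotation databases.
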