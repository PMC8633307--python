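# Methods

## Variant filter cascade

The cascade evaluates three rules in a fixed order (frequency →
consequence/conservation → pathogenicity) and stops at the first failure; the
verdict carries an audit trail of every rule evaluated so any reordering
would be observable. Decisions taken where the rule set is underspecified:

- **Missing database frequency is treated as 0** (absent = rare): a variant
  not reported in any population database passes the frequency rule. The
  alternative — requiring presence — would discard exactly the novel
  truncating alleles the recessive model is looking for.
- **The frequency rule requires every *reported* database to pass** (< 0.01
  strictly). When databases disagree, one common entry rejects the variant.
  This is the conservative reading; `FilterConfig.af_max` and the rule itself
  are overridable.
- **Truncating = {stopgain, stoploss, frameshift, splicing}.** These bypass
  both the GERP and M-CAP gates; conservation and missense classifiers are
  not defined for them.
- **The GERP gate (> 2.0 strictly) applies to missense variants only**, as
  the non-truncating amino-acid-changing class.
- **M-CAP gray zone [0.025, 0.6] is closed at both ends**; the auto-keep
  threshold (> 0.6), the rarity threshold and the GERP gate are strict
  inequalities ("higher than" / "lower than" readings), while "between"
  includes its endpoints.
- **Missense with missing M-CAP falls back to the two-tool vote**, the
  mechanism the rule set already uses inside the gray zone.
- **ClinVar is carried as annotation, never gated on.**

Recessive detection is unphased: two distinct kept heterozygous variants in
one gene count as compound het even though they could lie in cis. Without
parental genotypes this over-calls; it is the standard trade-off for
singleton cohorts and is documented on the candidate record (mechanism
field).

## Single-cell stage

QC thresholds (min 400 detected genes, 600–10,000 total UMI, max 15%
mitochondrial fraction) are strict inequalities: a cell sitting exactly on a
boundary is retained. Mitochondrial genes are recognized by the `MT-` name
prefix (case-insensitive), the convention of the human and mouse references.

- **Normalization**: per-cell library-size scaling to `scale_factor`
  (default 10,000, the community convention) followed by `log1p`. The per-cell identity
  `sum(exp(value) − 1) = scale_factor` is exact and is asserted in tests.
- **HVG selection** follows the variance-stabilizing ("vst") recipe: a
  lowess fit (span 0.3) of log10 gene variance on log10 gene mean yields an
  expected standard deviation per gene; raw counts standardized by it are
  clipped at sqrt(n_cells) and genes are ranked by the variance of the
  clipped values. The smoother span is configurable; ties break
  alphabetically for determinism.
- **Regress-out** uses per-gene OLS on the configured covariates
  (mitochondrial fraction, total UMI) with an intercept; residuals are
  centered, scaled to unit variance and clipped at ±10. Constant covariates
  are dropped with a warning, degrading gracefully to plain z-scoring.
- **PCA** uses a full SVD; each component's sign is fixed by forcing its
  largest-magnitude loading positive, making embeddings reproducible across
  runs without a seed.
- **Clustering** builds a k-nearest-neighbor graph (default `snn_k` = 20,
  the convention of Seurat-style workflows; only the 40 PCs and the
  resolution are pinned parameters of the pipeline), reweights edges by the Jaccard overlap of the two endpoints'
  neighbor sets (each set includes the cell itself), and partitions with
  Leiden modularity (RB configuration null model) at resolution 0.5 under a
  fixed seed. At this resolution a handful of tiny satellite clusters can
  split off large types; downstream checks therefore evaluate each type's
  majority cluster.
- **Markers**: per cluster, genes expressed in ≥ 30% of in-cluster cells
  with log fold-change ≥ 0.6, where the fold-change is the natural log of
  (mean de-logged expression + 1) in-cluster vs all other cells — the scale
  on which the 0.6 threshold is conventionally applied. Ranking is by
  two-sided Mann-Whitney rank-sum p-value, the default marker test of
  Seurat-style workflows.
- **Cell-type assignment** scores each cluster per reference type by the
  count of that type's canonical markers among the cluster's markers and
  assigns the best-scoring type. A cluster with ≥ 2 canonical markers of
  each of two or more types is flagged a doublet and discarded before
  profile aggregation; manual overrides are accepted.
- **UMAP** (n_neighbors 40, min_dist 0.3, fixed seed) is computed only for
  visualization and feeds nothing downstream.

## Co-expression score

"Co-expressed within the same cell types" is usually judged by eye from dot
plots; this package makes it quantitative:

    combined(g, s) = w · (ρ(g, s) + 1)/2 + (1 − w) · J(g, s)

with Spearman rank correlation ρ of cell-type mean expression (robust to
absolute expression scale; a gene flat across all types has no rank signal
and is scored ρ = 0) and Jaccard overlap J of the cell-type sets where each
gene has pct_expressing ≥ 0.1. Defaults `w` = 0.5, `pct_on` = 0.1; both
components are reported so users can re-weight. Scoring requires ≥ 3 cell
types. Cross-dataset aggregation uses mean rank, charging a gene missing
from a dataset that dataset's worst rank + 1 — absence is penalized but not
disqualifying, since gene coverage differs between datasets. Datasets are
weighted equally.

## Cohort statistics

Percentages round half-away-from-zero (so 44.230…% prints as the clinical
table's 44.23). The 2×2 chi-square is Pearson's with 1 df, continuity
correction off by default (both exposed). Welch's t is computed from
summary statistics with Welch–Satterthwaite df. Mann-Whitney U uses the
exact null for small tie-free samples and the tie-corrected normal
approximation otherwise.

## Synthetic data: what it emulates, what it does not

The generators define the benchmark conditions:

- **Variant tables** (default 500 background variants over 9 samples):
  every background variant is constructed to fail exactly one named rule —
  frequency (one database ≥ 0.01), conservation (GERP ≤ 2), or
  pathogenicity (M-CAP below the gray zone, or gray zone with < 2 damaging
  votes) — or to pass benignly as a single heterozygous variant in its own
  gene (category fractions 0.4/0.3/0.2/0.1). This makes per-rule filter
  counts exactly recountable from the ledger. Planted truth mirrors the
  intended discovery pattern: a compound-het pair (conserved damaging
  missense + truncating variant absent from all databases) and a homozygous
  damaging missense.
- **Count matrices** (default 5 cell types × 300 cells × 2,000 genes):
  negative-binomial counts (dispersion θ = 10; variance μ + μ²/θ) with 40
  exclusive marker genes per type (mean 6 in-type, 0.02 elsewhere),
  baseline genes at mean U(0.5, 2), 13 mitochondrial genes whose means are
  set per type so clean cells land near a 5% mitochondrial fraction, and a
  seed gene plus planted co-expressed partners expressed (mean 5) exactly
  in the ureteric-bud / stromal / hepatoblast types, with planted null
  genes on the complementary types. QC outliers are appended at fractions
  2/2/2/5% (low-gene, low-UMI, high-UMI, ~40%-mito). All injected doublets
  combine one randomly drawn type pair so they are numerous enough to form
  their own flaggable cluster.
- **Cohort tables**: per-group Bernoulli events at the observed prevalences
  (19.5% / 6.2%) and Gaussian continuous traits.

Deliberately not modeled: linkage disequilibrium, sequencing error, batch
effects, ambient RNA, gene-gene correlation beyond the planted structure,
and realistic library-size variation. Passing the recovery tests therefore
demonstrates the pipeline's correctness on its own model assumptions, not
performance on real droplet data, where QC thresholds interact with ambient
RNA and doublet rates in ways the simulation does not produce.

## Problem sizes

Unit tests run on 300–400-cell matrices; the pipeline-recovery benchmark
uses the full 5 × 300 × 2,000 default; the co-expression benchmark uses 20
replicates of 4 datasets at 5 × 40 × 300, sized so each replicate is
dominated by generation rather than scoring. The acceptance script uses the
same sizes.

## Known limitations

- Compound-het calls are unphased (over-call risk, see above).
- The doublet rule operates on clusters, not cells; doublets too few to form
  a cluster are absorbed silently.
- The co-expression score treats cell types as exchangeable observations;
  it does not weight types by size or relevance (e.g. kidney vs liver), and
  equal dataset weighting is a choice, not a finding.
- The integrated-candidate rule (recessive genotype ∧ panel membership,
  ordered by consensus co-expression rank) formalizes an informal clinical
  argument; the ordering is only as meaningful as the profiles behind it.
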