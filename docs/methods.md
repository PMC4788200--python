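# Methods

## Model and procedure

`mirlink` operationalizes three assumptions: miRNAs negatively regulate
their target mRNAs; candidate targets can be predicted from sequence;
and disease-relevant miRNAs/mRNAs are deregulated in the disease.  The
analysis therefore proceeds: (1) per-feature two-group differential
expression (annotation only — features are never dropped by DE, since
under-powered control groups would otherwise cause false negatives);
(2) a one-sided test of negative correlation for every miRNA × mRNA
pair; (3) multiple-testing correction over the family of *all* computed
pairs; (4) intersection of the significant negative pairs with one or
more prediction databases, requiring `min_dat_sum` supporting
databases; (5) scoring, network export, target-count summaries and
hypergeometric enrichment; (6) optionally, integration across several
datasets.

### One-sided correlation test

The null H₀: ρ ≥ 0 is composite; the p-value is taken at the boundary
ρ = 0 (the supremum over the null), which is the standard practice for
one-sided correlation tests.  Pearson uses the exact-under-normality
statistic t = r·√(n−2)/√(1−r²) with the lower tail of t(n−2).  Spearman
applies the same machinery to tie-corrected ranks — a large-sample
approximation whose error at n ≈ 15 can reach ~0.01 in mid-range
p-values and falls below Monte-Carlo resolution by n ≈ 40 (the oracle
tests use n = 40 for this reason).  Kendall uses tau-b with the
normal approximation, and is refused above a configurable pair-count
ceiling (default 2·10⁶) because its per-pair cost is O(n log n) against
Pearson's O(n).  Constant features yield (cor 0, p 1, flagged) instead
of NaN so the row-count contract n_miRNA × n_mRNA always holds.
Correlations are computed one miRNA row at a time (BLAS gemv) within
row blocks: block size changes peak intermediate memory, never the
result, which is bitwise identical for any blocking.

### Differential expression

All four tests report the same four quantities: `logratio` (case −
control mean difference, log2 units), `meanExp` (grand mean), `pval`,
`adj.pval`.  Within each group samples are processed in sorted-id
order, so results are bit-identical under column permutations.

- **t-test**: Student (default) or Welch.  Zero-variance-in-both-groups
  features get p = 1 when means agree and the smallest positive double
  otherwise, with a logged note — the data admit no variance estimate,
  and this keeps the output total.
- **Wilcoxon**: exact null for small tie-free samples, tie-corrected
  normal approximation otherwise; effect summaries stay mean-based.
- **Moderated t**: empirical-Bayes shrinkage of per-feature pooled
  variances toward a scaled inverse-chi-square prior fitted by method
  of moments on log-variances; with `trend=True` the prior variance is
  a lowess-smooth function of mean expression (span 0.5, configurable)
  and requires ≥ 10 features.  p-values use residual + prior degrees of
  freedom; `prior_df=0` recovers the ordinary t.  The implementation is
  cross-checked against the reference R implementation in the test
  suite (tight agreement without trend; the trend variant differs in
  lowess iteration details across implementations).
- **Rank product**: geometric mean of a feature's fold-change rank over
  all case × control sample pairings.  The two-sided statistic is the
  smaller of the down- and up-regulation rank products, so one
  permutation tail covers both directions and null p-values are uniform
  by construction; p-values pool the permutation null over all features
  (≥ 100 label permutations enforced).  Chosen over the gamma
  approximation for small-sample exactness.  Adjustment is always BH.

BH and Bonferroni go through `statsmodels.stats.multitest`; the test
suite checks them against a brute-force step-up implementation.

### Score and summaries

score(a, b) = −2·(a·b) on the two log-ratios: symmetric, positive
exactly when fold-changes oppose.  (Read as a linear product, not an
exponentiation: only the linear form can produce the positive scores
that opposed fold-changes are defined to have.)  The per-miRNA
false-positive ratio is 100·(1 − confirmed/predicted) with the
denominator restricted to predictions among *expressed* features —
otherwise the ratio would depend on genes the dataset cannot test.
Target-count summaries partition all expressed mRNAs into
{0,1,…,5,>5}-regulator categories and report a cumulative coverage
curve over miRNAs in decreasing target-count order.

### Networks and enrichment

Nodes store kind (miRNA/mRNA), log-ratio and direction (up/down/flat =
sign of the log-ratio); edges store score, database support and
adjusted p.  Export is Cytoscape SIF (`mirna TAB regulates TAB mrna`)
plus node/edge attribute TSVs with sorted, deterministic line order;
shapes and colours (conventionally miRNA = square, up = red,
down = green) are left to a style file because only the attributes are
a testable contract.  Enrichment is the hypergeometric upper tail
P[X ≥ k] against a universe defaulting to the dataset's expressed
mRNAs, BH-adjusted across tested sets; sets below `min_set` members are
skipped.  Only over-representation is tested, and no GO-graph
conditional elimination is performed (flat test).

### Multi-dataset integration

A pair is *measured* in a dataset when both features pass expression
filtering there.  The cross-dataset pair matrix holds pairs measured in
every dataset and significant+predicted in at least one; Venn cells
partition interactions by the exact set of datasets calling them.  A
pair is *specific* to a focal dataset when called there, called
nowhere else, and measurable everywhere else — non-significance in a
dataset that could not even test the pair is not evidence of
specificity, so such pairs are excluded (with a logged count).
Pair-profile clustering is Lloyd k-means (k-means++ seeding, n_init =
10 restarts, fixed seed; k = 4 by default); reported centres are
cluster-mean correlation profiles.  Datasets are then related by
average-linkage hierarchical clustering on Euclidean distances between
their centre columns (the linkage is not dictated by the method and is
configurable in code), and by PCA computed from the correlation matrix
of dataset profiles (standardized variables), so component variances
sum to the number of datasets.

## Synthetic data: what it does and does not emulate

The generator produces log2-scale Gaussian expression — miRNAs
N(8, 1), target mRNAs `baseline + 8β − β·miRNA + N(0, noise_sd)` — with
a two-group design (fraction `de_fraction` = 0.2 of features shifted by
±`de_shift` = 1 log2 unit in cases by default), one planted regulator
per target mRNA, and databases listing each true pair with probability
`db_sensitivity` plus `db_decoy_rate` × n_true uniformly drawn decoys.
The planted within-group correlation has the closed form
ρ = −β/√(β² + noise²) (σ_miRNA = 1), so recovery tests compare against
an exact truth.  The defaults model a moderately powered two-group
bulk study; the recovery scenario (300 × 3,000 features, 30+30
samples, 500 true pairs, β = 0.75 → ρ ≈ −0.6, sensitivity 0.9, 5×
decoys) sizes the problem to ~0.9M pairs, which keeps a full run in
seconds while preserving the multiplicity structure of a real study.

It deliberately omits: count-level noise (a secondary Poisson-lognormal
generator exists only to exercise the raw-count median filter),
normalization and batch artifacts, correlated co-regulation (each
target has one regulator; miRNA competition for shared targets is not
modelled), and identifier-version drift between expression data and
databases.  Passing recovery tests therefore demonstrate the
statistical machinery under the generative assumptions, not robustness
to real-data preprocessing problems — those live upstream of this tool
(inputs are assumed normalized).

## Numerical and design choices

- Missing values are rejected at ingestion with the offending cells
  listed; silent pairwise-complete handling would let n vary per pair.
- Median-count filter boundary is strict (< threshold removed): a
  feature with median exactly 10 is kept.  Default pseudocount 1 for
  log2 of counts.
- `align_dataset` orders samples canonically (sorted ids), making the
  dataset independent of input column order.
- Log-ratios are case − control; swapping the group labels negates
  them and leaves two-sided p-values unchanged.
- p-values are floored at the smallest positive double so pval ∈ (0, 1].
- Deterministic orderings everywhere ties can arise: top interactions
  sort by (adj.pval, pval, miRNA, mRNA); exported files sort lines.
- The multiple-testing family is all computed pairs (one family per
  dataset), so summary percentages are fractions of n_miRNA × n_mRNA.
- `significant_pairs` accepts alpha ∈ (0, 1]; the comparison is strict,
  making alpha = 1 the vacuous threshold.
- The pipeline's manifest checksums cover text outputs; PNG plots are
  presentation artifacts and are excluded.  Identical configs reproduce
  byte-identical manifests.
- Database pair lists are joined by exact string id; alias/version
  resolution (e.g. between miRNA naming revisions) is the caller's
  preprocessing.  Unmatched ids surface as zero flags, not errors.
- Report problem sizes: the documentation and acceptance runs use the
  300 × 3,000 × 60 synthetic study as the reference scale — large
  enough for a realistic multiplicity burden, small enough to re-run
  interactively.

## Known limitations

- No modelling of miRNA competition or combinatorial regulation; the
  per-pair test treats pairs independently.
- Spearman/Kendall p-values are approximations (see above); exact
  enumeration appears only in tests.
- Conditional (GO-graph-aware) enrichment is not implemented.
- The moderated-t trend variant depends on the lowess smoother's
  details; cross-implementation agreement is qualitative, not
  bitwise.
- Only two-group designs are supported (no covariates or contrasts).
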