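# Methods

This note documents the statistical model behind `crosscell`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Homologous HVG selection

**Ortholog filtering.** The comparison assumes a gene bijection between the
two species. From an Ensembl-style table, only rows with homology type
`one2one` and binary orthology confidence 1 are kept (the confidence column
name is remappable). Any gene that still appears in more than one retained
row — a data inconsistency — is removed together with all its rows, rather
than keeping an arbitrary one; the downstream intersection logic relies on
the bijection being strict. The filter is idempotent.

**Standardized variance.** The per-gene variance statistic is the
variance-stabilizing ("vst") standardized variance computed on raw counts:

- fit a local polynomial regression (tricube weights, nearest-neighbour
  span 0.3, degree 2) of log10 variance on log10 mean over genes with
  positive mean and variance;
- standardize each count by the gene mean and the trend-predicted standard
  deviation, clip standardized values above at √N (N = cells);
- report Var = Σz²/(N−1); zero-variance genes score 0.

Under a null in which a gene's variance sits on the global mean–variance
trend, the statistic is ≈ 1 (the Poisson calibration test checks the median
lies in [0.9, 1.1] on 2000 × 500 Poisson data). The implementation was
cross-checked once against Seurat 5.3.0 `FindVariableFeatures(selection
.method="vst")` on a frozen 100 × 100 fixture (r = 0.9993, max |Δ| = 0.053;
residual differences come from loess windowing details) and that reference
output is kept as a regression fixture. The statistic is a plain function,
so alternative dispersion measures can be swapped in.

**Mean cutoff.** Selection is `var_std > mean(var_std over candidates)`,
strictly, where the candidate set is the ortholog bijection restricted to
genes present in the matrix. Strict inequality makes degenerate inputs safe:
an all-equal candidate set, or a single candidate, selects nothing.
Zero-variance genes stay in the candidate mean (they score 0, lowering the
cutoff); this is configurable by pre-filtering the candidate list. The
homologous-HVG set is the bijection restricted to genes selected in both
species, so its size is bounded by either species' selection.

## Cell-type correspondence

Group profiles are per-group **medians**; for a lognorm matrix the medians
are taken on the linear normalized scale (`undo_log=True`; the median
commutes with the monotone log1p, so this is a scale choice, not a different
statistic). Profiles are normalized as `log(1+x) − rowMeans(log(1+x))`,
which removes each gene's baseline and leaves its across-group pattern; a
gene expressed identically in all groups contributes a zero row. Cross-
species similarity is the Pearson correlation of centered profile columns
over the homologous-HVG pairs (at least 3 required). Constant columns yield
NaN, never an imputed 0 — a zero would masquerade as "no correlation".

The correspondence is computed on log-normalized data without any batch
integration; integration-corrected matrices can be substituted upstream if
available, but are outside this package's scope.

## Label scoring (projection stand-in)

`score_labels` assigns reference group labels to query cells by Pearson
correlation to group centroids, rectified at zero and renormalized so each
row sums to 1 (uniform when every correlation is non-positive or a cell is
constant); ties take the earliest label. Two conventions matter:

- **Centroids are means, not medians.** Median profiles of weakly expressed
  genes quantize to zero and discard most of the per-cell signal (held-out
  accuracy ~0.76 with medians vs ~0.96 with mean centroids on the same
  data); means are the natural centroid for per-cell scoring, while medians
  remain the display convention for correspondence. Use
  `group_profiles(stat="mean")` + `center_profiles` (plain row-centering,
  no second log).
- **Symmetric baseline removal.** Query expression is centered per gene by
  its mean across the query cells, mirroring the row-centering of the
  reference; correlating raw query vectors against centered centroids mixes
  baseline with pattern and costs ~10 points of accuracy.

These conventions (and the tie/negative-correlation handling) are this
package's own choices; they are deterministic and oracle-checkable, which
is why they replace anchor- or classifier-based projection.

## TF modules

TF–TF similarity is the Pearson correlation distance `d = √((1−r)/2)`,
mapping r ∈ [−1, 1] onto [0, 1]. When a pseudotime is provided, each TF's
expression is first smoothed along it (sliding-window mean over a 0.2
fraction of cells) so that r captures the shared shape of the expression
trend along the trajectory; raw per-cell correlations between
count-sampled genes are bounded well below 1 by sampling noise (for NB
counts with inverse-dispersion k, two genes driven by the same trend f(t)
satisfy r ≤ Var(f)/(Var(f)+E[f²]/k), ≈ 0.33 at k = 2 regardless of
expression level), which would make even perfectly co-regulated TFs look
dissimilar. Constant TFs get r := 0 (d = √½) with a warning so the matrix
stays clusterable. Correlations within 1e-12 of ±1 are snapped to exact
values before the square root, which otherwise amplifies float rounding
into ~1e-8 distances.

Clustering is UPGMA (size-weighted average linkage) implemented with a
deterministic lexicographic tie-break on cluster ids; scipy's average
linkage serves as an independent oracle in the tests, never as the
implementation. Merge heights are non-decreasing (ultrametric).

The tree cut is static with a minimum module size: cutting at height h
applies all merges with height ≤ h; branches of size ≥ `min_size` become
modules numbered by decreasing size, smaller branches are unassigned (id
0). `height="auto"` cuts inside the **largest gap** between consecutive
merge heights — the classic separation between within-cluster agglomeration
and the late merges joining genuinely distinct clusters. (A rule that
maximizes the number of min-size modules was considered and rejected: any
clean 30-leaf branch contains several size-≥5 sub-branches at lower
heights, so such a rule systematically over-fragments real modules.) The
cut function is pluggable; a full dynamic hybrid tree cut is out of
proportion for well-separated modules.

## Gene-set scores, trends, differential expression

**Module score.** Genes are ranked by dataset-average expression into 24
equal-frequency bins; each set gene draws 100 control genes from its bin
(with replacement when the bin is smaller) with a caller-supplied seed, and
the score is mean(set) − mean(pooled controls) per cell. The score is
invariant to global additive shifts and ≈ 0 for random sets; the null
calibration checks that the mean absolute per-set bias (|mean over cells|)
over 100 random 20-gene sets stays below 0.05. Defaults follow the
established binned-control convention; the seed is mandatory and echoed in
the returned parameters.

**Pseudotime trends.** Cells are sorted by pseudotime and smoothed with a
centered sliding-window mean over ⌈0.2·N⌉ neighbours (edges truncated).
A windowed mean preserves monotonicity and is exactly checkable; loess-like
smoothers can sit behind the same interface.

**Wilcoxon DE.** Per gene, a two-sided rank-sum test: exact null
distribution when both groups have ≤ 10 cells and the gene has no ties
across the pooled groups, otherwise the normal approximation with tie and
continuity corrections (the asymptotic path is vectorized across genes and
matches `scipy.stats.mannwhitneyu` to float precision). Fold change is
`ln((mean_A(expm1 v)+1)/(mean_B(expm1 v)+1))` — the expm1-mean ratio with
pseudocount 1 on the linear normalized scale, natural log. Adjustment is
Benjamini–Hochberg; significance is adjusted P < 1e-4. Marker signatures
take the top-k (default 20) significant upregulated genes by fold change,
ties broken by smaller adjusted P then symbol order.

## Synthetic generator

`generate_species_pair` emulates the statistical structure the method
assumes: two species sharing cell types through a one-to-one ortholog
bijection.

- Baseline log-means ~ Normal(ln 0.5, 1) per gene, shared across species.
- Counts ~ NB(mean · cell depth factor, size 2): variance μ + μ²/2, typical
  droplet-data overdispersion. Depth factors are log-normal (σ = 0.3).
- **Planted HVGs** (300 by default): one randomly chosen "high" cell type
  per gene at a 2.0-fold multiplier, shared across species with
  Normal(0, 0.1) jitter on the log effect.
- **TF modules** (two of 30): monotone log-mean trends along a per-cell
  Uniform(0,1) latent pseudotime, opposite directions per module, 4-fold
  end-to-end. TF-module genes draw their baseline from Normal(ln 2, 0.25)
  rather than the global baseline: regulator trends on near-zero counts
  carry no recoverable signal under any method, and the well-known
  trajectory regulators this emulates are robustly detected genes.
- **DE genes** (50): a 2.0-fold multiplier in the first cell type, on the
  global baseline.
- The ortholog table is the true bijection plus 50 one-to-many decoy rows
  (real genes paired with fabricated paralog symbols) and 50 low-confidence
  rows (mismatched real pairs, confidence 0), so the homology filter is
  exercised; filtering returns exactly the true bijection.
- Fixed seeds give byte-identical output (one integer RNG stream, no
  order-dependent accumulation).

These defaults are frozen as **default-v1** (`src/crosscell/data/
default-v1.yaml`): 5 types × 100 cells, 2000 genes, 300 planted HVG pairs
at 2-fold, NB size 2, two 30-TF modules, 50 DE genes at 2-fold, seed 1.
All recovery experiments run on these conditions.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, depth profiles of any particular protocol, many-to-many homology
families, or correlated gene programs beyond the planted structure. Passing
recovery tests therefore demonstrates the algorithms behave as specified on
data satisfying their assumptions, not performance on real cross-species
atlases.

## What the default conditions can and cannot support

Quantities in `results/acceptance.json` are recomputed from scratch by
`scripts/acceptance.py`; the experiment sizes (100 seeds for correspondence,
1000/200/100 cases for the oracle checks, one default-v1 run for the
recovery metrics) were chosen to finish in a couple of minutes on one CPU.

Three honest limitations of the frozen conditions, derived analytically and
confirmed by simulation, are worth stating explicitly:

- **HVG-pair recovery is partial at 2-fold.** A 2-fold effect confined to
  one of five cell types adds only ~0.16·μ² between-type variance against
  a μ + μ²/2 NB null — a ~5–15% lift in standardized variance, well inside
  the null spread. Observed pair-level recovery is ~0.50 sensitivity /
  ~0.32 precision; ≥ 0.8/0.8 would require ~6-fold planted effects. The
  conditions are kept as frozen, and the corresponding recovery test
  documents the shortfall rather than loosening the bar.
- **Type correspondence and label transfer are nevertheless robust**: null
  ortholog pairs contribute near-zero centered profile rows, so the
  correspondence argmax recovers the planted 5-type pairing in 100/100
  seeded runs, and held-out cells are assigned to their planted type with
  ~0.96 accuracy (mean centroids over the planted pairs). With the
  pipeline-derived shared HVG set (two-thirds false positives at 2-fold)
  per-cell accuracy drops to ~0.73 — per-cell noise, not the scorer, is
  the limit.
- **A 2-fold DE effect at 100 vs 100 cells cannot clear adjusted
  P < 1e-4.** Rank-sum p-values on normalized data land at ~1e-5..1e-7
  at best (per-cell normalization breaks count ties noisily, costing ~100×
  in p versus raw counts), so essentially no gene survives the 1e-4 FDR
  bar. The marker-recovery test therefore plants a clearly detectable
  4-fold effect (where ≥ 19/20 of the top-20 markers are planted across
  calibration seeds); the 2-fold regime is reported here as a limitation.
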