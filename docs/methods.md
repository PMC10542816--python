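# Methods

This note documents the generative model behind the synthetic cohorts, the
statistical procedures in each pipeline stage, the defaults and why they
were chosen, and what the validation suite does and does not establish.

## Synthetic cohorts

### Count model

Each cell draws a type from its condition's composition vector and a total
UMI depth from a log-normal distribution (default meanlog = log 1500,
sdlog = 0.45, with a per-condition scale factor so depth differs between
conditions and the downsampling stage has real work to do). Gene rates are
`baseline_mean · 2^(marker lfc) · 2^(loading · u)` where the marker term
applies to a type's marker genes and `u` is the cell's latent-axis
coordinate (below). Overdispersion enters through a per-cell, per-gene
gamma factor with mean 1 and variance α_g; the depth is then allocated
multinomially over the gamma-perturbed rates. Marginally each gene behaves
like a negative binomial with variance μ + αμ² (mean μ, dispersion α);
α = 0 degenerates to plain multinomial (Poisson-like) sampling. This
mean/dispersion parameterization was chosen to match the NB exact marker
test downstream.

A Beta-jittered fraction of each cell's depth (mean 4–5%, concentration 50)
is routed to the mitochondrial genes, so a realistic minority of cells
fails the mito QC cutoff and the filter is genuinely testable.

### Latent axis

The crypt preset carries a 1-D latent coordinate on the stem and
transit-amplifying types, `u ~ N(shift(condition), 1)`, with loadings
drawn N(0.45, 0.12) on 100 genes. This produces a PC1-like differentiation
gradient: the absolute correlation between `u` and the first principal
component of the axis genes exceeds 0.8 in validation. The old condition
shifts the coordinate by +1 SD, which the density-shift test is expected to
detect.

### Composition and planted odds ratios

For a type with baseline frequency p, an odds ratio ψ is planted by setting
the second condition's frequency to odds/(1+odds) with odds = ψ·p/(1−p).
Because frequencies must sum to one, a designated "absorber" type takes up
the slack; null types keep their baseline frequency exactly, so their true
OR is exactly 1 (this matters: renormalizing all types would leak spurious
shifts into the nulls at n = 9,000). Presets:

- `crypt10` — 10 crypt epithelial types, stem type marked by an Lgr5-like
  gene, equal composition across young/old, latent axis shifted +1 SD in
  old stem/TA cells. 1,500 cells/condition.
- `immune9` — 9 immune types; old condition enriches the ILC2-like type
  (OR 3 from baseline 5%) and the cytotoxic-T-like type (OR 5 from 3%),
  depletes the naive-T absorber (OR ≈ 0.29), leaves six types at OR 1.
  4,500 cells/condition.
- `organoid7` — 7 organoid types; treatment enriches the goblet-like type
  (OR 3), the enterocyte pool absorbs. 2,000 cells/condition.

Marker programs are 8 genes per type at log2 FC 3 with baseline means in
[2, 6] — strong enough that estimated fold changes survive the pseudocount
and clusters separate cleanly, weak enough in aggregate (< 3% of total
counts) that size factors are not distorted.

### Hashtags

Each cell's true tag follows its sample of origin. Total hashtag reads are
log-normal (median 200); a singlet puts 1 − background (default
background 2%) of its read mass on its true tag, with the background spread
uniformly over all tags. Doublets split the signal between two tags with a
uniform [0.35, 0.65] share; low-signal cells draw fewer than 10 total
reads by construction. The read-count distribution is a convention, not an
estimate — no public per-cell hashtag read statistics exist to calibrate
against — but the classification operating point (≥ 98% singlet accuracy at
2% background) is insensitive to its exact shape.

### What the generator does not emulate

Ambient RNA, batch effects, read-level errors, doublets in the *expression*
matrix (hashtag doublets only), gene–gene correlation beyond the latent
axis, and zero inflation beyond what the NB law produces. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to artifacts the model excludes.

## Pipeline stages

### Demultiplexing

Cells with < 10 hashtag reads are `low_signal` (discarded); otherwise a tag
is "present" when it carries ≥ `presence_fraction` (default 0.2) of the
cell's reads, and 1/2/3/≥4 present tags map to single/double/triple/
multiple. The presence-fraction rule is this package's explicit rendering
of a hashtag-ratio criterion; only the category names and the 10-read floor
are fixed by convention, so the fraction is a configurable parameter. A
cell above the read floor whose largest tag fraction is still below the
threshold is called `multiple` (signal spread too thin to call).

### Depth equalization

Per-sample median UMI counts are equalized by thinning every cell of an
over-sequenced sample to `round(total · target/median_sample)` molecules
drawn **without replacement** (multivariate hypergeometric) from the cell's
counts. Hypergeometric rather than binomial thinning guarantees counts
never exceed their originals and matches the read-subsampling semantics;
the per-gene marginal is exactly hypergeometric, which the test suite
verifies by a chi-square goodness-of-fit at 10,000 replicates. The default
target is the minimum per-sample median (kept as a float so the shallowest
sample is untouched exactly).

### QC

Boundary conventions, pinned in `QcThresholds` and by tests: detected genes
within [min, max] **inclusive**; total UMI **strictly** below the cap;
mito percent **strictly** below the cap. The mito criterion is interpreted
as the mitochondrial percentage of per-cell counts — the only unit under
which the conventional cutoff values (8 for immune cells, 20 for organoid
cells) are plausible. Immune defaults: genes in [200, 1500], UMI < 5000,
mito < 8%.

### Normalization

Two conventions, selected by `mode`: `scale_to_median` (each cell scaled to
the median per-cell total, then log10(1 + x) — the crypt-style convention)
and `scale_to_target` (fixed target, default 1e4, natural log — the
Seurat-style convention). The metadata (mode, target, pseudocount, log
base) travels with the matrix so downstream stages can de-log exactly.

### Variable genes

- `mvp`: dispersion = variance/mean computed on the **de-logged** normalized
  scale (where it is interpretable as an overdispersion index; the scale is
  recorded in the selection parameters so the choice is auditable). Genes
  are placed in 20 equal-frequency bins by mean; dispersion is Z-scored
  within each bin; selection keeps genes with mean in [0.0125, 2] and
  Z > 0.9. On i.i.d. nulls the selected fraction matches the normal tail
  P(Z > 0.9) ≈ 0.18.
- `vst`: lowess (span 0.3) regression of log10 variance on log10 mean
  supplies each gene's expected SD; values are standardized by observed
  mean and trend SD, clipped at √n_cells, and genes are ranked by the
  variance of the clipped standardized values (default top 2,000). The
  local fit is the conventional reading of a fitted mean–variance line
  model; span 0.3 is a fixed default.

The full-pipeline configuration also accepts `hvg_method: none` (PCA on all
genes), appropriate for compact synthetic panels where every gene is
informative and for the crypt-style workflow that does not select features.

### Dimension reduction and clustering

PCA via SVD of the centered, unit-variance-scaled matrix (R `prcomp`
convention, ddof = 1), top 20 components by default; zero-variance genes
are dropped with a warning; loadings are orthonormal and explained
variances non-increasing by construction.

k-means: Lloyd iterations, best of `n_init = 10` seeded starts, k = 9 by
default. When k-means is run with fewer clusters than there are reference
cell types, two types can share a cluster; the pipeline then splits the
best-scoring cluster for each unused reference set by re-clustering with
k2 = 2 and re-annotates — mirroring the workflow in which a merged
secretory cluster is resolved by a second k-means pass.

SNN: Euclidean kNN graph (k = 20 neighbors, excluding the query point
itself), edges weighted by the Jaccard overlap of the two cells' neighbor
sets (self included), pruned below 1/15, partitioned by greedy modularity
maximization (networkx). The algorithm is deterministic given the
embedding; the seed is recorded for provenance only. The neighbor
convention makes a fully-connected neighborhood reduce to a complete
uniform graph with a single community — the natural degenerate case.

Annotation: each cluster takes the reference marker set with the highest
mean gene-wise-Z expression over the cluster's cells; ties break to the
lexicographically first name and are flagged; the full score table is
emitted for manual review, since cluster identity assignment is ultimately
a curation step.

### Markers (NB exact test)

Size factors are per-cell totals over the median total. The pooled rate per
gene is Σx/Σs. Dispersion: method-of-moments on size-factor-normalized
counts, φ̂ = (v − μ·mean(1/s))/μ², clipped at 0, then shrunk toward the
pooled mean dispersion with weight v̂/(v̂ + τ²) where v̂ is the delta-method
sampling variance of φ̂ (≈ 2(μ + φμ²)²/(nμ⁴)) and τ² the excess between-gene
variance. The exact shrinkage weights are an implementation choice
validated through simulation: type-I error at α = 0.05 lands in
[0.035, 0.05] on NB nulls at 200 vs 200 cells (slightly conservative, as
expected for a discrete exact test).

The test conditions on the total of the two group sums. Each group sum is
treated as NB with mean A·q and variance A·q + φq²·Σs² (A = summed size
factors, Σs² over the group's cells); the two-sided p sums the joint
probabilities of all splits no more likely than the observed one — the
point-probability convention for 2×2 exact tests, which also makes the test
symmetric under swapping cluster and complement. Support windows are
truncated at the 1e-14 quantiles for tractability.

log2 fold change: `log2((1 + mean_in)/(1 + mean_out))` on size-factor-
normalized means. The pseudocount keeps zero-expressing groups finite at
the cost of attenuating fold changes of weakly expressed genes — markers
must be reasonably expressed for the estimate to approach truth, which the
preset marker design respects. Marker rule, applied literally: lfc ≥ 2 and
BH-adjusted p < 0.05, sorted by lfc then adjusted p. BH was chosen as the
adjustment because it is the field default for marker screens; note that
the step-up procedure is **not** idempotent (re-adjusting adjusted values
changes them), so only monotonicity and boundedness are asserted as
invariants.

### Gene-set scoring

Z-scaling is always computed over the **whole** scaling population (all
cells or all samples jointly), never per group — scores must be comparable
across groups, and the scaling population is recorded in the result. Bulk
reading (unit = gene): a set gene's score per group is its mean Z over the
group's units and groups are compared by the paired Wilcoxon signed-rank
test across genes — pairing by gene is the only unit shared across groups
in bulk designs. Single-cell reading (unit = cell): per-cell mean Z over
set genes, unpaired rank-sum between groups. Zero differences in the
signed-rank test are dropped (classical convention) with the count
reported; exact p by enumeration for n ≤ 20 without ties, otherwise the
normal approximation with tie and continuity corrections.

Boxplot summaries use linear-interpolation (type-7) quartiles — no
convention was fixed externally, so the numpy default is used — with
whiskers at the most extreme observations within 1.5·IQR of the quartiles.

Cross-contrast correlation: per gene set, R² of the least-squares fit of
one contrast's per-gene effects on the other's over the set's shared genes
(≥ 3 required; smaller sets are skipped with a warning); set categories are
compared by a two-sided rank-sum test on their R² distributions.

### Composition statistics

The urn: population N = m + n pooled cells, K = k type-C cells, n_draw = m
treatment cells. This is the standard 2×2 reading of a sampling-without-
replacement null for composition tables. Reported per type: both one-sided
tails P(X ≤ q), P(X ≥ q), and the two-sided point-probability p (the
2×2 exact-test convention). The odds ratio is the sample cross-product,
with the Haldane 0.5 correction applied — and flagged — iff a zero cell
exists. The CI inverts the Fisher noncentral hypergeometric tails at
α/2 per side (the convention of exact conditional test routines); it
contains the conditional MLE and is conservative, with empirical coverage
≈ 97% at a nominal 95% — coverage below nominal would be a defect,
coverage above is inherent to exact inversion. The inversion brackets the
root around ψ = 1 in log space (brentq, xtol 1e-8); `compute_ci=False`
skips it where only effect size and p are needed, since the inversion
dominates runtime on large tables. No multiple-testing correction is
applied across cell types by default; `bh_adjust` is available.

Condition orientation: the treatment condition defaults to the
later-appearing label in the cell vector (generated cohorts emit the
reference condition first) and can always be set explicitly via
`condition_pair=(treatment, control)`. Swapping conditions maps OR to
1/OR, reciprocates the CI, and leaves the two-sided p unchanged.

## Validation problem sizes

The validation and acceptance suites use: all urns N ≤ 12 for enumeration
checks; all group sizes ≤ 8 (rank-sum) and n ≤ 10 (signed-rank) for exact
rank-test enumeration, one representative per achievable statistic (the
exact p depends on the data only through the statistic when values are
distinct); 100 simulated cohorts of 9,000 cells for composition recovery;
2,000 tables (margins 200/200, k = 40) for CI coverage; 10,000 replicates
for the thinning law; 1,000-gene NB nulls at 200 vs 200 cells and 4-fold
spikes at 500 vs 500 for the marker test; 1,000 null and 100 shifted
replicates at 200 cells/group for set scoring; and 100-seed batteries for
clustering and density-shift power. The full suite runs in a few minutes
on one CPU.

## Known limitations

- The NB exact test approximates each *group sum* as a single NB
  distribution matched by mean and variance; this is exact only for equal
  size factors but is empirically well calibrated at realistic depth
  spread (lognormal sd 0.4).
- Fold-change estimates are attenuated for weakly expressed genes by the
  pseudocount; the marker rule is correspondingly conservative there.
- Greedy modularity has a resolution limit: very large, loosely connected
  communities can be split. Community counts are stable (±2 of truth) on
  the presets but should not be treated as a consistent estimator of the
  number of cell types.
- Exact conditional CIs are conservative by construction; if tighter
  intervals matter more than guaranteed coverage, a mid-p variant would be
  the place to extend.
- The hashtag read model is a convention (log-normal totals, uniform
  background); real background is tag- and batch-specific.
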