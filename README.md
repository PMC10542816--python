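# cryptshift

Single-cell UMI analysis for multi-condition cohort designs — hashtag
demultiplexing, QC, depth equalization, clustering and annotation, negative
binomial exact marker tests, gene-set Z-score enrichment, and **exact
hypergeometric differential cell-type abundance statistics** — exercised
end-to-end on synthetic cohorts with known ground truth.

## Who this is for

Analysts comparing cell-type composition and expression programs between two
conditions (young vs. old tissue, control vs. cytokine-treated organoids)
from pooled, antibody-hashtagged 10x-style experiments. The package covers
the full chain from raw UMI triplets to per-cell-type effect sizes, and
ships a first-class synthetic-data generator so every statistical claim in
the pipeline can be validated against planted truth.

## The statistics at the core

**Differential abundance.** For a cell type *C*, with *m* cells sequenced in
the treatment condition and *n* in the control, *k* cells of type *C*
overall and *q* of them in the treatment, the null of no shift makes *q*
hypergeometric — *k* type-*C* cells drawn without replacement into the
*m*-cell treatment group from the *m + n* pooled cells. The effect size is
the cross-product odds ratio of the 2×2 table [[q, m−q], [k−q, n−(k−q)]];
its 95% confidence interval inverts the exact conditional (Fisher
noncentral hypergeometric) test, and the two-sided p-value sums the
probabilities of all outcomes no more likely than the observed one. The
same urn law powers gene-set Venn-overlap tests.

**Marker genes.** Per-gene UMI counts are modeled as negative binomial with
mean μ, dispersion α (variance μ + αμ²) and per-cell size factors (total
UMI over the median total). Dispersions are estimated by the method of
moments and shrunk toward the pooled dispersion with an empirical-Bayes
weight; a cluster is tested against its complement by an exact two-sided
test on the two group sums conditional on their total. Markers are genes
with log2 fold change ≥ 2 and BH-adjusted p < 0.05.

**Signature scores.** Normalized expression is Z-scaled per gene across all
cells jointly; a gene set's score is the mean Z (per cell, compared between
groups by Wilcoxon rank-sum, or per gene, compared by the paired Wilcoxon
signed-rank test). Exact rank-test p-values are computed by enumeration at
small n.

**Hashtag demultiplexing.** Cells with < 10 hashtag reads are `low_signal`;
otherwise a tag is present when it carries ≥ 20% of the cell's hashtag
reads, and the number of present tags maps to `single` / `double` /
`triple` / `multiple`. Only singles are retained.

## Worked example

```python
import cryptshift as cs

spec = cs.make_preset("immune9")          # 9 immune types, young vs old
m, truth = cs.simulate_counts(spec, seed=1)
hashtags, truth = cs.simulate_hashtags(truth, n_tags=4, seed=2)

demux = cs.classify_hashtags(hashtags, min_reads=10, presence_fraction=0.2)
print(f"{(demux.category == 'single').sum()} of {m.n_cells} cells "
      "demultiplexed as singlets")

table = cs.tabulate_composition(truth.cell_type, truth.condition)
for cell_type in ("ilc2", "cytotoxic_t", "b_cell"):
    res = cs.abundance_shift_test(table, cell_type)
    print(f"{cell_type:12s} OR={res.odds_ratio:5.2f} "
          f"95% CI [{res.ci_low:.2f}, {res.ci_high:.2f}] "
          f"p={res.p_two_sided:.2e}")
```

prints

```
8401 of 9000 cells demultiplexed as singlets
ilc2         OR= 3.20 95% CI [2.72, 3.78] p=6.33e-51
cytotoxic_t  OR= 5.28 95% CI [4.36, 6.42] p=3.73e-86
b_cell       OR= 0.92 95% CI [0.80, 1.06] p=2.64e-01
```

The `immune9` preset plants odds ratios of 3 (ILC2-like) and 5
(cytotoxic-T-like) for the old condition and leaves six types unshifted;
the test recovers both planted effects at overwhelming significance while
the null B-cell type stays flat.

The same analysis is available from the shell:

```sh
cryptshift simulate --preset immune9 --seed 1 --out ds/
cryptshift demux ds/ --min-reads 10 --presence-fraction 0.2
cryptshift composition ds/ --level 0.95
cryptshift run --preset crypt10 --seed 1 --out run/   # full pipeline
```

## Layout

| module | contents |
| --- | --- |
| `cryptshift.synthetic_data` | presets (`crypt10`, `immune9`, `organoid7`), count/hashtag generators, ground truth |
| `cryptshift.io_pipeline` | `UmiMatrix`, MatrixMarket triplet + GMT I/O, config, full-pipeline orchestration |
| `cryptshift.demux_qc` | hashtag classification, hypergeometric downsampling, QC filters, normalization |
| `cryptshift.dimred_cluster` | mvp/vst variable genes, PCA, k-means/SNN clustering, annotation, density shifts |
| `cryptshift.markers_de` | NB exact test, Wilcoxon rank-sum, BH adjustment, marker selection |
| `cryptshift.geneset_scoring` | Z-scaling, set scores, signed-rank test, boxplot stats, effect correlations |
| `cryptshift.composition_stats` | composition tables, odds ratios, exact CIs, hypergeometric tests |

See `docs/methods.md` for the statistical models, parameter defaults, and
known limitations.
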