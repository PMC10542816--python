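import numpy as np
import pytest
from scipy import stats

from cryptshift import (
    HashtagCounts,
    QcThresholds,
    classify_hashtags,
    downsample_to_common_depth,
    filter_cells_qc,
    mito_percent,
    normalize_log,
)
from cryptshift.demux_qc import thin_cell_counts

from conftest import make_umi


def make_hashtags(rows, n_tags=3):
    rows = np.asarray(rows, dtype=np.int64)
    return HashtagCounts(
        counts=rows,
        tag_names=[f"tag{j+1}" for j in range(rows.shape[1])],
        cell_ids=[f"c{i}" for i in range(rows.shape[0])],
    )


class TestClassifyHashtags:
    @pytest.mark.parametrize(
        "row,expected_category,expected_tag",
        [
            ((9, 0, 0), "low_signal", ""),
            ((100, 0, 0), "single", "tag1"),
            ((50, 50, 0), "double", ""),
            ((10, 10, 10), "triple", ""),
            ((0, 12, 0), "single", "tag2"),
        ],
    )
    def test_category_examples(self, row, expected_category, expected_tag):
        res = classify_hashtags(make_hashtags([row]))
        assert res.category[0] == expected_category
        assert res.assigned_tag[0] == expected_tag

    def test_pure_signal_fraction_is_one(self):
        res = classify_hashtags(make_hashtags([(100, 0, 0)]))
        assert res.top_tag_fraction[0] == 1.0

    def test_four_present_tags_is_multiple(self):
        res = classify_hashtags(
            HashtagCounts(
                counts=np.array([[25, 25, 25, 25]]),
                tag_names=["a", "b", "c", "d"],
                cell_ids=["c0"],
            )
        )
        assert res.category[0] == "multiple"

    def test_partition_property(self, rng):
        counts = rng.integers(0, 60, size=(500, 4))
        res = classify_hashtags(make_hashtags(counts, n_tags=4))
        assert set(res.category) <= {
            "single",
            "double",
            "triple",
            "multiple",
            "low_signal",
        }
        # every retained (single) cell has >= min_reads hashtag reads
        singles = res.category == "single"
        assert (counts[singles].sum(axis=1) >= 10).all()
        # assigned tag defined iff single
        assert (res.assigned_tag[singles] != "").all()
        assert (res.assigned_tag[~singles] == "").all()

    def test_invalid_presence_fraction(self):
        with pytest.raises(ValueError, match="presence_fraction"):
            classify_hashtags(make_hashtags([(5, 5, 5)]), presence_fraction=0)


class TestDownsample:
    def test_target_at_median_is_identity(self):
        m = make_umi([[4, 2, 0], [1, 1, 1], [5, 0, 5]])
        med = int(np.median(m.cell_totals()))
        out = downsample_to_common_depth(m, seed=0, target=med)
        assert (out.counts != m.counts).nnz == 0

    def test_single_gene_mass_thins_exactly(self):
        # counts (4,0,0) thinned to total 2 can only be (2,0,0)
        row = np.array([4, 0, 0], dtype=np.int64)
        out = thin_cell_counts(row, 2, np.random.default_rng(0))
        np.testing.assert_array_equal(out, [2, 0, 0])

    def test_two_sample_medians_equalize(self, rng):
        counts = rng.poisson(20, size=(60, 40))
        sample = ["hi"] * 30 + ["lo"] * 30
        counts[:30] *= 2  # sample "hi" has ~double depth
        m = make_umi(counts, sample=sample)
        out = downsample_to_common_depth(m, seed=1)
        totals = out.cell_totals()
        samples = np.asarray(out.sample_label, dtype=object)
        med_lo = np.median(totals[samples == "lo"])
        med_hi = np.median(totals[samples == "hi"])
        assert abs(med_hi - med_lo) <= 1
        # untouched sample
        np.testing.assert_array_equal(
            out.counts[30:].toarray(), m.counts[30:].toarray()
        )

    def test_counts_never_increase(self, rng):
        counts = rng.poisson(5, size=(40, 25))
        counts[:20] *= 3
        m = make_umi(counts, sample=["a"] * 20 + ["b"] * 20)
        out = downsample_to_common_depth(m, seed=2)
        assert (out.counts.toarray() <= m.counts.toarray()).all()

    def test_expected_gene_totals_preserved_proportionally(self):
        # mean over replicate seeds of a gene's thinned total tracks
        # rate * original
        row = np.array([600, 300, 100], dtype=np.int64)
        rate = 0.5
        new_total = int(round(row.sum() * rate))
        sums = np.zeros(3)
        reps = 200
        for s in range(reps):
            sums += thin_cell_counts(row, new_total, np.random.default_rng(s))
        means = sums / reps
        np.testing.assert_allclose(means, rate * row, rtol=0.02)

    def test_marginal_law_is_hypergeometric(self):
        # repeated thinning of one cell: one gene's marginal follows the
        # hypergeometric(total, gene_count, new_total) law
        row = np.array([30, 70], dtype=np.int64)
        new_total = 40
        draws = np.array(
            [
                thin_cell_counts(row, new_total, np.random.default_rng(s))[0]
                for s in range(2000)
            ]
        )
        dist = stats.hypergeom(100, 30, new_total)
        support = np.arange(dist.support()[0], dist.support()[1] + 1)
        expected = dist.pmf(support) * len(draws)
        observed = np.array([(draws == k).sum() for k in support])
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2(keep.sum() - 1).sf(chi2)
        assert p > 0.01

    def test_invalid_target_rejected(self):
        m = make_umi([[4, 2, 0]])
        with pytest.raises(ValueError, match="target"):
            downsample_to_common_depth(m, seed=0, target=0)


class TestMitoPercent:
    def test_examples(self):
        mito = np.array([True, False, False])
        m = make_umi([[8, 46, 46], [0, 0, 0], [0, 5, 5]], mito_flags=mito)
        np.testing.assert_allclose(mito_percent(m), [8.0, 0.0, 0.0])

    def test_no_mito_genes_all_zero(self):
        m = make_umi([[3, 4], [5, 6]])
        np.testing.assert_array_equal(mito_percent(m), [0.0, 0.0])


class TestFilterCellsQc:
    @pytest.fixture
    def seven_cell_fixture(self):
        """Hand-built 7-cell matrix; exactly cells 0, 1, 2 pass QC.

        Thresholds: genes detected in [2, 4] inclusive, UMI < 50 strict,
        mito < 8% strict.  mito gene is column 0.
        """
        counts = np.array(
            [
                [1, 20, 10, 0, 0, 0],   # 3 genes, 31 UMI, 3.2% mito -> pass
                [0, 10, 10, 10, 10, 0], # 4 genes, 40 UMI, 0% mito   -> pass
                [1, 30, 0, 0, 0, 0],    # 2 genes, 31 UMI, 3.2%     -> pass
                [0, 49, 0, 0, 0, 0],    # 1 gene: too few genes
                [0, 1, 1, 1, 1, 1],     # 5 genes: too many genes
                [0, 25, 25, 0, 0, 0],   # 50 UMI: at the strict bound
                [4, 20, 20, 0, 0, 0],   # 9.1% mito
            ]
        )
        mito = np.array([True, False, False, False, False, False])
        th = QcThresholds(min_genes=2, max_genes=4, max_umi=50, max_mito_pct=8)
        return make_umi(counts, mito_flags=mito), th

    def test_exactly_designed_cells_pass(self, seven_cell_fixture):
        m, th = seven_cell_fixture
        out, report = filter_cells_qc(m, th, return_report=True)
        assert list(out.cell_ids) == ["c0", "c1", "c2"]
        assert report["kept"] == 3
        assert report["removed_gene_count"] == 2
        assert report["removed_umi"] == 1
        assert report["removed_mito"] == 1

    def test_gene_bounds_inclusive_umi_strict(self):
        # 200 detected genes kept (inclusive); UMI == max removed (strict)
        n_genes = 250
        row_ok = np.zeros(n_genes, dtype=np.int64)
        row_ok[:200] = 1
        row_umi = np.zeros(n_genes, dtype=np.int64)
        row_umi[:100] = 50  # 5000 total
        m = make_umi(np.vstack([row_ok, row_umi]))
        th = QcThresholds(min_genes=200, max_genes=1500, max_umi=5000,
                          max_mito_pct=8)
        out = filter_cells_qc(m, th)
        assert list(out.cell_ids) == ["c0"]

    def test_idempotent(self, seven_cell_fixture):
        m, th = seven_cell_fixture
        once = filter_cells_qc(m, th)
        twice = filter_cells_qc(once, th)
        assert list(twice.cell_ids) == list(once.cell_ids)
        assert (twice.counts != once.counts).nnz == 0

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QcThresholds(min_genes=10, max_genes=5)


class TestNormalizeLog:
    def test_equal_totals_zero_maps_to_zero(self):
        m = make_umi([[2, 0], [0, 2]])
        nm = normalize_log(m)
        assert nm.values[0, 1] == 0.0
        assert nm.metadata["log_base"] == "10"

    def test_scaling_to_median_equalizes_totals(self):
        m = make_umi([[100, 0], [0, 200]])
        nm = normalize_log(m, pseudocount=1)
        # invert the log to recover scaled totals
        scaled = 10 ** nm.values - 1
        np.testing.assert_allclose(scaled.sum(axis=1), [150, 150])

    def test_scale_to_target_arithmetic(self):
        # count 1 in a cell of total 10,000 at target 10,000 -> log10(2)
        row = np.zeros(50, dtype=np.int64)
        row[0] = 1
        row[1] = 9999
        m = make_umi([row])
        nm = normalize_log(m, mode="scale_to_target", target=10000)
        assert nm.values[0, 0] == pytest.approx(np.log10(2), abs=1e-12)

    def test_zero_pseudocount_with_zeros_rejected(self):
        m = make_umi([[1, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_log(m, pseudocount=0)

    def test_zero_total_cell_maps_to_log_pseudocount(self):
        m = make_umi([[4, 4], [0, 0]])
        nm = normalize_log(m, pseudocount=1)
        np.testing.assert_array_equal(nm.values[1], [0.0, 0.0])
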