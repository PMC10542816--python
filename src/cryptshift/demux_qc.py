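"""Hashtag demultiplexing, depth equalization, QC filtering, normalization.

Cell hashing labels each cell with an oligo-tagged antibody identifying its
sample of origin; demultiplexing reads the per-cell tag count vector back
into a sample assignment.  Cells are sorted into the categories ``single`` /
``double`` / ``triple`` / ``multiple`` by how many tags carry an appreciable
fraction of the cell's hashtag reads, and cells with fewer than 10 hashtag
reads in total are set aside as ``low_signal``.  Only ``single`` cells are
retained downstream.

Depth equalization thins every cell of an over-sequenced sample by a
without-replacement (hypergeometric) draw so that per-sample median UMI
counts match a common target, after which per-cell totals are scaled and
log-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_pipeline import UmiMatrix

CATEGORIES = ("single", "double", "triple", "multiple", "low_signal")


@dataclass
class HashtagCounts:
    """Cells x tags non-negative integer hashtag read counts."""

    counts: np.ndarray
    tag_names: list[str]
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x tags)")
        if self.counts.shape[1] != len(self.tag_names):
            raise ValueError("tag_names length mismatch")
        if self.counts.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative hashtag counts")
        if len(self.tag_names) < 1:
            raise ValueError("need at least one tag")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.tag_names)
        df.insert(0, "cell_id", np.asarray(self.cell_ids, dtype=str))
        return df


@dataclass
class DemuxResult:
    """Per-cell hashtag category with the assigned tag for singles."""

    category: np.ndarray  # str per cell, one of CATEGORIES
    assigned_tag: np.ndarray  # str per cell; "" unless category == "single"
    top_tag_fraction: np.ndarray  # float in [0, 1]
    cell_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.asarray(self.cell_ids, dtype=str),
                "category": self.category,
                "assigned_tag": self.assigned_tag,
                "top_tag_fraction": self.top_tag_fraction,
            }
        )


@dataclass
class QcThresholds:
    """Cell-level QC cutoffs with their boundary conventions pinned.

    ``min_genes``/``max_genes`` bound the number of detected genes
    inclusively ("between" read as closed interval); ``max_umi`` and
    ``max_mito_pct`` are strict upper bounds.
    """

    min_genes: int = 200
    max_genes: int = 1500
    max_umi: int = 5000
    max_mito_pct: float = 8.0
    # boundary conventions, recorded so tests can pin them
    gene_bounds_inclusive: bool = field(default=True, init=False)
    umi_bound_strict: bool = field(default=True, init=False)
    mito_bound_strict: bool = field(default=True, init=False)

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes > max_genes")
        if min(self.min_genes, self.max_genes, self.max_umi) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.max_mito_pct < 0:
            raise ValueError("max_mito_pct must be >= 0")


@dataclass
class NormalizedMatrix:
    """Cells x genes real-valued normalized expression.

    ``values`` is dense float (normalization destroys sparsity of zeros only
    when pseudocount-logged values of zero counts are nonzero; with the
    default pseudocount 1 zeros stay zero, but the dense contract keeps the
    downstream linear algebra simple).  ``metadata`` records the target
    scale, pseudocount, and log base so the provenance of every value is
    auditable.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    metadata: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized matrix has non-finite entries")
        for key in ("mode", "log_base", "pseudocount", "target"):
            if key not in self.metadata:
                raise ValueError(f"normalization metadata missing {key!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def classify_hashtags(
    h: HashtagCounts, min_reads: int = 10, presence_fraction: float = 0.2
) -> DemuxResult:
    """Sort cells into hashtag categories by the per-cell tag read profile.

    A cell with total hashtag reads below ``min_reads`` is ``low_signal``.
    Otherwise a tag is "present" when it carries at least
    ``presence_fraction`` of the cell's hashtag reads; the number of present
    tags maps to single (1) / double (2) / triple (3) / multiple (>= 4).
    Only singles receive an assigned tag.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    if h.counts.shape[0] == 0:
        raise ValueError("empty hashtag table")
    totals = h.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(
            totals[:, None] > 0, h.counts / np.maximum(totals, 1)[:, None], 0.0
        )
    top_frac = fractions.max(axis=1)
    n_present = (fractions >= presence_fraction).sum(axis=1)

    category = np.empty(len(totals), dtype=object)
    assigned = np.full(len(totals), "", dtype=object)
    low = totals < min_reads
    category[low] = "low_signal"
    for n, name in ((1, "single"), (2, "double"), (3, "triple")):
        category[~low & (n_present == n)] = name
    category[~low & (n_present >= 4)] = "multiple"
    # >= min_reads but no tag reaching the presence fraction: treat as
    # multiple (signal spread too thin to call)
    category[~low & (n_present == 0)] = "multiple"

    singles = ~low & (n_present == 1)
    tag_names = np.asarray(h.tag_names, dtype=object)
    assigned[singles] = tag_names[np.argmax(fractions[singles], axis=1)]
    return DemuxResult(
        category=category,
        assigned_tag=assigned,
        top_tag_fraction=top_frac,
        cell_ids=h.cell_ids,
    )


# ---------------------------------------------------------------------------
# Depth equalization
# ---------------------------------------------------------------------------


def thin_cell_counts(
    row: np.ndarray, new_total: int, rng: np.random.Generator
) -> np.ndarray:
    """Hypergeometric (without replacement) thinning of one cell's counts."""
    total = int(row.sum())
    if new_total >= total:
        return row.copy()
    if new_total <= 0:
        return np.zeros_like(row)
    return rng.multivariate_hypergeometric(row.astype(np.int64), new_total)


def downsample_to_common_depth(
    m: UmiMatrix, seed: int, target: int | None = None
) -> UmiMatrix:
    """Equalize per-sample median UMI by thinning cells without replacement.

    Each sample whose median per-cell total exceeds ``target`` (default: the
    minimum over samples of the median per-cell UMI) has every cell thinned
    to ``round(total * target / median_sample)`` UMIs drawn hypergeometrically
    from the cell's molecules, so counts never increase and samples already
    at or below target are untouched.
    """
    samples = np.asarray(m.sample_label, dtype=object)
    totals = m.cell_totals()
    uniq = sorted(set(samples))
    if not uniq:
        return m.copy()
    medians = {s: float(np.median(totals[samples == s])) for s in uniq}
    if target is None:
        # keep the minimum-median sample exactly untouched (medians can be
        # half-integers)
        target = float(min(medians.values()))
    if target <= 0:
        raise ValueError("target must be positive")
    min_median = min(medians.values())
    if target > min_median:
        raise ValueError(
            f"target {target} exceeds minimum per-sample median {min_median}"
        )
    rng = np.random.default_rng(seed)
    new_counts = m.counts.tolil(copy=True)
    csr = m.counts.tocsr()
    for s in uniq:
        med = medians[s]
        if med <= target:
            continue
        rate = target / med
        for i in np.flatnonzero(samples == s):
            start, end = csr.indptr[i], csr.indptr[i + 1]
            row_data = csr.data[start:end]
            row_idx = csr.indices[start:end]
            total = int(row_data.sum())
            new_total = int(round(total * rate))
            thinned = thin_cell_counts(row_data.astype(np.int64), new_total, rng)
            new_counts.rows[i] = row_idx[thinned > 0].tolist()
            new_counts.data[i] = thinned[thinned > 0].tolist()
    return UmiMatrix(
        counts=new_counts.tocsr(),
        cell_ids=m.cell_ids.copy(),
        gene_ids=m.gene_ids.copy(),
        mito_flags=m.mito_flags.copy(),
        sample_label=m.sample_label.copy(),
        condition_label=m.condition_label.copy(),
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def mito_percent(m: UmiMatrix) -> np.ndarray:
    """Percent of each cell's UMIs falling on mitochondrial genes.

    Cells with zero total counts report 0.
    """
    totals = m.cell_totals().astype(float)
    if not m.mito_flags.any():
        return np.zeros(m.n_cells)
    mito_totals = np.asarray(
        m.counts[:, np.flatnonzero(m.mito_flags)].sum(axis=1)
    ).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_totals / np.maximum(totals, 1e-300), 0.0)
    return pct


def filter_cells_qc(
    m: UmiMatrix, th: QcThresholds, return_report: bool = False
):
    """Keep cells passing all QC criteria; genes are untouched.

    Criteria (conventions pinned in :class:`QcThresholds`):
    ``min_genes <= detected <= max_genes`` (inclusive), total UMI strictly
    below ``max_umi``, mito percent strictly below ``max_mito_pct``.
    """
    detected = m.genes_detected()
    totals = m.cell_totals()
    mito = mito_percent(m)
    pass_genes = (detected >= th.min_genes) & (detected <= th.max_genes)
    pass_umi = totals < th.max_umi
    pass_mito = mito < th.max_mito_pct
    keep = pass_genes & pass_umi & pass_mito
    report = {
        "removed_gene_count": int((~pass_genes).sum()),
        "removed_umi": int((~pass_umi).sum()),
        "removed_mito": int((~pass_mito).sum()),
        "removed_total": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    out = m.subset_cells(keep)
    if return_report:
        return out, report
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_log(
    m: UmiMatrix,
    mode: str = "scale_to_median",
    log_base: str = "10",
    pseudocount: float = 1.0,
    target: float | None = None,
) -> NormalizedMatrix:
    """Scale each cell's counts to a common total, then log-transform.

    ``mode='scale_to_median'`` scales every cell so its total equals the
    median of per-cell totals (the crypt-style convention, paired with
    log10); ``mode='scale_to_target'`` scales to a fixed ``target`` (the
    Seurat-style convention, typically 1e4 with natural log).  Zero-total
    cells map to a constant row of log(pseudocount).
    """
    if mode not in ("scale_to_median", "scale_to_target"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if str(log_base) not in ("10", "e"):
        raise ValueError("log_base must be '10' or 'e'")
    totals = m.cell_totals().astype(float)
    if not (totals > 0).any():
        raise ValueError("no cell with nonzero total")
    if mode == "scale_to_median":
        target_val = float(np.median(totals[totals > 0])) if target is None else float(target)
    else:
        if target is None:
            target_val = 1e4
        else:
            target_val = float(target)
    dense = np.asarray(m.counts.todense(), dtype=float)
    if pseudocount == 0 and (dense == 0).any():
        raise ValueError("pseudocount 0 with zero counts present (log of zero)")
    factors = np.where(totals > 0, target_val / np.maximum(totals, 1e-300), 0.0)
    scaled = dense * factors[:, None]
    logfun = np.log10 if str(log_base) == "10" else np.log
    values = logfun(pseudocount + scaled)
    meta = {
        "mode": mode,
        "log_base": str(log_base),
        "pseudocount": float(pseudocount),
        "target": target_val,
    }
    return NormalizedMatrix(
        values=values,
        cell_ids=m.cell_ids.copy(),
        gene_ids=m.gene_ids.copy(),
        metadata=meta,
    )
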