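"""Gene-set Z-score enrichment, rank tests, boxplot summaries, correlations.

The signature-scoring convention: normalized expression is Z-scaled per gene
across ALL units (samples or cells) jointly, never per group — the scaling
population is recorded in the result so this is auditable.  A gene set's
score is then the mean Z, either per gene within a group of units (bulk
reading: one paired observation per gene, compared by Wilcoxon signed-rank)
or per cell over the set's genes (single-cell reading: unpaired cells,
compared by Wilcoxon rank-sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_pipeline import GeneSetCollection
from .markers_de import wilcoxon_rank_sum


@dataclass
class ZMatrix:
    """Units x genes matrix of per-gene Z scores.

    ``center``/``scale`` record the per-gene statistics of the scaling
    population; ``zero_variance`` flags genes mapped to all-zero.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    unit_ids: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray
    scaling_population: str = "all_units"

    def __post_init__(self) -> None:
        ok = ~self.zero_variance
        if ok.any() and self.values.shape[0] > 1:
            col_mean = self.values[:, ok].mean(axis=0)
            col_sd = self.values[:, ok].std(axis=0, ddof=1)
            if np.abs(col_mean).max() > 1e-8 or np.abs(col_sd - 1).max() > 1e-8:
                raise ValueError("Z matrix columns are not standardized")


@dataclass
class EnrichmentResult:
    """Scores and test outcome for one gene set."""

    set_name: str
    unit: str  # 'gene', 'sample', or 'cell'
    scores: dict[str, np.ndarray]  # group -> per-unit scores
    group_means: dict[str, float]
    test: str  # 'wilcoxon_paired' or 'wilcoxon_unpaired'
    statistic: float
    p_value: float
    n_genes_used: int = 0
    n_genes_missing: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        for g, s in self.scores.items():
            if len(s) == 0:
                raise ValueError(f"group {g!r} is empty")


@dataclass
class SetCorrelation:
    """Cross-contrast agreement of per-gene effects within one set."""

    set_name: str
    n_genes: int
    r_squared: float
    category: str = ""
    effects_a: np.ndarray = field(default_factory=lambda: np.array([]))
    effects_b: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")
        if self.n_genes < 3:
            raise ValueError("set correlation needs >= 3 genes")


@dataclass
class BoxplotStats:
    """Quartiles, whiskers at the extreme points within 1.5*IQR, outliers."""

    q1: float
    q2: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartiles out of order")


# ---------------------------------------------------------------------------
# Z-scaling
# ---------------------------------------------------------------------------


def zscale(
    values: np.ndarray,
    gene_ids=None,
    unit_ids=None,
) -> ZMatrix:
    """Center and unit-variance scale each gene across all units (ddof=1).

    Zero-variance genes map to all-zero columns and are flagged.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 units")
    n_units, n_genes = values.shape
    gene_ids = (
        np.asarray(gene_ids, dtype=object)
        if gene_ids is not None
        else np.array([f"g{j}" for j in range(n_genes)], dtype=object)
    )
    unit_ids = (
        np.asarray(unit_ids, dtype=object)
        if unit_ids is not None
        else np.array([f"u{i}" for i in range(n_units)], dtype=object)
    )
    center = values.mean(axis=0)
    scale = values.std(axis=0, ddof=1)
    zero_var = scale == 0
    safe = np.where(zero_var, 1.0, scale)
    z = (values - center[None, :]) / safe[None, :]
    z[:, zero_var] = 0.0
    return ZMatrix(
        values=z,
        gene_ids=gene_ids,
        unit_ids=unit_ids,
        center=center,
        scale=scale,
        zero_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# Set scoring
# ---------------------------------------------------------------------------


def score_set(
    z: ZMatrix,
    set_genes: list[str],
    unit: str,
    groups: dict[str, np.ndarray],
    set_name: str = "",
) -> EnrichmentResult:
    """Mean-Z enrichment of one gene set between two groups of units.

    ``unit='gene'``: the score of each set gene is its mean Z over a group's
    units; the two groups are compared by a paired (per-gene) Wilcoxon
    signed-rank test.  ``unit='cell'``: each unit's score is its mean Z over
    the set genes; groups are compared by an unpaired Wilcoxon rank-sum
    test.  Set genes absent from the matrix are ignored (counted).
    """
    if unit not in ("gene", "cell", "sample"):
        raise ValueError(f"unknown unit {unit!r}")
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    pos = {g: j for j, g in enumerate(z.gene_ids)}
    cols = sorted(pos[g] for g in set(set_genes) if g in pos)
    missing = len(set(set_genes)) - len(cols)
    if len(cols) < 3:
        raise ValueError(
            f"only {len(cols)} set genes present in the matrix (need >= 3)"
        )
    names = sorted(groups)
    masks = {g: np.asarray(groups[g], dtype=bool) for g in names}
    for g, mask in masks.items():
        if not mask.any():
            raise ValueError(f"group {g!r} is empty")

    if unit == "gene":
        scores = {
            g: z.values[np.ix_(masks[g], cols)].mean(axis=0) for g in names
        }
        diffs = scores[names[1]] - scores[names[0]]
        statistic, p = wilcoxon_signed_rank(diffs)
        test = "wilcoxon_paired"
    else:
        scores = {
            g: z.values[np.ix_(masks[g], cols)].mean(axis=1) for g in names
        }
        statistic, p = wilcoxon_rank_sum(scores[names[0]], scores[names[1]])
        test = "wilcoxon_unpaired"
    return EnrichmentResult(
        set_name=set_name,
        unit=unit,
        scores=scores,
        group_means={g: float(s.mean()) for g, s in scores.items()},
        test=test,
        statistic=float(statistic),
        p_value=float(p),
        n_genes_used=len(cols),
        n_genes_missing=missing,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(differences, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classical convention; the count is
    reported via a warning).  Exact p by enumeration of sign assignments
    for n <= 20 without tied magnitudes; otherwise the normal approximation
    with tie and continuity corrections.  All-zero input returns p = 1 with
    a warning rather than erroring.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    nonzero = d[d != 0]
    n_zero = d.size - nonzero.size
    if n_zero:
        warnings.warn(f"dropped {n_zero} zero differences")
    if nonzero.size == 0:
        warnings.warn("all differences are zero; p = 1")
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if mode == "auto":
        mode = "exact" if (nonzero.size <= 20 and not has_ties) else "normal-approx"
    if mode == "exact" and has_ties:
        mode = "normal-approx"
    method = "exact" if mode == "exact" else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", method=method, correction=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Boxplot summary
# ---------------------------------------------------------------------------


def boxplot_stats(values) -> BoxplotStats:
    """Quartiles (linear-interpolation convention) and 1.5*IQR whiskers.

    Whiskers sit at the most extreme observed points within 1.5*IQR of the
    quartiles; everything outside is an outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisk_lo = float(inside.min()) if inside.size else float(q1)
    whisk_hi = float(inside.max()) if inside.size else float(q3)
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        whisker_low=whisk_lo,
        whisker_high=whisk_hi,
        outliers=np.sort(outliers),
    )


# ---------------------------------------------------------------------------
# Cross-contrast fold-change correlation
# ---------------------------------------------------------------------------


def foldchange_correlation(
    eff_a: dict[str, float],
    eff_b: dict[str, float],
    sets: GeneSetCollection,
) -> list[SetCorrelation]:
    """Per-set R^2 between two per-gene effect vectors (e.g. two contrasts).

    For each set, the coefficient of determination of the least-squares fit
    of ``eff_b`` on ``eff_a`` over the set's genes present in both vectors.
    Sets with fewer than 3 shared genes are skipped with a warning.
    """
    shared_ns = set(eff_a) & set(eff_b)
    if not shared_ns:
        raise ValueError("effect vectors have disjoint gene namespaces")
    out: list[SetCorrelation] = []
    for name in sets.names():
        genes = [g for g in sets[name] if g in shared_ns]
        if len(genes) < 3:
            warnings.warn(f"set {name!r}: only {len(genes)} shared genes; skipped")
            continue
        a = np.array([eff_a[g] for g in genes], dtype=float)
        b = np.array([eff_b[g] for g in genes], dtype=float)
        if np.std(a) == 0 or np.std(b) == 0:
            r2 = 0.0
        else:
            r2 = float(stats.linregress(a, b).rvalue ** 2)
        out.append(
            SetCorrelation(
                set_name=name,
                n_genes=len(genes),
                r_squared=min(r2, 1.0),
                category=sets.categories.get(name, ""),
                effects_a=a,
                effects_b=b,
            )
        )
    return out


def compare_category_r2(
    correlations: list[SetCorrelation], category_a: str, category_b: str
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of R^2 between two set categories."""
    ra = [c.r_squared for c in correlations if c.category == category_a]
    rb = [c.r_squared for c in correlations if c.category == category_b]
    if not ra or not rb:
        raise ValueError("both categories need at least one set")
    return wilcoxon_rank_sum(ra, rb)
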