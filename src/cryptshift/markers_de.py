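"""Cluster-specific marker tests: NB exact (sseq-style) and Wilcoxon.

The sseq-style test models per-gene UMI counts as negative binomial with
per-cell size factors (total UMI over the median total).  The per-gene
dispersion is estimated by the method of moments and shrunk toward the
pooled dispersion with an empirical-Bayes weight derived from the sampling
variance of the per-gene estimates.  Differential expression of a cluster
against its complement is then an exact two-sided test on the two group
sums conditional on their total: the p-value sums the probabilities of all
splits no more likely than the observed one under the null NB laws of the
group sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dimred_cluster import ClusterAssignment
from .io_pipeline import UmiMatrix


@dataclass
class MarkerRow:
    """One gene x cluster differential-expression record."""

    gene: str
    cluster: int
    log2_fc: float
    mean_in: float
    mean_out: float
    p_value: float
    adj_p_value: float
    test: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if not np.isfinite(self.log2_fc):
            raise ValueError("log2 fold change must be finite")


def rows_to_frame(rows: list[MarkerRow]) -> pd.DataFrame:
    cols = [
        "gene",
        "cluster",
        "log2_fc",
        "mean_in",
        "mean_out",
        "p_value",
        "adj_p_value",
        "test",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.__dict__ for r in rows])[cols]


# ---------------------------------------------------------------------------
# sseq-style NB exact test
# ---------------------------------------------------------------------------


def _nb_dist(mean: float, var: float):
    """A frozen count distribution with the given mean/variance.

    NB when var > mean, else Poisson (the NB boundary case).
    """
    if var > mean > 0:
        r = mean * mean / (var - mean)
        p = r / (r + mean)
        return stats.nbinom(r, p)
    return stats.poisson(max(mean, 1e-300))


def estimate_sseq_params(
    counts_in: np.ndarray,
    counts_out: np.ndarray,
    size_in: np.ndarray,
    size_out: np.ndarray,
) -> dict:
    """Pooled NB rate and shrunken dispersion per gene.

    ``counts_*`` are cells x genes dense arrays for the two groups;
    ``size_*`` their per-cell size factors.  Dispersion is the method-of-
    moments estimate on size-factor-normalized counts, shrunk toward the
    pooled mean dispersion with weight ``v / (v + tau2)`` where ``v`` is the
    delta-method sampling variance of each gene's estimate and ``tau2`` the
    excess between-gene variance.
    """
    x = np.vstack([counts_in, counts_out]).astype(float)
    s = np.concatenate([size_in, size_out]).astype(float)
    n = len(s)
    y = x / s[:, None]
    mu = y.mean(axis=0)
    var = y.var(axis=0, ddof=1)
    inv_s_mean = float(np.mean(1.0 / s))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_mm = np.where(
            mu > 0, (var - mu * inv_s_mean) / np.maximum(mu, 1e-300) ** 2, 0.0
        )
    phi_mm = np.clip(phi_mm, 0.0, None)
    # delta-method sampling variance of the MoM dispersion estimator
    with np.errstate(invalid="ignore", divide="ignore"):
        v_hat = np.where(
            mu > 0,
            2.0 * (mu + phi_mm * mu**2) ** 2 / (n * np.maximum(mu, 1e-300) ** 4),
            np.inf,
        )
    zeta = float(phi_mm[np.isfinite(v_hat)].mean()) if np.isfinite(v_hat).any() else 0.0
    finite = np.isfinite(v_hat)
    between = float(phi_mm[finite].var()) if finite.sum() > 1 else 0.0
    tau2 = max(between - float(v_hat[finite].mean()) if finite.any() else 0.0, 1e-12)
    w = np.ones_like(phi_mm)
    w[finite] = v_hat[finite] / (v_hat[finite] + tau2)
    phi = w * zeta + (1.0 - w) * phi_mm
    # pooled rate per gene (size-factor weighted)
    q = x.sum(axis=0) / s.sum()
    return {"q": q, "phi": phi, "phi_mm": phi_mm, "zeta": zeta, "weight": w}


def _exact_split_pvalue(dist_a, dist_b, s_a: int, total: int) -> float:
    """Two-sided exact p for the split (s_a, total - s_a) of group sums.

    Conditional on the total, sums the joint probabilities of all splits no
    more likely than the observed one (point-probability two-sided rule).
    """
    # restrict to a window carrying all but ~1e-12 of conditional mass
    lo_a = int(dist_a.ppf(1e-14))
    hi_a = int(dist_a.ppf(1 - 1e-14))
    lo_b = int(dist_b.ppf(1e-14))
    hi_b = int(dist_b.ppf(1 - 1e-14))
    lo = max(0, lo_a, total - hi_b)
    hi = min(total, hi_a, total - lo_b)
    lo = min(lo, s_a)
    hi = max(hi, s_a)
    k = np.arange(lo, hi + 1)
    log_joint = dist_a.logpmf(k) + dist_b.logpmf(total - k)
    obs = dist_a.logpmf(s_a) + dist_b.logpmf(total - s_a)
    finite = np.isfinite(log_joint)
    if not finite.any() or not np.isfinite(obs):
        return 1.0
    log_joint = log_joint[finite]
    m = log_joint.max()
    probs = np.exp(log_joint - m)
    denom = probs.sum()
    num = probs[log_joint <= obs + 1e-7].sum()
    return float(min(1.0, num / denom))


def sseq_exact_test(
    m: UmiMatrix,
    assign: ClusterAssignment,
    cluster_id: int,
    min_mean: float = 0.1,
) -> list[MarkerRow]:
    """NB exact test of one cluster against all other cells.

    Genes with overall size-factor-normalized mean below ``min_mean`` are
    excluded.  The log2 fold change compares size-factor-normalized group
    means with pseudocount 1.  P-values are not yet multiplicity-adjusted;
    pass the result through :func:`bh_adjust` / :func:`select_markers`.
    """
    in_mask = assign.labels == cluster_id
    if not in_mask.any() or in_mask.all():
        raise ValueError("cluster and complement must both be non-empty")
    if in_mask.sum() < 2:
        raise ValueError("cluster must have at least 2 cells")
    totals = m.cell_totals().astype(float)
    if (totals <= 0).any():
        raise ValueError("all cells must have nonzero totals for size factors")
    size = totals / np.median(totals)
    x = np.asarray(m.counts.todense(), dtype=np.int64)
    gene_ids = np.asarray(m.gene_ids, dtype=object)

    params = estimate_sseq_params(
        x[in_mask], x[~in_mask], size[in_mask], size[~in_mask]
    )
    q, phi = params["q"], params["phi"]
    keep = q >= min_mean

    s_in = float(size[in_mask].sum())
    s_out = float(size[~in_mask].sum())
    ss_in = float((size[in_mask] ** 2).sum())
    ss_out = float((size[~in_mask] ** 2).sum())

    rows: list[MarkerRow] = []
    pvals = []
    for j in np.flatnonzero(keep):
        qj, phij = float(q[j]), float(phi[j])
        sum_in = int(x[in_mask, j].sum())
        sum_out = int(x[~in_mask, j].sum())
        mean_a = s_in * qj
        var_a = mean_a + phij * qj * qj * ss_in
        mean_b = s_out * qj
        var_b = mean_b + phij * qj * qj * ss_out
        p = _exact_split_pvalue(
            _nb_dist(mean_a, var_a), _nb_dist(mean_b, var_b), sum_in,
            sum_in + sum_out,
        )
        mean_in_norm = sum_in / s_in
        mean_out_norm = sum_out / s_out
        lfc = float(np.log2((1.0 + mean_in_norm) / (1.0 + mean_out_norm)))
        rows.append(
            MarkerRow(
                gene=str(gene_ids[j]),
                cluster=int(cluster_id),
                log2_fc=lfc,
                mean_in=float(mean_in_norm),
                mean_out=float(mean_out_norm),
                p_value=p,
                adj_p_value=1.0,
                test="sseq",
            )
        )
        pvals.append(p)
    adj = bh_adjust(pvals) if pvals else []
    for r, a in zip(rows, adj):
        r.adj_p_value = float(a)
    return rows


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x, y, mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test with midranks for ties.

    ``mode='exact'`` enumerates the null distribution (valid without ties);
    ``mode='normal-approx'`` uses the normal approximation with tie and
    continuity corrections; ``mode='auto'`` picks exact when
    ``len(x) + len(y) <= 16`` and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (len(x) + len(y) <= 16 and not has_ties) else "normal-approx"
    if mode == "exact" and has_ties:
        mode = "normal-approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Multiplicity adjustment and marker selection
# ---------------------------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_markers(
    rows: list[MarkerRow], lfc_min: float = 2.0, alpha: float = 0.05
) -> list[MarkerRow]:
    """Keep rows with log2 FC >= ``lfc_min`` and adjusted p < ``alpha``.

    Sorted by log2 FC descending, then adjusted p ascending.
    """
    kept = [r for r in rows if r.log2_fc >= lfc_min and r.adj_p_value < alpha]
    return sorted(kept, key=lambda r: (-r.log2_fc, r.adj_p_value))
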