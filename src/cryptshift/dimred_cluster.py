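"""Variable-gene selection, PCA, clustering, annotation, density shifts.

Two highly-variable-gene selectors are provided.  ``mvp`` computes per-gene
dispersion (variance/mean) on the normalized (not log-transformed) scale,
bins genes into equal-frequency bins by mean expression, Z-scores dispersion
within each bin, and keeps genes inside a mean window whose dispersion Z
exceeds a cutoff.  ``vst`` fits a smooth trend of log10 variance on log10
mean, standardizes each gene's values by its observed mean and trend SD with
clipping, and ranks genes by the variance of the standardized values.

Clustering is either Lloyd k-means (best of ``n_init`` seeded starts) or a
shared-nearest-neighbor graph (Jaccard edge weights over kNN neighbor sets,
weak edges pruned) partitioned by greedy modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
import statsmodels.api as sm

from .demux_qc import NormalizedMatrix
from .io_pipeline import GeneSetCollection


@dataclass
class FeatureSelection:
    """Per-gene variability statistics and the selected gene ids."""

    gene_ids: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray  # mvp: var/mean; vst: variance of standardized
    dispersion_z: np.ndarray  # mvp within-bin Z; vst: standardized variance
    selected: list[str]
    method: str
    params: dict

    def __post_init__(self) -> None:
        missing = set(self.selected) - set(self.gene_ids)
        if missing:
            raise ValueError(f"selected genes outside namespace: {sorted(missing)}")


@dataclass
class Embedding:
    """PCA scores/loadings with explained variances."""

    scores: np.ndarray  # cells x components
    loadings: np.ndarray  # genes x components, orthonormal columns
    explained_variance: np.ndarray  # non-increasing
    gene_ids: np.ndarray
    centered: bool
    scaled: bool

    def __post_init__(self) -> None:
        ev = self.explained_variance
        if np.any(np.diff(ev) > 1e-8):
            raise ValueError("explained variances must be non-increasing")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings are not orthonormal")


@dataclass
class ClusterAssignment:
    """Per-cell integer labels in [1, k] with an optional annotation map."""

    labels: np.ndarray
    k: int
    method: str
    seed: int
    annotation: dict[int, str] = field(default_factory=dict)
    annotation_scores: dict | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.size:
            if labels.min() < 1 or labels.max() > self.k:
                raise ValueError("labels must lie in [1, k]")
            present = np.unique(labels)
            if len(present) != self.k:
                raise ValueError("every cluster must be non-empty")
        self.labels = labels


@dataclass
class DensityShift:
    """KDE comparison of one embedding axis between two conditions."""

    grid: np.ndarray
    densities: dict[str, np.ndarray]
    median_difference: float
    ks_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        dx = np.diff(self.grid).mean()
        for cond, dens in self.densities.items():
            if (dens < 0).any():
                raise ValueError("negative density")
            mass = float(np.trapezoid(dens, self.grid))
            if abs(mass - 1.0) > 1e-3:
                raise ValueError(
                    f"density for {cond!r} integrates to {mass:.4f}, not 1"
                )
        del dx


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------


def select_hvg_mvp(
    nm: NormalizedMatrix,
    n_bins: int = 20,
    mean_low: float = 0.0125,
    mean_high: float = 2.0,
    z_cutoff: float = 0.9,
) -> FeatureSelection:
    """Binned-dispersion selection (mean window + within-bin dispersion Z).

    Dispersion is variance/mean computed on the de-logged normalized scale
    (``base**value - pseudocount``), so it is interpretable as an
    overdispersion index.  Genes are placed into ``n_bins`` equal-frequency
    bins by mean; within each bin the dispersion is Z-scored; selection
    keeps genes with mean in ``[mean_low, mean_high]`` and Z > ``z_cutoff``.
    """
    vals = _delog(nm)
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    nonzero = mean > 0
    if nonzero.sum() < n_bins:
        raise ValueError(
            f"need at least n_bins={n_bins} genes with nonzero mean"
        )
    z = np.zeros_like(disp)
    order = np.argsort(mean[nonzero], kind="stable")
    nz_idx = np.flatnonzero(nonzero)[order]
    for chunk in np.array_split(nz_idx, n_bins):
        d = disp[chunk]
        sd = d.std(ddof=1) if len(d) > 1 else 0.0
        z[chunk] = (d - d.mean()) / sd if sd > 0 else 0.0
    keep = nonzero & (mean >= mean_low) & (mean <= mean_high) & (z > z_cutoff)
    gene_ids = np.asarray(nm.gene_ids, dtype=object)
    return FeatureSelection(
        gene_ids=gene_ids,
        mean=mean,
        dispersion=disp,
        dispersion_z=z,
        selected=list(gene_ids[keep]),
        method="mvp",
        params={
            "n_bins": n_bins,
            "mean_low": mean_low,
            "mean_high": mean_high,
            "z_cutoff": z_cutoff,
            "dispersion_scale": "normalized_delogged",
        },
    )


def _delog(nm: NormalizedMatrix) -> np.ndarray:
    base = 10.0 if nm.metadata["log_base"] == "10" else np.e
    return np.maximum(base ** nm.values - nm.metadata["pseudocount"], 0.0)


def select_hvg_vst(
    nm: NormalizedMatrix, n_select: int = 2000, clip_max: float | None = None
) -> FeatureSelection:
    """Variance-stabilizing selection against a fitted mean-variance trend.

    A local (lowess, span 0.3) regression of log10 variance on log10 mean
    over genes with nonzero variance supplies each gene's expected SD; each
    gene's values are standardized by observed mean and trend SD, clipped at
    ``clip_max`` (default sqrt(n_cells)), and genes are ranked by the
    variance of the clipped standardized values.
    """
    vals = _delog(nm)
    n_cells, n_genes = vals.shape
    if n_select > n_genes:
        raise ValueError(f"n_select {n_select} > n_genes {n_genes}")
    if clip_max is None:
        clip_max = float(np.sqrt(n_cells))
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    usable = (mean > 0) & (var > 0)
    expected_var = np.zeros(n_genes)
    if usable.sum() >= 3:
        lx = np.log10(mean[usable])
        ly = np.log10(var[usable])
        fit = sm.nonparametric.lowess(ly, lx, frac=0.3, return_sorted=False)
        expected_var[usable] = 10.0 ** fit
    std_var = np.zeros(n_genes)
    ok = usable & (expected_var > 0)
    if ok.any():
        sd = np.sqrt(expected_var[ok])
        z = (vals[:, ok] - mean[ok][None, :]) / sd[None, :]
        np.clip(z, -clip_max, clip_max, out=z)
        std_var[ok] = z.var(axis=0, ddof=1)
    order = np.argsort(-std_var, kind="stable")
    gene_ids = np.asarray(nm.gene_ids, dtype=object)
    selected = list(gene_ids[order[:n_select]])
    return FeatureSelection(
        gene_ids=gene_ids,
        mean=mean,
        dispersion=std_var,
        dispersion_z=std_var,
        selected=selected,
        method="vst",
        params={"n_select": n_select, "clip_max": clip_max, "span": 0.3},
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def run_pca(
    nm: NormalizedMatrix,
    genes: list[str] | None = None,
    center: bool = True,
    scale: bool = True,
    n_components: int = 20,
) -> Embedding:
    """PCA on the (optionally centered/unit-scaled) normalized matrix.

    Zero-variance genes are dropped with a warning when ``scale`` is on.
    Loadings are orthonormal; explained variances are the leading sample
    eigenvalues in non-increasing order.
    """
    if nm.n_cells < 2:
        raise ValueError("PCA needs at least 2 cells")
    gene_ids = np.asarray(nm.gene_ids, dtype=object)
    if genes is not None:
        pos = {g: j for j, g in enumerate(gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise ValueError(f"genes not in matrix: {missing[:5]}")
        cols = np.array([pos[g] for g in genes])
    else:
        cols = np.arange(nm.n_genes)
    X = nm.values[:, cols].astype(float)
    used = gene_ids[cols]
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            import warnings

            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance genes before "
                "scaled PCA"
            )
            X = X[:, keep]
            used = used[keep]
            sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no usable genes for PCA")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu[None, :]
    if scale:
        Xc = Xc / sd[None, :]
    max_rank = min(Xc.shape[0] - (1 if center else 0), Xc.shape[1])
    n_components = int(min(n_components, max_rank))
    if n_components < 1:
        raise ValueError("n_components must be >= 1 after capping")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    explained = (s[:n_components] ** 2) / (Xc.shape[0] - 1)
    return Embedding(
        scores=scores,
        loadings=loadings,
        explained_variance=explained,
        gene_ids=used,
        centered=center,
        scaled=scale,
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def kmeans_cluster(
    emb: Embedding, k: int = 9, n_init: int = 10, seed: int = 0
) -> ClusterAssignment:
    """Lloyd k-means, best of ``n_init`` starts, labels in [1, k]."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = emb.scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(emb.scores)
    labels = km.labels_ + 1
    return ClusterAssignment(labels=labels, k=k, method="kmeans", seed=seed)


def subcluster(
    emb: Embedding,
    assign: ClusterAssignment,
    cluster_id: int,
    k2: int = 2,
    n_init: int = 10,
    seed: int = 0,
) -> ClusterAssignment:
    """Re-partition one cluster into ``k2`` pieces, appended after existing labels.

    The split cluster's cells receive labels ``cluster_id`` (first piece) and
    ``k+1 .. k+k2-1`` (remaining pieces); all other cells keep their labels.
    """
    mask = assign.labels == cluster_id
    if cluster_id < 1 or cluster_id > assign.k or not mask.any():
        raise ValueError(f"cluster {cluster_id} not present")
    if mask.sum() < k2:
        raise ValueError(
            f"cluster {cluster_id} has {int(mask.sum())} cells < k2={k2}"
        )
    km = KMeans(
        n_clusters=k2, n_init=n_init, random_state=seed, algorithm="lloyd"
    ).fit(emb.scores[mask])
    new_labels = assign.labels.copy()
    sub = km.labels_
    # piece 0 keeps the original id; pieces 1..k2-1 get fresh ids
    fresh = assign.k + np.arange(1, k2)
    relabel = np.concatenate(([cluster_id], fresh))
    new_labels[mask] = relabel[sub]
    return ClusterAssignment(
        labels=new_labels,
        k=assign.k + k2 - 1,
        method=assign.method + "+subcluster",
        seed=seed,
    )


def snn_cluster(
    emb: Embedding,
    k_neighbors: int = 20,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Shared-nearest-neighbor modularity clustering.

    Builds the Euclidean kNN graph on the embedding, weights each edge by
    the Jaccard overlap of the two cells' neighbor sets (self included),
    prunes edges below ``prune``, and partitions by greedy modularity
    maximization.  Deterministic given the embedding (the seed is recorded
    for provenance; the algorithm itself has no random step).
    """
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    n = emb.scores.shape[0]
    if n <= k_neighbors:
        raise ValueError("need more cells than k_neighbors")
    # query k+1 and drop each point itself: "k nearest neighbors" excludes self
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb.scores)
    _, idx_full = nn.kneighbors(emb.scores)
    idx = np.empty((n, k_neighbors), dtype=int)
    for i, row in enumerate(idx_full):
        idx[i] = [j for j in row if j != i][:k_neighbors]
    neighbor_sets = [set(row) | {i} for i, row in enumerate(idx)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neighbor_sets[i] & neighbor_sets[j])
            union = len(neighbor_sets[i] | neighbor_sets[j])
            w = inter / union
            if w >= prune:
                g.add_edge(i, j, weight=w)
    communities = nx.algorithms.community.greedy_modularity_communities(
        g, weight="weight"
    )
    labels = np.empty(n, dtype=int)
    # stable label order: communities sorted by their smallest member
    ordered = sorted(communities, key=min)
    for lab, comm in enumerate(ordered, start=1):
        labels[list(comm)] = lab
    return ClusterAssignment(
        labels=labels, k=len(ordered), method="snn_modularity", seed=seed
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def annotate_clusters(
    nm: NormalizedMatrix,
    assign: ClusterAssignment,
    reference: GeneSetCollection,
) -> ClusterAssignment:
    """Label each cluster with the reference set scoring highest on it.

    The score of set S in cluster c is the mean over cluster cells and
    S-genes of the gene-wise Z-scaled expression.  Ties break to the
    lexicographically first set name and are flagged in the score table.
    """
    gene_ids = np.asarray(nm.gene_ids, dtype=object)
    pos = {g: j for j, g in enumerate(gene_ids)}
    set_cols = {
        name: [pos[g] for g in genes if g in pos]
        for name, genes in reference.sets.items()
    }
    if not any(set_cols.values()):
        raise ValueError("no reference gene present in the matrix")
    mu = nm.values.mean(axis=0)
    sd = nm.values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (nm.values - mu[None, :]) / np.maximum(sd, 1e-300), 0.0)
    annotation: dict[int, str] = {}
    table: dict[int, dict] = {}
    for c in range(1, assign.k + 1):
        cells = assign.labels == c
        scores = {}
        for name in sorted(set_cols):
            cols = set_cols[name]
            scores[name] = float(z[np.ix_(cells, cols)].mean()) if cols else -np.inf
        best = max(sorted(scores), key=lambda nm_: scores[nm_])
        tie = sum(1 for v in scores.values() if v == scores[best]) > 1
        annotation[c] = best
        table[c] = {"scores": scores, "tie": tie}
    return replace(assign, annotation=annotation, annotation_scores=table)


def annotated_types(assign: ClusterAssignment) -> np.ndarray:
    """Per-cell annotated cell-type labels (requires prior annotation)."""
    if not assign.annotation:
        raise ValueError("assignment is not annotated")
    return np.array(
        [assign.annotation[c] for c in assign.labels], dtype=object
    )


# ---------------------------------------------------------------------------
# 1-D density shift
# ---------------------------------------------------------------------------


def density_shift_1d(
    emb: Embedding,
    axis: int,
    cell_mask: np.ndarray,
    condition_label: np.ndarray,
    grid_size: int = 512,
) -> DensityShift:
    """Compare one embedding axis between two conditions on masked cells.

    Gaussian KDE (Silverman bandwidth) per condition on a shared grid;
    the reported test is the two-sample Kolmogorov-Smirnov statistic.
    ``axis`` is 1-based (axis=1 is PC1).
    """
    if not 1 <= axis <= emb.scores.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    mask = np.asarray(cell_mask, dtype=bool)
    conds = np.asarray(condition_label, dtype=object)
    uniq = sorted(set(conds[mask]))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 conditions among masked cells, got {uniq}")
    values = {}
    for cond in uniq:
        v = emb.scores[mask & (conds == cond), axis - 1]
        if len(v) == 0:
            raise ValueError(f"no masked cells in condition {cond!r}")
        if len(v) < 10:
            raise ValueError(f"fewer than 10 masked cells in condition {cond!r}")
        values[cond] = v
    allv = np.concatenate(list(values.values()))
    pad = 3 * allv.std()
    grid = np.linspace(allv.min() - pad, allv.max() + pad, grid_size)
    densities = {}
    for cond, v in values.items():
        kde = stats.gaussian_kde(v, bw_method="silverman")
        dens = kde(grid)
        densities[cond] = dens / np.trapezoid(dens, grid)
    ks = stats.ks_2samp(values[uniq[0]], values[uniq[1]])
    return DensityShift(
        grid=grid,
        densities=densities,
        median_difference=float(
            np.median(values[uniq[1]]) - np.median(values[uniq[0]])
        ),
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
    )
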