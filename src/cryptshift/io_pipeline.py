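"""Readers/writers for the standard exchange formats plus pipeline orchestration.

The package's in-memory unit of exchange is :class:`UmiMatrix` — a sparse
cells x genes matrix of non-negative integer UMI counts with aligned cell and
gene identifiers, per-gene mitochondrial flags, and per-cell sample /
condition labels.  All matrices in this package are cells-in-rows; every
writer records that convention in its header comment.

On disk the matrix travels as the standard 10x-style triplet
(``matrix.mtx`` in MatrixMarket coordinate integer format, ``barcodes.tsv``,
``features.tsv``).  Gene sets travel as GMT.  Gene identity matching is
exact-string and case-sensitive throughout: synthetic data controls its own
namespace, so no symbol aliasing is attempted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("cryptshift")

MITO_PREFIX_DEFAULT = "mt-"


def configure_logging(level: str = "INFO") -> None:
    """Attach a stream handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class UmiMatrix:
    """Sparse cells x genes UMI count matrix with aligned annotations.

    Attributes
    ----------
    counts
        ``scipy.sparse.csr_matrix`` of shape (n_cells, n_genes), dtype
        integer, entries >= 0.  Row/column reductions and nonzero iteration
        never densify.
    cell_ids, gene_ids
        Unique string identifiers (barcodes / feature ids).
    mito_flags
        Boolean per gene; True marks a mitochondrial gene.
    sample_label, condition_label
        String per cell; empty strings where not applicable.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    mito_flags: np.ndarray
    sample_label: np.ndarray
    condition_label: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        self.sample_label = np.asarray(self.sample_label, dtype=object)
        self.condition_label = np.asarray(self.condition_label, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != n_cells {n_cells}"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != n_genes {n_genes}"
            )
        if len(self.mito_flags) != n_genes:
            raise ValueError("mito_flags length mismatch")
        if len(self.sample_label) != n_cells or len(self.condition_label) != n_cells:
            raise ValueError("per-cell label length mismatch")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    # -- convenience reductions (sparse-safe) --

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMI per cell."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.diff(self.counts.indptr)

    def gene_means(self) -> np.ndarray:
        return np.asarray(self.counts.mean(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "UmiMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return UmiMatrix(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            mito_flags=self.mito_flags,
            sample_label=self.sample_label[idx],
            condition_label=self.condition_label[idx],
        )

    def copy(self) -> "UmiMatrix":
        return UmiMatrix(
            counts=self.counts.copy(),
            cell_ids=self.cell_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            mito_flags=self.mito_flags.copy(),
            sample_label=self.sample_label.copy(),
            condition_label=self.condition_label.copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set."""

    sets: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if not all(isinstance(g, str) for g in genes):
                raise ValueError(f"gene set {name!r} has non-string ids")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# 10x triplet reader / writer
# ---------------------------------------------------------------------------


def read_10x_triplet(
    directory: str | Path, mito_prefix: str = MITO_PREFIX_DEFAULT
) -> UmiMatrix:
    """Read a matrix.mtx / barcodes.tsv / features.tsv triplet.

    The MatrixMarket file stores genes x cells or cells x genes; this package
    writes cells-in-rows and reads back the same orientation, checked against
    the sidecar lengths.  Mitochondrial flags are set from ``mito_prefix``
    (case-sensitive prefix match on the gene id).

    Raises
    ------
    ValueError
        on dimension mismatch, duplicate barcodes, or non-integer entries.
    """
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None, dtype=str
    )
    features = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None, dtype=str
    )
    cell_ids = barcodes[0].to_numpy(dtype=object)
    gene_ids = features[0].to_numpy(dtype=object)
    if mat.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(cell_ids)} barcodes, {len(gene_ids)} features)"
        )
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate barcodes in barcodes.tsv")
    data = np.asarray(mat.data if sp.issparse(mat) else mat)
    if data.size and not np.allclose(data, np.round(data)):
        raise ValueError("matrix.mtx contains non-integer entries")
    counts = sp.csr_matrix(mat).astype(np.int64)
    sample = barcodes[1].to_numpy(dtype=object) if barcodes.shape[1] > 1 else np.full(
        len(cell_ids), "", dtype=object
    )
    condition = (
        barcodes[2].to_numpy(dtype=object)
        if barcodes.shape[1] > 2
        else np.full(len(cell_ids), "", dtype=object)
    )
    mito = np.array([g.startswith(mito_prefix) for g in gene_ids], dtype=bool)
    return UmiMatrix(counts, cell_ids, gene_ids, mito, sample, condition)


def write_10x_triplet(m: UmiMatrix, directory: str | Path) -> None:
    """Write the triplet; matrix.mtx is coordinate integer, cells in rows."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = m.counts.tocoo()
    scipy.io.mmwrite(
        directory / "matrix.mtx",
        coo,
        field="integer",
        comment="cryptshift UMI counts; rows = cells, columns = genes",
    )
    pd.DataFrame(
        {0: m.cell_ids, 1: m.sample_label, 2: m.condition_label}
    ).to_csv(directory / "barcodes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({0: m.gene_ids}).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description column doubles as the category tag when non-empty.
    Lines with fewer than three fields (no genes) raise with the line number.
    """
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: need name, description, "
                    f"and at least one gene"
                )
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"malformed GMT line {lineno}: empty gene list")
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            sets[name] = genes
            if desc:
                categories[name] = desc
    return GeneSetCollection(sets, categories)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.sets.items():
            desc = gsc.categories.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Pipeline configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All stage parameters for an end-to-end run.

    Every random stage takes its seed from ``seed`` (one integer drives the
    whole run via numpy's SeedSequence spawning, so reruns are bit-identical).
    """

    preset: str = "immune9"
    seed: int = 0
    out_dir: str = "pipeline_out"
    # override the preset's cohort size (cells per condition); None keeps it
    n_cells_per_condition: int | None = None
    # stage toggles
    do_demux: bool = True
    do_downsample: bool = True
    do_qc: bool = True
    # demux
    min_hashtag_reads: int = 10
    presence_fraction: float = 0.2
    # qc
    min_genes: int = 200
    max_genes: int = 1500
    max_umi: int = 5000
    max_mito_pct: float = 8.0
    # normalization
    norm_mode: str = "scale_to_median"
    log_base: str = "10"
    pseudocount: float = 1.0
    # hvg ("mvp", "vst", or "none" = all genes)
    hvg_method: str = "mvp"
    n_hvg: int = 2000
    hvg_mean_low: float = 0.0125
    hvg_mean_high: float = 2.0
    hvg_z_cutoff: float = 0.9
    # dimred / clustering
    n_pcs: int = 20
    cluster_method: str = "kmeans"
    k: int = 9
    n_init: int = 10
    k_neighbors: int = 20
    # markers
    marker_test: str = "sseq"
    min_mean: float = 0.1
    lfc_min: float = 2.0
    alpha: float = 0.05
    # composition
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> demux -> downsample -> QC -> normalize -> HVG -> PCA ->
    cluster -> annotate -> markers -> enrichment -> composition.

    Writes per-stage TSV/JSON outputs under ``config.out_dir`` plus
    ``run_report.json`` logging every parameter, seed, and library version.
    Returns the report dict.  Reruns with the same config are bit-identical.
    """
    # imports here: this module defines the containers the stage modules use
    from . import composition_stats, demux_qc, dimred_cluster, geneset_scoring
    from . import markers_de, synthetic_data

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": _library_versions(),
        "stages": {},
    }

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("simulate")
        spec = synthetic_data.make_preset(config.preset)
        spec = replace(spec, seed=config.seed)
        if config.n_cells_per_condition is not None:
            spec = replace(
                spec, n_cells_per_condition=config.n_cells_per_condition
            )
        m, truth = synthetic_data.simulate_counts(spec, seed=config.seed)
        hashtags, truth = synthetic_data.simulate_hashtags(
            truth, n_tags=4, seed=config.seed + 1
        )
        report["stages"]["simulate"] = {
            "n_cells": m.n_cells,
            "n_genes": m.n_genes,
            "seed": config.seed,
        }

        if config.do_demux:
            _stage("demux")
            demux = demux_qc.classify_hashtags(
                hashtags,
                min_reads=config.min_hashtag_reads,
                presence_fraction=config.presence_fraction,
            )
            demux.to_frame().to_csv(out / "demux.tsv", sep="\t", index=False)
            keep = demux.category == "single"
            m = m.subset_cells(keep)
            truth = truth.subset(keep)
            report["stages"]["demux"] = {
                "kept_singles": int(keep.sum()),
                "category_counts": {
                    c: int((demux.category == c).sum())
                    for c in np.unique(demux.category)
                },
            }

        if config.do_downsample:
            _stage("downsample")
            m = demux_qc.downsample_to_common_depth(m, seed=config.seed + 2)
            report["stages"]["downsample"] = {
                "median_umi": float(np.median(m.cell_totals()))
            }

        if config.do_qc:
            _stage("qc")
            th = demux_qc.QcThresholds(
                min_genes=config.min_genes,
                max_genes=config.max_genes,
                max_umi=config.max_umi,
                max_mito_pct=config.max_mito_pct,
            )
            n_before = m.n_cells
            m, qc_report = demux_qc.filter_cells_qc(m, th, return_report=True)
            truth = truth.subset(
                np.isin(truth.cell_ids, np.asarray(m.cell_ids, dtype=object))
            )
            with open(out / "qc_report.json", "w") as fh:
                json.dump(qc_report, fh, indent=2)
            report["stages"]["qc"] = {
                "cells_before": n_before,
                "cells_after": m.n_cells,
                **qc_report,
            }

        _stage("normalize")
        mode = config.norm_mode
        log_base = config.log_base
        nm = demux_qc.normalize_log(
            m, mode=mode, log_base=log_base, pseudocount=config.pseudocount
        )
        report["stages"]["normalize"] = dict(nm.metadata)

        _stage("hvg")
        if config.hvg_method == "none":
            genes_for_pca = None
            report["stages"]["hvg"] = {"method": "none", "n_selected": nm.n_genes}
        else:
            if config.hvg_method == "mvp":
                fs = dimred_cluster.select_hvg_mvp(
                    nm,
                    mean_low=config.hvg_mean_low,
                    mean_high=config.hvg_mean_high,
                    z_cutoff=config.hvg_z_cutoff,
                )
            elif config.hvg_method == "vst":
                fs = dimred_cluster.select_hvg_vst(
                    nm, n_select=min(config.n_hvg, nm.n_genes)
                )
            else:
                raise ValueError(f"unknown hvg_method {config.hvg_method!r}")
            genes_for_pca = fs.selected
            if len(genes_for_pca) < config.n_pcs:
                raise ValueError(
                    f"HVG selection kept {len(genes_for_pca)} genes, fewer "
                    f"than n_pcs={config.n_pcs}; relax the HVG parameters"
                )
            report["stages"]["hvg"] = {
                "method": fs.method,
                "n_selected": len(fs.selected),
            }

        _stage("pca")
        emb = dimred_cluster.run_pca(
            nm, genes=genes_for_pca, n_components=min(config.n_pcs, m.n_cells - 1)
        )
        pd.DataFrame(
            emb.scores,
            index=np.asarray(m.cell_ids, dtype=str),
            columns=[f"PC{i + 1}" for i in range(emb.scores.shape[1])],
        ).to_csv(out / "embedding.tsv", sep="\t")

        _stage("cluster")
        if config.cluster_method == "kmeans":
            assign = dimred_cluster.kmeans_cluster(
                emb, k=config.k, n_init=config.n_init, seed=config.seed + 3
            )
        else:
            assign = dimred_cluster.snn_cluster(
                emb, k_neighbors=config.k_neighbors, seed=config.seed + 3
            )
        report["stages"]["cluster"] = {
            "method": assign.method,
            "k": assign.k,
        }

        _stage("annotate")
        reference = synthetic_data.marker_reference(spec)
        assign = dimred_cluster.annotate_clusters(nm, assign, reference)
        # when k-means used fewer clusters than there are reference types,
        # two types can share a cluster; split the best-scoring cluster for
        # each unused reference set (re-clustering with k2 = 2) and
        # re-annotate, mirroring the merged-secretory-cluster workflow
        if config.cluster_method == "kmeans":
            for _ in range(len(reference) - assign.k):
                unused = sorted(
                    set(reference.names()) - set(assign.annotation.values())
                )
                if not unused:
                    break
                target_set = unused[0]
                best_cluster = max(
                    assign.annotation_scores,
                    key=lambda c: assign.annotation_scores[c]["scores"][target_set],
                )
                if (assign.labels == best_cluster).sum() < 2:
                    break
                assign = dimred_cluster.subcluster(
                    emb, assign, best_cluster, k2=2, seed=config.seed + 4
                )
                assign = dimred_cluster.annotate_clusters(nm, assign, reference)
        pd.DataFrame(
            {
                "cell_id": np.asarray(m.cell_ids, dtype=str),
                "cluster": assign.labels,
                "cell_type": [assign.annotation[c] for c in assign.labels],
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)

        _stage("markers")
        marker_frames = []
        for cid in range(1, assign.k + 1):
            if (assign.labels == cid).sum() < 2:
                continue
            rows = markers_de.sseq_exact_test(
                m, assign, cluster_id=cid, min_mean=config.min_mean
            )
            selected = markers_de.select_markers(
                rows, lfc_min=config.lfc_min, alpha=config.alpha
            )
            marker_frames.append(markers_de.rows_to_frame(selected))
        markers_df = (
            pd.concat(marker_frames, ignore_index=True)
            if marker_frames
            else markers_de.rows_to_frame([])
        )
        markers_df.to_csv(out / "markers.tsv", sep="\t", index=False)
        report["stages"]["markers"] = {"n_selected": int(len(markers_df))}

        _stage("enrichment")
        z = geneset_scoring.zscale(
            nm.values, gene_ids=nm.gene_ids, unit_ids=nm.cell_ids
        )
        enrich_rows = []
        conditions = np.asarray(m.condition_label, dtype=object)
        uniq_cond = sorted(set(conditions))
        if len(uniq_cond) == 2:
            groups = {c: conditions == c for c in uniq_cond}
            gene_ns = set(nm.gene_ids)
            for set_name in reference.names():
                genes = [g for g in reference[set_name] if g in gene_ns]
                if len(genes) < 3:
                    continue
                res = geneset_scoring.score_set(
                    z,
                    genes,
                    unit="cell",
                    groups=groups,
                    set_name=set_name,
                )
                enrich_rows.append(
                    {
                        "set": set_name,
                        "unit": res.unit,
                        **{f"mean_{g}": v for g, v in res.group_means.items()},
                        "statistic": res.statistic,
                        "p": res.p_value,
                    }
                )
        pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        _stage("composition")
        annotated = dimred_cluster.annotated_types(assign)
        table = composition_stats.tabulate_composition(
            annotated, conditions
        )
        comp_rows = []
        for cell_type in table.cell_types:
            res = composition_stats.abundance_shift_test(
                table, cell_type, level=config.ci_level
            )
            comp_rows.append(res.to_dict())
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(out / "composition.tsv", sep="\t", index=False)
        report["stages"]["composition"] = {"n_types": len(comp_rows)}
    except Exception as exc:  # re-raise with the failing stage named
        stage = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return report


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
    }
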