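"""Ground-truthed synthetic UMI matrices, hashtag reads, and gene sets.

The generator emulates the statistical structure the downstream analysis
assumes: multi-condition (young/old or control/IFNg) cohorts of cells drawn
from discrete cell types with negative-binomial gene counts, per-type marker
fold-changes, per-cell sequencing depth heterogeneity, a mitochondrial count
fraction, an optional latent differentiation axis that imprints a PC1-like
gradient on a block of genes, and condition-dependent cell-type composition
with known odds ratios.

Counts follow a gamma-multinomial scheme: a cell's total UMI is drawn
log-normal, a per-cell/per-gene gamma factor with variance ``alpha_g``
multiplies the gene's rate, and the depth is allocated multinomially.  The
marginal per-gene law is then negative-binomial-like with variance
``mu + alpha * mu**2`` (mean ``mu``, dispersion ``alpha``); ``alpha = 0``
degenerates to plain multinomial (Poisson-like) sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .demux_qc import HashtagCounts
from .io_pipeline import GeneSetCollection, UmiMatrix, write_10x_triplet

PRESETS = ("crypt10", "immune9", "organoid7")


@dataclass
class LatentAxis:
    """A 1-D latent coordinate (differentiation-like) for selected types.

    Cells of ``affected_types`` draw a coordinate ``u ~ N(shift[cond], 1)``;
    each affected gene's log2 rate gains ``loading * u``.  ``condition_shift``
    is expressed in SD units of the coordinate.
    """

    affected_types: list[str]
    gene_loadings: dict[str, float]
    condition_shift: dict[str, float]


@dataclass
class SyntheticSpec:
    """Full description of one synthetic cohort."""

    n_cells_per_condition: int
    cell_types: list[str]
    composition: dict[str, np.ndarray]  # condition -> prob vector over types
    n_genes: int
    marker_map: dict[str, tuple[list[str], float]]  # type -> (genes, log2 FC)
    baseline_mean: np.ndarray  # per gene, > 0
    nb_dispersion: np.ndarray  # per gene, >= 0
    depth_distribution: dict  # meanlog, sdlog, condition_scale
    mito_genes: list[str]
    mito_fraction: float
    gene_ids: list[str] = field(default_factory=list)
    latent_axis: LatentAxis | None = None
    geneset_shifts: list[tuple[list[str], str, float]] = field(default_factory=list)
    mito_beta_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_condition < 0:
            raise ValueError("n_cells_per_condition must be >= 0")
        if not self.gene_ids:
            self.gene_ids = [f"gene{i:05d}" for i in range(self.n_genes)]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length != n_genes")
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        self.nb_dispersion = np.asarray(self.nb_dispersion, dtype=float)
        if len(self.baseline_mean) != self.n_genes:
            raise ValueError("baseline_mean length != n_genes")
        if len(self.nb_dispersion) != self.n_genes:
            raise ValueError("nb_dispersion length != n_genes")
        if (self.baseline_mean <= 0).any():
            raise ValueError("baseline means must be > 0")
        if (self.nb_dispersion < 0).any():
            raise ValueError("dispersions must be >= 0")
        gene_set = set(self.gene_ids)
        for t, (genes, _) in self.marker_map.items():
            if t not in self.cell_types:
                raise ValueError(f"marker_map type {t!r} not in cell_types")
            missing = set(genes) - gene_set
            if missing:
                raise ValueError(f"marker genes not in gene ids: {sorted(missing)}")
        if set(self.mito_genes) - gene_set:
            raise ValueError("mito_genes not in gene ids")
        for cond, probs in self.composition.items():
            probs = np.asarray(probs, dtype=float)
            self.composition[cond] = probs
            if len(probs) != len(self.cell_types):
                raise ValueError(f"composition[{cond!r}] length mismatch")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"composition[{cond!r}] does not sum to 1")
        if not 0 <= self.mito_fraction < 1:
            raise ValueError("mito_fraction must lie in [0, 1)")

    @property
    def conditions(self) -> list[str]:
        return list(self.composition)

    def true_odds_ratios(self) -> dict[str, float]:
        """Per-type odds ratio of the second condition vs the first.

        Derived from the composition vectors: odds of belonging to type t in
        condition B over the same odds in condition A.
        """
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError("odds ratios need exactly two conditions")
        pa = self.composition[conds[0]]
        pb = self.composition[conds[1]]
        odds_a = pa / (1 - pa)
        odds_b = pb / (1 - pb)
        return dict(zip(self.cell_types, odds_b / odds_a))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "n_cells_per_condition": self.n_cells_per_condition,
            "cell_types": self.cell_types,
            "composition": {
                c: [float(x) for x in v] for c, v in self.composition.items()
            },
            "n_genes": self.n_genes,
            "marker_map": {
                t: {"genes": g, "log2fc": float(l)}
                for t, (g, l) in self.marker_map.items()
            },
            "depth_distribution": self.depth_distribution,
            "mito_genes": self.mito_genes,
            "mito_fraction": float(self.mito_fraction),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Per-cell generative truth aligned with the emitted matrix."""

    cell_ids: np.ndarray
    cell_type: np.ndarray
    condition: np.ndarray
    sample: np.ndarray
    latent: np.ndarray  # latent-axis coordinate; nan for unaffected cells
    true_odds_ratios: dict[str, float]
    marker_map: dict[str, tuple[list[str], float]]
    hashtag: np.ndarray | None = None  # true tag per cell
    is_doublet: np.ndarray | None = None
    is_low_signal: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.cell_ids)

    def subset(self, mask_or_idx) -> "GroundTruth":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GroundTruth(
            cell_ids=self.cell_ids[idx],
            cell_type=self.cell_type[idx],
            condition=self.condition[idx],
            sample=self.sample[idx],
            latent=self.latent[idx],
            true_odds_ratios=self.true_odds_ratios,
            marker_map=self.marker_map,
            hashtag=None if self.hashtag is None else self.hashtag[idx],
            is_doublet=None if self.is_doublet is None else self.is_doublet[idx],
            is_low_signal=(
                None if self.is_low_signal is None else self.is_low_signal[idx]
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": np.asarray(self.cell_ids, dtype=str),
                "cell_type": self.cell_type,
                "condition": self.condition,
                "sample": self.sample,
                "latent": self.latent,
            }
        )
        if self.hashtag is not None:
            df["hashtag"] = self.hashtag
            df["is_doublet"] = self.is_doublet
            df["is_low_signal"] = self.is_low_signal
        return df


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _base_gene_panel(
    rng: np.random.Generator,
    cell_types: list[str],
    marker_genes: dict[str, list[str]],
    n_filler: int,
    n_mito: int = 13,
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Assemble gene ids, baseline means and dispersions for a preset.

    Marker genes get baseline means drawn in [2, 6] (well-measured, so log2
    fold-changes survive the pseudocount), filler genes span a log-normal
    range, mito genes get modest means (their counts are driven by the
    routed mito fraction, not by these rates).
    """
    mito_ids = [f"mt-gene{i:02d}" for i in range(n_mito)]
    named = [g for genes in marker_genes.values() for g in genes]
    filler = [f"gene{i:05d}" for i in range(n_filler)]
    gene_ids = named + filler + mito_ids
    n_genes = len(gene_ids)
    means = np.empty(n_genes)
    means[: len(named)] = rng.uniform(2.0, 6.0, size=len(named))
    means[len(named) : len(named) + n_filler] = np.minimum(
        rng.lognormal(mean=-1.2, sigma=1.4, size=n_filler), 30.0
    )
    means[len(named) + n_filler :] = rng.uniform(1.0, 3.0, size=n_mito)
    dispersions = np.clip(rng.gamma(shape=2.0, scale=0.1, size=n_genes), 0.02, 1.5)
    return gene_ids, means, dispersions, mito_ids


def _marker_names(cell_types: list[str], n_markers: int, special: dict[str, str]):
    out: dict[str, list[str]] = {}
    for t in cell_types:
        names = [f"{t}_mk{j}" for j in range(n_markers)]
        if t in special:
            names[0] = special[t]
        out[t] = names
    return out


def make_preset(name: str) -> SyntheticSpec:
    """Return a fully populated :class:`SyntheticSpec` for a named scenario.

    ``crypt10``  — 10 intestinal crypt epithelial types (stem with an
    Lgr5-like marker, transit-amplifying, absorptive and secretory lineages)
    across young/old, with a latent differentiation axis shifted +1 SD in old
    stem/TA cells.

    ``immune9``  — 9 lamina propria immune types across young/old with
    old-enriched ILC2-like (true OR 3) and cytotoxic-T-like (true OR 5)
    populations and a depleted naive-T-like population absorbing the mass.

    ``organoid7`` — 7 organoid epithelial types across control/IFNg with a
    treated-condition secretory (goblet-like) enrichment (true OR 3).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    rng = np.random.default_rng(abs(hash(name)) % (2**31))

    if name == "crypt10":
        cell_types = [
            "stem",
            "ta",
            "progenitor_early",
            "progenitor_late",
            "enterocyte",
            "goblet",
            "paneth",
            "tuft",
            "enteroendocrine",
            "deep_crypt_secretory",
        ]
        special = {
            "stem": "Lgr5",
            "goblet": "Muc2",
            "paneth": "Lyz1",
            "tuft": "Dclk1",
            "enteroendocrine": "Chga",
        }
        marker_genes = _marker_names(cell_types, 8, special)
        gene_ids, means, disps, mito_ids = _base_gene_panel(
            rng, cell_types, marker_genes, n_filler=900
        )
        comp = np.array(
            [0.18, 0.16, 0.12, 0.10, 0.16, 0.09, 0.07, 0.04, 0.04, 0.04]
        )
        composition = {"young": comp, "old": comp.copy()}
        axis_genes = {
            f"gene{i:05d}": float(l)
            for i, l in zip(range(100), rng.normal(0.45, 0.12, size=100))
        }
        latent = LatentAxis(
            affected_types=["stem", "ta"],
            gene_loadings=axis_genes,
            condition_shift={"young": 0.0, "old": 1.0},
        )
        return SyntheticSpec(
            n_cells_per_condition=1500,
            cell_types=cell_types,
            composition=composition,
            n_genes=len(gene_ids),
            marker_map={t: (marker_genes[t], 3.0) for t in cell_types},
            baseline_mean=means,
            nb_dispersion=disps,
            depth_distribution={
                "meanlog": float(np.log(1500)),
                "sdlog": 0.45,
                "condition_scale": {"young": 1.0, "old": 1.3},
            },
            mito_genes=mito_ids,
            mito_fraction=0.04,
            gene_ids=gene_ids,
            latent_axis=latent,
        )

    if name == "immune9":
        cell_types = [
            "b_cell",
            "plasma_cell",
            "cd4_t",
            "naive_t",
            "ilc2",
            "ilc3",
            "cytotoxic_t",
            "macrophage",
            "dendritic",
        ]
        special = {"ilc2": "Gata3", "cytotoxic_t": "Ccl5", "b_cell": "Cd19"}
        marker_genes = _marker_names(cell_types, 8, special)
        gene_ids, means, disps, mito_ids = _base_gene_panel(
            rng, cell_types, marker_genes, n_filler=900
        )
        # young composition: ILC2 5%, cytotoxic-T 3%, naive-T 30%, six null
        # types sharing 62%.  Old condition plants exact odds ratios 3 (ILC2)
        # and 5 (cytotoxic-T); null types keep their young frequency (OR 1);
        # naive-T absorbs the excess (depleted, OR ~0.29).
        young = {
            "b_cell": 0.62 / 6,
            "plasma_cell": 0.62 / 6,
            "cd4_t": 0.62 / 6,
            "naive_t": 0.30,
            "ilc2": 0.05,
            "ilc3": 0.62 / 6,
            "cytotoxic_t": 0.03,
            "macrophage": 0.62 / 6,
            "dendritic": 0.62 / 6,
        }

        def _odds_shift(p: float, odds_ratio: float) -> float:
            odds = p / (1 - p) * odds_ratio
            return odds / (1 + odds)

        old = dict(young)
        old["ilc2"] = _odds_shift(young["ilc2"], 3.0)
        old["cytotoxic_t"] = _odds_shift(young["cytotoxic_t"], 5.0)
        old["naive_t"] = 1.0 - sum(
            v for k, v in old.items() if k not in ("naive_t",)
        )
        composition = {
            "young": np.array([young[t] for t in cell_types]),
            "old": np.array([old[t] for t in cell_types]),
        }
        return SyntheticSpec(
            n_cells_per_condition=4500,
            cell_types=cell_types,
            composition=composition,
            n_genes=len(gene_ids),
            marker_map={t: (marker_genes[t], 3.0) for t in cell_types},
            baseline_mean=means,
            nb_dispersion=disps,
            depth_distribution={
                "meanlog": float(np.log(1500)),
                "sdlog": 0.45,
                "condition_scale": {"young": 1.0, "old": 1.25},
            },
            mito_genes=mito_ids,
            mito_fraction=0.04,
            gene_ids=gene_ids,
        )

    # organoid7
    cell_types = [
        "stem",
        "ta",
        "enterocyte",
        "goblet",
        "paneth",
        "enteroendocrine",
        "tuft",
    ]
    special = {"stem": "Lgr5", "goblet": "Muc2", "paneth": "Lyz1"}
    marker_genes = _marker_names(cell_types, 8, special)
    gene_ids, means, disps, mito_ids = _base_gene_panel(
        rng, cell_types, marker_genes, n_filler=900
    )
    control = {
        "stem": 0.22,
        "ta": 0.20,
        "enterocyte": 0.28,
        "goblet": 0.08,
        "paneth": 0.08,
        "enteroendocrine": 0.07,
        "tuft": 0.07,
    }
    odds = control["goblet"] / (1 - control["goblet"]) * 3.0
    treated = dict(control)
    treated["goblet"] = odds / (1 + odds)
    treated["enterocyte"] = 1.0 - sum(
        v for k, v in treated.items() if k != "enterocyte"
    )
    composition = {
        "control": np.array([control[t] for t in cell_types]),
        "ifng": np.array([treated[t] for t in cell_types]),
    }
    return SyntheticSpec(
        n_cells_per_condition=2000,
        cell_types=cell_types,
        composition=composition,
        n_genes=len(gene_ids),
        marker_map={t: (marker_genes[t], 3.0) for t in cell_types},
        baseline_mean=means,
        nb_dispersion=disps,
        depth_distribution={
            "meanlog": float(np.log(1500)),
            "sdlog": 0.45,
            "condition_scale": {"control": 1.0, "ifng": 1.15},
        },
        mito_genes=mito_ids,
        mito_fraction=0.05,
        gene_ids=gene_ids,
    )


def marker_reference(spec: SyntheticSpec) -> GeneSetCollection:
    """The preset's marker gene sets, as used for cluster annotation."""
    return GeneSetCollection(
        {t: list(genes) for t, (genes, _) in spec.marker_map.items()}
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_cell_types(
    spec: SyntheticSpec, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (cell_ids, cell_type, condition) without generating counts.

    This is the composition layer of :func:`simulate_counts`; both share the
    same draw so truth labels line up.
    """
    rng = np.random.default_rng(seed)
    types, conds = [], []
    for cond in spec.conditions:
        probs = spec.composition[cond]
        idx = rng.choice(len(spec.cell_types), size=spec.n_cells_per_condition, p=probs)
        types.append(np.array(spec.cell_types, dtype=object)[idx])
        conds.append(np.full(spec.n_cells_per_condition, cond, dtype=object))
    cell_type = np.concatenate(types) if types else np.array([], dtype=object)
    condition = np.concatenate(conds) if conds else np.array([], dtype=object)
    cell_ids = np.array(
        [f"cell{i:06d}" for i in range(len(cell_type))], dtype=object
    )
    return cell_ids, cell_type, condition


def simulate_counts(
    spec: SyntheticSpec, seed: int
) -> tuple[UmiMatrix, GroundTruth]:
    """Generate a UMI matrix and its ground truth, deterministic given seed."""
    rng = np.random.default_rng(seed)
    cell_ids, cell_type, condition = simulate_cell_types(spec, seed)
    n_cells = len(cell_ids)
    gene_ids = np.array(spec.gene_ids, dtype=object)
    n_genes = spec.n_genes
    mito_mask = np.isin(gene_ids, np.array(spec.mito_genes, dtype=object))
    type_index = {t: i for i, t in enumerate(spec.cell_types)}
    two_conditions = len(spec.conditions) == 2

    if n_cells == 0:
        empty = sp.csr_matrix((0, n_genes), dtype=np.int64)
        truth = GroundTruth(
            cell_ids=cell_ids,
            cell_type=cell_type,
            condition=condition,
            sample=condition.copy(),
            latent=np.array([]),
            true_odds_ratios=spec.true_odds_ratios() if two_conditions else {},
            marker_map=spec.marker_map,
        )
        m = UmiMatrix(
            counts=empty,
            cell_ids=cell_ids,
            gene_ids=gene_ids,
            mito_flags=mito_mask,
            sample_label=condition.copy(),
            condition_label=condition,
        )
        return m, truth

    # per-cell depth (log-normal, condition-scaled)
    dd = spec.depth_distribution
    scale = np.array(
        [dd.get("condition_scale", {}).get(c, 1.0) for c in condition]
    )
    depth = np.maximum(
        1,
        np.round(
            rng.lognormal(mean=dd["meanlog"], sigma=dd["sdlog"], size=n_cells) * scale
        ).astype(np.int64),
    )

    # mito routing: Beta-jittered fraction of each cell's depth
    if spec.mito_fraction > 0 and mito_mask.any():
        conc = spec.mito_beta_concentration
        a = spec.mito_fraction * conc
        b = (1 - spec.mito_fraction) * conc
        frac = rng.beta(a, b, size=n_cells)
        d_mito = rng.binomial(depth, frac)
    else:
        d_mito = np.zeros(n_cells, dtype=np.int64)
    d_rest = depth - d_mito

    # log2 rate matrix: baseline + marker fold-changes + latent axis +
    # condition-specific gene-set shifts
    log2_base = np.log2(spec.baseline_mean)
    type_lfc = np.zeros((len(spec.cell_types), n_genes))
    gene_pos = {g: j for j, g in enumerate(gene_ids)}
    for t, (genes, lfc) in spec.marker_map.items():
        cols = [gene_pos[g] for g in genes]
        type_lfc[type_index[t], cols] += lfc

    latent = np.full(n_cells, np.nan)
    latent_term = np.zeros((n_cells, 1))
    loadings = np.zeros(n_genes)
    if spec.latent_axis is not None:
        la = spec.latent_axis
        affected = np.isin(cell_type, np.array(la.affected_types, dtype=object))
        shift = np.array([la.condition_shift.get(c, 0.0) for c in condition])
        u = rng.normal(loc=shift, scale=1.0, size=n_cells)
        latent[affected] = u[affected]
        for g, l in la.gene_loadings.items():
            loadings[gene_pos[g]] = l
        latent_term = np.where(affected, u, 0.0)[:, None]

    cond_shift = np.zeros((n_cells, n_genes))
    for genes, cond, delta in spec.geneset_shifts:
        rows = condition == cond
        cols = [gene_pos[g] for g in genes if g in gene_pos]
        cond_shift[np.ix_(rows, cols)] += delta

    t_idx = np.array([type_index[t] for t in cell_type])
    log2_rate = (
        log2_base[None, :]
        + type_lfc[t_idx]
        + latent_term * loadings[None, :]
        + cond_shift
    )
    rate = np.exp2(log2_rate)

    # gamma overdispersion factor per cell/gene: mean 1, variance alpha_g
    alpha = spec.nb_dispersion
    gamma = np.ones_like(rate)
    pos = alpha > 0
    if pos.any():
        shape = 1.0 / alpha[pos]
        gamma[:, pos] = rng.gamma(shape=shape[None, :], scale=alpha[pos][None, :],
                                  size=(n_cells, int(pos.sum())))
    w = rate * gamma

    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    nonmito_idx = np.flatnonzero(~mito_mask)
    mito_idx = np.flatnonzero(mito_mask)
    for i in range(n_cells):
        wi = w[i, nonmito_idx]
        counts[i, nonmito_idx] = rng.multinomial(d_rest[i], wi / wi.sum())
        if d_mito[i] > 0 and len(mito_idx):
            wm = w[i, mito_idx]
            counts[i, mito_idx] = rng.multinomial(d_mito[i], wm / wm.sum())

    m = UmiMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        mito_flags=mito_mask,
        sample_label=condition.copy(),
        condition_label=condition,
    )
    truth = GroundTruth(
        cell_ids=cell_ids,
        cell_type=cell_type,
        condition=condition,
        sample=condition.copy(),
        latent=latent,
        true_odds_ratios=spec.true_odds_ratios() if two_conditions else {},
        marker_map=spec.marker_map,
    )
    return m, truth


def simulate_hashtags(
    truth: GroundTruth,
    n_tags: int = 4,
    reads_per_cell: dict | None = None,
    doublet_rate: float = 0.05,
    low_signal_rate: float = 0.02,
    background_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[HashtagCounts, GroundTruth]:
    """Generate per-cell hashtag read counts with doublet contamination.

    Singlet cells concentrate ``1 - background_fraction`` of their hashtag
    reads on their true tag (background spread uniformly over all tags);
    doublets split the signal between two tags (each share drawn uniform in
    [0.35, 0.65]); low-signal cells receive fewer than 10 reads in total.
    """
    if not 0 <= doublet_rate <= 1 or not 0 <= low_signal_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if background_fraction >= 0.5:
        raise ValueError(
            "background_fraction >= 0.5 makes the signal unidentifiable"
        )
    if background_fraction < 0:
        raise ValueError("background_fraction must be >= 0")
    if n_tags < 1:
        raise ValueError("need at least one tag")
    if reads_per_cell is None:
        reads_per_cell = {"meanlog": float(np.log(200)), "sdlog": 0.5}
    rng = np.random.default_rng(seed)
    n = len(truth)
    tag_names = [f"tag{j + 1}" for j in range(n_tags)]

    # true tag follows the sample of origin (round-robin over unique samples)
    uniq = sorted(set(truth.sample))
    sample_tag = {s: j % n_tags for j, s in enumerate(uniq)}
    true_tag_idx = np.array([sample_tag[s] for s in truth.sample], dtype=int)

    is_doublet = rng.random(n) < doublet_rate
    is_low = (~is_doublet) & (rng.random(n) < low_signal_rate)

    totals = np.maximum(
        1,
        np.round(
            rng.lognormal(reads_per_cell["meanlog"], reads_per_cell["sdlog"], size=n)
        ).astype(np.int64),
    )
    totals[is_low] = rng.integers(0, 10, size=int(is_low.sum()))

    probs = np.full((n, n_tags), background_fraction / n_tags)
    signal = 1.0 - background_fraction
    second = (true_tag_idx + rng.integers(1, max(n_tags, 2), size=n)) % n_tags
    share = rng.uniform(0.35, 0.65, size=n)
    rows = np.arange(n)
    probs[rows, true_tag_idx] += np.where(is_doublet, signal * share, signal)
    add_second = is_doublet & (second != true_tag_idx)
    probs[rows[add_second], second[add_second]] += (
        signal * (1 - share[add_second])
    )
    # doublet whose partner drew the same tag (only possible when n_tags == 1)
    same = is_doublet & (second == true_tag_idx)
    probs[rows[same], true_tag_idx[same]] += signal * (1 - share[same])
    probs /= probs.sum(axis=1, keepdims=True)

    counts = np.empty((n, n_tags), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(totals[i], probs[i])

    hashtags = HashtagCounts(
        counts=counts, tag_names=tag_names, cell_ids=truth.cell_ids.copy()
    )
    updated = replace(
        truth,
        hashtag=np.array([tag_names[j] for j in true_tag_idx], dtype=object),
        is_doublet=is_doublet,
        is_low_signal=is_low,
    )
    return hashtags, updated


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------


def write_dataset(
    m: UmiMatrix,
    truth: GroundTruth,
    hashtags: HashtagCounts | None,
    spec: SyntheticSpec,
    out_dir: str | Path,
) -> None:
    """Write matrix triplet, hashtags.tsv, truth.tsv, and spec.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_10x_triplet(m, out)
    if hashtags is not None:
        hashtags.to_frame().to_csv(out / "hashtags.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    spec.to_yaml(out / "spec.yaml")
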