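"""Synthetic RNA-seq data with known ground truth.

Generates everything the downstream stages consume — two-group count
matrices, a 7-cell-type reference transcriptome with an ID map, and a
category annotation map — with the planted truth recorded so recovery can be
measured.  The defaults emulate the study design this pipeline targets:
negative-binomial counts with 4 replicates per group, moderate library-size
variation, a 5% planted fraction of differentially expressed (DE) genes at
|log2FC| = 2, one annotation category enriched 5-fold for DE genes, and a
cell-type reference over the seven canonical CNS populations.

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
call, so outputs are bit-identical for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .de import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CNS_CELL_TYPES",
    "simulate_counts",
    "simulate_celltype_reference",
    "simulate_annotation",
]

CNS_CELL_TYPES = (
    "astrocytes",
    "neurons",
    "endothelial",
    "microglia",
    "OPC",
    "newly_formed_oligodendrocytes",
    "myelinating_oligodendrocytes",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    ``mean_log_expression`` is the natural-log location of the log-normal
    gene-mean distribution (scale fixed at 1); ``dispersion`` is the NB
    dispersion phi in Var = mu + phi*mu^2; ``library_size_cv`` the
    coefficient of variation of per-sample depth multipliers.
    """

    n_genes: int = 5000
    n_replicates_per_group: int = 4
    mean_log_expression: float = 4.0
    dispersion: float = 0.1
    library_size_cv: float = 0.2
    fraction_de: float = 0.05
    lfc_magnitude: float = 2.0
    n_cell_types: int = 7
    marker_fraction: float = 0.2
    below_background_fraction: float = 0.05
    unmapped_fraction: float = 0.05
    n_categories: int = 20
    n_enriched_categories: int = 1
    enriched_category_fold: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive_ints = (
            "n_genes", "n_replicates_per_group", "n_cell_types",
            "n_categories", "n_enriched_categories",
        )
        for name in positive_ints:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("fraction_de", "marker_fraction",
                     "below_background_fraction", "unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be non-negative, got {self.dispersion!r}")
        if self.library_size_cv < 0:
            raise ValueError(
                f"library_size_cv must be non-negative, got {self.library_size_cv!r}"
            )
        if self.lfc_magnitude <= 0:
            raise ValueError(f"lfc_magnitude must be positive, got {self.lfc_magnitude!r}")
        if self.enriched_category_fold < 1:
            raise ValueError(
                f"enriched_category_fold must be >= 1, got {self.enriched_category_fold!r}"
            )
        if self.n_enriched_categories > self.n_categories:
            raise ValueError("n_enriched_categories exceeds n_categories")

    def replace(self, **kwargs) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)


@dataclass
class SyntheticTruth:
    """Planted ground truth; fields are filled by the generator that knows them."""

    gene_ids: pd.Index
    de_flags: pd.Series | None = None          # bool per gene
    true_lfc: pd.Series | None = None          # log2, 0 where not DE
    gene_means: pd.Series | None = None        # control-group NB mean per gene
    marker_celltype: pd.Series | None = None   # cell-type label or None per gene
    below_background: pd.Series | None = None  # bool per gene
    enriched_categories: set = field(default_factory=set)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        if not self.gene_ids.equals(other.gene_ids):
            raise ValueError("cannot merge truths over different gene sets")
        out = SyntheticTruth(self.gene_ids)
        for name in ("de_flags", "true_lfc", "gene_means", "marker_celltype", "below_background"):
            out_val = getattr(other, name)
            setattr(out, name, out_val if out_val is not None else getattr(self, name))
        out.enriched_categories = self.enriched_categories | other.enriched_categories
        return out


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i:06d}" for i in range(1, n + 1)], name="gene_id")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _size_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=n)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Simulate an injured and an age-matched control count matrix.

    Gene means are log-normal; per-sample depth multipliers are log-normal
    with the configured CV; a ``fraction_de`` subset of genes carries a
    planted log2 fold change of magnitude ``lfc_magnitude`` in the injured
    group, signs split evenly up/down.  Counts are NB draws with mean
    mu_g * s_j * 2^(lfc_g) in the injured group.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_rep = config.n_replicates_per_group

    mu = rng.lognormal(config.mean_log_expression, 1.0, size=config.n_genes)

    n_de = int(round(config.fraction_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[1::2] = -1.0
    signs = rng.permutation(signs)
    true_lfc = np.zeros(config.n_genes)
    true_lfc[de_idx] = signs * config.lfc_magnitude
    de_flags = true_lfc != 0

    s = _size_factors(rng, 2 * n_rep, config.library_size_cv)
    s_inj, s_ctl = s[:n_rep], s[n_rep:]

    inj_mean = mu[:, None] * s_inj[None, :] * (2.0 ** true_lfc)[:, None]
    ctl_mean = mu[:, None] * s_ctl[None, :]
    inj_counts = _nb_draw(rng, inj_mean, config.dispersion)
    ctl_counts = _nb_draw(rng, ctl_mean, config.dispersion)

    inj_samples = [f"injured_{i+1}" for i in range(n_rep)]
    ctl_samples = [f"control_{i+1}" for i in range(n_rep)]
    injured = CountMatrix(
        counts=pd.DataFrame(inj_counts, index=genes, columns=inj_samples),
        groups=pd.Series("injured", index=inj_samples),
    )
    control = CountMatrix(
        counts=pd.DataFrame(ctl_counts, index=genes, columns=ctl_samples),
        groups=pd.Series("control", index=ctl_samples),
    )
    truth = SyntheticTruth(
        gene_ids=genes,
        de_flags=pd.Series(de_flags, index=genes),
        true_lfc=pd.Series(true_lfc, index=genes),
        gene_means=pd.Series(mu, index=genes),
    )
    return injured, control, truth


def simulate_celltype_reference(config: SimulationConfig):
    """Simulate a cell-type reference transcriptome plus ID map.

    Marker genes concentrate >= 90% of their reference expression in one cell
    type (95% planted); non-markers are near-uniform across cell types; a
    ``below_background_fraction`` of genes sits below 0.1 FPKM in every cell
    type; an ``unmapped_fraction`` of source IDs is withheld from the ID map.

    Returns ``(CellTypeReference, SyntheticTruth)`` with ``marker_celltype``
    and ``below_background`` populated.
    """
    from .celltype import CellTypeReference  # local import to avoid a cycle

    if config.n_cell_types < 2:
        raise ValueError(f"n_cell_types must be >= 2, got {config.n_cell_types}")
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_ids(config.n_genes)
    k = config.n_cell_types
    cell_types = (
        list(CNS_CELL_TYPES) if k == 7 else [f"celltype_{i+1}" for i in range(k)]
    )

    n = config.n_genes
    n_below = int(round(config.below_background_fraction * n))
    below_idx = rng.choice(n, size=n_below, replace=False)
    below = np.zeros(n, dtype=bool)
    below[below_idx] = True

    eligible = np.flatnonzero(~below)
    n_marker = int(round(config.marker_fraction * n))
    n_marker = min(n_marker, len(eligible))
    marker_idx = rng.choice(eligible, size=n_marker, replace=False)
    marker_ct = rng.integers(0, k, size=n_marker)

    base = rng.lognormal(2.0, 1.0, size=n)
    expr = rng.dirichlet(np.full(k, 50.0), size=n) * (base * k)[:, None]
    for i, ct in zip(marker_idx, marker_ct):
        w = np.full(k, 0.05 / (k - 1))
        w[ct] = 0.95
        expr[i] = base[i] * k * w
    expr[below] = rng.uniform(0.0, 0.08, size=(n_below, k))

    ref_ids = pd.Index([f"REF_{g}" for g in genes], name="reference_id")
    expression = pd.DataFrame(expr, index=ref_ids, columns=cell_types)

    n_unmapped = int(round(config.unmapped_fraction * n))
    unmapped_idx = set(rng.choice(n, size=n_unmapped, replace=False).tolist())
    id_map = pd.DataFrame(
        [
            (g, f"REF_{g}")
            for i, g in enumerate(genes)
            if i not in unmapped_idx
        ],
        columns=["source_id", "reference_id"],
    )

    marker_labels = pd.Series([None] * n, index=genes, dtype=object)
    for i, ct in zip(marker_idx, marker_ct):
        marker_labels.iloc[i] = cell_types[ct]

    truth = SyntheticTruth(
        gene_ids=genes,
        marker_celltype=marker_labels,
        below_background=pd.Series(below, index=genes),
    )
    return CellTypeReference(expression=expression, id_map=id_map), truth


def simulate_annotation(config: SimulationConfig, truth: SyntheticTruth):
    """Simulate an annotation map with planted enriched categories.

    Categories are sampled independently over the full gene universe (genes
    may belong to several).  Each enriched category receives DE genes at
    ``enriched_category_fold`` times the global DE rate; the enriched
    category IDs are added to ``truth.enriched_categories`` in place.
    """
    from .enrich import AnnotationMap  # local import to avoid a cycle

    if truth.de_flags is None:
        raise ValueError("truth.de_flags required to plant enrichment")
    rng = np.random.default_rng(config.seed + 2)
    genes = np.asarray(truth.gene_ids)
    n = len(genes)
    de_mask = truth.de_flags.to_numpy()
    de_genes = genes[de_mask]
    other_genes = genes[~de_mask]
    global_rate = de_mask.mean()

    lo = max(2, n // 100)
    hi = max(lo + 1, n // 10)
    categories: dict[str, set] = {}
    names: dict[str, str] = {}
    enriched_ids = [f"CAT{i:03d}" for i in range(1, config.n_enriched_categories + 1)]
    for c in range(1, config.n_categories + 1):
        cat_id = f"CAT{c:03d}"
        size = int(rng.integers(lo, hi + 1))
        if cat_id in enriched_ids and global_rate > 0:
            target_rate = min(1.0, config.enriched_category_fold * global_rate)
            n_de = min(int(round(size * target_rate)), len(de_genes))
            n_bg = min(size - n_de, len(other_genes))
            members = set(rng.choice(de_genes, size=n_de, replace=False))
            members |= set(rng.choice(other_genes, size=n_bg, replace=False))
        else:
            members = set(rng.choice(genes, size=min(size, n), replace=False))
        if not members:
            raise ValueError(f"category {cat_id} would be empty")
        categories[cat_id] = members
        names[cat_id] = f"synthetic category {c}"
    truth.enriched_categories |= set(enriched_ids)
    return AnnotationMap(
        categories=categories, names=names, reference_genes=set(genes)
    )
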