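"""Consensus calling across DE scorers and gene-set algebra.

A gene enters the consensus set for a contrast when at least ``min_support``
of the three scorers call it significant (padj and |log2FC| thresholds) with
concordant direction; its reported fold change is the mean over the scorers
that called it, ignoring non-significant scorers.  Cross-time-point and
cross-age comparisons are plain set algebra over the resulting gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .de import DEResult

__all__ = [
    "Thresholds",
    "ConsensusGeneSet",
    "threshold_filter",
    "vote",
    "venn_counts",
    "shared_fraction",
    "unique_genes",
    "sets_from_overlap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Significance cutoffs; inclusive mode uses padj <= and |log2FC| >=."""

    padj_max: float = 0.05
    abs_log2fc_min: float = 1.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.padj_max <= 1.0:
            raise ValueError(f"padj_max must lie in (0, 1], got {self.padj_max!r}")
        if self.abs_log2fc_min < 0:
            raise ValueError(
                f"abs_log2fc_min must be non-negative, got {self.abs_log2fc_min!r}"
            )


@dataclass
class ConsensusGeneSet:
    """Genes supported by >= min_support scorers for one labeled contrast.

    ``table`` columns: support (int), avg_log2fc, direction (+1/-1); indexed
    by gene ID.
    """

    label: str
    table: pd.DataFrame
    min_support: int = 2
    conflicts: list = field(default_factory=list)

    @property
    def genes(self) -> set:
        return set(self.table.index)

    def direction(self, gene: str) -> int:
        return int(self.table.loc[gene, "direction"])


def threshold_filter(result: DEResult, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Genes passing the padj and |log2FC| cutoffs for one scorer.

    Returns a frame with columns log2FC and direction, indexed by gene ID.
    """
    if "padj" not in result.table.columns:
        raise ValueError(f"DEResult {result.method_id!r} has no padj column")
    tab = result.table
    if thresholds.inclusive:
        keep = (tab["padj"] <= thresholds.padj_max) & (
            tab["log2FC"].abs() >= thresholds.abs_log2fc_min
        )
    else:
        keep = (tab["padj"] < thresholds.padj_max) & (
            tab["log2FC"].abs() > thresholds.abs_log2fc_min
        )
    out = tab.loc[keep, ["log2FC"]].copy()
    out["direction"] = out["log2FC"].apply(lambda x: 1 if x > 0 else -1)
    return out


def vote(
    filtered: dict[str, pd.DataFrame],
    min_support: int = 2,
    label: str = "",
) -> ConsensusGeneSet:
    """Combine per-scorer significant sets by >= min_support voting.

    ``filtered`` maps scorer ID to the output of :func:`threshold_filter`.
    Genes whose supporting scorers disagree in direction are excluded and
    logged.  avg_log2fc is the mean of the significant scorers' fold changes.
    """
    if not 1 <= min_support:
        raise ValueError("min_support must be >= 1")
    if len(filtered) < 2 and min_support > 1:
        raise ValueError("need at least two scorer sets to vote")
    rows = []
    conflicts = []
    all_genes = set().union(*(set(f.index) for f in filtered.values())) if filtered else set()
    for gene in all_genes:
        calls = [
            (sid, f.loc[gene, "log2FC"])
            for sid, f in filtered.items()
            if gene in f.index
        ]
        if len(calls) < min_support:
            continue
        dirs = {1 if lfc > 0 else -1 for _, lfc in calls}
        if len(dirs) > 1:
            conflicts.append(gene)
            logger.warning("sign conflict for gene %s among supporters; excluded", gene)
            continue
        avg = sum(lfc for _, lfc in calls) / len(calls)
        rows.append((gene, len(calls), avg, 1 if avg > 0 else -1))
    table = pd.DataFrame(
        rows, columns=["gene_id", "support", "avg_log2fc", "direction"]
    ).set_index("gene_id").sort_index()
    return ConsensusGeneSet(
        label=label, table=table, min_support=min_support, conflicts=sorted(conflicts)
    )


def venn_counts(sets: dict[str, set]) -> dict:
    """Exact region cardinalities for 2 or 3 labeled sets.

    Returns a dict keyed by frozensets of labels (the labels whose sets a
    region's elements belong to, and no others) plus ``"union"``.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 sets")
    labels = list(sets)
    union = set().union(*sets.values())
    regions: dict = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set().union(*(sets[l] for l in labels if l not in combo), set())
            regions[frozenset(combo)] = len(inside - outside)
    regions["union"] = len(union)
    return regions


def shared_fraction(a: set, b: set) -> int:
    """Percentage of ``a`` also in ``b``, to the nearest integer percent."""
    if not a:
        raise ValueError("first set is empty")
    return int(round(100.0 * len(a & b) / len(a)))


def unique_genes(a: set, b: set) -> set:
    """Genes in ``a`` but not ``b`` (e.g. one injury age minus the other)."""
    return set(a) - set(b)


def sets_from_overlap(size_a: int, size_b: int, overlap: int,
                      labels: tuple[str, str] = ("A", "B")) -> dict[str, set]:
    """Construct two labeled placeholder sets with given sizes and overlap.

    Lets printed Venn cardinalities be fed back through the set algebra.
    """
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds a set size")
    shared = {f"shared_{i}" for i in range(overlap)}
    a = shared | {f"a_{i}" for i in range(size_a - overlap)}
    b = shared | {f"b_{i}" for i in range(size_b - overlap)}
    return {labels[0]: a, labels[1]: b}
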