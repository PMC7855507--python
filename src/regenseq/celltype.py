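"""Cell-type association of gene sets against a CNS reference transcriptome.

Consensus genes are mapped onto a reference giving each gene's expression in
seven CNS cell types (astrocytes, neurons, endothelial cells, microglia,
OPCs, newly formed and myelinating oligodendrocytes), background-filtered at
0.1 FPKM, expressed as percentage-of-sum profiles, clustered hierarchically
within time-point groups, and ranked for the most strongly regulated genes
unique to one injury age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellTypeReference",
    "ClusterResult",
    "map_ids",
    "background_filter",
    "percentage_profile",
    "percentage_profiles",
    "correlation_distance_matrix",
    "cluster_profiles",
    "top_unique",
    "BACKGROUND_FPKM",
]

logger = logging.getLogger(__name__)

BACKGROUND_FPKM = 0.1


@dataclass
class CellTypeReference:
    """Reference expression (FPKM) per cell type plus a source->reference ID map.

    ``expression`` is indexed by reference ID with one column per cell type;
    ``id_map`` has columns source_id, reference_id and may map one source ID
    to several reference rows.
    """

    expression: pd.DataFrame
    id_map: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("reference expression values must be non-negative")
        required = {"source_id", "reference_id"}
        if not required <= set(self.id_map.columns):
            raise ValueError("id_map needs source_id and reference_id columns")

    @property
    def cell_types(self) -> list[str]:
        return list(self.expression.columns)


def map_ids(genes: set, ref: CellTypeReference) -> tuple[pd.Series, list]:
    """Map source gene IDs to reference rows; report unmappable genes.

    Returns (mapping, dropped): a Series source_id -> reference_id for every
    retained gene, and the sorted list of genes with no mapping.  A source ID
    mapping to several reference rows resolves to the row with the largest
    total expression (logged).
    """
    if ref.id_map.empty:
        raise ValueError("id_map is empty")
    lookup = ref.id_map.groupby("source_id")["reference_id"].apply(list)
    totals = ref.expression.sum(axis=1)
    mapped: dict[str, str] = {}
    dropped: list = []
    for gene in sorted(genes):
        targets = lookup.get(gene)
        if targets is None:
            dropped.append(gene)
            continue
        targets = [t for t in targets if t in ref.expression.index]
        if not targets:
            dropped.append(gene)
            continue
        if len(targets) > 1:
            targets = sorted(targets, key=lambda t: (-totals[t], t))
            logger.info(
                "source ID %s maps to %d reference rows; kept %s (largest total)",
                gene, len(targets), targets[0],
            )
        mapped[gene] = targets[0]
    if dropped:
        logger.warning("%d gene IDs had no reference mapping", len(dropped))
    return pd.Series(mapped, dtype=object), dropped


def background_filter(
    mapping: pd.Series,
    ref: CellTypeReference,
    threshold: float = BACKGROUND_FPKM,
) -> tuple[pd.Series, list]:
    """Drop genes whose reference expression never rises above ``threshold``.

    The maximum over cell types must strictly exceed the threshold.  Returns
    (retained mapping, excluded source IDs).
    """
    rows = ref.expression.loc[mapping.to_numpy()]
    keep = (rows.max(axis=1) > threshold).to_numpy()
    excluded = sorted(mapping.index[~keep])
    if excluded:
        logger.warning("%d genes at or below background %.3g excluded", len(excluded), threshold)
    return mapping[keep], excluded


def percentage_profile(values: np.ndarray | pd.Series) -> np.ndarray:
    """One gene's expression as percentages of its sum across cell types."""
    v = np.asarray(values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot form a percentage profile from a zero-sum row")
    return 100.0 * v / total


def percentage_profiles(mapping: pd.Series, ref: CellTypeReference) -> pd.DataFrame:
    """Percentage-of-sum profiles for mapped, background-passing genes.

    Indexed by source ID, one column per cell type; every row sums to 100.
    """
    rows = ref.expression.loc[mapping.to_numpy()].to_numpy(dtype=float)
    sums = rows.sum(axis=1)
    if (sums <= 0).any():
        bad = mapping.index[sums <= 0].tolist()
        raise ValueError(f"zero-sum reference rows for genes: {bad}")
    return pd.DataFrame(
        100.0 * rows / sums[:, None], index=mapping.index, columns=ref.cell_types
    )


# ---------------------------------------------------------------------------
# hierarchical clustering (average linkage, correlation distance)
# ---------------------------------------------------------------------------

def correlation_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows.

    Constant rows have undefined correlation; the distance is defined as 0
    between two constant rows and 1 between a constant and a varying row.
    """
    x = profiles.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    d = 1.0 - unit @ unit.T
    flat = norms == 0
    if flat.any():
        d[flat, :] = 1.0
        d[:, flat] = 1.0
        d[np.ix_(flat, flat)] = 0.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterResult:
    """Deterministic agglomeration of one time-point block."""

    order: list                       # leaf IDs, left to right
    merges: list = field(default_factory=list)  # (members_left, members_right, distance)


def _agglomerate(ids: list, dist: np.ndarray) -> ClusterResult:
    """Average-linkage agglomeration with deterministic tie-breaking.

    Cluster-cluster distance is the mean pairwise distance over original
    members (UPGMA).  Ties in the merge distance are broken by the
    lexicographically smallest member IDs of the candidate pair; at each
    merge the subtree holding the smallest ID goes left.
    """
    n = len(ids)
    clusters: dict[int, list] = {i: [i] for i in range(n)}
    # current cluster-cluster mean distances
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    min_id = {i: ids[i] for i in range(n)}
    merges = []
    trees: dict[int, list] = {i: [ids[i]] for i in range(n)}
    next_key = n
    while len(clusters) > 1:
        best = None
        for pair, dd in d.items():
            i, j = sorted(pair, key=lambda k: min_id[k])
            key = (dd, min_id[i], min_id[j])
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _, _), i, j = best
        merge_dist = d[frozenset((i, j))]
        members = {i: clusters.pop(i), j: clusters.pop(j)}
        left, right = (i, j) if min_id[i] <= min_id[j] else (j, i)
        merges.append((
            [ids[m] for m in members[left]],
            [ids[m] for m in members[right]],
            merge_dist,
        ))
        new_members = members[i] + members[j]
        new_tree = trees.pop(left) + trees.pop(right)
        d = {p: v for p, v in d.items() if i not in p and j not in p}
        for k in clusters:
            d[frozenset((next_key, k))] = float(
                np.mean(dist[np.ix_(new_members, clusters[k])])
            )
        clusters[next_key] = new_members
        trees[next_key] = new_tree
        min_id[next_key] = min(min_id[i], min_id[j])
        next_key += 1
    (root,) = trees.values()
    return ClusterResult(order=root, merges=merges)


def cluster_profiles(
    profiles: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict[str, ClusterResult]:
    """Cluster percentage profiles hierarchically within time-point blocks.

    ``groups`` assigns each profile row to a block; a single block named
    "all" is used when omitted.  Blocks with one profile pass through;
    empty blocks are skipped with a log entry.
    """
    if groups is None:
        groups = pd.Series("all", index=profiles.index)
    results: dict[str, ClusterResult] = {}
    for label in pd.unique(groups):
        members = profiles.loc[groups[groups == label].index.intersection(profiles.index)]
        if members.empty:
            logger.info("time-point block %r is empty; skipped", label)
            continue
        if len(members) == 1:
            results[label] = ClusterResult(order=list(members.index))
            continue
        dist = correlation_distance_matrix(members)
        results[label] = _agglomerate(list(members.index), dist)
    return results


def top_unique(
    fold_changes: pd.Series,
    n: int = 10,
) -> tuple[pd.Series, pd.Series]:
    """Top up- and down-regulated genes of a unique set by |log2FC|.

    Returns (up, down): the ``n`` largest positive fold changes in descending
    order and the ``n`` most negative in ascending order; shorter lists are
    returned whole.  Ties break lexicographically by gene ID.
    """
    df = fold_changes.rename("avg_log2fc").rename_axis("gene_id").reset_index()
    up = df[df["avg_log2fc"] > 0].sort_values(
        ["avg_log2fc", "gene_id"], ascending=[False, True]
    ).head(n)
    down = df[df["avg_log2fc"] < 0].sort_values(
        ["avg_log2fc", "gene_id"], ascending=[True, True]
    ).head(n)
    return (
        up.set_index("gene_id")["avg_log2fc"],
        down.set_index("gene_id")["avg_log2fc"],
    )
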