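"""Category over/underrepresentation by binomial test with Bonferroni control.

For a study set of n genes and a category holding K of the N universe genes,
the number of study genes in the category is compared with Binomial(n, K/N):
p_over = P(X >= k) and p_under = P(X <= k); the reported p-value is the
smaller tail and the direction is that tail's.  Bonferroni multiplies by the
number of categories tested (capped at 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .consensus import ConsensusGeneSet

__all__ = [
    "AnnotationMap",
    "binomial_overrep",
    "bonferroni_adjust",
    "significant_categories",
    "extract_category_genes",
    "UNCLASSIFIED",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class AnnotationMap:
    """category_id -> gene set over a fixed reference universe."""

    categories: dict[str, set]
    reference_genes: set
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat_id, genes in self.categories.items():
            if not genes:
                raise ValueError(f"category {cat_id!r} is empty")
            stray = genes - self.reference_genes
            if stray:
                raise ValueError(
                    f"category {cat_id!r} contains genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def with_unclassified(self) -> "AnnotationMap":
        """Collect genes in no category into an 'unclassified' category."""
        classified = set().union(*self.categories.values())
        rest = self.reference_genes - classified
        if not rest:
            return self
        cats = dict(self.categories)
        cats[UNCLASSIFIED] = rest
        names = dict(self.names)
        names[UNCLASSIFIED] = UNCLASSIFIED
        return AnnotationMap(cats, self.reference_genes, names)


def binomial_overrep(study: set, ann: AnnotationMap) -> pd.DataFrame:
    """Binomial over/underrepresentation of a study set in each category.

    Study genes outside the reference universe are dropped with a warning.
    Columns: observed, study_size, expected, fold_enrichment, direction,
    pvalue; indexed by category_id.
    """
    if not study:
        raise ValueError("study set is empty")
    stray = set(study) - ann.reference_genes
    if stray:
        logger.warning(
            "%d study genes outside the reference universe dropped", len(stray)
        )
    kept = set(study) & ann.reference_genes
    if not kept:
        raise ValueError("no study gene is in the reference universe")
    n = len(kept)
    N = len(ann.reference_genes)
    rows = []
    for cat_id, members in ann.categories.items():
        K = len(members)
        k = len(kept & members)
        p = K / N
        p_over = float(binom.sf(k - 1, n, p))
        p_under = float(binom.cdf(k, n, p))
        direction = "over" if p_over <= p_under else "under"
        expected = n * p
        rows.append(
            (
                cat_id, k, n, expected,
                k / expected if expected > 0 else np.nan,
                direction, min(p_over, p_under),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category_id", "observed", "study_size", "expected",
            "fold_enrichment", "direction", "pvalue",
        ],
    ).set_index("category_id")


def bonferroni_adjust(results: pd.DataFrame, m: int | None = None) -> pd.DataFrame:
    """Add p_bonf = min(1, pvalue * m); m defaults to the categories tested."""
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(results):
        raise ValueError(f"m={m} is smaller than the {len(results)} tested categories")
    out = results.copy()
    out["p_bonf"] = np.minimum(1.0, out["pvalue"] * m)
    out.attrs["bonferroni_m"] = m
    logger.info("Bonferroni correction with m=%d", m)
    return out


def significant_categories(
    results: pd.DataFrame,
    alpha: float = 0.05,
    drop_unclassified: bool = True,
) -> pd.DataFrame:
    """Categories with p_bonf <= alpha, with a -log10(p_bonf) column.

    The synthetic 'unclassified' catch-all is removed when flagged.
    """
    if "p_bonf" not in results.columns:
        raise ValueError("results lack p_bonf; run bonferroni_adjust first")
    out = results.loc[results["p_bonf"] <= alpha].copy()
    if drop_unclassified and UNCLASSIFIED in out.index:
        out = out.drop(index=UNCLASSIFIED)
    with np.errstate(divide="ignore"):
        out["neg_log10_p_bonf"] = -np.log10(out["p_bonf"])
    return out.sort_values("p_bonf")


def extract_category_genes(
    category_id: str,
    ann: AnnotationMap,
    consensus_sets: list[ConsensusGeneSet],
) -> pd.DataFrame:
    """Per-gene fold-change table for one category across contrasts.

    Rows are category genes found in at least one consensus set; columns are
    the consensus labels; cells hold avg_log2fc or NaN where the gene was not
    called in that contrast.
    """
    if category_id not in ann.categories:
        raise ValueError(f"unknown category {category_id!r}")
    members = ann.categories[category_id]
    cols = {}
    for cs in consensus_sets:
        hit = members & cs.genes
        cols[cs.label] = cs.table.loc[sorted(hit), "avg_log2fc"]
    table = pd.DataFrame(cols)
    table = table.loc[table.notna().any(axis=1)].sort_index()
    table.index.name = "gene_id"
    return table
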