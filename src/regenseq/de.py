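"""Differential expression testing on count matrices.

Three scorers share one negative-binomial exact-test core and differ only in
how per-sample sequencing depth is normalized:

* ``UQ``   — upper-quartile size factors (75th percentile of each sample's
  counts over genes detected in at least one sample).
* ``MOR``  — median-of-ratios size factors (median over all-positive genes of
  the ratio of each sample's count to the per-gene geometric mean).
* ``FPKM`` — depth-rescaled FPKM pseudo-counts, which reduce algebraically to
  total-count size factors (FPKM times gene length times the geometric-mean
  depth over 1e9 equals the raw count scaled by geomean-depth/depth).

For each gene the test conditions on the total pseudo-count across both
groups: under the null the group-1 sum A and group-2 sum B are independent
negative binomials with sizes n1/phi and n2/phi (a sum of n i.i.d. NB(mu, phi)
variables is NB(n*mu, phi/n)), so the conditional law of A given A+B=T is
computed exactly by normalizing f1(a)*f2(T-a) over a = 0..T.  In the
dispersion-zero limit this is exactly the binomial conditional test with
success probability n1/(n1+n2).  Two-sided p-values double the smaller tail
(observed value included in both tails) and are capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "DEResult",
    "size_factors_upper_quartile",
    "size_factors_median_of_ratios",
    "size_factors_total_count",
    "fpkm_matrix",
    "estimate_dispersion",
    "nb_test",
    "adjust_bh",
    "run_de_suite",
]

DEFAULT_PSEUDO_COUNT = 1.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with sample IDs as columns; values must
        be non-negative integers.
    groups
        Series mapping each sample ID to its group label (e.g. "injured",
        "control").
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)) or np.isnan(values).any():
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def require_replicates(self, min_per_group: int = 2) -> None:
        sizes = self.groups.value_counts()
        small = sizes[sizes < min_per_group]
        if len(small):
            raise ValueError(
                f"groups with fewer than {min_per_group} samples: {small.index.tolist()}"
            )

    @staticmethod
    def concat(a: "CountMatrix", b: "CountMatrix") -> "CountMatrix":
        """Column-bind two matrices over the same genes."""
        if not a.counts.index.equals(b.counts.index):
            raise ValueError("gene IDs differ between matrices")
        return CountMatrix(
            counts=pd.concat([a.counts, b.counts], axis=1),
            groups=pd.concat([a.groups, b.groups]),
        )


@dataclass
class DEResult:
    """Per-gene scores from one DE scorer.

    ``table`` columns: base_mean, log2FC, pvalue and (after BH adjustment)
    padj; indexed by gene ID.  log2FC is injured over control.
    """

    method_id: str
    table: pd.DataFrame
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    extra: dict = field(default_factory=dict)

    def with_padj(self) -> "DEResult":
        tab = self.table.copy()
        tab["padj"] = adjust_bh(tab["pvalue"].to_numpy())
        return DEResult(self.method_id, tab, self.pseudo_count, dict(self.extra))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _rescale_unit_geomean(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def size_factors_upper_quartile(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Upper-quartile size factors, rescaled to unit geometric mean.

    The 75th percentile (linear interpolation between order statistics) is
    taken per sample over genes with a nonzero count in at least one sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    detected = mat.loc[mat.sum(axis=1) > 0]
    zero_samples = detected.columns[(detected != 0).sum(axis=0) == 0].tolist()
    if zero_samples:
        raise ValueError(f"samples with all-zero counts: {zero_samples}")
    uq = np.percentile(detected.to_numpy(), 75, axis=0)
    if (uq <= 0).any():
        bad = detected.columns[uq <= 0].tolist()
        raise ValueError(f"upper quartile is zero for samples: {bad}")
    return pd.Series(_rescale_unit_geomean(uq), index=mat.columns)


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the per-gene geometric mean.

    Reference genes are those with no zero count in any sample.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    positive = mat.loc[(mat > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has all-positive counts; cannot form the reference")
    logs = np.log(positive.to_numpy(dtype=float))
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=mat.columns)


def size_factors_total_count(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Total-count size factors (the FPKM scorer's normalization)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = mat.sum(axis=0).to_numpy(dtype=float)
    if (totals <= 0).any():
        bad = mat.columns[totals <= 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    return pd.Series(_rescale_unit_geomean(totals), index=mat.columns)


def fpkm_matrix(counts: CountMatrix | pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    FPKM_gj = count_gj * 1e9 / (length_g * total_j).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    missing = mat.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without a length: {missing.tolist()[:10]}")
    lens = lengths.reindex(mat.index).to_numpy(dtype=float)
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = mat.sum(axis=0).to_numpy(dtype=float)
    return pd.DataFrame(
        mat.to_numpy(dtype=float) * 1e9 / (lens[:, None] * totals[None, :]),
        index=mat.index,
        columns=mat.columns,
    )


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: CountMatrix,
    factors: pd.Series,
    shrink: bool = True,
    shrink_weight: float = 0.5,
    n_bins: int = 10,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene on normalized counts.

    Within each group, phi_k = max(0, var - mean) / mean^2; estimates are
    pooled across groups with degrees-of-freedom weights.  With ``shrink``
    the raw estimate is averaged 50/50 with the mean dispersion of genes in
    the same expression decile, which stabilizes small-replicate estimates.
    """
    counts.require_replicates(2)
    q = counts.counts.to_numpy(dtype=float) / factors.reindex(counts.sample_ids).to_numpy()
    groups = counts.groups.to_numpy()
    num = np.zeros(q.shape[0])
    den = 0.0
    for g in np.unique(groups):
        sub = q[:, groups == g]
        n_k = sub.shape[1]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_k = np.where(m > 0, np.maximum(0.0, v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n_k - 1) * phi_k
        den += n_k - 1
    raw = num / den
    if not shrink:
        return pd.Series(raw, index=counts.gene_ids)
    base_mean = q.mean(axis=1)
    order = np.argsort(base_mean, kind="mergesort")
    bins = np.empty(len(base_mean), dtype=int)
    bins[order] = np.minimum((np.arange(len(base_mean)) * n_bins) // max(len(base_mean), 1), n_bins - 1)
    trend = np.zeros(n_bins)
    for b in range(n_bins):
        mask = bins == b
        trend[b] = raw[mask].mean() if mask.any() else 0.0
    shrunk = (1 - shrink_weight) * raw + shrink_weight * trend[bins]
    return pd.Series(shrunk, index=counts.gene_ids)


# ---------------------------------------------------------------------------
# exact test core
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    """log PMF of NB with given mean and size (size -> inf is Poisson)."""
    if not math.isfinite(size):
        return k * math.log(mean) - mean - gammaln(k + 1.0)
    log_p = math.log(size) - math.log(size + mean)
    log_q = math.log(mean) - math.log(size + mean)
    return gammaln(k + size) - gammaln(size) - gammaln(k + 1.0) + size * log_p + k * log_q


def exact_conditional_pvalue(
    a_obs: int, total: int, n1: int, n2: int, dispersion: float
) -> float:
    """Two-sided exact conditional p-value for group-1 sum ``a_obs``.

    Conditions on the total ``a_obs + b_obs`` of the two group sums, each a
    negative binomial with common per-sample mean and per-sample dispersion
    ``dispersion``; doubles the smaller tail, capped at 1.
    """
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    a = np.arange(total + 1)
    if dispersion <= 0:
        size1 = size2 = math.inf
    else:
        size1 = n1 / dispersion
        size2 = n2 / dispersion
    logp = _nb_logpmf(a, n1 * mu, size1) + _nb_logpmf(total - a, n2 * mu, size2)
    logp -= logsumexp(logp)
    p = np.exp(logp)
    p_low = p[: a_obs + 1].sum()
    p_high = p[a_obs:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def nb_test(
    counts: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    method_id: str = "NB",
    test_group: str | None = None,
) -> DEResult:
    """Exact NB conditional test for a two-group comparison.

    Per-gene pseudo-counts (counts divided by size factors, rounded) are
    summed within groups; the conditional distribution of the test group's
    sum given the total yields the two-sided p-value.  log2FC compares mean
    normalized counts with ``pseudo_count`` added to each group mean.
    """
    labels = counts.group_labels()
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if test_group is None:
        test_group = labels[0]
    other = [g for g in labels if g != test_group][0]
    fac = factors.reindex(counts.sample_ids).to_numpy()
    q = counts.counts.to_numpy(dtype=float) / fac
    mask1 = (counts.groups == test_group).to_numpy()
    mask2 = (counts.groups == other).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    pseudo = np.rint(q).astype(np.int64)
    a_sums = pseudo[:, mask1].sum(axis=1)
    totals = a_sums + pseudo[:, mask2].sum(axis=1)
    disp = dispersions.reindex(counts.gene_ids).to_numpy()
    pvals = np.array(
        [
            exact_conditional_pvalue(int(a), int(t), n1, n2, float(d))
            for a, t, d in zip(a_sums, totals, disp)
        ]
    )
    mean1 = q[:, mask1].mean(axis=1)
    mean2 = q[:, mask2].mean(axis=1)
    log2fc = np.log2((mean1 + pseudo_count) / (mean2 + pseudo_count))
    table = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2FC": log2fc,
            "pvalue": pvals,
        },
        index=counts.gene_ids,
    )
    return DEResult(method_id=method_id, table=table, pseudo_count=pseudo_count)


def adjust_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the three-scorer suite
# ---------------------------------------------------------------------------

def run_de_suite(
    counts: CountMatrix,
    lengths: pd.Series | None = None,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    test_group: str | None = None,
) -> dict[str, DEResult]:
    """Run the UQ, MOR and FPKM scorers on one two-group count matrix.

    Each scorer estimates its own dispersions under its own size factors and
    is BH-adjusted independently.  ``lengths`` is only needed to expose the
    FPKM matrix itself; the FPKM scorer's depth-rescaled pseudo-counts are
    equivalent to total-count normalization, so the test does not require it.
    """
    counts.require_replicates(2)
    results: dict[str, DEResult] = {}
    for method_id, factor_fn in (
        ("UQ", size_factors_upper_quartile),
        ("MOR", size_factors_median_of_ratios),
        ("FPKM", size_factors_total_count),
    ):
        factors = factor_fn(counts)
        disp = estimate_dispersion(counts, factors)
        res = nb_test(
            counts, factors, disp, pseudo_count=pseudo_count,
            method_id=method_id, test_group=test_group,
        )
        results[method_id] = res.with_padj()
    return results
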