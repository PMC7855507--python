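"""Candidate-gene expression tables with row-relative scaling and flags.

Builds the regeneration-associated / developmental gene view: group-mean
FPKM for a user-supplied candidate list across control and injured groups,
min–max scaled within each row, with per-cell injury significance flags and
a per-gene development flag taken from consensus DE calls.  The development
contrast (young control vs old control) runs through the identical consensus
machinery as the injury contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusGeneSet

__all__ = ["ExpressionProfileTable", "row_relative", "build_profile_table"]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionProfileTable:
    """Candidate-gene group means plus scaled values and significance flags."""

    values: pd.DataFrame          # gene x group mean FPKM
    scaled_values: pd.DataFrame   # row-relative, in [0, 1]
    injury_flags: pd.DataFrame    # gene x injured-group booleans ('*')
    development_flags: pd.Series  # per-gene boolean ('#')
    missing: list = field(default_factory=list)


def row_relative(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Min–max scale each row to [0, 1]; constant rows map to 0.5."""
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.5)
    if squeeze:
        out = out[0]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def build_profile_table(
    candidates: list,
    group_fpkm: dict[str, pd.DataFrame],
    injury_calls: dict[str, ConsensusGeneSet] | None = None,
    development_calls: ConsensusGeneSet | None = None,
) -> ExpressionProfileTable:
    """Assemble the candidate-gene expression table.

    Parameters
    ----------
    candidates
        Gene IDs of interest; IDs absent from every FPKM table are reported
        in ``missing`` rather than raising (mirrors genes absent from the
        genome annotation).
    group_fpkm
        Ordered mapping of group label -> FPKM matrix (genes x samples) for
        that group; column order of the output follows insertion order.
    injury_calls
        Mapping of injured-group label -> consensus set for that group's
        injury-vs-control contrast; sets the per-cell '*' flags.
    development_calls
        Consensus set of the control-vs-control development contrast; sets
        the per-gene '#' flags.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    labels = list(group_fpkm)
    present = [
        g for g in candidates if any(g in fp.index for fp in group_fpkm.values())
    ]
    missing = [g for g in candidates if g not in present]
    if missing:
        logger.warning("%d candidate genes not found in any FPKM table", len(missing))
    values = pd.DataFrame(index=pd.Index(present, name="gene_id"), columns=labels, dtype=float)
    for label, fp in group_fpkm.items():
        hit = [g for g in present if g in fp.index]
        values.loc[hit, label] = fp.loc[hit].mean(axis=1)
    values = values.fillna(0.0)

    scaled = row_relative(values)

    injury_calls = injury_calls or {}
    flags = pd.DataFrame(False, index=values.index, columns=labels)
    for label, cs in injury_calls.items():
        if label not in flags.columns:
            raise ValueError(f"injury call label {label!r} is not an FPKM group")
        flags[label] = [g in cs.genes for g in values.index]

    dev_genes = development_calls.genes if development_calls is not None else set()
    dev_flags = pd.Series([g in dev_genes for g in values.index], index=values.index)

    return ExpressionProfileTable(
        values=values,
        scaled_values=scaled,
        injury_flags=flags,
        development_flags=dev_flags,
        missing=missing,
    )
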