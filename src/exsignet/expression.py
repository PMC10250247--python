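"""Group-average expression and the percentile-based low/high cutoffs.

The pipeline never consumes per-cell values directly: every decision is
made on the *average* expression of a gene within a cell group.  A gene
is called lowly expressed when its group mean falls below the maximum,
over all groups, of the per-group 50th percentile of nonzero means, and
highly expressed when it exceeds the minimum of the per-group 90th
percentiles.  Taking the max of the low cutoffs and the min of the high
ones accommodates groups whose expression distributions differ widely.

Ligands classified low in *every* group (or absent from the measured
genes altogether, treated as zero) are potential external signals:
candidates for signals the measured cells receive from outside the
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GroupExpression:
    """Gene x cell-group matrix of average expression values.

    ``means`` is indexed by gene symbol with one column per group; all
    values are non-negative library-normalized units, taken as provided.
    """

    means: pd.DataFrame

    def __post_init__(self) -> None:
        if self.means.columns.duplicated().any():
            raise ValidationError("duplicate group labels")
        if self.means.index.duplicated().any():
            raise ValidationError("duplicate gene symbols")
        if (self.means.to_numpy() < 0).any():
            raise ValidationError("average expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.means.index)

    @property
    def groups(self) -> list[str]:
        return list(self.means.columns)

    def mean(self, gene: str, group: str) -> float:
        """Average expression of ``gene`` in ``group``; unmeasured genes are 0."""
        if group not in self.means.columns:
            raise ValidationError(f"unknown cell group {group!r}")
        if gene not in self.means.index:
            return 0.0
        return float(self.means.at[gene, group])


@dataclass
class ExpressionCutoffs:
    """Low/high expression cutoffs derived from per-group percentiles."""

    low_cutoff: float
    high_cutoff: float
    per_group_p_low: dict[str, float]
    per_group_p_high: dict[str, float]
    p_low: float = 50.0
    p_high: float = 90.0


def group_means(
    expr_matrix: pd.DataFrame,
    cell_labels: Mapping[str, str] | pd.Series,
) -> GroupExpression:
    """Average each gene over the cells of every group (zeros included).

    Parameters
    ----------
    expr_matrix
        Genes x cells expression matrix (non-negative, pre-normalized).
    cell_labels
        Mapping from cell ID (column of ``expr_matrix``) to group label.
        Every column must be labelled; a label referring to no cell in
        the matrix is an error (that group would be empty).
    """
    labels = pd.Series(dict(cell_labels) if not isinstance(cell_labels, pd.Series)
                       else cell_labels)
    unlabeled = [c for c in expr_matrix.columns if c not in labels.index]
    if unlabeled:
        raise ValidationError(f"cells without a group label: {unlabeled[:5]}")
    labels = labels.reindex(expr_matrix.columns)
    declared = set(pd.Series(dict(cell_labels) if not isinstance(cell_labels, pd.Series)
                             else cell_labels).unique())
    present = set(labels.unique())
    for group in sorted(declared - present):
        raise ValidationError(f"cell group {group!r} has no cells in the matrix")
    if (expr_matrix.to_numpy() < 0).any():
        raise ValidationError("expression matrix must be non-negative")
    means = expr_matrix.T.groupby(labels).mean().T
    means.columns = [str(c) for c in means.columns]
    return GroupExpression(means)


def percentile_cutoffs(
    gexpr: GroupExpression,
    p_low: float = 50.0,
    p_high: float = 90.0,
    method: str = "linear",
) -> ExpressionCutoffs:
    """Derive the low/high cutoffs from per-group percentiles.

    Per group, genes with zero mean are removed and the ``p_low``-th and
    ``p_high``-th percentiles of the remaining means are computed (linear
    interpolation between order statistics by default).  The low cutoff
    is the maximum of the ``p_low`` percentiles over groups; the high
    cutoff is the minimum of the ``p_high`` percentiles.
    """
    lows: dict[str, float] = {}
    highs: dict[str, float] = {}
    for group in gexpr.groups:
        vals = gexpr.means[group].to_numpy(dtype=float)
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise ValidationError(
                f"cell group {group!r} has no gene with nonzero average expression"
            )
        lows[group] = float(np.percentile(nonzero, p_low, method=method))
        highs[group] = float(np.percentile(nonzero, p_high, method=method))
    low_cutoff = max(lows.values())
    high_cutoff = min(highs.values())
    if high_cutoff < low_cutoff:
        logger.warning(
            "high cutoff %.4g is below low cutoff %.4g (heterogeneous groups); "
            "'high' classification takes precedence", high_cutoff, low_cutoff,
        )
    return ExpressionCutoffs(low_cutoff, high_cutoff, lows, highs, p_low, p_high)


def classify_gene(
    gexpr: GroupExpression,
    cutoffs: ExpressionCutoffs,
    gene: str,
    group: str,
) -> str:
    """Classify a gene's group mean as ``"low"``, ``"high"`` or ``"intermediate"``.

    Strict inequalities: high when mean > high cutoff, low when mean <
    low cutoff, ties fall to intermediate.  When the cutoffs overlap
    (high cutoff below low cutoff) the high call takes precedence.
    Genes absent from the measured gene list have mean 0 and come out low.
    """
    mean = gexpr.mean(gene, group)
    if mean > cutoffs.high_cutoff:
        return "high"
    if mean < cutoffs.low_cutoff:
        return "low"
    return "intermediate"


def potential_external_signals(
    ligands: Iterable[str],
    gexpr: GroupExpression,
    cutoffs: ExpressionCutoffs,
) -> set[str]:
    """Ligands lowly expressed in every cell group, or unmeasured entirely.

    These are the candidate signals that the measured cells cannot be
    producing themselves; downstream-activity evidence (high receptors
    and TFs) is still required to call them external signals.
    """
    result: set[str] = set()
    measured = set(gexpr.genes)
    for ligand in ligands:
        if ligand not in measured:
            result.add(ligand)
            continue
        if all(classify_gene(gexpr, cutoffs, ligand, g) == "low"
               for g in gexpr.groups):
            result.add(ligand)
    return result
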