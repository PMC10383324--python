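"""Group contrasts, the >=1.5-fold differential filter, expression clustering
and differential-set comparison.

The per-protein contrast is ``logfc = log2(mean_case / mean_control)`` with
means taken over non-missing replicates on the linear intensity scale
(arithmetic mean of intensities, then log of the ratio -- the proteomics
convention; a ``summary="log-mean"`` switch averages log-intensities
instead).  A protein needs at least two non-missing replicates in each group
for its contrast to be defined; otherwise it is flagged missing and excluded
from filters and permutation backgrounds.

The fold-change filter selects proteins whose expression differs from
control by strictly more than the given fold in either direction:
``|logfc| > log2(fold)``; a ratio of exactly 1.5 is therefore NOT selected
at the default threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import AbundanceMatrix, ContrastVector, DifferentialSet
from .errors import UsageError

__all__ = [
    "compute_contrast",
    "fold_change_filter",
    "cluster_expression",
    "compare_sets",
    "ClusterResult",
]


def compute_contrast(
    matrix: AbundanceMatrix,
    case_group: str,
    summary: str = "linear-mean",
    min_replicates: int = 2,
) -> ContrastVector:
    """Log2 fold change of ``case_group`` versus the matrix's control group.

    Parameters
    ----------
    matrix
        Abundance matrix with group design.
    case_group
        Group to contrast against ``matrix.control_group``; must differ from it.
    summary
        ``"linear-mean"`` (default): log2 of the ratio of arithmetic means of
        linear intensities.  ``"log-mean"``: difference of mean log2
        intensities.
    min_replicates
        Minimum non-missing replicates required in each group; proteins below
        it get a NaN (missing-flagged) contrast.
    """
    if case_group == matrix.control_group:
        raise UsageError("case group must differ from the control group")
    case_cols = matrix.samples_of(case_group)
    ctrl_cols = matrix.samples_of(matrix.control_group)
    case = matrix.values[case_cols]
    ctrl = matrix.values[ctrl_cols]
    n_case = case.notna().sum(axis=1)
    n_ctrl = ctrl.notna().sum(axis=1)
    if summary == "linear-mean":
        logfc = np.log2(case.mean(axis=1, skipna=True) / ctrl.mean(axis=1, skipna=True))
    elif summary == "log-mean":
        logfc = np.log2(case).mean(axis=1, skipna=True) - np.log2(ctrl).mean(axis=1, skipna=True)
    else:
        raise UsageError(f"unknown summary {summary!r}")
    invalid = (n_case < min_replicates) | (n_ctrl < min_replicates) | ~np.isfinite(logfc)
    logfc = logfc.where(~invalid)
    n_used = pd.concat([n_case, n_ctrl], axis=1).min(axis=1).astype(int)
    return ContrastVector(
        logfc=logfc.astype(float),
        case_group=case_group,
        control_group=matrix.control_group,
        n_used=n_used,
    )


def fold_change_filter(contrast: ContrastVector, fold: float = 1.5) -> DifferentialSet:
    """Select proteins changed strictly more than ``fold`` times vs control."""
    if fold <= 1:
        raise UsageError(f"fold threshold must be > 1, got {fold}")
    cut = np.log2(fold)
    # strict ">" with an ulp-scale tolerance so a ratio of exactly `fold`
    # (or 1/fold, which differs from -log2(fold) in the last bit) is excluded
    tol = 1e-12 * max(1.0, cut)
    selected = contrast.logfc.index[contrast.valid & (contrast.logfc.abs() - cut > tol)]
    return DifferentialSet(
        label=contrast.label,
        members=frozenset(selected),
        criterion=f"fold>{fold}",
        fold=fold,
    )


@dataclass
class ClusterResult:
    """Hierarchical clustering of the protein x contrast logFC matrix."""

    protein_order: list  # leaf order
    linkage: np.ndarray  # scipy merge record
    proteins: list  # lexicographic row order used for the linkage
    contrast_labels: list


def cluster_expression(
    contrasts: Sequence[ContrastVector],
    selected: DifferentialSet | Sequence[str],
) -> ClusterResult:
    """Average-linkage Euclidean clustering of selected proteins' logFC rows.

    Rows are sorted by protein id before the linkage is computed, which makes
    the leaf order deterministic and invariant to the caller's input order;
    distance ties resolve by the lexicographic row order.
    """
    if len(contrasts) < 2:
        raise UsageError("clustering needs at least 2 contrasts")
    members = selected.members if isinstance(selected, DifferentialSet) else set(selected)
    proteins = sorted(members)
    if len(proteins) < 2:
        raise UsageError("clustering needs at least 2 proteins")
    mat = pd.DataFrame(
        {c.label: c.logfc.reindex(proteins) for c in contrasts}, index=proteins
    )
    if mat.isna().to_numpy().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()
        raise UsageError(f"proteins lack a valid logFC in some contrast: {bad[:5]}")
    z = hierarchy.linkage(pdist(mat.to_numpy(), metric="euclidean"), method="average")
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        protein_order=[proteins[i] for i in order],
        linkage=z,
        proteins=proteins,
        contrast_labels=[c.label for c in contrasts],
    )


def compare_sets(sets: Sequence[DifferentialSet]) -> dict[frozenset, int]:
    """Exact Venn-partition counts over two or more differential sets.

    Returns a mapping from the frozenset of set labels an element belongs to
    (non-empty combinations only) to the number of union elements with
    exactly that membership pattern.  Counts over all regions sum to the
    union size.
    """
    if len(sets) < 2:
        raise UsageError("need at least 2 sets to compare")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise UsageError(f"duplicate set labels: {labels}")
    union = set().union(*(s.members for s in sets))
    counts: dict[frozenset, int] = {}
    for el in union:
        key = frozenset(s.label for s in sets if el in s.members)
        counts[key] = counts.get(key, 0) + 1
    return counts
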