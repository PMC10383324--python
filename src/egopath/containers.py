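"""Core in-memory containers shared by every pipeline stage.

The pipeline's entry point is an :class:`AbundanceMatrix` (proteins x samples,
linear-scale intensities with group labels), from which per-group
:class:`ContrastVector` objects (log2 fold changes vs the control group) are
derived.  Interaction data live in an :class:`InteractionNetwork` (a thin
wrapper over an undirected :class:`networkx.Graph`), and gene sets in
:class:`PathwayDefinition` objects whose members carry a +1 (component /
activator) or -1 (repressor) role sign.  Permutation tests return a
:class:`PermutationResult` carrying the observed statistic, the null sample
and the empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, UsageError

__all__ = [
    "AbundanceMatrix",
    "InteractionNetwork",
    "PathwayDefinition",
    "ContrastVector",
    "DifferentialSet",
    "Module",
    "PermutationResult",
]


@dataclass
class AbundanceMatrix:
    """Proteins x samples abundance table with a group design.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        Entries are linear-scale intensities (> 0) or NaN for missing.
    sample_to_group
        Maps every sample id to its group label.
    control_group
        The reference group; must appear in ``sample_to_group`` values.
    """

    values: pd.DataFrame
    sample_to_group: dict[str, str]
    control_group: str

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate protein ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate sample ids: {dups[:5]}")
        missing_groups = [s for s in cols if s not in self.sample_to_group]
        if missing_groups:
            raise ConfigurationError(
                f"samples without a group assignment: {missing_groups}"
            )
        if self.control_group not in set(self.sample_to_group.values()):
            raise ConfigurationError(
                f"control group {self.control_group!r} has no samples"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ConfigurationError("abundance values must be > 0 or missing")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance (sample-sheet) order, control first."""
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.sample_to_group[s]
            if g not in seen:
                seen.append(g)
        if self.control_group in seen:
            seen.remove(self.control_group)
        return [self.control_group] + seen

    def samples_of(self, group: str) -> list[str]:
        members = [s for s in self.sample_ids if self.sample_to_group[s] == group]
        if not members:
            raise UsageError(f"unknown group {group!r}")
        return members

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.sample_to_group == other.sample_to_group
            and self.control_group == other.control_group
        )


@dataclass
class InteractionNetwork:
    """Undirected simple protein-interaction graph (no self-loops)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ConfigurationError(f"self-loops present: {loops[:5]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class PathwayDefinition:
    """Named gene set whose members carry role signs (+1 activator, -1 repressor)."""

    pathway_id: str
    name: str
    members: dict[str, int]  # protein id -> sign in {+1, -1}

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError(f"pathway {self.pathway_id!r} has no members")
        bad = {p: s for p, s in self.members.items() if s not in (1, -1)}
        if bad:
            raise ConfigurationError(
                f"pathway {self.pathway_id!r}: invalid signs {bad}"
            )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def repressors(self) -> set[str]:
        return {p for p, s in self.members.items() if s == -1}


@dataclass
class ContrastVector:
    """Per-protein log2 fold change of one case group versus the control group.

    ``logfc`` is NaN where the contrast is undefined (fewer than two
    non-missing replicates in either group).  ``n_used`` records, per protein,
    the smaller of the two per-group non-missing replicate counts.
    """

    logfc: pd.Series
    case_group: str
    control_group: str
    n_used: pd.Series

    @property
    def protein_ids(self) -> pd.Index:
        return self.logfc.index

    @property
    def valid(self) -> pd.Series:
        return self.logfc.notna()

    @property
    def background(self) -> list[str]:
        """Sorted protein ids with a valid (finite) log fold change."""
        return sorted(self.logfc.index[self.valid])

    @property
    def label(self) -> str:
        return f"{self.case_group}_vs_{self.control_group}"

    def negated(self) -> "ContrastVector":
        return ContrastVector(
            logfc=-self.logfc,
            case_group=self.control_group,
            control_group=self.case_group,
            n_used=self.n_used.copy(),
        )


@dataclass
class DifferentialSet:
    """Proteins selected as differential under one criterion for one contrast."""

    label: str
    members: frozenset
    criterion: str = ""
    fold: float | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Module:
    """Ego module: a seed protein plus its direct interactors in the background."""

    seed_protein: str
    members: frozenset

    def __post_init__(self) -> None:
        if self.seed_protein not in self.members:
            raise ConfigurationError("module seed must be a member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PermutationResult:
    """Observed statistic against a permutation null.

    ``p`` follows the add-one convention for sampled nulls
    (``(count + 1) / (n_perm + 1)``, never 0) and exact counting when the null
    is exhaustive.  ``undefined`` marks statistics that could not be computed
    (e.g. a correlation over fewer than three members).
    """

    statistic: str
    observed: float
    null: np.ndarray
    n_perm: int
    p: float | None
    seed: int | None
    sided: str  # "two-sided" | "upper"
    exhaustive: bool = False
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.p is not None and not (0.0 < self.p <= 1.0):
            raise ConfigurationError(f"empirical p out of range: {self.p}")

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null)) if len(self.null) else float("nan")

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null, ddof=1)) if len(self.null) > 1 else 0.0
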