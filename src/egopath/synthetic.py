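"""Synthetic three-group proteomics study generator.

Emulates the statistical structure the analysis pipeline assumes: a sham
control group plus a lesion (UCCAO) group and a lesion+treatment group,
~10 replicates each; log-normal protein abundances over a BioGRID-style
interaction network; optional planted effects -- an ego module (a seed
protein and its direct neighbors) shifted by delta on the log scale in one
group, and a pathway whose activator members shift up and repressor members
shift down in one group; and Y-maze / object-recognition behavior sessions
with tunable alternation and novelty-preference rates.

The network is Erdos-Renyi G(n, p) with p = mean_degree / (n - 1): the
module statistic only uses first-neighbor adjacency, so no richer topology
is required.  All randomness descends from a single scenario seed through
fixed named sub-streams, so every artifact is bit-reproducible and
independent of generation order.

Arm-entry sequences never re-enter the arm just left; each subsequent entry
is an alternation (three distinct arms in the last three entries) with
probability exactly ``alternation_prob``, giving the closed-form expectation
``E[alternation %] = 100 * alternation_prob`` used as an oracle in tests.
Exploration-time pairs draw the total time from an exponential distribution
and split it by a Beta fraction with mean ``novelty_preference``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .behavior import ArmEntrySequence, ExplorationRecord
from .containers import AbundanceMatrix, InteractionNetwork, PathwayDefinition
from .errors import ConfigurationError
from .permutation import child_seed

__all__ = [
    "SimulationScenario",
    "BehaviorScenario",
    "PlantedModule",
    "PlantedPathway",
    "generate_network",
    "generate_abundances",
    "generate_pathways",
    "generate_behavior",
    "BehaviorData",
    "expected_alternation_percent",
]

# sub-stream keys (order-independent reproducibility)
_NET, _PATHWAYS, _ABUND, _BEHAV = 11, 12, 13, 14

DEFAULT_GROUPS = ("SHAM", "UCCAO", "UCCAO_MF")


@dataclass(frozen=True)
class PlantedModule:
    """Shift the seed protein and its direct neighbors by delta (natural-log
    scale) in one non-control group."""

    seed_protein: str
    group: str
    delta: float


@dataclass(frozen=True)
class PlantedPathway:
    """Shift one pathway's members in one group: activators by +shift,
    repressors by -shift (natural-log scale)."""

    pathway_id: str
    group: str
    shift: float
    repressor_fraction: float | None = None  # overrides the scenario default


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one synthetic proteomics study.

    Defaults reproduce the study design the pipeline targets: three groups
    (control first) with 10 replicates each over 200 proteins, a mean
    interaction degree of 6, log-normal baseline abundances and i.i.d.
    Gaussian replicate noise on the natural-log scale (sd 0.35, a typical
    label-free replicate spread).
    """

    n_proteins: int = 200
    mean_degree: float = 6.0
    groups: tuple = DEFAULT_GROUPS
    n_replicates_per_group: int = 10
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.35
    planted_modules: tuple = ()
    planted_pathways: tuple = ()
    n_pathways: int = 20
    pathway_size: int | None = None  # default: min(10, n_proteins // 2)
    repressor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 3:
            raise ConfigurationError("n_proteins must be >= 3")
        if self.mean_degree <= 0:
            raise ConfigurationError("mean_degree must be > 0")
        if self.mean_degree >= self.n_proteins:
            raise ConfigurationError("mean_degree must be < n_proteins")
        if self.n_replicates_per_group < 2:
            raise ConfigurationError("need >= 2 replicates per group")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if len(self.groups) < 2 or len(set(self.groups)) != len(self.groups):
            raise ConfigurationError("groups must be >= 2 distinct labels")
        if self.pathway_size is not None and self.pathway_size > self.n_proteins:
            raise ConfigurationError("pathway size exceeds protein count")
        if not 0 <= self.repressor_fraction <= 1:
            raise ConfigurationError("repressor_fraction must be in [0, 1]")
        for pm in self.planted_modules:
            if not math.isfinite(pm.delta):
                raise ConfigurationError(f"planted delta not finite: {pm}")

    @property
    def control_group(self) -> str:
        return self.groups[0]

    @property
    def resolved_pathway_size(self) -> int:
        if self.pathway_size is not None:
            return self.pathway_size
        return max(1, min(10, self.n_proteins // 2))


@dataclass(frozen=True)
class BehaviorScenario:
    """Parameters of one synthetic behavior cohort.

    ``alternation_prob`` and ``novelty_preference`` may be a single float or
    a per-group mapping.  The default exploration time scale puts ~20% of
    total exploration times below the 5 s exclusion threshold.
    """

    n_animals_per_group: int = 10
    groups: tuple = DEFAULT_GROUPS
    alternation_prob: float | dict = 0.7
    n_entries: int = 25
    novelty_preference: float | dict = 0.65
    exploration_time_scale: float = 22.41  # seconds; P(total < 5 s) ~= 0.2
    preference_concentration: float = 20.0  # Beta concentration of the split
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("alternation_prob", self.alternation_prob),
                        ("novelty_preference", self.novelty_preference)):
            vals = v.values() if isinstance(v, dict) else [v]
            if any(not 0 <= x <= 1 for x in vals):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_entries < 3:
            raise ConfigurationError("n_entries must be >= 3")
        if self.n_animals_per_group < 1:
            raise ConfigurationError("need >= 1 animal per group")
        if self.exploration_time_scale <= 0:
            raise ConfigurationError("exploration_time_scale must be > 0")

    def _per_group(self, value) -> dict:
        if isinstance(value, dict):
            missing = [g for g in self.groups if g not in value]
            if missing:
                raise ConfigurationError(f"groups without a value: {missing}")
            return dict(value)
        return {g: value for g in self.groups}


def _protein_ids(n: int) -> list[str]:
    return [f"P{i + 1:06d}" for i in range(n)]


def generate_network(scenario: SimulationScenario) -> InteractionNetwork:
    """Erdos-Renyi interaction network over proteins P000001..P<n>."""
    rng = child_seed(scenario.seed, _NET)
    p = min(1.0, scenario.mean_degree / (scenario.n_proteins - 1))
    g = nx.gnp_random_graph(scenario.n_proteins, p, seed=rng)
    ids = _protein_ids(scenario.n_proteins)
    g = nx.relabel_nodes(g, dict(enumerate(ids)))
    return InteractionNetwork(graph=g)


def _repressor_count(size: int, fraction: float) -> int:
    # round half up
    return int(math.floor(size * fraction + 0.5))


def generate_pathways(
    network: InteractionNetwork, scenario: SimulationScenario
) -> list[PathwayDefinition]:
    """``n_pathways`` random signed gene sets over the network's proteins.

    Pathway ids are PW0001..; members are sampled without replacement and a
    ``round(size * repressor_fraction)`` subset (round half up) gets sign -1.
    Deterministic given the scenario seed, independent of other generators.
    """
    rng = child_seed(scenario.seed, _PATHWAYS)
    nodes = sorted(network.nodes)
    overrides = {pp.pathway_id: pp for pp in scenario.planted_pathways}
    pathways = []
    for i in range(scenario.n_pathways):
        pid = f"PW{i + 1:04d}"
        size = scenario.resolved_pathway_size
        if size > len(nodes):
            raise ConfigurationError(f"pathway size {size} > {len(nodes)} proteins")
        members = [nodes[j] for j in rng.choice(len(nodes), size=size, replace=False)]
        frac = scenario.repressor_fraction
        if pid in overrides and overrides[pid].repressor_fraction is not None:
            frac = overrides[pid].repressor_fraction
        n_rep = _repressor_count(size, frac)
        rep_idx = set(rng.choice(size, size=n_rep, replace=False)) if n_rep else set()
        pathways.append(PathwayDefinition(
            pathway_id=pid, name=f"synthetic pathway {i + 1}",
            members={m: (-1 if j in rep_idx else 1) for j, m in enumerate(members)}))
    unknown = set(overrides) - {pw.pathway_id for pw in pathways}
    if unknown:
        raise ConfigurationError(f"planted pathway ids not generated: {sorted(unknown)}")
    return pathways


def generate_abundances(
    network: InteractionNetwork,
    scenario: SimulationScenario,
    pathways: Sequence[PathwayDefinition] | None = None,
) -> AbundanceMatrix:
    """Log-normal abundance matrix with the scenario's planted effects.

    abundance = exp(baseline_i + shift_{i,g} + noise) with the baseline drawn
    once per protein, a planted module shifting the seed protein and its
    direct neighbors by delta in its group only, and a planted pathway
    shifting activators by +shift and repressors by -shift in its group.
    The control group never carries a shift.
    """
    ids = _protein_ids(scenario.n_proteins)
    if set(ids) != network.nodes:
        raise ConfigurationError("network nodes do not match the scenario's proteins")
    for pm in scenario.planted_modules:
        if pm.seed_protein not in network.nodes:
            raise ConfigurationError(f"planted seed {pm.seed_protein!r} not in network")
        if pm.group not in scenario.groups:
            raise ConfigurationError(f"unknown group {pm.group!r} in planted module")
        if pm.group == scenario.control_group:
            raise ConfigurationError("control group cannot carry a planted shift")
    for pp in scenario.planted_pathways:
        if pp.group not in scenario.groups:
            raise ConfigurationError(f"unknown group {pp.group!r} in planted pathway")
        if pp.group == scenario.control_group:
            raise ConfigurationError("control group cannot carry a planted shift")

    rng = child_seed(scenario.seed, _ABUND)
    baseline = rng.normal(scenario.baseline_log_mean, scenario.baseline_log_sd,
                          size=scenario.n_proteins)

    shift = pd.DataFrame(0.0, index=ids, columns=list(scenario.groups))
    for pm in scenario.planted_modules:
        members = {pm.seed_protein} | network.neighbors(pm.seed_protein)
        shift.loc[sorted(members), pm.group] += pm.delta
    if scenario.planted_pathways:
        if pathways is None:
            pathways = generate_pathways(network, scenario)
        by_id = {pw.pathway_id: pw for pw in pathways}
        for pp in scenario.planted_pathways:
            if pp.pathway_id not in by_id:
                raise ConfigurationError(f"unknown planted pathway {pp.pathway_id!r}")
            for m, s in by_id[pp.pathway_id].members.items():
                shift.loc[m, pp.group] += s * pp.shift

    cols, data = [], []
    for g in scenario.groups:
        for r in range(scenario.n_replicates_per_group):
            cols.append(f"{g}_{r + 1}")
            noise = rng.normal(0.0, scenario.noise_sd, size=scenario.n_proteins)
            data.append(np.exp(baseline + shift[g].to_numpy() + noise))
    values = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    sample_to_group = {c: c.rsplit("_", 1)[0] for c in cols}
    return AbundanceMatrix(values=values, sample_to_group=sample_to_group,
                           control_group=scenario.control_group)


@dataclass
class BehaviorData:
    arm_sequences: list  # ArmEntrySequence
    explorations: list  # ExplorationRecord (NOR and NLR per animal)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        seqs = pd.DataFrame(
            {"animal_id": s.animal_id, "group": s.group,
             "entries": "".join(s.entries)} for s in self.arm_sequences)
        expl = pd.DataFrame(
            {"animal_id": e.animal_id, "group": e.group, "phase": e.phase,
             "time_novel": e.time_novel, "time_familiar": e.time_familiar}
            for e in self.explorations)
        return seqs, expl


def expected_alternation_percent(scenario: BehaviorScenario, group: str) -> float:
    """Closed-form expectation of the alternation % under the generator."""
    return 100.0 * scenario._per_group(scenario.alternation_prob)[group]


def generate_behavior(scenario: BehaviorScenario) -> BehaviorData:
    """Arm-entry sequences and NOR/NLR exploration-time pairs per animal."""
    rng = child_seed(scenario.seed, _BEHAV)
    alt = scenario._per_group(scenario.alternation_prob)
    pref = scenario._per_group(scenario.novelty_preference)
    arms = np.array(["A", "B", "C"])
    seqs, expl = [], []
    for g in scenario.groups:
        for a in range(scenario.n_animals_per_group):
            aid = f"{g}_M{a + 1:02d}"
            # first two entries: distinct arms; afterwards never the same arm
            # twice in a row, alternating (third distinct arm) w.p. alt[g]
            entries = [str(rng.choice(arms))]
            entries.append(str(rng.choice(arms[arms != entries[0]])))
            for _ in range(scenario.n_entries - 2):
                prev2, prev1 = entries[-2], entries[-1]
                third = next(x for x in arms if x not in (prev2, prev1))
                entries.append(third if rng.random() < alt[g] else prev2)
            seqs.append(ArmEntrySequence(animal_id=aid, group=g, entries=tuple(entries)))
            for phase in ("NOR", "NLR"):
                total = rng.exponential(scenario.exploration_time_scale)
                nu = pref[g]
                kappa = scenario.preference_concentration
                if nu in (0.0, 1.0):
                    frac = nu
                else:
                    frac = rng.beta(nu * kappa, (1 - nu) * kappa)
                expl.append(ExplorationRecord(
                    animal_id=aid, group=g, phase=phase,
                    time_novel=float(frac * total),
                    time_familiar=float((1 - frac) * total)))
    return BehaviorData(arm_sequences=seqs, explorations=expl)
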