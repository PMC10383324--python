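"""Interaction-network ego-module statistics with permutation nulls.

For each measured protein ("seed"), the module is the seed together with its
direct interactors that carry a valid contrast value (the "background").
The module's mean and standard deviation of member log2 fold changes are
compared with those of randomly selected protein sets of the same size drawn
from the background (1000 draws by default); the mean uses a two-sided
empirical p (distance from the null mean), the SD an upper-tailed one.
Between-contrast comparison uses the Pearson correlation of the module
members' logFC in the two contrasts, with significance from the same kind of
random-set null.

Nulls are drawn independently for every seed protein, without replacement
within a draw.  Small backgrounds switch to exhaustive enumeration of all
same-size subsets with exact p counting (no add-one correction).

An alternative null (``null="ego"``) draws from ego modules of matching size
instead of free random sets, when at least 50 such modules exist; this is
closer to a literal reading of "random modules" but infeasible for module
sizes with few or no representatives, which is why random sets are the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ContrastVector,
    DifferentialSet,
    InteractionNetwork,
    Module,
    PermutationResult,
)
from .errors import ContractError, UsageError
from .permutation import (
    all_index_sets,
    child_seed,
    draw_index_sets,
    empirical_p,
    n_subsets,
)

__all__ = [
    "build_module",
    "module_stats",
    "random_module_null",
    "module_significance",
    "module_correlation",
    "select_de_proteins",
    "NullSample",
    "ModuleSelection",
]

#: minimum count of matching-size ego modules for the "ego" null to apply
MIN_EGO_NULL_POOL = 50


def build_module(network: InteractionNetwork, seed_protein: str, background: set) -> Module:
    """Ego module of ``seed_protein``: seed plus measured direct interactors."""
    if seed_protein not in network.nodes:
        raise LookupError(f"seed {seed_protein!r} not in the interaction network")
    if seed_protein not in background:
        raise LookupError(f"seed {seed_protein!r} has no measured contrast")
    members = {seed_protein} | (network.neighbors(seed_protein) & set(background))
    return Module(seed_protein=seed_protein, members=frozenset(members))


def module_stats(module: Module, contrast: ContrastVector) -> tuple[float, float]:
    """Arithmetic mean and sample SD (ddof=1) of member logFCs.

    Size-1 modules have SD 0 by convention.  Raises ContractError if any
    member lacks a valid logFC -- the caller must restrict the module to the
    background first.
    """
    vals = contrast.logfc.reindex(sorted(module.members))
    if vals.isna().any():
        bad = vals.index[vals.isna()].tolist()
        raise ContractError(f"module members without valid logFC: {bad[:5]}")
    x = vals.to_numpy(dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return mean, sd


@dataclass
class NullSample:
    """Permutation null of (mean, sd) pairs for random same-size protein sets.

    ``center`` is the exact null expectation of the subset mean (the
    background mean), used as the two-sided reference point.
    """

    means: np.ndarray
    sds: np.ndarray
    size: int
    exhaustive: bool
    seed: int | None
    center: float | None = None

    @property
    def n(self) -> int:
        return len(self.means)


def _background_values(background, contrast: ContrastVector) -> np.ndarray:
    vals = contrast.logfc.reindex(sorted(background))
    if vals.isna().any():
        bad = vals.index[vals.isna()].tolist()
        raise ContractError(f"background proteins without valid logFC: {bad[:5]}")
    return vals.to_numpy(dtype=float)


def random_module_null(
    background,
    size: int,
    contrast: ContrastVector,
    n_perm: int = 1000,
    seed: int | None = 0,
    exhaustive: bool | None = None,
    rng: np.random.Generator | None = None,
) -> NullSample:
    """(mean, sd) null from random same-size subsets of the background.

    ``exhaustive=None`` enumerates all subsets whenever there are at most
    ``n_perm`` of them; pass True/False to force either mode.
    """
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    x = _background_values(background, contrast)
    n_bg = x.size
    if size > n_bg:
        raise UsageError(f"module size {size} exceeds background size {n_bg}")
    if exhaustive is None:
        exhaustive = n_subsets(n_bg, size) <= n_perm
    if exhaustive:
        idx = all_index_sets(n_bg, size)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        idx = draw_index_sets(rng, n_bg, size, n_perm)
    draws = x[idx]
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1) if size > 1 else np.zeros(len(idx))
    return NullSample(means=means, sds=sds, size=size, exhaustive=exhaustive,
                      seed=seed, center=float(x.mean()))


def module_significance(
    observed: tuple[float, float], null: NullSample, seed: int | None = None
) -> dict[str, PermutationResult]:
    """Empirical significance of an observed (mean, sd) against a null sample.

    The mean is tested two-sided (distance from the null mean), the SD
    upper-tailed.  Exhaustive nulls use exact counts; sampled nulls the
    add-one rule.
    """
    obs_mean, obs_sd = observed
    p_mean = empirical_p(obs_mean, null.means, "two-sided", null.exhaustive,
                         center=null.center)
    p_sd = empirical_p(obs_sd, null.sds, "upper", null.exhaustive)
    common = dict(n_perm=null.n, seed=seed if seed is not None else null.seed,
                  exhaustive=null.exhaustive)
    return {
        "mean": PermutationResult(statistic="module_mean", observed=obs_mean,
                                  null=null.means, p=p_mean, sided="two-sided", **common),
        "sd": PermutationResult(statistic="module_sd", observed=obs_sd,
                                null=null.sds, p=p_sd, sided="upper", **common),
    }


def module_correlation(
    module: Module,
    contrast_a: ContrastVector,
    contrast_b: ContrastVector,
    background=None,
    n_perm: int = 1000,
    seed: int | None = 0,
    exhaustive: bool | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Pearson correlation of member logFCs between two contrasts, with a
    random-set permutation null.

    Modules smaller than 3 or with a zero-variance member vector yield an
    undefined result (no p).  The null draws random same-size member sets
    from the common background (proteins valid in both contrasts) and
    recomputes r; two-sided empirical p with the add-one rule.
    """
    members = sorted(module.members)
    a = contrast_a.logfc.reindex(members).to_numpy(dtype=float)
    b = contrast_b.logfc.reindex(members).to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ContractError("module members lack valid logFC in a contrast")

    def _undefined() -> PermutationResult:
        return PermutationResult(
            statistic="module_correlation", observed=float("nan"),
            null=np.empty(0), n_perm=0, p=None, seed=seed,
            sided="two-sided", undefined=True)

    if len(members) < 3 or a.std() == 0 or b.std() == 0:
        return _undefined()
    obs_r = float(np.corrcoef(a, b)[0, 1])

    if background is None:
        common = contrast_a.valid & contrast_b.valid
        background = set(contrast_a.logfc.index[common])
    bg = sorted(background)
    xa = contrast_a.logfc.reindex(bg).to_numpy(dtype=float)
    xb = contrast_b.logfc.reindex(bg).to_numpy(dtype=float)
    if np.isnan(xa).any() or np.isnan(xb).any():
        raise ContractError("background proteins lack valid logFC in a contrast")
    size = len(members)
    if size > len(bg):
        raise UsageError("module larger than the common background")
    if exhaustive is None:
        exhaustive = n_subsets(len(bg), size) <= n_perm
    if exhaustive:
        idx = all_index_sets(len(bg), size)
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        idx = draw_index_sets(rng, len(bg), size, n_perm)
    da, db = xa[idx], xb[idx]
    da_c = da - da.mean(axis=1, keepdims=True)
    db_c = db - db.mean(axis=1, keepdims=True)
    denom = np.sqrt((da_c**2).sum(axis=1) * (db_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null_r = np.where(denom > 0, (da_c * db_c).sum(axis=1) / denom, 0.0)
    p = empirical_p(obs_r, null_r, "two-sided", exhaustive)
    return PermutationResult(
        statistic="module_correlation", observed=obs_r, null=null_r,
        n_perm=len(null_r), p=p, seed=seed, sided="two-sided",
        exhaustive=exhaustive)


def _ego_null(
    network: InteractionNetwork,
    background: set,
    size: int,
    contrast: ContrastVector,
    n_perm: int,
    rng: np.random.Generator,
) -> NullSample | None:
    """Null over ego modules of matching size, or None if the pool is small."""
    pool = []
    for node in sorted(background & network.nodes):
        m = build_module(network, node, background)
        if m.size == size:
            pool.append(m)
    if len(pool) < MIN_EGO_NULL_POOL:
        return None
    picks = rng.integers(0, len(pool), size=n_perm)
    stats = [module_stats(pool[i], contrast) for i in picks]
    means = np.array([s[0] for s in stats])
    sds = np.array([s[1] for s in stats])
    return NullSample(means=means, sds=sds, size=size, exhaustive=False, seed=None)


@dataclass
class ModuleSelection:
    """Full output of a network-based differential-protein selection run."""

    per_seed: pd.DataFrame  # one row per (seed protein, contrast)
    per_pair: pd.DataFrame  # one row per (seed protein, contrast pair)
    de_sets: dict[str, DifferentialSet] = field(default_factory=dict)
    untestable: list[str] = field(default_factory=list)  # measured but not in network


def select_de_proteins(
    network: InteractionNetwork,
    contrasts: list[ContrastVector],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    null: str = "sets",
    background: set | None = None,
    pair_correlation: bool = True,
) -> ModuleSelection:
    """Select differential proteins by ego-module mean significance.

    Every background protein that is a network node is used as a module
    seed; a protein is selected for a contrast when its module-mean
    empirical p is below ``alpha``.  For each pair of contrasts the module
    Pearson correlation and its permutation p are additionally computed
    (seeds whose module correlation p is below ``alpha`` form the
    between-contrast set, labelled ``"caseA-caseB"``).

    Background proteins absent from the network are reported in
    ``untestable`` rather than silently dropped.  Output is bit-identical
    for a fixed ``seed``.
    """
    if not 0 <= alpha < 1:
        raise UsageError(f"alpha must be in [0, 1), got {alpha}")
    if null not in ("sets", "ego"):
        raise UsageError(f"unknown null mode {null!r}")

    rows, pair_rows = [], []
    de_sets: dict[str, DifferentialSet] = {}
    untestable: set[str] = set()

    for ci, contrast in enumerate(contrasts):
        bg = set(background) if background is not None else set(contrast.background)
        bg &= set(contrast.logfc.index[contrast.valid])
        seeds_in_net = sorted(bg & network.nodes)
        untestable |= bg - network.nodes
        selected = []
        for si, sp in enumerate(seeds_in_net):
            mod = build_module(network, sp, bg)
            obs = module_stats(mod, contrast)
            rng = child_seed(seed, 0, ci, si)
            if null == "ego":
                ns = _ego_null(network, bg, mod.size, contrast, n_perm, rng)
                if ns is None:
                    ns = random_module_null(bg, mod.size, contrast, n_perm, rng=rng)
            else:
                ns = random_module_null(bg, mod.size, contrast, n_perm, rng=rng)
            res = module_significance(obs, ns, seed=seed)
            sel = res["mean"].p is not None and res["mean"].p < alpha
            if sel:
                selected.append(sp)
            rows.append({
                "seed_protein": sp, "contrast": contrast.label,
                "module_size": mod.size, "mean": obs[0], "sd": obs[1],
                "null_mean": res["mean"].null_mean, "null_sd": res["mean"].null_sd,
                "p_mean": res["mean"].p, "p_sd": res["sd"].p,
                "n_perm": ns.n, "exhaustive": ns.exhaustive, "selected": sel,
            })
        label = contrast.label
        de_sets[label] = DifferentialSet(
            label=label, members=frozenset(selected),
            criterion=f"module_mean_p<{alpha}")

    if pair_correlation:
        for ai in range(len(contrasts)):
            for bi in range(ai + 1, len(contrasts)):
                ca, cb = contrasts[ai], contrasts[bi]
                common = set(ca.background) & set(cb.background)
                if background is not None:
                    common &= set(background)
                seeds_in_net = sorted(common & network.nodes)
                pair_label = f"{ca.case_group}-{cb.case_group}"
                selected = []
                for si, sp in enumerate(seeds_in_net):
                    mod = build_module(network, sp, common)
                    rng = child_seed(seed, 1, ai, bi, si)
                    res = module_correlation(
                        mod, ca, cb, background=common, n_perm=n_perm, rng=rng,
                        seed=seed)
                    sel = res.p is not None and res.p < alpha
                    if sel:
                        selected.append(sp)
                    pair_rows.append({
                        "seed_protein": sp, "pair": pair_label,
                        "module_size": mod.size, "r": res.observed,
                        "p": res.p, "n_perm": res.n_perm,
                        "undefined": res.undefined, "selected": sel,
                    })
                de_sets[pair_label] = DifferentialSet(
                    label=pair_label, members=frozenset(selected),
                    criterion=f"module_correlation_p<{alpha}")

    per_seed = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["seed_protein", "contrast", "module_size", "mean", "sd",
                 "null_mean", "null_sd", "p_mean", "p_sd", "n_perm",
                 "exhaustive", "selected"])
    per_pair = pd.DataFrame(pair_rows) if pair_rows else pd.DataFrame(
        columns=["seed_protein", "pair", "module_size", "r", "p", "n_perm",
                 "undefined", "selected"])
    return ModuleSelection(per_seed=per_seed, per_pair=per_pair,
                           de_sets=de_sets, untestable=sorted(untestable))
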