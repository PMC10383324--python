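"""Rodent behavioral scoring and routine group statistics.

Two printed formulas from the study design are implemented exactly:

* Y-maze spontaneous alternation (%) = actual alternations /
  (total arm entries - 2) x 100, where an alternation is a window of three
  consecutive entries into three distinct arms (overlapping windows; the
  denominator equals the number of such windows);
* novel object/location recognition index = time exploring the novel object
  (or location) / total exploration time, with records excluded when the
  total exploration time is below 5 s.

Group comparison mirrors the usual analysis of such data: one-way ANOVA
followed by Fisher's least-significant-difference (LSD) pairwise tests on
the pooled within-group variance, a Brown-Forsythe/Levene check of variance
homogeneity, and Pearson correlation of a molecular marker against the
recognition index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError

__all__ = [
    "ArmEntrySequence",
    "ExplorationRecord",
    "spontaneous_alternation",
    "recognition_index",
    "group_compare",
    "marker_memory_correlation",
    "RecognitionResult",
    "GroupComparison",
    "CorrelationResult",
]

ARM_LABELS = ("A", "B", "C")
MIN_EXPLORATION_S = 5.0  # exclusion threshold on total exploration time


@dataclass
class ArmEntrySequence:
    animal_id: str
    group: str
    entries: tuple  # ordered arm labels from {A, B, C}

    def __post_init__(self) -> None:
        bad = [a for a in self.entries if a not in ARM_LABELS]
        if bad:
            raise UsageError(f"unknown arm labels {bad[:5]} (expected {ARM_LABELS})")


@dataclass
class ExplorationRecord:
    animal_id: str
    group: str
    phase: str  # "NOR" | "NLR"
    time_novel: float  # seconds
    time_familiar: float

    def __post_init__(self) -> None:
        if self.phase not in ("NOR", "NLR"):
            raise UsageError(f"phase must be NOR or NLR, got {self.phase!r}")
        if not (np.isfinite(self.time_novel) and np.isfinite(self.time_familiar)):
            raise UsageError("exploration times must be finite")
        if self.time_novel < 0 or self.time_familiar < 0:
            raise UsageError("exploration times must be non-negative")


def spontaneous_alternation(entries: Sequence[str]) -> float | None:
    """Spontaneous alternation percentage of an arm-entry sequence.

    Returns None (undefined) for sequences shorter than 3 entries.
    Consecutive re-entries into the same arm are legitimate entries and
    count in the denominator.
    """
    seq = entries.entries if isinstance(entries, ArmEntrySequence) else tuple(entries)
    n = len(seq)
    if n < 3:
        return None
    alternations = sum(
        1 for i in range(n - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    return 100.0 * alternations / (n - 2)


@dataclass
class RecognitionResult:
    index: float | None
    excluded: bool
    total_time: float


def recognition_index(
    record: ExplorationRecord | tuple[float, float],
    min_total_s: float = MIN_EXPLORATION_S,
) -> RecognitionResult:
    """time_novel / (time_novel + time_familiar), or excluded if the animal
    explored for less than ``min_total_s`` seconds in total."""
    if isinstance(record, ExplorationRecord):
        tn, tf = record.time_novel, record.time_familiar
    else:
        tn, tf = record
    total = tn + tf
    if total < min_total_s or total == 0:
        return RecognitionResult(index=None, excluded=True, total_time=total)
    return RecognitionResult(index=tn / total, excluded=False, total_time=total)


@dataclass
class GroupComparison:
    """One-way ANOVA with LSD pairwise tests and a variance-homogeneity check."""

    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    lsd: pd.DataFrame  # columns: group_a, group_b, diff, t, p
    levene_stat: float
    levene_p: float
    group_means: dict
    degenerate: bool  # zero pooled within-group variance


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    levene_center: str = "median",
) -> GroupComparison:
    """One-way ANOVA + LSD pairwise p-values + Levene/Brown-Forsythe test.

    ``levene_center="median"`` (default) gives the Brown-Forsythe variant
    (absolute deviations from group medians); ``"mean"`` the classic Levene.
    Groups with zero pooled within-group variance are flagged degenerate and
    p collapses to the smallest representable value when means differ.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise UsageError("every group needs at least 2 values")

    n_total = sum(a.size for a in arrays)
    k = len(groups)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_w = ss_within / df_w
    degenerate = ms_w == 0
    if degenerate:
        f = np.inf if ss_between > 0 else 0.0
        p = np.finfo(float).tiny if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(stats.f.sf(f, df_b, df_w))

    lsd_rows = []
    for ga, gb in combinations(groups, 2):
        a, b = values_by_group[ga], values_by_group[gb]
        a, b = np.asarray(a, float), np.asarray(b, float)
        diff = a.mean() - b.mean()
        if degenerate:
            t = np.inf if diff != 0 else 0.0
            pt = np.finfo(float).tiny if diff != 0 else 1.0
        else:
            se = np.sqrt(ms_w * (1 / a.size + 1 / b.size))
            t = diff / se
            pt = float(2 * stats.t.sf(abs(t), df_w))
        lsd_rows.append({"group_a": ga, "group_b": gb, "diff": diff, "t": t, "p": pt})

    lev_stat, lev_p = stats.levene(*arrays, center=levene_center)
    return GroupComparison(
        f=float(f), p=float(p), df_between=df_b, df_within=df_w,
        ms_within=float(ms_w), lsd=pd.DataFrame(lsd_rows),
        levene_stat=float(lev_stat), levene_p=float(lev_p),
        group_means={g: float(a.mean()) for g, a in zip(groups, arrays)},
        degenerate=degenerate,
    )


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p: float
    n: int
    undefined: bool = False


def marker_memory_correlation(marker, recognition) -> CorrelationResult:
    """Pearson correlation of a molecular marker against recognition indices."""
    x = np.asarray(marker, dtype=float)
    y = np.asarray(recognition, dtype=float)
    if x.size != y.size:
        raise UsageError("marker and recognition vectors differ in length")
    if x.size < 3:
        raise UsageError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 int(x.size), undefined=True)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue), n=int(x.size))
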