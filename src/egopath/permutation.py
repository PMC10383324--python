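"""Shared permutation-null machinery.

Two conventions are used throughout the package:

* sampled nulls use the add-one empirical p-value,
  ``p = (count + 1) / (n_perm + 1)``, which can never be 0;
* exhaustive nulls (full enumeration of all same-size subsets) use exact
  counts, ``p = count / n_subsets``; the observed set is itself one of the
  enumerated subsets, so the count is at least 1.

Two-sidedness is defined by distance from the null mean:
``count = #{ |null_i - center| >= |observed - center| }`` with
``center = mean(null)``.  A tiny absolute/relative tolerance absorbs
floating-point jitter so that exact ties (and exact shift invariances)
count as ties.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from .errors import UsageError

_TIE_TOL = 1e-9


def empirical_p(
    observed: float,
    null: np.ndarray,
    sided: str = "two-sided",
    exhaustive: bool = False,
    center: float | None = None,
) -> float:
    """Empirical p-value of ``observed`` against a null sample.

    For two-sided tests the distance is measured from ``center``; pass the
    statistic's exact null expectation when it has a closed form (it does for
    subset means and signed subset sums), which keeps sampled p-values
    unbiased for their exhaustive counterparts.  When ``center`` is None the
    sample mean of the null is used.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise UsageError("empty null sample")
    if sided == "two-sided":
        if center is None:
            center = null.mean()
        dist = np.abs(null - center)
        thresh = abs(observed - center)
    elif sided == "upper":
        dist = null
        thresh = observed
    else:
        raise UsageError(f"unknown sidedness {sided!r}")
    tol = _TIE_TOL * max(1.0, abs(thresh))
    count = int(np.sum(dist >= thresh - tol))
    if exhaustive:
        return count / null.size
    return (count + 1) / (null.size + 1)


def draw_index_sets(
    rng: np.random.Generator, n_background: int, size: int, n_draws: int
) -> np.ndarray:
    """Uniform random size-``size`` subsets of ``range(n_background)``.

    Returns an ``(n_draws, size)`` integer array; each row is drawn without
    replacement, rows are independent.
    """
    if size > n_background:
        raise UsageError(f"set size {size} exceeds background size {n_background}")
    if size <= 0:
        raise UsageError("set size must be positive")
    u = rng.random((n_draws, n_background))
    if size == n_background:
        return np.tile(np.arange(n_background), (n_draws, 1))
    return np.argpartition(u, size - 1, axis=1)[:, :size]


def all_index_sets(n_background: int, size: int) -> np.ndarray:
    """All C(n, k) size-``size`` subsets of ``range(n_background)``, one per row."""
    if size > n_background:
        raise UsageError(f"set size {size} exceeds background size {n_background}")
    return np.array(list(combinations(range(n_background), size)), dtype=np.intp)


def n_subsets(n_background: int, size: int) -> int:
    return comb(n_background, size)


def child_seed(root_seed: int, *key: int) -> np.random.Generator:
    """Deterministic independent RNG stream for (root seed, key path)."""
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
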