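"""Permutation tests on pattern occurrence frequencies.

Two groups of trials are compared on their frequency vectors over the
three pattern families (R, PA = PA1+PA2, PI = PI1+PI2).  The test
statistic is the omnibus sum of squared group-mean differences over the
three families; the null distribution comes from re-assigning the
exchangeable units (trials, or subgroup means in the subgroup variant)
to groups while preserving group sizes.  Sampled tests use the add-one
estimator ``p = (1 + #{S* >= S_obs}) / (B + 1)``; designs small enough
to enumerate are tested exactly instead.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .core import substream

#: Enumerate the exact null instead of sampling when the number of
#: distinct group re-assignments is at most this.
EXHAUSTIVE_LIMIT = 20_000


@dataclass
class PermutationResult:
    """Outcome of one permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    method: str  # "sampled" | "exhaustive"
    seed: int | None = None
    null_statistics: np.ndarray | None = None


def _stat_from_sums(sum_a: np.ndarray, total: np.ndarray, na: int, nb: int) -> np.ndarray:
    """Sum of squared mean differences, vectorized over permutations."""
    mean_a = sum_a / na
    mean_b = (total - sum_a) / nb
    d = mean_a - mean_b
    return (d * d).sum(axis=-1)


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 9_999,
    seed: int | None = None,
    exhaustive: bool | None = None,
    keep_null: bool = False,
) -> PermutationResult:
    """Two-group permutation test on frequency vectors.

    Parameters
    ----------
    a, b
        Arrays of shape ``(n_units, k)`` — one frequency vector per
        exchangeable unit.
    n_permutations
        Number of sampled re-assignments B (ignored in exhaustive mode).
    exhaustive
        Force or forbid exact enumeration; by default enumeration is used
        whenever the design admits at most :data:`EXHAUSTIVE_LIMIT`
        distinct re-assignments.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 exchangeable units")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the frequency categories")
    pooled = np.vstack([a, b])
    n, na, nb = len(pooled), len(a), len(b)
    total = pooled.sum(axis=0)
    observed = float(_stat_from_sums(a.sum(axis=0), total, na, nb))
    n_distinct = comb(n, na)
    if exhaustive is None:
        exhaustive = n_distinct <= EXHAUSTIVE_LIMIT
    if exhaustive:
        idx = np.array(list(combinations(range(n), na)), dtype=int)
        sums = pooled[idx].sum(axis=1)
        null = _stat_from_sums(sums, total, na, nb)
        hits = int(np.sum(null >= observed - 1e-12))
        p = hits / n_distinct
        return PermutationResult(
            statistic=observed,
            p_value=float(p),
            n_permutations=n_distinct,
            method="exhaustive",
            seed=seed,
            null_statistics=null if keep_null else None,
        )
    rng = substream(seed, "perm-test")
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    sums = pooled[order[:, :na]].sum(axis=1)
    null = _stat_from_sums(sums, total, na, nb)
    hits = int(np.sum(null >= observed - 1e-12))
    p = (1 + hits) / (n_permutations + 1)
    return PermutationResult(
        statistic=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        method="sampled",
        seed=seed,
        null_statistics=null if keep_null else None,
    )


def perm_test_trials(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 9_999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Permutation test with individual trials as the exchangeable unit."""
    return permutation_test(a, b, n_permutations, seed, exhaustive)


def perm_test_subgroups(
    a: np.ndarray,
    subgroups_a: np.ndarray,
    b: np.ndarray,
    subgroups_b: np.ndarray,
    n_permutations: int = 9_999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> PermutationResult:
    """Permutation test on subgroup-mean frequency vectors.

    Trials are first averaged within each subgroup (the squads that
    played together); subgroups are then the exchangeable units, which
    respects their internal dependence.
    """
    ma = _subgroup_means(a, subgroups_a)
    mb = _subgroup_means(b, subgroups_b)
    return permutation_test(ma, mb, n_permutations, seed, exhaustive)


def _subgroup_means(x: np.ndarray, subgroups: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    subgroups = np.asarray(subgroups)
    if len(subgroups) != len(x):
        raise ValueError("one subgroup id per trial is required")
    ids = np.unique(subgroups)
    if len(ids) < 2:
        raise ValueError("at least 2 subgroups per group are required")
    return np.vstack([x[subgroups == g].mean(axis=0) for g in ids])
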