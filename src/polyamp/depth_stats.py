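"""Read-depth modelling: how many reads guarantee seeing every allele.

A tetraploid locus carries up to four alleles (two homeologous copies, up to
two alleles each).  Given the allele proportions p_1..p_k, the probability
that n reads drawn with replacement contain every allele is the inverse
coupon collector's problem, solved exactly by inclusion-exclusion:

    P(all seen) = sum over subsets S of {1..k} of (-1)^|S| (1 - sum_{i in S} p_i)^n

A Monte-Carlo estimator (multinomial draws) is provided as a cross-check,
and an origin-forced regression estimates the ratio of copy-B to copy-A
reads that parameterizes unequal-proportion curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def _validate_proportions(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("proportions must be a nonempty 1-D vector")
    if np.any(arr <= 0):
        raise ValueError("all proportions must be > 0")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {arr.sum()!r}")
    return arr


def proportions_from_ratio(ratio: float, alleles_per_copy: int = 1) -> np.ndarray:
    """Two-copy proportions (1, ratio)/(1+ratio), optionally split per allele.

    ``ratio`` is the B:A read ratio (e.g. 1.29); with ``alleles_per_copy=2``
    each copy's mass is split equally between its two alleles, giving a
    four-category vector.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    base = np.array([1.0, ratio]) / (1.0 + ratio)
    if alleles_per_copy == 1:
        return base
    return np.repeat(base / alleles_per_copy, alleles_per_copy)


def prob_all_observed(p: Sequence[float], n: int) -> float:
    """Exact P(every category observed in n draws), by inclusion-exclusion."""
    arr = _validate_proportions(p)
    if n < 0:
        raise ValueError("n must be >= 0")
    k = arr.size
    if n < k:
        return 0.0
    total = 1.0  # empty subset
    for m in range(1, k + 1):
        sign = -1.0 if m % 2 else 1.0
        for subset in combinations(range(k), m):
            miss = 1.0 - arr[list(subset)].sum()
            if miss > 0:
                total += sign * miss**n
            elif miss == 0 and n == 0:
                total += sign
    return min(1.0, max(0.0, total))


def prob_all_observed_mc(
    p: Sequence[float],
    n: int,
    reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Monte-Carlo estimate: fraction of ``reps`` multinomial draws of size n
    containing every category."""
    arr = _validate_proportions(p)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n, arr, size=reps)
    return float(np.all(counts > 0, axis=1).mean())


def min_reads(p: Sequence[float], confidence: float) -> int:
    """Smallest n with P(all categories observed) >= confidence (analytic)."""
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    arr = _validate_proportions(p)
    n = arr.size
    while prob_all_observed(arr, n) < confidence:
        n += 1
    return n


def depth_table(p: Sequence[float], n_max: int) -> pd.DataFrame:
    """Analytic (n, probability) curve for n = 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    arr = _validate_proportions(p)
    rows = [(n, prob_all_observed(arr, n)) for n in range(1, n_max + 1)]
    return pd.DataFrame(rows, columns=["n", "probability"])


@dataclass
class RegressionResult:
    """Origin-forced regression of copy-B on copy-A read counts.

    ``t_statistic`` tests slope == 1 (are the two copies amplified evenly?)
    with ``degrees_of_freedom`` = number of pairs - 1.
    """

    slope: float
    standard_error: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    n_pairs: int
    note: str = ""

    def summary(self) -> str:
        return (
            f"B:A ratio = {self.slope:.4g} +/- {self.standard_error:.4g} "
            f"(t_{self.degrees_of_freedom} = {self.t_statistic:.4g}; "
            f"P = {self.p_value:.4g})"
            + (f" [{self.note}]" if self.note else "")
        )


def copy_ratio_regression(pairs: Iterable[tuple[float, float]]) -> RegressionResult:
    """Fit B = slope * A through the origin and t-test slope against 1.

    slope = sum(A*B) / sum(A^2); the standard error comes from the residual
    variance of the origin-forced fit with n-1 degrees of freedom.
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 (A, B) pairs")
    a, b = data[:, 0], data[:, 1]
    ssa = float(np.sum(a * a))
    if ssa == 0:
        raise ValueError("all copy-A counts are zero; slope undefined")
    slope = float(np.sum(a * b) / ssa)
    n = data.shape[0]
    df = n - 1
    resid = b - slope * a
    s2 = float(np.sum(resid**2)) / df
    se = math.sqrt(s2 / ssa)
    if se == 0.0:
        t = math.inf if slope != 1.0 else 0.0
        pval = 0.0 if slope != 1.0 else 1.0
        note = "perfect fit: zero residual variance" if slope != 1.0 else ""
    else:
        t = (slope - 1.0) / se
        pval = 2.0 * float(stats.t.sf(abs(t), df))
        note = ""
    return RegressionResult(slope, se, t, df, pval, n, note)
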