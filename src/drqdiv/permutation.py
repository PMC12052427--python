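"""Permutational inference on assemblage compositions.

The omnibus test is a one-way distance-based MANOVA (PERMANOVA): a
pseudo-F statistic computed from sums of squared dissimilarities,

    SS_total   = (1/N) Σ_{i<j} d(i,j)²
    SS_within  = Σ_g (1/n_g) Σ_{i<j within g} d(i,j)²
    F          = (SS_between / (a − 1)) / (SS_within / (N − a)),

with significance assessed by randomly permuting group labels. Pairwise
dissimilarities between (D, R, Q) compositions use Bray–Curtis, which on
unit-sum triplets reduces to half the L1 distance. Univariate follow-up
tests on a single component use the classical one-way F with the same
permutation scheme; for a one-way design this is equivalent to PERMANOVA
on Euclidean distances of the raw values.

p-values use the add-one convention p = (n_ge + 1) / (n_perm + 1), which
keeps the test valid (p is never 0) and counts ties conservatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "PermutationTestResult",
    "bray_curtis_matrix",
    "permanova_pseudo_f",
    "permanova_test",
    "univariate_perm_anova",
]


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_perm: int
    n_ge: int
    group_sizes: tuple[int, ...]
    seed: int | None
    method: str = "monte-carlo"

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_perm + 1) - 1e-15


def bray_curtis_matrix(compositions) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between (D, R, Q) compositions.

    ``compositions`` is a DataFrame with columns D, R, Q (extra columns
    ignored), or any (n, 3) array. BC(x, y) = Σ|x_k − y_k| / Σ(x_k + y_k);
    for unit-sum triplets this is half the L1 distance.
    """
    if isinstance(compositions, pd.DataFrame):
        ids = [str(i) for i in compositions.index.to_flat_index()]
        x = compositions[["D", "R", "Q"]].to_numpy(dtype=float)
    else:
        x = np.asarray(
            [c.as_tuple() if hasattr(c, "as_tuple") else c for c in compositions],
            dtype=float,
        )
        ids = [str(i) for i in range(len(x))]
    if len(x) < 2:
        raise ValueError("need at least two compositions")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=ids)


def _group_index(labels) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(np.asarray(labels))
    sizes = np.bincount(codes)
    return codes, sizes


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    n = d2.shape[0]
    a = sizes.size
    ss_total = d2.sum() / (2.0 * n)
    onehot = np.eye(a)[codes]  # N × a
    within_blocks = np.einsum("ig,ij,jg->g", onehot, d2, onehot)
    ss_within = float((within_blocks / (2.0 * sizes)).sum())
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_between > 1e-12 * max(ss_total, 1.0) else math.nan
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _validate(dm: DistanceMatrix, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(dm.data, dtype=float)
    codes, sizes = _group_index(labels)
    n, a = d.shape[0], sizes.size
    if len(codes) != n:
        raise ValueError("labels length does not match distance matrix")
    if a < 2:
        raise ValueError("need at least two groups")
    if n - a < 1:
        raise ValueError("residual degrees of freedom are zero (N − a = 0)")
    if not np.any(d > 0):
        raise ValueError("all dissimilarities are zero: no test is possible")
    return d * d, codes, sizes


def permanova_pseudo_f(dm: DistanceMatrix, labels) -> float:
    """Observed pseudo-F for a one-way grouping of the points in ``dm``.

    Returns ``inf`` when all within-group dissimilarities are zero but
    groups differ (perfect separation).
    """
    d2, codes, sizes = _validate(dm, labels)
    f = _pseudo_f(d2, codes, sizes)
    if math.isnan(f):
        raise ValueError("all dissimilarities are zero: no test is possible")
    return f


def _perm_pvalue(f_obs: float, f_perm: np.ndarray) -> tuple[int, float]:
    n_ge = int(np.sum(f_perm >= f_obs))
    return n_ge, (n_ge + 1) / (len(f_perm) + 1)


def permanova_test(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """One-way PERMANOVA with a label-permutation null.

    Labels are permuted uniformly at random ``n_perm`` times (Monte Carlo);
    with ``exhaustive=True`` every distinct label arrangement is enumerated
    instead (feasible for small N only) and ``n_perm``/``seed`` are
    ignored. Ties (permuted F equal to the observed F) count against the
    null; an infinite observed statistic is beaten only by permutations
    that also separate the groups perfectly.
    """
    d2, codes, sizes = _validate(dm, labels)
    f_obs = _pseudo_f(d2, codes, sizes)
    if math.isnan(f_obs):
        raise ValueError("all dissimilarities are zero: no test is possible")

    if exhaustive:
        f_perm = np.array(
            [
                _pseudo_f(d2, np.asarray(arr, dtype=int), sizes)
                for arr in multiset_permutations(codes.tolist())
            ]
        )
        n_ge, p = _perm_pvalue(f_obs, f_perm)
        return PermutationTestResult(
            f_obs, p, len(f_perm), n_ge, tuple(int(s) for s in sizes), seed, "exhaustive"
        )

    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = _pseudo_f(d2, codes[rng.permutation(codes.size)], sizes)
    n_ge, p = _perm_pvalue(f_obs, f_perm)
    return PermutationTestResult(
        f_obs, p, n_perm, n_ge, tuple(int(s) for s in sizes), seed, "monte-carlo"
    )


def _anova_f(x: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    grand = x.mean()
    group_means = np.bincount(codes, weights=x) / sizes
    ss_between = float(sizes @ (group_means - grand) ** 2)
    ss_within = float(((x - group_means[codes]) ** 2).sum())
    a, n = sizes.size, x.size
    if ss_within <= 0:
        return math.inf if ss_between > 0 else math.nan
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def univariate_perm_anova(
    values,
    labels,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Permutation one-way ANOVA on a single diversity component."""
    x = np.asarray(values, dtype=float)
    codes, sizes = _group_index(labels)
    if sizes.size < 2:
        raise ValueError("need at least two groups")
    if x.size - sizes.size < 1:
        raise ValueError("residual degrees of freedom are zero")
    if np.allclose(x, x[0]):
        raise ValueError("zero total variance: no test is possible")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    f_obs = _anova_f(x, codes, sizes)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for b in range(n_perm):
        f_perm[b] = _anova_f(x[rng.permutation(x.size)], codes, sizes)
    n_ge, p = _perm_pvalue(f_obs, f_perm)
    return PermutationTestResult(
        f_obs, p, n_perm, n_ge, tuple(int(s) for s in sizes), seed, "monte-carlo"
    )
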