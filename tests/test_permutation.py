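"""Bray–Curtis distances, the pseudo-F statistic and permutation p-values."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from drqdiv import (
    bray_curtis_matrix,
    permanova_pseudo_f,
    permanova_test,
    univariate_perm_anova,
)

from conftest import random_simplex


def dm_of(d, ids=None):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(d, ids=ids or [str(i) for i in range(d.shape[0])])


def points_dm(pts):
    pts = np.asarray(pts, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return dm_of(0.5 * (d + d.T))


def pseudo_f_oracle(d: np.ndarray, labels) -> float:
    """Pseudo-F evaluated with explicit loops (independent path)."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_within += sum(
            d[i, j] ** 2 for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    if ss_within == 0:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((0.2, 0.3, 0.5), (0.2, 0.3, 0.5), 0.0),
            ((1, 0, 0), (0, 1, 0), 1.0),
            ((0.5, 0.25, 0.25), (0.25, 0.5, 0.25), 0.25),
        ],
    )
    def test_hand_computed_pairs(self, x, y, expected):
        df = pd.DataFrame([x, y], columns=["D", "R", "Q"])
        dm = bray_curtis_matrix(df)
        assert dm[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_equals_half_l1_on_unit_sum_triplets(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            x, y = random_simplex(rng, 3), random_simplex(rng, 3)
            dm = bray_curtis_matrix(pd.DataFrame([x, y], columns=["D", "R", "Q"]))
            assert dm[0, 1] == pytest.approx(0.5 * np.abs(x - y).sum(), abs=1e-12)

    def test_requires_two_compositions(self):
        with pytest.raises(ValueError):
            bray_curtis_matrix(pd.DataFrame([[1, 0, 0]], columns=["D", "R", "Q"]))


class TestPseudoF:
    def test_hand_computed_four_points(self):
        # two groups of two: within distances 1 and 2, across distances 3
        d = np.array(
            [
                [0, 1, 3, 3],
                [1, 0, 3, 3],
                [3, 3, 0, 2],
                [3, 3, 2, 0],
            ],
            dtype=float,
        )
        labels = ["a", "a", "b", "b"]
        # SS_total = (1+4+9·4)/4 = 10.25 ; SS_within = 1/2 + 4/2 = 2.5
        # F = (7.75/1) / (2.5/2) = 6.2
        assert permanova_pseudo_f(dm_of(d), labels) == pytest.approx(6.2)

    def test_perfect_separation_gives_infinity(self):
        pts = [[0, 0], [0, 0], [5, 5], [5, 5]]
        f = permanova_pseudo_f(points_dm(pts), ["a", "a", "b", "b"])
        assert math.isinf(f)

    def test_all_zero_distances_error(self):
        with pytest.raises(ValueError):
            permanova_pseudo_f(dm_of(np.zeros((4, 4))), ["a", "a", "b", "b"])

    def test_zero_residual_df_errors(self):
        with pytest.raises(ValueError):
            permanova_pseudo_f(points_dm([[0], [1]]), ["a", "b"])

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 2))
        labels = ["a", "a", "a", "b", "b", "b", "c", "c"]
        dm = points_dm(pts)
        f = permanova_pseudo_f(dm, labels)
        renamed = [{"a": "x", "b": "y", "c": "z"}[lab] for lab in labels]
        assert permanova_pseudo_f(dm, renamed) == pytest.approx(f)
        perm = rng.permutation(8)
        dm2 = dm_of(dm.data[np.ix_(perm, perm)])
        assert permanova_pseudo_f(dm2, [labels[i] for i in perm]) == pytest.approx(f)

    @pytest.mark.parametrize("rep", range(5))
    def test_matches_loop_oracle_and_skbio(self, rep):
        rng = np.random.default_rng(700 + rep)
        n = int(rng.integers(6, 12))
        pts = rng.normal(size=(n, 3))
        labels = rng.choice(["a", "b", "c"], size=n).tolist()
        if len(set(labels)) < 2:
            labels[0] = "a" if labels[0] != "a" else "b"
        dm = points_dm(pts)
        f = permanova_pseudo_f(dm, labels)
        assert f == pytest.approx(pseudo_f_oracle(dm.data, labels), abs=1e-10)
        ref = skbio_permanova(dm, grouping=labels, permutations=0)
        assert f == pytest.approx(ref["test statistic"], abs=1e-10)


class TestPermanovaTest:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        dm = points_dm(rng.normal(size=(10, 2)))
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova_test(dm, labels, n_perm=199, seed=42)
        r2 = permanova_test(dm, labels, n_perm=199, seed=42)
        assert (r1.statistic, r1.p_value, r1.n_ge) == (r2.statistic, r2.p_value, r2.n_ge)
        assert r1.p_value == (r1.n_ge + 1) / (r1.n_perm + 1)

    def test_exhaustive_on_separated_groups_reaches_floor(self):
        # balanced 3+3, maximally separated: only the identity and the
        # group-swapped arrangements reach the observed (infinite) statistic
        pts = [[0, 0]] * 3 + [[9, 9]] * 3
        dm = points_dm(pts)
        res = permanova_test(dm, ["a"] * 3 + ["b"] * 3, exhaustive=True)
        assert math.isinf(res.statistic)
        assert res.method == "exhaustive"
        assert res.n_perm == 20  # C(6,3) distinct label arrangements
        # smallest achievable p for these data under (n_ge+1)/(n_perm+1)
        assert res.p_value == pytest.approx((res.n_ge + 1) / 21)
        assert res.n_ge == 2

    def test_monte_carlo_converges_to_exhaustive_enumeration(self):
        rng = np.random.default_rng(91)
        pts = rng.normal(size=(7, 2))
        pts[4:] += 1.5
        labels = ["a"] * 4 + ["b"] * 3
        dm = points_dm(pts)
        f_obs = pseudo_f_oracle(dm.data, labels)
        # independent oracle: enumerate all 7! label orderings
        count = total = 0
        for perm in itertools.permutations(range(7)):
            total += 1
            count += pseudo_f_oracle(dm.data, [labels[i] for i in perm]) >= f_obs
        p_exact = count / total
        res = permanova_test(dm, labels, n_perm=4999, seed=17)
        se = math.sqrt(p_exact * (1 - p_exact) / res.n_perm)
        assert abs(res.p_value - p_exact) <= 3 * se + 1 / res.n_perm

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(55)
        n_datasets, rejections = 400, 0
        for i in range(n_datasets):
            pts = rng.normal(size=(10, 3))
            dm = points_dm(pts)
            res = permanova_test(dm, ["a"] * 5 + ["b"] * 5, n_perm=99,
                                 seed=int(rng.integers(2**31)))
            # p <= alpha: exact size floor(alpha(B+1))/(B+1) = 0.05 at B = 99
            rejections += res.p_value <= 0.05
        from scipy.stats import binom

        lo, hi = binom.interval(0.99, n_datasets, 0.05)
        assert lo <= rejections <= hi

    def test_n_perm_must_be_positive(self):
        dm = points_dm([[0, 0], [1, 1], [2, 0], [3, 1]])
        with pytest.raises(ValueError):
            permanova_test(dm, ["a", "a", "b", "b"], n_perm=0, seed=1)


class TestUnivariate:
    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            univariate_perm_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"],
                                  n_perm=99, seed=0)

    def test_equals_euclidean_permanova_pseudo_f(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = univariate_perm_anova(x, labels, n_perm=9, seed=0)
        dm = points_dm(x[:, None])
        assert res.statistic == pytest.approx(permanova_pseudo_f(dm, labels))
        # and against the classical one-way F
        from scipy.stats import f_oneway

        f_ref = f_oneway(x[:4], x[4:8], x[8:]).statistic
        assert res.statistic == pytest.approx(f_ref)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(77)
        n_datasets, rejections = 400, 0
        for _ in range(n_datasets):
            x = rng.normal(size=12)
            res = univariate_perm_anova(x, ["a"] * 6 + ["b"] * 6, n_perm=99,
                                        seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        from scipy.stats import binom

        lo, hi = binom.interval(0.99, n_datasets, 0.05)
        assert lo <= rejections <= hi
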