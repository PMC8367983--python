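"""The nonparametric battery against independent oracles.

Kruskal-Wallis is checked against scipy.stats.kruskal, Holm against
statsmodels.multipletests, Dunn against a from-scratch recomputation of mean
ranks and the tie term written here (sorting-based, no shared code), and
Pearson against the textbook covariance formula.
"""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from polyatails.stats import (
    compare_groups,
    dunn_pairwise,
    holm_adjust,
    kruskal_wallis,
    pearson_on_intersection,
    rank_epsilon_squared,
)


def _random_groups(rng, max_groups=4, ties=True):
    k = int(rng.integers(2, max_groups + 1))
    sizes = rng.integers(3, 15, k)
    if ties:  # integer support forces ties
        return [rng.integers(0, 10, n).astype(float) for n in sizes]
    return [rng.normal(size=n) for n in sizes]


def _manual_ranks(pooled):
    """Mid-ranks by explicit sorting, independent of scipy."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = mid
        i = j + 1
    return ranks


class TestKruskalWallis:
    def test_identical_groups_are_null(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fully_separated_equal_groups(self):
        # mean ranks 2, 5, 8: H = 12/(9*10)*(3*4+3*25+3*64) - 30 = 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_all_values_tied_returns_null_not_error(self):
        h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])

    def test_matches_scipy_on_random_tied_data(self, rng):
        for _ in range(100):
            groups = _random_groups(rng)
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = sps.kruskal(*groups)
            assert h == pytest.approx(float(h_ref), abs=1e-10)
            assert p == pytest.approx(float(p_ref), rel=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        groups = _random_groups(rng, ties=False)
        transformed = [np.exp(g) + 7 for g in groups]
        assert kruskal_wallis(groups) == pytest.approx(kruskal_wallis(transformed))


class TestRankEpsilonSquared:
    def test_closed_forms(self):
        assert rank_epsilon_squared(0.0, 50) == 0.0
        assert rank_epsilon_squared(4.0, 9) == pytest.approx(0.5)  # 4*10/80
        assert rank_epsilon_squared(8.0, 9) == pytest.approx(1.0)  # H = n-1

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rank_epsilon_squared(1.0, 1)

    def test_bounded_on_random_data(self, rng):
        for _ in range(50):
            groups = _random_groups(rng)
            h, _ = kruskal_wallis(groups)
            eps = rank_epsilon_squared(h, sum(len(g) for g in groups))
            assert 0.0 <= eps <= 1.0


class TestDunnPairwise:
    def test_identical_groups_give_zero_z(self):
        for pr in dunn_pairwise([[1, 2, 3], [1, 2, 3], [1, 2, 3]]):
            assert pr.z == pytest.approx(0.0, abs=1e-12)
            assert pr.p_raw == pytest.approx(1.0)

    def test_label_swap_negates_z(self, rng):
        a, b, c = _random_groups(rng, max_groups=3), None, None
        while len(a) != 3:
            a = _random_groups(rng, max_groups=3)
        z_abc = {(p.group_a, p.group_b): p.z for p in dunn_pairwise(a, ["A", "B", "C"])}
        swapped = [a[1], a[0], a[2]]
        z_bac = {(p.group_a, p.group_b): p.z for p in dunn_pairwise(swapped, ["B", "A", "C"])}
        assert z_bac[("B", "A")] == pytest.approx(-z_abc[("A", "B")])

    def test_all_tied_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            dunn_pairwise([[3, 3], [3, 3]])

    def test_matches_from_scratch_recomputation(self, rng):
        for _ in range(100):
            groups = _random_groups(rng)
            results = dunn_pairwise(groups)
            pooled = [float(x) for g in groups for x in g]
            ranks = _manual_ranks(pooled)
            n_total = len(pooled)
            tie = sum(c**3 - c for c in Counter(pooled).values())
            var = n_total * (n_total + 1) / 12 - tie / (12 * (n_total - 1))
            offsets = np.cumsum([0] + [len(g) for g in groups])
            mean_ranks = [
                np.mean(ranks[offsets[i] : offsets[i + 1]]) for i in range(len(groups))
            ]
            for pr, (i, j) in zip(results, itertools.combinations(range(len(groups)), 2)):
                se = np.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                assert pr.z == pytest.approx(z, abs=1e-10)
                assert pr.p_raw == pytest.approx(min(1.0, 2 * sps.norm.sf(abs(z))), abs=1e-12)


class TestHolmAdjust:
    def test_two_value_closed_form(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 21)))
            ours = holm_adjust(p)
            _, ref, _, _ = multipletests(p, method="holm")
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone(self, rng):
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])


class TestPearsonOnIntersection:
    def test_perfect_linear_relations(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        r, n = pearson_on_intersection(x, 2 * x + 1)
        assert (r, n) == (pytest.approx(1.0), 4)
        r, _ = pearson_on_intersection(x, -x)
        assert r == pytest.approx(-1.0)

    def test_placeholders_and_missing_keys_excluded(self):
        x = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 0.01, "e": 9.0})
        y = pd.Series({"a": 2.0, "b": 4.0, "c": 6.0, "d": 8.0, "f": 1.0})
        r, n = pearson_on_intersection(x, y)
        assert n == 3  # d is a placeholder in x, e/f unshared
        assert r == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        keys = [f"T{i}" for i in range(200)]
        x = pd.Series(rng.normal(size=200), index=keys)
        y = pd.Series(0.4 * x.to_numpy() + rng.normal(size=200), index=keys)
        r, n = pearson_on_intersection(x, y)
        a, b = x.to_numpy(), y.to_numpy()
        want = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        assert n == 200
        assert r == pytest.approx(float(want), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        x = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
        y = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            pearson_on_intersection(x, y)
        with pytest.raises(ValueError):
            pearson_on_intersection(y[:2], y[:2])


class TestCompareGroups:
    def test_family_is_holm_adjusted_and_consistent(self, rng):
        groups = [rng.normal(loc=m, size=25) for m in (0.0, 0.3, 1.2)]
        result, pairs = compare_groups(groups, ["a", "b", "c"])
        assert result.group_sizes == (25, 25, 25)
        adj = holm_adjust([p.p_raw for p in pairs])
        assert [p.p_holm for p in pairs] == pytest.approx(adj)
        for p in pairs:
            assert p.p_holm >= p.p_raw - 1e-15
            assert p.significant == (p.p_holm <= 0.001)
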