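"""Statistics layer: exact small-sample tests, fits, fold changes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podosim import (
    fold_change,
    kruskal_wallis_dunn,
    linear_fit,
    mann_whitney_u,
    spearman_rho,
)


def brute_force_mw_p(x, y):
    """Independent enumeration oracle for the two-sided Mann-Whitney p."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(comb) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = mann_whitney_u([5, 5, 5], [5, 5, 5], mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (2, 7), (8, 8)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.8, 1, n2)
            res = mann_whitney_u(x, y, mode="exact")
            assert res.p_value == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact_at_8_plus_8(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        exact = mann_whitney_u(x, y, mode="exact").p_value
        approx = mann_whitney_u(x, y, mode="asymptotic").p_value
        assert abs(exact - approx) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 50), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 50), min_size=2, max_size=6),
    )
    def test_exact_p_valid_and_symmetric(self, x, y):
        p_xy = mann_whitney_u(x, y, mode="exact").p_value
        p_yx = mann_whitney_u(y, x, mode="exact").p_value
        assert 0.0 < p_xy <= 1.0
        assert p_xy == pytest.approx(p_yx, abs=1e-12)


class TestKruskalWallisDunn:
    def test_identical_groups_null(self):
        res = kruskal_wallis_dunn([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(v["p_adjusted"] == pytest.approx(1.0) for v in res.pairwise.values())

    def test_fully_separated_ranks_hand_value(self):
        """Ranks (1-3), (4-6), (7-9) give H = 7.2."""
        res = kruskal_wallis_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_adjustment_never_decreases_p(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0, 0.5, 1.5)]
        res = kruskal_wallis_dunn(groups)
        for v in res.pairwise.values():
            assert v["p_adjusted"] >= v["p_unadjusted"] - 1e-12

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="mann_whitney_u"):
            kruskal_wallis_dunn([[1, 2], [3, 4]])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_hand_worked_ranks(self):
        """Ranks (1..5) vs (2,1,4,3,5): rho = 1 - 6*4/120 = 0.8."""
        res = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.statistic == pytest.approx(0.8)

    def test_exact_small_sample_p_matches_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        res = spearman_rho(x, y)
        # enumeration over all 120 orderings of y
        from scipy.stats import spearmanr

        rho_obs = spearmanr(x, y).statistic
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(spearmanr(x, perm).statistic) >= abs(rho_obs) - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            res = spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)


class TestLinearFit:
    def test_collinear_points(self):
        res = linear_fit([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_y_degenerate(self):
        res = linear_fit([0, 1, 2, 3], [4, 4, 4, 4])
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2, 2, 2], [1, 2, 3])

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(0, 2, 10)
        y = 1.3 * x - 0.7 + rng.normal(0, 0.5, 10)
        res = linear_fit(x, y)
        # independent route: solve the least-squares normal equations
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
        assert res.slope == pytest.approx(slope, abs=1e-6)
        assert res.intercept == pytest.approx(intercept, abs=1e-6)


class TestFoldChange:
    def test_insulin_style_fold(self):
        assert fold_change([6.4, 6.4], [1.0, 1.0]) == pytest.approx(6.4)

    def test_identical_groups(self):
        assert fold_change([2.0, 4.0], [2.0, 4.0]) == pytest.approx(1.0)

    def test_reciprocal_identity(self, rng):
        a = rng.lognormal(0, 0.3, 8)
        b = rng.lognormal(0.5, 0.3, 8)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change([1.0], [0.0])
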