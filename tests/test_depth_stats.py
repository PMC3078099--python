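"""Inverse coupon-collector depth model and the copy-ratio regression."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyamp.depth_stats import (
    copy_ratio_regression,
    depth_table,
    min_reads,
    prob_all_observed,
    prob_all_observed_mc,
    proportions_from_ratio,
)


def brute_force_prob(p, n):
    """Exhaustive enumeration over all |p|^n outcomes (tiny n only)."""
    k = len(p)
    total = 0.0
    for outcome in itertools.product(range(k), repeat=n):
        if set(outcome) == set(range(k)):
            prob = 1.0
            for i in outcome:
                prob *= p[i]
            total += prob
    return total


def test_two_equal_categories_closed_form():
    """P(both of two equal alleles seen in n reads) = 1 - 2^(1-n)."""
    for n in range(1, 51):
        assert prob_all_observed([0.5, 0.5], n) == pytest.approx(
            1 - 2.0 ** (1 - n), abs=1e-14
        )


def test_four_equal_alleles_exhaustive_enumeration():
    """n=4 draws of 4 equal alleles: 4!/4^4 = 24/256 by enumeration."""
    assert brute_force_prob([0.25] * 4, 4) == pytest.approx(24 / 256)
    assert prob_all_observed([0.25] * 4, 4) == pytest.approx(24 / 256, abs=1e-12)


@pytest.mark.parametrize("n", [4, 5, 6, 7])
def test_inclusion_exclusion_matches_brute_force_unequal(n):
    p = [0.1, 0.2, 0.3, 0.4]
    assert prob_all_observed(p, n) == pytest.approx(brute_force_prob(p, n), abs=1e-12)


def test_tetraploid_locus_needs_sixteen_reads_analytically():
    """The 95% threshold for four equal alleles sits between 15 and 16 reads."""
    p = [0.25] * 4
    assert prob_all_observed(p, 15) == pytest.approx(0.946729, abs=1e-6)
    assert prob_all_observed(p, 16) == pytest.approx(0.960001, abs=1e-6)
    assert min_reads(p, 0.95) == 16


def test_unequal_copy_ratio_needs_five_to_seven_reads():
    """With the observed nuclear copy ratios, both copies are seen with 95%
    confidence within five to seven reads."""
    assert min_reads(proportions_from_ratio(1.29), 0.95) == 6
    assert 5 <= min_reads(proportions_from_ratio(1.87), 0.95) <= 8


def test_fewer_reads_than_categories_gives_zero():
    assert prob_all_observed([0.25] * 4, 3) == 0.0
    assert prob_all_observed([0.25] * 4, 0) == 0.0


def test_monte_carlo_agrees_with_analytic():
    p = [0.25] * 4
    exact = prob_all_observed(p, 15)
    est = prob_all_observed_mc(p, 15, reps=10_000, seed=1)
    se = math.sqrt(exact * (1 - exact) / 10_000)
    assert abs(est - exact) <= 4 * se


def test_monte_carlo_determinism_and_degenerate_case():
    assert prob_all_observed_mc([1.0], 5, reps=100, seed=3) == 1.0
    a = prob_all_observed_mc([0.3, 0.7], 8, reps=2000, seed=42)
    b = prob_all_observed_mc([0.3, 0.7], 8, reps=2000, seed=42)
    assert a == b


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(0.05, 1.0), min_size=2, max_size=6),
    st.integers(1, 40),
)
def test_probability_properties(weights, n):
    """Monotone in n, invariant under permutation, bounded in [0, 1]."""
    p = np.array(weights) / sum(weights)
    prob = prob_all_observed(p, n)
    assert 0.0 <= prob <= 1.0
    assert prob <= prob_all_observed(p, n + 1) + 1e-12
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(p))
    assert prob_all_observed(p[perm], n) == pytest.approx(prob, abs=1e-12)


def test_min_reads_is_the_crossing_point():
    for p in ([0.25] * 4, proportions_from_ratio(1.29), [0.1, 0.9]):
        n = min_reads(p, 0.95)
        assert prob_all_observed(p, n) >= 0.95
        assert prob_all_observed(p, n - 1) < 0.95


def test_depth_table_matches_pointwise():
    table = depth_table([0.5, 0.5], 10)
    assert list(table["n"]) == list(range(1, 11))
    for _, row in table.iterrows():
        assert row["probability"] == pytest.approx(1 - 2.0 ** (1 - row["n"]), abs=1e-14)
    assert table["probability"].is_monotonic_increasing


# --- copy-ratio regression -------------------------------------------------


def test_regression_slope_formula_example():
    """slope = sum(AB)/sum(A^2) on the worked four-pair example."""
    r = copy_ratio_regression([(10, 18), (20, 27), (30, 55), (40, 52)])
    assert r.slope == pytest.approx(4450 / 3000, abs=1e-12)
    assert r.degrees_of_freedom == 3
    assert 0 <= r.p_value <= 1


def test_regression_identity_and_perfect_fit():
    r = copy_ratio_regression([(1, 1), (2, 2), (3, 3)])
    assert r.slope == pytest.approx(1.0)
    assert r.t_statistic == pytest.approx(0.0)
    r2 = copy_ratio_regression([(1, 2), (2, 4), (3, 6)])
    assert r2.slope == pytest.approx(2.0)
    assert r2.standard_error == 0.0
    assert math.isinf(r2.t_statistic)
    assert r2.note


def test_regression_agrees_with_least_squares_oracle():
    """Origin-forced fit vs statsmodels OLS (no intercept) on random data."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12345)
    for _ in range(100):
        n = rng.integers(3, 30)
        a = rng.uniform(1, 100, n)
        b = 1.5 * a + rng.normal(0, 10, n)
        ours = copy_ratio_regression(list(zip(a, b)))
        ols = sm.OLS(b, a).fit()
        assert ours.slope == pytest.approx(ols.params[0], rel=1e-10)
        assert ours.standard_error == pytest.approx(ols.bse[0], rel=1e-8)
        assert ours.degrees_of_freedom == n - 1


def test_regression_input_validation():
    with pytest.raises(ValueError):
        copy_ratio_regression([(1, 2)])
    with pytest.raises(ValueError):
        copy_ratio_regression([(0, 1), (0, 2)])
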