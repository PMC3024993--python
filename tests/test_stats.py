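"""Estimators against hand-coded oracles and known contingency tables."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import make_person
from statuslink.ascertainment import classify
from statuslink.records import IndigenousFlag
from statuslink.stats import (
    CrossTab,
    chi_square,
    complement_pct,
    death_cross_tab,
    excess_pct,
    relative_risk,
    round_half_up,
    underestimation_pct,
    wilson_interval,
)

POS, NEG, MISS = IndigenousFlag.POSITIVE, IndigenousFlag.NEGATIVE, IndigenousFlag.MISSING


# --- independent oracles -----------------------------------------------------


def wilson_oracle(k, n, conf):
    """Wilson score interval from first principles (solve the score inequality)."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    p = k / n
    centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
    return centre - half, centre + half


def katz_oracle(a, n1, b, n2, conf):
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2)
    rr = (a / n1) / (b / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    return rr * math.exp(-z * se), rr * math.exp(z * se)


# --- percentage estimators ---------------------------------------------------


def test_underestimation_pct_examples():
    assert underestimation_pct(714, 975) == 26.8
    assert underestimation_pct(3060, 3696) == 17.2
    assert underestimation_pct(42, 42) == 0.0


def test_underestimation_pct_domain():
    with pytest.raises(ValueError):
        underestimation_pct(1, 0)
    with pytest.raises(ValueError):
        underestimation_pct(10, 5)


def test_excess_pct_examples():
    assert excess_pct(3060, 83) == 2.7
    assert excess_pct(3060, 636) == 20.8
    assert excess_pct(7, 0) == 0.0
    with pytest.raises(ValueError):
        excess_pct(0, 5)


@given(st.integers(1, 10_000), st.integers(0, 10_000))
def test_shortfall_and_excess_are_consistent(observed, added):
    """(1 − u/100)(1 + e/100) = 1: the two conventions describe one ratio."""
    revised = observed + added
    u = underestimation_pct(observed, revised, ndigits=None)
    e = excess_pct(observed, added, ndigits=None)
    assert (1 - u / 100) * (1 + e / 100) == pytest.approx(1.0, rel=1e-12)


def test_round_half_up_ties_go_up():
    assert round_half_up(26.75, 1) == 26.8
    assert round_half_up(17.5, 0) == 18.0


# --- Wilson ------------------------------------------------------------------


@pytest.mark.parametrize(
    "k, n", [(1, 10), (5, 10), (714, 975), (50, 1000), (999, 1000), (3, 7)]
)
@pytest.mark.parametrize("conf", [0.90, 0.95, 0.99])
def test_wilson_matches_first_principles(k, n, conf):
    est = wilson_interval(k, n, conf)
    low, high = wilson_oracle(k, n, conf)
    assert est.ci_low == pytest.approx(low, abs=1e-10)
    assert est.ci_high == pytest.approx(high, abs=1e-10)
    assert 0 < est.ci_low < est.point < est.ci_high < 1


def test_wilson_zero_numerator():
    est = wilson_interval(0, 10)
    assert est.ci_low == 0.0 and est.ci_high > 0


def test_wilson_narrows_with_n():
    wide = wilson_interval(5, 10)
    narrow = wilson_interval(500, 1000)
    assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)


def test_complement_transform_swaps_bounds():
    est = complement_pct(wilson_interval(714, 975))
    assert est.rounded() == (26.8, 24.1, 29.6)
    # Wald on the same cells gives (24.0, 29.5) and must not be produced
    p = 714 / 975
    wald_low = (1 - (p + 1.959964 * math.sqrt(p * (1 - p) / 975))) * 100
    assert round_half_up(wald_low, 1) == 24.0
    assert est.rounded()[1] != 24.0


# --- relative risk -----------------------------------------------------------


def test_relative_risk_identical_rates_is_unity():
    est = relative_risk(10, 100, 30, 300)
    assert est.point == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


@pytest.mark.parametrize(
    "a, n1, b, n2",
    [(10, 100, 5, 100), (73, 859, 842, 18950), (3, 30, 20, 200), (50, 60, 40, 80)],
)
def test_relative_risk_matches_katz_oracle(a, n1, b, n2):
    est = relative_risk(a, n1, b, n2)
    low, high = katz_oracle(a, n1, b, n2, 0.95)
    assert est.point == pytest.approx((a / n1) / (b / n2))
    assert est.ci_low == pytest.approx(low) and est.ci_high == pytest.approx(high)


@pytest.mark.parametrize("a, n1, b, n2", [(10, 100, 5, 100), (7, 50, 21, 90)])
def test_relative_risk_matches_statsmodels(a, n1, b, n2):
    """Independent route: the contingency-table implementation in statsmodels."""
    from statsmodels.stats.contingency_tables import Table2x2

    sm = Table2x2([[a, n1 - a], [b, n2 - b]])
    est = relative_risk(a, n1, b, n2)
    assert est.point == pytest.approx(sm.riskratio)
    assert (est.ci_low, est.ci_high) == pytest.approx(sm.riskratio_confint(0.05))


@given(
    st.integers(1, 50), st.integers(50, 200), st.integers(1, 50), st.integers(50, 200)
)
def test_relative_risk_inversion_symmetry(a, n1, b, n2):
    assert relative_risk(a, n1, b, n2).point == pytest.approx(
        1.0 / relative_risk(b, n2, a, n1).point
    )


def test_relative_risk_zero_numerator_flagged():
    est = relative_risk(0, 10, 5, 100)
    assert not est.defined and est.point == 0.0


# --- chi-square --------------------------------------------------------------


def test_chi_square_identical_rows():
    res = chi_square([[10, 20], [10, 20]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_known_table():
    res = chi_square([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(6.667, abs=5e-4)
    assert res.df == 1


def test_chi_square_df_and_low_expected_warning():
    assert chi_square([[5, 5], [5, 5], [5, 5]]).df == 2
    assert chi_square([[1, 9], [2, 8]]).low_expected


@given(
    st.lists(
        st.tuples(st.integers(1, 40), st.integers(1, 40)), min_size=2, max_size=5
    )
)
def test_chi_square_matches_expected_count_arithmetic(rows):
    """Brute-force Pearson statistic from marginal-product expected counts."""
    table = np.array(rows, dtype=float)
    res = chi_square(table)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    stat = ((table - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(stat, rel=1e-10)
    assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)


# --- death cross-tabulation --------------------------------------------------


def test_cross_tab_from_published_style_counts():
    ct = CrossTab.from_counts((654, 60), (188, 18048), (73, 786))
    assert ct.n_deaths == 19809
    assert ct.death_positive_total == 714
    assert ct.hospital_positive_total == 915
    assert ct.union_positive_total == 975


def test_death_cross_tab_counts_only_deceased():
    people = [
        make_person([POS, POS], death_flag=POS, pid="a"),  # hospital+ / death+
        make_person([NEG, NEG], death_flag=POS, pid="b"),  # hospital− / death+
        make_person([POS, NEG], death_flag=MISS, pid="c"),  # hospital+ / missing
        make_person([NEG, NEG], death_flag=NEG, pid="d"),
        make_person([POS, POS], pid="e"),  # alive: excluded
    ]
    ct = death_cross_tab(classify(p) for p in people)
    assert ct.row(POS) == (1, 1)
    assert ct.row(NEG) == (0, 1)
    assert ct.row(MISS) == (1, 0)
    assert ct.n_deaths == 4
    assert ct.union_positive_total == 3  # a, b, c


def test_cross_tab_degenerate_inputs():
    empty = death_cross_tab([])
    assert empty.n_deaths == 0
    assert not empty.missingness_rr().defined
    with pytest.raises(ValueError):
        empty.underascertainment()
    all_missing = CrossTab.from_counts((0, 0), (0, 0), (3, 7))
    assert not all_missing.missingness_rr().defined
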