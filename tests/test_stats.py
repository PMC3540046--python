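"""Exact 2x2 statistics: Fisher P, odds ratios, Bonferroni, mean comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hla2x2.stats import (CountTable2x2, bonferroni, compare_means,
                          compare_means_raw, fisher_two_sided, fmt_p,
                          odds_ratio_ci)


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaustive point-probability sum over the
    hypergeometric support, using exact integer binomials."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2) == 0 or min(k, n - k) == 0:
        return 1.0
    denom = math.comb(n, k)
    support = range(max(0, k - r2), min(r1, k) + 1)
    pmf = {x: math.comb(r1, x) * math.comb(r2, k - x) / denom for x in support}
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestFisher:
    def test_single_discordant_chromosome(self):
        # support {0,1}: P = 362/1770
        t = CountTable2x2(1, 361, 0, 1408)
        assert fisher_two_sided(t) == pytest.approx(362 / 1770, rel=1e-9)
        assert round(fisher_two_sided(t), 4) == 0.2045

    def test_symmetric_table_is_one(self):
        assert fisher_two_sided(CountTable2x2(1, 1, 1, 1)) == 1.0

    def test_degenerate_margin_returns_one(self):
        assert fisher_two_sided(CountTable2x2(0, 0, 5, 7)) == 1.0
        assert fisher_two_sided(CountTable2x2(0, 5, 0, 7)) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            CountTable2x2(-1, 2, 3, 4)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 51, size=4)
            p = fisher_two_sided(CountTable2x2(int(a), int(b), int(c), int(d)))
            q = fisher_enumeration(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(q, abs=1e-12, rel=1e-9)

    @given(st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50), st.integers(0, 50))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_transpose_and_double_swap_invariance(self, a, b, c, d):
        p = fisher_two_sided(CountTable2x2(a, b, c, d))
        p_t = fisher_two_sided(CountTable2x2(a, c, b, d))
        p_sw = fisher_two_sided(CountTable2x2(d, c, b, a))
        assert p == pytest.approx(p_t, rel=1e-9, abs=1e-12)
        assert p == pytest.approx(p_sw, rel=1e-9, abs=1e-12)


class TestOddsRatio:
    def test_published_headline_table(self):
        # 38/362 vs 52/1408 chromosomes
        or_, lo, hi, corrected = odds_ratio_ci(CountTable2x2(38, 324, 52, 1356))
        assert (round(or_, 2), round(lo, 2), round(hi, 2)) == (3.06, 1.98, 4.73)
        assert not corrected

    def test_haldane_anscombe_on_zero_cell(self):
        or_, lo, hi, corrected = odds_ratio_ci(CountTable2x2(1, 361, 0, 1408))
        assert corrected
        assert or_ == pytest.approx((1.5 * 1408.5) / (361.5 * 0.5), rel=1e-12)
        assert round(or_, 2) == 11.69
        assert lo < or_ < hi

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_identity_table(self, k):
        or_, lo, hi, corrected = odds_ratio_ci(CountTable2x2(k, k, k, k))
        assert or_ == 1.0 and lo < 1.0 < hi and not corrected

    @given(st.integers(1, 200), st.integers(1, 200),
           st.integers(1, 200), st.integers(1, 200))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_row_swap_inverts(self, a, b, c, d):
        or1, lo1, hi1, _ = odds_ratio_ci(CountTable2x2(a, b, c, d))
        or2, lo2, hi2, _ = odds_ratio_ci(CountTable2x2(c, d, a, b))
        assert or2 == pytest.approx(1 / or1, rel=1e-12)
        assert lo2 == pytest.approx(1 / hi1, rel=1e-9)
        assert hi2 == pytest.approx(1 / lo1, rel=1e-9)

    def test_monotone_in_target_case_cell(self):
        ors = [odds_ratio_ci(CountTable2x2(a, 50, 10, 90))[0] for a in range(1, 30)]
        assert all(x < y for x, y in zip(ors, ors[1:]))

    def test_ci_narrows_as_cells_scale(self):
        widths = []
        for k in (1, 4, 16):
            _, lo, hi, _ = odds_ratio_ci(CountTable2x2(8 * k, 20 * k, 5 * k, 30 * k))
            widths.append(math.log(hi) - math.log(lo))
        assert widths[0] > widths[1] > widths[2]


class TestBonferroni:
    def test_reference_correction(self):
        p = fisher_two_sided(CountTable2x2(38, 324, 52, 1356))
        assert float(f"{bonferroni(p, 28):.3g}") == pytest.approx(3.79e-5, rel=1e-3)

    def test_identity_and_cap(self):
        assert bonferroni(0.0123, 1) == 0.0123
        assert bonferroni(0.5, 10) == 1.0

    @given(st.floats(0, 1), st.integers(1, 100))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, p, m):
        pc = bonferroni(p, m)
        assert p <= pc <= 1.0
        assert bonferroni(p, m + 1) >= pc

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def t_sf_oracle(t: float, df: float) -> float:
    """Numeric-integration oracle for the t survival function (scipy-free)."""
    const = math.exp(math.lgamma((df + 1) / 2) - math.lgamma(df / 2)) / math.sqrt(df * math.pi)
    x = np.linspace(t, t + 400, 4_000_001)
    pdf = const * (1 + x ** 2 / df) ** (-(df + 1) / 2)
    return float(np.trapezoid(pdf, x))


class TestCompareMeans:
    def test_identical_groups_give_p_one(self):
        assert compare_means(50, 10.0, 2.0, 60, 10.0, 2.0) == pytest.approx(1.0)

    def test_age_comparison_welch(self):
        # Welch statistic: t = -4.1 / sqrt(13.1^2/181 + 11.8^2/704)
        p = compare_means(181, 59.8, 13.1, 704, 63.9, 11.8, method="welch")
        se2 = 13.1 ** 2 / 181 + 11.8 ** 2 / 704
        t = 4.1 / math.sqrt(se2)
        df = se2 ** 2 / ((13.1 ** 2 / 181) ** 2 / 180 + (11.8 ** 2 / 704) ** 2 / 703)
        assert p == pytest.approx(2 * t_sf_oracle(t, df), rel=1e-5)
        assert round(p, 4) == 0.0002

    def test_student_variant_differs(self):
        welch = compare_means(181, 59.8, 13.1, 704, 63.9, 11.8, method="welch")
        student = compare_means(181, 59.8, 13.1, 704, 63.9, 11.8, method="student")
        assert student < welch  # pooled variance understates the case-group spread

    @pytest.mark.parametrize("method", ["welch", "student"])
    def test_summary_equals_raw(self, method):
        rng = np.random.default_rng(11)
        x = rng.normal(0.0, 1.0, 40)
        y = rng.normal(0.4, 1.6, 55)
        p_summary = compare_means(
            len(x), float(x.mean()), float(x.std(ddof=1)),
            len(y), float(y.mean()), float(y.std(ddof=1)), method=method,
        )
        assert p_summary == pytest.approx(compare_means_raw(x, y, method), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_means(1, 0.0, 1.0, 10, 0.0, 1.0)
        with pytest.raises(ValueError):
            compare_means(5, 0.0, 0.0, 10, 0.0, 1.0)


def test_p_value_display_switches_to_scientific():
    assert fmt_p(0.2045) == "0.2045"
    assert fmt_p(1.35e-6) == "1.35e-06"
    assert fmt_p(0.0471) == "0.0471"
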