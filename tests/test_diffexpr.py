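"""Exact count test, normalization, significance calls and ddCt math."""

import math
import random

import numpy as np
import pytest
from scipy.stats import nbinom

from soymir.data import de_reference
from soymir.diffexpr import (
    CtRecord,
    SignificanceParams,
    ac_p_value,
    ac_pointmass,
    ddct_fold_change,
    flag,
    log2_ratio,
    normalize,
    threshold_calls,
)


def log_pvalue_oracle(x, y, n1, n2, trunc=100_000):
    """Brute-force min-tail via direct evaluation of the point mass in log
    space (math.lgamma, max-scaled plain summation); returns log p."""
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)

    def lp(k):
        return (
            k * log_r
            + math.lgamma(x + k + 1)
            - math.lgamma(x + 1)
            - math.lgamma(k + 1)
            - (x + k + 1) * log_1pr
        )

    def log_tail(ks):
        logs = [lp(k) for k in ks]
        m = max(logs)
        return m + math.log(sum(math.exp(v - m) for v in logs))

    lower = log_tail(range(0, y + 1))
    upper = log_tail(range(y, trunc + 1))
    return min(lower, upper, 0.0)


def pvalue_oracle(x, y, n1, n2, trunc=100_000):
    p = math.exp(log_pvalue_oracle(x, y, n1, n2, trunc))
    return min(max(p, 5e-324), 1.0)


def oracle_rel_error(x, y, n1, n2):
    """Relative disagreement between ac_p_value and the brute-force oracle.

    Compared on the linear scale where doubles represent the value with full
    precision; below that floor the log-space values of both routes are
    compared (|delta log p| is the relative error of p itself).
    """
    from soymir.diffexpr import ac_log_p_value

    ref = pvalue_oracle(x, y, n1, n2)
    if ref >= 1e-290:
        return abs(ac_p_value(x, y, n1, n2) - ref) / ref
    return abs(ac_log_p_value(x, y, n1, n2) - log_pvalue_oracle(x, y, n1, n2))


class TestNormalize:
    def test_per_ten_million(self):
        assert normalize(250, 2.5e7) == pytest.approx(100.0)

    def test_zero_count(self):
        assert normalize(0, 12345) == 0.0

    def test_full_library(self):
        assert normalize(5000, 5000) == pytest.approx(1e7)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(1, 0)


class TestLog2Ratio:
    def test_equal_normalized_values(self):
        assert log2_ratio(10, 10, 1000, 1000) == 0.0

    def test_twofold(self):
        assert log2_ratio(20, 10, 1000, 1000) == pytest.approx(1.0)

    def test_zero_count_is_nan(self):
        assert math.isnan(log2_ratio(0, 50, 1000, 1000))
        assert math.isnan(log2_ratio(50, 0, 1000, 1000))


class TestPointmass:
    def test_zero_zero_is_half(self):
        assert ac_pointmass(0, 0, 1e7, 1e7) == pytest.approx(0.5, rel=1e-12)

    def test_one_one_is_quarter(self):
        assert ac_pointmass(1, 1, 1e7, 1e7) == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize("x", range(6))
    def test_distribution_normalizes(self, x):
        ks = np.arange(0, 10_000)
        total = ac_pointmass(ks, x, 3e6, 7e6).sum()
        assert total == pytest.approx(1.0, abs=1e-12)


class TestPValue:
    def test_zero_zero(self):
        assert ac_p_value(0, 0, 1e7, 1e7) == 0.5

    def test_balanced_counts_are_exactly_half(self):
        rng = random.Random(3)
        for _ in range(20):
            x = rng.randint(0, 400)
            n = rng.uniform(1e6, 1e8)
            assert ac_p_value(x, x, n, n) == 0.5

    def test_extreme_lower_tail_closed_form(self):
        # y=0 given x=100 at equal sizes: single point mass 2^-101
        assert ac_p_value(100, 0, 1e7, 1e7) == pytest.approx(
            2.0**-101, rel=1e-12
        )

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(17)
        for _ in range(120):
            x, y = rng.randint(0, 500), rng.randint(0, 500)
            n1, n2 = rng.uniform(1e6, 1e8), rng.uniform(1e6, 1e8)
            assert oracle_rel_error(x, y, n1, n2) < 1e-10, (x, y, n1, n2)

    def test_cross_check_negative_binomial_tails(self):
        """Independent route: the conditional distribution is negative
        binomial with x+1 successes at probability N1/(N1+N2)."""
        rng = random.Random(23)
        for _ in range(60):
            x, y = rng.randint(0, 200), rng.randint(0, 200)
            n1, n2 = rng.uniform(1e6, 1e8), rng.uniform(1e6, 1e8)
            s = n1 / (n1 + n2)
            lower = nbinom.cdf(y, x + 1, s)
            upper = nbinom.sf(y - 1, x + 1, s) if y > 0 else 1.0
            ref = min(max(min(lower, upper), 5e-324), 1.0)
            if ref < 1e-12:  # betainc loses relative precision in far tails
                continue
            assert ac_p_value(x, y, n1, n2) == pytest.approx(ref, rel=1e-8)

    def test_monotone_away_from_conditional_mode(self):
        x, n1, n2 = 80, 1.9e7, 2.1e7
        mode = int(x * n2 / n1)
        ps_up = [ac_p_value(x, y, n1, n2) for y in range(mode + 5, mode + 200, 10)]
        assert all(a > b for a, b in zip(ps_up, ps_up[1:]))
        ps_down = [ac_p_value(x, y, n1, n2) for y in range(mode - 5, 0, -5)]
        assert all(a > b for a, b in zip(ps_down, ps_down[1:]))

    def test_in_unit_interval(self):
        rng = random.Random(5)
        for _ in range(50):
            p = ac_p_value(
                rng.randint(0, 1000),
                rng.randint(0, 1000),
                rng.uniform(1e5, 1e9),
                rng.uniform(1e5, 1e9),
            )
            assert 0.0 < p <= 1.0


class TestFlag:
    def test_strong_upregulation_called(self):
        assert flag(2.79, 1e-10, 500, 3500) == "up"

    def test_small_ratio_never_called(self):
        assert flag(0.49, 1e-30, 5000, 7000) == "none"

    def test_p_gate(self):
        assert flag(3.0, 0.01, 500, 4000) == "none"

    def test_abundance_gate(self):
        assert flag(3.0, 1e-10, 10, 80) == "none"

    def test_nan_ratio_never_called(self):
        assert flag(float("nan"), 1e-10, 0, 500) == "none"

    def test_strict_vs_rounded_threshold_at_exactly_one(self):
        # a printed -1.00 is called down under the rounded (inclusive) rule
        # but not under the strict internal rule
        strict = SignificanceParams()
        rounded = SignificanceParams(rounded=True)
        assert flag(-1.0, 1e-10, 400, 200, strict) == "none"
        assert flag(-1.0, 1e-10, 400, 200, rounded) == "down"


class TestPublishedShortlist:
    """Direction calls recomputed from the curated printed log2 grid."""

    def test_calls_reproduce_published_flags(self):
        table = de_reference()
        for comp in ("MON_A32", "DP3_JAC", "A32_JAC"):
            calls = threshold_calls(table[f"log2_{comp}"], inclusive=True)
            assert calls == list(table[f"flag_{comp}"]), comp

    def test_call_counts_per_comparison(self):
        table = de_reference()
        calls = {
            comp: threshold_calls(table[f"log2_{comp}"], inclusive=True)
            for comp in ("MON_A32", "DP3_JAC", "A32_JAC")
        }
        assert calls["MON_A32"].count("down") == 10
        assert calls["MON_A32"].count("up") == 0
        assert calls["DP3_JAC"].count("up") == 2
        assert calls["DP3_JAC"].count("down") == 1
        assert calls["A32_JAC"].count("up") == 10
        assert calls["A32_JAC"].count("down") == 3

    def test_extreme_ratios(self):
        table = de_reference()
        values = table[[c for c in table.columns if c.startswith("log2_")]]
        assert values.max().max() == pytest.approx(2.79)
        assert values.min().min() == pytest.approx(-1.94)
        assert (
            table.loc[values["log2_A32_JAC"].idxmax(), "mirna"] == "miR398c"
        )
        assert (
            table.loc[values["log2_MON_A32"].idxmin(), "mirna"] == "miR390a-5p"
        )


class TestDdct:
    def test_equal_cts_give_unity(self):
        ct = CtRecord(20, 18, 22, 20)
        assert ddct_fold_change(ct) == pytest.approx(1.0)

    def test_one_cycle_halves(self):
        ct = CtRecord(21, 18, 20, 18)
        assert ddct_fold_change(ct) == pytest.approx(0.5)

    def test_minus_two_cycles_quadruple(self):
        ct = CtRecord(18, 18, 20, 18)
        assert ddct_fold_change(ct) == pytest.approx(4.0)

    def test_missing_ct_rejected(self):
        with pytest.raises(ValueError):
            CtRecord(20, 18, 0, 20)
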