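import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aedisparity import (HostTable, TableFamily, lr_statistic, mlr,
                         normal_p_two_sided, prr_statistic, ror_statistic,
                         z_statistic)
from aedisparity.stats import test_family as apply_test


def _table(a1, a2, b1, b2, unit="u"):
    return HostTable("by_drug", unit, "c", a1, a2, b1, b2)


class TestLR:
    def test_proportional_table_is_zero(self):
        assert lr_statistic(_table(10, 10, 90, 90)) == pytest.approx(0.0, abs=1e-12)

    def test_zero_exposed_cell_is_finite(self):
        # 0 * log 0 = 0 convention
        v = lr_statistic(_table(0, 10, 90, 90))
        assert math.isfinite(v) and v > 0

    def test_matches_observed_vs_expected_form(self):
        # LR = sum_s n_s log(n_s / E_s), E_s = M_s n / N
        t = _table(12, 34, 47818, 53044)
        n, N = t.n_exposed, t.n
        e1, e2 = t.m1 * n / N, t.m2 * n / N
        alt = t.a1 * math.log(t.a1 / e1) + t.a2 * math.log(t.a2 / e2)
        assert lr_statistic(t) == pytest.approx(alt, rel=1e-12)

    def test_zero_margin_is_domain_error(self):
        with pytest.raises(ValueError, match="margin"):
            lr_statistic(_table(0, 10, 0, 90))

    def test_invariant_under_group_swap(self):
        t = _table(7, 19, 311, 290)
        assert lr_statistic(t) == pytest.approx(lr_statistic(t.swapped()), rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(1, 500), st.integers(1, 500))
    def test_nonnegative_and_zero_only_at_null_proportion(self, a1, a2, b1, b2):
        t = _table(a1, a2, b1, b2)
        if t.n_exposed == 0:
            return
        v = lr_statistic(t)
        assert v >= 0
        at_null = abs(t.a1 / t.n_exposed - t.p_null) < 1e-12
        assert (v < 1e-9) == at_null

    def test_increases_away_from_expected_count(self):
        # fixed margins, a1 sweeping away from n * p in both directions
        m1, m2, n = 1000, 1000, 100
        centre = 50
        prev_up = prev_dn = lr_statistic(_table(centre, n - centre, m1 - centre, m2 - (n - centre)))
        for step in range(1, 30):
            up = lr_statistic(_table(centre + step, n - centre - step,
                                     m1 - centre - step, m2 - (n - centre - step)))
            dn = lr_statistic(_table(centre - step, n - centre + step,
                                     m1 - centre + step, m2 - (n - centre + step)))
            assert up > prev_up and dn > prev_dn
            prev_up, prev_dn = up, dn


class TestMLR:
    def test_is_maximum(self):
        assert mlr([67.2388, 6.1345, 4.4538]) == 67.2388
        assert mlr([3.5]) == 3.5

    def test_matches_exhaustive_comparison(self):
        rng = np.random.default_rng(0)
        xs = rng.exponential(size=40).tolist()
        assert mlr(xs) == sorted(xs, reverse=True)[0]

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            mlr([])


class TestZ:
    def test_zero_at_expected_split(self):
        # a1 = n * p exactly: p = 0.5, n = 20, a1 = 10
        assert z_statistic(_table(10, 10, 490, 490)) == pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_under_group_swap(self):
        t = _table(30, 10, 470, 490)
        assert z_statistic(t) == pytest.approx(-z_statistic(t.swapped()), rel=1e-12)

    def test_chisquare_limit_matches_squared_z(self):
        # 2 LR ~ z^2 for large tables under the null (chi2(1) limit)
        rng = np.random.default_rng(42)
        m1 = m2 = 200_000
        n = 1000
        p = 0.5
        for _ in range(20):
            a1 = int(rng.binomial(n, p))
            t = _table(a1, n - a1, m1 - a1, m2 - (n - a1))
            assert 2 * lr_statistic(t) == pytest.approx(z_statistic(t) ** 2, rel=5e-2, abs=1e-3)

    def test_two_sided_p_uniform_under_null(self):
        # large n: two-sided normal p is ~Uniform(0,1) across null draws
        rng = np.random.default_rng(3)
        m1 = m2 = 500_000
        n = 2000
        ps = []
        for _ in range(400):
            a1 = int(rng.binomial(n, 0.5))
            t = _table(a1, n - a1, m1 - a1, m2 - (n - a1))
            ps.append(normal_p_two_sided(z_statistic(t)))
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSubgroupRatios:
    def test_proportional_table_ratio_one(self):
        prr, _ = prr_statistic(_table(10, 10, 90, 90))
        ror, _ = ror_statistic(_table(10, 10, 90, 90))
        assert prr == pytest.approx(1.0)
        assert ror == pytest.approx(1.0)

    def test_prr_direct_arithmetic(self):
        # aspirin cells; oracle = direct evaluation of the defining ratio
        t = _table(135, 94, 47695, 52984)
        prr, zp = prr_statistic(t)
        direct = (135 / 229) / ((47830 - 135) / (100908 - 229))
        assert prr == pytest.approx(direct, rel=1e-12)
        assert math.isfinite(zp)
        assert math.copysign(1, zp) == math.copysign(1, z_statistic(t))

    def test_prr_sigma_closed_form(self):
        # p = 0.5, M1 = M2 = 1000, n = 100:
        # sigma2 = p(1-p) (M1 / (p (M1 - n p)))^2 = 0.25 * (1000/475)^2
        from aedisparity.stats import prr_z_arrays
        a1 = 50
        _, z = prr_z_arrays(a1, 50, 1000, 1000)
        sigma2 = 0.25 * (1000 / (0.5 * (1000 - 100 * 0.5))) ** 2
        # at a1 = n p the log-PRR equals its centering, so z = 0 regardless
        assert z == pytest.approx(0.0, abs=1e-12)
        assert sigma2 == pytest.approx(0.25 * (1000 / 475) ** 2)

    def test_ror_direct_arithmetic(self):
        ror, _ = ror_statistic(_table(20, 10, 80, 90))
        assert ror == pytest.approx((20 / 10) / (80 / 90), rel=1e-12)

    def test_ror_inverts_under_group_swap(self):
        t = _table(20, 10, 80, 90)
        r, z = ror_statistic(t)
        rs, zs = ror_statistic(t.swapped())
        assert rs == pytest.approx(1 / r, rel=1e-12)
        assert zs == pytest.approx(-z, rel=1e-9)

    def test_zero_cell_is_degenerate_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            prr_statistic(_table(0, 10, 90, 90))
        with pytest.raises(ValueError, match="degenerate"):
            ror_statistic(_table(10, 0, 90, 90))

    def test_printed_variant_differs(self):
        t = _table(30, 40, 1000, 1100)
        _, z_cons = prr_statistic(t, variant="consistent")
        _, z_print = prr_statistic(t, variant="printed")
        assert z_cons != pytest.approx(z_print)


class TestNormalP:
    def test_reference_points(self):
        assert normal_p_two_sided(0.0) == pytest.approx(1.0)
        assert normal_p_two_sided(1.959964) == pytest.approx(0.05, abs=1e-6)
        assert normal_p_two_sided(-1.959964) == pytest.approx(0.05, abs=1e-6)


class TestTestFamily:
    def test_lrt_leaves_p_unset(self, analgesics):
        res = apply_test(analgesics, "lrt")
        assert all(r.p_raw is None for r in res)
        assert all(r.statistic >= 0 for r in res)

    def test_normal_carries_p(self, analgesics):
        res = apply_test(analgesics, "normal")
        assert all(0 <= r.p_raw <= 1 for r in res)

    def test_unknown_method(self, analgesics):
        with pytest.raises(ValueError):
            apply_test(analgesics, "fisher")
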