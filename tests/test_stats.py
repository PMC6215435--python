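import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scipy_stats

import zfcardio as z
from zfcardio.errors import SampleTooSmallError


class TestDagostinoPearson:
    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        for n in (8, 12, 30, 200, 2000):
            x = rng.normal(size=n)
            k2, p = z.dagostino_pearson(x)
            ref = scipy_stats.normaltest(x)
            assert k2 == pytest.approx(ref.statistic, rel=1e-8)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_normal_samples_usually_pass(self):
        rng = np.random.default_rng(2)
        passes = sum(z.dagostino_pearson(rng.normal(size=2000))[1] > 0.05 for _ in range(100))
        assert passes >= 90

    def test_skewed_sample_rejected(self):
        rng = np.random.default_rng(3)
        _, p = z.dagostino_pearson(rng.exponential(size=2000))
        assert p < 1e-3

    def test_small_sample_rejected(self):
        with pytest.raises(SampleTooSmallError):
            z.dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0])


class TestStudentT:
    def test_hand_evaluated_pooled_formula(self):
        # a={1,2,3}, b={2,3,4}: s²_pooled = 1, se = √(2/3), t = −√(3/2)
        t, p = z.student_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-math.sqrt(1.5), rel=1e-12)
        ref = scipy_stats.ttest_ind([1, 2, 3], [2, 3, 4], equal_var=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_samples(self):
        t, p = z.student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_reference_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 25))
            b = rng.normal(0.5, 2.0, size=rng.integers(2, 25))
            t, p = z.student_t(a, b)
            ref = scipy_stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)


def _enumerated_mwu_p(a, b):
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = scipy_stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            ranks[list(c)].sum() - n1 * (n1 + 1) / 2
            for c in itertools.combinations(range(len(pooled)), n1)
        ]
    )
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


class TestMannWhitney:
    def test_exact_matches_enumeration_small_n(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            u, p, method = z.mann_whitney_u(a, b)
            assert method == "exact"
            assert p == pytest.approx(_enumerated_mwu_p(a, b), abs=1e-12)

    def test_exact_matches_reference(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(size=rng.integers(3, 15))
            b = rng.normal(size=rng.integers(3, 15))
            u, p, _ = z.mann_whitney_u(a, b)
            ref = scipy_stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_tied_data_uses_corrected_normal_approximation(self):
        a = [1, 2, 2, 3, 3, 3, 4] * 3
        b = [2, 3, 3, 4, 4, 4, 5] * 3
        u, p, method = z.mann_whitney_u(a, b)
        assert method == "normal"
        ref = scipy_stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    @given(
        a=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10),
        b=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10),
    )
    @settings(max_examples=100, deadline=None)
    def test_u_plus_uprime_identity(self, a, b):
        u1, _, _ = z.mann_whitney_u(a, b)
        u2, _, _ = z.mann_whitney_u(b, a)
        assert u1 + u2 == pytest.approx(len(a) * len(b))


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        r = z.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_two_tailed == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=12), rng.normal(1, 1, size=9)
        r1 = z.compare_groups(a, b, policy="t")
        r2 = z.compare_groups(b, a, policy="t")
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_two_tailed == pytest.approx(r2.p_two_tailed)

    def test_sd_uses_n_minus_one(self):
        r = z.compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert r.sd_a == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        r = z.compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert r.p_two_tailed == 1.0 and r.flag is not None
        r2 = z.compare_groups([2.0, 2.0], [3.0, 3.0])
        assert r2.p_two_tailed == 0.0 and r2.flag is not None

    def test_policy_can_force_either_test(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert z.compare_groups(a, b, policy="t").test_used == "t"
        assert z.compare_groups(a, b, policy="mwu").test_used == "mannwhitney"

    def test_nonnormal_group_routes_to_mannwhitney(self):
        rng = np.random.default_rng(9)
        a = rng.exponential(size=200) ** 3
        b = rng.normal(size=200)
        r = z.compare_groups(a, b)
        assert r.test_used == "mannwhitney"
        assert r.normality_p_a < 0.05

    def test_small_groups_skip_normality_and_use_t(self):
        r = z.compare_groups([1.0, 2.0, 3.0], [2.0, 4.0, 5.0])
        assert r.normality_p_a is None and r.test_used == "t"

    def test_type_one_error_auto_policy(self):
        rng = np.random.default_rng(10)
        rejections = sum(
            z.compare_groups(rng.normal(size=15), rng.normal(size=15)).p_two_tailed < 0.05
            for _ in range(2000)
        )
        assert 0.03 <= rejections / 2000 <= 0.07


class TestScreeningEfficiency:
    @pytest.mark.parametrize(
        "pos,total,pct", [(21, 28, 75.0), (20, 28, 71.4), (28, 28, 100.0), (0, 10, 0.0), (1, 26, 3.8), (3, 14, 21.4)]
    )
    def test_printed_percentages(self, pos, total, pct):
        assert z.screening_efficiency(pos, total).percent == pct

    def test_half_up_rounding(self):
        # 1/8 = 12.5% stays 12.5; 5/16 = 31.25% rounds half-up to 31.3
        assert z.screening_efficiency(5, 16).percent == 31.3

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            z.screening_efficiency(5, 4)
        with pytest.raises(ValueError):
            z.screening_efficiency(0, 0)
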