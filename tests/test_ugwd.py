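"""Distribution kernel: pmf correctness, moments, tail, limits, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gwreg import ParameterError, UGWDParams, ugwd_logpmf, ugwd_moments, ugwd_pmf, ugwd_rvs
from gwreg.simulate import sample_hierarchy

pos = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


def pochhammer_oracle(y, a, k, rho):
    """Brute-force pmf: Pochhammer ratios multiplied term by term in plain arithmetic."""
    val = 1.0
    for r in range(y):
        val *= (a + r) * (k + r) / ((a + k + rho + r) * (r + 1))
    # normalizing constant Gamma(a+rho)Gamma(k+rho)/(Gamma(a+k+rho)Gamma(rho))
    val *= math.gamma(a + rho) * math.gamma(k + rho) / (math.gamma(a + k + rho) * math.gamma(rho))
    return val


class TestLogpmf:
    def test_partial_fraction_closed_form(self):
        # a=k=1, rho=2 collapses to 4/((y+1)(y+2)(y+3))
        y = np.arange(0, 1001)
        got = ugwd_pmf(y, UGWDParams(1, 1, 2))
        want = 4.0 / ((y + 1.0) * (y + 2.0) * (y + 3.0))
        assert np.max(np.abs(got / want - 1.0)) < 1e-12
        assert np.isclose(ugwd_logpmf(0, UGWDParams(1, 1, 2)), np.log(2.0 / 3.0))

    @pytest.mark.parametrize("a,k,rho,y", [(2, 3, 4, 5), (1.5, 0.7, 2.2, 0), (0.3, 8, 5, 12)])
    def test_matches_bruteforce_pochhammer(self, a, k, rho, y):
        got = ugwd_pmf(y, UGWDParams(a, k, rho))
        assert got == pytest.approx(pochhammer_oracle(y, a, k, rho), rel=1e-10)

    def test_no_overflow_at_large_arguments(self):
        lp = ugwd_logpmf(10_000, UGWDParams(1e4, 1e4, 1e4))
        assert np.isfinite(lp) and lp <= 0.0

    def test_normalization_monotone_to_one(self):
        for params in [UGWDParams(2, 3, 5), UGWDParams(0.5, 1.2, 2.5)]:
            y = np.arange(0, 20001)
            cum = np.cumsum(ugwd_pmf(y, params))
            assert np.all(np.diff(cum) >= 0)
            assert cum[-1] <= 1.0 + 1e-12
            assert cum[-1] > 0.999

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=pos, k=pos, rho=pos, y=st.integers(min_value=0, max_value=200))
    def test_symmetry_in_a_and_k(self, a, k, rho, y):
        assert ugwd_logpmf(y, a=a, k=k, rho=rho) == pytest.approx(
            ugwd_logpmf(y, a=k, k=a, rho=rho), rel=1e-12, abs=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            UGWDParams(-1, 1, 2)
        with pytest.raises(ParameterError):
            ugwd_logpmf(-1, UGWDParams(1, 1, 2))
        with pytest.raises(ParameterError):
            ugwd_logpmf(1.5, UGWDParams(1, 1, 2))

    @pytest.mark.parametrize("a,k,rho", [(1.0, 1.0, 2.0), (0.6, 0.9, 1.4)])
    def test_power_law_tail(self, a, k, rho):
        # f(y) * y^(rho+1) stabilizes: within 1% between y=1e3 and y=1e4
        params = UGWDParams(a, k, rho)
        c1 = ugwd_pmf(1000, params) * 1000.0 ** (params.rho + 1)
        c2 = ugwd_pmf(10_000, params) * 10_000.0 ** (params.rho + 1)
        assert c2 > 0
        assert abs(c1 / c2 - 1.0) < 0.01

    def test_power_law_constant_converges(self):
        # the O(1/y) correction shrinks decade over decade for any params
        params = UGWDParams(2.0, 3.0, 4.0)
        c = [float(ugwd_pmf(y, params)) * y ** (params.rho + 1) for y in (1_000, 10_000, 100_000)]
        assert abs(c[1] / c[2] - 1.0) < abs(c[0] / c[2] - 1.0)
        assert abs(c[1] / c[2] - 1.0) < 0.01


class TestLimits:
    def test_negbin1_limit(self):
        # k = rho = c -> infinity with mu fixed: NB(mu, 1/2) (constant var/mean ratio 2)
        mu = 2.5
        y = np.arange(0, 51)
        target = stats.nbinom.pmf(y, mu, 0.5)
        errs = []
        for c in (1e2, 1e4):
            a = mu * (c - 1.0) / c
            errs.append(np.max(np.abs(ugwd_pmf(y, a=a, k=c, rho=c) - target)))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3

    def test_negbin2_limit(self):
        # rho -> infinity with k fixed, mu/k bounded: NB(k, k/(k+mu)) (quadratic variance)
        mu, k = 1.5, 2.0
        y = np.arange(0, 51)
        target = stats.nbinom.pmf(y, k, k / (k + mu))
        errs = []
        for rho in (1e2, 1e4):
            a = mu * (rho - 1.0) / k
            errs.append(np.max(np.abs(ugwd_pmf(y, a=a, k=k, rho=rho) - target)))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3


class TestMoments:
    def test_reproduces_reported_partition_proportions(self):
        # worked partition at mu=1.931035, k=1.567578, rho=6.852336:
        # proportions (0.2930119, 0.1550451, 0.551943)
        mu, k, rho = 1.931035, 1.567578, 6.852336
        m = ugwd_moments(UGWDParams(mu * (rho - 1.0) / k, k, rho))
        r, l, p = m.proportions
        assert r == pytest.approx(0.2930119, rel=5e-5)
        assert l == pytest.approx(0.1550451, rel=5e-5)
        assert p == pytest.approx(0.551943, rel=5e-5)

    def test_boundary_cases_flagged_in_band(self):
        m = ugwd_moments(UGWDParams(1, 1, 2))  # heavy tail: mean 1, infinite variance
        assert m.mean == pytest.approx(1.0)
        assert np.isnan(m.variance)
        m2 = ugwd_moments(UGWDParams(1, 1, 0.5))
        assert np.isnan(m2.mean)

    def test_variance_matches_truncated_sum(self):
        params = UGWDParams(2, 3, 5)
        y = np.arange(0, 2_000_000)
        f = ugwd_pmf(y, params)
        mean_num = float(np.sum(y * f))
        var_num = float(np.sum(y**2 * f)) - mean_num**2
        m = ugwd_moments(params)
        assert m.mean == pytest.approx(mean_num, rel=1e-6)
        assert m.variance == pytest.approx(var_num, rel=1e-6)
        assert m.variance == pytest.approx(m.randomness + m.liability + m.proneness)


class TestSampling:
    def test_determinism_and_empty(self):
        p = UGWDParams(2, 3, 5)
        assert ugwd_rvs(p, n=0, seed=1).size == 0
        a = ugwd_rvs(p, n=50, seed=123)
        b = ugwd_rvs(p, n=50, seed=123)
        assert np.array_equal(a, b)
        assert a.dtype == np.int64 and np.all(a >= 0)

    def test_sample_moments_match_theory(self):
        p = UGWDParams(2, 3, 5)
        m = ugwd_moments(p)
        x = ugwd_rvs(p, n=100_000, seed=5)
        se = np.sqrt(m.variance / x.size)
        assert abs(x.mean() - m.mean) < 3 * se  # mean a*k/(rho-1) = 1.5
        assert x.var() == pytest.approx(m.variance, rel=0.1)

    def test_two_stage_and_three_stage_samplers_agree(self):
        # beta-NB route vs Poisson-Gamma-BetaII genesis: same binned law
        n = 100_000
        p = UGWDParams(2, 3, 5)
        x1 = ugwd_rvs(p, n=n, seed=11)
        x2 = sample_hierarchy(a=p.a, k=p.k, rho=p.rho, n=n, seed=12).y
        edges = list(range(0, 10)) + [15, 10_000_000]
        c1, _ = np.histogram(x1, bins=edges)
        c2, _ = np.histogram(x2, bins=edges)
        _, pval, _, _ = stats.chi2_contingency(np.vstack([c1, c2]))
        assert pval > 0.001

    def test_hierarchy_matches_exact_pmf(self):
        n = 100_000
        p = UGWDParams(2, 3, 5)
        x = sample_hierarchy(a=p.a, k=p.k, rho=p.rho, n=n, seed=9).y
        kmax = 12
        obs = np.bincount(np.minimum(x, kmax), minlength=kmax + 1)
        probs = ugwd_pmf(np.arange(kmax + 1), p)
        probs[kmax] = 1.0 - probs[:kmax].sum()
        _, pval = stats.chisquare(obs, probs * n)
        assert pval > 0.001

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            ugwd_rvs(a=-1, k=1, rho=2, n=5)
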