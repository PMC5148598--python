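"""Univariate generalized Waring distribution (UGWD).

The UGWD is a three-parameter heavy-tailed count distribution that arises as
a beta mixture of negative binomials (equivalently, a Poisson-Gamma-BetaII
hierarchy).  Its probability mass function is

    f(y) = [ (a)_y (k)_y / (a+k+rho)_y ] *
           Gamma(a+rho) Gamma(k+rho) / (Gamma(a+k+rho) Gamma(rho)) / y!

where ``(alpha)_r = Gamma(alpha+r)/Gamma(alpha)`` is the Pochhammer symbol
(rising factorial) and a, k, rho > 0.  The mean a*k/(rho-1) exists only for
rho > 1 and the variance only for rho > 2; the tail is a power law with
exponent rho + 1, so low moments can be infinite even when the pmf is proper.

When the variance exists it splits into three additive, interpretable
components:

* randomness  mu                      -- the underlying Poisson chance,
* liability   mu*(k+1)/(rho-2)        -- varying exposure to risk (gamma stage),
* proneness   mu^2*(k+rho-1)/(k*(rho-2)) -- stable individual differences
                                           (beta stage).

All pmf work is done in log space with log-gamma functions so that shape
parameters and counts up to ~1e4 cause no overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import ParameterError

__all__ = [
    "UGWDParams",
    "ugwd_logpmf",
    "ugwd_pmf",
    "ugwd_moments",
    "ugwd_rvs",
    "Moments",
]


@dataclass(frozen=True)
class UGWDParams:
    """Parameter triple (a, k, rho) of the generalized Waring distribution.

    ``a`` and ``k`` are exchangeable shape parameters (the pmf is symmetric
    in them); ``rho`` controls the power-law tail.  In the regression model
    ``k`` is tied to liability and ``a`` varies with the covariates.
    """

    a: float
    k: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("a", "k", "rho"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"UGWD parameter {name} must be a positive finite real, got {v!r}")

    @property
    def mean(self) -> float:
        """a*k/(rho-1); NaN when rho <= 1 (mean does not exist)."""
        if self.rho <= 1:
            return float("nan")
        return self.a * self.k / (self.rho - 1.0)


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (np.any(y < 0) or np.any(y != np.floor(y)) or not np.all(np.isfinite(y.astype(float)))):
        raise ParameterError("y must contain non-negative integers")
    return y.astype(float)


# Stirling tail sum(B_2n / (2n(2n-1) z^(2n-1))); truncation error < 1e-18 for z >= 32
_STIRLING_COEF = (
    1.0 / 12.0, -1.0 / 360.0, 1.0 / 1260.0, -1.0 / 1680.0, 1.0 / 1188.0,
)
_STIRLING_MIN = 32.0


def _stirling_tail(z):
    inv2 = 1.0 / (z * z)
    s = _STIRLING_COEF[4]
    for c in _STIRLING_COEF[3::-1]:
        s = s * inv2 + c
    return s / z


def _lgamma_diff(x, d):
    """lnGamma(x+d) - lnGamma(x) with small *absolute* error.

    The naive difference of two O(x ln x) log-gammas loses ~1e-12 absolute
    precision by x ~ 1e3; for large arguments a Stirling-based expansion of
    the difference keeps every intermediate on the scale of the result.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    x, d = np.broadcast_arrays(x, d)
    small = np.minimum(x, x + d) < _STIRLING_MIN
    out = np.empty_like(x)
    if np.any(small):
        xs, ds = x[small], d[small]
        out[small] = gammaln(xs + ds) - gammaln(xs)
    if np.any(~small):
        xl, dl = x[~small], d[~small]
        out[~small] = (
            (xl - 0.5) * np.log1p(dl / xl)
            + dl * np.log(xl + dl)
            - dl
            + _stirling_tail(xl + dl)
            - _stirling_tail(xl)
        )
    return out


def ugwd_logpmf(y, params: UGWDParams | None = None, *, a=None, k=None, rho=None):
    """Log probability mass of the UGWD, stable in log-gamma arithmetic.

    Accepts either a :class:`UGWDParams` or keyword parameters; ``a`` may be
    an array broadcasting against ``y`` (one shape per observation, as in the
    regression model where a_i = mu_i*(rho-1)/k).

    All work happens on the scale of the result (paired log-gamma
    differences), so shape parameters and counts up to ~1e4 neither overflow
    nor lose the ~1e-12 relative accuracy of the pmf.

    Returns a float for scalar input, an ndarray otherwise.
    """
    if params is not None:
        a, k, rho = params.a, params.k, params.rho
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0) or (np.ndim(k) == 0 and k <= 0) or (np.ndim(rho) == 0 and rho <= 0):
        raise ParameterError("UGWD parameters must be positive")
    scalar = np.ndim(y) == 0 and a.ndim == 0
    yf = _check_counts(y)
    # constant: lnG(a+rho)-lnG(a) + lnG(k+rho)-lnG(k) - lnG(rho), paired to stay small
    const = _lgamma_diff(a, rho) + _lgamma_diff(k, rho) - gammaln(rho)
    # y-dependent part grouped as (a)_y/(1)_y divided by (a+k+rho)_y/(k)_y
    out = const + _lgamma_diff(1.0 + yf, a - 1.0) - _lgamma_diff(k + yf, a + rho)
    return float(out) if scalar else out


def ugwd_pmf(y, params: UGWDParams | None = None, **kw):
    """exp(ugwd_logpmf)."""
    return np.exp(ugwd_logpmf(y, params, **kw))


@dataclass(frozen=True)
class Moments:
    """Mean, variance and the three-way variance split of a UGWD.

    Undefined quantities are NaN rather than raised: the mean requires
    rho > 1, the variance (and all three components) rho > 2.
    """

    mean: float
    variance: float
    randomness: float
    liability: float
    proneness: float

    @property
    def proportions(self) -> tuple[float, float, float]:
        t = self.variance
        return (self.randomness / t, self.liability / t, self.proneness / t)


def ugwd_moments(params: UGWDParams) -> Moments:
    """Mean, variance and the randomness/liability/proneness decomposition.

    randomness = mu, liability = mu*(k+1)/(rho-2),
    proneness = mu^2*(k+rho-1)/(k*(rho-2)); the variance is their sum.
    """
    a, k, rho = params.a, params.k, params.rho
    nan = float("nan")
    if rho <= 1:
        return Moments(nan, nan, nan, nan, nan)
    mu = a * k / (rho - 1.0)
    if rho <= 2:
        return Moments(mu, nan, nan, nan, nan)
    randomness = mu
    liability = (k + 1.0) / (rho - 2.0) * mu
    proneness = mu * mu * (k + rho - 1.0) / (k * (rho - 2.0))
    return Moments(mu, randomness + liability + proneness, randomness, liability, proneness)


def ugwd_rvs(params: UGWDParams | None = None, n: int = 1, seed=None, *, a=None, k=None, rho=None, rng=None):
    """Draw i.i.d. UGWD variates.

    Uses the exact two-stage beta-negative-binomial route: p ~ Beta(rho, k),
    then Y ~ NegativeBinomial(a, p).  This is the same distribution as the
    three-stage Poisson-Gamma-BetaII genesis but needs no rejection step.

    ``a`` may be an array of length ``n`` (per-observation shapes); ``seed``
    may be anything ``numpy.random.default_rng`` accepts, or pass ``rng``
    directly.
    """
    if params is not None:
        a, k, rho = params.a, params.k, params.rho
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0) or k <= 0 or rho <= 0:
        raise ParameterError("UGWD parameters must be positive")
    if n < 0:
        raise ParameterError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if a.ndim == 1 and a.size != n:
        raise ParameterError(f"per-observation a has length {a.size}, expected n={n}")
    p = rng.beta(rho, k, size=n)
    # numpy's NB counts failures before `a` successes with success prob p,
    # which is exactly the beta-negative-binomial mixture matching the pmf
    return rng.negative_binomial(a, p).astype(np.int64)
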