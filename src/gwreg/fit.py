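"""Maximum-likelihood fitting of the generalized Waring regression model.

The model: counts y_i | x_i ~ UGWD(a_i, k, rho) with log link
mu_i = exp(x_i' beta + offset_i) and a_i = mu_i * (rho - 1) / k, so beta
parameterizes the conditional mean and (k, rho) carry the overdispersion
structure.  The likelihood is maximized by a three-stage strategy:

  A. quasi-Newton (BFGS) on the unconstrained parameterization
     (beta, k0, rho0) with k = exp(k0), rho = 1 + exp(rho0) -- the
     reparameterization guarantees rho > 1, hence a finite mean;
  B. Nelder-Mead simplex on the same unconstrained surface;
  C. bounded L-BFGS-B on the natural scale (beta, k, rho) with
     k >= 1e-5, rho >= 1 + 1e-5, started from the better of A/B.

Standard errors for all natural-scale parameters come from the numerical
Hessian at stage C's optimum.  Selecting only an unconstrained method
(``method="BFGS"`` or ``"Nelder-Mead"``) yields SEs for (beta, k0, rho0);
k and rho are then reported as point estimates only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from scipy import stats

from .design import DesignMatrix
from .exceptions import ConvergenceError, DataValidationError, ParameterError
from .ugwd import ugwd_logpmf

__all__ = ["FitResult", "neg_loglik", "fit_gw", "wald_summary", "WaldSummary"]

_PENALTY = 1e12  # returned to the optimizer instead of raising on invalid points

_DEFAULT_CONTROL = {
    "gtol": 1e-6,
    "maxiter": 500,
    "eta_max": 500.0,  # cap on the linear predictor to avoid exp overflow
}


def _unpack(theta, p, parameterization, fixed_k):
    beta = np.asarray(theta[:p], dtype=float)
    rest = theta[p:]
    if parameterization == "log":
        if fixed_k is None:
            k = np.exp(rest[0])
            rho = 1.0 + np.exp(rest[1])
        else:
            k = float(fixed_k)
            rho = 1.0 + np.exp(rest[0])
    elif parameterization == "natural":
        if fixed_k is None:
            k, rho = rest[0], rest[1]
        else:
            k, rho = float(fixed_k), rest[0]
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return beta, float(k), float(rho)


def neg_loglik(theta, design: DesignMatrix, parameterization: str = "log", fixed_k: float | None = None) -> float:
    """Negative weighted log-likelihood of the GWRM at packed parameters.

    ``theta`` is (beta, k0, rho0) under the ``"log"`` parameterization or
    (beta, k, rho) under ``"natural"``; with ``fixed_k`` the k slot is
    omitted.  Invalid or numerically non-finite points return a large
    penalty instead of raising, so any optimizer can probe freely.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        return _PENALTY
    beta, k, rho = _unpack(theta, design.p, parameterization, fixed_k)
    # hard domain guards: far outside any plausible fit, where the paired
    # log-gamma evaluation itself would lose precision
    if not (1e-8 < k < 1e8) or not (1.0 < rho < 1e8):
        return _PENALTY
    eta = design.X @ beta + design.offset
    if np.any(eta > _DEFAULT_CONTROL["eta_max"]):
        return _PENALTY
    mu = np.exp(eta)
    a = mu * (rho - 1.0) / k
    if np.any(a <= 0) or np.any(a > 1e10) or not np.all(np.isfinite(a)):
        return _PENALTY
    with np.errstate(all="ignore"):
        ll = ugwd_logpmf(design.y, a=a, k=k, rho=rho)
    total = float(np.sum(design.weights * ll))
    if not np.isfinite(total):
        return _PENALTY
    return -total


@dataclass
class FitResult:
    """A fitted generalized Waring regression model."""

    beta: np.ndarray
    k: float
    rho: float
    fixed_k: float | None
    param_names: list[str]       # names of the free parameters, in packing order
    se: np.ndarray | None        # SEs aligned with param_names (None if unavailable)
    vcov: np.ndarray | None
    se_scale: str                # "natural" (k, rho) or "log" (k0, rho0)
    loglik: float
    aic: float
    bic: float
    npar: int
    df_residual: int
    converged: int               # 0 = success (stage C status, or the single stage run)
    method_label: str
    fitted_mu: np.ndarray
    design: DesignMatrix
    message: str = ""
    start_values: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.design.n

    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.design.column_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FitResult n={self.n} npar={self.npar} loglik={self.loglik:.2f} "
            f"AIC={self.aic:.1f} k={self.k:.4g} rho={self.rho:.4g} code={self.converged}>"
        )


def _poisson_start(design: DesignMatrix) -> np.ndarray:
    """Start beta at the Poisson log-link fit (stable mean-model initialization)."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                design.y,
                design.X,
                family=sm.families.Poisson(),
                offset=design.offset,
                freq_weights=design.weights,
            ).fit()
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return beta
    except Exception:
        pass
    beta = np.zeros(design.p)
    if design.intercept and design.p >= 1:
        mean_y = max(float(np.average(design.y, weights=design.weights)), 0.05)
        beta[0] = np.log(mean_y) - float(np.mean(design.offset))
    return beta


def _numeric_hessian(fun, x, eps=1e-5):
    from statsmodels.tools.numdiff import approx_hess2

    return approx_hess2(np.asarray(x, dtype=float), fun, epsilon=None)


def fit_gw(
    design: DesignMatrix,
    kstart: float = 1.0,
    rostart: float = 2.0,
    betastart=None,
    fixed_k: float | None = None,
    method: str | None = None,
    control: dict | None = None,
    hessian: bool = True,
) -> FitResult:
    """Fit the GWRM by maximum likelihood.

    ``method=None`` runs the full A/B/C strategy (SEs for every parameter on
    the natural scale).  ``method="BFGS"`` or ``"Nelder-Mead"`` runs that
    single unconstrained stage (SEs on the (beta, k0, rho0) scale only);
    ``method="L-BFGS-B"`` runs only the bounded natural-scale stage.

    Non-convergence never raises: the result carries a nonzero ``converged``
    code and a warning is emitted.
    """
    if kstart <= 0 or rostart <= 1:
        raise ParameterError("kstart must be > 0 and rostart > 1")
    if fixed_k is not None and fixed_k <= 0:
        raise ParameterError("fixed_k must be positive")
    ctrl = dict(_DEFAULT_CONTROL)
    ctrl.update(control or {})
    p = design.p
    if p == 0:
        raise DataValidationError("design has no columns; request an intercept or covariates")

    beta0 = np.asarray(betastart, dtype=float) if betastart is not None else _poisson_start(design)
    if beta0.shape != (p,):
        raise DataValidationError(f"betastart must have length {p}")

    disp_log = [np.log(kstart), np.log(rostart - 1.0)]
    if fixed_k is not None:
        disp_log = disp_log[1:]
    x0_log = np.concatenate([beta0, disp_log])

    def f_log(th):
        return neg_loglik(th, design, "log", fixed_k)

    def f_nat(th):
        return neg_loglik(th, design, "natural", fixed_k)

    def central_grad(fun):
        # scaled central differences: accurate enough for a clean L-BFGS-B
        # line search where scipy's default forward differences stall
        def grad(th):
            th = np.asarray(th, dtype=float)
            g = np.empty_like(th)
            for i in range(th.size):
                h = 1e-6 * max(1.0, abs(th[i]))
                e = np.zeros_like(th)
                e[i] = h
                g[i] = (fun(th + e) - fun(th - e)) / (2.0 * h)
            return g

        return grad

    def run(fun, x0, meth):
        opts = {"maxiter": ctrl["maxiter"]}
        kwargs = {}
        if meth == "BFGS":
            opts["gtol"] = ctrl["gtol"]
            kwargs["jac"] = central_grad(fun)
        if meth == "Nelder-Mead":
            opts["maxiter"] = max(ctrl["maxiter"], 200 * len(x0))
            opts["xatol"] = 1e-8
            opts["fatol"] = 1e-8
        if meth == "L-BFGS-B":
            lb = [-np.inf] * p + ([1e-5] if fixed_k is None else []) + [1.0 + 1e-5]
            kwargs["bounds"] = [(l, np.inf) if np.isfinite(l) else (None, None) for l in lb]
            kwargs["jac"] = central_grad(fun)
            opts["maxiter"] = ctrl["maxiter"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return scipy.optimize.minimize(fun, x0, method=meth, options=opts, **kwargs)

    n_disp = 1 if fixed_k is not None else 2
    disp_names_nat = (["rho"] if fixed_k is not None else ["k", "rho"])
    disp_names_log = (["rho0"] if fixed_k is not None else ["k0", "rho0"])

    start_values = {"beta": beta0.tolist(), "kstart": kstart, "rostart": rostart}

    if method in ("BFGS", "Nelder-Mead", "nlm"):
        meth = "BFGS" if method == "nlm" else method
        res = run(f_log, x0_log, meth)
        beta, k, rho = _unpack(res.x, p, "log", fixed_k)
        se = vcov = None
        if hessian:
            se, vcov = _se_from_hessian(f_log, res.x)
        code = 0 if res.success else 1
        return _assemble(
            design, beta, k, rho, fixed_k, se, vcov, "log",
            design.column_names + disp_names_log, -res.fun, code, meth,
            res.message if not res.success else "", start_values,
        )

    if method == "L-BFGS-B":
        x0_nat = np.concatenate([beta0, ([kstart] if fixed_k is None else []) + [rostart]])
        best_x, best_label = x0_nat, "L-BFGS-B"
    elif method is None or method == "default":
        res_a = run(f_log, x0_log, "BFGS")
        res_b = run(f_log, x0_log, "Nelder-Mead")
        cands = [r for r in (res_a, res_b) if np.isfinite(r.fun)]
        if not cands:
            raise ConvergenceError("both unconstrained stages failed to produce a finite likelihood")
        best = min(cands, key=lambda r: r.fun)
        b, kk, rr = _unpack(best.x, p, "log", fixed_k)
        if not (np.all(np.isfinite(b)) and np.isfinite(kk) and np.isfinite(rr)) or best.fun >= _PENALTY:
            b, kk, rr = beta0, kstart, rostart
        best_x = np.concatenate([b, ([kk] if fixed_k is None else []) + [rr]])
        best_label = "L-BFGS-B"
    else:
        raise ParameterError(f"unknown method {method!r}")

    res_c = run(f_nat, best_x, "L-BFGS-B")
    if not np.isfinite(res_c.fun) or res_c.fun >= _PENALTY:
        raise ConvergenceError("bounded refit failed to produce a finite likelihood")
    beta, k, rho = _unpack(res_c.x, p, "natural", fixed_k)
    se = vcov = None
    if hessian:
        se, vcov = _se_from_hessian(f_nat, res_c.x)
    code = 0 if res_c.success else int(res_c.status) or 1
    if code != 0:
        # a stalled line search at an interior stationary point is convergence:
        # accept when the gradient is at finite-difference noise level
        g_now = central_grad(f_nat)(res_c.x)
        if np.max(np.abs(g_now)) < 1e-2:
            code = 0
    if code != 0:
        warnings.warn(f"GWRM fit did not formally converge: {res_c.message}", stacklevel=2)
    return _assemble(
        design, beta, k, rho, fixed_k, se, vcov, "natural",
        design.column_names + disp_names_nat, -res_c.fun, code, best_label,
        str(res_c.message) if code else "", start_values,
    )


def _se_from_hessian(fun, x):
    try:
        H = _numeric_hessian(fun, x)
        vcov = np.linalg.inv(H)
        d = np.diag(vcov)
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise np.linalg.LinAlgError("non-positive diagonal")
        return np.sqrt(d), vcov
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("Hessian is singular or indefinite; standard errors unavailable", stacklevel=3)
        return None, None


def _assemble(design, beta, k, rho, fixed_k, se, vcov, se_scale, names, loglik, code, label, message, start_values):
    npar = design.p + (1 if fixed_k is not None else 2)
    n = design.n
    mu = np.exp(design.X @ beta + design.offset)
    return FitResult(
        beta=np.asarray(beta, dtype=float),
        k=float(k),
        rho=float(rho),
        fixed_k=fixed_k,
        param_names=list(names),
        se=None if se is None else np.asarray(se, dtype=float),
        vcov=vcov,
        se_scale=se_scale,
        loglik=float(loglik),
        aic=-2.0 * loglik + 2.0 * npar,
        bic=-2.0 * loglik + np.log(n) * npar,
        npar=npar,
        df_residual=n - npar,
        converged=code,
        method_label=label,
        fitted_mu=mu,
        design=design,
        message=message,
        start_values=start_values,
    )


@dataclass
class WaldSummary:
    """Coefficient table with Wald tests plus dispersion and fit blocks."""

    coefficients: pd.DataFrame   # Estimate, Std. Error, z value, Pr(>|z|)
    dispersion: pd.DataFrame     # k, rho (or k0, rho0) with SEs, no tests
    fit: dict                    # loglik, aic, bic, df, code, method

    def __str__(self) -> str:
        out = ["Coefficients:", self.coefficients.to_string(float_format=lambda v: f"{v:.4g}"), ""]
        out += [
            "Fit:",
            f"  log-likelihood {self.fit['loglik']:.1f}   AIC {self.fit['aic']:.1f}   "
            f"BIC {self.fit['bic']:.1f}   df {self.fit['df_residual']}",
            "",
            "betaII:",
            self.dispersion.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
            f"Degrees of Freedom: {self.fit['n'] - 1} Total (i.e. Null); {self.fit['df_residual']} Residual",
            f"Code of convergence: {self.fit['converged']}",
            f"Method: {self.fit['method']}",
        ]
        return "\n".join(out)


def wald_summary(fit: FitResult) -> WaldSummary:
    """Per-coefficient Wald tests (z = estimate/SE, two-sided normal p).

    Dispersion parameters are reported with SEs but no p-values; when the
    fit ran without a usable Hessian every SE-derived column is NaN.
    """
    p = fit.design.p
    est = fit.beta
    if fit.se is not None:
        se_beta = fit.se[:p]
        z = est / se_beta
        pvals = 2.0 * stats.norm.sf(np.abs(z))
    else:
        se_beta = np.full(p, np.nan)
        z = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    coef = pd.DataFrame(
        {"Estimate": est, "Std. Error": se_beta, "z value": z, "Pr(>|z|)": pvals},
        index=fit.design.column_names,
    )

    disp_names = fit.param_names[p:]
    if fit.se_scale == "natural":
        disp_est = [fit.rho] if fit.fixed_k is not None else [fit.k, fit.rho]
    else:
        disp_est = [np.log(fit.rho - 1.0)] if fit.fixed_k is not None else [np.log(fit.k), np.log(fit.rho - 1.0)]
    disp_se = fit.se[p:] if fit.se is not None else np.full(len(disp_names), np.nan)
    disp = pd.DataFrame({"Estimate": disp_est, "Std. Error": disp_se}, index=disp_names)

    return WaldSummary(
        coefficients=coef,
        dispersion=disp,
        fit={
            "loglik": fit.loglik,
            "aic": fit.aic,
            "bic": fit.bic,
            "df_residual": fit.df_residual,
            "n": fit.n,
            "converged": fit.converged,
            "method": fit.method_label,
        },
    )
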