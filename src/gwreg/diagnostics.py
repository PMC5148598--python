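"""Residuals and the normal plot with a parametric-bootstrap envelope.

Because the GWRM is not a GLM, its residuals have no known reference
distribution; the practical check is a simulated envelope.  For each of
``rep`` replicates a response vector is drawn from the fitted model at the
observed covariates, the model is refitted to it, and that replicate's
residuals are sorted.  The per-rank min/max over replicates forms a band;
with the default rep = 19 the largest absolute residual of the real data
escapes the band with probability 1/20 when the model is correct (the real
data is then exchangeable with the 19 replicates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .exceptions import ConvergenceError, PartitionUndefinedError
from .fit import FitResult, fit_gw
from .inference import partvar
from .ugwd import ugwd_logpmf, ugwd_rvs

__all__ = ["residuals", "deviance", "simulate_envelope", "EnvelopeResult", "plot_envelope"]

_TYPES = ("pearson", "deviance", "response")


def _deviance_contributions(y, mu, k, rho):
    """d_i = 2[ln f(y_i | mu=y_i) - ln f(y_i | mu=mu_i)] holding (k, rho) fixed.

    At y=0 the saturated term uses the limit mu -> 0+ (pmf -> 1, log-term 0).
    mu = y is not the exact single-observation maximizer for this
    distribution, so d_i can come out marginally negative when mu_i falls
    between y_i and the true maximizer; such values are clamped to 0.
    """
    y = np.asarray(y, dtype=float)
    a_fit = mu * (rho - 1.0) / k
    ll_fit = ugwd_logpmf(y, a=a_fit, k=k, rho=rho)
    ll_sat = np.zeros_like(ll_fit)
    pos = y > 0
    if np.any(pos):
        a_sat = y[pos] * (rho - 1.0) / k
        ll_sat[pos] = ugwd_logpmf(y[pos], a=a_sat, k=k, rho=rho)
    d = 2.0 * (ll_sat - ll_fit)
    return np.maximum(d, 0.0)


def deviance(fit: FitResult) -> float:
    """Sum of the per-observation deviance contributions D = sum d_i."""
    return float(np.sum(_deviance_contributions(fit.design.y, fit.fitted_mu, fit.k, fit.rho)))


def residuals(fit: FitResult, type: str = "pearson") -> np.ndarray:
    """Residuals in original row order.

    response : y - mu_hat
    pearson  : (y - mu_hat)/sqrt(V_hat), V_hat the three-component total
               variance at each row (needs rho_hat > 2)
    deviance : sign(y - mu_hat) * sqrt(d_i)
    """
    if type not in _TYPES:
        raise ValueError(f"type must be one of {_TYPES}")
    y = fit.design.y.astype(float)
    mu = fit.fitted_mu
    raw = y - mu
    if type == "response":
        return raw
    if type == "pearson":
        if fit.rho <= 2.0:
            raise PartitionUndefinedError(
                f"pearson residuals undefined: rho_hat = {fit.rho:.4f} <= 2 gives infinite variance"
            )
        total = partvar(fit).total_variance
        return raw / np.sqrt(total)
    d = _deviance_contributions(y, mu, fit.k, fit.rho)
    return np.sign(raw) * np.sqrt(d)


@dataclass
class EnvelopeResult:
    """Ordered residuals with per-rank simulated bounds."""

    residual_type: str
    ordered_residuals: np.ndarray
    reference_quantiles: np.ndarray   # Blom-scored expected normal order statistics
    lower: np.ndarray
    upper: np.ndarray
    n_outside: int
    rep: int
    seed: int
    sim_max_abs: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def extreme_escapes(self) -> bool:
        """Whether the largest absolute real residual exceeds every replicate's."""
        return float(np.max(np.abs(self.ordered_residuals))) > float(np.max(self.sim_max_abs))

    def to_dict(self) -> dict:
        return {
            "residual_type": self.residual_type,
            "ordered_residuals": self.ordered_residuals.tolist(),
            "reference_quantiles": self.reference_quantiles.tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "n_outside": int(self.n_outside),
            "rep": int(self.rep),
            "seed": int(self.seed),
            "sim_max_abs": self.sim_max_abs.tolist(),
        }


def _one_replicate(fit: FitResult, rtype: str, ss: np.random.SeedSequence) -> tuple[np.ndarray, float]:
    """Simulate y* from the fitted model, refit, return sorted residuals."""
    d = fit.design
    a = fit.fitted_mu * (fit.rho - 1.0) / fit.k
    last_exc: Exception | None = None
    for child in ss.spawn(3):  # up to 3 attempts with fresh derived seeds
        rng = np.random.default_rng(child)
        ysim = ugwd_rvs(a=a, k=fit.k, rho=fit.rho, n=d.n, rng=rng)
        sim_design = type(d)(
            y=ysim, X=d.X, offset=d.offset, weights=d.weights,
            column_names=d.column_names, response_name=d.response_name,
            terms=d.terms, categorical_levels=d.categorical_levels,
            offset_col=d.offset_col, offset_log=d.offset_log,
            weights_col=d.weights_col, intercept=d.intercept,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_gw(
                    sim_design,
                    betastart=fit.beta,
                    kstart=fit.k,
                    rostart=max(fit.rho, 1.0 + 1e-4),
                    fixed_k=fit.fixed_k,
                    method="L-BFGS-B",
                    hessian=False,
                )
            r = np.sort(residuals(refit, rtype))
            if np.all(np.isfinite(r)):
                return r, float(np.max(np.abs(r)))
            last_exc = ConvergenceError("non-finite replicate residuals")
        except Exception as exc:
            last_exc = exc
    raise ConvergenceError(f"envelope replicate failed after 3 attempts: {last_exc}")


def simulate_envelope(
    fit: FitResult,
    type: str = "pearson",
    rep: int = 19,
    seed: int = 0,
    parallel: bool = False,
    ncores: int = 2,
) -> EnvelopeResult:
    """Parametric-bootstrap envelope for the normal plot of residuals.

    Each replicate draws responses from the fitted model at the observed
    covariates and refits before computing residuals, so the band reflects
    estimation noise as well as sampling noise.  Per-replicate seeds are
    derived from ``seed`` by index, so the result is bit-identical whether
    run serially or on any number of workers, and the first ``rep``
    replicates are nested across increasing ``rep``.
    """
    if rep < 1:
        raise ValueError("rep must be >= 1")
    if type not in _TYPES:
        raise ValueError(f"type must be one of {_TYPES}")
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(rep)
    if parallel and ncores > 1:
        results = Parallel(n_jobs=ncores)(
            delayed(_one_replicate)(fit, type, c) for c in children
        )
    else:
        results = [_one_replicate(fit, type, c) for c in children]
    sims = np.vstack([r for r, _ in results])
    sim_max_abs = np.array([m for _, m in results])
    lower = sims.min(axis=0)
    upper = sims.max(axis=0)
    real = np.sort(residuals(fit, type))
    n = real.size
    ranks = np.arange(1, n + 1)
    ref_q = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    n_outside = int(np.sum((real < lower) | (real > upper)))
    return EnvelopeResult(
        residual_type=type,
        ordered_residuals=real,
        reference_quantiles=ref_q,
        lower=lower,
        upper=upper,
        n_outside=n_outside,
        rep=rep,
        seed=int(seed),
        sim_max_abs=sim_max_abs,
    )


def plot_envelope(env: EnvelopeResult, path: str | None = None, ax=None):
    """Normal plot of ordered residuals with the simulated band."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    q = env.reference_quantiles
    ax.fill_between(q, env.lower, env.upper, color="0.85", label=f"envelope (rep={env.rep})")
    ax.plot(q, env.lower, color="0.4", lw=0.8)
    ax.plot(q, env.upper, color="0.4", lw=0.8)
    ax.plot(q, env.ordered_residuals, "o", ms=3, color="C0", label=f"{env.residual_type} residuals")
    ax.set_xlabel("normal order statistics")
    ax.set_ylabel(f"ordered {env.residual_type} residuals")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
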