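"""Prediction, variance partition, likelihood-ratio tests and stepwise selection.

The variance partition is the model's distinguishing output: at each
covariate pattern the conditional variance splits into

    randomness = mu,
    liability  = mu * (k+1)/(rho-2),
    proneness  = mu^2 * (k+rho-1) / (k*(rho-2)),

attributing variation to pure Poisson chance, to differing exposures to
risk (the gamma mixing stage, tied to external factors), and to stable
individual differences not captured by the covariates (the beta stage).
The partition exists only when rho > 2 (finite variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import design_matrix_for, build_design
from .exceptions import DataValidationError, PartitionUndefinedError
from .fit import FitResult, fit_gw

__all__ = [
    "predict_mean",
    "partvar",
    "PartitionTable",
    "lrt",
    "TestResult",
    "scan_terms",
    "step_select",
]


def predict_mean(fit: FitResult, newdata: pd.DataFrame | None = None, type: str = "response") -> np.ndarray:
    """Predicted linear predictor (``type="link"``) or mean (``"response"``).

    ``newdata`` must contain every covariate column of the model (and the
    offset source column when the model has one); ``None`` uses the
    fitting data.
    """
    if type not in ("response", "link"):
        raise ValueError("type must be 'response' or 'link'")
    if newdata is None:
        eta = fit.design.X @ fit.beta + fit.design.offset
    else:
        X, off = design_matrix_for(fit.design, newdata)
        eta = X @ fit.beta + off
    return np.exp(eta) if type == "response" else eta


@dataclass
class PartitionTable:
    """Per-row variance partition of a fitted model.

    ``absolute`` holds the three components in squared response units;
    ``proportion`` the same rows normalized to sum to one.
    """

    mu: np.ndarray
    absolute: pd.DataFrame
    proportion: pd.DataFrame
    total_variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = self.absolute.copy()
        out.insert(0, "mu", self.mu)
        out["Total"] = self.total_variance
        for c in ("Randomness", "Liability", "Proneness"):
            out[f"Prop.{c}"] = self.proportion[c].to_numpy()
        return out


_COMPONENTS = ["Randomness", "Liability", "Proneness"]


def partvar(fit: FitResult, newdata: pd.DataFrame | None = None) -> PartitionTable:
    """Split the conditional variance at each covariate pattern.

    Raises :class:`PartitionUndefinedError` when rho_hat <= 2 (the variance,
    hence the partition, does not exist); warns when rho_hat is within 1e-3
    of that boundary, where the components are numerically explosive.
    """
    k, rho = fit.k, fit.rho
    if rho <= 2.0:
        raise PartitionUndefinedError(
            f"variance partition undefined: rho_hat = {rho:.4f} <= 2 implies infinite variance"
        )
    if rho <= 2.001:
        warnings.warn(
            f"rho_hat = {rho:.6f} is near the infinite-variance boundary; components are unstable",
            stacklevel=2,
        )
    mu = predict_mean(fit, newdata)
    randomness = mu
    liability = (k + 1.0) / (rho - 2.0) * mu
    proneness = mu**2 * (k + rho - 1.0) / (k * (rho - 2.0))
    absolute = pd.DataFrame(
        np.column_stack([randomness, liability, proneness]), columns=_COMPONENTS
    )
    total = absolute.sum(axis=1).to_numpy()
    proportion = absolute.div(total, axis=0)
    return PartitionTable(mu=mu, absolute=absolute, proportion=proportion, total_variance=total)


@dataclass(frozen=True)
class TestResult:
    """A chi-squared test: statistic, degrees of freedom, upper-tail p."""

    statistic: float
    df: int
    p_value: float


def lrt(fit_null: FitResult, fit_full: FitResult) -> TestResult:
    """Likelihood-ratio test of nested GWRM fits.

    statistic = 2*(l_full - l_null) against chi-squared with the difference
    in free parameters as df.  The null's columns must be a subset of the
    full's and both fits must use the same rows, offset and weights.
    """
    if not set(fit_null.design.column_names) <= set(fit_full.design.column_names):
        raise DataValidationError("models are not nested: null model columns not contained in full model")
    dn, df_ = fit_null.design, fit_full.design
    if dn.n != df_.n or not np.array_equal(dn.y, df_.y):
        raise DataValidationError("fits use different responses/rows; LRT is not defined")
    if not (np.allclose(dn.offset, df_.offset) and np.allclose(dn.weights, df_.weights)):
        raise DataValidationError("fits use different offsets or weights; LRT is not defined")
    ddf = fit_full.npar - fit_null.npar
    if ddf <= 0:
        if set(fit_null.design.column_names) == set(fit_full.design.column_names):
            return TestResult(0.0, max(ddf, 1), 1.0) if ddf > 0 else TestResult(
                max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik)), 1, 1.0
            )
        raise DataValidationError("full model has no extra parameters")
    statistic = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(statistic, ddf))
    return TestResult(float(statistic), int(ddf), p)


def _refit(fit: FitResult, terms: list[str]) -> FitResult:
    d = fit.design
    if d.source_data is None:
        raise DataValidationError("original data not attached to the fit; cannot refit candidate models")
    ref = {c: lv[0] for c, lv in d.categorical_levels.items()}
    nd = build_design(
        d.source_data,
        response=d.response_name,
        covariates=terms,
        offset=d.offset_col,
        offset_log=d.offset_log,
        weights=d.weights_col,
        reference_levels=ref,
        intercept=d.intercept,
    )
    if nd.n != d.n:
        raise DataValidationError(
            "candidate model uses a different row set (missing values in scope terms); "
            "drop incomplete rows before fitting"
        )
    return fit_gw(nd, betastart=None, fixed_k=fit.fixed_k, hessian=False)


def scan_terms(
    fit: FitResult,
    scope: list[str],
    mode: str = "add1",
    criterion: str = "AIC",
) -> pd.DataFrame:
    """Evaluate all single-term additions (``add1``) or deletions (``drop1``).

    Returns one row per candidate (plus ``<none>`` for the current model),
    sorted by the criterion; under ``criterion="LRT"`` the table carries the
    statistic, df and p of each nested comparison instead of an information
    criterion ordering (still sorted, by p-value).  Candidates whose refit
    does not converge are kept in the table and flagged.
    """
    if mode not in ("add1", "drop1"):
        raise ValueError("mode must be 'add1' or 'drop1'")
    if criterion not in ("AIC", "BIC", "LRT"):
        raise ValueError("criterion must be 'AIC', 'BIC' or 'LRT'")
    current = list(fit.design.terms)
    if mode == "add1":
        candidates = [t for t in scope if t not in current]
        term_sets = {t: current + [t] for t in candidates}
    else:
        candidates = [t for t in current if t in scope] if scope else list(current)
        term_sets = {t: [u for u in current if u != t] for t in candidates}

    rows = [{"term": "<none>", "npar": fit.npar, "AIC": fit.aic, "BIC": fit.bic,
             "loglik": fit.loglik, "converged": fit.converged == 0}]
    for t, terms in term_sets.items():
        try:
            cand = _refit(fit, terms)
            row = {"term": t, "npar": cand.npar, "AIC": cand.aic, "BIC": cand.bic,
                   "loglik": cand.loglik, "converged": cand.converged == 0}
            if criterion == "LRT":
                small, big = (fit, cand) if mode == "add1" else (cand, fit)
                tr = lrt(small, big)
                row.update({"LRT": tr.statistic, "df": tr.df, "Pr(Chi)": tr.p_value})
        except Exception as exc:  # refit failure is information, not a crash
            row = {"term": t, "npar": np.nan, "AIC": np.nan, "BIC": np.nan,
                   "loglik": np.nan, "converged": False, "error": str(exc)}
        rows.append(row)
    tab = pd.DataFrame(rows)
    sort_col = "Pr(Chi)" if criterion == "LRT" else criterion
    if sort_col in tab.columns:
        tab = tab.sort_values(sort_col, na_position="last", kind="stable").reset_index(drop=True)
    return tab


_TIE_TOL = 1e-8


def step_select(
    start: FitResult,
    scope: list[str],
    direction: str = "both",
    criterion: str = "AIC",
):
    """Greedy stepwise selection by single-term moves.

    At each round every admissible addition (and deletion, under ``both`` or
    ``backward``) is refitted; the move that most improves the criterion is
    taken, stopping when no move strictly improves it.  Ties within 1e-8
    keep the smaller model.  Returns ``(selected_fit, trace)`` where the
    trace lists every candidate evaluated at every round.
    """
    if direction not in ("forward", "backward", "both"):
        raise ValueError("direction must be 'forward', 'backward' or 'both'")
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    crit = lambda f: f.aic if criterion == "AIC" else f.bic
    current = start
    trace: list[dict] = []
    while True:
        moves: list[tuple[str, str, FitResult]] = []
        cur_terms = list(current.design.terms)
        if direction in ("forward", "both"):
            for t in scope:
                if t not in cur_terms:
                    moves.append(("add", t, cur_terms + [t]))
        if direction in ("backward", "both"):
            for t in cur_terms:
                moves.append(("drop", t, [u for u in cur_terms if u != t]))
        round_rows = []
        best = None
        for action, term, terms in moves:
            try:
                cand = _refit(current, terms)
                value = crit(cand)
                ok = cand.converged == 0
            except Exception as exc:
                cand, value, ok = None, np.nan, False
                round_rows.append({"action": action, "term": term, criterion: np.nan,
                                   "converged": False, "error": str(exc)})
                continue
            round_rows.append({"action": action, "term": term, criterion: value, "converged": ok})
            if not np.isfinite(value):
                continue
            improves = value < crit(current) - _TIE_TOL
            if improves and (best is None or value < crit(best[2]) - _TIE_TOL
                             or (abs(value - crit(best[2])) <= _TIE_TOL and cand.npar < best[2].npar)):
                best = (action, term, cand)
        trace.append({"current_terms": cur_terms, criterion: crit(current), "candidates": round_rows})
        if best is None:
            break
        current = best[2]
    # the selected model is refit once more with a Hessian for usable SEs
    if current is not start:
        current = fit_gw(current.design, fixed_k=current.fixed_k, hessian=True)
    return current, trace
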