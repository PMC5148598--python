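"""Design-matrix construction for the Waring regression model.

Covariates are additive terms: numeric columns enter as-is, string/categorical
columns are dummy-coded against a reference level (L-1 indicator columns for L
levels).  An optional offset column supplies a log-exposure term with
coefficient fixed at 1, and an optional weights column supplies non-negative
case weights.  Rows with missing values in any used column are dropped
(listwise deletion) with the count recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

__all__ = ["DesignMatrix", "build_design", "design_matrix_for"]


@dataclass
class DesignMatrix:
    """Response, covariate matrix and metadata for one model specification."""

    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray
    weights: np.ndarray
    column_names: list[str]
    response_name: str
    terms: list[str]
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)
    offset_col: str | None = None
    offset_log: bool = False
    weights_col: str | None = None
    n_dropped: int = 0
    intercept: bool = True
    source_data: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def metadata(self) -> dict:
        """JSON-serializable description sufficient to rebuild X for new data."""
        return {
            "response": self.response_name,
            "terms": list(self.terms),
            "column_names": list(self.column_names),
            "categorical_levels": {c: list(v) for c, v in self.categorical_levels.items()},
            "offset_col": self.offset_col,
            "offset_log": self.offset_log,
            "weights_col": self.weights_col,
            "intercept": self.intercept,
            "n": int(self.n),
        }


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def _encode_terms(
    data: pd.DataFrame,
    terms: list[str],
    categorical_levels: dict[str, list[str]],
    intercept: bool,
    strict_levels: bool,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        cols.append(np.ones(len(data)))
        names.append("(Intercept)")
    for term in terms:
        s = data[term]
        if term in categorical_levels:
            levels = categorical_levels[term]
            vals = s.astype(str)
            if strict_levels:
                unseen = sorted(set(vals) - set(levels))
                if unseen:
                    raise DataValidationError(
                        f"column {term!r} contains level(s) not seen at fit time: {unseen}"
                    )
            for lev in levels[1:]:  # levels[0] is the reference
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            v = pd.to_numeric(s, errors="coerce").to_numpy(dtype=float)
            if np.any(~np.isfinite(v)):
                raise DataValidationError(f"column {term!r} has non-finite or non-numeric entries")
            cols.append(v)
            names.append(term)
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names


def build_design(
    data: pd.DataFrame,
    response: str,
    covariates: list[str] | tuple[str, ...] = (),
    offset: str | None = None,
    offset_log: bool = False,
    weights: str | None = None,
    reference_levels: dict[str, str] | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Assemble a :class:`DesignMatrix` from a data frame.

    Parameters
    ----------
    data : DataFrame with the response, covariate and optional offset/weight columns.
    response : name of the non-negative integer count column.
    covariates : additive terms; string/categorical columns are dummy-coded.
    offset : exposure column added to the linear predictor with coefficient 1;
        set ``offset_log=True`` if the column holds the raw exposure (e.g.
        matches played) so its log is used.
    weights : optional non-negative case weights.
    reference_levels : reference category per categorical term (default:
        lexicographically first level).
    """
    reference_levels = reference_levels or {}
    used = [response, *covariates]
    for c in (offset, weights):
        if c is not None:
            used.append(c)
    missing_cols = [c for c in used if c not in data.columns]
    if missing_cols:
        raise DataValidationError(f"column(s) not found in data: {missing_cols}")

    sub = data[list(dict.fromkeys(used))]
    keep = sub.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} row(s) with missing values", stacklevel=2)
    sub = sub.loc[keep]
    if len(sub) == 0:
        raise DataValidationError("no complete rows remain after missing-value removal")

    y_raw = pd.to_numeric(sub[response], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(y_raw)):
        bad = np.nonzero(~np.isfinite(y_raw))[0][:5]
        raise DataValidationError(f"response {response!r} is non-numeric at row(s) {bad.tolist()}")
    if np.any(y_raw < 0) or np.any(y_raw != np.floor(y_raw)):
        raise DataValidationError(f"response {response!r} must hold non-negative integer counts")
    y = y_raw.astype(np.int64)

    categorical_levels: dict[str, list[str]] = {}
    for term in covariates:
        if _is_categorical(sub[term]):
            levels = sorted(sub[term].astype(str).unique())
            ref = reference_levels.get(term, levels[0])
            if ref not in levels:
                raise DataValidationError(f"reference level {ref!r} not present in column {term!r}")
            categorical_levels[term] = [ref] + [l for l in levels if l != ref]

    X, names = _encode_terms(sub, list(covariates), categorical_levels, intercept, strict_levels=False)

    if offset is not None:
        off = pd.to_numeric(sub[offset], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(off)):
            raise DataValidationError(f"offset column {offset!r} has non-numeric entries")
        if offset_log:
            if np.any(off <= 0):
                raise DataValidationError("exposure must be strictly positive to take its log")
            off = np.log(off)
    else:
        off = np.zeros(len(sub))

    if weights is not None:
        w = pd.to_numeric(sub[weights], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise DataValidationError(f"weights column {weights!r} must be non-negative reals")
    else:
        w = np.ones(len(sub))

    return DesignMatrix(
        y=y,
        X=X,
        offset=off,
        weights=w,
        column_names=names,
        response_name=response,
        terms=list(covariates),
        categorical_levels=categorical_levels,
        offset_col=offset,
        offset_log=offset_log,
        weights_col=weights,
        n_dropped=n_dropped,
        intercept=intercept,
        source_data=data,
    )


def design_matrix_for(design_meta: DesignMatrix | dict, newdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild (X, offset) for new rows using a fitted design's metadata.

    Raises :class:`DataValidationError` when a categorical column carries a
    level unseen at fit time, naming the level.
    """
    if isinstance(design_meta, DesignMatrix):
        meta = design_meta.metadata()
    else:
        meta = design_meta
    missing = [c for c in meta["terms"] if c not in newdata.columns]
    if missing:
        raise DataValidationError(f"newdata is missing covariate column(s): {missing}")
    X, names = _encode_terms(
        newdata,
        list(meta["terms"]),
        {c: list(v) for c, v in meta["categorical_levels"].items()},
        meta["intercept"],
        strict_levels=True,
    )
    if names != list(meta["column_names"]):
        raise DataValidationError("rebuilt design columns do not match the fitted model")
    if meta["offset_col"] is not None:
        if meta["offset_col"] not in newdata.columns:
            raise DataValidationError(f"newdata is missing offset column {meta['offset_col']!r}")
        off = pd.to_numeric(newdata[meta["offset_col"]], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(off)):
            raise DataValidationError("offset column has non-numeric entries")
        if meta["offset_log"]:
            if np.any(off <= 0):
                raise DataValidationError("exposure must be strictly positive to take its log")
            off = np.log(off)
    else:
        off = np.zeros(len(newdata))
    return X, off
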