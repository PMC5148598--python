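"""Reading tabular datasets and serializing fits, partitions and envelopes."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix
from .diagnostics import EnvelopeResult
from .exceptions import DataValidationError
from .fit import FitResult
from .inference import PartitionTable

__all__ = [
    "read_dataset",
    "fit_to_json",
    "fit_from_json",
    "envelope_to_json",
    "partition_to_csv",
]


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a CSV (header row required) or a whitespace-delimited table.

    Whitespace tables cover R ``write.table``-style files such as season/
    position/matches/goals exports.  Malformed rows raise with the line
    number; an empty file raises an empty-data error.
    """
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"file not found: {path}")
    text_head = path.read_text().lstrip()
    if not text_head:
        raise DataValidationError(f"file is empty: {path}")
    first_line = text_head.splitlines()[0]
    sep = "," if "," in first_line else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0 or len(df) == 0:
        raise DataValidationError(f"no data rows in {path}")
    return df


def _design_stub(meta: dict) -> DesignMatrix:
    empty = np.empty(0)
    return DesignMatrix(
        y=np.empty(0, dtype=np.int64), X=np.empty((0, len(meta["column_names"]))),
        offset=empty, weights=empty,
        column_names=list(meta["column_names"]), response_name=meta["response"],
        terms=list(meta["terms"]),
        categorical_levels={c: list(v) for c, v in meta["categorical_levels"].items()},
        offset_col=meta["offset_col"], offset_log=meta["offset_log"],
        weights_col=meta["weights_col"], intercept=meta["intercept"],
    )


def fit_to_json(fit: FitResult, path: str | Path | None = None) -> dict:
    """Serialize a fit (estimates, uncertainty, fit statistics, design metadata)."""
    obj = {
        "beta": fit.beta.tolist(),
        "k": fit.k,
        "rho": fit.rho,
        "fixed_k": fit.fixed_k,
        "param_names": list(fit.param_names),
        "se": None if fit.se is None else fit.se.tolist(),
        "vcov": None if fit.vcov is None else np.asarray(fit.vcov).tolist(),
        "se_scale": fit.se_scale,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "npar": fit.npar,
        "df_residual": fit.df_residual,
        "converged": fit.converged,
        "method": fit.method_label,
        "message": fit.message,
        "design": fit.design.metadata(),
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj


def fit_from_json(source: str | Path | dict) -> FitResult:
    """Rebuild a fit from its JSON form.

    The reloaded object carries no data rows, so prediction and partition
    require explicit ``newdata``; everything else (estimates, SEs, AIC/BIC)
    is intact.
    """
    if isinstance(source, (str, Path)):
        obj = json.loads(Path(source).read_text())
    else:
        obj = source
    design = _design_stub(obj["design"])
    return FitResult(
        beta=np.asarray(obj["beta"], dtype=float),
        k=float(obj["k"]),
        rho=float(obj["rho"]),
        fixed_k=obj.get("fixed_k"),
        param_names=list(obj["param_names"]),
        se=None if obj.get("se") is None else np.asarray(obj["se"], dtype=float),
        vcov=None if obj.get("vcov") is None else np.asarray(obj["vcov"], dtype=float),
        se_scale=obj["se_scale"],
        loglik=float(obj["loglik"]),
        aic=float(obj["aic"]),
        bic=float(obj["bic"]),
        npar=int(obj["npar"]),
        df_residual=int(obj["df_residual"]),
        converged=int(obj["converged"]),
        method_label=obj["method"],
        fitted_mu=np.empty(0),
        design=design,
        message=obj.get("message", ""),
    )


def envelope_to_json(env: EnvelopeResult, path: str | Path | None = None) -> dict:
    obj = env.to_dict()
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj


def partition_to_csv(part: PartitionTable, path: str | Path) -> None:
    part.to_frame().to_csv(path, index_label="row")
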