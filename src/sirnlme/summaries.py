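"""Uncertainty summary metrics and cross-method comparison tables.

All metrics operate on a set of parameter vectors (whatever method produced
it): relative standard error, empirical 95% confidence interval, relative
CI width, CI asymmetry ratio, and the chi-square degrees of freedom of the
set's dOFV distribution normalized by the parameter count.  Quantiles use
linear interpolation of order statistics (the numpy default, type 7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagnostics
from .comparators import MethodRun
from .model_core import Dataset, ParameterVector, evaluate_ofv

__all__ = [
    "Ci95",
    "rse",
    "ci95",
    "relative_width",
    "asymmetry",
    "method_metrics",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ci95:
    lower: float
    median: float
    upper: float


def rse(vectors: np.ndarray, theta_hat: np.ndarray) -> np.ndarray:
    """Per-parameter relative standard error, in percent:
    100 * SD(vectors) / |theta_hat|.  NaN (flagged) where theta_hat is 0."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    t = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    sd = X.std(axis=0, ddof=1)
    out = np.full(t.shape, np.nan)
    ok = t != 0.0
    if not ok.all():
        logger.warning("RSE undefined for %d zero-valued estimates", int((~ok).sum()))
    out[ok] = 100.0 * sd[ok] / np.abs(t[ok])
    return out


def ci95(vectors: np.ndarray, min_n: int = 40) -> list[Ci95]:
    """Empirical 95% CI per parameter: 2.5th, 50th and 97.5th percentiles."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} vectors for a 95% CI, got {X.shape[0]}")
    q = np.percentile(X, [2.5, 50.0, 97.5], axis=0)
    return [Ci95(lower=q[0, j], median=q[1, j], upper=q[2, j]) for j in range(X.shape[1])]


def relative_width(ci: Ci95, theta_hat: float) -> float:
    """(upper - lower) / theta_hat; signed by the estimate.  Medians over
    parameters are taken on the magnitude."""
    if theta_hat == 0.0:
        logger.warning("relative CI width undefined for a zero-valued estimate")
        return np.nan
    return (ci.upper - ci.lower) / theta_hat


def asymmetry(ci: Ci95) -> float:
    """(upper - median) / (median - lower): 1 for a symmetric CI, above 1
    for a right-skewed one.  +inf (flagged) when the lower distance is 0."""
    upper_d = ci.upper - ci.median
    lower_d = ci.median - ci.lower
    if lower_d <= 0.0:
        if upper_d <= 0.0:
            return np.nan
        logger.warning("asymmetry ratio is infinite: zero lower distance")
        return np.inf
    return upper_d / lower_d


def method_metrics(
    run: MethodRun,
    theta_hat: ParameterVector,
    model=None,
    data: Dataset | None = None,
    reference_ofv: float | None = None,
) -> pd.DataFrame:
    """Tidy per-parameter metric table for one method run.

    With ``model``/``data`` given, each vector is scored against the model
    to obtain dOFVs, and the run's chi-square df (normalized by the number
    of estimated parameters) is attached; otherwise the df columns are
    omitted with a notice.
    """
    spec = run.spec
    mask = np.asarray(spec.estimated_flags, dtype=bool)
    names = list(spec.estimated_names)
    t = theta_hat.values[mask]
    X = run.values
    r = rse(X, t)
    cis = ci95(X)
    rows = []
    for j, name in enumerate(names):
        rows.append(
            {
                "method": run.method,
                "parameter": name,
                "estimate": t[j],
                "rse": r[j],
                "ci95_lower": cis[j].lower,
                "ci95_median": cis[j].median,
                "ci95_upper": cis[j].upper,
                "relative_width": relative_width(cis[j], t[j]),
                "asymmetry": asymmetry(cis[j]),
            }
        )
    table = pd.DataFrame(rows)
    if model is not None and data is not None:
        if reference_ofv is None:
            reference_ofv = evaluate_ofv(model, data, theta_hat)
        dofvs = np.empty(run.n)
        template = theta_hat.values.copy()
        for i in range(run.n):
            v = template.copy()
            v[mask] = X[i]
            dofvs[i] = evaluate_ofv(model, data, theta_hat.replace_values(v)) - reference_ofv
        ok = np.isfinite(dofvs)
        est = diagnostics.estimate_df(dofvs[ok], k_params=int(mask.sum()))
        table["df"] = est.df
        table["normalized_df"] = est.normalized_df
    else:
        logger.info("no model/data supplied: df columns omitted for method %s", run.method)
    return table


def compare_methods(
    runs: list[MethodRun],
    theta_hat: ParameterVector,
    model=None,
    data: Dataset | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-parameter and per-method-median comparison tables across methods.

    Medians over parameters use the standard even-count rule (mean of the
    two central order statistics); relative widths are aggregated on their
    magnitude so sign conventions of negative estimates do not cancel.
    """
    specs = {id(r.spec) for r in runs}
    if len({tuple(r.spec.names) for r in runs}) != 1:
        raise ValueError("all method runs must share one ParameterSpec")
    del specs
    per_param = pd.concat(
        [method_metrics(r, theta_hat, model=model, data=data) for r in runs],
        ignore_index=True,
    )
    agg = {
        "rse": ("rse", "median"),
        "relative_width": ("relative_width", lambda s: np.median(np.abs(s))),
        "asymmetry": ("asymmetry", "median"),
    }
    medians = per_param.groupby("method", sort=False).agg(**agg).reset_index()
    if "normalized_df" in per_param.columns:
        df_col = per_param.groupby("method", sort=False)["normalized_df"].first()
        medians = medians.merge(df_col.reset_index(), on="method")
    return per_param, medians
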