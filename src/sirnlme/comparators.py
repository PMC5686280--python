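"""Comparison methods: covariance-matrix draws, case bootstrap, and SSE.

Each comparator produces a set of parameter vectors on the same footing as
SIR resamples (default 1000 vectors), so downstream summary metrics — RSE,
CI width, asymmetry, dOFV degrees of freedom — are computed identically
across methods:

* ``cov_uncertainty`` draws from the asymptotic multivariate normal,
  truncated to the parameter bounds by rejection.
* ``case_bootstrap`` resamples subjects (individual data vectors) with
  replacement and re-estimates the model on each bootstrap dataset.
* ``sse`` (stochastic simulation and estimation, a parametric bootstrap)
  simulates datasets from the fitted model on the original design and
  re-estimates on each.

Bootstrap and SSE runs are retained regardless of the optimizer's
termination status; only non-finite results are dropped (with a count),
since they cannot enter any summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import proposal as prop
from .model_core import Dataset, ParameterSpec, ParameterVector, estimate_parameters, simulate_dataset

__all__ = ["MethodRun", "cov_uncertainty", "case_bootstrap", "sse"]

logger = logging.getLogger(__name__)

DEFAULT_N = 1000


@dataclass(frozen=True)
class MethodRun:
    """A parameter-vector set produced by one uncertainty method."""

    method: str  # sir | cov | boot | sse
    spec: ParameterSpec
    values: np.ndarray                  # (n, k) over estimated parameters
    converged: np.ndarray | None = None  # per-vector termination status
    n_dropped: int = 0
    settings: dict | None = None

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def cov_uncertainty(
    center: ParameterVector, cov: np.ndarray, n: int = DEFAULT_N,
    seed: int | np.random.Generator = 0,
) -> MethodRun:
    """n multivariate-normal draws from the asymptotic covariance, truncated
    to the parameter bounds by rejection."""
    p = prop.from_covariance(center, cov)
    drawn = prop.sample(p, n, seed)
    return MethodRun(
        method="cov",
        spec=center.spec,
        values=drawn.values,
        settings={"n": n, "rejected": drawn.n_rejected},
    )


def _estimate_batch(model, datasets, start, n_params_mask):
    values, status = [], []
    n_dropped = 0
    for data in datasets:
        try:
            res = estimate_parameters(model, data, start=start)
        except Exception as exc:  # estimation crash: record as failed
            logger.warning("estimation failed on one replicate: %s", exc)
            n_dropped += 1
            continue
        v = res.estimate.values[n_params_mask]
        if not np.all(np.isfinite(v)):
            n_dropped += 1
            continue
        values.append(v)
        status.append(res.converged)
    return np.array(values), np.array(status, dtype=bool), n_dropped


def case_bootstrap(
    model, data: Dataset, n: int = DEFAULT_N,
    seed: int | np.random.Generator = 0,
    start: ParameterVector | None = None,
) -> MethodRun:
    """Case (subject-level) bootstrap: resample individuals with replacement
    to the original subject count, re-estimate on each bootstrap dataset.

    All runs are retained regardless of the optimizer's termination status;
    non-finite estimates are dropped with a logged count.
    """
    subjects = data.unique_subjects
    if subjects.size < 2:
        logger.warning("case bootstrap over a single subject: zero-variance vectors")
    rng = np.random.default_rng(seed)
    datasets = (
        data.subset_subjects(rng.choice(subjects, size=subjects.size, replace=True))
        for _ in range(n)
    )
    mask = np.asarray(model.spec.estimated_flags, dtype=bool)
    values, status, dropped = _estimate_batch(model, datasets, start, mask)
    if dropped:
        logger.warning("dropped %d non-finite bootstrap estimates", dropped)
    return MethodRun(
        method="boot", spec=model.spec, values=values,
        converged=status, n_dropped=dropped, settings={"n": n},
    )


def sse(
    model, design: Dataset, theta_hat: ParameterVector, n: int = DEFAULT_N,
    seed: int | np.random.Generator = 0,
) -> MethodRun:
    """Stochastic simulation and estimation (parametric bootstrap):
    simulate n datasets from the fitted model on the original design and
    re-estimate the model on each."""
    rng = np.random.default_rng(seed)
    datasets = (simulate_dataset(model, theta_hat, design, rng) for _ in range(n))
    mask = np.asarray(model.spec.estimated_flags, dtype=bool)
    values, status, dropped = _estimate_batch(model, datasets, theta_hat, mask)
    if dropped:
        logger.warning("dropped %d non-finite SSE estimates", dropped)
    return MethodRun(
        method="sse", spec=model.spec, values=values,
        converged=status, n_dropped=dropped, settings={"n": n},
    )
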