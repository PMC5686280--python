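"""Built-in synthetic fixtures: model + simulated dataset + reference truth.

Every fixture is regenerated bit-identically from its (name, seed) pair, so
tests and examples need no stored data.  The conjugate toy is the analytic
anchor of the whole package: a known-variance normal-means model whose
estimator has an exactly known sampling distribution, so the correctness of
the full SIR pipeline can be checked against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import comparators
from .model_core import (
    ConjugateNormalModel,
    Dataset,
    LinearMixedModel,
    OneCompOralPK,
    ParameterVector,
    simulate_dataset,
)

__all__ = ["Fixture", "make_fixture", "limited_bootstrap_vectors", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "conjugate_toy",
    "linear_mixed_small",
    "linear_mixed_large",
    "onecomp_pk_sparse",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    model: object
    theta_true: ParameterVector
    design: Dataset
    data: Dataset
    seed: int
    truth_covariance: np.ndarray | None = None  # exact estimator covariance, if known


def _grid_design(n_subjects: int, times: np.ndarray) -> Dataset:
    ids = np.repeat(np.arange(n_subjects), times.size)
    t = np.tile(times, n_subjects)
    return Dataset(ids, t, np.zeros(ids.size))


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build one of the named fixtures, reproducibly from (name, seed).

    conjugate_toy       5 known-variance normal means, 50 obs per group
    linear_mixed_small  random-intercept line, 20 subjects x 4 observations
    linear_mixed_large  same model, 200 subjects x 4 observations
    onecomp_pk_sparse   one-compartment oral PK, 30 subjects x 3 samples
    """
    if name == "conjugate_toy":
        model = ConjugateNormalModel(n_groups=5, sigma0=1.0)
        theta = ParameterVector(model.spec, np.array([1.0, -0.5, 2.0, 0.3, 4.0]))
        n_per = 50
        design = _grid_design(model.n_groups, np.arange(n_per, dtype=float))
        data = simulate_dataset(model, theta, design, seed)
        truth = np.diag(np.full(model.n_groups, model.sigma0**2 / n_per))
        return Fixture(name, model, theta, design, data, seed, truth)
    if name in ("linear_mixed_small", "linear_mixed_large"):
        model = LinearMixedModel()
        theta = ParameterVector(model.spec, np.array([10.0, 2.0, 1.0, 0.5]))
        n_sub = 20 if name == "linear_mixed_small" else 200
        design = _grid_design(n_sub, np.array([0.0, 1.0, 2.0, 3.0]))
        data = simulate_dataset(model, theta, design, seed)
        return Fixture(name, model, theta, design, data, seed, None)
    if name == "onecomp_pk_sparse":
        model = OneCompOralPK()
        theta = ParameterVector(
            model.spec, np.array([5.0, 50.0, 0.09, 0.09, 0.01])
        )
        design = _grid_design(30, np.array([0.5, 2.0, 8.0]))
        data = simulate_dataset(model, theta, design, seed)
        return Fixture(name, model, theta, design, data, seed, None)
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def limited_bootstrap_vectors(
    fixture: Fixture, n: int = 200, seed: int = 0
) -> np.ndarray:
    """A limited case bootstrap (default 200 replicates) whose vectors can
    seed the first SIR proposal when no covariance matrix is available."""
    run = comparators.case_bootstrap(fixture.model, fixture.data, n=n, seed=seed)
    return run.values
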