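"""Model/dataset abstractions and built-in mixed-effects models.

The uncertainty machinery in this package only ever needs one thing from a
model: the objective function value (OFV, minus two times the log-likelihood
up to an additive constant shared across parameter vectors) of a dataset at
an arbitrary parameter vector.  That contract is :class:`OfvEvaluator`.

Two built-in model families implement it with tractable likelihoods so the
whole workflow runs without any external estimation software:

* ``LinearMixedModel`` — y_ij = th1 + th2*x_ij + eta_i + eps_ij with
  eta_i ~ N(0, omega2) and eps_ij ~ N(0, sigma2).  The marginal likelihood
  is an exact compound-symmetric multivariate normal, evaluated in closed
  form via the Sherman–Morrison identity.
* ``OneCompOralPK`` — one-compartment oral-absorption pharmacokinetics with
  log-normal inter-individual variability on clearance and volume and a
  proportional residual error; the marginal likelihood is approximated by
  the Laplace method (adaptive Gauss–Hermite quadrature is available as a
  cross-check).

OFV convention: the full ``n*log(2*pi)`` constant is included, so the
linear-mixed OFV equals ``-2 * log`` of the exact marginal normal density.
Only OFV differences (dOFV) are consumed downstream, so the convention is
immaterial to results but makes oracle comparisons exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.differentiate import jacobian as _nd_jacobian

__all__ = [
    "ParameterSpec",
    "ParameterVector",
    "Dataset",
    "OfvEvaluator",
    "EstimationResult",
    "LinearMixedModel",
    "OneCompOralPK",
    "ConjugateNormalModel",
    "evaluate_ofv",
    "simulate_dataset",
    "estimate_parameters",
]

_LOG2PI = np.log(2.0 * np.pi)

PARAM_CLASSES = frozenset(
    {"fixed_effect", "iiv_variance", "iov_variance", "residual_variance", "correlation"}
)
_VARIANCE_CLASSES = frozenset({"iiv_variance", "iov_variance", "residual_variance"})


@dataclass(frozen=True)
class ParameterSpec:
    """Names, classes, estimation flags and bounds of a model's parameters.

    Parameters with ``estimated_flags`` False are fixed and excluded from the
    uncertainty distribution.  Variance-class parameters are lower-bounded at
    zero regardless of the user-supplied bounds.
    """

    names: tuple[str, ...]
    classes: tuple[str, ...]
    estimated_flags: tuple[bool, ...] = ()
    bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.names)
        classes = tuple(self.classes)
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        if len(classes) != len(names):
            raise ValueError("classes must align with names")
        unknown = set(classes) - PARAM_CLASSES
        if unknown:
            raise ValueError(f"unknown parameter classes: {sorted(unknown)}")
        flags = tuple(self.estimated_flags) or (True,) * len(names)
        if len(flags) != len(names):
            raise ValueError("estimated_flags must align with names")
        bounds = tuple(self.bounds) or tuple(
            (0.0, np.inf) if c in _VARIANCE_CLASSES else (-np.inf, np.inf)
            for c in classes
        )
        if len(bounds) != len(names):
            raise ValueError("bounds must align with names")
        fixed = []
        for c, (lo, hi) in zip(classes, bounds):
            if c in _VARIANCE_CLASSES and lo < 0.0:
                lo = 0.0
            fixed.append((float(lo), float(hi)))
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "estimated_flags", flags)
        object.__setattr__(self, "bounds", tuple(fixed))

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_estimated(self) -> int:
        return int(sum(self.estimated_flags))

    @property
    def estimated_names(self) -> tuple[str, ...]:
        return tuple(n for n, f in zip(self.names, self.estimated_flags) if f)

    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    def within_bounds(self, values: np.ndarray, atol: float = 0.0) -> bool:
        v = np.asarray(values, dtype=float)
        return bool(np.all(v >= self.lower() - atol) and np.all(v <= self.upper() + atol))


@dataclass(frozen=True)
class ParameterVector:
    """One point in the joint parameter space, aligned with a ParameterSpec."""

    spec: ParameterSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.spec),):
            raise ValueError(
                f"expected {len(self.spec)} values, got shape {v.shape}"
            )
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.names.index(name)])

    def replace_values(self, values: np.ndarray) -> "ParameterVector":
        return replace(self, values=np.asarray(values, dtype=float))

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.spec.names))


@dataclass(frozen=True)
class Dataset:
    """Rectangular longitudinal dataset: one row per observation.

    ``subject_ids`` maps each observation to its subject; ``times`` carries
    the within-subject design variable (observation time, or a generic
    covariate x for the linear model); ``dv`` holds the continuous response.
    """

    subject_ids: np.ndarray
    times: np.ndarray
    dv: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.subject_ids)
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.dv, dtype=float)
        if not (ids.shape == t.shape == y.shape) or ids.ndim != 1:
            raise ValueError("subject_ids, times and dv must be equal-length 1-D")
        if ids.size == 0:
            raise ValueError("dataset is empty")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "dv", y)

    @property
    def n_obs(self) -> int:
        return int(self.dv.size)

    @property
    def unique_subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return int(self.unique_subjects.size)

    def subject_index(self) -> np.ndarray:
        """0-based dense subject index per observation (sorted unique ids)."""
        return np.searchsorted(self.unique_subjects, self.subject_ids)

    def subset_subjects(self, ids: Sequence, relabel: bool = True) -> "Dataset":
        """Dataset restricted to ``ids``, one block per requested id in order.

        With ``relabel`` (the default) each block receives a fresh subject id
        0..len(ids)-1, so repeated ids — as produced by a case bootstrap —
        become distinct subjects.
        """
        blocks_id, blocks_t, blocks_y = [], [], []
        for new, sid in enumerate(ids):
            mask = self.subject_ids == sid
            if not mask.any():
                raise KeyError(f"unknown subject id {sid!r}")
            blocks_id.append(
                np.full(int(mask.sum()), new if relabel else sid)
            )
            blocks_t.append(self.times[mask])
            blocks_y.append(self.dv[mask])
        return Dataset(
            np.concatenate(blocks_id), np.concatenate(blocks_t), np.concatenate(blocks_y)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ID": self.subject_ids, "TIME": self.times, "DV": self.dv}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Dataset":
        return cls(
            frame["ID"].to_numpy(), frame["TIME"].to_numpy(float), frame["DV"].to_numpy(float)
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


@runtime_checkable
class OfvEvaluator(Protocol):
    """Contract: anything that can score a parameter vector on a dataset.

    ``ofv`` must be deterministic and equal to -2*log-likelihood up to an
    additive constant shared across vectors; only differences are consumed
    downstream.  A non-finite return signals evaluation failure for that
    vector (the SIR engine assigns it importance ratio 0 and counts it).
    """

    spec: ParameterSpec

    def ofv(self, data: Dataset, theta: ParameterVector) -> float: ...


@dataclass(frozen=True)
class EstimationResult:
    estimate: ParameterVector
    ofv: float
    covariance: np.ndarray  # over estimated parameters, spec order
    converged: bool
    n_evaluations: int = 0


def _group_sums(idx: np.ndarray, n_groups: int, *arrays: np.ndarray):
    return tuple(np.bincount(idx, weights=a, minlength=n_groups) for a in arrays)


@dataclass(frozen=True)
class LinearMixedModel:
    """Random-intercept linear model with exact marginal likelihood.

    Parameters (in spec order): intercept ``theta1``, slope ``theta2``,
    between-subject variance ``omega2``, residual variance ``sigma2``.
    """

    spec: ParameterSpec = field(
        default_factory=lambda: ParameterSpec(
            names=("theta1", "theta2", "omega2", "sigma2"),
            classes=("fixed_effect", "fixed_effect", "iiv_variance", "residual_variance"),
        )
    )

    def ofv(self, data: Dataset, theta: ParameterVector) -> float:
        th1, th2, om2, sg2 = theta.values
        if sg2 <= 0.0 or om2 < 0.0:
            return np.inf
        idx = data.subject_index()
        n_sub = data.n_subjects
        r = data.dv - th1 - th2 * data.times
        n_i = np.bincount(idx, minlength=n_sub).astype(float)
        (ss_i, s_i) = _group_sums(idx, n_sub, r * r, r)
        # Sherman-Morrison on V_i = sg2*I + om2*J
        denom = sg2 + n_i * om2
        quad = (ss_i - om2 * s_i**2 / denom) / sg2
        logdet = (n_i - 1.0) * np.log(sg2) + np.log(denom)
        ofv = float(np.sum(n_i * _LOG2PI + logdet + quad))
        return ofv if np.isfinite(ofv) else np.inf

    def ofv_by_subject(self, data: Dataset, theta: ParameterVector) -> np.ndarray:
        th1, th2, om2, sg2 = theta.values
        idx = data.subject_index()
        n_sub = data.n_subjects
        r = data.dv - th1 - th2 * data.times
        n_i = np.bincount(idx, minlength=n_sub).astype(float)
        ss_i, s_i = _group_sums(idx, n_sub, r * r, r)
        denom = sg2 + n_i * om2
        quad = (ss_i - om2 * s_i**2 / denom) / sg2
        logdet = (n_i - 1.0) * np.log(sg2) + np.log(denom)
        return n_i * _LOG2PI + logdet + quad

    def simulate(
        self, theta: ParameterVector, design: Dataset, rng: np.random.Generator
    ) -> Dataset:
        th1, th2, om2, sg2 = theta.values
        idx = design.subject_index()
        eta = rng.normal(0.0, np.sqrt(om2), design.n_subjects)
        eps = rng.normal(0.0, np.sqrt(sg2), design.n_obs)
        y = th1 + th2 * design.times + eta[idx] + eps
        return Dataset(design.subject_ids.copy(), design.times.copy(), y)

    def start_values(self, data: Dataset) -> ParameterVector:
        # moment start: OLS for the line, pooled residual split half/half
        t, y = data.times, data.dv
        slope, intercept = np.polyfit(t, y, 1) if np.ptp(t) > 0 else (0.0, y.mean())
        resid = y - intercept - slope * t
        v = max(float(np.var(resid)), 1e-6)
        return ParameterVector(self.spec, np.array([intercept, slope, v / 2, v / 2]))


@dataclass(frozen=True)
class OneCompOralPK:
    """One-compartment oral PK with IIV on CL and V, proportional error.

    Individual prediction for dose D at time t:
        f(t) = D*ka / (V_i*(ka - ke_i)) * (exp(-ke_i*t) - exp(-ka*t)),
    with ke_i = CL_i/V_i, CL_i = CL*exp(eta1), V_i = V*exp(eta2),
    eta ~ N(0, diag(omega2_cl, omega2_v)), y = f*(1 + eps), eps ~ N(0, sigma2).

    The marginal likelihood integrates the two etas per subject; by default a
    Laplace approximation at the empirical-Bayes mode is used.  Setting
    ``method="agq"`` switches to adaptive Gauss–Hermite quadrature centred at
    the same mode (tensor grid, ``agq_nodes`` points per axis).
    """

    dose: float = 100.0
    ka: float = 1.5
    method: str = "laplace"
    agq_nodes: int = 9
    spec: ParameterSpec = field(
        default_factory=lambda: ParameterSpec(
            names=("cl", "v", "omega2_cl", "omega2_v", "sigma2"),
            classes=(
                "fixed_effect",
                "fixed_effect",
                "iiv_variance",
                "iiv_variance",
                "residual_variance",
            ),
            bounds=((1e-6, np.inf), (1e-6, np.inf), (0, np.inf), (0, np.inf), (1e-10, np.inf)),
        )
    )

    def _pred(self, t: np.ndarray, cl_i: float, v_i: float) -> np.ndarray:
        ke = cl_i / v_i
        ka = self.ka
        if abs(ka - ke) < 1e-10:
            ke = ka * (1 - 1e-8)
        return self.dose * ka / (v_i * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))

    def _neg2_log_joint(self, eta, t, y, cl, v, om2, sg2):
        f = self._pred(t, cl * np.exp(eta[0]), v * np.exp(eta[1]))
        var = sg2 * np.maximum(f, 1e-12) ** 2
        data_term = np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var)
        prior = (
            eta[0] ** 2 / om2[0] + eta[1] ** 2 / om2[1]
            + np.log(2 * np.pi * om2[0]) + np.log(2 * np.pi * om2[1])
        )
        return data_term + prior

    def _subject_ofv(self, t, y, values) -> float:
        cl, v, om2cl, om2v, sg2 = values
        if min(cl, v, sg2) <= 0 or min(om2cl, om2v) <= 1e-10:
            return np.inf
        om2 = (om2cl, om2v)
        g = lambda e: 0.5 * self._neg2_log_joint(e, t, y, cl, v, om2, sg2)
        res = optimize.minimize(g, np.zeros(2), method="BFGS")
        mode = res.x
        h = _finite_hessian(g, mode, rel_step=1e-4)
        sign, logdet = np.linalg.slogdet(h)
        if sign <= 0:  # saddle or numerical failure: fall back to prior curvature
            h = np.diag([1.0 / om2cl, 1.0 / om2v])
            logdet = float(np.log(1.0 / om2cl) + np.log(1.0 / om2v))
        if self.method == "laplace":
            # -2 log L ~= 2 g(mode) + log|H| - d log(2 pi)
            return 2.0 * res.fun + logdet - 2.0 * _LOG2PI
        return self._agq_subject(g, mode, h)

    def _agq_subject(self, g, mode, h) -> float:
        from numpy.polynomial.hermite_e import hermegauss

        nodes, weights = hermegauss(self.agq_nodes)
        L = np.linalg.cholesky(np.linalg.inv(h))
        g0 = g(mode)
        total = 0.0
        for i, zi in enumerate(nodes):
            for j, zj in enumerate(nodes):
                z = np.array([zi, zj])
                e = mode + L @ z
                total += (
                    weights[i] * weights[j]
                    * np.exp(-(g(e) - g0) + 0.5 * (zi**2 + zj**2))
                )
        sign, logdet_l = np.linalg.slogdet(L)
        log_lik = -g0 + logdet_l + np.log(total)
        return -2.0 * float(log_lik)

    def ofv_by_subject(self, data: Dataset, theta: ParameterVector) -> np.ndarray:
        idx = data.subject_index()
        out = np.empty(data.n_subjects)
        for k in range(data.n_subjects):
            m = idx == k
            out[k] = self._subject_ofv(data.times[m], data.dv[m], theta.values)
        return out

    def ofv(self, data: Dataset, theta: ParameterVector) -> float:
        per = self.ofv_by_subject(data, theta)
        total = float(np.sum(per))
        return total if np.isfinite(total) else np.inf

    def simulate(
        self, theta: ParameterVector, design: Dataset, rng: np.random.Generator
    ) -> Dataset:
        cl, v, om2cl, om2v, sg2 = theta.values
        idx = design.subject_index()
        eta1 = rng.normal(0.0, np.sqrt(om2cl), design.n_subjects)
        eta2 = rng.normal(0.0, np.sqrt(om2v), design.n_subjects)
        y = np.empty(design.n_obs)
        for k in range(design.n_subjects):
            m = idx == k
            f = self._pred(design.times[m], cl * np.exp(eta1[k]), v * np.exp(eta2[k]))
            y[m] = f * (1.0 + rng.normal(0.0, np.sqrt(sg2), int(m.sum())))
        return Dataset(design.subject_ids.copy(), design.times.copy(), y)

    def start_values(self, data: Dataset) -> ParameterVector:
        return ParameterVector(self.spec, np.array([5.0, 50.0, 0.1, 0.1, 0.02]))


@dataclass(frozen=True)
class ConjugateNormalModel:
    """Known-variance normal means: p independent groups, exact quadratic OFV.

    Group k has n_k observations y ~ N(mu_k, sigma0^2) with sigma0 known.
    The maximum-likelihood estimator is the vector of group means with exact
    sampling covariance diag(sigma0^2/n_k); dOFV at mu is the exact quadratic
    form sum_k n_k (mu_k - ybar_k)^2 / sigma0^2, so when mu is drawn from the
    estimator's sampling distribution, dOFV ~ chi-square(p).  This makes the
    model an analytic end-to-end anchor for the SIR machinery.
    """

    n_groups: int = 5
    sigma0: float = 1.0

    @property
    def spec(self) -> ParameterSpec:
        return ParameterSpec(
            names=tuple(f"mu{k + 1}" for k in range(self.n_groups)),
            classes=("fixed_effect",) * self.n_groups,
        )

    def ofv(self, data: Dataset, theta: ParameterVector) -> float:
        idx = data.subject_index()
        if data.n_subjects != self.n_groups:
            raise ValueError("dataset groups do not match model dimension")
        r = data.dv - theta.values[idx]
        return float(
            np.sum(r * r) / self.sigma0**2 + data.n_obs * np.log(2 * np.pi * self.sigma0**2)
        )

    def ofv_by_subject(self, data: Dataset, theta: ParameterVector) -> np.ndarray:
        idx = data.subject_index()
        r2 = (data.dv - theta.values[idx]) ** 2
        n_i = np.bincount(idx, minlength=self.n_groups).astype(float)
        return (
            np.bincount(idx, weights=r2, minlength=self.n_groups) / self.sigma0**2
            + n_i * np.log(2 * np.pi * self.sigma0**2)
        )

    def simulate(
        self, theta: ParameterVector, design: Dataset, rng: np.random.Generator
    ) -> Dataset:
        idx = design.subject_index()
        y = theta.values[idx] + rng.normal(0.0, self.sigma0, design.n_obs)
        return Dataset(design.subject_ids.copy(), design.times.copy(), y)

    def exact_estimate(self, data: Dataset) -> tuple[ParameterVector, np.ndarray]:
        """Group means and their exact sampling covariance."""
        idx = data.subject_index()
        n_i = np.bincount(idx, minlength=self.n_groups).astype(float)
        means = np.bincount(idx, weights=data.dv, minlength=self.n_groups) / n_i
        cov = np.diag(self.sigma0**2 / n_i)
        return ParameterVector(self.spec, means), cov

    def start_values(self, data: Dataset) -> ParameterVector:
        return self.exact_estimate(data)[0]


def evaluate_ofv(model: OfvEvaluator, data: Dataset, theta: ParameterVector) -> float:
    """OFV of ``theta``; returns +inf (never raises) on evaluation failure."""
    if data.n_obs == 0:
        raise ValueError("dataset is empty")
    try:
        val = model.ofv(data, theta)
    except (FloatingPointError, np.linalg.LinAlgError, ValueError, OverflowError):
        return np.inf
    return float(val) if np.isfinite(val) else np.inf


def simulate_dataset(
    model, theta: ParameterVector, design: Dataset, seed: int | np.random.Generator
) -> Dataset:
    """Simulate a dataset from ``model`` at ``theta`` on the given design."""
    if not model.spec.within_bounds(theta.values):
        raise ValueError("theta outside declared bounds")
    rng = np.random.default_rng(seed)
    return model.simulate(theta, design, rng)


def _finite_hessian(f: Callable, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian with per-coordinate relative steps."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _psd_project(a: np.ndarray) -> np.ndarray:
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    return (v * np.clip(w, 0.0, None)) @ v.T


def estimate_parameters(
    model,
    data: Dataset,
    start: ParameterVector | None = None,
    covariance: str = "hessian",
) -> EstimationResult:
    """Minimize the OFV and return estimates with an asymptotic covariance.

    The covariance of the estimated parameters is the inverse of the numeric
    Hessian of OFV/2 at the optimum (``covariance="hessian"``, the default)
    or the robust sandwich Hessian^-1 * (per-subject score cross-product) *
    Hessian^-1 (``covariance="sandwich"``).  Non-convergence returns the
    best-found vector flagged ``converged=False`` rather than raising.
    """
    if isinstance(model, ConjugateNormalModel):
        est, cov = model.exact_estimate(data)
        return EstimationResult(est, evaluate_ofv(model, data, est), cov, True)
    spec = model.spec
    if start is None:
        start = model.start_values(data)
    est_mask = np.asarray(spec.estimated_flags, dtype=bool)
    base = start.values.copy()

    def full(x: np.ndarray) -> np.ndarray:
        v = base.copy()
        v[est_mask] = x
        return v

    def obj(x: np.ndarray) -> float:
        return evaluate_ofv(model, data, start.replace_values(full(x)))

    lo, hi = spec.lower()[est_mask], spec.upper()[est_mask]
    # keep variances strictly interior so the Hessian is finite
    eps = 1e-8 * np.maximum(np.abs(base[est_mask]), 1.0)
    bounds = list(zip(np.where(np.isfinite(lo), lo + eps, None),
                      np.where(np.isfinite(hi), hi - eps, None)))
    x0 = np.clip(base[est_mask], lo + eps, np.where(np.isfinite(hi), hi - eps, np.inf))
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
    xhat = res.x if res.fun <= obj(x0) else x0
    fhat = min(float(res.fun), obj(x0))
    half = lambda x: 0.5 * obj(x)
    p = int(est_mask.sum())
    try:
        H = _finite_hessian(half, xhat)
        if not np.all(np.isfinite(H)):
            raise np.linalg.LinAlgError("non-finite Hessian")
        cov = np.linalg.pinv(H)
        if covariance == "sandwich":
            cov = _sandwich(model, data, start.replace_values(full(xhat)), est_mask, H)
        cov = _psd_project(cov)
    except np.linalg.LinAlgError:
        # boundary optimum (e.g. a variance estimated at ~0): curvature is
        # not informative there; estimates are still returned
        cov = np.full((p, p), np.nan)
    return EstimationResult(
        start.replace_values(full(xhat)), fhat, cov, bool(res.success), int(res.nfev)
    )


def _sandwich(model, data, theta, est_mask, H) -> np.ndarray:
    """Hessian^-1 * sum_i g_i g_i^T * Hessian^-1 with per-subject scores of OFV/2."""
    base = theta.values.copy()

    def per_subject(x: np.ndarray) -> np.ndarray:
        v = base.copy()
        v[est_mask] = x
        return 0.5 * model.ofv_by_subject(data, theta.replace_values(v))

    xhat = base[est_mask]
    jac = _nd_jacobian(
        lambda xs: np.apply_along_axis(per_subject, 0, xs), xhat
    ).df  # (n_subjects, p)
    B = jac.T @ jac
    Hinv = np.linalg.pinv(H)
    return Hinv @ B @ Hinv
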