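"""Proposal distributions for SIR: multivariate normal and multivariate Box-Cox.

A proposal must support three things: drawing parameter vectors, evaluating
the density of a vector relative to the density at the final estimates
(relPDF), and being inflated (all variances and covariances multiplied by a
single factor, leaving correlations untouched).

The multivariate Box-Cox proposal applies a per-parameter power transform
z_k = ((x_k + s_k)^lambda_k - 1)/lambda_k (log(x_k + s_k) when lambda_k = 0)
and models z as multivariate normal, so correlations are linear on the
transformed scale and each margin can be symmetric (lambda ~ 1) or
right-skewed (lambda ~ 0, log-normal-like).  Shape parameters are fitted per
parameter by profile likelihood on the marginals; shifts keep the support
positive for sign-indefinite parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .model_core import ParameterSpec, ParameterVector

__all__ = [
    "MvnProposal",
    "BoxCoxProposal",
    "from_covariance",
    "generic_proposal",
    "inflate",
    "fit_boxcox",
    "sample",
    "relpdf",
    "GENERIC_RSE",
]

logger = logging.getLogger(__name__)

# relative standard errors, by parameter class, of the generic first proposal
GENERIC_RSE = {
    "fixed_effect": 0.30,
    "iiv_variance": 0.50,
    "iov_variance": 0.50,
    "residual_variance": 0.10,
    "correlation": 0.30,
}

_MAX_REJECTION_RATE = 0.5


def _ensure_psd(cov: np.ndarray, label: str = "covariance") -> np.ndarray:
    """Symmetrize and clip tiny negative eigenvalues; warn if repair was needed."""
    cov = np.asarray(cov, dtype=float)
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() < 0.0:
        scale = max(w.max(), 0.0)
        if w.min() < -1e-8 * max(scale, 1.0):
            logger.warning(
                "%s is indefinite (min eigenvalue %.3e); clipping to nearest PSD",
                label, w.min(),
            )
        else:
            logger.warning("%s had numerical-noise negative eigenvalues; repaired", label)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        cov = 0.5 * (cov + cov.T)
    return cov


@dataclass(frozen=True)
class MvnProposal:
    """Multivariate normal proposal centred at the final estimates."""

    center: ParameterVector
    covariance: np.ndarray

    def __post_init__(self) -> None:
        cov = _ensure_psd(self.covariance)
        k = self.center.spec.n_estimated
        if cov.shape != (k, k):
            raise ValueError(
                f"covariance is {cov.shape}, expected ({k}, {k}) over estimated parameters"
            )
        object.__setattr__(self, "covariance", cov)

    @property
    def spec(self) -> ParameterSpec:
        return self.center.spec

    def _center_est(self) -> np.ndarray:
        mask = np.asarray(self.spec.estimated_flags, dtype=bool)
        return self.center.values[mask]

    def logpdf(self, values: np.ndarray) -> np.ndarray:
        return stats.multivariate_normal(
            mean=self._center_est(), cov=self.covariance, allow_singular=True
        ).logpdf(np.atleast_2d(values))

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(
            self._center_est(), self.covariance, size=n, method="eigh"
        )

    def marginal_sds(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass(frozen=True)
class BoxCoxProposal:
    """Multivariate Box-Cox proposal: MVN on the per-parameter transformed scale."""

    center: ParameterVector
    shapes: np.ndarray       # lambda_k
    shifts: np.ndarray       # s_k, so x_k + s_k > 0 on the fitted support
    mean_z: np.ndarray
    covariance_z: np.ndarray
    zero_variance_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = self.center.spec.n_estimated
        shapes = np.asarray(self.shapes, dtype=float)
        shifts = np.asarray(self.shifts, dtype=float)
        mean_z = np.asarray(self.mean_z, dtype=float)
        cov = _ensure_psd(self.covariance_z, "transformed-scale covariance")
        if not (shapes.shape == shifts.shape == mean_z.shape == (k,)):
            raise ValueError("shape/shift/mean dimensions must match estimated parameters")
        if cov.shape != (k, k):
            raise ValueError("transformed-scale covariance has wrong shape")
        object.__setattr__(self, "shapes", shapes)
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "mean_z", mean_z)
        object.__setattr__(self, "covariance_z", cov)

    @property
    def spec(self) -> ParameterSpec:
        return self.center.spec

    def _center_est(self) -> np.ndarray:
        mask = np.asarray(self.spec.estimated_flags, dtype=bool)
        return self.center.values[mask]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """x -> z; NaN where x + s <= 0 (outside support)."""
        x = np.atleast_2d(x)
        shifted = x + self.shifts
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(
                self.shapes == 0.0,
                np.log(np.where(shifted > 0, shifted, np.nan)),
                (np.sign(shifted) * np.abs(shifted) ** self.shapes - 1.0)
                / np.where(self.shapes == 0.0, 1.0, self.shapes),
            )
        z = np.where(shifted > 0, z, np.nan)
        return z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        """z -> x; NaN where lambda*z + 1 <= 0 (unreachable on the x scale)."""
        z = np.atleast_2d(z)
        lam = self.shapes
        with np.errstate(invalid="ignore", divide="ignore"):
            base = lam * z + 1.0
            x = np.where(
                lam == 0.0,
                np.exp(z),
                np.where(base > 0, base, np.nan) ** np.where(lam == 0.0, 1.0, 1.0 / lam),
            )
        return x - self.shifts

    def logpdf(self, values: np.ndarray) -> np.ndarray:
        """Log density on the x scale, including the Jacobian prod (x+s)^(lam-1).

        Returns -inf outside the support (x_k + s_k <= 0).
        """
        x = np.atleast_2d(values)
        z = self.transform(x)
        out = np.full(x.shape[0], -np.inf)
        ok = ~np.isnan(z).any(axis=1)
        if ok.any():
            mvn = stats.multivariate_normal(
                mean=self.mean_z, cov=self.covariance_z, allow_singular=True
            )
            log_jac = np.sum(
                (self.shapes - 1.0) * np.log(x[ok] + self.shifts), axis=1
            )
            out[ok] = np.atleast_1d(mvn.logpdf(z[ok])) + log_jac
        return out

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.multivariate_normal(self.mean_z, self.covariance_z, size=n, method="eigh")
        return self.inverse(z)

    def marginal_sds(self) -> np.ndarray:
        # on the transformed scale; used for inflation bookkeeping only
        return np.sqrt(np.diag(self.covariance_z))


Proposal = MvnProposal | BoxCoxProposal


def from_covariance(center: ParameterVector, cov: np.ndarray) -> MvnProposal:
    """Multivariate-normal proposal from final estimates and their covariance.

    Slightly indefinite matrices (as published covariance matrices often are)
    are repaired to the nearest PSD matrix by eigenvalue clipping.
    """
    cov = np.asarray(cov, dtype=float)
    k = center.spec.n_estimated
    if cov.ndim != 2 or cov.shape != (k, k):
        raise ValueError(
            f"covariance must be ({k}, {k}) to match the estimated parameters"
        )
    return MvnProposal(center=center, covariance=cov)


def generic_proposal(center: ParameterVector, spec: ParameterSpec | None = None) -> MvnProposal:
    """Generic diagonal proposal: class-specific relative standard errors.

    Fixed effects get 30% RSE, inter-individual/inter-occasion variabilities
    50%, residual variabilities 10%; no correlations.  Zero-valued parameters
    admit no relative SE and raise (supply an explicit covariance instead).
    """
    spec = spec or center.spec
    mask = np.asarray(spec.estimated_flags, dtype=bool)
    values = center.values[mask]
    classes = [c for c, f in zip(spec.classes, spec.estimated_flags) if f]
    names = [n for n, f in zip(spec.names, spec.estimated_flags) if f]
    sds = np.empty(values.size)
    for i, (v, c, n) in enumerate(zip(values, classes, names)):
        if v == 0.0:
            raise ValueError(
                f"parameter {n!r} is zero: a generic RSE cannot be formed; "
                "provide an explicit absolute SE or covariance"
            )
        sds[i] = GENERIC_RSE[c] * abs(v)
    return MvnProposal(center=center, covariance=np.diag(sds**2))


def inflate(p: Proposal, factor: float) -> Proposal:
    """Widen a proposal by multiplying all variances and covariances by ``factor``.

    The center (and, for Box-Cox, the shapes and shifts) is unchanged, and so
    are all pairwise correlations.  Factors below 1 are rejected: inflation
    exists to widen underestimated proposals, never to shrink them.
    """
    if factor < 1.0:
        raise ValueError("inflation factor must be >= 1")
    if isinstance(p, MvnProposal):
        return replace(p, covariance=p.covariance * factor)
    return replace(p, covariance_z=p.covariance_z * factor)


def _profile_lambda(x: np.ndarray, grid: np.ndarray) -> float:
    """Box-Cox shape maximizing the profile log-likelihood of one margin."""
    lls = np.array([stats.boxcox_llf(l, x) for l in grid])
    best = grid[int(np.argmax(lls))]
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x),
        bounds=(max(best - span, grid[0]), min(best + span, grid[-1])),
        method="bounded",
    )
    return float(res.x) if res.fun <= -lls.max() else float(best)


def _shift_for(x: np.ndarray) -> float:
    if x.min() > 0.0:
        return 0.0
    rng_ = x.max() - x.min()
    return float(-x.min() + 0.1 * (rng_ if rng_ > 0 else 1.0))


def fit_boxcox(
    vectors: np.ndarray | list[ParameterVector],
    center: ParameterVector,
    fixed_shapes: dict[str, float] | None = None,
    cap_correlation: float | None = None,
    shape_grid: np.ndarray | None = None,
) -> BoxCoxProposal:
    """Fit a multivariate Box-Cox distribution to a set of parameter vectors.

    Per-parameter shapes are profile-likelihood estimates on the marginals
    over a grid on [-2, 2] with a local refinement; ``fixed_shapes`` maps
    parameter classes (e.g. ``{"fixed_effect": 1.0, "iiv_variance": 0.0}``)
    to shapes that are honored exactly, leaving only the moments to fit.
    The transformed-scale covariance is the sample covariance of z; with
    ``cap_correlation`` set, off-diagonal correlations exceeding the cap in
    magnitude are shrunk to it.
    """
    spec = center.spec
    mask = np.asarray(spec.estimated_flags, dtype=bool)
    if isinstance(vectors, list):
        X = np.array([v.values for v in vectors])[:, mask]
    else:
        X = np.asarray(vectors, dtype=float)
        if X.shape[1] == len(spec):
            X = X[:, mask]
    n, k = X.shape
    if n < 50:
        raise ValueError(f"need at least 50 vectors to fit a Box-Cox proposal, got {n}")
    if n <= k:
        raise ValueError("need more vectors than parameters")
    classes = [c for c, f in zip(spec.classes, spec.estimated_flags) if f]
    grid = shape_grid if shape_grid is not None else np.linspace(-2.0, 2.0, 41)
    shapes = np.empty(k)
    shifts = np.empty(k)
    degenerate = np.zeros(k, dtype=bool)
    for j in range(k):
        xj = X[:, j]
        if np.ptp(xj) == 0.0:
            shapes[j] = 1.0
            shifts[j] = _shift_for(xj)
            degenerate[j] = True
            logger.warning("parameter %d has zero spread; shape fixed at 1", j)
            continue
        shifts[j] = _shift_for(xj)
        if fixed_shapes is not None and classes[j] in fixed_shapes:
            shapes[j] = float(fixed_shapes[classes[j]])
            if shapes[j] == 0.0 and (xj + shifts[j]).min() <= 0:
                shifts[j] = _shift_for(xj)
        else:
            shapes[j] = _profile_lambda(xj + shifts[j], grid)
    proto = BoxCoxProposal(
        center=center,
        shapes=shapes,
        shifts=shifts,
        mean_z=np.zeros(k),
        covariance_z=np.eye(k),
    )
    Z = proto.transform(X)
    mean_z = Z.mean(axis=0)
    cov_z = np.cov(Z, rowvar=False)
    cov_z = np.atleast_2d(cov_z)
    if degenerate.any():
        d = np.diag(cov_z).copy()
        d[degenerate] = 0.0
        cov_z[degenerate, :] = 0.0
        cov_z[:, degenerate] = 0.0
        cov_z[np.diag_indices(k)] = d
    if cap_correlation is not None:
        cov_z = _cap_correlations(cov_z, cap_correlation)
    return BoxCoxProposal(
        center=center,
        shapes=shapes,
        shifts=shifts,
        mean_z=mean_z,
        covariance_z=cov_z,
        zero_variance_flags=degenerate if degenerate.any() else None,
    )


def _cap_correlations(cov: np.ndarray, cap: float) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    clipped = np.clip(corr, -cap, cap)
    np.fill_diagonal(clipped, 1.0)
    if not np.allclose(clipped, corr):
        logger.warning("correlations exceeding %.2f were capped", cap)
    return clipped * np.outer(sd, sd)


@dataclass(frozen=True)
class SampleResult:
    values: np.ndarray  # (n, k) over estimated parameters
    n_rejected: int


def sample(
    p: Proposal, M: int, seed: int | np.random.Generator, max_batches: int = 40
) -> SampleResult:
    """Draw M vectors, rejecting (and redrawing) any that violate bounds.

    Truncation is by rejection, never clipping: clipped draws would place
    probability atoms on the bounds and corrupt the density ratios.  A
    rejection rate above 50% aborts — the proposal is grossly misplaced
    relative to the parameter bounds.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    spec = p.spec
    mask = np.asarray(spec.estimated_flags, dtype=bool)
    lo, hi = spec.lower()[mask], spec.upper()[mask]
    kept: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    n_rejected = 0
    for _ in range(max_batches):
        need = M - n_kept
        batch = p.draw(max(need, 1), rng)
        finite = ~np.isnan(batch).any(axis=1)
        ok = finite & np.all(batch >= lo, axis=1) & np.all(batch <= hi, axis=1)
        n_drawn += batch.shape[0]
        n_rejected += int((~ok).sum())
        if ok.any():
            kept.append(batch[ok])
            n_kept += int(ok.sum())
        if n_kept >= M:
            break
        if n_drawn >= 2 * M and n_rejected / n_drawn > _MAX_REJECTION_RATE:
            raise RuntimeError(
                f"proposal rejection rate {n_rejected / n_drawn:.0%} exceeds 50%: "
                "the proposal is grossly misplaced relative to the parameter bounds"
            )
    if n_kept < M:
        raise RuntimeError("could not draw enough in-bounds vectors from the proposal")
    if n_rejected:
        logger.info("rejected %d out-of-bounds draws while sampling %d vectors",
                    n_rejected, M)
    values = np.concatenate(kept)[:M]
    return SampleResult(values=values, n_rejected=n_rejected)


def relpdf(p: Proposal, values: np.ndarray) -> np.ndarray:
    """Proposal density at each vector relative to the density at the center.

    Vectors outside the proposal's support get relPDF 0 (their importance
    ratio is then set to 0 upstream and they are excluded from resampling).
    """
    mask = np.asarray(p.spec.estimated_flags, dtype=bool)
    c = p.center.values[mask]
    log_c = float(np.atleast_1d(p.logpdf(c[None, :]))[0])
    log_v = np.atleast_1d(p.logpdf(np.atleast_2d(values)))
    with np.errstate(over="ignore"):
        out = np.exp(log_v - log_c)
    out[~np.isfinite(log_v)] = 0.0
    return out
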