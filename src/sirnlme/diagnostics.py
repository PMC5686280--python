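"""dOFV-distribution diagnostics.

If a set of m resampled vectors represents the true parameter uncertainty,
the distribution of their dOFV (OFV minus the OFV at the final estimates)
is expected to follow a chi-square distribution with degrees of freedom at
or below the number of estimated parameters.  Everything here quantifies
that picture: empirical dOFV percentile curves, a chi-square reference, a
maximum-likelihood df estimate, a resampling-noise envelope, and the
numeric convergence/underestimation decisions built on them.

The convergence rule is a numeric operationalization of a visual criterion
("the two last resample curves are overlaid up to sampling noise"): the
previous iteration's curve must lie inside the current iteration's noise
envelope at a configurable fraction of percentiles.  The default fraction
(70% over the 5-95 percentile band) is calibrated so that two independent
resamplings of the same weighted sample are accepted in at least 90% of
seeds: quantile curves are strongly correlated across percentiles, so a
single sampling excursion can push a long contiguous run of percentiles
outside a pointwise 95% envelope, and demanding 90% containment rejects
about a quarter of genuinely-equivalent curve pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "DofvCurve",
    "DfEstimate",
    "NoiseEnvelope",
    "estimate_df",
    "dofv_curve",
    "reference_curve",
    "check_underestimation",
    "noise_envelope",
    "check_convergence",
    "temporal_trends",
    "TemporalTrends",
]

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILES = np.arange(1.0, 100.0)


@dataclass(frozen=True)
class DofvCurve:
    """dOFV value at each percentile of a distribution."""

    percentiles: np.ndarray
    dofv: np.ndarray
    source: str  # proposal | resamples | reference

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        d = np.asarray(self.dofv, dtype=float)
        if p.shape != d.shape or p.ndim != 1:
            raise ValueError("percentile grid and values must be equal-length 1-D")
        if np.any(np.diff(d) < -1e-12):
            raise ValueError("dOFV curve must be nondecreasing in percentile")
        object.__setattr__(self, "percentiles", p)
        object.__setattr__(self, "dofv", d)


@dataclass(frozen=True)
class DfEstimate:
    df: float
    normalized_df: float | None
    n: int
    degenerate: bool = False
    n_clipped: int = 0
    n_dropped_zero: int = 0


@dataclass(frozen=True)
class NoiseEnvelope:
    percentiles: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    coverage: float
    n_replicates: int


def estimate_df(
    dofvs: np.ndarray, k_params: int | None = None, min_n: int = 30
) -> DfEstimate:
    """Maximum-likelihood chi-square degrees of freedom of a dOFV sample.

    Fits chi-square(df) — a gamma with shape df/2 and scale 2 — by solving
    the digamma score equation mean(log x) - log 2 = psi(df/2) with 1-D root
    finding.  Negative inputs (possible with Monte-Carlo OFV noise or local
    minima) are clipped to 0 and counted; exact zeros carry no information
    for the log-based score and are dropped from the fit with a count.
    """
    x = np.asarray(dofvs, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} dOFV values, got {x.size}")
    n_clipped = int((x < 0).sum())
    if n_clipped:
        logger.warning("clipped %d negative dOFV values to 0 for df fitting", n_clipped)
        x = np.clip(x, 0.0, None)
    pos = x[x > 0.0]
    n_dropped = int(x.size - pos.size)  # zeros after clipping
    if pos.size == 0:
        return DfEstimate(
            df=0.0,
            normalized_df=0.0 if k_params else None,
            n=int(x.size),
            degenerate=True,
            n_clipped=n_clipped,
            n_dropped_zero=n_dropped,
        )
    target = float(np.mean(np.log(pos))) - np.log(2.0)
    # psi is increasing: bracket the root in shape a = df/2
    lo, hi = 1e-8, 1.0
    while special.digamma(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    a = optimize.brentq(lambda s: special.digamma(s) - target, lo, hi)
    df = 2.0 * float(a)
    degenerate = bool(np.ptp(pos) == 0.0)
    if degenerate:
        logger.warning("dOFV sample has zero variance; df estimate is low-variance")
    return DfEstimate(
        df=df,
        normalized_df=df / k_params if k_params else None,
        n=int(x.size),
        degenerate=degenerate,
        n_clipped=n_clipped,
        n_dropped_zero=n_dropped,
    )


def dofv_curve(
    dofvs: np.ndarray,
    percentile_grid: np.ndarray | None = None,
    source: str = "resamples",
) -> DofvCurve:
    """Empirical dOFV quantiles at the percentile grid (type-7 interpolation)."""
    x = np.asarray(dofvs, dtype=float)
    if x.size == 0:
        raise ValueError("empty dOFV sample")
    grid = DEFAULT_PERCENTILES if percentile_grid is None else np.asarray(percentile_grid)
    return DofvCurve(grid, np.percentile(x, grid), source)


def reference_curve(
    k_params: int, percentile_grid: np.ndarray | None = None
) -> DofvCurve:
    """chi-square(k) quantile curve — the reference a well-calibrated
    uncertainty distribution's dOFV should not exceed."""
    grid = DEFAULT_PERCENTILES if percentile_grid is None else np.asarray(percentile_grid)
    return DofvCurve(grid, stats.chi2.ppf(grid / 100.0, df=k_params), "reference")


def check_underestimation(
    proposal_curve: DofvCurve,
    k_params: int,
    band: tuple[float, float] = (10.0, 90.0),
    fraction: float = 0.5,
    margin: float = 0.05,
) -> bool:
    """Is the proposal's dOFV curve (partly or fully) below the chi-square
    reference?

    True when the proposal curve lies below the chi-square(k) quantile at
    more than ``fraction`` of the percentiles inside ``band`` — the signature
    of an underestimated initial uncertainty, which calls for inflation.
    A percentile only counts as below when the curve sits under the
    reference by more than the relative ``margin``: for a proposal matching
    the reference exactly, each empirical quantile falls below the true one
    with probability one half, and a strict comparison would flag it on a
    coin flip.
    """
    grid = proposal_curve.percentiles
    sel = (grid >= band[0]) & (grid <= band[1])
    ref = stats.chi2.ppf(grid[sel] / 100.0, df=k_params)
    below = proposal_curve.dofv[sel] < (1.0 - margin) * ref
    return bool(below.mean() > fraction)


def noise_envelope(
    dofvs: np.ndarray,
    weights: np.ndarray,
    m: int,
    B: int = 200,
    coverage: float = 0.95,
    seed: int | np.random.Generator = 0,
    percentile_grid: np.ndarray | None = None,
) -> NoiseEnvelope:
    """Resampling-noise band around a dOFV curve.

    Replays the weighted without-replacement resampling ``B`` times with
    distinct child seeds and takes the per-percentile empirical coverage
    interval of the resulting quantile curves.
    """
    if B < 100:
        raise ValueError("need at least 100 replicates for a stable envelope")
    from .sir_engine import _weighted_order  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    grid = DEFAULT_PERCENTILES if percentile_grid is None else np.asarray(percentile_grid)
    dofvs = np.asarray(dofvs, dtype=float)
    w = np.asarray(weights, dtype=float)
    curves = np.empty((B, grid.size))
    for b in range(B):
        order = _weighted_order(w, rng)[:m]
        curves[b] = np.percentile(dofvs[order], grid)
    alpha = (1.0 - coverage) / 2.0
    return NoiseEnvelope(
        percentiles=grid,
        lower=np.quantile(curves, alpha, axis=0),
        upper=np.quantile(curves, 1.0 - alpha, axis=0),
        coverage=coverage,
        n_replicates=B,
    )


def check_convergence(
    curve_current: DofvCurve,
    envelope_current: NoiseEnvelope,
    curve_previous: DofvCurve,
    band: tuple[float, float] = (5.0, 95.0),
    fraction: float = 0.7,
) -> bool:
    """Are two consecutive resample dOFV curves overlaid up to sampling noise?

    True when the previous iteration's curve lies inside the current
    iteration's noise envelope at >= ``fraction`` of the percentiles in
    ``band``.
    """
    if not np.array_equal(curve_current.percentiles, curve_previous.percentiles) or \
            not np.array_equal(curve_current.percentiles, envelope_current.percentiles):
        raise ValueError("percentile grids differ between curves and envelope")
    grid = curve_current.percentiles
    sel = (grid >= band[0]) & (grid <= band[1])
    inside = (
        (curve_previous.dofv[sel] >= envelope_current.lower[sel])
        & (curve_previous.dofv[sel] <= envelope_current.upper[sel])
    )
    return bool(inside.mean() >= fraction)


@dataclass(frozen=True)
class TemporalTrends:
    bin_fractions: np.ndarray  # per-bin fraction of draws from the top IR quintile
    trend_statistic: float     # Mann-Kendall S normalized to [-1, 1]
    p_value: float             # one-sided, for a decreasing trend (smaller of
    #                            the trend test and the first-vs-last bin test)
    depletion_detected: bool


def temporal_trends(
    resample_indices: np.ndarray,
    ir: np.ndarray,
    n_bins: int = 5,
    alpha: float = 0.05,
) -> TemporalTrends:
    """Depletion diagnostic over the (ordered) resampling sequence.

    Splits the resampling order into ``n_bins`` consecutive bins and tracks
    the per-bin fraction of draws coming from the top IR quintile of the
    sampled pool.  Under sequential without-replacement resampling, a
    decreasing fraction means the high-weight region of the proposal is
    being exhausted — the signal that results could still improve with a
    larger sample pool M.  Two one-sided tests are combined (each at
    ``alpha/2``): a Mann-Kendall trend test across bins, which catches
    gradual depletion, and a first-vs-last bin two-proportion test, which
    catches the abrupt exhaustion a few dominant weights produce.
    """
    order = np.asarray(resample_indices)
    ir = np.asarray(ir, dtype=float)
    if order.ndim != 1 or order.size < n_bins:
        raise ValueError("resampling sequence shorter than the number of bins")
    # top quintile by rank (robust to ties in the weights)
    n_top = max(int(np.ceil(ir.size / 5)), 1)
    top = set(np.argsort(ir, kind="stable")[::-1][:n_top].tolist())
    is_high = np.array([i in top for i in order])
    bins = np.array_split(is_high, n_bins)
    fractions = np.array([b.mean() for b in bins])
    s = 0
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            s += np.sign(fractions[j] - fractions[i])
    var_s = n_bins * (n_bins - 1) * (2 * n_bins + 5) / 18.0
    if s < 0:
        z = (s + 1) / np.sqrt(var_s)
    elif s > 0:
        z = (s - 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p_trend = float(stats.norm.cdf(z))  # small when decreasing
    n_pairs = n_bins * (n_bins - 1) / 2.0
    # first-vs-last bin: one-sided two-proportion z-test for a drop
    n1, n2 = bins[0].size, bins[-1].size
    f1, f2 = fractions[0], fractions[-1]
    pooled = (bins[0].sum() + bins[-1].sum()) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    p_drop = float(stats.norm.sf((f1 - f2) / se)) if se > 0 else 1.0
    detected = bool(
        s <= 0 and (p_trend < alpha / 2.0 or p_drop < alpha / 2.0)
    )
    return TemporalTrends(
        bin_fractions=fractions,
        trend_statistic=float(s / n_pairs),
        p_value=min(p_trend, p_drop),
        depletion_detected=detected,
    )
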