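"""Causal-effect estimators for two-sample MR on harmonized instruments.

Every estimator consumes per-variant pairs (γ_j, σ_Xj, Γ_j, σ_Yj) and works
on the per-variant Wald ratios θ̂_j = Γ_j/γ_j with first-order SEs
s_j = σ_Yj/|γ_j|:

* ``ivw_random_effects`` — inverse-variance-weighted mean of the ratios,
  weights w_j = γ_j²/σ_Yj² = s_j⁻², with a *multiplicative* random-effects
  variance inflation floored at 1: SE = (Σw)^{-1/2} · max(1, √(Q/(J−1))).
* ``mr_egger`` — weighted regression of Γ on γ *with* an intercept (weights
  1/σ_Yj², γ re-signed positive first); the intercept estimates average
  directional pleiotropy, the slope the causal effect under InSIDE.
* ``weighted_median`` — weighted median of the ratios; consistent when
  valid instruments carry >50% of the weight.
* ``weighted_mode`` — mode of a kernel-smoothed weighted ratio density;
  consistent when the largest homogeneous cluster of instruments is valid
  (ZEMPA assumption).
* ``contamination_mixture`` — profile likelihood over candidate causal
  effects in a two-component model (valid: θ̂_j ~ N(θ, s_j²); invalid:
  θ̂_j ~ N(0, s_j²+ψ²)); reports a possibly disjoint 95% confidence set.

Inference uses the standard normal reference throughout, the convention for
summary-data MR. All estimators are invariant to re-expressing any subset of
variants for the other allele (simultaneous sign flip of γ_j and Γ_j).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import EstimationError
from .harmonize import HarmonizedVariant, wald_ratios

logger = logging.getLogger("ivmr")

_Z975 = stats.norm.ppf(0.975)
_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


@dataclass
class MREstimate:
    """One method's causal estimate on the log-OR (or outcome-unit) scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    q_stat: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    #: union of 95% intervals (contamination mixture only)
    ci_set: list[tuple[float, float]] | None = None
    exposure_scale: str = "sd"

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


def _ratios(variants: Sequence[HarmonizedVariant], minimum: int, method: str):
    theta, s, kept, excluded = wald_ratios(variants)
    if excluded:
        logger.info("%s: %d variant(s) with γ=0 excluded", method, len(excluded))
    if len(kept) < minimum:
        raise EstimationError(
            f"{method} needs >= {minimum} usable instruments, got {len(kept)}"
        )
    return theta, s, kept


def _two_sided_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def _finish(method, beta, se, j, **kw) -> MREstimate:
    z = beta / se if se > 0 else math.inf * np.sign(beta)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z975 * se),
        ci_high=float(beta + _Z975 * se),
        pval=_two_sided_p(z),
        n_variants=j,
        **kw,
    )


def ivw_random_effects(variants: Sequence[HarmonizedVariant]) -> MREstimate:
    """Random-effects inverse-variance-weighted estimate.

    β = Σ w_j θ̂_j / Σ w_j with w_j = γ_j²/σ_Yj² — equivalent to weighted
    regression of Γ on γ through the origin with weights 1/σ_Yj². The
    fixed-effect SE (Σw)^{-1/2} is inflated by max(1, √(Q/(J−1))) where Q is
    Cochran's Q, the multiplicative random-effects model. A single instrument
    degrades to its Wald ratio (with a warning).
    """
    theta, s, kept = _ratios(variants, 1, "ivw_re")
    j = len(kept)
    if j == 1:
        logger.warning("ivw_re: single instrument; estimate equals its Wald ratio")
        return _finish("ivw_re", theta[0], s[0], 1)
    w = s**-2.0
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - beta) ** 2))
    scale = max(1.0, math.sqrt(q / (j - 1)))
    return _finish("ivw_re", beta, se_fixed * scale, j, q_stat=q)


def ivw_fixed_effects(variants: Sequence[HarmonizedVariant]) -> MREstimate:
    """Fixed-effect IVW (no heterogeneity inflation); mainly diagnostic."""
    theta, s, kept = _ratios(variants, 1, "ivw_fe")
    w = s**-2.0
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - beta) ** 2)) if len(kept) > 1 else None
    return _finish("ivw_fe", beta, se, len(kept), q_stat=q)


def mr_egger(variants: Sequence[HarmonizedVariant]) -> MREstimate:
    """MR-Egger regression: weighted fit of Γ on γ with an intercept.

    Each variant is first re-signed so γ_j > 0 (the fit is not invariant to
    allele coding otherwise). Slope = causal estimate; intercept = average
    directional pleiotropy. Both SEs carry the multiplicative random-effects
    inflation max(1, √(Q_egger/(J−2))).
    """
    _, _, kept = _ratios(variants, 3, "egger")
    gamma = np.array([abs(v.gamma) for v in kept])
    sign = np.array([1.0 if v.gamma > 0 else -1.0 for v in kept])
    big_gamma = sign * np.array([v.Gamma for v in kept])
    se_y = np.array([v.se_y for v in kept])
    j = len(kept)
    if np.ptp(gamma) < 1e-12 * max(1.0, float(np.max(gamma))):
        raise EstimationError(
            "egger: all oriented γ equal; slope and intercept not separable"
        )
    x = sm.add_constant(gamma)
    fit = sm.WLS(big_gamma, x, weights=se_y**-2.0).fit()
    intercept, slope = fit.params
    # fixed-effect covariance = (X'WX)^-1, independent of residual scale
    cov_fixed = np.asarray(fit.normalized_cov_params)
    resid = big_gamma - fit.fittedvalues
    q = float(np.sum(se_y**-2.0 * resid**2))
    scale = max(1.0, math.sqrt(q / (j - 2)))
    se_slope = math.sqrt(cov_fixed[1, 1]) * scale
    se_int = math.sqrt(cov_fixed[0, 0]) * scale
    return _finish(
        "egger",
        slope,
        se_slope,
        j,
        q_stat=q,
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_pval=_two_sided_p(intercept / se_int),
    )


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median.

    Sort ratios ascending, normalize weights to sum 1, compute the midpoint
    cumulative rank S_j = Σ_{k<=j} w_k − w_j/2, then linearly interpolate θ
    against S at 0.5 (clamped to the extreme ratios outside [S_1, S_J]).
    """
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order] / np.sum(w)
    s = np.cumsum(ww) - ww / 2.0
    return float(np.interp(0.5, s, th))


def _bootstrap_se(
    kept: Sequence[HarmonizedVariant],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap SE: resample (γ_j, Γ_j) from normal laws with
    their reported SEs, recompute the point estimate each time."""
    if n_boot <= 0:
        return math.nan
    rng = np.random.default_rng(seed)
    gamma = np.array([v.gamma for v in kept])
    se_x = np.array([v.se_x for v in kept])
    big_gamma = np.array([v.Gamma for v in kept])
    se_y = np.array([v.se_y for v in kept])
    est = np.empty(n_boot)
    for b in range(n_boot):
        g = gamma + se_x * rng.standard_normal(gamma.size)
        gg = big_gamma + se_y * rng.standard_normal(gamma.size)
        ok = g != 0
        theta = gg[ok] / g[ok]
        s = se_y[ok] / np.abs(g[ok])
        est[b] = point_fn(theta, s**-2.0)
    return float(np.std(est, ddof=1))


def weighted_median(
    variants: Sequence[HarmonizedVariant], n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent as long as valid instruments contribute more than half of the
    total inverse-variance weight. ``n_boot=0`` skips the bootstrap and
    returns the point estimate with ``se = NaN``.
    """
    theta, s, kept = _ratios(variants, 3, "weighted_median")
    w = s**-2.0
    beta = _weighted_median(theta, w)
    se = _bootstrap_se(kept, lambda th, wt: _weighted_median(th, wt), n_boot, seed)
    if math.isnan(se):
        return MREstimate(
            "weighted_median", beta, math.nan, math.nan, math.nan, math.nan, len(kept)
        )
    return _finish("weighted_median", beta, se, len(kept))


def _weighted_mode(
    theta: np.ndarray, w: np.ndarray, bandwidth_factor: float, grid_size: int = 512
) -> float:
    """Argmax of a Gaussian-kernel weighted density of the ratios.

    Bandwidth = factor · 0.9 · min(SD, MAD/0.6745) · J^{-1/5} (Silverman's
    rule with robust scale). Grid spans the ratios ± 3 bandwidths. Exact
    ties resolve to the smaller candidate (argmax of an ascending grid).
    """
    if theta.size == 1 or np.ptp(theta) == 0:
        return float(theta[0])
    sd = float(np.std(theta, ddof=1))
    mad = float(np.median(np.abs(theta - np.median(theta)))) / 0.6745
    scale = min(sd, mad) if mad > 0 else sd
    h = bandwidth_factor * 0.9 * scale * theta.size ** (-1 / 5)
    if h <= 0:
        return float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    variants: Sequence[HarmonizedVariant],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimator (kernel density argmax) with bootstrap SE.

    If all ratios coincide the density is degenerate and the common ratio is
    returned directly.
    """
    theta, s, kept = _ratios(variants, 3, "weighted_mode")
    w = s**-2.0
    beta = _weighted_mode(theta, w, bandwidth_factor)
    se = _bootstrap_se(
        kept, lambda th, wt: _weighted_mode(th, wt, bandwidth_factor), n_boot, seed
    )
    if math.isnan(se):
        return MREstimate(
            "weighted_mode", beta, math.nan, math.nan, math.nan, math.nan, len(kept)
        )
    return _finish("weighted_mode", beta, se, len(kept))


def contamination_mixture(
    variants: Sequence[HarmonizedVariant],
    psi: float | None = None,
    n_grid: int = 1001,
) -> MREstimate:
    """Contamination-mixture estimator via profile likelihood on a grid.

    For each candidate θ the log-likelihood contribution of variant j is the
    larger of log N(θ̂_j; θ, s_j²) (valid) and log N(θ̂_j; 0, s_j²+ψ²)
    (invalid); the profile likelihood sums the per-variant maxima. The
    estimate is the grid argmax; the 95% confidence set is
    {θ : 2(ℓ_max − ℓ(θ)) <= 3.841} and may be a union of disjoint intervals
    (``ci_set``); ``ci_low``/``ci_high`` bound the interval containing the
    estimate and ``se`` is that interval's width / (2·1.96), a convenience
    normal-scale summary. ψ defaults to 1.5 × SD of the Wald ratios. The
    p-value is the likelihood-ratio test of θ = 0 against χ²₁.
    """
    theta_hat, s, kept = _ratios(variants, 3, "contamination_mixture")
    j = len(kept)
    if psi is None:
        sd = float(np.std(theta_hat, ddof=1))
        psi = 1.5 * sd
    span_lo = float(theta_hat.min() - 2 * s.max())
    span_hi = float(theta_hat.max() + 2 * s.max())

    def loglik(grid: np.ndarray) -> np.ndarray:
        valid = stats.norm.logpdf(theta_hat[None, :], loc=grid[:, None], scale=s[None, :])
        if psi > 0:
            invalid = stats.norm.logpdf(
                theta_hat, loc=0.0, scale=np.sqrt(s**2 + psi**2)
            )
            contrib = np.maximum(valid, invalid[None, :])
        else:
            contrib = valid
        return contrib.sum(axis=1)

    if span_hi <= span_lo or not np.isfinite(span_hi - span_lo):
        beta = float(theta_hat[0])
        return MREstimate(
            "contamination_mixture", beta, 0.0, beta, beta, math.nan, j,
            ci_set=[(beta, beta)],
        )

    grid = np.linspace(span_lo, span_hi, max(n_grid, 1000))
    ll = loglik(grid)
    i_max = int(np.argmax(ll))
    beta = float(grid[i_max])
    l_max = float(ll[i_max])
    inside = 2 * (l_max - ll) <= _CHI2_95_1DF
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    own = next((iv for iv in intervals if iv[0] <= beta <= iv[1]), intervals[0])
    se = (own[1] - own[0]) / (2 * _Z975)
    l0 = float(loglik(np.array([0.0]))[0])
    pval = float(stats.chi2.sf(2 * (l_max - l0), 1))
    if len(intervals) > 1:
        logger.info(
            "contamination_mixture: confidence set has %d disjoint intervals",
            len(intervals),
        )
    return MREstimate(
        "contamination_mixture",
        beta,
        float(se),
        own[0],
        own[1],
        pval,
        j,
        ci_set=intervals,
    )


def cochran_q(
    variants: Sequence[HarmonizedVariant], beta: float, df_reduction: int = 1
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic about a given causal estimate.

    Q = Σ w_j (θ̂_j − β)² with IVW weights; df = J − df_reduction (1 for
    IVW, 2 for Egger); p from the chi-square reference.
    """
    theta, s, kept = _ratios(variants, 2, "cochran_q")
    w = s**-2.0
    q = float(np.sum(w * (theta - beta) ** 2))
    df = len(kept) - df_reduction
    p = float(stats.chi2.sf(q, df)) if df > 0 else math.nan
    return q, df, p


#: method label -> (callable, minimum number of instruments)
METHOD_REGISTRY = {
    "ivw_re": (ivw_random_effects, 1),
    "egger": (mr_egger, 3),
    "weighted_median": (weighted_median, 3),
    "weighted_mode": (weighted_mode, 3),
    "contamination_mixture": (contamination_mixture, 3),
}
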