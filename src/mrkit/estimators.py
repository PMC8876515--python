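"""Causal-effect estimators for harmonized two-sample summary data.

Implements the inverse-variance-weighted (IVW) combination of per-SNP
Wald ratios, the interpolated weighted-median estimator with parametric
bootstrap standard errors, and MR-Egger weighted regression with an
unconstrained intercept.  All estimates are log odds ratios per SD of
the exposure; :func:`to_odds_ratio` exponentiates.

Conventions: weights are first-order (outcome variance only); standard
errors for IVW/Egger under the random-effects model use multiplicative
inflation floored at 1; p-values are two-sided normal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from mrkit.summary_io import InstrumentSet

__all__ = [
    "RatioEstimate",
    "MrEstimate",
    "EggerResult",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "mr_egger",
    "to_odds_ratio",
    "Z95",
]

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: outcome beta over exposure beta."""

    snp_id: str
    theta: float
    se: float

    @property
    def weight(self) -> float:
        return self.se ** -2


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate on the log-OR scale with its OR transform."""

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "theta": self.theta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus the directional-pleiotropy intercept."""

    slope: MrEstimate
    intercept: float
    intercept_se: float
    intercept_pval: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope.to_dict(),
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
        }


def _estimate(method: str, theta: float, se: float, n_snps: int) -> MrEstimate:
    lo, hi = theta - Z95 * se, theta + Z95 * se
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(theta) / se))) if se > 0 else 1.0
    if se == 0:
        pval = 0.0 if theta != 0 else 1.0
    return MrEstimate(
        method=method, theta=float(theta), se=float(se),
        ci_low=float(lo), ci_high=float(hi), pval=max(pval, np.finfo(float).tiny),
        n_snps=n_snps,
        odds_ratio=float(np.exp(theta)),
        or_ci_low=float(np.exp(lo)), or_ci_high=float(np.exp(hi)),
    )


def wald_ratios(instruments: InstrumentSet) -> list[RatioEstimate]:
    """Per-SNP causal ratios with first-order delta-method SEs.

    theta_j = beta_outcome / beta_exposure; se_j = se_outcome / |beta_exposure|.
    """
    bx, _, by, sy = instruments.arrays()
    zero = np.flatnonzero(bx == 0.0)
    if zero.size:
        bad = [instruments.snp_ids[i] for i in zero]
        raise ValueError(f"exposure beta is zero for {bad}; Wald ratio undefined")
    theta = by / bx
    se = sy / np.abs(bx)
    return [
        RatioEstimate(snp_id=s, theta=float(t), se=float(e))
        for s, t, e in zip(instruments.snp_ids, theta, se)
    ]


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Return (theta, fixed-effect se, Cochran Q) for the IVW combination."""
    w = (bx / sy) ** 2
    theta_j = by / bx
    sw = w.sum()
    theta = float((w * theta_j).sum() / sw)
    se_fixed = float(sw ** -0.5)
    q = float((w * (theta_j - theta) ** 2).sum())
    return theta, se_fixed, q


def ivw(instruments: InstrumentSet, model: str = "random") -> MrEstimate:
    """Inverse-variance-weighted combination of Wald ratios.

    Equivalent to weighted least squares of outcome on exposure betas
    through the origin with inverse outcome-variance weights.  The point
    estimate is identical under both models; ``model="random"``
    multiplies the SE by ``max(1, sqrt(Q/(J-1)))``.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    if len(instruments) < 2:
        raise ValueError(
            "IVW needs >= 2 instruments; use wald_ratios() for a single SNP"
        )
    bx, _, by, sy = instruments.arrays()
    if np.any(bx == 0.0):
        raise ValueError("exposure beta of zero; remove the SNP upstream")
    theta, se, q = _ivw_core(bx, by, sy)
    if model == "random":
        se *= max(1.0, np.sqrt(q / (len(instruments) - 1)))
    return _estimate(f"ivw_{model}", theta, se, len(instruments))


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    """Interpolated 50th weighted percentile of ordered ratios."""
    order = np.argsort(theta_j, kind="stable")
    t = theta_j[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / ww.sum()
    return float(np.interp(0.5, s, t))


def _weighted_median_points(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted medians for (R, J) matrices of ratios and weights."""
    order = np.argsort(theta, axis=1, kind="stable")
    t = np.take_along_axis(theta, order, axis=1)
    ww = np.take_along_axis(w, order, axis=1)
    s = (np.cumsum(ww, axis=1) - 0.5 * ww) / ww.sum(axis=1, keepdims=True)
    out = np.empty(theta.shape[0])
    for i in range(theta.shape[0]):
        out[i] = np.interp(0.5, s[i], t[i])
    return out


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 2000,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The point estimate is the linear interpolation of ordered Wald
    ratios against standardized cumulative weights at 0.5.  The SE is
    the standard deviation of the point estimate over ``n_boot``
    replicates drawing ``beta* ~ Normal(beta_hat, se)`` in both samples.
    Ordering ties are broken by snp_id for determinism.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    tab = instruments.table.sort_values("snp_id", kind="stable")
    bx = tab["beta_exposure"].to_numpy(float)
    sx = tab["se_exposure"].to_numpy(float)
    by = tab["beta_outcome"].to_numpy(float)
    sy = tab["se_outcome"].to_numpy(float)
    if np.any(bx == 0.0):
        raise ValueError("exposure beta of zero; remove the SNP upstream")

    theta_j = by / bx
    w = (bx / sy) ** 2
    theta = _weighted_median_point(theta_j, w)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, bx.size))
    by_star = rng.normal(by, sy, size=(n_boot, by.size))
    bx_star = np.where(bx_star == 0.0, np.finfo(float).tiny, bx_star)
    theta_star = by_star / bx_star
    w_star = (bx_star / sy) ** 2
    boots = _weighted_median_points(theta_star, w_star)
    se = float(np.std(boots, ddof=1))
    est = _estimate("weighted_median", theta, se, len(instruments))
    if n_boot < 100:
        est = replace(est, method="weighted_median[low_n_boot]")
    return est


def mr_egger(instruments: InstrumentSet) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Instruments are first oriented so every exposure beta is positive
    (negating both betas where needed).  Weights are inverse outcome
    variances; both SEs carry multiplicative random-effects inflation
    ``max(1, sqrt(RSS/(J-2)))``.
    """
    if len(instruments) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    bx, _, by, sy = instruments.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx = bx * flip
    by = by * flip
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure betas identical after orientation; "
                         "Egger design matrix is collinear")

    w = sy ** -2.0
    X = np.column_stack([np.ones_like(bx), bx])
    xtw = X.T * w
    cov_unscaled = np.linalg.inv(xtw @ X)
    coef = cov_unscaled @ (xtw @ by)
    resid = by - X @ coef
    rss = float((w * resid ** 2).sum())
    j = len(instruments)
    sigma = max(1.0, np.sqrt(rss / (j - 2)))
    se = np.sqrt(np.diag(cov_unscaled)) * sigma

    slope = _estimate("egger_slope", coef[1], se[1], j)
    icp_p = float(min(1.0, 2.0 * stats.norm.sf(abs(coef[0]) / se[0]))) if se[0] > 0 else 1.0
    return EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_pval=max(icp_p, np.finfo(float).tiny),
    )


def to_odds_ratio(estimate: MrEstimate) -> MrEstimate:
    """Re-derive the OR fields from the log-OR fields (idempotent)."""
    return replace(
        estimate,
        odds_ratio=float(np.exp(estimate.theta)),
        or_ci_low=float(np.exp(estimate.ci_low)),
        or_ci_high=float(np.exp(estimate.ci_high)),
    )
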