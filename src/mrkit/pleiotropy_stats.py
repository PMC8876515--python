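"""Stage-2 pleiotropy diagnostics.

Cochran's Q heterogeneity test with the I-squared index and its
test-based (Higgins-Thompson) confidence interval, and the residual-sum
resampling global / outlier / distortion tests (MR-PRESSO style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mrkit.summary_io import InstrumentSet

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "mr_presso",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with I-squared (percent) and its 95% CI."""

    q: float
    df: int
    pval: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float

    def to_dict(self) -> dict:
        return {
            "Q": self.q, "df": self.df, "pval": self.pval,
            "I2_percent": self.i2,
            "I2_ci_low_percent": self.i2_ci_low,
            "I2_ci_high_percent": self.i2_ci_high,
        }


@dataclass(frozen=True)
class PressoResult:
    """Global, per-SNP outlier, and distortion resampling tests.

    ``distortion_pval`` is ``None`` when no outliers were flagged — the
    test is then not defined, and its absence is explicit.
    """

    global_rss: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outliers: list[str]
    distortion_pval: float | None
    n_sim: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "global_rss": self.global_rss,
            "global_pval": self.global_pval,
            "per_snp_pvals": dict(self.per_snp_pvals),
            "outliers": list(self.outliers),
            "distortion_pval": self.distortion_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _h_to_i2(h2: float) -> float:
    """Map H^2 = Q/df to I-squared percent, truncated to [0, 100]."""
    if h2 <= 1.0:
        return 0.0
    return float(min(100.0, (1.0 - 1.0 / h2) * 100.0))


def cochran_q(instruments: InstrumentSet) -> HeterogeneityResult:
    """Cochran's Q across per-SNP Wald ratios about the fixed-effect IVW.

    I-squared is ``max(0, (Q - df)/Q) * 100``; its 95% CI uses the
    test-based method for ln H (H = sqrt(Q/df)), back-transformed and
    truncated to [0, 100].
    """
    j = len(instruments)
    if j < 2:
        raise ValueError("Cochran's Q needs >= 2 instruments")
    bx, _, by, sy = instruments.arrays()
    w = (bx / sy) ** 2
    theta_j = by / bx
    theta = (w * theta_j).sum() / w.sum()
    q = float((w * (theta_j - theta) ** 2).sum())
    df = j - 1
    pval = float(stats.chi2.sf(q, df))

    i2 = _h_to_i2(q / df) if q > 0 else 0.0

    # test-based SE of ln H (Higgins & Thompson 2002)
    if q > j:
        se_ln_h = 0.5 * (np.log(q) - np.log(df)) / (np.sqrt(2 * q) - np.sqrt(2 * j - 3))
    elif j > 2:
        se_ln_h = np.sqrt(1.0 / (2 * (j - 2)) * (1.0 - 1.0 / (3 * (j - 2) ** 2)))
    else:
        se_ln_h = np.inf
    ln_h = 0.5 * np.log(max(q, np.finfo(float).tiny) / df)
    z = stats.norm.ppf(0.975)
    h2_lo = float(np.exp(2 * (ln_h - z * se_ln_h)))
    h2_hi = float(np.exp(2 * (ln_h + z * se_ln_h)))
    ci_lo, ci_hi = _h_to_i2(h2_lo), _h_to_i2(h2_hi)
    ci_lo = min(ci_lo, i2)
    ci_hi = max(ci_hi, i2)
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2,
                               i2_ci_low=ci_lo, i2_ci_high=ci_hi)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes (origin-constrained WLS), vectorized.

    Works on 1-D arrays or (R, J) matrices along the last axis.
    """
    s1 = (w * bx * by).sum(axis=-1, keepdims=True)
    s2 = (w * bx * bx).sum(axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Residual-sum resampling test for horizontally pleiotropic outliers.

    The observed statistic is the weighted residual sum of squares of
    each outcome beta about its leave-one-out IVW prediction.  The null
    distribution is built by redrawing both betas from their sampling
    distributions (outcome betas centred on the leave-one-out
    predictions) and recomputing the statistic ``n_sim`` times.  Per-SNP
    outlier p-values come from each SNP's simulated residual
    distribution, Bonferroni-corrected by the instrument count; the
    distortion test compares the post-removal change in the IVW estimate
    against removals of random subsets of the same size.
    """
    j = len(instruments)
    if j < 4:
        raise ValueError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")
    bx, sx, by, sy = instruments.arrays()
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("degenerate zero standard error in instrument set")

    w = sy ** -2.0
    loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - bx * loo) ** 2
    rss_obs = float(resid_obs.sum())

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(bx * loo, sy, size=(n_sim, j))
    loo_star = _loo_slopes(bx_star, by_star, w)
    resid_star = w * (by_star - bx_star * loo_star) ** 2
    rss_star = resid_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))

    per_snp_raw = (1 + np.sum(resid_star >= resid_obs, axis=0)) / (n_sim + 1)
    per_snp = np.minimum(1.0, per_snp_raw * j)
    ids = instruments.snp_ids
    per_snp_pvals = {s: float(p) for s, p in zip(ids, per_snp)}
    outliers = [s for s, p in zip(ids, per_snp) if p < outlier_alpha]

    distortion_pval: float | None = None
    if outliers:
        mask = ~np.isin(ids, outliers)
        if mask.sum() >= 2:
            theta_all = (w * bx * by).sum() / (w * bx * bx).sum()
            theta_no = ((w * bx * by)[mask].sum() / (w * bx * bx)[mask].sum())
            d_obs = abs(theta_all - theta_no)
            n_out = len(outliers)
            d_null = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(np.flatnonzero(mask), size=n_out, replace=True)
                keep = np.ones(j, bool)
                keep[drop] = False
                theta_b = ((w * bx * by)[keep].sum() / (w * bx * bx)[keep].sum())
                d_null[b] = abs(theta_all - theta_b)
            distortion_pval = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        per_snp_pvals=per_snp_pvals,
        outliers=outliers,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )
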