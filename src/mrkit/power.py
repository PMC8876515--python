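"""Instrument strength (R-squared, F) and binary-outcome power analysis.

R-squared sums ``2 * beta^2 * MAF * (1 - MAF) / var(X)`` over
instruments, folding effect-allele frequencies above 0.5 to minor-allele
frequencies.  Power for a binary outcome uses the noncentral chi-square
approximation with NCP = N * R2 * K(1-K) * (ln OR)^2, evaluated as a
two-sided normal form so power at OR = 1 equals alpha exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerResult",
    "variance_explained",
    "f_statistic",
    "power_binary",
    "detectable_or",
    "power_analysis",
]


@dataclass(frozen=True)
class PowerResult:
    """Instrument strength and power for one odds ratio under test."""

    r2: float
    f_stat: float
    f_convention: str
    ncp: float
    power: float
    odds_ratio: float
    alpha: float
    detectable_or_low: float | None = None
    detectable_or_high: float | None = None
    target_power: float | None = None

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "f_stat": self.f_stat,
            "f_convention": self.f_convention,
            "ncp": self.ncp,
            "power": self.power,
            "odds_ratio": self.odds_ratio,
            "alpha": self.alpha,
            "detectable_or_low": self.detectable_or_low,
            "detectable_or_high": self.detectable_or_high,
            "target_power": self.target_power,
        }


def variance_explained(instruments: pd.DataFrame, var_x: float = 1.0) -> float:
    """Proportion of exposure variance explained by the instruments.

    Expects columns ``beta`` and ``eaf``; frequencies above 0.5 are
    folded to the minor allele.  ``var_x`` is 1 for a standardized
    exposure.
    """
    if var_x <= 0:
        raise ValueError(f"var_x must be > 0, got {var_x}")
    eaf = instruments["eaf"].to_numpy(float)
    beta = instruments["beta"].to_numpy(float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf values must be strictly inside (0,1)")
    maf = np.minimum(eaf, 1.0 - eaf)
    return float((beta ** 2 * 2.0 * maf * (1.0 - maf)).sum() / var_x)


def f_statistic(r2: float, n: int, k: int = 1, convention: str = "mrnd") -> float:
    """First-stage F statistic for instrument strength.

    ``joint``: F = r2 (n - 1 - k) / ((1 - r2) k) for a k-instrument
    regression; ``mrnd``: F = r2 (n - 2) / (1 - r2), the single-degree
    form used by NCP-based power calculators.
    """
    if not (0.0 < r2 < 1.0):
        raise ValueError(f"r2 must be in (0,1), got {r2}")
    if convention == "joint":
        if n <= k + 1:
            raise ValueError(f"need n > k+1, got n={n}, k={k}")
        return float(r2 * (n - 1 - k) / ((1.0 - r2) * k))
    if convention == "mrnd":
        if n <= 2:
            raise ValueError(f"need n > 2, got n={n}")
        return float(r2 * (n - 2) / (1.0 - r2))
    raise ValueError(f"unknown convention {convention!r}")


def _ncp(n: float, r2: float, case_fraction: float, odds_ratio: float) -> float:
    return n * r2 * case_fraction * (1.0 - case_fraction) * np.log(odds_ratio) ** 2


def power_binary(
    n: float,
    r2: float,
    case_fraction: float,
    odds_ratio: float,
    alpha: float = 0.05,
) -> float:
    """Analytic power to detect ``odds_ratio`` with a binary outcome.

    Uses the noncentrality parameter N * R2 * K(1-K) * (ln OR)^2 and the
    two-sided normal form (both tails), so power at OR = 1 is exactly
    alpha and power is symmetric in ln OR.
    """
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must be in [0,1), got {r2}")
    if not (0.0 < case_fraction < 1.0):
        raise ValueError(f"case_fraction must be in (0,1), got {case_fraction}")
    if odds_ratio <= 0:
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    ncp = _ncp(n, r2, case_fraction, odds_ratio)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))


def detectable_or(
    n: float,
    r2: float,
    case_fraction: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Smallest protective and largest harmful OR detectable at ``target_power``.

    Bisects power in ln OR on each side of 1 until the power gap is
    below ``tol``; returns ``(or_low, or_high)`` with
    ``or_low < 1 < or_high``.
    """
    if not (alpha < target_power < 1.0):
        raise ValueError(
            f"target_power must be in (alpha, 1), got {target_power} with alpha={alpha}"
        )

    def gap(log_or: float) -> float:
        return power_binary(n, r2, case_fraction, float(np.exp(log_or)), alpha) - target_power

    hi = 0.1
    for _ in range(200):
        if gap(hi) >= 0:
            break
        hi *= 2.0
        if hi > 700:
            raise RuntimeError(
                f"detectable_or did not bracket target power {target_power} "
                f"(n={n}, r2={r2}, K={case_fraction}): power plateau below target"
            )
    lo = 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if gap(mid) >= 0:
            hi = mid
        else:
            lo = mid
        if abs(gap(0.5 * (lo + hi))) < tol:
            break
    else:
        raise RuntimeError(
            f"detectable_or bisection did not converge to |dpower| < {tol} "
            f"after {max_iter} iterations (last bracket [{lo}, {hi}] in ln OR)"
        )
    log_or = 0.5 * (lo + hi)
    # symmetry of power in ln OR makes the protective bound the reciprocal
    return float(np.exp(-log_or)), float(np.exp(log_or))


def power_analysis(
    n: float,
    r2: float,
    case_fraction: float,
    odds_ratio: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    n_exposure: int | None = None,
    k: int = 1,
    f_convention: str = "mrnd",
) -> PowerResult:
    """Bundle R2/F/NCP/power and detectable-OR bounds into one result."""
    n_for_f = n_exposure if n_exposure is not None else n
    f = f_statistic(r2, int(n_for_f), k=k, convention=f_convention)
    ncp = _ncp(n, r2, case_fraction, odds_ratio)
    pw = power_binary(n, r2, case_fraction, odds_ratio, alpha)
    or_lo, or_hi = detectable_or(n, r2, case_fraction, target_power, alpha)
    return PowerResult(
        r2=r2, f_stat=f, f_convention=f_convention, ncp=float(ncp), power=pw,
        odds_ratio=odds_ratio, alpha=alpha,
        detectable_or_low=or_lo, detectable_or_high=or_hi,
        target_power=target_power,
    )
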