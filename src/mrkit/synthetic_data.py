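"""Synthetic paired GWAS summary statistics with known causal truth.

Generates exposure / outcome / confounder summary tables in the same
TSV schema the I/O layer reads, with a configurable causal effect,
horizontal-pleiotropy regime, and planted confounder associations, so
every pipeline stage can be exercised without external downloads.

The exposure is standardized (var(X) = 1) so simulated betas are per-SD;
outcome standard errors use the case-control approximation
``1 / sqrt(2 N K (1-K) m (1-m))`` consistent with the power module's
noncentrality parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from mrkit import estimators
from mrkit.summary_io import InstrumentSet, harmonize

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "operating_characteristics",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violated")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one simulated two-sample MR dataset."""

    j: int = 100
    n_exposure: int = 400_000
    n_outcome: int = 30_000
    case_fraction: float = 0.35
    theta_true: float = 0.0
    r2_target: float = 0.015
    pleiotropy_mode: str = "none"
    mu_alpha: float = 0.0
    tau_alpha: float = 0.0
    invalid_fraction: float = 0.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    confounder_traits: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ValueError(f"j must be >= 1, got {self.j}")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case_fraction must be in (0,1), got {self.case_fraction}")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError(f"invalid_fraction must be in [0,1], got {self.invalid_fraction}")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"eaf_range must be inside (0,1), got {self.eaf_range}")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}, got {self.pleiotropy_mode!r}"
            )
        if not (0.0 < self.r2_target < 1.0):
            raise ValueError(f"r2_target must be in (0,1), got {self.r2_target}")


@dataclass(frozen=True)
class SimulationTruth:
    """The generating parameters behind one simulated dataset."""

    gamma: np.ndarray
    alpha: np.ndarray
    theta_true: float
    confounder_associated: dict[str, list[str]]
    snp_ids: list[str]


def _summary_frame(snp_ids, eaf, beta, se, n) -> pd.DataFrame:
    z = np.abs(beta / se)
    pval = np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": eaf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": n,
    })


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], SimulationTruth]:
    """Draw one paired exposure/outcome/confounder dataset.

    True per-SD exposure effects are scaled so the instruments jointly
    explain ``r2_target`` of the (unit) exposure variance; estimated
    betas are drawn around the truth with the frequency-based standard
    errors; outcome betas are ``theta_true * gamma + alpha`` with direct
    effects per ``pleiotropy_mode``.  The same seed yields byte-identical
    tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    j = cfg.j
    snp_ids = [f"rs{900000 + i}" for i in range(j)]

    eaf = rng.uniform(*cfg.eaf_range, size=j)
    maf = np.minimum(eaf, 1.0 - eaf)
    het = 2.0 * maf * (1.0 - maf)

    # raw effect shapes, then scale to hit the target variance explained
    gamma_raw = rng.normal(0.02, 0.008, size=j)
    gamma_raw = np.where(np.abs(gamma_raw) < 1e-4, 1e-4, gamma_raw)
    raw_r2 = float((gamma_raw ** 2 * het).sum())
    scale = np.sqrt(cfg.r2_target / raw_r2)
    gamma = gamma_raw * scale
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"target R2 {cfg.r2_target} infeasible for J={j}, eaf_range={cfg.eaf_range}")

    n_invalid = int(round(cfg.invalid_fraction * j))
    invalid = np.zeros(j, bool)
    invalid[rng.choice(j, size=n_invalid, replace=False)] = True
    alpha = np.zeros(j)
    if cfg.pleiotropy_mode == "balanced":
        alpha[invalid] = rng.normal(0.0, cfg.tau_alpha, size=n_invalid)
    elif cfg.pleiotropy_mode == "directional":
        alpha[invalid] = rng.normal(cfg.mu_alpha, cfg.tau_alpha, size=n_invalid)
    elif cfg.pleiotropy_mode == "inside_violated":
        noise = rng.normal(0.0, cfg.tau_alpha, size=n_invalid)
        alpha[invalid] = cfg.mu_alpha + 0.5 * gamma[invalid] + noise

    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * maf * (1.0 - maf))
    beta_x = rng.normal(gamma, se_x)
    k = cfg.case_fraction
    se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * k * (1.0 - k) * maf * (1.0 - maf))
    gamma_y = cfg.theta_true * gamma + alpha
    beta_y = rng.normal(gamma_y, se_y)

    exposure = _summary_frame(snp_ids, eaf, beta_x, se_x, cfg.n_exposure)
    outcome = _summary_frame(snp_ids, eaf, beta_y, se_y, cfg.n_outcome)

    confounders: dict[str, pd.DataFrame] = {}
    associated: dict[str, list[str]] = {}
    for trait, frac in cfg.confounder_traits.items():
        n_assoc = int(round(frac * j))
        idx = rng.choice(j, size=n_assoc, replace=False)
        pvals = rng.uniform(0.0, 1.0, size=j)
        pvals[idx] = 10.0 ** (-rng.uniform(5.0, 12.0, size=n_assoc))
        se_c = np.full(j, 0.01)
        z = stats.norm.isf(pvals / 2.0)
        beta_c = z * se_c * rng.choice([-1.0, 1.0], size=j)
        confounders[trait] = _summary_frame(snp_ids, eaf, beta_c, se_c, cfg.n_exposure)
        # recompute pvals column to exactly the planted values
        confounders[trait]["pval"] = pvals
        associated[trait] = [snp_ids[i] for i in sorted(idx)]

    truth = SimulationTruth(
        gamma=gamma, alpha=alpha, theta_true=cfg.theta_true,
        confounder_associated=associated, snp_ids=snp_ids,
    )
    return exposure, outcome, confounders, truth


def _dataset_instruments(exposure: pd.DataFrame, outcome: pd.DataFrame) -> InstrumentSet:
    return harmonize(exposure, outcome)


def operating_characteristics(
    config: SimulationConfig,
    n_reps: int = 100,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo bias / SE / coverage / rejection per estimator.

    Runs ``n_reps`` independent datasets (seeds spawned from
    ``config.seed``) and summarises each estimator's mean bias about
    ``theta_true``, empirical SE of the point estimate, 95% CI coverage,
    and rejection rate of theta = 0 at the 0.05 level.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * n_reps)
    methods = ("ivw_random", "weighted_median", "egger_slope")
    est: dict[str, list] = {m: [] for m in methods}
    cover: dict[str, list] = {m: [] for m in methods}
    reject: dict[str, list] = {m: [] for m in methods}

    for r in range(n_reps):
        cfg = replace(config, seed=int(seeds[2 * r]))
        exposure, outcome, _, truth = simulate_dataset(cfg)
        inst = _dataset_instruments(exposure, outcome)
        results = {
            "ivw_random": estimators.ivw(inst, model="random"),
            "weighted_median": estimators.weighted_median(
                inst, n_boot=n_boot, seed=int(seeds[2 * r + 1])
            ),
            "egger_slope": estimators.mr_egger(inst).slope,
        }
        for m, e in results.items():
            est[m].append(e.theta)
            cover[m].append(e.ci_low <= truth.theta_true <= e.ci_high)
            reject[m].append(e.pval < 0.05)

    rows = []
    for m in methods:
        vals = np.asarray(est[m])
        rows.append({
            "method": m,
            "n_reps": n_reps,
            "theta_true": config.theta_true,
            "mean_bias": float(vals.mean() - config.theta_true),
            "empirical_se": float(vals.std(ddof=1)),
            "coverage_95": float(np.mean(cover[m])),
            "rejection_rate_05": float(np.mean(reject[m])),
            "seed": config.seed,
        })
    return pd.DataFrame(rows)
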