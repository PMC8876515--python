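"""End-to-end analysis pipeline.

Runs read -> genome-wide filter -> harmonize -> confounder screen ->
heterogeneity / Egger-intercept / residual-resampling diagnostics ->
IVW + weighted-median + Egger estimates -> OR conversion -> instrument
strength and power, and assembles a deterministic machine-readable
report in which every input SNP is accounted for as retained or removed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import mrkit
from mrkit import estimators, instrument_filter, pleiotropy_stats, power as power_mod
from mrkit.estimators import EggerResult, MrEstimate
from mrkit.summary_io import InstrumentSet, harmonize, read_summary_stats

__all__ = ["PipelineStageError", "run_pipeline", "scatter_data", "load_config", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "thresholds": {
        "genome_wide": 5e-8,
        "screen_alpha": 0.05,
        "screen_m": None,          # default: pre-screen instrument count
        "palindromic_eaf_window": 0.08,
    },
    "confounder_screen": True,
    "estimators": {"n_boot": 2000},
    "presso": {"n_sim": 1000, "outlier_alpha": 0.05},
    "power": {
        "alpha": 0.05,
        "target_power": 0.80,
        "case_fraction": None,
        "n_outcome": None,
        "odds_ratio": None,        # default: the IVW odds ratio
    },
    "seed": None,
}


class PipelineStageError(RuntimeError):
    """An analysis stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def _merge(defaults: Mapping, overrides: Mapping) -> dict:
    out = dict(defaults)
    for k, v in overrides.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON pipeline configuration, filling in defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, cfg)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: Mapping[str, Any] | str | Path) -> dict:
    """Execute the full analysis and return the report as a dict.

    ``config`` is a mapping (or a path to a YAML file) naming the
    exposure and outcome tables, optional per-trait confounder tables,
    thresholds, and seeds.  Any stage failure raises
    :class:`PipelineStageError`; no partial report is produced.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(DEFAULTS, config)

    th = cfg["thresholds"]
    seed = cfg.get("seed")

    exposure = _stage("read_exposure")(read_summary_stats)(cfg["exposure"])
    outcome = _stage("read_outcome")(read_summary_stats)(cfg["outcome"])
    confounders = {
        trait: _stage(f"read_confounder:{trait}")(read_summary_stats)(path)
        for trait, path in (cfg.get("confounders") or {}).items()
    }

    exposure_sig, gw_event = _stage("genome_wide_filter")(
        instrument_filter.genome_wide_filter
    )(exposure, threshold=th["genome_wide"])

    instruments: InstrumentSet = _stage("harmonize")(harmonize)(
        exposure_sig, outcome, palindromic_eaf_window=th["palindromic_eaf_window"]
    )
    instruments.provenance.insert(0, gw_event)
    instruments.initial_size = len(exposure)
    instruments._check()

    screen_block: dict | None = None
    if cfg["confounder_screen"] and confounders:
        screen = _stage("confounder_screen")(instrument_filter.confounder_screen)(
            instruments, confounders, alpha=th["screen_alpha"], m=th["screen_m"]
        )
        instruments = _stage("apply_exclusions")(instrument_filter.apply_exclusions)(
            instruments, screen
        )
        screen_block = screen.to_dict()

    het = _stage("cochran_q")(pleiotropy_stats.cochran_q)(instruments)
    egger: EggerResult = _stage("mr_egger")(estimators.mr_egger)(instruments)
    presso = _stage("mr_presso")(pleiotropy_stats.mr_presso)(
        instruments,
        n_sim=cfg["presso"]["n_sim"],
        seed=seed,
        outlier_alpha=cfg["presso"]["outlier_alpha"],
    )

    ivw_fixed = _stage("ivw")(estimators.ivw)(instruments, model="fixed")
    ivw_random = _stage("ivw")(estimators.ivw)(instruments, model="random")
    wm = _stage("weighted_median")(estimators.weighted_median)(
        instruments, n_boot=cfg["estimators"]["n_boot"], seed=seed
    )

    pw_cfg = cfg["power"]
    power_block: dict | None = None
    if pw_cfg["case_fraction"] is not None:
        n_outcome = pw_cfg["n_outcome"]
        if n_outcome is None and "n" in outcome.columns:
            n_outcome = float(outcome["n"].median())
        if n_outcome is not None:
            r2 = _stage("power")(power_mod.variance_explained)(
                instruments.table.rename(
                    columns={"beta_exposure": "beta"}
                )[["beta", "eaf"]]
            )
            or_test = pw_cfg["odds_ratio"] or ivw_random.odds_ratio
            n_exposure = float(exposure["n"].median()) if "n" in exposure.columns else None
            result = _stage("power")(power_mod.power_analysis)(
                n=n_outcome, r2=r2, case_fraction=pw_cfg["case_fraction"],
                odds_ratio=or_test, alpha=pw_cfg["alpha"],
                target_power=pw_cfg["target_power"],
                n_exposure=int(n_exposure) if n_exposure else None,
                k=len(instruments),
            )
            power_block = result.to_dict()

    report = {
        "tool": {"name": "mrkit", "version": mrkit.__version__},
        "seed": seed,
        "inputs": {
            "exposure": {"path": str(cfg["exposure"]), "n_rows": int(len(exposure))},
            "outcome": {"path": str(cfg["outcome"]), "n_rows": int(len(outcome))},
            "confounders": {
                t: {"path": str(p), "n_rows": int(len(confounders[t]))}
                for t, p in (cfg.get("confounders") or {}).items()
            },
        },
        "filters": instruments.provenance_dict(),
        "n_instruments": len(instruments),
        "retained_snps": instruments.snp_ids,
        "confounder_screen": screen_block,
        "heterogeneity": het.to_dict(),
        "egger_intercept": {
            "estimate": egger.intercept,
            "se": egger.intercept_se,
            "pval": egger.intercept_pval,
        },
        "presso": presso.to_dict(),
        "estimates": {
            "ivw_fixed": ivw_fixed.to_dict(),
            "ivw_random": ivw_random.to_dict(),
            "weighted_median": wm.to_dict(),
            "egger": egger.slope.to_dict(),
        },
        "power": power_block,
    }

    # every input SNP accounted for: retained or removed with reason
    removed = sum(len(f["removed"]) for f in report["filters"])
    assert removed + len(instruments) == len(exposure), "provenance does not reconcile"
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Serialize the report deterministically (sorted keys, fixed layout)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def scatter_data(
    instruments: InstrumentSet,
    mr_estimates: list[MrEstimate],
    egger: EggerResult | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-SNP effect scatter plus fitted lines for each estimator.

    Returns ``(points, lines)``: points holds one row per instrument
    (exposure/outcome betas and SEs), lines holds slope and intercept
    per method (the Egger line carries its intercept; others pass
    through the origin).
    """
    if len(instruments) == 0:
        raise ValueError("cannot build scatter data from an empty instrument set")
    points = instruments.table[
        ["snp_id", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome"]
    ].copy()
    rows = [
        {"method": est.method, "slope": est.theta, "intercept": 0.0}
        for est in mr_estimates
    ]
    if egger is not None:
        rows.append({
            "method": "egger", "slope": egger.slope.theta, "intercept": egger.intercept,
        })
    return points, pd.DataFrame(rows, columns=["method", "slope", "intercept"])
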