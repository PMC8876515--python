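"""Stage-1 instrument filtering.

Genome-wide-significance selection of exposure instruments and the
Bonferroni-corrected confounder screen that removes candidate
instruments associated with any known confounder trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from mrkit.summary_io import FilterEvent, InstrumentSet

__all__ = [
    "ConfounderScreen",
    "bonferroni_threshold",
    "genome_wide_filter",
    "confounder_screen",
    "apply_exclusions",
]

GENOME_WIDE_SIGNIFICANCE = 5e-8


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level controlling the family-wise rate at ``alpha``.

    >>> round(bonferroni_threshold(0.05, 162), 7)
    3.086e-04
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def genome_wide_filter(
    table: pd.DataFrame,
    threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> tuple[pd.DataFrame, FilterEvent]:
    """Retain exposure associations with ``pval < threshold``.

    Returns the filtered table and a provenance event listing removals.
    """
    mask = table["pval"] < threshold
    removed = tuple(table.loc[~mask, "snp_id"])
    event = FilterEvent("genome_wide_significance", removed, threshold=threshold)
    return table.loc[mask].reset_index(drop=True), event


@dataclass
class ConfounderScreen:
    """Result of screening instruments against confounder GWAS tables."""

    traits: list[str]
    threshold: float
    excluded: set[str]
    per_trait_counts: dict[str, int]
    untested: dict[str, list[str]] = field(default_factory=dict)
    m: int | None = None

    def __post_init__(self) -> None:
        for trait, count in self.per_trait_counts.items():
            if count < 0 or count > len(self.excluded):
                raise ValueError(
                    f"per-trait count for {trait} ({count}) inconsistent with "
                    f"{len(self.excluded)} total exclusions"
                )

    def to_dict(self) -> dict:
        return {
            "traits": self.traits,
            "threshold": self.threshold,
            "m": self.m,
            "n_excluded": len(self.excluded),
            "excluded": sorted(self.excluded),
            "per_trait_counts": dict(self.per_trait_counts),
            "untested": {t: sorted(v) for t, v in self.untested.items()},
        }


def confounder_screen(
    instruments: InstrumentSet,
    confounders: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    m: int | None = None,
) -> ConfounderScreen:
    """Flag instruments associated with any confounder trait.

    A SNP is excluded when its p-value with ANY confounder is below
    ``bonferroni_threshold(alpha, m)``.  ``m`` defaults to the pre-screen
    instrument count.  SNPs absent from a confounder table cannot be
    tested for that trait and are logged as untested, never excluded on
    that basis.
    """
    if not confounders:
        raise ValueError(
            "empty confounder map: the screen would be vacuous; "
            "disable the screen explicitly instead"
        )
    if m is None:
        m = len(instruments)
    threshold = bonferroni_threshold(alpha, m)

    snp_ids = instruments.snp_ids
    excluded: set[str] = set()
    per_trait: dict[str, int] = {}
    untested: dict[str, list[str]] = {}
    for trait, table in confounders.items():
        pvals = dict(zip(table["snp_id"], table["pval"]))
        hits = [s for s in snp_ids if s in pvals and pvals[s] < threshold]
        missing = [s for s in snp_ids if s not in pvals]
        per_trait[trait] = len(hits)
        if missing:
            untested[trait] = missing
        excluded.update(hits)

    return ConfounderScreen(
        traits=list(confounders),
        threshold=threshold,
        excluded=excluded,
        per_trait_counts=per_trait,
        untested=untested,
        m=m,
    )


def apply_exclusions(instruments: InstrumentSet, screen: ConfounderScreen) -> InstrumentSet:
    """Remove screened-out SNPs, appending a provenance event.

    Raises ``KeyError`` if the screen references SNPs that are not in the
    instrument set (it must have been built from the same list).
    """
    return instruments.removed_filter(
        screen.excluded, "confounder_screen", threshold=screen.threshold
    )
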