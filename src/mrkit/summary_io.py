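"""Reading, validation, and allele harmonization of GWAS summary statistics.

The canonical on-disk format is a tab- (or comma-) separated table with a
header row and columns ``snp_id effect_allele other_allele eaf beta se
pval [n]``.  Foreign headers are supported through a column-name mapping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantAssociation",
    "HarmonizedInstrument",
    "InstrumentSet",
    "FilterEvent",
    "SummaryStatsError",
    "RowValidationError",
    "read_summary_stats",
    "write_summary_stats",
    "validate_table",
    "harmonize",
    "load_table1_fixture",
    "TABLE1_FIXTURE_SHA256",
]

MANDATORY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("n",)

#: frozen digest of the packaged instrument fixture (162 rows)
TABLE1_FIXTURE_SHA256 = "a5aa6be0a17438ca131ad213bab905c6ee3d38d101d6c6b4bf45b0891b5e4538"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# actions recorded on harmonized records
KEPT_AS_IS = "kept_as_is"
ALLELE_FLIP = "allele_flip"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISSING = "dropped_missing"
DROPPED_MISMATCH = "allele_mismatch"


class SummaryStatsError(ValueError):
    """Configuration-level problem with a summary-statistic table."""


class RowValidationError(SummaryStatsError):
    """One or more rows violate the per-record invariants.

    Carries a list of ``(line_number, field, message)`` tuples so callers
    can report every offending row at once.
    """

    def __init__(self, failures: Sequence[tuple[int, str, str]]):
        self.failures = list(failures)
        detail = "; ".join(f"line {ln}: {fld}: {msg}" for ln, fld, msg in self.failures[:20])
        more = "" if len(self.failures) <= 20 else f" (+{len(self.failures) - 20} more)"
        super().__init__(f"{len(self.failures)} invalid row(s): {detail}{more}")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record in one GWAS."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        problems = _record_problems(
            self.eaf, self.beta, self.se, self.pval,
            self.effect_allele, self.other_allele, self.n,
        )
        if problems:
            field_, msg = problems[0]
            raise ValueError(f"{self.snp_id}: {field_}: {msg}")


def _record_problems(eaf, beta, se, pval, ea, oa, n) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    if not np.isfinite(eaf) or not (0.0 < eaf < 1.0):
        out.append(("eaf", f"must be strictly inside (0,1), got {eaf}"))
    if not np.isfinite(beta):
        out.append(("beta", f"must be finite, got {beta}"))
    if not np.isfinite(se) or se <= 0.0:
        out.append(("se", f"must be > 0, got {se}"))
    if not np.isfinite(pval) or not (0.0 < pval <= 1.0):
        out.append(("pval", f"must be in (0,1], got {pval}"))
    if str(ea) == str(oa):
        out.append(("effect_allele", f"effect and other allele identical ({ea})"))
    if n is not None and not (pd.isna(n) or (float(n).is_integer() and n > 0)):
        out.append(("n", f"must be a positive integer, got {n}"))
    return out


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on the same effect allele."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float
    action: str = KEPT_AS_IS


@dataclass(frozen=True)
class FilterEvent:
    """One provenance entry: a named filter, the SNPs it removed, its threshold."""

    name: str
    removed: tuple[str, ...]
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "filter": self.name,
            "n_removed": len(self.removed),
            "removed": list(self.removed),
            "threshold": self.threshold,
        }


@dataclass
class InstrumentSet:
    """Ordered collection of harmonized instruments plus a removal ledger.

    ``table`` holds only retained records (columns ``snp_id,
    beta_exposure, se_exposure, beta_outcome, se_outcome, eaf, action``);
    every removal is recorded in ``provenance``.
    """

    table: pd.DataFrame
    provenance: list[FilterEvent] = field(default_factory=list)
    initial_size: int | None = None

    def __post_init__(self) -> None:
        if self.initial_size is None:
            self.initial_size = len(self.table) + sum(len(e.removed) for e in self.provenance)
        self._check()

    def _check(self) -> None:
        ids = self.table["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate snp_id in instrument set: {dup}")
        removed = sum(len(e.removed) for e in self.provenance)
        if removed != self.initial_size - len(self.table):
            raise ValueError(
                f"provenance removals ({removed}) do not reconcile initial size "
                f"{self.initial_size} with current size {len(self.table)}"
            )
        retained = set(ids)
        for e in self.provenance:
            clash = retained.intersection(e.removed)
            if clash:
                raise ValueError(f"SNPs both retained and removed by '{e.name}': {sorted(clash)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exposure, se_exposure, beta_outcome, se_outcome)."""
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )

    def removed_filter(self, subset_ids: Iterable[str], name: str,
                       threshold: float | None = None) -> "InstrumentSet":
        """Return a new set without ``subset_ids``, appending a provenance event."""
        ids = set(subset_ids)
        unknown = ids - set(self.table["snp_id"])
        if unknown:
            raise KeyError(f"cannot remove unknown SNPs: {sorted(unknown)}")
        mask = ~self.table["snp_id"].isin(ids)
        removed = tuple(self.table.loc[~mask, "snp_id"])
        return InstrumentSet(
            table=self.table.loc[mask].reset_index(drop=True),
            provenance=self.provenance + [FilterEvent(name, removed, threshold)],
            initial_size=self.initial_size,
        )

    def provenance_dict(self) -> list[dict]:
        return [e.to_dict() for e in self.provenance]


def _resolve_columns(columns: Sequence[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical column names to the file's actual header names."""
    mapping: dict[str, str] = {}
    cmap = dict(column_map or {})
    for canonical in MANDATORY_COLUMNS + OPTIONAL_COLUMNS:
        source = cmap.get(canonical, canonical)
        if source in columns:
            mapping[canonical] = source
        elif canonical in MANDATORY_COLUMNS:
            raise SummaryStatsError(
                f"missing mandatory column '{canonical}'"
                + (f" (mapped from '{source}')" if source != canonical else "")
                + f"; file has columns {list(columns)}"
            )
    return mapping


def validate_table(df: pd.DataFrame, *, line_offset: int = 2) -> None:
    """Validate every row against the record invariants.

    ``line_offset`` converts a 0-based row index into a file line number
    (2 for a file with a single header line).
    """
    failures: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        n = row["n"] if "n" in df.columns else None
        for fld, msg in _record_problems(
            row["eaf"], row["beta"], row["se"], row["pval"],
            row["effect_allele"], row["other_allele"], n,
        ):
            failures.append((int(idx) + line_offset, fld, msg))
    if failures:
        raise RowValidationError(failures)


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a GWAS summary-statistic table.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    column_map
        Optional mapping ``canonical name -> file header name`` for
        foreign headers.
    sep
        Field separator; autodetected (tab, then comma) when ``None``.

    Returns
    -------
    DataFrame with canonical columns, every row validated.

    Raises
    ------
    SummaryStatsError
        If a mandatory column is absent.
    RowValidationError
        If any row violates a record invariant; the error lists line
        numbers and offending fields.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    mapping = _resolve_columns(list(raw.columns), column_map)
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    df["snp_id"] = df["snp_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    failures: list[tuple[int, str, str]] = []
    for col in ("eaf", "beta", "se", "pval") + (("n",) if "n" in df.columns else ()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        for idx in df.index[bad]:
            failures.append((int(idx) + 2, col, f"unparseable numeric value {df.at[idx, col]!r}"))
        df[col] = coerced
    if failures:
        raise RowValidationError(failures)

    validate_table(df)
    return df.reset_index(drop=True)


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical summary-statistic table as TSV (full precision)."""
    cols = [c for c in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _complement_pair(a1: str, a2: str) -> tuple[str, str]:
    return _COMPLEMENT.get(a1, a1), _COMPLEMENT.get(a2, a2)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_eaf_window: float = 0.08,
) -> InstrumentSet:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    Matching is by ``snp_id`` only.  For each exposure SNP present in the
    outcome table: identical allele pairs are kept as-is; swapped pairs
    have the outcome beta negated and EAF reflected (``allele_flip``);
    strand complements are resolved before declaring a mismatch.
    Palindromic SNPs (A/T or C/G) with exposure EAF within
    ``palindromic_eaf_window`` of 0.5 are dropped as strand-ambiguous.
    Exposure SNPs absent from the outcome are dropped as missing; allele
    pairs sharing no allele (nor a complement) are dropped with an
    explicit mismatch reason.  Every drop is recorded in provenance.
    """
    outcome_by_id = {r.snp_id: r for r in outcome.itertuples(index=False)}

    kept: list[dict] = []
    dropped: dict[str, list[str]] = {
        DROPPED_MISSING: [],
        DROPPED_PALINDROMIC: [],
        DROPPED_MISMATCH: [],
    }

    for row in exposure.itertuples(index=False):
        ea_x, oa_x = row.effect_allele, row.other_allele
        out = outcome_by_id.get(row.snp_id)
        if out is None:
            dropped[DROPPED_MISSING].append(row.snp_id)
            continue

        if _is_palindromic(ea_x, oa_x) and abs(row.eaf - 0.5) < palindromic_eaf_window:
            dropped[DROPPED_PALINDROMIC].append(row.snp_id)
            continue

        ea_y, oa_y = out.effect_allele, out.other_allele
        pair_x = (ea_x, oa_x)
        # exact matches take precedence over strand-complement matches:
        # for palindromic pairs the complement of a swap equals the identity
        if (ea_y, oa_y) == pair_x:
            action, beta_out = KEPT_AS_IS, out.beta
        elif (oa_y, ea_y) == pair_x:
            action, beta_out = ALLELE_FLIP, -out.beta
        elif _complement_pair(ea_y, oa_y) == pair_x:
            action, beta_out = KEPT_AS_IS, out.beta
        elif _complement_pair(oa_y, ea_y) == pair_x:
            action, beta_out = ALLELE_FLIP, -out.beta
        else:
            dropped[DROPPED_MISMATCH].append(row.snp_id)
            continue

        kept.append({
            "snp_id": row.snp_id,
            "beta_exposure": row.beta,
            "se_exposure": row.se,
            "beta_outcome": beta_out,
            "se_outcome": out.se,
            "eaf": row.eaf,
            "action": action,
        })

    table = pd.DataFrame(
        kept,
        columns=["snp_id", "beta_exposure", "se_exposure",
                 "beta_outcome", "se_outcome", "eaf", "action"],
    )
    provenance = [
        FilterEvent("harmonize:" + DROPPED_MISSING, tuple(dropped[DROPPED_MISSING])),
        FilterEvent(
            "harmonize:" + DROPPED_PALINDROMIC,
            tuple(dropped[DROPPED_PALINDROMIC]),
            threshold=palindromic_eaf_window,
        ),
        FilterEvent("harmonize:" + DROPPED_MISMATCH, tuple(dropped[DROPPED_MISMATCH])),
    ]
    return InstrumentSet(table=table, provenance=provenance, initial_size=len(exposure))


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged 162-variant educational-attainment instrument table.

    Raises
    ------
    SummaryStatsError
        If the packaged file's checksum does not match the frozen digest.
    """
    ref = resources.files("mrkit").joinpath("data/table1_education_instruments.tsv")
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != TABLE1_FIXTURE_SHA256:
        raise SummaryStatsError(
            f"packaged fixture checksum mismatch: got {digest}, expected {TABLE1_FIXTURE_SHA256}"
        )
    with resources.as_file(ref) as p:
        df = read_summary_stats(p)
    if len(df) != 162:
        raise SummaryStatsError(f"fixture must contain 162 records, found {len(df)}")
    return df
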