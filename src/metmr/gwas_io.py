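"""Data model and TSV readers/writers for variant-level GWAS summary statistics.

The canonical on-disk dialect is a GWAS-SSF-like tab-separated table with
snake_case column names (``rsid, chrom, pos, effect_allele, other_allele,
eaf, beta, se, pval, n, n_cases, trait_id, gene``).  Source resources with
different headers are adapted through an explicit ``dialect`` mapping — never
by guessing.  Positions are 1-based; matching between exposure and outcome
tables is by rsID, with chrom/pos used only for region exclusions.

Content problems are *flagged*, never silently dropped: each record carries
at most one primary exclusion reason-code from ``{non_acgt, missing_field,
bad_range, duplicate}``, and :func:`validate_table` produces an accounting
report with ``n_input = n_valid + |exclusions|`` exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: trait kinds a SummaryTable may carry
EXPOSURE_QUANTITATIVE = "exposure_quantitative"
OUTCOME_BINARY = "outcome_binary"

#: canonical fields, in on-disk column order
CANONICAL_FIELDS = (
    "rsid",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "trait_id",
    "gene",
)

#: fields that must be present as columns (others may be absent or empty)
REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")

#: exclusion reason-codes, in priority order (first applicable wins)
REASON_MISSING = "missing_field"
REASON_NON_ACGT = "non_acgt"
REASON_BAD_RANGE = "bad_range"
REASON_DUPLICATE = "duplicate"

#: result-table column order (one row per metabolite × outcome, n_snv = 1)
RESULT_COLUMNS = (
    "metabolite",
    "outcome",
    "rsid",
    "gene",
    "beta",
    "se",
    "OR",
    "CI_low",
    "CI_high",
    "pval",
    "tier",
    "n_snv",
    "R2",
    "F",
    "proxy_rsid",
    "proxy_r2",
)


@dataclass
class AssociationRecord:
    """One variant's summary association in one GWAS.

    ``beta`` is the per-effect-allele effect: SD units of the exposure for
    quantitative traits, log-odds for binary outcomes.  ``eaf`` is the
    effect-allele frequency; it may be missing (``None``), which is permitted
    at read time but makes palindromic resolution impossible downstream.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    trait_id: str = ""
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None
    n_cases: int | None = None
    gene: str | None = None
    exclusion: str | None = None  # primary reason-code set by validation

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.effect_allele, self.other_allele)

    def is_valid(self) -> bool:
        return self.exclusion is None


def _as_float(x) -> float | None:
    if x is None:
        return None
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _primary_reason(rec: AssociationRecord) -> str | None:
    """First applicable reason-code for a single record (duplicates are a
    table-level property and handled in :func:`validate_table`)."""
    if not rec.rsid:
        return REASON_MISSING
    for value in (rec.beta, rec.se, rec.pval):
        if _as_float(value) is None:
            return REASON_MISSING
    if not rec.effect_allele or not rec.other_allele:
        return REASON_MISSING
    ea, oa = str(rec.effect_allele).upper(), str(rec.other_allele).upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES or ea == oa:
        # indels, multi-character alleles and degenerate A/A rows all land here
        return REASON_NON_ACGT
    if rec.eaf is not None and not (0.0 <= rec.eaf <= 1.0):
        return REASON_BAD_RANGE
    if rec.se <= 0:
        return REASON_BAD_RANGE
    if not (0.0 < rec.pval <= 1.0):
        return REASON_BAD_RANGE
    if rec.n is not None and rec.n <= 0:
        return REASON_BAD_RANGE
    return None


@dataclass
class SummaryTable:
    """Ordered collection of :class:`AssociationRecord` for one trait kind."""

    records: list[AssociationRecord]
    trait_kind: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_kind not in (EXPOSURE_QUANTITATIVE, OUTCOME_BINARY):
            raise ValueError(f"unknown trait_kind: {self.trait_kind!r}")

    def __len__(self) -> int:
        return len(self.records)

    def valid_records(self) -> list[AssociationRecord]:
        return [r for r in self.records if r.exclusion is None]

    def rsids(self) -> set[str]:
        return {r.rsid for r in self.valid_records()}

    def by_rsid(self) -> dict[str, AssociationRecord]:
        """First valid record per rsid (tables are per-trait downstream)."""
        out: dict[str, AssociationRecord] = {}
        for r in self.valid_records():
            out.setdefault(r.rsid, r)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=list(CANONICAL_FIELDS) + ["exclusion"])
        return df


@dataclass
class ValidationReport:
    """Accounting of a validation pass: ``n_input = n_valid + |exclusions|``."""

    n_input: int
    n_valid: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_valid + len(self.exclusions):
            raise ValueError("validation accounting violated")


def validate_table(table: SummaryTable) -> ValidationReport:
    """Flag invalid records and report counts.

    Validation never raises on content problems; it assigns each failing
    record exactly one primary reason-code.  Re-validation is idempotent:
    flags are recomputed from scratch each call, so a second pass changes
    nothing.
    """
    exclusions: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for rec in table.records:
        reason = _primary_reason(rec)
        if reason is None:
            key = (rec.rsid, rec.trait_id)
            if key in seen:
                reason = REASON_DUPLICATE
            else:
                seen.add(key)
        rec.exclusion = reason
        if reason is not None:
            exclusions.append((rec.rsid, reason))
    return ValidationReport(
        n_input=len(table.records),
        n_valid=len(table.records) - len(exclusions),
        exclusions=exclusions,
    )


def read_summary_stats(
    path: str | Path,
    trait_kind: str,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    provenance: str = "",
) -> SummaryTable:
    """Read a tab-separated summary-statistics file into a SummaryTable.

    Parameters
    ----------
    path
        TSV file with a header row.
    trait_kind
        ``"exposure_quantitative"`` or ``"outcome_binary"``.
    dialect
        Mapping from canonical field names to the source file's column
        names; canonical names present in the file need not be listed.
    trait_id
        Trait label applied to every record when the file has no
        ``trait_id`` column.

    Raises
    ------
    ValueError
        If a required canonical column cannot be resolved (the error names
        the canonical column), or the file is unreadable.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:  # unreadable file is a hard error
        raise ValueError(f"cannot read summary statistics file {path}: {exc}") from exc

    dialect = dict(dialect or {})
    colmap: dict[str, str] = {}
    for canon in CANONICAL_FIELDS:
        source = dialect.get(canon, canon)
        if source in df.columns:
            colmap[canon] = source
    for canon in REQUIRED_FIELDS:
        if canon not in colmap:
            raise ValueError(
                f"missing required column {canon!r} in {path} "
                f"(mapped from {dialect.get(canon, canon)!r})"
            )

    def get(row, canon, default=None):
        src = colmap.get(canon)
        if src is None:
            return default
        val = row[src]
        return default if val == "" else val

    records: list[AssociationRecord] = []
    for _, row in df.iterrows():
        eaf = _as_float(get(row, "eaf"))
        n = _as_float(get(row, "n"))
        n_cases = _as_float(get(row, "n_cases"))
        pos = _as_float(get(row, "pos"))
        records.append(
            AssociationRecord(
                rsid=str(get(row, "rsid", "")),
                effect_allele=str(get(row, "effect_allele", "")).upper(),
                other_allele=str(get(row, "other_allele", "")).upper(),
                beta=_as_float(get(row, "beta")),
                se=_as_float(get(row, "se")),
                pval=_as_float(get(row, "pval")),
                trait_id=str(get(row, "trait_id", trait_id or "")),
                chrom=get(row, "chrom"),
                pos=int(pos) if pos is not None else None,
                eaf=eaf,
                n=int(n) if n is not None else None,
                n_cases=int(n_cases) if n_cases is not None else None,
                gene=get(row, "gene"),
            )
        )
    table = SummaryTable(records=records, trait_kind=trait_kind, provenance=provenance)
    validate_table(table)  # rows failing parsing carry exclusion flags
    return table


def write_summary_stats(table: SummaryTable, path: str | Path) -> None:
    """Write a SummaryTable in the canonical TSV dialect."""
    df = table.to_frame().drop(columns=["exclusion"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_results(results: Sequence, path: str | Path) -> None:
    """Write MR results as an audit-grade TSV (one row per pair, n_snv = 1).

    Accepts :class:`metmr.mr.MRResult` objects (anything with a ``to_row``
    method) or plain mappings with the :data:`RESULT_COLUMNS` keys.  Values
    round-trip through :func:`read_results` to 12 significant digits.
    """
    if results is None or len(results) == 0:
        raise ValueError("write_results requires a non-empty result collection")
    rows = []
    for r in results:
        rows.append(r.to_row() if hasattr(r, "to_row") else dict(r))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as exc:
        raise ValueError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back into a DataFrame (inverse of write_results).

    Default NA parsing is disabled so the ``null`` significance tier reads
    back as the string it is; only empty cells become missing.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    for col in ("metabolite", "outcome", "rsid", "gene", "tier", "proxy_rsid"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    return df
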