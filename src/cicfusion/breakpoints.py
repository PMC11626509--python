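"""Literature-derived fusion breakpoint records and their harmonization.

Records follow the harmonized-database schema: one row per reported fusion
case, a junction encoded as (last retained base of the 5′ partner, first
retained base of the 3′ partner) on named transcript references, and any
junction bases that the original report could not attribute to either partner
kept verbatim in ``ambiguous_junction_bases``.

Harmonization resolves that ambiguity entirely onto the 5′ partner (the
convention used when curating CIC-rearranged fusions): ``k`` ambiguous bases
extend ``five_prime_last_base`` by ``k`` and leave the 3′ coordinate alone.
This happens *before* any reading-frame computation, because junction phase
depends on the assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .reference import NT_ALPHABET, TranscriptReference

EVIDENCE_SOURCES = frozenset({"RNA", "DNA", "unknown"})
RESOLUTIONS = frozenset({"nucleotide", "exon"})
#: 3′ partner genes observed in the curated CIC-fusion cohort.  Extensible via
#: the ``partner_whitelist`` argument of :func:`parse_breakpoint_table`.
DEFAULT_PARTNER_WHITELIST = frozenset({"DUX4", "NUTM1", "LEUTX", "FOXO4"})

LAST_RETAINED = "last_retained"
FIRST_LOST = "first_lost"


class HarmonizationError(ValueError):
    """Junction harmonization would leave the reference sequence."""


@dataclass(frozen=True)
class BreakpointRecord:
    case_id: str
    publication_id: str
    five_prime_gene: str
    three_prime_gene: str
    evidence_source: str
    resolution: str
    five_prime_last_base: Optional[int]
    three_prime_first_base: Optional[int]
    ambiguous_junction_bases: str = ""
    five_prime_accession: str = ""
    three_prime_accession: str = ""
    notes: str = ""
    harmonization_notes: tuple[str, ...] = ()
    warning_flags: tuple[str, ...] = ()

    def validate(
        self, refs: Mapping[str, TranscriptReference] | None = None
    ) -> list[str]:
        """Return a list of invariant-violation reasons (empty when valid)."""
        problems = []
        if self.evidence_source not in EVIDENCE_SOURCES:
            problems.append(f"unknown evidence source {self.evidence_source!r}")
        if self.resolution not in RESOLUTIONS:
            problems.append(f"unknown resolution {self.resolution!r}")
        if self.resolution == "nucleotide":
            if self.five_prime_last_base is None and self.three_prime_first_base is None:
                problems.append("nucleotide-level record with no coordinates")
        bad = set(self.ambiguous_junction_bases.upper()) - NT_ALPHABET
        if bad:
            problems.append(f"ambiguous bases contain non-ACGTN {sorted(bad)}")
        for coord, acc, label in (
            (self.five_prime_last_base, self.five_prime_accession, "5'"),
            (self.three_prime_first_base, self.three_prime_accession, "3'"),
        ):
            if coord is not None and coord < 1:
                problems.append(f"{label} coordinate {coord} < 1")
            if refs is not None and coord is not None and acc in refs:
                if coord > len(refs[acc]):
                    problems.append(
                        f"{label} coordinate {coord} outside {acc} "
                        f"(length {len(refs[acc])})"
                    )
        return problems

    @property
    def has_both_coordinates(self) -> bool:
        return (
            self.five_prime_last_base is not None
            and self.three_prime_first_base is not None
        )


@dataclass
class HarmonizedDatabase:
    records: list[BreakpointRecord]
    provenance: str = ""
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (row label, reason)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.case_id in seen:
                raise ValueError(f"duplicate case_id {rec.case_id!r}")
            seen.add(rec.case_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


_SCHEMA_COLUMNS = (
    "case_id",
    "publication_id",
    "five_prime_gene",
    "three_prime_gene",
    "evidence_source",
    "resolution",
    "five_prime_last_base",
    "three_prime_first_base",
    "ambiguous_junction_bases",
    "five_prime_accession",
    "three_prime_accession",
    "notes",
)


def _coerce_coord(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.upper() in ("NA", "NAN", "NONE", "NULL"):
            return None
    return int(value)  # raises ValueError for garbage — caught by the parser


def _coerce_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def parse_breakpoint_table(
    source: Path | str | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
    partner_whitelist: Iterable[str] | None = DEFAULT_PARTNER_WHITELIST,
    junction_convention: str = LAST_RETAINED,
    refs: Mapping[str, TranscriptReference] | None = None,
) -> HarmonizedDatabase:
    """Read a breakpoint table (TSV/CSV/spreadsheet or DataFrame).

    ``column_map`` maps schema field names to the table's column names
    (identity by default).  Rows violating record invariants — unknown partner
    gene under the whitelist, unparseable or out-of-range coordinates — are
    collected in ``db.rejects`` with a reason, never silently dropped.

    ``junction_convention`` accepts ``"last_retained"`` (native) or
    ``"first_lost"``, where the 5′ column holds the first base *not* retained
    (converted by −1) and the 3′ column the last base not retained (+1).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        provenance = "in-memory dataframe"
    else:
        path = Path(source)
        provenance = str(path)
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path)
        elif path.suffix.lower() == ".csv":
            df = pd.read_csv(path)
        else:
            df = pd.read_csv(path, sep="\t")
    if junction_convention not in (LAST_RETAINED, FIRST_LOST):
        raise ValueError(f"unknown junction convention {junction_convention!r}")

    colmap = {f: f for f in _SCHEMA_COLUMNS}
    if column_map:
        colmap.update(column_map)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")

    whitelist = set(partner_whitelist) if partner_whitelist is not None else None
    records: list[BreakpointRecord] = []
    rejects: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        label = _coerce_str(row[colmap["case_id"]]) or f"row {idx}"
        try:
            bp5 = _coerce_coord(row[colmap["five_prime_last_base"]])
            bp3 = _coerce_coord(row[colmap["three_prime_first_base"]])
        except (ValueError, TypeError):
            rejects.append((label, "unparseable coordinate"))
            continue
        if junction_convention == FIRST_LOST:
            bp5 = None if bp5 is None else bp5 - 1
            bp3 = None if bp3 is None else bp3 + 1
        rec = BreakpointRecord(
            case_id=label,
            publication_id=_coerce_str(row[colmap["publication_id"]]),
            five_prime_gene=_coerce_str(row[colmap["five_prime_gene"]]),
            three_prime_gene=_coerce_str(row[colmap["three_prime_gene"]]),
            evidence_source=_coerce_str(row[colmap["evidence_source"]]) or "unknown",
            resolution=_coerce_str(row[colmap["resolution"]]),
            five_prime_last_base=bp5,
            three_prime_first_base=bp3,
            ambiguous_junction_bases=_coerce_str(
                row[colmap["ambiguous_junction_bases"]]
            ).upper(),
            five_prime_accession=_coerce_str(row[colmap["five_prime_accession"]]),
            three_prime_accession=_coerce_str(row[colmap["three_prime_accession"]]),
            notes=_coerce_str(row[colmap["notes"]]),
        )
        if whitelist is not None and rec.three_prime_gene not in whitelist:
            rejects.append((label, f"unknown partner {rec.three_prime_gene!r}"))
            continue
        problems = rec.validate(refs)
        if problems:
            rejects.append((label, "; ".join(problems)))
            continue
        records.append(rec)
    return HarmonizedDatabase(records, provenance=provenance, rejects=rejects)


def assign_ambiguous_bases(
    rec: BreakpointRecord, ref5: TranscriptReference | None = None
) -> BreakpointRecord:
    """Resolve ambiguous junction bases onto the 5′ partner.

    ``k`` ambiguous bases extend ``five_prime_last_base`` by ``k``; the 3′
    coordinate is untouched.  When a 5′ reference is supplied the ambiguous
    bases are checked against the reference sequence at the extended
    positions; a mismatch sets a warning flag rather than failing (published
    junction sequences occasionally disagree with the reference).  Idempotent.
    """
    k = len(rec.ambiguous_junction_bases)
    if k == 0:
        return rec
    if rec.five_prime_last_base is None:
        raise HarmonizationError(
            f"{rec.case_id}: ambiguous bases but no 5' coordinate"
        )
    new_bp5 = rec.five_prime_last_base + k
    warning_flags = rec.warning_flags
    if ref5 is not None:
        if new_bp5 > len(ref5):
            raise HarmonizationError(
                f"{rec.case_id}: assigning {k} ambiguous bases extends past "
                f"the end of {ref5.accession}"
            )
        expected = ref5.sequence[rec.five_prime_last_base : new_bp5]
        if expected != rec.ambiguous_junction_bases.upper():
            warning_flags = warning_flags + ("ambiguous_base_mismatch",)
    note = (
        f"assigned {k} ambiguous junction base(s) "
        f"({rec.ambiguous_junction_bases}) to the 5' partner"
    )
    return replace(
        rec,
        five_prime_last_base=new_bp5,
        ambiguous_junction_bases="",
        harmonization_notes=rec.harmonization_notes + (note,),
        warning_flags=warning_flags,
    )


def filter_records(
    db: HarmonizedDatabase,
    partner_genes: Iterable[str] | None = None,
    evidence_source: str | None = None,
    resolution: str | None = None,
    both_coordinates_required: bool = False,
) -> HarmonizedDatabase:
    """Order-preserving subset; the applied criteria are appended to
    the provenance string so cohort denominators stay reproducible."""
    partners = set(partner_genes) if partner_genes is not None else None
    kept = []
    for rec in db.records:
        if partners is not None and rec.three_prime_gene not in partners:
            continue
        if evidence_source is not None and rec.evidence_source != evidence_source:
            continue
        if resolution is not None and rec.resolution != resolution:
            continue
        if both_coordinates_required and not rec.has_both_coordinates:
            continue
        kept.append(rec)
    crit = (
        f"filter(partners={sorted(partners) if partners else 'any'}, "
        f"evidence={evidence_source or 'any'}, resolution={resolution or 'any'}, "
        f"both_coordinates={both_coordinates_required})"
    )
    provenance = f"{db.provenance}; {crit}" if db.provenance else crit
    return HarmonizedDatabase(kept, provenance=provenance, rejects=list(db.rejects))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def to_dataframe(db: HarmonizedDatabase) -> pd.DataFrame:
    rows = []
    for rec in db.records:
        rows.append({col: getattr(rec, col) for col in _SCHEMA_COLUMNS})
    return pd.DataFrame(rows, columns=list(_SCHEMA_COLUMNS))


def write_breakpoint_table(db: HarmonizedDatabase, path: Path | str) -> None:
    """Emit the native tab-separated schema (re-parseable round trip)."""
    df = to_dataframe(db)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_jsonl(db: HarmonizedDatabase, path: Path | str) -> None:
    with open(path, "w") as fh:
        for rec in db.records:
            row = {f.name: getattr(rec, f.name) for f in fields(rec)}
            row["harmonization_notes"] = list(rec.harmonization_notes)
            row["warning_flags"] = list(rec.warning_flags)
            fh.write(json.dumps(row) + "\n")


def write_reject_report(db: HarmonizedDatabase, path: Path | str) -> None:
    lines = [f"{case}\t{reason}" for case, reason in db.rejects]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
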