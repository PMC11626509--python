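"""Transcript reference model and coordinate arithmetic.

A :class:`TranscriptReference` is an mRNA-sense nucleotide sequence carrying a
CDS span and named protein-domain annotations.  Everything downstream —
breakpoint harmonization, reading-frame classification, domain-retention
calling — is expressed in this coordinate system, so the conversions here
(transcript nucleotide ↔ CDS position ↔ codon phase ↔ protein residue) are the
foundation of the whole package.

Conventions
-----------
* All transcript coordinates are 1-based and inclusive (GenBank/RefSeq style).
* ``cds_end`` includes the stop codon; protein length excludes it.
* Codon phase is ``(nt - cds_start) mod 3``: phase 0 marks the first base of a
  codon.
* Standard genetic code only; codons containing ``N`` translate to ``X`` and
  never count as stop codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))
_AA_BY_CODON = dict(_STANDARD_TABLE.forward_table)

NT_ALPHABET = frozenset("ACGTN")

FIVE_PRIME_UTR = "five_prime_utr"
CDS = "cds"
THREE_PRIME_UTR = "three_prime_utr"


class ReferenceError(ValueError):
    """Invalid or unloadable transcript reference."""


def translate(seq: str, start: int = 1) -> tuple[str, bool]:
    """Translate ``seq`` from 1-based offset ``start`` up to the first stop.

    Returns ``(protein, stop_found)``.  The stop residue is excluded from the
    protein.  Codons containing ``N`` become ``'X'`` and never terminate
    translation; a trailing partial codon is ignored.
    """
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    residues = []
    for i in range(start - 1, len(seq) - 2, 3):
        codon = seq[i : i + 3].upper()
        if "N" in codon:
            residues.append("X")
            continue
        if codon in STOP_CODONS:
            return "".join(residues), True
        try:
            residues.append(_AA_BY_CODON[codon])
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at position {i + 1}")
    return "".join(residues), False


@dataclass(frozen=True)
class DomainAnnotation:
    """Named protein domain given as an inclusive 1-based residue range."""

    name: str
    residue_start: int
    residue_end: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.residue_start <= self.residue_end):
            raise ReferenceError(
                f"domain {self.name}: invalid residue range "
                f"{self.residue_start}..{self.residue_end}"
            )


@dataclass(frozen=True)
class Region:
    """Result of :func:`locate`: UTR membership or CDS position + phase."""

    region: str
    cds_pos: Optional[int] = None
    phase: Optional[int] = None


@dataclass
class TranscriptReference:
    accession: str
    gene_symbol: str
    sequence: str
    cds_start: int
    cds_end: int
    domains: tuple[DomainAnnotation, ...] = ()
    exons: Optional[tuple[tuple[int, int], ...]] = None
    internal_stop_warning: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.domains = tuple(self.domains)
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise ReferenceError(
                f"{self.accession}: sequence contains non-ACGTN characters {sorted(bad)}"
            )
        n = len(self.sequence)
        if not (1 <= self.cds_start < self.cds_end <= n):
            raise ReferenceError(
                f"{self.accession}: CDS {self.cds_start}..{self.cds_end} "
                f"outside sequence of length {n}"
            )
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ReferenceError(
                f"{self.accession}: CDS length not a multiple of 3"
            )
        protein, _ = translate(self.cds)
        # an internal stop shortens the translation; tolerate (warn) because
        # N-containing codons can mask genuine sense codons
        if len(protein) < self.protein_length:
            self.internal_stop_warning = True
            warnings.warn(
                f"{self.accession}: internal stop codon within annotated CDS",
                stacklevel=2,
            )
        for dom in self.domains:
            if dom.residue_end > self.protein_length:
                raise ReferenceError(
                    f"{self.accession}: domain {dom.name} "
                    f"({dom.residue_start}..{dom.residue_end}) outside protein "
                    f"of length {self.protein_length}"
                )
        if self.exons is not None:
            self.exons = tuple(tuple(iv) for iv in self.exons)
            pos = 1
            for s, e in self.exons:
                if s != pos or e < s:
                    raise ReferenceError(
                        f"{self.accession}: exon intervals must be sorted, "
                        f"disjoint and tile 1..{n}"
                    )
                pos = e + 1
            if pos != n + 1:
                raise ReferenceError(
                    f"{self.accession}: exons do not tile the transcript"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def protein_length(self) -> int:
        """Protein residues, stop codon excluded."""
        return self.cds_length // 3 - 1

    @property
    def protein(self) -> str:
        return translate(self.cds)[0]

    def domain(self, name: str) -> DomainAnnotation:
        for dom in self.domains:
            if dom.name == name:
                return dom
        raise KeyError(f"{self.accession}: no domain named {name!r}")


def residue_to_nt_interval(
    ref: TranscriptReference, residue_start: int, residue_end: int
) -> tuple[int, int]:
    """Map an inclusive protein residue range to transcript nucleotides.

    ``nt_start = cds_start + 3*(residue_start - 1)`` and
    ``nt_end = cds_start + 3*residue_end - 1``; the interval covers exactly
    the codons of the requested residues.
    """
    if not (1 <= residue_start <= residue_end <= ref.protein_length):
        raise ReferenceError(
            f"{ref.accession}: residue range {residue_start}..{residue_end} "
            f"outside protein of length {ref.protein_length}"
        )
    nt_start = ref.cds_start + 3 * (residue_start - 1)
    nt_end = ref.cds_start + 3 * residue_end - 1
    return nt_start, nt_end


def domain_nt_interval(
    ref: TranscriptReference, domain: DomainAnnotation
) -> tuple[int, int]:
    return residue_to_nt_interval(ref, domain.residue_start, domain.residue_end)


def locate(ref: TranscriptReference, nt: int) -> Region:
    """Classify a transcript coordinate as 5′ UTR, CDS (with position/phase),
    or 3′ UTR."""
    if not (1 <= nt <= len(ref)):
        raise ReferenceError(
            f"{ref.accession}: coordinate {nt} outside sequence of length {len(ref)}"
        )
    if nt < ref.cds_start:
        return Region(FIVE_PRIME_UTR)
    if nt > ref.cds_end:
        return Region(THREE_PRIME_UTR)
    return Region(CDS, cds_pos=nt - ref.cds_start + 1, phase=(nt - ref.cds_start) % 3)


# ---------------------------------------------------------------------------
# loading: GenBank flat files, or FASTA plus a sidecar annotation file
# ---------------------------------------------------------------------------

def _parse_sidecar(path: Path) -> dict:
    """Sidecar annotation: tab-separated key/value rows plus domain/exon rows.

    ::

        accession   NM_015125.5
        gene_symbol CIC
        cds_start   194
        cds_end     5023
        domain      C1  1464  1519  [source]
        exon        1   213          (optional)
    """
    out: dict = {"domains": [], "exons": []}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        if key in ("accession", "gene_symbol"):
            out[key] = parts[1]
        elif key in ("cds_start", "cds_end"):
            out[key] = int(parts[1])
        elif key == "domain":
            source = parts[4] if len(parts) > 4 else ""
            out["domains"].append(
                DomainAnnotation(parts[1], int(parts[2]), int(parts[3]), source)
            )
        elif key == "exon":
            out["exons"].append((int(parts[1]), int(parts[2])))
        else:
            raise ReferenceError(f"{path}: unknown sidecar row type {key!r}")
    return out


def write_sidecar(ref: TranscriptReference, path: Path | str) -> None:
    lines = [
        f"accession\t{ref.accession}",
        f"gene_symbol\t{ref.gene_symbol}",
        f"cds_start\t{ref.cds_start}",
        f"cds_end\t{ref.cds_end}",
    ]
    for dom in ref.domains:
        lines.append(
            f"domain\t{dom.name}\t{dom.residue_start}\t{dom.residue_end}\t{dom.source}"
        )
    if ref.exons:
        for s, e in ref.exons:
            lines.append(f"exon\t{s}\t{e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _looks_like_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith(">")
    raise ReferenceError(f"{path}: empty file")


def load_reference(
    source: Path | str,
    sidecar: Path | str | None = None,
    gene_symbol: str | None = None,
) -> TranscriptReference:
    """Load a transcript reference from a GenBank flat file or from a FASTA
    file with a sidecar annotation.

    GenBank records must carry exactly one CDS feature; a sidecar, when given
    alongside GenBank, contributes domain annotations (and may override the
    gene symbol).  FASTA input requires a sidecar that states the CDS span.
    """
    source = Path(source)
    side = _parse_sidecar(Path(sidecar)) if sidecar is not None else None

    if _looks_like_fasta(source):
        if side is None or "cds_start" not in side or "cds_end" not in side:
            raise ReferenceError(
                f"{source}: FASTA input requires a sidecar with a CDS span"
            )
        record = SeqIO.read(source, "fasta")
        accession = side.get("accession", record.id)
        gene = gene_symbol or side.get("gene_symbol", record.id)
        cds_start, cds_end = side["cds_start"], side["cds_end"]
        domains = side["domains"]
        exons = tuple(side["exons"]) or None
    else:
        record = SeqIO.read(source, "genbank")
        cds_feats = [f for f in record.features if f.type == "CDS"]
        accession = record.id
        if len(cds_feats) != 1:
            raise ReferenceError(
                f"{accession}: expected exactly one CDS feature, found {len(cds_feats)}"
            )
        feat = cds_feats[0]
        cds_start = int(feat.location.start) + 1
        cds_end = int(feat.location.end)
        gene = gene_symbol or feat.qualifiers.get("gene", [accession])[0]
        domains, exons = [], None
        if side is not None:
            domains = side["domains"]
            exons = tuple(side["exons"]) or None
            gene = gene_symbol or side.get("gene_symbol", gene)

    return TranscriptReference(
        accession=accession,
        gene_symbol=gene,
        sequence=str(record.seq),
        cds_start=cds_start,
        cds_end=cds_end,
        domains=tuple(domains),
        exons=exons,
    )
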