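"""Fusion junction classification, chimeric-protein prediction, and
protein-domain retention calling.

Given a harmonized junction (last retained base ``bp5`` on the 5′ reference,
first retained base ``bp3`` on the 3′ reference), the classifier decides, in
order:

1. ``bp5`` upstream of the 5′ CDS → ``five_prime_noncoding`` (no 5′ coding
   content at all);
2. ``bp5`` at or beyond the 5′ stop codon's last base → ``five_prime_readthrough``
   (the 5′ partner's own stop is retained, so no fusion ORF continues into the
   3′ partner);
3. ``bp3`` in the 3′ partner's 3′ UTR → ``utr_fusion`` (e.g. CIC joined to
   the DUX4 3′-UTR, typically truncating the 5′ protein at a stop shortly
   after the junction);
4. ``bp3`` in the 3′ partner's 5′ UTR → ``three_prime_upstream_of_cds``
   (out-of-cohort geometry; frame outcome is only defined by full-chimera
   translation and is recorded on the protein prediction);
5. both breakpoints in CDS → in-frame iff the retained 5′ CDS length and the
   3′ entry position have equal codon phase.

The protein prediction concatenates the retained transcript fragments and
translates from the 5′ CDS start, reporting whether translation terminates at
the 3′ partner's own stop codon (``native_3prime``), at any other stop
(``premature``), or runs off the transcript end (``none_found``), together
with the junction-to-stop distance in nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from .breakpoints import BreakpointRecord, HarmonizedDatabase, assign_ambiguous_bases
from .reference import (
    CDS,
    FIVE_PRIME_UTR,
    THREE_PRIME_UTR,
    DomainAnnotation,
    TranscriptReference,
    domain_nt_interval,
    locate,
    translate,
)

IN_FRAME = "in_frame_coding"
OUT_OF_FRAME = "out_of_frame_coding"
UTR_FUSION = "utr_fusion"
FIVE_PRIME_NONCODING = "five_prime_noncoding"
FIVE_PRIME_READTHROUGH = "five_prime_readthrough"
THREE_PRIME_UPSTREAM = "three_prime_upstream_of_cds"

CATEGORIES = (
    IN_FRAME,
    OUT_OF_FRAME,
    UTR_FUSION,
    FIVE_PRIME_NONCODING,
    FIVE_PRIME_READTHROUGH,
    THREE_PRIME_UPSTREAM,
)

RETAINED = "retained"
DISRUPTED = "disrupted"
LOST = "lost"

NATIVE_3PRIME = "native_3prime"
PREMATURE = "premature"
NONE_FOUND = "none_found"

NOT_ANNOTATABLE = "not_annotatable"


class AnnotationError(ValueError):
    pass


@dataclass
class ProteinPrediction:
    sequence: str
    junction_residue_index: int
    stop_origin: str
    junction_to_stop_nt: Optional[int]
    # chimera bookkeeping needed to map native 3'-partner residues into the
    # predicted protein (translation frame anchor and junction coordinates)
    translation_start: int = 0
    five_prime_last_base: int = 0
    three_prime_first_base: int = 0

    def __post_init__(self) -> None:
        if self.junction_residue_index > len(self.sequence) + 1:
            raise AnnotationError("junction residue index beyond protein end")


@dataclass
class FusionAnnotation:
    category: str
    n5_cds: int
    phase5: Optional[int]
    p3_cds: Optional[int]
    phase3: Optional[int]
    domain_status_genomic: dict[str, str] = field(default_factory=dict)
    domain_status_protein: dict[str, str] = field(default_factory=dict)
    protein: Optional[ProteinPrediction] = None
    warning_flags: tuple[str, ...] = ()


def _check_bounds(ref: TranscriptReference, bp: int, label: str) -> None:
    if not (1 <= bp <= len(ref)):
        raise AnnotationError(
            f"{label} breakpoint {bp} outside {ref.accession} (length {len(ref)})"
        )


def classify_fusion(
    ref5: TranscriptReference,
    bp5: int,
    ref3: TranscriptReference,
    bp3: int,
) -> FusionAnnotation:
    """Category and junction phases only; domain statuses and the protein
    prediction are filled in by :func:`annotate_database` (or the dedicated
    operations).  Ambiguous junction bases must already be assigned."""
    _check_bounds(ref5, bp5, "5'")
    _check_bounds(ref3, bp3, "3'")

    n5_cds = max(0, min(bp5, ref5.cds_end) - ref5.cds_start + 1)
    if bp5 < ref5.cds_start:
        return FusionAnnotation(FIVE_PRIME_NONCODING, 0, None, None, None)
    if bp5 >= ref5.cds_end:
        return FusionAnnotation(FIVE_PRIME_READTHROUGH, n5_cds, None, None, None)

    region3 = locate(ref3, bp3)
    phase5 = n5_cds % 3
    if region3.region == THREE_PRIME_UTR:
        return FusionAnnotation(UTR_FUSION, n5_cds, phase5, None, None)
    if region3.region == FIVE_PRIME_UTR:
        return FusionAnnotation(THREE_PRIME_UPSTREAM, n5_cds, phase5, None, None)

    p3_cds = region3.cds_pos
    phase3 = (p3_cds - 1) % 3
    category = IN_FRAME if phase5 == phase3 else OUT_OF_FRAME
    return FusionAnnotation(category, n5_cds, phase5, p3_cds, phase3)


def build_chimera(
    ref5: TranscriptReference, bp5: int, ref3: TranscriptReference, bp3: int
) -> str:
    """Chimeric mRNA: 5′ reference through ``bp5`` joined to the 3′ reference
    from ``bp3`` onward (both inclusive)."""
    return ref5.sequence[:bp5] + ref3.sequence[bp3 - 1 :]


def predict_fusion_protein(
    ref5: TranscriptReference,
    bp5: int,
    ref3: TranscriptReference,
    bp3: int,
) -> ProteinPrediction:
    """Translate the chimeric transcript from the 5′ partner's CDS start."""
    _check_bounds(ref5, bp5, "5'")
    _check_bounds(ref3, bp3, "3'")
    if bp5 < ref5.cds_start:
        raise AnnotationError(
            "no fusion ORF: 5' breakpoint upstream of the 5' CDS start"
        )
    chimera = build_chimera(ref5, bp5, ref3, bp3)
    protein, stop_found = translate(chimera, start=ref5.cds_start)

    n5_cds = bp5 - ref5.cds_start + 1
    junction_residue_index = min(n5_cds // 3 + 1, len(protein) + 1)

    if not stop_found:
        stop_origin, junction_to_stop_nt = NONE_FOUND, None
    else:
        stop_chim_start = ref5.cds_start + 3 * len(protein)  # first base of stop
        junction_to_stop_nt = stop_chim_start - bp5
        # native stop of the 3' partner sits at cds_end3-2..cds_end3; it maps
        # into the chimera only when fully retained (bp3 <= cds_end3 - 2)
        native_start = (
            bp5 + (ref3.cds_end - 2) - bp3 + 1 if bp3 <= ref3.cds_end - 2 else None
        )
        stop_origin = NATIVE_3PRIME if stop_chim_start == native_start else PREMATURE
    return ProteinPrediction(
        sequence=protein,
        junction_residue_index=junction_residue_index,
        stop_origin=stop_origin,
        junction_to_stop_nt=junction_to_stop_nt,
        translation_start=ref5.cds_start,
        five_prime_last_base=bp5,
        three_prime_first_base=bp3,
    )


def domain_status_genomic(
    ref: TranscriptReference,
    domain: DomainAnnotation,
    bp: int,
    side: str,
) -> str:
    """Retention call from the breakpoint position alone.

    On the 5′ side a domain is retained when the breakpoint lies at or beyond
    the domain's last nucleotide (a junction after the 3′ end of the domain
    preserves it entirely); on the 3′ side, when the breakpoint enters at or
    before the domain's first nucleotide.
    """
    _check_bounds(ref, bp, side)
    d_s, d_e = domain_nt_interval(ref, domain)
    if side == "five_prime":
        if bp >= d_e:
            return RETAINED
        if bp >= d_s:
            return DISRUPTED
        return LOST
    if side == "three_prime":
        if bp <= d_s:
            return RETAINED
        if bp <= d_e:
            return DISRUPTED
        return LOST
    raise ValueError(f"side must be five_prime or three_prime, got {side!r}")


def domain_status_protein(
    prediction: ProteinPrediction,
    ref: TranscriptReference,
    domain: DomainAnnotation,
    side: str,
) -> str:
    """Retention call from the predicted protein.

    A domain residue counts as present only when its native codon survives
    intact in the chimera, frame-aligned with the fusion ORF, and the
    translated residue matches its native identity (an ``X`` from sequence
    uncertainty never counts).  This sees premature stops that the genomic
    call cannot.
    """
    native = ref.protein
    present = 0
    total = domain.residue_end - domain.residue_start + 1
    pred = prediction.sequence
    for j in range(domain.residue_start, domain.residue_end + 1):
        codon_start = ref.cds_start + 3 * (j - 1)
        if side == "five_prime":
            # codon fully within the retained 5' fragment, residue index j
            if codon_start + 2 > prediction.five_prime_last_base:
                continue
            r = j
        elif side == "three_prime":
            if codon_start < prediction.three_prime_first_base:
                continue
            chim_pos = (
                prediction.five_prime_last_base
                + codon_start
                - prediction.three_prime_first_base
                + 1
            )
            if (chim_pos - prediction.translation_start) % 3 != 0:
                continue  # not frame-aligned with the fusion ORF
            r = (chim_pos - prediction.translation_start) // 3 + 1
        else:
            raise ValueError(f"side must be five_prime or three_prime, got {side!r}")
        if r <= len(pred) and pred[r - 1] != "X" and pred[r - 1] == native[j - 1]:
            present += 1
    if present == total:
        return RETAINED
    return DISRUPTED if present > 0 else LOST


@dataclass
class AnnotatedRecord:
    record: BreakpointRecord
    annotation: Optional[FusionAnnotation]
    status: str  # "ok", "not_annotatable", or "failed"
    reason: str = ""


def _qualified(gene: str, domain: DomainAnnotation) -> str:
    return f"{gene}:{domain.name}"


def annotate_record(
    rec: BreakpointRecord,
    refs: Mapping[str, TranscriptReference],
) -> AnnotatedRecord:
    if rec.resolution != "nucleotide":
        return AnnotatedRecord(rec, None, NOT_ANNOTATABLE, "nucleotide resolution required")
    if not rec.has_both_coordinates:
        return AnnotatedRecord(rec, None, NOT_ANNOTATABLE, "both junction coordinates required")
    try:
        ref5 = refs[rec.five_prime_accession]
        ref3 = refs[rec.three_prime_accession]
    except KeyError as exc:
        return AnnotatedRecord(rec, None, "failed", f"missing reference {exc.args[0]}")
    try:
        rec = assign_ambiguous_bases(rec, ref5)
        bp5, bp3 = rec.five_prime_last_base, rec.three_prime_first_base
        ann = classify_fusion(ref5, bp5, ref3, bp3)
        if ann.category != FIVE_PRIME_NONCODING:
            ann.protein = predict_fusion_protein(ref5, bp5, ref3, bp3)
        for dom in ref5.domains:
            key = _qualified(ref5.gene_symbol, dom)
            ann.domain_status_genomic[key] = domain_status_genomic(
                ref5, dom, bp5, "five_prime"
            )
            if ann.protein is not None:
                ann.domain_status_protein[key] = domain_status_protein(
                    ann.protein, ref5, dom, "five_prime"
                )
        for dom in ref3.domains:
            key = _qualified(ref3.gene_symbol, dom)
            ann.domain_status_genomic[key] = domain_status_genomic(
                ref3, dom, bp3, "three_prime"
            )
            if ann.protein is not None:
                ann.domain_status_protein[key] = domain_status_protein(
                    ann.protein, ref3, dom, "three_prime"
                )
        ann.warning_flags = rec.warning_flags
    except (ValueError, KeyError) as exc:  # record-level, never fatal
        return AnnotatedRecord(rec, None, "failed", str(exc))
    return AnnotatedRecord(rec, ann, "ok")


def annotate_database(
    db: HarmonizedDatabase,
    refs: Mapping[str, TranscriptReference],
) -> list[AnnotatedRecord]:
    """Deterministic, order-preserving annotation of a harmonized cohort.

    Exon-level and one-sided records receive a ``not_annotatable`` sentinel;
    per-record failures (e.g. an unresolvable accession) are collected, not
    fatal.
    """
    return [annotate_record(rec, refs) for rec in db.records]


def ambiguous_assignment_diagnostic(
    db: HarmonizedDatabase,
    refs: Mapping[str, TranscriptReference],
) -> list[str]:
    """Case ids whose category would differ had the ambiguous junction bases
    been assigned to the 3′ partner instead of the 5′ one.

    Per-record ambiguity length is data; this diagnostic surfaces every
    record whose frame/UTR call hinges on the assignment convention.
    """
    flagged = []
    for rec in db.records:
        k = len(rec.ambiguous_junction_bases)
        if (
            k == 0
            or rec.resolution != "nucleotide"
            or not rec.has_both_coordinates
            or rec.five_prime_accession not in refs
            or rec.three_prime_accession not in refs
        ):
            continue
        ref5 = refs[rec.five_prime_accession]
        ref3 = refs[rec.three_prime_accession]
        try:
            cat5 = classify_fusion(
                ref5, rec.five_prime_last_base + k, ref3, rec.three_prime_first_base
            ).category
            cat3 = classify_fusion(
                ref5, rec.five_prime_last_base, ref3, rec.three_prime_first_base - k
            ).category
        except AnnotationError:
            flagged.append(rec.case_id)
            continue
        if cat5 != cat3:
            flagged.append(rec.case_id)
    return flagged


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def annotations_to_dataframe(results: list[AnnotatedRecord]):
    """Flat tabular export, one column per domain status."""
    import pandas as pd

    domain_keys = sorted(
        {
            k
            for res in results
            if res.annotation is not None
            for k in res.annotation.domain_status_genomic
        }
    )
    rows = []
    for res in results:
        row = {
            "case_id": res.record.case_id,
            "three_prime_gene": res.record.three_prime_gene,
            "status": res.status,
            "reason": res.reason,
            "category": res.annotation.category if res.annotation else None,
            "phase5": res.annotation.phase5 if res.annotation else None,
            "phase3": res.annotation.phase3 if res.annotation else None,
        }
        ann = res.annotation
        if ann is not None and ann.protein is not None:
            row["stop_origin"] = ann.protein.stop_origin
            row["junction_to_stop_nt"] = ann.protein.junction_to_stop_nt
        else:
            row["stop_origin"] = None
            row["junction_to_stop_nt"] = None
        for k in domain_keys:
            row[f"genomic[{k}]"] = (
                ann.domain_status_genomic.get(k) if ann is not None else None
            )
            row[f"protein[{k}]"] = (
                ann.domain_status_protein.get(k) if ann is not None else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations_jsonl(results: list[AnnotatedRecord], path) -> None:
    import json

    with open(path, "w") as fh:
        for res in results:
            ann = res.annotation
            row = {
                "case_id": res.record.case_id,
                "status": res.status,
                "reason": res.reason,
            }
            if ann is not None:
                row.update(
                    category=ann.category,
                    n5_cds=ann.n5_cds,
                    phase5=ann.phase5,
                    p3_cds=ann.p3_cds,
                    phase3=ann.phase3,
                    domain_status_genomic=ann.domain_status_genomic,
                    domain_status_protein=ann.domain_status_protein,
                )
                if ann.protein is not None:
                    row["protein"] = {
                        "sequence": ann.protein.sequence,
                        "junction_residue_index": ann.protein.junction_residue_index,
                        "stop_origin": ann.protein.stop_origin,
                        "junction_to_stop_nt": ann.protein.junction_to_stop_nt,
                    }
            fh.write(json.dumps(row) + "\n")
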