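"""Synthetic transcript references and breakpoint cohorts with known labels.

The generator emulates the statistical structure of the curated CIC-fusion
cohort: a fixed 5′ gene fused to a mix of 3′ partners, a configurable share
of 3′-UTR fusions, an in-frame share among genuine coding fusions, and a
domain-retention share among the in-frame ("bona fide") records.  Its default
composition is the published CIC::DUX4 analysis set — 74 RNA-derived
nucleotide-level junctions of which 32 are UTR fusions, 37 of the remaining
42 are in-frame, and 32 of those 37 retain the 5′ C1 domain.

Class counts follow deterministic largest-remainder apportionment of the
configured proportions (never multinomial draws), so the realized cohort
composition is *exact* and summary-level checks need no tolerances.  Each
record's label is drawn first and the junction coordinates are then
constructed to realize it; the emitted labels are the pipeline's test oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotate import DISRUPTED, IN_FRAME, LOST, OUT_OF_FRAME, RETAINED, UTR_FUSION
from .breakpoints import BreakpointRecord, HarmonizedDatabase
from .reference import (
    SENSE_CODONS,
    DomainAnnotation,
    TranscriptReference,
    domain_nt_interval,
)


class SimulationError(ValueError):
    """A configured label combination cannot be realized on the references."""


def largest_remainder(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Apportion ``n`` items to keys exactly, by largest remainder.

    Quotas are floored and the leftover items go to the largest fractional
    parts; ties break on key order for determinism.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    total = sum(proportions.values())
    if total <= 0:
        raise ValueError("proportions must sum to a positive value")
    keys = list(proportions)
    quotas = {k: n * proportions[k] / total for k in keys}
    counts = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), keys.index(k)))
    for k in by_remainder[:leftover]:
        counts[k] += 1
    return counts


def make_toy_reference(
    gene_symbol: str,
    utr5_len: int,
    n_codons: int,
    utr3_len: int,
    domains: Sequence[DomainAnnotation] = (),
    seed: int = 0,
    accession: Optional[str] = None,
) -> TranscriptReference:
    """Random toy transcript: the CDS opens with ATG, closes with TAA, and
    its internal codons are drawn uniformly from the 61 sense codons (no
    internal stops).  Deterministic under ``seed``."""
    if n_codons < 3:
        raise SimulationError("n_codons must be >= 3")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    utr5 = "".join(rng.choice(bases, size=utr5_len)) if utr5_len else ""
    utr3 = "".join(rng.choice(bases, size=utr3_len)) if utr3_len else ""
    internal = "".join(
        rng.choice(np.array(SENSE_CODONS), size=n_codons - 2)
    )
    cds = "ATG" + internal + "TAA"
    return TranscriptReference(
        accession=accession or f"SYN_{gene_symbol}.1",
        gene_symbol=gene_symbol,
        sequence=utr5 + cds + utr3,
        cds_start=utr5_len + 1,
        cds_end=utr5_len + 3 * n_codons,
        domains=tuple(domains),
    )


#: toy reference shapes: (utr5_len, n_codons, utr3_len, domains).  Scaled-down
#: stand-ins for the real transcripts, preserving the topology that matters —
#: a long 5′ gene with mid-CDS and C-terminal DNA-binding domains, partners
#: with homeodomains/transactivation regions and (for the UTR-fusion partner)
#: a long 3′ UTR.
DEFAULT_REFERENCE_SHAPES: dict[str, tuple[int, int, int, tuple[DomainAnnotation, ...]]] = {
    "CIC": (
        60,
        200,
        90,
        (
            DomainAnnotation("EBD", 20, 35, "synthetic"),
            DomainAnnotation("HMG", 50, 70, "synthetic"),
            DomainAnnotation("C1", 150, 170, "synthetic"),
        ),
    ),
    "DUX4": (
        30,
        140,
        220,
        (
            DomainAnnotation("HOX1", 10, 30, "synthetic"),
            DomainAnnotation("HOX2", 45, 65, "synthetic"),
            DomainAnnotation("TAD", 110, 135, "synthetic"),
        ),
    ),
    "NUTM1": (40, 180, 60, (DomainAnnotation("AD", 100, 130, "synthetic"),)),
    "LEUTX": (25, 100, 80, (DomainAnnotation("HOX", 20, 45, "synthetic"),)),
    "FOXO4": (35, 120, 70, (DomainAnnotation("FH", 30, 60, "synthetic"),)),
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the published CIC::DUX4 analysis-set composition
    (74 records: 32/74 UTR fusions, 37/42 in-frame among coding, 32/37
    C1-retaining among in-frame).
    """

    seed: int = 0
    n_records: int = 74
    five_prime_gene: str = "CIC"
    partner_mix: dict[str, float] = field(default_factory=lambda: {"DUX4": 1.0})
    frac_utr_fusion: float = 32 / 74
    frac_in_frame_given_coding: float = 37 / 42
    domain_retention_target: dict[str, float] = field(
        default_factory=lambda: {"C1": 32 / 37}
    )
    #: short junction microhomology is common in RT-PCR-derived junction
    #: sequences; most junctions are unambiguous, a minority carry 1–3 bases
    ambiguous_base_length_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05}
    )
    reference_shapes: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_SHAPES)
    )
    evidence_source: str = "RNA"

    def __post_init__(self) -> None:
        for name, p in [
            ("frac_utr_fusion", self.frac_utr_fusion),
            ("frac_in_frame_given_coding", self.frac_in_frame_given_coding),
            *[(f"retention[{k}]", v) for k, v in self.domain_retention_target.items()],
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if abs(sum(self.partner_mix.values()) - 1.0) > 1e-9:
            raise ValueError("partner_mix must sum to 1")
        if abs(sum(self.ambiguous_base_length_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("ambiguous_base_length_distribution must sum to 1")
        if len(self.domain_retention_target) > 1:
            raise ValueError(
                "exactly one focal 5' domain retention target is supported"
            )


@dataclass(frozen=True)
class TruthLabel:
    category: str
    phase5: Optional[int]
    phase3: Optional[int]
    domain_status: dict[str, str]


@dataclass
class TruthLabels:
    by_case: dict[str, TruthLabel]

    def write_json(self, path: Path | str) -> None:
        out = {
            case: {
                "category": lab.category,
                "phase5": lab.phase5,
                "phase3": lab.phase3,
                "domain_status": lab.domain_status,
            }
            for case, lab in self.by_case.items()
        }
        Path(path).write_text(json.dumps(out, indent=2) + "\n")


def build_references(config: SimulationConfig) -> dict[str, TranscriptReference]:
    """Toy references for the 5′ gene and every configured partner, each
    deterministically seeded from ``config.seed``."""
    genes = [config.five_prime_gene] + sorted(config.partner_mix)
    refs = {}
    for i, gene in enumerate(genes):
        if gene not in config.reference_shapes:
            raise SimulationError(f"no reference shape configured for {gene}")
        utr5, n_codons, utr3, domains = config.reference_shapes[gene]
        sub_seed = (config.seed * 1000 + i) % (2**31 - 1)
        refs[gene] = make_toy_reference(gene, utr5, n_codons, utr3, domains, sub_seed)
    return refs


def _genomic_truth(
    ref5: TranscriptReference, bp5: int, ref3: TranscriptReference, bp3: int
) -> dict[str, str]:
    """Boundary-arithmetic domain statuses used as the generator's labels."""
    status = {}
    for dom in ref5.domains:
        d_s, d_e = domain_nt_interval(ref5, dom)
        status[f"{ref5.gene_symbol}:{dom.name}"] = (
            RETAINED if bp5 >= d_e else DISRUPTED if bp5 >= d_s else LOST
        )
    for dom in ref3.domains:
        d_s, d_e = domain_nt_interval(ref3, dom)
        status[f"{ref3.gene_symbol}:{dom.name}"] = (
            RETAINED if bp3 <= d_s else DISRUPTED if bp3 <= d_e else LOST
        )
    return status


def _choice(rng: np.random.Generator, lo: int, hi: int, constraint: str) -> int:
    """Uniform integer in [lo, hi]; names the violated constraint when empty."""
    if hi < lo:
        raise SimulationError(f"empty breakpoint range for constraint: {constraint}")
    return int(rng.integers(lo, hi + 1))


def simulate_cohort(
    config: SimulationConfig,
    refs: Mapping[str, TranscriptReference] | None = None,
) -> tuple[HarmonizedDatabase, TruthLabels]:
    """Generate a cohort realizing the configured composition exactly.

    For each record the target label is fixed first (category, and for
    in-frame records the focal-domain retention state), then junction
    coordinates are sampled to realize it: in-frame junctions pair a CDS
    position on the 5′ gene with a phase-matched CDS entry on the partner
    (keeping the partner's stop codon intact), out-of-frame junctions use a
    mismatched phase, and UTR fusions enter the partner's 3′ UTR.  Ambiguous
    junction bases, when emitted, are taken verbatim from the 5′ reference at
    the extension positions and the stored 5′ coordinate is rolled back
    accordingly, so harmonization restores the constructed junction.
    """
    rng = np.random.default_rng(config.seed)
    if refs is None:
        refs = build_references(config)
    ref5 = refs[config.five_prime_gene]

    focal = None
    if config.domain_retention_target:
        name, prop = next(iter(config.domain_retention_target.items()))
        focal = (name, prop, domain_nt_interval(ref5, ref5.domain(name)))

    partner_counts = largest_remainder(config.n_records, config.partner_mix)
    amb_lengths = sorted(config.ambiguous_base_length_distribution)
    amb_probs = [config.ambiguous_base_length_distribution[k] for k in amb_lengths]

    records: list[BreakpointRecord] = []
    labels: dict[str, TruthLabel] = {}
    case_no = 0
    for partner in sorted(partner_counts):
        n_p = partner_counts[partner]
        if n_p == 0:
            continue
        ref3 = refs[partner]
        cat_counts = largest_remainder(
            n_p,
            {UTR_FUSION: config.frac_utr_fusion, "coding": 1 - config.frac_utr_fusion},
        )
        frame_counts = largest_remainder(
            cat_counts["coding"],
            {
                IN_FRAME: config.frac_in_frame_given_coding,
                OUT_OF_FRAME: 1 - config.frac_in_frame_given_coding,
            },
        )
        plan: list[tuple[str, Optional[bool]]] = [
            (UTR_FUSION, None)
        ] * cat_counts[UTR_FUSION]
        if focal is not None:
            ret_counts = largest_remainder(
                frame_counts[IN_FRAME], {RETAINED: focal[1], "other": 1 - focal[1]}
            )
            plan += [(IN_FRAME, True)] * ret_counts[RETAINED]
            plan += [(IN_FRAME, False)] * ret_counts["other"]
        else:
            plan += [(IN_FRAME, None)] * frame_counts[IN_FRAME]
        plan += [(OUT_OF_FRAME, None)] * frame_counts[OUT_OF_FRAME]

        for category, retain in plan:
            case_no += 1
            case_id = f"SIM-{case_no:04d}"
            if category == UTR_FUSION:
                bp5 = _choice(
                    rng, ref5.cds_start, ref5.cds_end - 1, "5' breakpoint in CDS"
                )
                bp3 = _choice(
                    rng,
                    ref3.cds_end + 1,
                    len(ref3),
                    f"3' UTR breakpoint on {partner}",
                )
                phase3 = None
                phase5 = (bp5 - ref5.cds_start + 1) % 3
            else:
                if retain is True:
                    # 5' junction at/after the focal domain's last nucleotide
                    bp5 = _choice(
                        rng,
                        focal[2][1],
                        ref5.cds_end - 1,
                        f"{focal[0]}-retaining 5' breakpoint",
                    )
                elif retain is False:
                    bp5 = _choice(
                        rng,
                        ref5.cds_start,
                        focal[2][1] - 1,
                        f"non-{focal[0]}-retaining 5' breakpoint",
                    )
                else:
                    bp5 = _choice(
                        rng, ref5.cds_start, ref5.cds_end - 1, "5' breakpoint in CDS"
                    )
                phase5 = (bp5 - ref5.cds_start + 1) % 3
                if category == IN_FRAME:
                    # phase-matched CDS entry, partner stop codon kept intact
                    first = ref3.cds_start + phase5
                    candidates = range(first, ref3.cds_end - 2 + 1, 3)
                    if len(candidates) == 0:
                        raise SimulationError(
                            f"no phase-{phase5} in-frame entry on {partner}"
                        )
                    bp3 = int(rng.choice(list(candidates)))
                else:
                    shift = int(rng.integers(1, 3))  # 1 or 2 → guaranteed mismatch
                    first = ref3.cds_start + (phase5 + shift) % 3
                    candidates = range(first, ref3.cds_end - 2 + 1, 3)
                    if len(candidates) == 0:
                        raise SimulationError(
                            f"no out-of-frame entry on {partner}"
                        )
                    bp3 = int(rng.choice(list(candidates)))
                phase3 = (bp3 - ref3.cds_start) % 3

            k = int(rng.choice(amb_lengths, p=amb_probs))
            k = min(k, bp5 - 1)  # never roll the stored coordinate below 1
            ambiguous = ref5.sequence[bp5 - k : bp5] if k else ""

            records.append(
                BreakpointRecord(
                    case_id=case_id,
                    publication_id="SIM",
                    five_prime_gene=config.five_prime_gene,
                    three_prime_gene=partner,
                    evidence_source=config.evidence_source,
                    resolution="nucleotide",
                    five_prime_last_base=bp5 - k,
                    three_prime_first_base=bp3,
                    ambiguous_junction_bases=ambiguous,
                    five_prime_accession=ref5.accession,
                    three_prime_accession=ref3.accession,
                    notes="synthetic",
                )
            )
            labels[case_id] = TruthLabel(
                category=category,
                phase5=phase5,
                phase3=phase3,
                domain_status=_genomic_truth(ref5, bp5, ref3, bp3),
            )

    db = HarmonizedDatabase(
        records,
        provenance=f"simulated cohort (seed={config.seed}, n={config.n_records})",
    )
    return db, TruthLabels(labels)
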