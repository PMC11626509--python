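"""Cohort-level statistics and plot-ready views of an annotated breakpoint set.

The analysis set mirrors the cohort arithmetic of the harmonized CIC-fusion
database: nucleotide-level, RNA-derived records with both junction
coordinates (optionally restricted to one 3′ partner).  The partition is

    analysis set = UTR fusions + coding fusions (+ other geometries)
    coding fusions = in-frame + out-of-frame

and a *bona fide* fusion is an in-frame coding fusion.  Domain-retention
fractions are reported among in-frame records, from the genomic
(breakpoint-position) call — a 5′ breakpoint after the domain's 3′ nucleotide
end retains the domain.

Every fraction carries its numerator and denominator explicitly (the same
paragraph of cohort arithmetic legitimately uses several denominators), and
the integer-percent display uses round-half-up, never altering the stored
exact counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .annotate import (
    IN_FRAME,
    OUT_OF_FRAME,
    RETAINED,
    UTR_FUSION,
    AnnotatedRecord,
)
from .reference import TranscriptReference, domain_nt_interval


def percent_display(numerator: int, denominator: int) -> int:
    """Integer percent with exact round-half-up (e.g. 32/74 → 43)."""
    if denominator == 0:
        return 0
    p = Fraction(100 * numerator, denominator)
    return int(p + Fraction(1, 2)) if p >= 0 else -int(-p + Fraction(1, 2))


@dataclass
class CohortFraction:
    numerator: int
    denominator: int

    @property
    def value(self) -> float:
        return self.numerator / self.denominator if self.denominator else 0.0

    @property
    def percent(self) -> int:
        return percent_display(self.numerator, self.denominator)


@dataclass
class CohortSummary:
    n_total_nucleotide: int
    n_total_exon: int
    n_by_partner: dict[str, int]
    n_analysis_set: int
    n_utr_fusion: int
    n_non_utr: int
    n_in_frame: int
    n_out_of_frame: int
    n_other_categories: dict[str, int]
    n_domain_retained: dict[str, int]
    fractions: dict[str, CohortFraction]
    filter_provenance: str = ""
    caveats: tuple[str, ...] = (
        "breakpoint discovery in the source literature is subject to "
        "PCR-primer ascertainment bias; no correction is applied",
    )

    def to_dict(self) -> dict:
        return {
            "n_total_nucleotide": self.n_total_nucleotide,
            "n_total_exon": self.n_total_exon,
            "n_by_partner": self.n_by_partner,
            "n_analysis_set": self.n_analysis_set,
            "n_utr_fusion": self.n_utr_fusion,
            "n_non_utr": self.n_non_utr,
            "n_in_frame": self.n_in_frame,
            "n_out_of_frame": self.n_out_of_frame,
            "n_other_categories": self.n_other_categories,
            "n_domain_retained": self.n_domain_retained,
            "fractions": {
                name: {
                    "numerator": f.numerator,
                    "denominator": f.denominator,
                    "value": f.value,
                    "percent_display": f.percent,
                }
                for name, f in self.fractions.items()
            },
            "filter_provenance": self.filter_provenance,
            "caveats": list(self.caveats),
        }


def _in_analysis_set(
    res: AnnotatedRecord, partner: Optional[str], evidence_source: str
) -> bool:
    rec = res.record
    return (
        res.status == "ok"
        and rec.resolution == "nucleotide"
        and rec.evidence_source == evidence_source
        and rec.has_both_coordinates
        and (partner is None or rec.three_prime_gene == partner)
    )


def summarize(
    results: list[AnnotatedRecord],
    partner: Optional[str] = None,
    focal_domains: Iterable[str] = (),
    evidence_source: str = "RNA",
) -> CohortSummary:
    """Partition an annotated cohort into the summary counts and fractions.

    ``focal_domains`` are gene-qualified names (e.g. ``"CIC:C1"``) whose
    genomic retention is counted among in-frame records.  An empty analysis
    set yields a summary of zeros, never an error.
    """
    focal_domains = tuple(focal_domains)
    n_by_partner: dict[str, int] = {}
    n_nt = n_ex = 0
    for res in results:
        rec = res.record
        n_by_partner[rec.three_prime_gene] = n_by_partner.get(rec.three_prime_gene, 0) + 1
        if rec.resolution == "nucleotide":
            n_nt += 1
        elif rec.resolution == "exon":
            n_ex += 1

    analysis = [r for r in results if _in_analysis_set(r, partner, evidence_source)]
    n_analysis = len(analysis)
    n_utr = sum(1 for r in analysis if r.annotation.category == UTR_FUSION)
    n_in = sum(1 for r in analysis if r.annotation.category == IN_FRAME)
    n_out = sum(1 for r in analysis if r.annotation.category == OUT_OF_FRAME)
    n_non_utr = n_in + n_out
    n_other: dict[str, int] = {}
    for r in analysis:
        cat = r.annotation.category
        if cat not in (UTR_FUSION, IN_FRAME, OUT_OF_FRAME):
            n_other[cat] = n_other.get(cat, 0) + 1

    n_retained: dict[str, int] = {}
    for dom in focal_domains:
        n_retained[dom] = sum(
            1
            for r in analysis
            if r.annotation.category == IN_FRAME
            and r.annotation.domain_status_genomic.get(dom) == RETAINED
        )

    fractions = {
        "utr_fusion_of_analysis_set": CohortFraction(n_utr, n_analysis),
        "in_frame_of_non_utr": CohortFraction(n_in, n_non_utr),
    }
    for dom, k in n_retained.items():
        fractions[f"{dom}_retained_of_in_frame"] = CohortFraction(k, n_in)

    prov = (
        f"analysis set: nucleotide-level, {evidence_source} evidence, "
        f"both coordinates, partner={partner or 'any'}"
    )
    return CohortSummary(
        n_total_nucleotide=n_nt,
        n_total_exon=n_ex,
        n_by_partner=n_by_partner,
        n_analysis_set=n_analysis,
        n_utr_fusion=n_utr,
        n_non_utr=n_non_utr,
        n_in_frame=n_in,
        n_out_of_frame=n_out,
        n_other_categories=n_other,
        n_domain_retained=n_retained,
        fractions=fractions,
        filter_provenance=prov,
    )


@dataclass
class BreakpointScatterData:
    """One row per annotated nucleotide-level record in the analysis set,
    ordered by (partner gene, 5′ coordinate, case id)."""

    table: pd.DataFrame
    domain_tracks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    reference_lengths: dict[str, int] = field(default_factory=dict)
    cds_spans: dict[str, tuple[int, int]] = field(default_factory=dict)


def scatter_data(
    results: list[AnnotatedRecord],
    refs: Mapping[str, TranscriptReference] | None = None,
    partner: Optional[str] = None,
    evidence_source: str = "RNA",
) -> BreakpointScatterData:
    rows = []
    for res in results:
        if not _in_analysis_set(res, partner, evidence_source):
            continue
        rec = res.record
        rows.append(
            {
                "case_id": rec.case_id,
                "partner_gene": rec.three_prime_gene,
                "five_prime_coord": rec.five_prime_last_base
                + len(rec.ambiguous_junction_bases),
                "three_prime_coord": rec.three_prime_first_base,
                "category": res.annotation.category,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "partner_gene",
            "five_prime_coord",
            "three_prime_coord",
            "category",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["partner_gene", "five_prime_coord", "case_id"], kind="stable"
        ).reset_index(drop=True)
    tracks: dict[str, list[tuple[str, int, int]]] = {}
    lengths: dict[str, int] = {}
    cds_spans: dict[str, tuple[int, int]] = {}
    if refs is not None:
        for ref in refs.values():
            lengths[ref.gene_symbol] = len(ref)
            cds_spans[ref.gene_symbol] = (ref.cds_start, ref.cds_end)
            tracks[ref.gene_symbol] = [
                (dom.name, *domain_nt_interval(ref, dom)) for dom in ref.domains
            ]
    return BreakpointScatterData(table, tracks, lengths, cds_spans)


# ---------------------------------------------------------------------------
# rendering (presentation only — no statistic is computed here)
# ---------------------------------------------------------------------------

_CATEGORY_COLORS = {
    IN_FRAME: "#1f77b4",
    OUT_OF_FRAME: "#d62728",
    UTR_FUSION: "#ff7f0e",
}


def render_plots(
    scatter: BreakpointScatterData,
    summary: CohortSummary,
    outdir: Path | str,
    five_prime_gene: str = "CIC",
) -> list[Path]:
    """Write a breakpoint scatterplot (with domain tracks and marginal
    histograms) and an arc-style partner plot.  Returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    outdir = Path(outdir)
    if not outdir.exists():
        outdir.mkdir(parents=True)
    if not outdir.is_dir():
        raise NotADirectoryError(str(outdir))

    df = scatter.table
    partners = sorted(df["partner_gene"].unique()) if len(df) else []
    partner = partners[0] if len(partners) == 1 else None

    # --- scatter with marginals -------------------------------------------
    fig = plt.figure(figsize=(7, 7))
    gs = fig.add_gridspec(
        2, 2, width_ratios=(5, 1), height_ratios=(1, 5), hspace=0.05, wspace=0.05
    )
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    for a in (ax_top, ax_right):
        a.tick_params(labelbottom=False, labelleft=False)
    if len(df):
        for cat, sub in df.groupby("category"):
            ax.scatter(
                sub["five_prime_coord"],
                sub["three_prime_coord"],
                s=18,
                alpha=0.7,
                label=cat,
                color=_CATEGORY_COLORS.get(cat, "#7f7f7f"),
            )
        ax_top.hist(df["five_prime_coord"], bins=30, color="#999999")
        ax_right.hist(
            df["three_prime_coord"], bins=30, orientation="horizontal", color="#999999"
        )
        ax.legend(fontsize=7, loc="lower right")
    for name, s, e in scatter.domain_tracks.get(five_prime_gene, []):
        ax.axvspan(s, e, color="#2ca02c", alpha=0.15)
        ax.text(s, ax.get_ylim()[1], name, fontsize=6, va="top", rotation=90)
    if partner is not None:
        for name, s, e in scatter.domain_tracks.get(partner, []):
            ax.axhspan(s, e, color="#9467bd", alpha=0.15)
    ax.set_xlabel(f"{five_prime_gene} transcript position (nt)")
    ax.set_ylabel(f"{partner or '3prime partner'} transcript position (nt)")
    scatter_path = outdir / "breakpoint_scatter.png"
    fig.savefig(scatter_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    # --- arc-style partner plot -------------------------------------------
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"aspect": "equal"})
    genes = [five_prime_gene] + [g for g in scatter.reference_lengths if g != five_prime_gene]
    lengths = {g: scatter.reference_lengths.get(g, 1) for g in genes}
    total = sum(lengths.values()) or 1
    gap = 0.03 * 2 * np.pi
    spans: dict[str, tuple[float, float]] = {}
    theta = 0.0
    usable = 2 * np.pi - gap * len(genes)
    for g in genes:
        width = usable * lengths[g] / total
        spans[g] = (theta, theta + width)
        mid = theta + width / 2
        arc = np.linspace(theta, theta + width, 64)
        ax.plot(np.cos(arc), np.sin(arc), lw=8, solid_capstyle="butt")
        ax.text(1.18 * np.cos(mid), 1.18 * np.sin(mid), g, ha="center", va="center")
        theta += width + gap

    def angle(gene: str, coord: int) -> float:
        a, b = spans.get(gene, (0.0, 0.0))
        return a + (b - a) * coord / max(lengths.get(gene, 1), 1)

    for _, row in df.iterrows():
        t1 = angle(five_prime_gene, row["five_prime_coord"])
        t2 = angle(row["partner_gene"], row["three_prime_coord"])
        p0 = np.array([np.cos(t1), np.sin(t1)])
        p2 = np.array([np.cos(t2), np.sin(t2)])
        ts = np.linspace(0, 1, 50)[:, None]
        bez = (1 - ts) ** 2 * p0 + 2 * ts * (1 - ts) * 0 + ts**2 * p2
        ax.plot(
            bez[:, 0],
            bez[:, 1],
            lw=0.6,
            alpha=0.5,
            color=_CATEGORY_COLORS.get(row["category"], "#7f7f7f"),
        )
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.axis("off")
    arc_path = outdir / "breakpoint_arcs.png"
    fig.savefig(arc_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return [scatter_path, arc_path]


def write_summary(summary: CohortSummary, path: Path | str) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def summary_to_tsv(summary: CohortSummary, path: Path | str) -> None:
    rows = [
        ("n_total_nucleotide", summary.n_total_nucleotide, "", ""),
        ("n_total_exon", summary.n_total_exon, "", ""),
        ("n_analysis_set", summary.n_analysis_set, "", ""),
        ("n_utr_fusion", summary.n_utr_fusion, "", ""),
        ("n_non_utr", summary.n_non_utr, "", ""),
        ("n_in_frame", summary.n_in_frame, "", ""),
        ("n_out_of_frame", summary.n_out_of_frame, "", ""),
    ]
    for name, f in summary.fractions.items():
        rows.append((name, f"{f.numerator}/{f.denominator}", f.value, f.percent))
    with open(path, "w") as fh:
        fh.write("statistic\tcount\tfraction\tpercent_display\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
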