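# Methods

## Coordinate model

All transcript coordinates are 1-based and inclusive, following
GenBank/RefSeq convention, because curated fusion breakpoints are reported
against RefSeq mRNA records. The CDS span includes the stop codon
(`cds_end` is its last base) while protein length excludes it, matching how
RefSeq CDS features are written. Codon phase is `(nt − cds_start) mod 3`,
so phase 0 marks the first base of a codon. Protein domains are stored as
residue ranges and converted to nucleotide intervals on demand
(`nt_start = cds_start + 3(r_start − 1)`, `nt_end = cds_start + 3·r_end − 1`),
since domain boundaries in the literature are given as residues (e.g. the
CIC C1 domain R1464–M1519) while breakpoints are nucleotides.

Translation uses the standard genetic code only (no selenocysteine — not
needed for these genes). Codons containing `N` translate to `X` and never
count as stop codons; a trailing partial codon is ignored. An internal stop
inside an annotated CDS is a warning, not an error, because `N`-containing
records can mask sense codons.

## Junction convention and harmonization

A junction is the pair (last retained base of the 5′ partner, first retained
base of the 3′ partner). This is unambiguous under RefSeq coordinates and
matches how RT-PCR-derived junction sequences are reported; an ingest switch
converts tables encoded as "first lost base" (5′ column −1, 3′ column +1).

Junction reads often contain a few bases of microhomology that could belong
to either partner. Harmonization resolves all such ambiguous bases onto the
5′ partner — extending the 5′ coordinate by their count — *before* any frame
computation, because junction phase depends on the assignment. The operation
is idempotent; when a reference is available the ambiguous bases are checked
against it and a mismatch sets a warning flag rather than failing. A
diagnostic (`ambiguous_assignment_diagnostic`) lists every record whose
category would change under the opposite (3′) assignment, since the
literature does not report how often this matters.

Exon-level records are retained in the database but excluded from all
nucleotide-level computations (annotated with a `not_annotatable` sentinel):
exon numbering is not consistent across the references used by different
reports, so exon-level coordinates cannot be trusted for frame arithmetic.
Rows failing validation are collected into a reject report with reasons,
never silently dropped, so cohort denominators stay reproducible.

## Classification

Decision order: (1) 5′ breakpoint upstream of the 5′ CDS →
`five_prime_noncoding`; (2) 5′ breakpoint at/after the last base of the 5′
stop codon → `five_prime_readthrough` (the 5′ partner's own stop is
retained, so no fusion ORF extends into the partner); (3) 3′ entry in the
partner's 3′ UTR → `utr_fusion`; (4) 3′ entry in the partner's 5′ UTR →
`three_prime_upstream_of_cds`; (5) both in CDS → in-frame iff
`n5 mod 3 = (p3 − 1) mod 3`.

The phase rule is exact where both breakpoints are in CDS; the test suite
checks it against an independent brute-force oracle that builds the chimera
explicitly and asks whether the 3′ partner's native codon grid lands on the
fusion ORF's enumerated codon boundaries. The two definitions agree
everywhere, including the rare case where the junction-spanning hybrid codon
happens to spell a stop: such a record is still `in_frame_coding` (frame
membership is the definition), and its prediction reports
`stop_origin = premature`.

`three_prime_upstream_of_cds` is kept as a terminal category rather than
being refolded into in/out-of-frame: the in-frame invariant requires equal
phases, and phase is undefined outside the CDS. The frame outcome of these
(out-of-cohort, never observed in the curated data) geometries is recorded
on the protein prediction via `stop_origin` instead.

## Protein prediction and domain status

The chimeric mRNA is `ref5[1..bp5] ++ ref3[bp3..end]`, translated from the
5′ CDS start. `junction_residue_index = ⌊n5/3⌋ + 1` points at the first
junction- or 3′-derived residue; for junctions with non-zero phase the
hybrid codon's residue is assigned to the junction, which keeps residue
bookkeeping deterministic. The terminating stop is `native_3prime` only
when its chimeric position coincides with the 3′ partner's own stop codon
read in its native frame; `junction_to_stop_nt` is reported as a plain
number and no threshold defines "shortly after the breakpoint" — UTR
fusions frequently, but not definitionally, truncate at a nearby stop.

Genomic domain status on the 5′ side: `retained` iff `bp ≥ d_e` (a
breakpoint at the domain's last nucleotide preserves the full final codon —
this is the convention under which breakpoints "after the 3′ end" of a
domain count as retaining it), `disrupted` for `d_s ≤ bp < d_e`, else
`lost`; mirrored on the 3′ side. Protein-level status counts a domain
residue as present only when its native codon survives intact,
frame-aligned with the fusion ORF, and translates to its native amino acid;
an `X` from sequence uncertainty never counts, which conservatively demotes
`retained` to `disrupted` under ambiguity. The protein-level call therefore
sees premature stops that position arithmetic cannot.

## Cohort summary

The analysis set is: nucleotide-level, RNA-derived, both coordinates
present, optionally one partner gene. "Bona fide" fusions are the in-frame
coding records of that set. The summary stores every fraction as an exact
numerator/denominator pair because the headline arithmetic legitimately
uses three denominators in one breath (74 → 32 UTR → 42 coding → 37
in-frame → 32 C1-retaining); display percentages are round-half-up integers
(43%, 88%, 86%) and rounding never touches the stored counts. Plot
renderers are presentation-only — no statistic is computed inside them. The
arc-style partner plot is drawn directly with matplotlib. A fixed caveat in
the summary provenance notes that breakpoint discovery in the literature is
subject to PCR-primer ascertainment bias; no correction exists, so none is
applied.

## Synthetic cohorts

The generator's defaults are the study conditions of the curated CIC::DUX4
analysis set: n = 74, 32/74 UTR fusions, 37/42 in-frame among coding, 32/37
focal-domain-retaining among in-frame, partner mix 100% DUX4. Class counts
use deterministic largest-remainder apportionment (ties broken by key
order) rather than multinomial sampling, so the realized composition is
exact and summary-level tests need no tolerances. Each record's label is
drawn first and junction coordinates are then sampled to realize it:
in-frame junctions pair a 5′ CDS position with a phase-matched 3′ CDS entry
that keeps the partner's stop codon intact; out-of-frame junctions shift
the entry phase by 1 or 2; UTR fusions enter the partner's 3′ UTR.
Retention targets are realized by restricting the 5′ breakpoint to
`[d_e, cds_end − 1]` (retaining) or `[cds_start, d_e − 1]` (not); exactly
one focal 5′ domain target is supported per run, since several overlapping
retention constraints are jointly under-determined. An unrealizable
constraint (e.g. UTR fusions requested against a partner with no 3′ UTR)
raises an error naming the constraint.

Emitted ambiguous junction bases are taken verbatim from the 5′ reference
at the extension positions — mirroring how real junction reads share
sequence with both partners — and the stored 5′ coordinate is rolled back
by their count, so harmonization restores the constructed junction exactly;
lengths follow a configurable distribution defaulting to 0 bases 70% /
1 base 15% / 2 bases 10% / 3 bases 5%, a realistic microhomology profile
for RT-PCR junction reads. All randomness flows through one
`numpy.random.Generator` seeded by the single config seed; identical
configs emit byte-identical tables.

Toy references are scaled-down stand-ins (CDS of 100–200 codons versus
thousands in the real transcripts) that preserve the topology that matters:
a long 5′ gene with mid-CDS and C-terminal domains, partners with
N-terminal DNA-binding and C-terminal transactivation regions, and a long
3′ UTR on the UTR-fusion partner. What passing tests on synthetic cohorts
show is that the coordinate arithmetic, harmonization, classification, and
retention logic are exact; they do not exercise real-data pathologies such
as transcript-version drift between reports, mis-curated coordinates, or
reference/junction sequence disagreement beyond the simulated mismatch
flag.

## Quantitation helpers

ΔCt relative expression is 2^(Ct_housekeeping − Ct_target). Anchor
normalization maps the negative-control (EV) mean to 0% and the full-length
fusion (CD4) mean to 100%; equal anchor means are an error. Šidák
adjustment is 1 − (1 − p)^m computed via `expm1`/`log1p` to stay monotone
for very small p, with m the number of comparisons actually made
(caller-supplied). Technical replicates are averaged within an experiment
before experiment-level aggregation, since the order changes the effective
n of downstream tests. One-way ANOVA delegates to `scipy.stats.f_oneway`
after rejecting zero within-group variance (undefined F). Tumor volume is
the ellipsoid approximation (π/6)·l·w·h; crystal-violet totals are
(mean − background)·area. No published per-replicate raw values exist for
these assays, so this module is verified by its algebraic properties and
direct-arithmetic oracles only.

## Problem sizes

The test suite and acceptance script use toy references of ≤ 2,000 codons,
1,000 random junction pairs across five geometries for the oracle check,
and a grid of ~10 simulator configurations of 30–74 records; the full run
completes in a few seconds.
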