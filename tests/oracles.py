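"""Independent brute-force oracles used to check the classifier.

These deliberately avoid the package's phase arithmetic: frame membership is
decided by enumerating the codon-boundary positions of the fusion ORF over
the explicitly constructed chimeric sequence and asking whether the 3′
partner's native codon grid lands on them.
"""

from cicfusion.annotate import (
    FIVE_PRIME_NONCODING,
    FIVE_PRIME_READTHROUGH,
    IN_FRAME,
    OUT_OF_FRAME,
    THREE_PRIME_UPSTREAM,
    UTR_FUSION,
)


def oracle_category(ref5, bp5, ref3, bp3):
    if bp5 < ref5.cds_start:
        return FIVE_PRIME_NONCODING
    if bp5 >= ref5.cds_end:
        return FIVE_PRIME_READTHROUGH
    if bp3 > ref3.cds_end:
        return UTR_FUSION
    if bp3 < ref3.cds_start:
        return THREE_PRIME_UPSTREAM

    chimera = ref5.sequence[:bp5] + ref3.sequence[bp3 - 1 :]
    # first intact native codon of the 3' partner at or after the junction
    c0 = bp3
    while (c0 - ref3.cds_start) % 3 != 0:
        c0 += 1
    chim_pos = bp5 + (c0 - bp3) + 1
    codon_starts = set(range(ref5.cds_start, len(chimera) + 3, 3))
    return IN_FRAME if chim_pos in codon_starts else OUT_OF_FRAME


def manual_anova_ss(groups):
    """Textbook sum-of-squares arithmetic for one-way ANOVA."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        (v - sum(g) / len(g)) ** 2 for g in groups for v in g
    )
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)
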