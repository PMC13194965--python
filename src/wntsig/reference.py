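"""Published reference statistics for worked examples.

The study this pipeline operationalizes reported, for eight Wnt-reporter-
derived gene sets (up- or down-regulated DEGs of each cell line x serum
comparison), the pairwise studentized-range ("HSD") statistics separating
the MLIA subtype from LAR, BLIA and BLIS in a 699-tumor TNBC cohort.  The
underlying cohort is not public, but the printed statistics themselves are
valid inputs to the minimum-HSD summary and the discriminatory ranking; they
serve as worked examples and regression anchors.
"""

from __future__ import annotations

from .discrimination import HSDSummary, PairStat, min_hsd_summary

__all__ = [
    "REFERENCE_SUBTYPE_SIZES",
    "REFERENCE_FOCAL_SUBTYPE",
    "REFERENCE_HSD_PAIRS",
    "reference_hsd_summaries",
]

#: Sample sizes of the reference TNBC cohort (n = 699).
REFERENCE_SUBTYPE_SIZES = {"LAR": 137, "MLIA": 121, "BLIA": 199, "BLIS": 242}
REFERENCE_FOCAL_SUBTYPE = "MLIA"

#: Gene set name -> pairwise HSD statistic for MLIA vs (LAR, BLIA, BLIS),
#: as published.  Names encode: rank index, cell line, direction, serum.
REFERENCE_HSD_PAIRS: dict[str, dict[str, float]] = {
    "1_231_up_low":        {"LAR": 9.2960,  "BLIA": 12.0883, "BLIS": 12.4921},
    "2_231_down_low":      {"LAR": 7.4858,  "BLIA": 15.8397, "BLIS": 9.2341},
    "3_436_up_low":        {"LAR": 11.2013, "BLIA": 17.8621, "BLIS": 11.8320},
    "4_436_down_low":      {"LAR": 6.1634,  "BLIA": 9.3091,  "BLIS": 7.0964},
    "5_231_up_standard":   {"LAR": 9.9889,  "BLIA": 13.3504, "BLIS": 13.5261},
    "6_231_down_standard": {"LAR": 8.1561,  "BLIA": 14.7582, "BLIS": 5.4800},
    "7_436_up_standard":   {"LAR": 10.6394, "BLIA": 17.4561, "BLIS": 11.3186},
    "8_436_down_standard": {"LAR": 6.0908,  "BLIA": 8.0855,  "BLIS": 10.1611},
}


def reference_hsd_summaries() -> list[tuple[str, HSDSummary]]:
    """The published pairwise statistics as focal-summarized HSD objects.

    Adjusted p-values are not part of the published table, so each pair
    carries ``p = NaN``; the minimum-HSD summary and ranking depend only
    on the q statistics.
    """
    out = []
    for name, row in REFERENCE_HSD_PAIRS.items():
        pairs = [
            PairStat(group_i=REFERENCE_FOCAL_SUBTYPE, group_j=other, q=q)
            for other, q in row.items()
        ]
        out.append((name, min_hsd_summary(pairs, REFERENCE_FOCAL_SUBTYPE)))
    return out
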