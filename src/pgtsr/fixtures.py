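"""In-study worked-example fixtures for the two PGT-SR pedigrees.

Two balanced-reciprocal-translocation carriers: patient 1 with
46,XX,t(2;5)(q14.2;p13.1) and patient 2 with 46,XY,t(13;17)(q11;q11.2).
The fixtures hold the published per-embryo karyotype strings of the reference
embryos (verbatim), the windowed breakpoint localizations from the embryo
copy-number analysis, and the single-base breakpoints from split long reads.

Coordinates assume GRCh37.  Values not published as coordinates (the
non-tabulated embryos' statuses, and per-embryo segment coordinates) are
SYNTHETIC ENCODINGS of the described results, built from the window centers
and chromosome ends; they are marked as such and no test asserts their
invented band/size tokens.
"""
from __future__ import annotations

from .cnv import CopyNumberSegment, KaryotypeCall, parse_karyotype_string
from .genome import TranslocationSpec

#: GRCh37 chromosome lengths for the chromosomes involved
GRCH37_LENGTHS = {
    "chr2": 243_199_373,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr13": 115_169_878,
    "chr17": 81_195_210,
}

PATIENT_SPECS = {
    "patient1": TranslocationSpec(
        chrom_a="chr2", chrom_b="chr5",
        bp_a=125_157_514, bp_b=35_465_883,
        arm_a="q", arm_b="p", carrier_parent="maternal",
        band_a="q14.2", band_b="p13.1"),
    "patient2": TranslocationSpec(
        chrom_a="chr13", chrom_b="chr17",
        bp_a=26_208_296, bp_b=33_942_282,
        arm_a="q", arm_b="q", carrier_parent="paternal",
        band_a="q11", band_b="q11.2"),
}

#: verbatim published karyotype strings of the reference embryos
TABLE1_STRINGS = {
    "patient1": {
        "B": "46, XN, +2q(q14.3→q37.3,~118Mb,×3), -5p(pter→p13.2,~35Mb,×1)",
        "F": "46, XN, -2q(q14.3→q14.3,~5Mb,×1), -2q(q21.1→q37.1,~104Mb,×1), "
             "-2q(q37.1→q37.3,~8Mb,×1), +5p(pter→p13.2,~35Mb,×3)",
        "G": "46, XN, -2q(q14.3→q37.3,~118Mb,×1), +5p(p15.33→p13.2,~34Mb,×3), "
             "+6q(q11.1→q14.1,~20Mb,×3,mos,~31%), -10q(q24.2→q25.1,~11Mb,×1,mos,~33%)",
        "H": "46, XN, +2q(q14.3→q37.3,~118Mb,×3), -5p(pter→p13.2,~35Mb,×1)",
        "K": "46, XX, +Xp(p21.3→p11.4,~14Mb,×3,mos,~31%), -2q(q14.3→q37.3,~118Mb,×1), "
             "+5p(pter→p13.2,~35Mb,×3)",
    },
    "patient2": {
        "D": "46, XN, -13q(q12.13→q34,~88Mb,×1), +14q(q22.1→q32.33,~52Mb,×3,mos,~51%), "
             "+17q(q12→q25.3,~46Mb,×3)",
        "E": "46, XN, -5p(pter→p15.1,~16Mb,×1), -13q(q12.11→q12.12,~6Mb,×1), "
             "+17p(×3), +17q(q11.2→q12,~8Mb,×3)",
        "G": "46, XN, +13q(q12.13→q34,~88Mb,×3), -17q(q12→q25.3,~46Mb,×1)",
        "H": "46, XN, -13q(q12.13→q34,~88Mb,×1), +17q(q12→q25.3,~46Mb,×3)",
        "I": "46, XN, +13q(q12.13→q34,~88Mb,×3), -17q(q12→q25.3,~46Mb,×1)",
    },
}

#: SYNTHETIC ENCODINGS of the non-tabulated embryos' described statuses
#: (euploid embryos are empty calls; the abnormal ones get placeholder segment
#: tokens with invented bands/sizes that only convey which chromosome was hit
#: and whether the event was mosaic)
OTHER_EMBRYO_STRINGS = {
    "patient1": {
        "A": "46, XN, -1q(×1)",                       # abnormal chromosome 1
        "C": "46, XN",
        "D": "46, XN",
        "E": "46, XN",
        "I": "46, XN, +15p(×3,mos,~30%)",             # trisomy 15p mosaicism
        "J": "46, XN",
    },
    "patient2": {
        "A": "46, XN",
        "B": "46, XN",
        "C": "46, XN",
        "F": "46, XN, -6q(×1)",                       # monosomy 6q
        "J": "46, XN, -7p(×1), -7q(×1)",              # monosomy 7
        "K": "46, XN, -10q(q21.1→q22.1,~10Mb,×1,mos,~40%)",  # monosomy 10q mosaicism
        "L": "46, XN",
    },
}

#: published windowed breakpoint localizations (center ± half-window, bp)
CNV_WINDOWS = {
    "patient1": {"chr2": (125_200_001, 200_000), "chr5": (35_500_001, 200_000)},
    "patient2": {"chr13": (26_200_001, 200_000), "chr17": (34_000_001, 200_000)},
}

#: published single-base breakpoints from split long reads
SPLIT_READ_BREAKPOINTS = {
    "patient1": {"chr2": 125_157_514, "chr5": 35_465_883},
    "patient2": {"chr13": 26_208_296, "chr17": 33_942_282},
}


def all_karyotype_calls(patient: str) -> list[KaryotypeCall]:
    """Every embryo of a pedigree as a parsed karyotype call (verbatim strings
    for the reference embryos, synthetic encodings for the rest)."""
    merged = dict(TABLE1_STRINGS[patient])
    merged.update(OTHER_EMBRYO_STRINGS[patient])
    return [parse_karyotype_string(text, embryo_id=eid)
            for eid, text in sorted(merged.items())]


def reference_segment_encoding(patient: str) -> dict[str, list[CopyNumberSegment]]:
    """SYNTHETIC coordinate encoding of the reference embryos' unbalanced
    segments on the translocation chromosomes.

    Terminal segments are anchored at the published window centers and the
    GRCh37 chromosome ends; the one interstitial/whole-arm pattern (patient-2
    embryo E) uses approximate inner coordinates, which by design only affect
    the consensus spread, never the modal position.
    """
    spec = PATIENT_SPECS[patient]
    if patient == "patient1":
        c2, c5 = CNV_WINDOWS[patient]["chr2"][0], CNV_WINDOWS[patient]["chr5"][0]
        end2 = GRCH37_LENGTHS["chr2"]
        full_2q = lambda cn: CopyNumberSegment("chr2", c2, end2, float(cn), cn)
        full_5p = lambda cn: CopyNumberSegment("chr5", 1, c5 - 1, float(cn), cn)
        return {
            "B": [full_2q(3), full_5p(1)],
            # fragmented 2q monosomy: three pieces, innermost edge at the center
            "F": [CopyNumberSegment("chr2", c2, 130_200_000, 1.0, 1),
                  CopyNumberSegment("chr2", 130_800_001, 234_800_000, 1.0, 1),
                  CopyNumberSegment("chr2", 235_000_001, end2, 1.0, 1),
                  full_5p(3)],
            # G's 5p gain starts inside p15.33 rather than at pter
            "G": [full_2q(1),
                  CopyNumberSegment("chr5", 1_300_001, c5 - 1, 3.0, 3)],
            "H": [full_2q(3), full_5p(1)],
            "K": [full_2q(1), full_5p(3)],
        }
    c13, c17 = CNV_WINDOWS[patient]["chr13"][0], CNV_WINDOWS[patient]["chr17"][0]
    end13, end17 = GRCH37_LENGTHS["chr13"], GRCH37_LENGTHS["chr17"]
    full_13q = lambda cn: CopyNumberSegment("chr13", c13, end13, float(cn), cn)
    full_17q = lambda cn: CopyNumberSegment("chr17", c17, end17, float(cn), cn)
    return {
        "D": [full_13q(1), full_17q(3)],
        # E: small interstitial 13q loss + whole 17p / proximal 17q gain
        "E": [CopyNumberSegment("chr13", 20_000_001, 26_000_000, 1.0, 1),
              CopyNumberSegment("chr17", 1, 22_200_000, 3.0, 3),
              CopyNumberSegment("chr17", 26_000_001, 34_000_000, 3.0, 3)],
        "G": [full_13q(3), full_17q(1)],
        "H": [full_13q(1), full_17q(3)],
        "I": [full_13q(3), full_17q(1)],
    }
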