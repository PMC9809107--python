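"""Recompute the two pedigrees' published worked-example numbers from fixtures.

Everything here is derived at run time by the package's own operations from
the fixture inputs (karyotype strings, encoded reference segments, split-read
breakpoints, GRCh37 lengths): reference-embryo counts, the four windowed
breakpoint localizations, CNV-vs-split-read concordance distances, and the
whole-Mb size labels of the patient-1 unbalanced segments.
"""
from __future__ import annotations

from . import breakpoints as bp
from . import cnv
from .fixtures import (CNV_WINDOWS, GRCH37_LENGTHS, PATIENT_SPECS,
                       SPLIT_READ_BREAKPOINTS, all_karyotype_calls,
                       reference_segment_encoding)

#: bin width of the embryo copy-number profiles behind the published windows
WINDOW_BIN_WIDTH = 200_000


def reference_embryos(patient: str) -> list[str]:
    spec = PATIENT_SPECS[patient]
    refs = cnv.select_reference_embryos(all_karyotype_calls(patient), spec)
    return sorted(c.embryo_id for c in refs)


def localize_patient(patient: str) -> dict[str, bp.BreakpointEstimate]:
    """CNV-boundary consensus over the encoded reference-embryo segments."""
    spec = PATIENT_SPECS[patient]
    return bp.localize_from_cnv(
        reference_segment_encoding(patient), spec, GRCH37_LENGTHS,
        bin_width=WINDOW_BIN_WIDTH)


def concordance_patient(patient: str) -> dict[str, bp.Concordance]:
    """Distance between the windowed and the single-base estimates."""
    spec = PATIENT_SPECS[patient]
    cnv_est = localize_patient(patient)
    out = {}
    for chrom in spec.chromosomes:
        split = bp.BreakpointEstimate(
            chrom, SPLIT_READ_BREAKPOINTS[patient][chrom], 0, "split_read", 1)
        out[chrom] = bp.check_concordance(cnv_est[chrom], split)
    return out


def patient1_size_labels() -> dict[str, int]:
    """Whole-Mb size labels of the patient-1 unbalanced segments, recomputed
    from the single-base breakpoints.

    - 5p: pter to the chr5 breakpoint -> segment [1, bp5]
    - distal 2q: the chr2 breakpoint to 2qter -> segment [bp2, len(chr2)]
    """
    bp2 = SPLIT_READ_BREAKPOINTS["patient1"]["chr2"]
    bp5 = SPLIT_READ_BREAKPOINTS["patient1"]["chr5"]
    return {
        "5p": cnv.size_label_mb(1, bp5),
        "2q_distal": cnv.size_label_mb(bp2, GRCH37_LENGTHS["chr2"]),
    }


def summary() -> dict:
    """All worked-example quantities in one dictionary."""
    out: dict = {"patients": {}}
    total_breakpoints = 0
    for patient in ("patient1", "patient2"):
        loc = localize_patient(patient)
        conc = concordance_patient(patient)
        total_breakpoints += len(loc)
        out["patients"][patient] = {
            "reference_embryos": reference_embryos(patient),
            "breakpoints": {
                c: {"position": e.position, "half_window": e.half_window,
                    "support": e.support}
                for c, e in sorted(loc.items())},
            "concordance": {
                c: {"distance_bp": v.distance, "within_window": v.within_window}
                for c, v in sorted(conc.items())},
            "published_window": {c: list(w) for c, w in CNV_WINDOWS[patient].items()},
        }
    out["n_breakpoints_localized"] = total_breakpoints
    out["patient1_size_labels_mb"] = patient1_size_labels()
    return out
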