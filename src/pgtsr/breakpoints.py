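"""Breakpoint localization: CNV-boundary consensus and split-read junctions.

Two independent estimators of the same translocation breakpoints:

- ``localize_from_cnv`` pools, across reference embryos, the copy-number
  segment boundary adjacent to each unbalanced segment — kilobase resolution,
  windowed (the resolution of binned embryo-biopsy profiles);
- ``detect_junctions`` clusters breakend pairs from split long-read alignments
  — single-base resolution on error-free reads.

``check_concordance`` measures the distance between the two.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome import TranslocationSpec, ValidationError
from .cnv import CopyNumberSegment


# ---------------------------------------------------------------------------
# read QC and statistics
# ---------------------------------------------------------------------------

def qc_filter_reads(reads, min_mean_qscore: float = 7.0):
    """Drop reads with mean qscore strictly below the threshold (7.0 passes)."""
    return [r for r in reads if r.mean_qscore >= min_mean_qscore]


@dataclass
class ReadStats:
    n_reads: int
    total_bases: int
    mean_length: float
    n50: int
    mean_depth: float


def read_stats(reads, genome_size: int) -> ReadStats:
    """Count/length/N50/depth summary.

    N50 is the largest length L such that reads of length >= L contain at
    least half of all sequenced bases (largest-first scan).
    """
    if genome_size <= 0:
        raise ValidationError("genome size must be > 0")
    if not reads:
        warnings.warn("read_stats over zero reads")
        return ReadStats(0, 0, 0.0, 0, 0.0)
    lengths = np.sort(np.array([r.length for r in reads]))[::-1]
    total = int(lengths.sum())
    csum = np.cumsum(lengths)
    n50 = int(lengths[np.searchsorted(csum, total / 2.0)])
    return ReadStats(
        n_reads=len(lengths), total_bases=total,
        mean_length=float(total / len(lengths)), n50=n50,
        mean_depth=float(total / genome_size),
    )


# ---------------------------------------------------------------------------
# CNV-boundary consensus
# ---------------------------------------------------------------------------

@dataclass
class BreakpointEstimate:
    chrom: str
    position: int
    half_window: int
    method: str  # cnv_boundary | split_read
    support: int

    def __post_init__(self):
        if self.half_window < 0 or self.support < 1:
            raise ValidationError("invalid breakpoint estimate")


def boundary_candidates(
    segments: list[CopyNumberSegment], chrom: str, chrom_length: int
) -> list[int]:
    """Breakpoint-adjacent boundaries from one embryo's called segments.

    The boundary is the edge of the unbalanced (non-mosaic) region that faces
    the normal part of the chromosome: for a q-terminal event the start of the
    abnormal region, for a p-terminal event one past its end.  An interstitial
    abnormal region contributes both edges.
    """
    abn = [s for s in segments
           if s.chrom == chrom and s.cn is not None and s.cn != 2
           and s.mosaic_fraction is None]
    if not abn:
        return []
    lo = min(s.start for s in abn)
    hi = max(s.end for s in abn)
    touches_start = lo == 1
    touches_end = hi >= chrom_length
    if touches_end and not touches_start:
        return [lo]
    if touches_start and not touches_end:
        return [hi + 1]
    if touches_start and touches_end:  # whole chromosome: no internal boundary
        return []
    return [lo, hi + 1]


def consensus_boundary(
    candidates_by_embryo: dict[str, list[int]], chrom: str, bin_width: int,
    grid: int | None = None,
) -> BreakpointEstimate:
    """Pool per-embryo boundary candidates into one windowed estimate.

    Representative = modal position (median on ties, then the smaller
    coordinate).  ``half_window`` = max(bin width, half the spread of the
    member candidates), where members are candidates within 2 bins of the
    representative; outliers (e.g. an interstitial fragment in one embryo)
    still count toward ``support`` but not toward the window.
    """
    all_pos: list[int] = []
    contributing = 0
    for _, cands in sorted(candidates_by_embryo.items()):
        if cands:
            contributing += 1
            all_pos.extend(cands)
    if not all_pos:
        raise ValidationError(
            f"no reference-embryo boundaries on {chrom}: carrier status cannot be "
            f"resolved without at least one reference embryo")
    if grid:
        all_pos = [int(round((p - 1) / grid)) * grid + 1 for p in all_pos]
    counts = Counter(all_pos)
    top = max(counts.values())
    modal = sorted(p for p, c in counts.items() if c == top)
    rep = int(modal[len(modal) // 2]) if len(modal) % 2 == 1 else int(
        sorted(modal)[len(modal) // 2 - 1])
    members = [p for p in all_pos if abs(p - rep) <= 2 * bin_width]
    spread = max(members) - min(members)
    return BreakpointEstimate(
        chrom=chrom, position=rep, half_window=max(bin_width, spread // 2),
        method="cnv_boundary", support=contributing,
    )


def localize_from_cnv(
    segments_by_embryo: dict[str, list[CopyNumberSegment]],
    spec: TranslocationSpec, lengths: dict[str, int], bin_width: int,
    grid: int | None = None,
) -> dict[str, BreakpointEstimate]:
    """One windowed breakpoint estimate per translocation chromosome."""
    if not segments_by_embryo:
        raise ValidationError(
            "no reference embryos: carrier status cannot be resolved without at "
            "least one embryo with unbalanced segments on both translocation chromosomes")
    out = {}
    for chrom in spec.chromosomes:
        cands = {
            embryo: boundary_candidates(segs, chrom, lengths[chrom])
            for embryo, segs in segments_by_embryo.items()
        }
        out[chrom] = consensus_boundary(cands, chrom, bin_width, grid=grid)
    return out


# ---------------------------------------------------------------------------
# split-read junction clustering
# ---------------------------------------------------------------------------

@dataclass
class JunctionCluster:
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    read_ids: list[str] = field(default_factory=list)
    member_coords: list[tuple[int, int]] = field(default_factory=list)
    partner_index: int | None = None  # index of the reciprocal cluster, if any

    @property
    def support(self) -> int:
        return len(self.read_ids)


def _read_candidates(read) -> list[tuple[str, int, str, str, int, str, str]]:
    """Breakend-pair candidates from adjacent blocks on different chromosomes.

    Canonical order: the side with the lexicographically smaller chromosome
    first (flipping both strands when the read traverses B before A).
    """
    cands = []
    blocks = read.blocks
    for b1, b2 in zip(blocks[:-1], blocks[1:]):
        if b1.chrom == b2.chrom:
            continue
        p1 = b1.end if b1.strand == "+" else b1.start
        p2 = b2.start if b2.strand == "+" else b2.end
        c1, s1, c2, s2 = b1.chrom, b1.strand, b2.chrom, b2.strand
        if c1 > c2:
            flip = {"+": "-", "-": "+"}
            c1, p1, s1, c2, p2, s2 = c2, p2, flip[s2], c1, p1, flip[s1]
        cands.append((c1, p1, s1, c2, p2, s2, read.read_id))
    return cands


def _mode_coord(values: list[int]) -> int:
    counts = Counter(values)
    top = max(counts.values())
    modal = sorted(v for v, c in counts.items() if c == top)
    if len(modal) % 2 == 1:
        return int(modal[len(modal) // 2])
    return int(modal[len(modal) // 2 - 1])


def detect_junctions(
    reads, tolerance: int = 10, min_support: int = 3
) -> list[JunctionCluster]:
    """Greedy clustering of interchromosomal breakend pairs.

    Candidates sharing (chrom pair, strand pair) join an existing cluster when
    both coordinates are within ``tolerance`` of the cluster representative
    (the running modal coordinate).  Clusters below ``min_support`` are
    discarded; reciprocal partners (opposite orientation, offset <= 1 bp on
    both sides) are cross-linked as one translocation with two junctions.
    """
    candidates = []
    for read in reads:
        candidates.extend(_read_candidates(read))
    candidates.sort(key=lambda c: (c[0], c[3], c[2], c[5], c[1], c[4], c[6]))

    clusters: list[JunctionCluster] = []
    for c1, p1, s1, c2, p2, s2, rid in candidates:
        placed = False
        for cl in clusters:
            if (cl.chrom1, cl.strand1, cl.chrom2, cl.strand2) != (c1, s1, c2, s2):
                continue
            if abs(p1 - cl.pos1) <= tolerance and abs(p2 - cl.pos2) <= tolerance:
                cl.read_ids.append(rid)
                cl.member_coords.append((p1, p2))
                cl.pos1 = _mode_coord([m[0] for m in cl.member_coords])
                cl.pos2 = _mode_coord([m[1] for m in cl.member_coords])
                placed = True
                break
        if not placed:
            clusters.append(JunctionCluster(
                chrom1=c1, pos1=p1, strand1=s1, chrom2=c2, pos2=p2, strand2=s2,
                read_ids=[rid], member_coords=[(p1, p2)]))

    clusters = [cl for cl in clusters if cl.support >= min_support]
    flip = {"+": "-", "-": "+"}
    for i, a in enumerate(clusters):
        for j, b in enumerate(clusters):
            if j <= i:
                continue
            if (a.chrom1, a.chrom2) == (b.chrom1, b.chrom2) \
                    and b.strand1 == flip[a.strand1] and b.strand2 == flip[a.strand2] \
                    and abs(a.pos1 - b.pos1) <= 1 and abs(a.pos2 - b.pos2) <= 1:
                a.partner_index, b.partner_index = j, i
    return clusters


def breakpoints_from_junctions(
    clusters: list[JunctionCluster], spec: TranslocationSpec
) -> dict[str, BreakpointEstimate]:
    """Single-base breakpoint estimates on the two translocation chromosomes.

    Among clusters joining chrom_a and chrom_b, the junction whose chrom_a-side
    orientation matches the proximal fragment of der(A) ('+' for a q-arm
    breakpoint, '-' for p) reports the breakpoints directly; failing that, the
    best-supported cluster is used.
    """
    a, b = sorted(spec.chromosomes)
    relevant = [cl for cl in clusters if (cl.chrom1, cl.chrom2) == (a, b)]
    if not relevant:
        raise ValidationError(
            f"no junction cluster joins {spec.chrom_a} and {spec.chrom_b}")
    want_strand_a = "+" if spec.arm(a) == "q" else "-"
    preferred = [cl for cl in relevant if cl.strand1 == want_strand_a]
    pool = preferred or relevant
    best = max(pool, key=lambda cl: (cl.support, -cl.pos1))
    return {
        best.chrom1: BreakpointEstimate(best.chrom1, best.pos1, 0, "split_read", best.support),
        best.chrom2: BreakpointEstimate(best.chrom2, best.pos2, 0, "split_read", best.support),
    }


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass
class Concordance:
    chrom: str
    distance: int
    within_window: bool


def check_concordance(
    cnv_estimate: BreakpointEstimate, split_estimate: BreakpointEstimate
) -> Concordance:
    """Distance between the two estimators and whether the split-read position
    falls inside the CNV window."""
    if cnv_estimate.chrom != split_estimate.chrom:
        raise ValidationError(
            f"chromosome mismatch: {cnv_estimate.chrom} vs {split_estimate.chrom}")
    distance = abs(cnv_estimate.position - split_estimate.position)
    return Concordance(
        chrom=cnv_estimate.chrom, distance=distance,
        within_window=distance <= cnv_estimate.half_window,
    )
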