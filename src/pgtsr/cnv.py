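"""Copy-number profiling: normalization, segmentation, karyotype strings.

The karyotype-string dialect is the clinical PGT reporting form, e.g.::

    46, XN, +2q(q14.3→q37.3,~118Mb,×3), -5p(pter→p13.2,~35Mb,×1)

with optional mosaic annotation ``,mos,~31%`` and a band-less whole-arm form
``+17p(×3)``.  Serialization followed by parsing is the identity.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import CytobandMap, GenomeModel, TranslocationSpec, ValidationError, \
    norm_chrom, short_chrom
from .sim import BinCounts

SEX_CHROMS = {"chrX", "chrY"}

#: |mean CN - 2| below this is a normal disomic call
MOSAIC_LOW = 0.2
#: |mean CN - 2| above this is a full (non-mosaic) gain/loss
MOSAIC_HIGH = 0.7


# ---------------------------------------------------------------------------
# normalization and segmentation
# ---------------------------------------------------------------------------

def normalize_counts(bc: BinCounts) -> dict[str, np.ndarray]:
    """Per-bin copy-number estimates: CN = 2 * count / median autosomal count."""
    autosomal = np.concatenate([
        arr for chrom, arr in bc.counts.items() if chrom not in SEX_CHROMS
    ]) if bc.counts else np.array([])
    if autosomal.size == 0 or not (autosomal > 0).any():
        raise ValidationError("cannot normalize: no nonzero autosomal bin counts")
    med = float(np.median(autosomal))
    return {chrom: 2.0 * arr / med for chrom, arr in bc.counts.items()}


@dataclass
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    mean_cn: float
    cn: int | None = None
    mosaic_fraction: float | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("segment start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_abnormal(self) -> bool:
        return self.cn is not None and (self.cn != 2 or self.mosaic_fraction is not None)


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float] | None:
    """Least-squares optimal single split; returns (index, |Δmean|) or None."""
    n = len(x)
    if n < 2 * min_bins:
        return None
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(min_bins, n - min_bins + 1)
    left_mean = csum[k - 1] / k
    right_mean = (total - csum[k - 1]) / (n - k)
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    i = int(np.argmax(gain))  # ties -> smallest split index
    return int(k[i]), float(abs(left_mean[i] - right_mean[i]))


def _binseg(x: np.ndarray, lo: int, min_bins: int, threshold: float,
            out: list[tuple[int, int]]) -> None:
    split = _best_split(x, min_bins)
    if split is None or split[1] < threshold:
        out.append((lo, lo + len(x)))
        return
    k, _ = split
    _binseg(x[:k], lo, min_bins, threshold, out)
    _binseg(x[k:], lo + k, min_bins, threshold, out)


def segment_chromosome(
    cn: np.ndarray, chrom: str, bin_width: int, chrom_length: int | None = None,
    min_bins: int = 3, threshold: float = 0.3,
) -> list[CopyNumberSegment]:
    """Recursive binary segmentation on mean shift.

    A split is accepted only if it changes the mean by at least ``threshold``
    CN units with at least ``min_bins`` bins on each side; the boundary is the
    first bin of the right-hand segment.
    """
    if min_bins < 2:
        raise ValidationError("min segment bins must be >= 2")
    pieces: list[tuple[int, int]] = []
    _binseg(np.asarray(cn, dtype=float), 0, min_bins, threshold, pieces)
    segs = []
    for lo, hi in pieces:
        start = lo * bin_width + 1
        end = hi * bin_width
        if chrom_length is not None and hi == len(cn):
            end = chrom_length
        segs.append(CopyNumberSegment(
            chrom=chrom, start=start, end=end, mean_cn=float(np.mean(cn[lo:hi]))))
    return segs


def segment_profile(
    cn_by_chrom: dict[str, np.ndarray], bin_width: int,
    lengths: dict[str, int] | None = None, min_bins: int = 3, threshold: float = 0.3,
) -> list[CopyNumberSegment]:
    segs = []
    for chrom, cn in cn_by_chrom.items():
        length = lengths.get(chrom) if lengths else None
        segs.extend(segment_chromosome(cn, chrom, bin_width, length, min_bins, threshold))
    return segs


def refine_boundary(
    cn_fine: np.ndarray, bin_width_fine: int, boundary: int, window_bins: int = 25,
    min_bins: int = 2,
) -> int:
    """Re-localize a coarse boundary on a fine-binned profile.

    Looks at ±``window_bins`` fine bins around ``boundary`` and returns the
    best single-split position (first base of the right-hand side).
    """
    b_bin = (boundary - 1) // bin_width_fine
    lo = max(0, b_bin - window_bins)
    hi = min(len(cn_fine), b_bin + window_bins)
    split = _best_split(cn_fine[lo:hi], min_bins)
    if split is None:
        return boundary
    return (lo + split[0]) * bin_width_fine + 1


def call_segment_cn(mean_cn: float) -> tuple[int, float | None]:
    """Integer CN call plus mosaic fraction from a segment mean.

    Deviation d = mean - 2: |d| < 0.2 is normal; 0.2 <= |d| <= 0.7 is a mosaic
    gain/loss with fraction |d| (reported to whole percent); |d| > 0.7 is a
    full integer call (×0..×4).
    """
    if mean_cn < 0:
        raise ValidationError("segment mean CN must be >= 0")
    d = mean_cn - 2.0
    if abs(d) < MOSAIC_LOW:
        return 2, None
    if abs(d) <= MOSAIC_HIGH:
        cn = 3 if d > 0 else 1
        return cn, round(abs(d), 2)
    cn = int(np.clip(round(mean_cn), 0, 4))
    return cn, None


def annotate_calls(segments: list[CopyNumberSegment]) -> list[CopyNumberSegment]:
    out = []
    for seg in segments:
        cn, frac = call_segment_cn(seg.mean_cn)
        out.append(replace(seg, cn=cn, mosaic_fraction=frac))
    return out


# ---------------------------------------------------------------------------
# karyotype strings
# ---------------------------------------------------------------------------

def size_label_mb(start: int, end: int) -> int:
    """Whole-Mb size label convention: floor(segment length / 1 Mb)."""
    return (end - start + 1) // 1_000_000


_BAND = r"(?:[pq][\d.]+|pter|qter)"
_SEG_RE = re.compile(
    r"^(?P<sign>[+-])(?P<chrom>\d+|X|Y)(?P<arm>[pq])\("
    r"(?:(?P<b1>" + _BAND + r")→(?P<b2>" + _BAND + r"),~(?P<size>\d+)Mb,)?"
    r"×(?P<cn>\d)"
    r"(?:,mos,~(?P<mos>\d+)%)?"
    r"\)$"
)


@dataclass
class SegmentCall:
    """One parsed/serializable segment-call token of a karyotype string."""

    sign: str              # '+' gain | '-' loss
    chrom: str             # short token, e.g. '2' or 'X'
    arm: str
    band_start: str | None = None
    band_end: str | None = None
    size_mb: int | None = None
    cn: int = 2
    mosaic_pct: int | None = None
    start: int | None = None  # optional 1-based coordinates
    end: int | None = None

    @property
    def is_mosaic(self) -> bool:
        return self.mosaic_pct is not None

    def serialize(self) -> str:
        core = f"{self.sign}{self.chrom}{self.arm}("
        if self.band_start is not None:
            core += f"{self.band_start}→{self.band_end},~{self.size_mb}Mb,"
        core += f"×{self.cn}"
        if self.mosaic_pct is not None:
            core += f",mos,~{self.mosaic_pct}%"
        return core + ")"


def parse_segment_call(text: str) -> SegmentCall:
    m = _SEG_RE.match(text.strip())
    if m is None:
        raise ValidationError(f"segment call does not match the karyotype grammar: {text!r}")
    g = m.groupdict()
    return SegmentCall(
        sign=g["sign"], chrom=g["chrom"], arm=g["arm"],
        band_start=g["b1"], band_end=g["b2"],
        size_mb=int(g["size"]) if g["size"] else None,
        cn=int(g["cn"]),
        mosaic_pct=int(g["mos"]) if g["mos"] else None,
    )


@dataclass
class KaryotypeCall:
    embryo_id: str
    segments: list[SegmentCall] = field(default_factory=list)
    modal: str = "46"
    sex: str = "XN"

    @property
    def is_euploid(self) -> bool:
        return len(self.segments) == 0

    def serialize(self) -> str:
        parts = [self.modal, self.sex] + [s.serialize() for s in self.segments]
        return ", ".join(parts)


def parse_karyotype_string(text: str, embryo_id: str = "") -> KaryotypeCall:
    """Parse a full karyotype string ('46, XN, +2q(...), ...')."""
    parts = [p.strip() for p in _split_top_level(text)]
    if len(parts) < 2:
        raise ValidationError(f"karyotype string too short: {text!r}")
    modal, sex = parts[0], parts[1]
    if not modal.isdigit():
        raise ValidationError(f"bad modal count token: {modal!r}")
    if not re.fullmatch(r"X[NXY]|XX|XY|XN", sex):
        raise ValidationError(f"bad sex token: {sex!r}")
    segments = [parse_segment_call(p) for p in parts[2:]]
    return KaryotypeCall(embryo_id=embryo_id, segments=segments, modal=modal, sex=sex)


def _split_top_level(text: str) -> list[str]:
    """Split on commas not inside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValidationError(f"unbalanced ')' in {text!r}")
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise ValidationError(f"missing ')' in {text!r}")
    parts.append("".join(cur))
    return parts


def to_karyotype_string(
    embryo_id: str, segments: list[CopyNumberSegment], cytobands: CytobandMap,
    sex: str = "XN", modal: str = "46",
) -> KaryotypeCall:
    """Serialize abnormal copy-number segments into a karyotype call.

    Only abnormal segments (integer CN != 2 or mosaic) produce tokens; bands
    are looked up in the cytoband map, 'pter'/'qter' are used at chromosome
    termini, and the size label is floor-to-Mb.
    """
    tokens = []
    for seg in segments:
        if not seg.is_abnormal:
            continue
        gain = (seg.cn is not None and seg.cn > 2) or (
            seg.mosaic_fraction is not None and seg.mean_cn > 2)
        sign = "+" if gain else "-"
        chrom_end = cytobands.chrom_end(seg.chrom)
        b1 = "pter" if seg.start == 1 else cytobands.band_at(seg.chrom, seg.start)
        b2 = "qter" if seg.end >= chrom_end else cytobands.band_at(seg.chrom, seg.end)
        # arm of the larger covered portion
        arm_start = "p" if b1 == "pter" else b1[0]
        arm_end = "q" if b2 == "qter" else b2[0]
        if arm_start == arm_end:
            arm = arm_start
        else:
            mid_band = cytobands.band_at(seg.chrom, (seg.start + seg.end) // 2)
            arm = mid_band[0]
        mos = None
        if seg.mosaic_fraction is not None:
            mos = int(round(seg.mosaic_fraction * 100))
        tokens.append(SegmentCall(
            sign=sign, chrom=short_chrom(seg.chrom), arm=arm,
            band_start=b1, band_end=b2, size_mb=size_label_mb(seg.start, seg.end),
            cn=int(seg.cn), mosaic_pct=mos, start=seg.start, end=seg.end))
    return KaryotypeCall(embryo_id=embryo_id, segments=tokens, modal=modal, sex=sex)


# ---------------------------------------------------------------------------
# embryo classification
# ---------------------------------------------------------------------------

@dataclass
class EmbryoClass:
    embryo_id: str
    label: str  # euploid | reference_unbalanced | other_abnormal
    involved: frozenset[str] = frozenset()


def classify_embryo(call: KaryotypeCall, spec: TranslocationSpec) -> EmbryoClass:
    """Reference embryos carry non-mosaic unbalanced segments on BOTH
    translocation chromosomes; mosaic-only events never qualify."""
    if call.is_euploid:
        return EmbryoClass(call.embryo_id, "euploid")
    unbalanced = {
        norm_chrom(s.chrom) for s in call.segments
        if s.cn != 2 and not s.is_mosaic
    }
    involved = unbalanced & {norm_chrom(spec.chrom_a), norm_chrom(spec.chrom_b)}
    if len(involved) == 2:
        return EmbryoClass(call.embryo_id, "reference_unbalanced", frozenset(involved))
    return EmbryoClass(call.embryo_id, "other_abnormal", frozenset(involved))


def select_reference_embryos(
    calls: list[KaryotypeCall], spec: TranslocationSpec
) -> list[EmbryoClass]:
    return [c for c in (classify_embryo(k, spec) for k in calls)
            if c.label == "reference_unbalanced"]
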