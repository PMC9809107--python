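"""Synthetic pedigree simulator for balanced reciprocal translocation carriers.

Emulates, with full ground truth, everything the downstream stages consume:

- the carrier parent's derivative chromosomes der(A)/der(B),
- meiotic segregation of the translocation quadrivalent (alternate,
  adjacent-1, adjacent-2, 3:1),
- embryos with true per-segment copy number, optional mosaicism and the
  transmitted carrier haplotype per breakpoint flank,
- overdispersed whole-genome-amplification-style binned read counts,
- SNP allele observations with allele dropout and genotyping error,
- long reads (nanopore-like length/quality marginals) sampled from the carrier
  genome, including junction-spanning split reads carrying phased SNP alleles.

Not emulated: base-level sequencing errors, amplification-bias profiles of a
real WGA chemistry, and within-arm crossover (recombination is exposed only as
an optional flank-haplotype switch on the transmitted normal homolog).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, TranslocationSpec, ValidationError

SEGREGATION_MODES = ("alternate", "adjacent1", "adjacent2", "three_to_one")
#: the four meiotic elements of the translocation quadrivalent
ELEMENTS = ("A_normal", "B_normal", "der_a", "der_b")


@dataclass(frozen=True)
class Fragment:
    """A genomic fragment of a derivative chromosome (1-based inclusive).

    ``strand`` is the orientation in which the derivative traverses the
    fragment: '-' means descending genomic coordinate (an inverted join, as in
    a q<->p exchange where the partner's p-terminal fragment is attached with
    its telomere facing outward).
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("fragment start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError("strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1


Breakend = tuple[str, int, str]  # (chrom, pos, strand)


@dataclass(frozen=True)
class DerivativePair:
    """The two derivative chromosomes, each an ordered list of fragments."""

    der_a: tuple[Fragment, ...]
    der_b: tuple[Fragment, ...]

    def fragments(self, name: str) -> tuple[Fragment, ...]:
        return self.der_a if name == "der_a" else self.der_b

    def junction(self, name: str) -> tuple[Breakend, Breakend]:
        """Breakend pair at the (single) junction of a derivative.

        Each breakend is the fragment base adjacent to the join, with the
        traversal strand.
        """
        f1, f2 = self.fragments(name)
        left = (f1.chrom, f1.end if f1.strand == "+" else f1.start, f1.strand)
        right = (f2.chrom, f2.start if f2.strand == "+" else f2.end, f2.strand)
        return left, right


def build_derivatives(spec: TranslocationSpec, genome: GenomeModel) -> DerivativePair:
    """Construct der(A) and der(B) as an exact base partition of A union B.

    der(A) keeps the centromere-bearing (proximal) part of A and gains the
    distal fragment of B; der(B) is the reciprocal.  Orientation is chosen so
    that telomeres face outward: a q<->p (or p<->q) exchange joins the partner
    fragment inverted, a q<->q or p<->p exchange joins it in direct orientation.
    """
    spec.validate_against(genome)
    a, b = spec.chrom_a, spec.chrom_b
    bp_a, bp_b = spec.bp_a, spec.bp_b
    len_a, len_b = genome.lengths[a], genome.lengths[b]
    arms = (spec.arm_a, spec.arm_b)

    if arms == ("q", "p"):
        der_a = (Fragment(a, 1, bp_a, "+"), Fragment(b, 1, bp_b, "-"))
        der_b = (Fragment(a, bp_a + 1, len_a, "-"), Fragment(b, bp_b + 1, len_b, "+"))
    elif arms == ("q", "q"):
        der_a = (Fragment(a, 1, bp_a, "+"), Fragment(b, bp_b + 1, len_b, "+"))
        der_b = (Fragment(b, 1, bp_b, "+"), Fragment(a, bp_a + 1, len_a, "+"))
    elif arms == ("p", "p"):
        der_a = (Fragment(b, 1, bp_b, "+"), Fragment(a, bp_a + 1, len_a, "+"))
        der_b = (Fragment(a, 1, bp_a, "+"), Fragment(b, bp_b + 1, len_b, "+"))
    else:  # ("p", "q")
        der_a = (Fragment(b, bp_b + 1, len_b, "-"), Fragment(a, bp_a + 1, len_a, "+"))
        der_b = (Fragment(a, 1, bp_a, "+"), Fragment(b, 1, bp_b, "-"))
    return DerivativePair(der_a=der_a, der_b=der_b)


def element_intervals(
    element: str, spec: TranslocationSpec, genome: GenomeModel,
    derivatives: DerivativePair,
) -> list[tuple[str, int, int]]:
    """Genomic intervals covered by one quadrivalent element."""
    if element == "A_normal":
        return [(spec.chrom_a, 1, genome.lengths[spec.chrom_a])]
    if element == "B_normal":
        return [(spec.chrom_b, 1, genome.lengths[spec.chrom_b])]
    if element in ("der_a", "der_b"):
        return [(f.chrom, f.start, f.end) for f in derivatives.fragments(element)]
    raise ValidationError(f"unknown element {element!r}")


def coverage_segments(
    intervals: list[tuple[str, int, int]], lengths: dict[str, int]
) -> dict[str, list[tuple[int, int, int]]]:
    """Per-chromosome (start, end, coverage) segments from a set of intervals.

    Uncovered stretches are reported with coverage 0, so the output tiles each
    chromosome exactly.
    """
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, length in lengths.items():
        events: dict[int, int] = {}
        for c, s, e in intervals:
            if c != chrom:
                continue
            events[s] = events.get(s, 0) + 1
            events[e + 1] = events.get(e + 1, 0) - 1
        edges = sorted(set([1, length + 1]) | set(events))
        segs, cov = [], 0
        for left, right in zip(edges[:-1], edges[1:]):
            cov += events.get(left, 0)
            if left <= length:
                segs.append((left, min(right - 1, length), cov))
        # merge equal-coverage neighbours
        merged = [segs[0]]
        for s, e, c in segs[1:]:
            ps, pe, pc = merged[-1]
            if c == pc:
                merged[-1] = (ps, e, c)
            else:
                merged.append((s, e, c))
        out[chrom] = merged
    return out


def is_balanced(
    elements: frozenset[str], spec: TranslocationSpec, genome: GenomeModel,
    derivatives: DerivativePair,
) -> bool:
    """True iff the gamete covers every base of A union B exactly once."""
    intervals = []
    for el in elements:
        intervals.extend(element_intervals(el, spec, genome, derivatives))
    lengths = {c: genome.lengths[c] for c in spec.chromosomes}
    segs = coverage_segments(intervals, lengths)
    return all(c == 1 for seglist in segs.values() for _, _, c in seglist)


@dataclass(frozen=True)
class GameteSpec:
    mode: str
    elements: frozenset[str]
    balanced: bool


#: the outcomes of each segregation mode (3:1 = the four 3-element gametes)
MODE_OUTCOMES: dict[str, list[frozenset[str]]] = {
    "alternate": [frozenset({"A_normal", "B_normal"}), frozenset({"der_a", "der_b"})],
    "adjacent1": [frozenset({"der_a", "B_normal"}), frozenset({"A_normal", "der_b"})],
    "adjacent2": [frozenset({"A_normal", "der_a"}), frozenset({"B_normal", "der_b"})],
    "three_to_one": [frozenset(set(ELEMENTS) - {el}) for el in ELEMENTS],
}


def segregate(
    spec: TranslocationSpec, genome: GenomeModel, derivatives: DerivativePair,
    mode: str, rng: np.random.Generator,
) -> GameteSpec:
    """Draw one gamete of the given segregation mode, uniformly over outcomes.

    The ``balanced`` flag is computed from base coverage, never hard-coded.
    """
    if mode not in MODE_OUTCOMES:
        raise ValidationError(f"unknown segregation mode {mode!r}")
    outcomes = MODE_OUTCOMES[mode]
    elements = outcomes[int(rng.integers(0, len(outcomes)))]
    return GameteSpec(mode=mode, elements=elements,
                      balanced=is_balanced(elements, spec, genome, derivatives))


@dataclass(frozen=True)
class MosaicEvent:
    chrom: str
    start: int
    end: int
    kind: str  # 'gained' | 'lost'
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("mosaic fraction outside [0,1]")
        if self.kind not in ("gained", "lost"):
            raise ValidationError("mosaic kind must be gained|lost")


@dataclass
class EmbryoTruth:
    """Ground truth for one simulated embryo.

    ``cn_segments`` maps chromosome -> list of (start, end, integer CN) before
    mosaic mixing; the partner parent is assumed to contribute one normal copy
    of each chromosome.  ``carrier_haplotypes`` maps (chrom, flank) -> tuple of
    carrier haplotype tags ('H1'/'H2') physically present in the embryo on that
    breakpoint flank.
    """

    embryo_id: str
    gamete: GameteSpec
    cn_segments: dict[str, list[tuple[int, int, int]]]
    carrier_status: str  # non_carrier | balanced_carrier | unbalanced
    carrier_haplotypes: dict[tuple[str, str], tuple[str, ...]]
    mosaic_events: tuple[MosaicEvent, ...] = ()


def make_embryo(
    spec: TranslocationSpec, genome: GenomeModel, derivatives: DerivativePair,
    gamete: GameteSpec, embryo_id: str,
    mosaic_events: tuple[MosaicEvent, ...] = (),
    der_haplotype: str = "H1",
) -> EmbryoTruth:
    """Combine a carrier gamete with a normal partner gamete into an embryo.

    The derivative chromosomes carry ``der_haplotype`` of both involved
    chromosomes (the translocation arose on one homolog of each); the
    transmitted normal homologs carry the other haplotype.
    """
    intervals = []
    for el in gamete.elements:
        intervals.extend(element_intervals(el, spec, genome, derivatives))
    # partner contributes one full copy of every chromosome
    for chrom, length in genome.lengths.items():
        intervals.append((chrom, 1, length))
    cn_segments = coverage_segments(intervals, genome.lengths)

    if gamete.elements == frozenset({"der_a", "der_b"}):
        status = "balanced_carrier"
    elif gamete.elements == frozenset({"A_normal", "B_normal"}):
        status = "non_carrier"
    else:
        status = "unbalanced"

    norm_hap = "H2" if der_haplotype == "H1" else "H1"
    covers = {
        "A_normal": {(spec.chrom_a, "proximal"): norm_hap, (spec.chrom_a, "distal"): norm_hap},
        "B_normal": {(spec.chrom_b, "proximal"): norm_hap, (spec.chrom_b, "distal"): norm_hap},
        # der(A) = proximal A + distal B; der(B) = proximal B + distal A
        "der_a": {(spec.chrom_a, "proximal"): der_haplotype,
                  (spec.chrom_b, "distal"): der_haplotype},
        "der_b": {(spec.chrom_b, "proximal"): der_haplotype,
                  (spec.chrom_a, "distal"): der_haplotype},
    }
    haps: dict[tuple[str, str], list[str]] = {
        (c, f): [] for c in spec.chromosomes for f in ("proximal", "distal")}
    for el in gamete.elements:
        for key, hap in covers[el].items():
            haps[key].append(hap)
    carrier_haplotypes = {k: tuple(sorted(v)) for k, v in haps.items()}

    return EmbryoTruth(
        embryo_id=embryo_id, gamete=gamete, cn_segments=cn_segments,
        carrier_status=status, carrier_haplotypes=carrier_haplotypes,
        mosaic_events=tuple(mosaic_events),
    )


def make_pedigree(
    spec: TranslocationSpec, genome: GenomeModel, derivatives: DerivativePair,
    n_embryos: int, mode_weights: dict[str, float], rng: np.random.Generator,
    der_haplotype: str = "H1",
) -> list[EmbryoTruth]:
    """Simulate a cohort of embryos with segregation modes drawn by weight."""
    modes = list(mode_weights)
    weights = np.array([mode_weights[m] for m in modes], dtype=float)
    weights /= weights.sum()
    embryos = []
    for i in range(n_embryos):
        mode = modes[int(rng.choice(len(modes), p=weights))]
        gamete = segregate(spec, genome, derivatives, mode, rng)
        embryo_id = f"E{i + 1:02d}"
        embryos.append(make_embryo(spec, genome, derivatives, gamete, embryo_id,
                                   der_haplotype=der_haplotype))
    return embryos


# ---------------------------------------------------------------------------
# binned counts
# ---------------------------------------------------------------------------

@dataclass
class BinCounts:
    """Fixed-width binned read counts; bin *i* covers [(i-1)w+1, iw]."""

    embryo_id: str
    bin_width: int
    counts: dict[str, np.ndarray]

    def n_bins(self, chrom: str) -> int:
        return len(self.counts[chrom])


def true_copy_profile(
    truth: EmbryoTruth, genome: GenomeModel, bin_width: int
) -> dict[str, np.ndarray]:
    """Expected (possibly fractional) copy number per bin.

    Mosaic events blend linearly: a gained fraction f adds f to the integer CN
    over the event interval, a lost fraction subtracts f.  Bins straddling a
    CN boundary get the length-weighted mean.
    """
    out = {}
    for chrom, length in genome.lengths.items():
        n_bins = -(-length // bin_width)  # ceil
        acc = np.zeros(n_bins, dtype=float)

        def add(start: int, end: int, value: float):
            if value == 0.0 or start > end:
                return
            first, last = (start - 1) // bin_width, (end - 1) // bin_width
            for b in range(first, last + 1):
                b_start, b_end = b * bin_width + 1, min((b + 1) * bin_width, length)
                overlap = min(end, b_end) - max(start, b_start) + 1
                acc[b] += value * overlap

        for start, end, cn in truth.cn_segments.get(chrom, [(1, length, 2)]):
            add(start, end, float(cn))
        for ev in truth.mosaic_events:
            if ev.chrom != chrom:
                continue
            add(ev.start, ev.end, ev.fraction if ev.kind == "gained" else -ev.fraction)

        widths = np.full(n_bins, bin_width, dtype=float)
        widths[-1] = length - (n_bins - 1) * bin_width
        out[chrom] = acc / widths
    return out


def simulate_bin_counts(
    expected_cn: dict[str, np.ndarray], mean_per_disomic_bin: float,
    dispersion: float, rng: np.random.Generator, embryo_id: str = "",
    bin_width: int = 0,
) -> BinCounts:
    """Overdispersed counts with mean m*CN/2 (negative binomial).

    The negative binomial is parameterized by (mean, dispersion) with
    Var = mu * (1 + dispersion), i.e. a constant overdispersion factor over
    Poisson (gamma-Poisson with n = mu/dispersion, p = 1/(1+dispersion)).
    dispersion = 0 is the deterministic degenerate case (counts =
    round(m*CN/2), no sampling at all).
    """
    if mean_per_disomic_bin <= 0:
        raise ValidationError("mean count per disomic bin must be > 0")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    counts = {}
    for chrom, cn in expected_cn.items():
        mu = mean_per_disomic_bin * np.asarray(cn, dtype=float) / 2.0
        if dispersion == 0:
            counts[chrom] = np.rint(mu).astype(np.int64)
        else:
            n = np.maximum(mu, 1e-12) / dispersion
            p = 1.0 / (1.0 + dispersion)
            drawn = rng.negative_binomial(n, p)
            counts[chrom] = np.where(mu <= 0, 0, drawn).astype(np.int64)
    return BinCounts(embryo_id=embryo_id, bin_width=bin_width, counts=counts)


def rebin_counts(bc: BinCounts, factor: int) -> BinCounts:
    """Aggregate to ``factor``-times-wider bins by summation."""
    if factor < 1:
        raise ValidationError("rebin factor must be >= 1")
    counts = {}
    for chrom, arr in bc.counts.items():
        n_out = -(-len(arr) // factor)
        padded = np.zeros(n_out * factor, dtype=arr.dtype)
        padded[: len(arr)] = arr
        counts[chrom] = padded.reshape(n_out, factor).sum(axis=1)
    return BinCounts(embryo_id=bc.embryo_id, bin_width=bc.bin_width * factor, counts=counts)


# ---------------------------------------------------------------------------
# SNP observations
# ---------------------------------------------------------------------------

def simulate_snp_observations(
    truths: list[EmbryoTruth], spec: TranslocationSpec, genome: GenomeModel,
    rng: np.random.Generator, ado: float = 0.0, error_rate: float = 0.0,
    depth: float = 30.0,
) -> pd.DataFrame:
    """Per-embryo observed alleles at every SNP of the genome model.

    For each site the alleles of the haplotypes actually present (carrier
    contribution per flank of the breakpoint, plus one partner allele) are
    collected; each present allele drops out independently with probability
    ``ado`` (if all drop, one survivor is kept so a site always reports at
    least one allele); each surviving allele is replaced by a random different
    base with probability ``error_rate``.

    Returns a long DataFrame: embryo, chrom, pos, alleles ('/'-joined sorted
    unique observed alleles), depths ('/'-joined per-allele read depths).
    """
    for rate in (ado, error_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValidationError("rates must be in [0,1]")
    base_arr = np.array(["A", "C", "G", "T"])
    frames = []
    for truth in truths:
        for chrom in spec.chromosomes:
            snps = genome.chrom_snps(chrom)
            if snps.empty:
                continue
            pos = snps["pos"].to_numpy()
            distal = spec.is_distal(chrom, pos)
            h1 = snps["h1"].to_numpy()
            h2 = snps["h2"].to_numpy()
            allele_of = {"H1": h1, "H2": h2}
            n = len(pos)

            # carrier allele slots: up to 3 copies (3:1 gametes)
            slots: list[np.ndarray] = []
            for flank, mask in (("proximal", ~distal), ("distal", distal)):
                haps = truth.carrier_haplotypes.get((chrom, flank), ())
                for k, hap in enumerate(haps):
                    while len(slots) < k + 1:
                        slots.append(np.full(n, "", dtype=object))
                    slots[k][mask] = allele_of[hap][mask]
            # one partner allele per site (partner gamete fixed per embryo/site)
            partner_pick = rng.integers(0, 2, n)
            partner = np.where(partner_pick == 0, snps["p1"].to_numpy(),
                               snps["p2"].to_numpy()).astype(object)
            slots.append(partner)

            mat = np.stack(slots, axis=1)  # n x k object array
            present = mat != ""
            drop = (rng.random(mat.shape) < ado) & present
            survive = present & ~drop
            # keep one random present allele where everything dropped
            dead = present.any(axis=1) & ~survive.any(axis=1)
            if dead.any():
                idx = np.where(dead)[0]
                for i in idx:
                    choices = np.where(present[i])[0]
                    survive[i, choices[rng.integers(0, len(choices))]] = True
            if error_rate > 0:
                err = (rng.random(mat.shape) < error_rate) & survive
                if err.any():
                    ei, ej = np.where(err)
                    for i, j in zip(ei, ej):
                        others = [b for b in base_arr if b != mat[i, j]]
                        mat[i, j] = others[rng.integers(0, 3)]

            obs_alleles = []
            obs_depths = []
            depth_draws = rng.poisson(depth, size=mat.shape) + 1
            for i in range(n):
                per_allele: dict[str, int] = {}
                for j in range(mat.shape[1]):
                    if survive[i, j]:
                        per_allele[mat[i, j]] = per_allele.get(mat[i, j], 0) + int(depth_draws[i, j])
                alleles = sorted(per_allele)
                obs_alleles.append("/".join(alleles))
                obs_depths.append("/".join(str(per_allele[a]) for a in alleles))
            frames.append(pd.DataFrame({
                "embryo": truth.embryo_id, "chrom": chrom, "pos": pos,
                "alleles": obs_alleles, "depths": obs_depths,
            }))
    if not frames:
        return pd.DataFrame(columns=["embryo", "chrom", "pos", "alleles", "depths"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

@dataclass
class AlignmentBlock:
    """One aligned block of a (possibly split) read.

    ``qstart``/``qend`` are 0-based half-open offsets in the read; genomic
    coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str
    qstart: int
    qend: int


@dataclass
class LongRead:
    read_id: str
    length: int
    mean_qscore: float
    blocks: list[AlignmentBlock]
    snp_alleles: list[tuple[str, int, str]] = field(default_factory=list)
    molecule: str = ""  # truth: which carrier molecule the read came from

    @property
    def spans_junction(self) -> bool:
        return any(b1.chrom != b2.chrom
                   for b1, b2 in zip(self.blocks[:-1], self.blocks[1:]))


def _blocks_for_interval(
    fragments: tuple[Fragment, ...], mol_start: int, mol_end: int
) -> list[AlignmentBlock]:
    """Map a molecule-coordinate interval (1-based incl.) to genomic blocks."""
    blocks = []
    offset = 0
    for frag in fragments:
        f_lo, f_hi = offset + 1, offset + len(frag)
        lo, hi = max(mol_start, f_lo), min(mol_end, f_hi)
        if lo <= hi:
            ls, le = lo - offset, hi - offset  # fragment-local 1-based
            if frag.strand == "+":
                gs, ge = frag.start + ls - 1, frag.start + le - 1
            else:
                gs, ge = frag.end - le + 1, frag.end - ls + 1
            blocks.append(AlignmentBlock(
                chrom=frag.chrom, start=gs, end=ge, strand=frag.strand,
                qstart=lo - mol_start, qend=hi - mol_start + 1))
        offset = f_hi
    return blocks


def simulate_long_reads(
    spec: TranslocationSpec, genome: GenomeModel, derivatives: DerivativePair,
    n_reads: int, rng: np.random.Generator,
    mean_length: float = 15_000.0, sigma_log: float = 0.45,
    qscore_mean: float = 12.0, qscore_sd: float = 1.5, low_q_frac: float = 0.0,
    der_haplotype: str = "H1", snp_error_rate: float = 0.0,
) -> list[LongRead]:
    """Sample reads uniformly from the carrier genome (both derivatives).

    Reads overlapping a derivative junction get two alignment blocks with the
    breakend orientation of the junction, and carry the SNP alleles of the
    haplotype physically present on the molecule of origin.  A fraction
    ``low_q_frac`` of reads is given mean qscores centred at 5 so the
    downstream quality filter has something to remove.
    """
    if n_reads <= 0:
        raise ValidationError("n_reads must be > 0")
    norm_hap = "H2" if der_haplotype == "H1" else "H1"
    molecules = [
        ("A_normal", (Fragment(spec.chrom_a, 1, genome.lengths[spec.chrom_a], "+"),), norm_hap),
        ("B_normal", (Fragment(spec.chrom_b, 1, genome.lengths[spec.chrom_b], "+"),), norm_hap),
        ("der_a", derivatives.der_a, der_haplotype),
        ("der_b", derivatives.der_b, der_haplotype),
    ]
    mol_lengths = np.array([sum(len(f) for f in frags) for _, frags, _ in molecules], float)
    probs = mol_lengths / mol_lengths.sum()

    snp_by_chrom = {
        chrom: genome.chrom_snps(chrom)[["pos", "h1", "h2"]].to_numpy()
        for chrom in spec.chromosomes
    }
    mu_log = np.log(mean_length) - sigma_log ** 2 / 2.0
    reads = []
    clipped = 0
    for i in range(n_reads):
        m = int(rng.choice(len(molecules), p=probs))
        name, frags, hap = molecules[m]
        mol_len = int(mol_lengths[m])
        length = max(200, int(rng.lognormal(mu_log, sigma_log)))
        if length > mol_len:
            clipped += 1
            length = mol_len
        start = int(rng.integers(1, mol_len - length + 2))
        end = start + length - 1
        blocks = _blocks_for_interval(frags, start, end)

        if rng.random() < low_q_frac:
            q = float(rng.normal(5.0, 1.0))
        else:
            q = float(rng.normal(qscore_mean, qscore_sd))
        q = max(1.0, q)

        snp_alleles: list[tuple[str, int, str]] = []
        for blk in blocks:
            table = snp_by_chrom.get(blk.chrom)
            if table is None or len(table) == 0:
                continue
            pos = table[:, 0].astype(int)
            sel = (pos >= blk.start) & (pos <= blk.end)
            col = 1 if hap == "H1" else 2
            for p, allele in zip(pos[sel], table[sel, col]):
                if snp_error_rate > 0 and rng.random() < snp_error_rate:
                    allele = [b for b in "ACGT" if b != allele][rng.integers(0, 3)]
                snp_alleles.append((blk.chrom, int(p), str(allele)))

        reads.append(LongRead(
            read_id=f"read{i + 1:06d}", length=length, mean_qscore=round(q, 2),
            blocks=blocks, snp_alleles=snp_alleles, molecule=name))
    if clipped:
        warnings.warn(f"{clipped} read(s) longer than their source molecule were clipped")
    return reads
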