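"""Genome model, translocation description, and cytoband maps.

Coordinates are 1-based and inclusive throughout the package; file writers
(BED/BEDPE) convert to 0-based half-open at the boundary.

A balanced reciprocal translocation t(A;B) exchanges the two distal (telomeric)
segments of non-homologous chromosomes A and B.  The breakpoint on each
chromosome is recorded as the last base of the *distal* fragment when the
exchanged arm is p (the distal fragment lies before the breakpoint) and the
last base of the *proximal* fragment when the exchanged arm is q (the distal
fragment lies after it).  This matches the convention under which the
derivative chromosome der(A) of a q<->p exchange is
``A:1..bp_a  +  B:bp_b..1 (inverted)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")


def norm_chrom(token: str) -> str:
    """Normalize a chromosome token to the internal 'chr*' form ('2' -> 'chr2')."""
    token = str(token)
    return token if token.startswith("chr") else f"chr{token}"


def short_chrom(chrom: str) -> str:
    """Inverse of :func:`norm_chrom` ('chr2' -> '2')."""
    return chrom[3:] if chrom.startswith("chr") else chrom


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class TranslocationSpec:
    """A reciprocal translocation t(chrom_a;chrom_b) carried by one parent.

    Parameters
    ----------
    chrom_a, chrom_b
        The two (distinct) chromosomes involved.
    bp_a, bp_b
        Breakpoint positions, 1-based.  ``bp`` is the boundary base of the
        fragment on the p-terminal side: for a q-arm exchange the proximal
        fragment is ``[1, bp]``; for a p-arm exchange the distal fragment is
        ``[1, bp]``.
    arm_a, arm_b
        Which arm carries the exchanged distal fragment ('p' or 'q').
    carrier_parent
        'maternal' or 'paternal'.
    """

    chrom_a: str
    chrom_b: str
    bp_a: int
    bp_b: int
    arm_a: str
    arm_b: str
    carrier_parent: str = "maternal"
    band_a: str | None = None
    band_b: str | None = None

    def __post_init__(self):
        if self.chrom_a == self.chrom_b:
            raise ValidationError("translocation chromosomes must differ")
        for arm in (self.arm_a, self.arm_b):
            if arm not in ("p", "q"):
                raise ValidationError(f"arm tag must be 'p' or 'q', got {arm!r}")
        for bp in (self.bp_a, self.bp_b):
            if bp < 1:
                raise ValidationError(f"breakpoint {bp} must be >= 1")
        if self.carrier_parent not in ("maternal", "paternal"):
            raise ValidationError(
                f"carrier_parent must be maternal|paternal, got {self.carrier_parent!r}"
            )

    # -- helpers -----------------------------------------------------------
    @property
    def chromosomes(self) -> tuple[str, str]:
        return (self.chrom_a, self.chrom_b)

    def breakpoint(self, chrom: str) -> int:
        if chrom == self.chrom_a:
            return self.bp_a
        if chrom == self.chrom_b:
            return self.bp_b
        raise KeyError(chrom)

    def arm(self, chrom: str) -> str:
        if chrom == self.chrom_a:
            return self.arm_a
        if chrom == self.chrom_b:
            return self.arm_b
        raise KeyError(chrom)

    def validate_against(self, genome: "GenomeModel") -> None:
        for chrom, bp in ((self.chrom_a, self.bp_a), (self.chrom_b, self.bp_b)):
            if chrom not in genome.lengths:
                raise ValidationError(f"{chrom} not in genome")
            if not 1 <= bp < genome.lengths[chrom]:
                raise ValidationError(
                    f"breakpoint {chrom}:{bp} outside [1, {genome.lengths[chrom]})"
                )

    def distal_interval(self, chrom: str, genome: "GenomeModel") -> tuple[int, int]:
        """The exchanged (telomeric) fragment of ``chrom`` as (start, end)."""
        bp, arm, length = self.breakpoint(chrom), self.arm(chrom), genome.lengths[chrom]
        return (bp + 1, length) if arm == "q" else (1, bp)

    def proximal_interval(self, chrom: str, genome: "GenomeModel") -> tuple[int, int]:
        """The centromere-retaining fragment of ``chrom`` as (start, end)."""
        bp, arm, length = self.breakpoint(chrom), self.arm(chrom), genome.lengths[chrom]
        return (1, bp) if arm == "q" else (bp + 1, length)

    def is_distal(self, chrom: str, pos) -> bool | np.ndarray:
        bp, arm = self.breakpoint(chrom), self.arm(chrom)
        pos = np.asarray(pos)
        out = pos > bp if arm == "q" else pos <= bp
        return bool(out) if out.ndim == 0 else out


@dataclass
class GenomeModel:
    """Chromosome lengths plus a phased SNP map for the carrier couple.

    ``snps`` columns:

    - ``chrom``, ``pos`` : site location (1-based, strictly increasing per chrom)
    - ``h1``, ``h2``     : carrier parent's two haplotype alleles
    - ``p1``, ``p2``     : partner parent's (unphased) genotype alleles
    """

    lengths: dict[str, int]
    snps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "pos", "h1", "h2", "p1", "p2"]))

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for chrom, length in self.lengths.items():
            if length < 1:
                raise ValidationError(f"{chrom} has non-positive length")
        if len(self.snps):
            for chrom, grp in self.snps.groupby("chrom", sort=False):
                if chrom not in self.lengths:
                    raise ValidationError(f"SNPs on unknown chromosome {chrom}")
                pos = grp["pos"].to_numpy()
                if not (np.diff(pos) > 0).all():
                    raise ValidationError(f"SNP positions on {chrom} not strictly increasing")
                if pos[0] < 1 or pos[-1] > self.lengths[chrom]:
                    raise ValidationError(f"SNP position outside {chrom}")
            for col in ("h1", "h2", "p1", "p2"):
                bad = ~self.snps[col].isin(BASES)
                if bad.any():
                    raise ValidationError(f"non-ACGT allele in column {col}")

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def chrom_snps(self, chrom: str) -> pd.DataFrame:
        return self.snps[self.snps["chrom"] == chrom]

    # -- constructors ------------------------------------------------------
    @classmethod
    def toy(
        cls,
        n_chromosomes: int = 2,
        length: int = 5_000_000,
        snp_spacing: int = 2_000,
        seed: int = 0,
        carrier_het_frac: float = 0.5,
        partner_hom_frac: float = 0.7,
    ) -> "GenomeModel":
        """A small biallelic-SNP genome on which whole pipelines run in seconds."""
        rng = np.random.default_rng(seed)
        lengths = {f"chr{i + 1}": int(length) for i in range(n_chromosomes)}
        rows = []
        for chrom in lengths:
            pos = np.arange(snp_spacing, length + 1, snp_spacing)
            n = len(pos)
            ref_idx = rng.integers(0, 4, n)
            alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
            ref = np.array(BASES)[ref_idx]
            alt = np.array(BASES)[alt_idx]
            carrier_het = rng.random(n) < carrier_het_frac
            carrier_hom_alt = rng.random(n) < 0.5
            h1 = np.where(carrier_het | ~carrier_hom_alt, ref, alt)
            h2 = np.where(carrier_het, alt, h1)
            partner_hom = rng.random(n) < partner_hom_frac
            partner_alt = rng.random(n) < 0.5
            p1 = np.where(partner_alt, alt, ref)
            p2 = np.where(partner_hom, p1, np.where(partner_alt, ref, alt))
            rows.append(pd.DataFrame(
                {"chrom": chrom, "pos": pos, "h1": h1, "h2": h2, "p1": p1, "p2": p2}))
        snps = pd.concat(rows, ignore_index=True)
        return cls(lengths=lengths, snps=snps)


class CytobandMap:
    """Band <-> coordinate lookup in the UCSC cytoBand.txt dialect.

    The file is tab-separated with 5 columns (chrom, 0-based start, end, band
    name, Giemsa stain); internally intervals are 1-based inclusive.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["chrom", "start", "end", "band", "stain"]
        if list(df.columns) != required:
            df = df[required]
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts > ends).any():
                raise ValidationError(f"inverted band interval on {chrom}")
            if (starts[1:] <= ends[:-1]).any():
                raise ValidationError(f"overlapping bands on {chrom}")

    @classmethod
    def from_ucsc(cls, path) -> "CytobandMap":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}")
                chrom, start, end, band, stain = parts
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise ValidationError(f"{path}:{lineno}: non-integer coordinate") from exc
                # UCSC is 0-based half-open; store 1-based inclusive.
                rows.append((norm_chrom(chrom), start_i + 1, end_i, band, stain))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])
        return cls(df)

    @classmethod
    def toy(cls, lengths: dict[str, int], bands_per_arm: int = 4,
            centromere_frac: float = 0.5) -> "CytobandMap":
        """Evenly spaced synthetic bands (p-arm then q-arm) for simulated genomes."""
        rows = []
        for chrom, length in lengths.items():
            cen = int(length * centromere_frac)
            for arm, a_start, a_end in (("p", 1, cen), ("q", cen + 1, length)):
                edges = np.linspace(a_start - 1, a_end, bands_per_arm + 1).astype(int)
                for i in range(bands_per_arm):
                    # UCSC-style numbering increases away from the centromere.
                    idx = bands_per_arm - i if arm == "p" else i + 1
                    rows.append((chrom, edges[i] + 1, edges[i + 1], f"{arm}1{idx}", "gneg"))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])
        return cls(df)

    # -- queries -----------------------------------------------------------
    def band_interval(self, chrom: str, band: str) -> tuple[int, int]:
        chrom = norm_chrom(chrom)
        hit = self.df[(self.df["chrom"] == chrom) & (self.df["band"] == band)]
        if hit.empty:
            raise KeyError(f"band {band} not found on {chrom}")
        return int(hit["start"].iloc[0]), int(hit["end"].iloc[0])

    def band_at(self, chrom: str, pos: int) -> str:
        chrom = norm_chrom(chrom)
        grp = self.df[self.df["chrom"] == chrom]
        hit = grp[(grp["start"] <= pos) & (grp["end"] >= pos)]
        if hit.empty:
            raise KeyError(f"no band contains {chrom}:{pos}")
        return str(hit["band"].iloc[0])

    def arm_at(self, chrom: str, pos: int) -> str:
        return self.band_at(chrom, pos)[0]

    def chrom_end(self, chrom: str) -> int:
        chrom = norm_chrom(chrom)
        grp = self.df[self.df["chrom"] == chrom]
        if grp.empty:
            raise KeyError(chrom)
        return int(grp["end"].max())

    def to_ucsc(self, path) -> None:
        out = self.df.copy()
        out["start"] = out["start"] - 1
        out.to_csv(path, sep="\t", header=False, index=False)
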