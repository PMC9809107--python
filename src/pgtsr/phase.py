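"""Haplotype linkage around translocation breakpoints and carrier calls.

The carrier parent is heterozygous along both translocation chromosomes; at
*informative* sites (carrier het, partner hom) the carrier haplotype an embryo
received is directly readable from its observed alleles.  Two independent
routes establish which carrier haplotype rides each derivative chromosome:

- reference embryos: an embryo monosomic for the distal segment of chromosome
  X received der(X); its proximal-X informative SNPs expose the derivative
  haplotype directly.  An embryo trisomic for distal X received the normal X
  homolog instead, so its proximal-X alleles expose the *normal-linked*
  haplotype and vote for the complement.
- junction-spanning long reads: any read crossing a derivative junction is
  physically a derivative molecule, so every informative SNP allele it carries
  belongs to the derivative haplotype of that SNP's chromosome.

Euploid embryos are then called carrier / non-carrier by majority vote over
proximal-flank informative SNPs against the resolved linkage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel, TranslocationSpec, ValidationError
from .cnv import CopyNumberSegment, KaryotypeCall


class PhaseError(ValueError):
    """Raised when haplotype linkage cannot be resolved consistently."""


def _other(hap: str) -> str:
    return "H2" if hap == "H1" else "H1"


# ---------------------------------------------------------------------------
# informative SNP selection
# ---------------------------------------------------------------------------

def select_informative_snps(
    snps: pd.DataFrame, spec: TranslocationSpec,
    breakpoints: dict[str, int], flank_window: int = 2_000_000,
    fully_informative_only: bool = True,
) -> pd.DataFrame:
    """Sites within ±``flank_window`` of a breakpoint where the carrier is
    heterozygous and (by default) the partner homozygous.

    Adds ``flank`` ('proximal'/'distal' relative to the derivative composition)
    and ``dist`` (bp to the breakpoint).  Warns per flank that ends up empty.
    """
    frames = []
    for chrom in spec.chromosomes:
        if chrom not in breakpoints:
            continue
        bp = breakpoints[chrom]
        grp = snps[snps["chrom"] == chrom].copy()
        grp = grp[(grp["pos"] >= bp - flank_window) & (grp["pos"] <= bp + flank_window)]
        carrier_het = grp["h1"] != grp["h2"]
        informative = carrier_het
        if fully_informative_only:
            informative = informative & (grp["p1"] == grp["p2"])
        grp = grp[informative]
        distal = spec.is_distal(chrom, grp["pos"].to_numpy())
        grp["flank"] = np.where(distal, "distal", "proximal")
        grp["dist"] = np.abs(grp["pos"] - bp)
        frames.append(grp)
    if not frames:
        return snps.iloc[0:0].assign(flank="", dist=0)
    out = pd.concat(frames, ignore_index=True)
    import warnings
    for chrom in spec.chromosomes:
        for flank in ("proximal", "distal"):
            if not ((out["chrom"] == chrom) & (out["flank"] == flank)).any():
                warnings.warn(f"no informative SNPs on the {flank} flank of {chrom}; "
                              f"downstream calls will be inconclusive")
    return out


def _observed_carrier_allele(obs: str, h1: str, h2: str, partner: str) -> str | None:
    """Which carrier haplotype a single-copy carrier contribution shows.

    Returns 'H1'/'H2' when exactly one carrier allele is visible after removing
    the partner allele, else None (dropout, error, or carrier allele hidden
    behind an identical partner allele).
    """
    alleles = set(obs.split("/")) - {partner, ""}
    if len(alleles) != 1:
        return None
    allele = alleles.pop()
    if allele == h1 and allele != h2:
        return "H1"
    if allele == h2 and allele != h1:
        return "H2"
    return None


# ---------------------------------------------------------------------------
# linkage from reference embryos
# ---------------------------------------------------------------------------

@dataclass
class ChromLinkage:
    haplotype: str | None
    votes_for: int
    votes_against: int

    @property
    def total(self) -> int:
        return self.votes_for + self.votes_against

    @property
    def consistency(self) -> float:
        return self.votes_for / self.total if self.total else 0.0


@dataclass
class HaplotypeLinkage:
    """Which carrier haplotype rides each derivative chromosome."""

    per_chrom: dict[str, ChromLinkage]
    source: str  # reference_embryos | junction_reads
    message: str = ""

    def resolved(self, chroms) -> bool:
        return all(c in self.per_chrom and self.per_chrom[c].haplotype is not None
                   for c in chroms)


def distal_cn_state(
    segments: list[CopyNumberSegment], spec: TranslocationSpec, chrom: str,
    genome: GenomeModel,
) -> int | None:
    """Integer CN over the distal (exchanged) segment of ``chrom`` (1 or 3 for
    the informative reference patterns; None when mixed/normal/mosaic)."""
    lo, hi = spec.distal_interval(chrom, genome)
    mid = (lo + hi) // 2
    for seg in segments:
        if seg.chrom == chrom and seg.start <= mid <= seg.end:
            if seg.mosaic_fraction is not None:
                return None
            return seg.cn
    return None


def phase_derivative_from_references(
    observations: pd.DataFrame,
    ref_distal_state: dict[str, dict[str, int]],
    spec: TranslocationSpec,
    informative: pd.DataFrame,
    consistency_threshold: float = 0.9,
) -> HaplotypeLinkage:
    """Vote, over reference embryos and proximal-flank informative SNPs, for
    the derivative-linked carrier haplotype of each translocation chromosome.

    ``ref_distal_state`` maps embryo -> chrom -> integer CN of the distal
    segment (1: embryo received der(chrom); 3: embryo received the normal
    homolog, so the observed haplotype votes for the complement).
    """
    if not ref_distal_state:
        raise ValidationError(
            "no reference embryos: derivative haplotypes cannot be phased")
    votes: dict[str, dict[str, int]] = {c: {"H1": 0, "H2": 0} for c in spec.chromosomes}
    prox = informative[informative["flank"] == "proximal"]

    for embryo, states in sorted(ref_distal_state.items()):
        emb_obs = observations[observations["embryo"] == embryo]
        for chrom in spec.chromosomes:
            state = states.get(chrom)
            if state not in (1, 3):
                continue
            sites = prox[prox["chrom"] == chrom]
            merged = sites.merge(emb_obs[emb_obs["chrom"] == chrom][["pos", "alleles"]],
                                 on="pos")
            for obs, h1, h2, p1 in zip(merged["alleles"], merged["h1"],
                                       merged["h2"], merged["p1"]):
                hap = _observed_carrier_allele(obs, h1, h2, p1)
                if hap is None:
                    continue
                voted = hap if state == 1 else _other(hap)
                votes[chrom][voted] += 1

    per_chrom = {}
    for chrom in spec.chromosomes:
        v = votes[chrom]
        total = v["H1"] + v["H2"]
        if total == 0:
            per_chrom[chrom] = ChromLinkage(None, 0, 0)
            continue
        top = max(v, key=lambda h: (v[h], h == "H1"))
        link = ChromLinkage(top, v[top], total - v[top])
        if link.consistency < consistency_threshold:
            raise PhaseError(
                f"phase not resolved on {chrom}: {v['H1']} H1 vs {v['H2']} H2 votes "
                f"(consistency {link.consistency:.2f} < {consistency_threshold})")
        per_chrom[chrom] = link
    return HaplotypeLinkage(per_chrom=per_chrom, source="reference_embryos")


# ---------------------------------------------------------------------------
# linkage from junction-spanning reads
# ---------------------------------------------------------------------------

def phase_from_junction_reads(
    reads, spec: TranslocationSpec, informative: pd.DataFrame,
    consistency_threshold: float = 0.9,
) -> HaplotypeLinkage:
    """Derivative haplotypes from alleles observed on junction-spanning reads.

    Per SNP, the majority allele over supporting reads decides that SNP's vote
    (ties abstain); SNP votes pool per chromosome.
    """
    info_idx = informative.set_index(["chrom", "pos"])
    # (chrom,pos) -> allele -> read count
    site_votes: dict[tuple[str, int], dict[str, int]] = {}
    for read in reads:
        if not read.spans_junction:
            continue
        for chrom, pos, allele in read.snp_alleles:
            if (chrom, pos) not in info_idx.index:
                continue
            site_votes.setdefault((chrom, pos), {}).setdefault(allele, 0)
            site_votes[(chrom, pos)][allele] += 1

    votes: dict[str, dict[str, int]] = {c: {"H1": 0, "H2": 0} for c in spec.chromosomes}
    for (chrom, pos), alleles in site_votes.items():
        site = info_idx.loc[(chrom, pos)]
        best = max(alleles.values())
        winners = [a for a, n in alleles.items() if n == best]
        if len(winners) != 1:
            continue
        allele = winners[0]
        if allele == site["h1"] and allele != site["h2"]:
            votes[chrom]["H1"] += 1
        elif allele == site["h2"] and allele != site["h1"]:
            votes[chrom]["H2"] += 1

    per_chrom = {}
    msgs = []
    for chrom in spec.chromosomes:
        v = votes[chrom]
        total = v["H1"] + v["H2"]
        if total == 0:
            per_chrom[chrom] = ChromLinkage(None, 0, 0)
            msgs.append(f"no junction-spanning read covers an informative SNP on {chrom}")
            continue
        top = max(v, key=lambda h: (v[h], h == "H1"))
        link = ChromLinkage(top, v[top], total - v[top])
        if link.consistency < consistency_threshold:
            raise PhaseError(
                f"junction-read phase not resolved on {chrom}: "
                f"{v['H1']} H1 vs {v['H2']} H2")
        per_chrom[chrom] = link
    return HaplotypeLinkage(per_chrom=per_chrom, source="junction_reads",
                            message="; ".join(msgs))


# ---------------------------------------------------------------------------
# carrier calls
# ---------------------------------------------------------------------------

@dataclass
class CarrierCall:
    embryo_id: str
    call: str  # carrier | non_carrier | inconclusive
    per_chrom: dict[str, dict] = field(default_factory=dict)
    reason: str = ""


def transmitted_haplotype(
    embryo_obs: pd.DataFrame, chrom: str, informative: pd.DataFrame,
    min_snps: int = 5, majority: float = 0.8, flank: str = "proximal",
) -> tuple[str | None, int, int]:
    """Majority-vote transmitted carrier haplotype on one flank.

    Returns (haplotype or None, supporting votes, conflicting votes).  Sites
    where only the partner allele is visible (dropout, or the transmitted
    carrier allele coincides with the partner allele) abstain.
    """
    sites = informative[(informative["chrom"] == chrom) & (informative["flank"] == flank)]
    chrom_obs = embryo_obs[embryo_obs["chrom"] == chrom]
    merged = sites.merge(chrom_obs[["pos", "alleles"]], on="pos")
    counts = {"H1": 0, "H2": 0}
    for obs, h1, h2, p1 in zip(merged["alleles"], merged["h1"],
                               merged["h2"], merged["p1"]):
        hap = _observed_carrier_allele(obs, h1, h2, p1)
        if hap is not None:
            counts[hap] += 1
    total = counts["H1"] + counts["H2"]
    if total < min_snps:
        return None, max(counts.values()) if total else 0, min(counts.values()) if total else 0
    top = max(counts, key=lambda h: (counts[h], h == "H1"))
    if counts[top] / total < majority:
        return None, counts[top], total - counts[top]
    return top, counts[top], total - counts[top]


def call_carrier_status(
    karyotype: KaryotypeCall,
    observations: pd.DataFrame,
    linkage: HaplotypeLinkage,
    spec: TranslocationSpec,
    informative: pd.DataFrame,
    min_snps: int = 5,
    majority: float = 0.8,
) -> CarrierCall:
    """Carrier / non-carrier verdict for one *euploid* embryo.

    The embryo is a carrier iff on both translocation chromosomes the
    transmitted carrier haplotype is the derivative-linked one; a non-carrier
    iff both are normal-linked; anything mixed or under-supported is
    inconclusive.  Unbalanced embryos are refused (carrier calls are only
    defined for balanced embryos).
    """
    if not karyotype.is_euploid:
        raise ValidationError(
            f"embryo {karyotype.embryo_id} is not euploid; carrier status is only "
            f"defined for balanced embryos")
    if not linkage.resolved(spec.chromosomes):
        return CarrierCall(karyotype.embryo_id, "inconclusive", {},
                           reason="derivative haplotype linkage unresolved")
    embryo_obs = observations[observations["embryo"] == karyotype.embryo_id]
    per_chrom = {}
    statuses = []
    for chrom in spec.chromosomes:
        hap, sup, con = transmitted_haplotype(
            embryo_obs, chrom, informative, min_snps=min_snps, majority=majority)
        der_hap = linkage.per_chrom[chrom].haplotype
        status = None if hap is None else ("derivative" if hap == der_hap else "normal")
        per_chrom[chrom] = {"transmitted": hap, "supporting": sup,
                            "conflicting": con, "linked_to": status}
        statuses.append(status)
    if None in statuses:
        return CarrierCall(karyotype.embryo_id, "inconclusive", per_chrom,
                           reason="insufficient or conflicting informative SNPs")
    if all(s == "derivative" for s in statuses):
        return CarrierCall(karyotype.embryo_id, "carrier", per_chrom)
    if all(s == "normal" for s in statuses):
        return CarrierCall(karyotype.embryo_id, "non_carrier", per_chrom)
    return CarrierCall(karyotype.embryo_id, "inconclusive", per_chrom,
                       reason="translocation chromosomes disagree")
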