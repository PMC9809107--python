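"""File-format plumbing: FASTQ, BED, BEDPE, SAM split alignments, TSV tables.

Internal coordinates are 1-based inclusive; BED/BEDPE writers emit 0-based
half-open, SAM goes through pysam.  Outputs are byte-stable given identical
inputs (sorted rows, fixed formats, no timestamps).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GenomeModel
from .sim import AlignmentBlock, BinCounts, LongRead

_BASES = np.array(list("ACGT"))


def write_fastq(reads: list[LongRead], path, rng: np.random.Generator) -> None:
    """FASTQ with random base content (reads carry no sequence-level signal;
    only lengths and mean qscores matter downstream)."""
    records = []
    for read in reads:
        seq = "".join(rng.choice(_BASES, size=read.length))
        rec = SeqRecord(Seq(seq), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(round(read.mean_qscore))] * read.length
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def write_truth_bed(reads: list[LongRead], path) -> None:
    """Every read's alignment blocks, 0-based half-open."""
    with open(path, "w") as fh:
        for read in reads:
            for i, blk in enumerate(read.blocks):
                fh.write(f"{blk.chrom}\t{blk.start - 1}\t{blk.end}\t"
                         f"{read.read_id};{i}\t0\t{blk.strand}\n")


def write_breakpoints_bedpe(clusters, path) -> None:
    with open(path, "w") as fh:
        for cl in sorted(clusters, key=lambda c: (c.chrom1, c.pos1, c.chrom2, c.pos2)):
            fh.write(f"{cl.chrom1}\t{cl.pos1 - 1}\t{cl.pos1}\t"
                     f"{cl.chrom2}\t{cl.pos2 - 1}\t{cl.pos2}\t"
                     f"junction\t{cl.support}\t{cl.strand1}\t{cl.strand2}\n")


# ---------------------------------------------------------------------------
# SAM split alignments
# ---------------------------------------------------------------------------

def _sa_tag(blocks: list[AlignmentBlock], skip: int, qlen: int) -> str:
    parts = []
    for i, blk in enumerate(blocks):
        if i == skip:
            continue
        cig = _cigar_string(blk, qlen)
        parts.append(f"{blk.chrom},{blk.start},{blk.strand},{cig},60,0")
    return ";".join(parts) + ";" if parts else ""


def _cigar_tuples(blk: AlignmentBlock, qlen: int) -> list[tuple[int, int]]:
    left, mid, right = blk.qstart, blk.qend - blk.qstart, qlen - blk.qend
    if blk.strand == "-":
        left, right = right, left
    out = []
    if left:
        out.append((4, left))
    out.append((0, mid))
    if right:
        out.append((4, right))
    return out


def _cigar_string(blk: AlignmentBlock, qlen: int) -> str:
    names = {0: "M", 4: "S"}
    return "".join(f"{n}{names[op]}" for op, n in _cigar_tuples(blk, qlen))


def write_split_sam(reads: list[LongRead], genome: GenomeModel, path) -> None:
    """One SAM record per alignment block; supplementary flag + SA tags on the
    non-primary blocks, qscore preserved in a 'qs' float tag."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in genome.lengths.items()],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            for i, blk in enumerate(read.blocks):
                a = pysam.AlignedSegment(header)
                a.query_name = read.read_id
                a.reference_name = blk.chrom
                a.reference_start = blk.start - 1
                a.mapping_quality = 60
                a.cigartuples = _cigar_tuples(blk, read.length)
                flag = 0
                if blk.strand == "-":
                    flag |= 16
                if i > 0:
                    flag |= 2048
                a.flag = flag
                tags = [("qs", float(read.mean_qscore))]
                sa = _sa_tag(read.blocks, i, read.length)
                if sa:
                    tags.append(("SA", sa))
                a.set_tags(tags)
                out.write(a)


def read_split_sam(path) -> list[LongRead]:
    """Reconstruct split reads (ordered alignment blocks) from a SAM file."""
    by_name: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            cig = aln.cigartuples or []
            left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            right = cig[-1][1] if len(cig) > 1 and cig[-1][0] in (4, 5) else 0
            mid = sum(n for op, n in cig if op in (0, 7, 8))
            qlen = left + mid + right
            if aln.is_reverse:
                qstart = right
            else:
                qstart = left
            blk = AlignmentBlock(
                chrom=aln.reference_name, start=aln.reference_start + 1,
                end=aln.reference_end, strand="-" if aln.is_reverse else "+",
                qstart=qstart, qend=qstart + mid)
            entry = by_name.setdefault(aln.query_name, {
                "blocks": [], "qlen": qlen,
                "qs": float(aln.get_tag("qs")) if aln.has_tag("qs") else 0.0})
            entry["blocks"].append(blk)
    reads = []
    for name in sorted(by_name):
        entry = by_name[name]
        blocks = sorted(entry["blocks"], key=lambda b: b.qstart)
        reads.append(LongRead(read_id=name, length=entry["qlen"],
                              mean_qscore=entry["qs"], blocks=blocks))
    return reads


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_bin_counts_tsv(all_counts: list[BinCounts], path) -> None:
    rows = []
    for bc in all_counts:
        for chrom, arr in bc.counts.items():
            starts = np.arange(len(arr)) * bc.bin_width + 1
            rows.append(pd.DataFrame({
                "embryo": bc.embryo_id, "chrom": chrom, "bin_start": starts,
                "bin_width": bc.bin_width, "count": arr}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_bin_counts_tsv(path) -> list[BinCounts]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for embryo, grp in df.groupby("embryo", sort=True):
        width = int(grp["bin_width"].iloc[0])
        counts = {chrom: g.sort_values("bin_start")["count"].to_numpy(dtype=np.int64)
                  for chrom, g in grp.groupby("chrom", sort=True)}
        out.append(BinCounts(embryo_id=str(embryo), bin_width=width, counts=counts))
    return out


def write_snp_obs_tsv(obs: pd.DataFrame, path) -> None:
    obs.sort_values(["embryo", "chrom", "pos"]).to_csv(path, sep="\t", index=False)


def read_snp_obs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
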