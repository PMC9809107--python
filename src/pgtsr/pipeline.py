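"""End-to-end orchestration: simulate -> CNV -> breakpoints -> phase -> report.

Every stage threshold lives in :class:`PipelineConfig`; a master seed
deterministically derives per-stage generators, so config + seed fully
determine every output byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import breakpoints as bp
from . import cnv, phase, sim
from .genome import CytobandMap, GenomeModel, TranslocationSpec
from . import io as pio

log = logging.getLogger("pgtsr")


@dataclass
class PipelineConfig:
    """All tunables of the toy-pedigree pipeline (units: bp unless noted)."""

    seed: int = 1
    # genome / translocation
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    snp_spacing: int = 2_000
    bp_a: int = 3_000_000
    bp_b: int = 1_200_000
    arm_a: str = "q"
    arm_b: str = "p"
    carrier_parent: str = "maternal"
    # pedigree
    n_embryos: int = 12
    mode_weights: dict = field(default_factory=lambda: {
        "alternate": 0.5, "adjacent1": 0.3, "adjacent2": 0.2, "three_to_one": 0.0})
    # optional planted mosaic events: dicts with embryo, chrom, start, end,
    # kind (gained|lost), fraction
    mosaic_events: list = field(default_factory=list)
    # counts
    bin_width_fine: int = 25_000
    coarse_factor: int = 4          # coarse bins = 100 kb
    mean_count_fine: float = 100.0  # per disomic fine bin
    dispersion: float = 0.1
    # SNP observations
    ado: float = 0.05
    snp_error_rate: float = 0.002
    snp_depth: float = 30.0
    # long reads
    n_reads: int = 8_000   # ~6x depth on the 20 Mb carrier genome
    read_mean_length: float = 15_000.0
    qscore_mean: float = 12.0
    qscore_sd: float = 1.5
    low_q_frac: float = 0.05
    min_mean_qscore: float = 7.0
    # segmentation / calling
    min_segment_bins: int = 3
    change_threshold: float = 0.3
    refine_window_bins: int = 25
    # junctions
    cluster_tolerance: int = 10
    min_junction_support: int = 3
    # phasing / carrier calls
    flank_window: int = 2_000_000
    min_informative_snps: int = 5
    vote_majority: float = 0.8
    phase_consistency: float = 0.9

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SimBundle:
    genome: GenomeModel
    spec: TranslocationSpec
    derivatives: sim.DerivativePair
    cytobands: CytobandMap
    truths: list[sim.EmbryoTruth]
    bin_counts: list[sim.BinCounts]     # fine bins
    snp_obs: pd.DataFrame
    reads: list[sim.LongRead]


def simulate_stage(cfg: PipelineConfig) -> SimBundle:
    rngs = _rngs(cfg.seed, ["pedigree", "counts", "snps", "reads"])
    genome = GenomeModel.toy(
        n_chromosomes=cfg.n_chromosomes, length=cfg.chrom_length,
        snp_spacing=cfg.snp_spacing, seed=cfg.seed)
    spec = TranslocationSpec(
        chrom_a="chr1", chrom_b="chr2", bp_a=cfg.bp_a, bp_b=cfg.bp_b,
        arm_a=cfg.arm_a, arm_b=cfg.arm_b, carrier_parent=cfg.carrier_parent)
    derivatives = sim.build_derivatives(spec, genome)
    cytobands = CytobandMap.toy(genome.lengths)
    truths = sim.make_pedigree(
        spec, genome, derivatives, cfg.n_embryos, cfg.mode_weights, rngs["pedigree"])
    for ev in cfg.mosaic_events:
        ev = dict(ev)
        target = ev.pop("embryo")
        for t in truths:
            if t.embryo_id == target:
                t.mosaic_events = t.mosaic_events + (sim.MosaicEvent(**ev),)
    counts = []
    for truth in truths:
        expected = sim.true_copy_profile(truth, genome, cfg.bin_width_fine)
        counts.append(sim.simulate_bin_counts(
            expected, cfg.mean_count_fine, cfg.dispersion, rngs["counts"],
            embryo_id=truth.embryo_id, bin_width=cfg.bin_width_fine))
    snp_obs = sim.simulate_snp_observations(
        truths, spec, genome, rngs["snps"], ado=cfg.ado,
        error_rate=cfg.snp_error_rate, depth=cfg.snp_depth)
    reads = sim.simulate_long_reads(
        spec, genome, derivatives, cfg.n_reads, rngs["reads"],
        mean_length=cfg.read_mean_length, qscore_mean=cfg.qscore_mean,
        qscore_sd=cfg.qscore_sd, low_q_frac=cfg.low_q_frac)
    return SimBundle(genome, spec, derivatives, cytobands, truths, counts,
                     snp_obs, reads)


def cnv_stage(bundle: SimBundle, cfg: PipelineConfig):
    """Coarse segmentation + CN calls + karyotype strings + classification.

    Returns (karyotypes, classes, called segments per embryo at coarse
    resolution, normalized fine CN per embryo for boundary refinement).
    """
    karyotypes, classes, segments_by_embryo, fine_cn = {}, {}, {}, {}
    for bc in bundle.bin_counts:
        coarse = sim.rebin_counts(bc, cfg.coarse_factor)
        cn_coarse = cnv.normalize_counts(coarse)
        fine_cn[bc.embryo_id] = cnv.normalize_counts(bc)
        segs = cnv.annotate_calls(cnv.segment_profile(
            cn_coarse, coarse.bin_width, bundle.genome.lengths,
            min_bins=cfg.min_segment_bins, threshold=cfg.change_threshold))
        segments_by_embryo[bc.embryo_id] = segs
        call = cnv.to_karyotype_string(bc.embryo_id, segs, bundle.cytobands)
        karyotypes[bc.embryo_id] = call
        classes[bc.embryo_id] = cnv.classify_embryo(call, bundle.spec)
        log.info("embryo %s: %s (%s)", bc.embryo_id, call.serialize(),
                 classes[bc.embryo_id].label)
    return karyotypes, classes, segments_by_embryo, fine_cn


def breakpoint_stage(bundle: SimBundle, cfg: PipelineConfig, classes,
                     segments_by_embryo, fine_cn):
    """CNV consensus (with fine-bin boundary refinement) + split-read junctions."""
    ref_ids = [e for e, c in classes.items() if c.label == "reference_unbalanced"]
    refined: dict[str, list[int]] = {}
    candidates = {}
    for embryo in ref_ids:
        cands_by_chrom = {}
        for chrom in bundle.spec.chromosomes:
            raw = bp.boundary_candidates(
                segments_by_embryo[embryo], chrom, bundle.genome.lengths[chrom])
            cands_by_chrom[chrom] = [
                cnv.refine_boundary(fine_cn[embryo][chrom], cfg.bin_width_fine,
                                    b, cfg.refine_window_bins)
                for b in raw]
        candidates[embryo] = cands_by_chrom
    cnv_estimates = {}
    for chrom in bundle.spec.chromosomes:
        cnv_estimates[chrom] = bp.consensus_boundary(
            {e: candidates[e][chrom] for e in ref_ids}, chrom, cfg.bin_width_fine)

    passing = bp.qc_filter_reads(bundle.reads, cfg.min_mean_qscore)
    stats = bp.read_stats(passing, bundle.genome.total_length)
    clusters = bp.detect_junctions(
        passing, tolerance=cfg.cluster_tolerance, min_support=cfg.min_junction_support)
    split_estimates = bp.breakpoints_from_junctions(clusters, bundle.spec)
    concordance = {
        chrom: bp.check_concordance(cnv_estimates[chrom], split_estimates[chrom])
        for chrom in bundle.spec.chromosomes}
    return cnv_estimates, split_estimates, clusters, concordance, stats, passing


def phase_stage(bundle: SimBundle, cfg: PipelineConfig, karyotypes, classes,
                segments_by_embryo, split_estimates, passing_reads):
    breakpoints = {c: est.position for c, est in split_estimates.items()}
    informative = phase.select_informative_snps(
        bundle.genome.snps, bundle.spec, breakpoints, flank_window=cfg.flank_window)
    ref_state = {}
    for embryo, klass in classes.items():
        if klass.label != "reference_unbalanced":
            continue
        ref_state[embryo] = {
            chrom: phase.distal_cn_state(
                segments_by_embryo[embryo], bundle.spec, chrom, bundle.genome)
            for chrom in bundle.spec.chromosomes}
    linkage_ref = phase.phase_derivative_from_references(
        bundle.snp_obs, ref_state, bundle.spec, informative,
        consistency_threshold=cfg.phase_consistency)
    linkage_reads = phase.phase_from_junction_reads(
        passing_reads, bundle.spec, informative,
        consistency_threshold=cfg.phase_consistency)
    linkage = linkage_ref if linkage_ref.resolved(bundle.spec.chromosomes) else linkage_reads

    carrier_calls = {}
    for embryo, klass in sorted(classes.items()):
        if klass.label != "euploid":
            continue
        carrier_calls[embryo] = phase.call_carrier_status(
            karyotypes[embryo], bundle.snp_obs, linkage, bundle.spec, informative,
            min_snps=cfg.min_informative_snps, majority=cfg.vote_majority)
    return informative, linkage_ref, linkage_reads, carrier_calls


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: SimBundle
    karyotypes: dict
    classes: dict
    segments_by_embryo: dict
    cnv_estimates: dict
    split_estimates: dict
    clusters: list
    concordance: dict
    read_stats: bp.ReadStats
    informative: pd.DataFrame
    linkage_ref: phase.HaplotypeLinkage
    linkage_reads: phase.HaplotypeLinkage
    carrier_calls: dict


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    log.info("pipeline seed=%d thresholds: change=%.2f tol=%d support=%d "
             "flank=%d min_snps=%d majority=%.2f consistency=%.2f",
             cfg.seed, cfg.change_threshold, cfg.cluster_tolerance,
             cfg.min_junction_support, cfg.flank_window, cfg.min_informative_snps,
             cfg.vote_majority, cfg.phase_consistency)
    bundle = simulate_stage(cfg)
    karyotypes, classes, segments_by_embryo, fine_cn = cnv_stage(bundle, cfg)
    cnv_est, split_est, clusters, concordance, stats, passing = breakpoint_stage(
        bundle, cfg, classes, segments_by_embryo, fine_cn)
    informative, linkage_ref, linkage_reads, carrier_calls = phase_stage(
        bundle, cfg, karyotypes, classes, segments_by_embryo, split_est, passing)
    return PipelineResult(
        config=cfg, bundle=bundle, karyotypes=karyotypes, classes=classes,
        segments_by_embryo=segments_by_embryo, cnv_estimates=cnv_est,
        split_estimates=split_est, clusters=clusters, concordance=concordance,
        read_stats=stats, informative=informative, linkage_ref=linkage_ref,
        linkage_reads=linkage_reads, carrier_calls=carrier_calls)


def _linkage_dict(linkage: phase.HaplotypeLinkage) -> dict:
    return {
        "source": linkage.source,
        "per_chrom": {
            chrom: {"haplotype": l.haplotype, "votes_for": l.votes_for,
                    "votes_against": l.votes_against}
            for chrom, l in sorted(linkage.per_chrom.items())},
    }


def write_report(result: PipelineResult, outdir) -> dict[str, Path]:
    """TSV/BED/BEDPE/JSON report bundle; byte-stable for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    rows = [{"embryo": e, "class": result.classes[e].label,
             "karyotype": result.karyotypes[e].serialize()}
            for e in sorted(result.karyotypes)]
    files["karyotypes"] = outdir / "karyotypes.tsv"
    pd.DataFrame(rows).to_csv(files["karyotypes"], sep="\t", index=False)

    bp_rows = []
    for method, estimates in (("cnv_boundary", result.cnv_estimates),
                              ("split_read", result.split_estimates)):
        for chrom, est in sorted(estimates.items()):
            bp_rows.append({"chrom": chrom, "method": method, "position": est.position,
                            "half_window": est.half_window, "support": est.support})
    files["breakpoints"] = outdir / "breakpoints.tsv"
    pd.DataFrame(bp_rows).to_csv(files["breakpoints"], sep="\t", index=False)

    files["junctions"] = outdir / "junctions.bedpe"
    pio.write_breakpoints_bedpe(result.clusters, files["junctions"])

    conc = [{"chrom": c, "distance_bp": v.distance, "within_window": v.within_window}
            for c, v in sorted(result.concordance.items())]
    files["concordance"] = outdir / "concordance.tsv"
    pd.DataFrame(conc).to_csv(files["concordance"], sep="\t", index=False)

    calls = [{"embryo": e, "call": c.call,
              **{f"{chrom}_{k}": v for chrom, d in sorted(c.per_chrom.items())
                 for k, v in d.items()}}
             for e, c in sorted(result.carrier_calls.items())]
    files["carrier_calls"] = outdir / "carrier_calls.tsv"
    pd.DataFrame(calls).to_csv(files["carrier_calls"], sep="\t", index=False)

    files["haplotype_matrix"] = outdir / "haplotype_matrix.tsv"
    _write_haplotype_matrix(result, files["haplotype_matrix"])

    summary = {
        "n_embryos": len(result.karyotypes),
        "n_reference": sum(c.label == "reference_unbalanced"
                           for c in result.classes.values()),
        "n_euploid": sum(c.label == "euploid" for c in result.classes.values()),
        "carrier_calls": {e: c.call for e, c in sorted(result.carrier_calls.items())},
        "linkage_reference_embryos": _linkage_dict(result.linkage_ref),
        "linkage_junction_reads": _linkage_dict(result.linkage_reads),
        "read_stats": dataclasses.asdict(result.read_stats),
        "concordance": {c: {"distance_bp": v.distance, "within_window": v.within_window}
                        for c, v in sorted(result.concordance.items())},
    }
    files["summary"] = outdir / "summary.json"
    pio.write_json(summary, files["summary"])
    files["config"] = outdir / "config.yaml"
    result.config.to_yaml(files["config"])
    return files


def _write_haplotype_matrix(result: PipelineResult, path) -> None:
    """Rows = proximal informative SNPs, columns = euploid embryos, cells = the
    carrier haplotype read at that site ('.' when unreadable)."""
    prox = result.informative[result.informative["flank"] == "proximal"]
    euploid = sorted(e for e, c in result.classes.items() if c.label == "euploid")
    obs = result.bundle.snp_obs.set_index(["embryo", "chrom", "pos"])["alleles"]
    rows = []
    for _, site in prox.sort_values(["chrom", "pos"]).iterrows():
        row = {"chrom": site["chrom"], "pos": int(site["pos"]),
               "h1": site["h1"], "h2": site["h2"]}
        for e in euploid:
            key = (e, site["chrom"], int(site["pos"]))
            hap = None
            if key in obs.index:
                hap = phase._observed_carrier_allele(
                    obs[key], site["h1"], site["h2"], site["p1"])
            row[e] = hap or "."
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
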