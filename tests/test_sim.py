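"""Simulator unit and property tests: derivatives, segregation, counts, SNPs, reads."""
import numpy as np
import pytest

from pgtsr.genome import GenomeModel, TranslocationSpec, ValidationError
from pgtsr.sim import (MODE_OUTCOMES, MosaicEvent, build_derivatives,
                       element_intervals, make_embryo, segregate,
                       simulate_bin_counts, simulate_long_reads,
                       simulate_snp_observations, true_copy_profile)


# ---------------------------------------------------------------------------
# derivative construction
# ---------------------------------------------------------------------------

def per_base_coverage(fragments, lengths):
    cov = {c: np.zeros(l, dtype=int) for c, l in lengths.items()}
    for f in fragments:
        cov[f.chrom][f.start - 1: f.end] += 1
    return cov


def test_derivatives_partition_every_base_exactly_once(micro_genome):
    """Brute-force scan on a 2 kb genome: der(A) u der(B) tiles A u B exactly."""
    for arms in [("q", "p"), ("q", "q"), ("p", "p"), ("p", "q")]:
        spec = TranslocationSpec("chr1", "chr2", 400, 300, *arms)
        der = build_derivatives(spec, micro_genome)
        cov = per_base_coverage(der.der_a + der.der_b, micro_genome.lengths)
        for chrom in ("chr1", "chr2"):
            assert (cov[chrom] == 1).all(), f"arms={arms} chrom={chrom}"


def test_derivative_base_conservation_toy():
    genome = GenomeModel.toy(n_chromosomes=2, length=1_000, snp_spacing=500, seed=0)
    spec = TranslocationSpec("chr1", "chr2", 400, 300, "q", "p")
    der = build_derivatives(spec, genome)
    len_a = sum(len(f) for f in der.der_a)
    len_b = sum(len(f) for f in der.der_b)
    assert len_a == 400 + 300 == 700
    assert len_b == 600 + 700 == 1300
    assert len_a + len_b == 2000


def test_qp_junction_breakends_match_published_convention():
    """q<->p: der(A) = A:1..bp_a (+) then B:bp_b..1 (-), e.g. the t(2;5) case."""
    genome = GenomeModel(lengths={"chr2": 243_199_373, "chr5": 180_915_260})
    spec = TranslocationSpec("chr2", "chr5", 125_157_514, 35_465_883, "q", "p")
    der = build_derivatives(spec, genome)
    assert der.der_a[0].chrom == "chr2"
    assert (der.der_a[0].start, der.der_a[0].end, der.der_a[0].strand) == (1, 125_157_514, "+")
    assert (der.der_a[1].start, der.der_a[1].end, der.der_a[1].strand) == (1, 35_465_883, "-")
    left, right = der.junction("der_a")
    assert left == ("chr2", 125_157_514, "+")
    assert right == ("chr5", 35_465_883, "-")


def test_breakpoint_outside_chromosome_rejected(micro_genome):
    spec = TranslocationSpec("chr1", "chr2", 5_000, 300, "q", "p")
    with pytest.raises(ValidationError):
        build_derivatives(spec, micro_genome)


# ---------------------------------------------------------------------------
# segregation
# ---------------------------------------------------------------------------

def test_segregation_balance_by_mode(toy_spec, toy_genome, toy_derivatives, rng):
    """Alternate gametes are always balanced; adjacent/3:1 never are."""
    for _ in range(250):
        for mode, expect in [("alternate", True), ("adjacent1", False),
                             ("adjacent2", False), ("three_to_one", False)]:
            g = segregate(toy_spec, toy_genome, toy_derivatives, mode, rng)
            assert g.balanced is expect
            assert g.elements in MODE_OUTCOMES[mode]


def test_unknown_mode_rejected(toy_spec, toy_genome, toy_derivatives, rng):
    with pytest.raises(ValidationError):
        segregate(toy_spec, toy_genome, toy_derivatives, "nondisjunction", rng)


def test_adjacent1_copy_number_pattern(toy_spec, toy_genome, toy_derivatives, rng):
    """{der_a, B_normal}: monosomic distal q(A), trisomic distal p(B)."""
    while True:
        g = segregate(toy_spec, toy_genome, toy_derivatives, "adjacent1", rng)
        if g.elements == frozenset({"der_a", "B_normal"}):
            break
    emb = make_embryo(toy_spec, toy_genome, toy_derivatives, g, "X")
    cn = {(c, s, e): v for c, segs in emb.cn_segments.items() for s, e, v in segs}
    assert cn[("chr1", 1, 3_000_000)] == 2
    assert cn[("chr1", 3_000_001, 5_000_000)] == 1       # lost distal q(A)
    assert cn[("chr2", 1, 1_200_000)] == 3               # gained distal p(B)
    assert cn[("chr2", 1_200_001, 5_000_000)] == 2
    assert emb.carrier_status == "unbalanced"


def test_adjacent2_copy_number_pattern(toy_spec, toy_genome, toy_derivatives, rng):
    """{A_normal, der_a}: trisomic proximal A, disomic both distal fragments,
    monosomic rest of B."""
    while True:
        g = segregate(toy_spec, toy_genome, toy_derivatives, "adjacent2", rng)
        if g.elements == frozenset({"A_normal", "der_a"}):
            break
    emb = make_embryo(toy_spec, toy_genome, toy_derivatives, g, "X")
    cn = {(c, s, e): v for c, segs in emb.cn_segments.items() for s, e, v in segs}
    assert cn[("chr1", 1, 3_000_000)] == 3
    assert cn[("chr1", 3_000_001, 5_000_000)] == 2
    assert cn[("chr2", 1, 1_200_000)] == 2
    assert cn[("chr2", 1_200_001, 5_000_000)] == 1


def test_carrier_status_semantics(toy_spec, toy_genome, toy_derivatives, rng):
    g = segregate(toy_spec, toy_genome, toy_derivatives, "alternate", rng)
    emb = make_embryo(toy_spec, toy_genome, toy_derivatives, g, "X")
    if g.elements == frozenset({"der_a", "der_b"}):
        assert emb.carrier_status == "balanced_carrier"
    else:
        assert emb.carrier_status == "non_carrier"


# ---------------------------------------------------------------------------
# copy profiles and bin counts
# ---------------------------------------------------------------------------

def _embryo(toy_spec, toy_genome, toy_derivatives, elements, mosaic=()):
    from pgtsr.sim import GameteSpec, is_balanced
    g = GameteSpec("manual", frozenset(elements),
                   is_balanced(frozenset(elements), toy_spec, toy_genome, toy_derivatives))
    return make_embryo(toy_spec, toy_genome, toy_derivatives, g, "X",
                       mosaic_events=tuple(mosaic))


def test_true_copy_profile_plain_and_mosaic(toy_spec, toy_genome, toy_derivatives):
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"der_a", "B_normal"},
                  mosaic=[MosaicEvent("chr2", 2_000_001, 3_000_000, "gained", 0.31)])
    prof = true_copy_profile(emb, toy_genome, 100_000)
    assert prof["chr1"][0] == pytest.approx(2.0)
    assert prof["chr1"][-1] == pytest.approx(1.0)
    assert prof["chr2"][0] == pytest.approx(3.0)     # non-mosaic trisomy
    assert prof["chr2"][25] == pytest.approx(2.31)   # 2(1-f) + 3f
    assert prof["chr2"][-1] == pytest.approx(2.0)


def test_bin_straddling_boundary_is_length_weighted(toy_spec, toy_genome, toy_derivatives):
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"der_a", "B_normal"})
    # 800 kb bins: chr1 bin index 3 covers 2,400,001..3,200,000 -> 600k at CN2 + 200k at CN1
    prof = true_copy_profile(emb, toy_genome, 800_000)
    assert prof["chr1"][3] == pytest.approx((600_000 * 2 + 200_000 * 1) / 800_000)


def test_mosaic_fraction_range_enforced():
    with pytest.raises(ValidationError):
        MosaicEvent("chr1", 1, 100, "gained", 1.2)


def test_bin_count_means_and_overdispersion(rng):
    cn = {"chr1": np.full(10_000, 2.0)}
    bc = simulate_bin_counts(cn, 100.0, 0.1, rng)
    mean = bc.counts["chr1"].mean()
    assert mean == pytest.approx(100.0, rel=0.02)
    assert bc.counts["chr1"].var() >= mean * 0.9  # variance >= mean

    cn = {"chr1": np.full(10_000, 2.31)}
    bc = simulate_bin_counts(cn, 100.0, 0.1, rng)
    assert bc.counts["chr1"].mean() == pytest.approx(115.5, rel=0.02)


def test_bin_count_mean_within_three_standard_errors(rng):
    for cn_val in (1.0, 2.0, 3.0):
        n = 5_000
        bc = simulate_bin_counts({"c": np.full(n, cn_val)}, 80.0, 0.1, rng)
        mu = 80.0 * cn_val / 2
        se = np.sqrt(mu * 1.1 / n)
        assert abs(bc.counts["c"].mean() - mu) < 3 * se


def test_zero_dispersion_is_deterministic_rounding(rng):
    cn = {"chr1": np.array([2.0, 2.31, 1.0, 0.0])}
    bc = simulate_bin_counts(cn, 100.0, 0.0, rng)
    assert bc.counts["chr1"].tolist() == [100, 116, 50, 0]


def test_negative_dispersion_rejected(rng):
    with pytest.raises(ValidationError):
        simulate_bin_counts({"c": np.array([2.0])}, 100.0, -0.1, rng)


# ---------------------------------------------------------------------------
# SNP observations
# ---------------------------------------------------------------------------

def _informative_mask(genome, chrom):
    snps = genome.chrom_snps(chrom)
    return (snps["h1"] != snps["h2"]) & (snps["p1"] == snps["p2"])


def test_snp_observations_no_noise_disomic_het(toy_spec, toy_genome, toy_derivatives, rng):
    """ado=0, err=0: at carrier-het partner-hom disomic sites both the carrier
    and partner alleles are observed."""
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"A_normal", "B_normal"})
    obs = simulate_snp_observations([emb], toy_spec, toy_genome, rng)
    snps = toy_genome.chrom_snps("chr1").reset_index(drop=True)
    chrom_obs = obs[obs["chrom"] == "chr1"].reset_index(drop=True)
    info = _informative_mask(toy_genome, "chr1").reset_index(drop=True)
    # normal homolog carries H2: expected alleles = {h2, p1}
    expected = [
        "/".join(sorted({r.h2, r.p1})) for r in snps.itertuples()
    ]
    got = chrom_obs["alleles"].tolist()
    mism = [i for i in range(len(got)) if info[i] and got[i] != expected[i]]
    assert not mism


def test_monosomic_region_shows_only_partner_allele(toy_spec, toy_genome, toy_derivatives, rng):
    """Embryo with der(A) only: distal q(A) is monosomic, so carrier-het sites
    there expose the partner allele alone."""
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"der_a", "B_normal"})
    obs = simulate_snp_observations([emb], toy_spec, toy_genome, rng)
    snps = toy_genome.chrom_snps("chr1")
    distal = snps[snps["pos"] > toy_spec.bp_a]
    merged = obs.merge(distal, on=["chrom", "pos"])
    for r in merged.itertuples():
        assert set(r.alleles.split("/")) <= {r.p1, r.p2}


def test_full_ado_reports_exactly_one_allele(toy_spec, toy_genome, toy_derivatives, rng):
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"A_normal", "B_normal"})
    obs = simulate_snp_observations([emb], toy_spec, toy_genome, rng, ado=1.0)
    assert (obs["alleles"].str.split("/").str.len() == 1).all()


def test_rate_out_of_range_rejected(toy_spec, toy_genome, toy_derivatives, rng):
    emb = _embryo(toy_spec, toy_genome, toy_derivatives, {"A_normal", "B_normal"})
    with pytest.raises(ValidationError):
        simulate_snp_observations([emb], toy_spec, toy_genome, rng, ado=1.5)


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def test_long_reads_junction_blocks_and_flags(toy_spec, toy_genome, toy_derivatives, rng):
    reads = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 2_000, rng)
    junction = [r for r in reads if r.spans_junction]
    assert junction, "no junction-spanning reads sampled"
    for r in junction:
        if r.molecule == "der_a":
            b1, b2 = r.blocks
            # q<->p: der(A) junction ends at (A, bp_a, +) and resumes at (B, bp_b, -)
            assert (b1.chrom, b1.end, b1.strand) == ("chr1", toy_spec.bp_a, "+")
            assert (b2.chrom, b2.end, b2.strand) == ("chr2", toy_spec.bp_b, "-")
    single = [r for r in reads if len(r.blocks) == 1]
    assert all(not r.spans_junction for r in single)


def test_long_read_snp_alleles_follow_molecule_haplotype(toy_spec, toy_genome,
                                                         toy_derivatives, rng):
    reads = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 500, rng)
    snps = toy_genome.snps.set_index(["chrom", "pos"])
    for r in reads:
        col = "h1" if r.molecule in ("der_a", "der_b") else "h2"
        for chrom, pos, allele in r.snp_alleles:
            assert allele == snps.loc[(chrom, pos), col]


def test_low_quality_reads_flagged_for_qc(toy_spec, toy_genome, toy_derivatives, rng):
    reads = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 1_000, rng,
                                low_q_frac=0.2)
    n_low = sum(r.mean_qscore < 7.0 for r in reads)
    assert 0.1 < n_low / len(reads) < 0.35


def test_fixed_seed_gives_identical_reads(toy_spec, toy_genome, toy_derivatives):
    a = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 200,
                            np.random.default_rng(7))
    b = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 200,
                            np.random.default_rng(7))
    assert a == b
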