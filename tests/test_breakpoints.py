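"""Breakpoint mapping tests: QC, read stats, CNV consensus, junction clustering."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgtsr.breakpoints import (BreakpointEstimate, boundary_candidates,
                               breakpoints_from_junctions, check_concordance,
                               consensus_boundary, detect_junctions,
                               localize_from_cnv, qc_filter_reads, read_stats)
from pgtsr.cnv import (CopyNumberSegment, annotate_calls, normalize_counts,
                       segment_chromosome)
from pgtsr.genome import ValidationError
from pgtsr.sim import (AlignmentBlock, GameteSpec, LongRead, make_embryo,
                       simulate_bin_counts, simulate_long_reads,
                       true_copy_profile)


def _read(read_id="r", length=100, q=10.0, blocks=()):
    return LongRead(read_id=read_id, length=length, mean_qscore=q,
                    blocks=list(blocks))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def test_qc_threshold_is_strict_less_than():
    """Quality 7.0 passes; only reads strictly below the threshold are removed."""
    reads = [_read("a", q=6.9), _read("b", q=7.0), _read("c", q=12.0)]
    passing = qc_filter_reads(reads)
    assert [r.read_id for r in passing] == ["b", "c"]


def test_qc_empty_and_zero_threshold():
    assert qc_filter_reads([]) == []
    reads = [_read("a", q=1.0), _read("b", q=20.0)]
    assert qc_filter_reads(reads, min_mean_qscore=0) == reads


def test_qc_idempotent_and_order_independent(rng):
    reads = [_read(f"r{i}", q=float(q)) for i, q in enumerate(rng.uniform(2, 15, 50))]
    once = qc_filter_reads(reads)
    assert qc_filter_reads(once) == once
    shuffled = list(reads)
    rng.shuffle(shuffled)
    assert {r.read_id for r in qc_filter_reads(shuffled)} == {r.read_id for r in once}


# ---------------------------------------------------------------------------
# read stats
# ---------------------------------------------------------------------------

def _brute_force_n50(lengths):
    total = sum(lengths)
    for L in sorted(lengths, reverse=True):
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    return 0


def test_read_stats_worked_examples():
    reads = [_read(length=l) for l in (40, 30, 20, 10)]
    s = read_stats(reads, 1000)
    assert (s.total_bases, s.n50) == (100, 30)
    s = read_stats([_read(length=500)], 1000)
    assert (s.n50, s.mean_depth) == (500, 0.5)


def test_read_stats_zero_reads_warns():
    with pytest.warns(UserWarning):
        s = read_stats([], 1000)
    assert s.n50 == 0 and s.n_reads == 0


def test_read_stats_genome_size_validated():
    with pytest.raises(ValidationError):
        read_stats([_read()], 0)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.integers(1, 100_000), min_size=1, max_size=300))
def test_n50_matches_brute_force_oracle(lengths):
    reads = [_read(f"r{i}", length=l) for i, l in enumerate(lengths)]
    s = read_stats(reads, 10_000)
    assert s.n50 == _brute_force_n50(lengths)
    assert s.n50 in lengths  # N50 is a length present in the read set


# ---------------------------------------------------------------------------
# CNV-boundary consensus
# ---------------------------------------------------------------------------

def test_consensus_modal_position_and_support():
    est = consensus_boundary(
        {"e1": [125_200_001], "e2": [125_200_001], "e3": [125_400_001]},
        "chr2", bin_width=200_000)
    assert est.position == 125_200_001
    assert est.support == 3
    assert est.half_window == 200_000
    assert est.method == "cnv_boundary"


def test_consensus_single_embryo():
    est = consensus_boundary({"e1": [1_000_001]}, "chr1", bin_width=50_000)
    assert est.position == 1_000_001
    assert est.half_window == 50_000
    assert est.support == 1


def test_no_reference_embryos_is_an_error(toy_spec, toy_genome):
    with pytest.raises(ValidationError, match="carrier status"):
        localize_from_cnv({}, toy_spec, toy_genome.lengths, 100_000)
    with pytest.raises(ValidationError, match="reference"):
        consensus_boundary({"e1": []}, "chr1", 100_000)


def test_boundary_candidates_terminal_and_interstitial():
    segs = annotate_calls([CopyNumberSegment("chr1", 2_000_001, 5_000_000, 1.0)])
    assert boundary_candidates(segs, "chr1", 5_000_000) == [2_000_001]
    segs = annotate_calls([CopyNumberSegment("chr1", 1, 2_000_000, 3.0)])
    assert boundary_candidates(segs, "chr1", 5_000_000) == [2_000_001]
    segs = annotate_calls([CopyNumberSegment("chr1", 1_000_001, 2_000_000, 1.0)])
    assert boundary_candidates(segs, "chr1", 5_000_000) == [1_000_001, 2_000_001]


def test_localize_from_cnv_simulation_recovery(toy_spec, toy_genome, toy_derivatives):
    """|estimate - truth| <= bin width in >=95% of 100 seeded replicates,
    pooling three reference embryos per replicate."""
    bin_width = 100_000
    gametes = [GameteSpec("adjacent1", frozenset({"der_a", "B_normal"}), False),
               GameteSpec("adjacent1", frozenset({"A_normal", "der_b"}), False),
               GameteSpec("adjacent2", frozenset({"A_normal", "der_a"}), False)]
    truths = [make_embryo(toy_spec, toy_genome, toy_derivatives, g, f"e{i}")
              for i, g in enumerate(gametes)]
    profiles = [true_copy_profile(t, toy_genome, bin_width) for t in truths]
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(20_000 + seed)
        segs_by_embryo = {}
        for truth, prof in zip(truths, profiles):
            bc = simulate_bin_counts(prof, 400.0, 0.1, rng, bin_width=bin_width)
            cn = normalize_counts(bc)
            segs = []
            for chrom in toy_spec.chromosomes:
                segs.extend(annotate_calls(segment_chromosome(
                    cn[chrom], chrom, bin_width, toy_genome.lengths[chrom])))
            segs_by_embryo[truth.embryo_id] = segs
        est = localize_from_cnv(segs_by_embryo, toy_spec, toy_genome.lengths, bin_width)
        ok = (abs(est["chr1"].position - (toy_spec.bp_a + 1)) <= bin_width
              and abs(est["chr2"].position - (toy_spec.bp_b + 1)) <= bin_width)
        hits += ok
    assert hits >= 95


# ---------------------------------------------------------------------------
# junction detection
# ---------------------------------------------------------------------------

def _junction_read(rid, pos_a, pos_b):
    return _read(rid, length=200, q=12, blocks=[
        AlignmentBlock("chrA", pos_a - 99, pos_a, "+", 0, 100),
        AlignmentBlock("chrB", pos_b - 99, pos_b, "-", 100, 200)])


def test_junction_cluster_mode_representative():
    reads = [_junction_read("r1", 1_000_000, 500_000),
             _junction_read("r2", 1_000_000, 500_000),
             _junction_read("r3", 1_000_001, 500_000)]
    clusters = detect_junctions(reads, tolerance=10, min_support=3)
    assert len(clusters) == 1
    cl = clusters[0]
    assert (cl.chrom1, cl.pos1, cl.chrom2, cl.pos2) == ("chrA", 1_000_000, "chrB", 500_000)
    assert cl.support == 3


def test_min_support_filters_small_clusters():
    reads = [_junction_read("r1", 1_000_000, 500_000),
             _junction_read("r2", 1_000_000, 500_000)]
    assert detect_junctions(reads, min_support=3) == []


def test_clustering_is_permutation_invariant(rng):
    reads = [_junction_read(f"r{i}", 1_000_000 + int(rng.integers(-3, 4)),
                            500_000 + int(rng.integers(-3, 4)))
             for i in range(20)]
    ref = detect_junctions(reads)
    for _ in range(5):
        shuffled = list(reads)
        rng.shuffle(shuffled)
        got = detect_junctions(shuffled)
        assert [(c.chrom1, c.pos1, c.chrom2, c.pos2, c.support) for c in got] == \
               [(c.chrom1, c.pos1, c.chrom2, c.pos2, c.support) for c in ref]


def test_split_read_recovery_is_exact(toy_spec, toy_genome, toy_derivatives, rng):
    """Error-free simulated reads recover the planted junction to the base,
    and the reciprocal junctions are cross-linked as one translocation."""
    reads = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 12_000, rng)
    clusters = detect_junctions(reads, tolerance=10, min_support=3)
    assert len(clusters) == 2
    assert all(cl.partner_index is not None for cl in clusters)
    est = breakpoints_from_junctions(clusters, toy_spec)
    assert est["chr1"].position == toy_spec.bp_a
    assert est["chr2"].position == toy_spec.bp_b
    assert est["chr1"].half_window == 0
    # matches the simulator's own junction truth
    left, right = toy_derivatives.junction("der_a")
    assert (left[1], right[1]) == (toy_spec.bp_a, toy_spec.bp_b)


def test_truth_bed_agrees_with_detected_junction(toy_spec, toy_genome,
                                                 toy_derivatives, rng, tmp_path):
    from pgtsr.io import write_truth_bed
    reads = simulate_long_reads(toy_spec, toy_genome, toy_derivatives, 1_000, rng)
    bed = tmp_path / "truth.bed"
    write_truth_bed(reads, bed)
    junction_ends = set()
    rows = {}
    for line in bed.read_text().splitlines():
        chrom, start, end, name, _, strand = line.split("\t")
        rid, idx = name.split(";")
        rows.setdefault(rid, {})[int(idx)] = (chrom, int(start) + 1, int(end), strand)
    for rid, blocks in rows.items():
        if len(blocks) == 2 and blocks[0][0] != blocks[1][0]:
            b0, b1 = blocks[0], blocks[1]
            p0 = b0[2] if b0[3] == "+" else b0[1]
            p1 = b1[1] if b1[3] == "+" else b1[2]
            junction_ends.add((b0[0], p0, b1[0], p1))
    assert junction_ends <= {("chr1", toy_spec.bp_a, "chr2", toy_spec.bp_b),
                             ("chr1", toy_spec.bp_a + 1, "chr2", toy_spec.bp_b + 1)}
    assert junction_ends


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def test_concordance_published_arithmetic():
    cnv_est = BreakpointEstimate("chr2", 125_200_001, 200_000, "cnv_boundary", 5)
    split = BreakpointEstimate("chr2", 125_157_514, 0, "split_read", 20)
    c = check_concordance(cnv_est, split)
    assert c.distance == 42_487 and c.within_window

    cnv_est = BreakpointEstimate("chr17", 34_000_001, 200_000, "cnv_boundary", 5)
    split = BreakpointEstimate("chr17", 33_942_282, 0, "split_read", 20)
    c = check_concordance(cnv_est, split)
    assert c.distance == 57_719 and c.within_window


def test_concordance_identity_and_mismatch():
    a = BreakpointEstimate("chr1", 100, 50, "cnv_boundary", 2)
    b = BreakpointEstimate("chr1", 100, 0, "split_read", 5)
    assert check_concordance(a, b).distance == 0
    with pytest.raises(ValidationError):
        check_concordance(a, BreakpointEstimate("chr2", 100, 0, "split_read", 5))
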