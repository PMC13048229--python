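import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msabench.simulate import (
    DEFAULT_REGION_SIZES,
    ErrorProfile,
    Region,
    build_diploid_reference,
    extract_reads_from_sam,
    make_profile,
    random_sequence,
    reads_for_region,
    sample_regions,
    simulate_read,
)


class TestErrorProfile:
    def test_valid_profile(self):
        p = ErrorProfile(rate=0.1, p_sub=0.23, p_ins=0.31, p_del=0.46)
        assert p.rate == 0.1

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ErrorProfile(rate=0.1, p_sub=0.5, p_ins=0.5, p_del=0.5)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            ErrorProfile(rate=1.5, p_sub=1, p_ins=0, p_del=0)


class TestMakeProfile:
    def test_sub_only(self):
        p = make_profile("SUB", 0.05)
        assert (p.p_sub, p.p_ins, p.p_del) == (1.0, 0.0, 0.0)

    def test_mix_composition(self):
        p = make_profile("MIX", 0.10)
        assert (p.p_sub, p.p_ins, p.p_del) == (0.23, 0.31, 0.46)

    def test_zero_rate_del(self):
        assert make_profile("DEL", 0).rate == 0

    def test_case_insensitive(self):
        assert make_profile("mix", 0.1).p_del == 0.46

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown profile kind"):
            make_profile("SNP", 0.1)


class TestSimulateRead:
    def test_zero_rate_is_identity(self, rng):
        template = "ACGT" * 25
        read, truth = simulate_read(template, make_profile("MIX", 0.0), rng)
        assert read == template
        assert truth.n_errors == 0

    def test_all_deletions_empty_read(self, rng):
        template = "ACGTACGT"
        read, truth = simulate_read(template, make_profile("DEL", 1.0), rng)
        assert read == ""
        assert truth.n_del == len(template)

    def test_substitutions_always_change_base(self, rng):
        template = random_sequence(500, rng)
        read, truth = simulate_read(template, make_profile("SUB", 0.5), rng)
        for pos, op, base in truth.edits:
            assert op == "S"
            assert base != template[pos]

    def test_empty_template_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_read("", make_profile("MIX", 0.1), rng)

    @settings(max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        rate=st.sampled_from([0.0, 0.05, 0.2, 0.5, 1.0]),
        kind=st.sampled_from(["SUB", "INS", "DEL", "MIX"]),
    )
    def test_truth_log_round_trip(self, seed, rate, kind):
        rng = np.random.default_rng(seed)
        template = random_sequence(200, rng)
        read, truth = simulate_read(template, make_profile(kind, rate), rng)
        assert truth.apply(template) == read

    def test_mix_composition_recovered(self, rng):
        template = random_sequence(120_000, rng)
        _, truth = simulate_read(template, make_profile("MIX", 0.10), rng)
        n = truth.n_errors
        for observed, expected in (
            (truth.n_sub, 0.23),
            (truth.n_ins, 0.31),
            (truth.n_del, 0.46),
        ):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed / n - expected) < 3 * se

    def test_overall_rate_recovered(self, rng):
        length = 120_000
        template = random_sequence(length, rng)
        _, truth = simulate_read(template, make_profile("MIX", 0.10), rng)
        se = math.sqrt(0.1 * 0.9 / length)
        assert abs(truth.n_errors / length - 0.10) < 3 * se

    def test_same_seed_identical_reads(self):
        template = "ACGT" * 100
        profile = make_profile("MIX", 0.2)
        r1, t1 = simulate_read(template, profile, np.random.default_rng(7))
        r2, t2 = simulate_read(template, profile, np.random.default_rng(7))
        assert r1 == r2
        assert t1.edits == t2.edits


class TestSampleRegions:
    def test_default_sizes_cross_product(self, rng):
        regions = sample_regions(10_000, rng=rng)
        assert len(regions) == len(DEFAULT_REGION_SIZES) * 10

    def test_single_size_ten_positions(self, rng):
        regions = sample_regions(10_000, sizes=[100], n_per_size=10, rng=rng)
        assert len(regions) == 10
        assert all(r.length == 100 for r in regions)

    def test_exact_fit_single_placement(self, rng):
        regions = sample_regions(100, sizes=[100], n_per_size=1, rng=rng)
        assert regions == [Region(seq_id="ref", start=0, length=100)]

    def test_oversized_region_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds reference length"):
            sample_regions(50, sizes=[100], n_per_size=1, rng=rng)

    def test_all_sizes_fit_from_every_start(self, rng):
        ref_len = 12_000
        regions = sample_regions(ref_len, rng=rng)
        assert all(r.end <= ref_len for r in regions)

    def test_same_start_across_sizes(self, rng):
        regions = sample_regions(5000, sizes=[100, 200], n_per_size=3, rng=rng)
        starts_100 = [r.start for r in regions if r.length == 100]
        starts_200 = [r.start for r in regions if r.length == 200]
        assert starts_100 == starts_200


class TestReadsForRegion:
    def test_zero_rate_copies(self, rng):
        ref = random_sequence(1000, rng)
        region = Region(seq_id="ref", start=100, length=200)
        reads, truths = reads_for_region(ref, region, 10, make_profile("MIX", 0.0), rng)
        assert reads == [ref[100:300]] * 10
        assert all(t.n_errors == 0 for t in truths)

    def test_depth_respected(self, rng):
        ref = random_sequence(1000, rng)
        region = Region(seq_id="ref", start=0, length=500)
        reads, truths = reads_for_region(ref, region, 45, make_profile("MIX", 0.10), rng)
        assert len(reads) == len(truths) == 45

    def test_mean_error_rate_near_nominal(self, rng):
        ref = random_sequence(600, rng)
        region = Region(seq_id="ref", start=50, length=500)
        reads, truths = reads_for_region(ref, region, 45, make_profile("MIX", 0.10), rng)
        total_bases = 45 * 500
        realized = sum(t.n_errors for t in truths) / total_bases
        se = math.sqrt(0.1 * 0.9 / total_bases)
        assert abs(realized - 0.10) < 3 * se

    def test_diploid_balanced_split(self, rng):
        hap_a = random_sequence(400, rng)
        hap_b = random_sequence(400, rng)
        region = Region(seq_id="ref", start=0, length=400)
        reads, truths = reads_for_region(
            hap_a, region, 20, make_profile("MIX", 0.0), rng, haplotypes=(hap_a, hap_b)
        )
        assignment = [t.haplotype for t in truths]
        assert assignment.count(0) == assignment.count(1) == 10
        for read, hap in zip(reads, assignment):
            assert read == (hap_a if hap == 0 else hap_b)[:400]

    def test_odd_depth_off_by_one(self, rng):
        hap = random_sequence(100, rng)
        region = Region(seq_id="ref", start=0, length=100)
        _, truths = reads_for_region(
            hap, region, 21, make_profile("MIX", 0.0), rng, haplotypes=(hap, hap)
        )
        counts = [t.haplotype for t in truths]
        assert {counts.count(0), counts.count(1)} == {10, 11}

    def test_invalid_depth(self, rng):
        with pytest.raises(ValueError):
            reads_for_region("ACGT", Region("ref", 0, 4), 0, make_profile("MIX", 0.1), rng)


class TestBuildDiploidReference:
    def test_identical_haplotypes(self):
        dip = build_diploid_reference("ACGTACGT", "ACGTACGT")
        assert dip.iupac_seq == "ACGTACGT"
        assert dip.het_sites == ()

    def test_single_substitution(self):
        dip = build_diploid_reference("ACGT", "ACAT")
        assert dip.iupac_seq == "ACRT"
        assert dip.het_sites == ((2, "R"),)

    def test_indel_column_excluded(self):
        dip = build_diploid_reference("ACGT", "ACT")
        assert dip.iupac_seq == "ACGT"
        assert dip.het_sites == ()
        assert dip.excluded_sites == (2,)

    def test_insertion_in_second_haplotype_dropped(self):
        dip = build_diploid_reference("ACT", "ACGT")
        assert dip.iupac_seq == "ACT"
        assert dip.het_sites == ()

    def test_het_site_codes_have_two_nucleotides(self, rng):
        from msabench.iupac import nucleotide_set

        hap_a = random_sequence(300, rng)
        hap_b = list(hap_a)
        for pos in (50, 120, 200):
            hap_b[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[hap_b[pos]]
        dip = build_diploid_reference(hap_a, "".join(hap_b))
        assert len(dip.het_sites) == 3
        for pos, code in dip.het_sites:
            assert len(nucleotide_set(code)) == 2
            assert dip.iupac_seq[pos] == code

    def test_empty_haplotype_rejected(self):
        with pytest.raises(ValueError):
            build_diploid_reference("", "ACGT")


def _write_sam(path, ref_name, ref_len, reads):
    """reads: list of (name, pos, seq, cigar)."""
    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{ref_name}\tLN:{ref_len}",
    ]
    for name, pos, seq, cigar in reads:
        lines.append(
            f"{name}\t0\t{ref_name}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")


class TestExtractReadsFromSam:
    def test_exact_spanning_read_clipped_to_region(self, tmp_path, rng):
        ref = random_sequence(200, rng)
        sam = tmp_path / "aln.sam"
        _write_sam(sam, "chr1", 200, [("r1", 0, ref, "200M")])
        region = Region(seq_id="chr1", start=50, length=100)
        reads = extract_reads_from_sam(sam, region, 1, rng)
        assert reads == [ref[50:150]]

    def test_partially_overlapping_read_excluded(self, tmp_path, rng):
        ref = random_sequence(200, rng)
        sam = tmp_path / "aln.sam"
        _write_sam(
            sam,
            "chr1",
            200,
            [("r1", 0, ref[:100], "100M"), ("r2", 0, ref, "200M")],
        )
        region = Region(seq_id="chr1", start=50, length=100)
        reads = extract_reads_from_sam(sam, region, 1, rng)
        assert reads == [ref[50:150]]

    def test_insufficient_depth_errors_with_count(self, tmp_path, rng):
        ref = random_sequence(100, rng)
        sam = tmp_path / "aln.sam"
        _write_sam(sam, "chr1", 100, [("r1", 0, ref, "100M")])
        region = Region(seq_id="chr1", start=0, length=100)
        with pytest.raises(ValueError, match="only 1 reads"):
            extract_reads_from_sam(sam, region, 5, rng)
        assert extract_reads_from_sam(sam, region, 5, rng, allow_fewer=True) == [ref]

    def test_seeded_sampling_reproducible(self, tmp_path, rng):
        ref = random_sequence(120, rng)
        entries = [(f"r{i}", 0, ref, "120M") for i in range(30)]
        sam = tmp_path / "aln.sam"
        _write_sam(sam, "chr1", 120, entries)
        region = Region(seq_id="chr1", start=10, length=100)
        got1 = extract_reads_from_sam(sam, region, 5, np.random.default_rng(3))
        got2 = extract_reads_from_sam(sam, region, 5, np.random.default_rng(3))
        assert got1 == got2
        assert len(got1) == 5

    def test_insertion_inside_window_kept(self, tmp_path, rng):
        ref = random_sequence(100, rng)
        # read matches 0..50, inserts GG, matches 50..100
        seq = ref[:50] + "GG" + ref[50:]
        sam = tmp_path / "aln.sam"
        _write_sam(sam, "chr1", 100, [("r1", 0, seq, "50M2I50M")])
        region = Region(seq_id="chr1", start=40, length=20)
        reads = extract_reads_from_sam(sam, region, 1, rng)
        assert reads == [ref[40:50] + "GG" + ref[50:60]]
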