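"""Alignment I/O, masking, indel-marker scoring and site extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplospread.alignment import (
    MISSING,
    Alignment,
    AlignmentError,
    IndelMarker,
    InputError,
    RegionMask,
    code_indel_markers,
    extract_polymorphic_sites,
    mask_region,
    read_fasta_alignment,
    score_indel_marker,
    write_fasta_alignment,
)

from conftest import random_alignment


class TestReadWrite:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGT\n>s2\nACGA\n")
        aln = read_fasta_alignment(p)
        assert aln.length == 4 and aln.n_seqs == 2
        assert aln.ids == ("s1", "s2")

    def test_lowercase_folded(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nacgt\n")
        assert read_fasta_alignment(p).sequence("s1") == "ACGT"

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACGT\n>s2\nACGTA\n")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            Alignment.from_records([("s1", "AC"), ("s1", "AC")])

    def test_illegal_character_named(self):
        with pytest.raises(InputError, match=r"s1.*column 3|column 3.*s1"):
            Alignment.from_records([("s1", "ACXT")])

    def test_round_trip_bit_exact(self, tmp_path, rng):
        aln = random_alignment(rng, 6, 40, missing_rate=0.1)
        path = tmp_path / "rt.fasta"
        write_fasta_alignment(aln, path)
        assert read_fasta_alignment(path) == aln


class TestMaskRegion:
    def test_length_arithmetic(self, rng):
        aln = random_alignment(rng, 3, 10)
        assert mask_region(aln, RegionMask(3, 5)).length == 7

    def test_full_mask_rejected(self, rng):
        aln = random_alignment(rng, 3, 10)
        with pytest.raises(InputError):
            mask_region(aln, RegionMask(1, 10))

    def test_out_of_bounds_rejected(self, rng):
        aln = random_alignment(rng, 3, 10)
        with pytest.raises(InputError):
            mask_region(aln, RegionMask(8, 11))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        start=st.integers(1, 8),
        span=st.integers(0, 4),
    )
    def test_mask_commutes_with_subsetting(self, seed, start, span):
        """Masking then row-subsetting equals subsetting then masking."""
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, 5, 15)
        mask = RegionMask(start, min(start + span, 14))
        names = ["s2", "s4"]
        a = mask_region(aln, mask).subset(names)
        b = mask_region(aln.subset(names), mask)
        assert a == b

    def test_mask_commutes_with_polymorphic_extraction(self, rng):
        """Masking columns then extracting polymorphic sites equals
        extracting first and dropping the masked window (brute force on
        random alignments)."""
        for _ in range(30):
            aln = random_alignment(rng, 6, 20, alphabet="AT")
            mask = RegionMask(5, 9)
            masked_sites = {c for c, _ in extract_polymorphic_sites(mask_region(aln, mask))}
            direct = extract_polymorphic_sites(aln)
            expected = set()
            for c, _counts in direct:
                if c < mask.start:
                    expected.add(c)
                elif c > mask.end:
                    expected.add(c - mask.span)
            assert masked_sites == expected


class TestIndelMarker:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAA---TT", 1),        # clean gap run
            ("AAACGTTT", 0),        # clean nucleotide run
            ("AAA-CGTT", MISSING),  # partial gap is ambiguous
            ("AAANCGTT", MISSING),  # N inside the span
        ],
    )
    def test_gap_run_scoring(self, seq, expected):
        aln = Alignment.from_records([("s1", seq)])
        assert score_indel_marker(aln, IndelMarker(4, 6, "gap_run"))[0] == expected

    def test_no_gap_presence_state_inverts(self):
        aln = Alignment.from_records([("s1", "AAA---TT"), ("s2", "AAACGTTT")])
        scores = score_indel_marker(aln, IndelMarker(4, 6, "no_gap"))
        assert list(scores) == [0, 1]

    def test_output_shape_and_domain(self, rng):
        aln = random_alignment(rng, 9, 30, missing_rate=0.2)
        scores = score_indel_marker(aln, IndelMarker(10, 14))
        assert scores.shape == (9,)
        assert set(scores.tolist()) <= {0, 1, MISSING}


class TestPolymorphicSites:
    def test_complete_deletion_drops_gapped_column(self):
        # columns: 1=AAA (mono), 2=AAT (poly), 3=A-A (gapped → dropped)
        aln = Alignment.from_records([("s1", "AAA"), ("s2", "AA-"), ("s3", "ATA")])
        assert [c for c, _ in extract_polymorphic_sites(aln, "complete")] == [2]

    def test_pairwise_policy_keeps_gapped_polymorphic_column(self):
        aln = Alignment.from_records([("s1", "AAT"), ("s2", "AAT"), ("s3", "A-A")])
        assert [c for c, _ in extract_polymorphic_sites(aln, "pairwise")] == [3]

    def test_monomorphic_alignment_empty(self):
        aln = Alignment.from_records([("s1", "ACGT"), ("s2", "ACGT")])
        assert extract_polymorphic_sites(aln) == []

    def test_all_gap_column_excluded(self):
        aln = Alignment.from_records([("s1", "A-T"), ("s2", "A-A")])
        assert [c for c, _ in extract_polymorphic_sites(aln, "pairwise")] == [3]


class TestIndelCoding:
    def test_exclude_removes_span(self, rng):
        aln = random_alignment(rng, 4, 20)
        out = code_indel_markers(aln, [IndelMarker(5, 9)], "exclude")
        assert out.length == 15

    def test_code_appends_one_pseudo_column_per_marker(self):
        aln = Alignment.from_records(
            [("s1", "AA---TT"), ("s2", "AACGGTT"), ("s3", "AA--GTT")]
        )
        out = code_indel_markers(aln, [IndelMarker(3, 5)], "code")
        assert out.length == 7 - 3 + 1
        assert [s[-1] for _, s in out.records()] == ["T", "A", "N"]
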