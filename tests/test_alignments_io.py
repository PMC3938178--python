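"""Reference loading, strand assignment, 5' trimming and pileup building."""

import numpy as np
import pysam
import pytest

from methylvar.alignments_io import (DuplicateSequenceError, PileupMatrix,
                                     assign_bisulfite_strand, build_pileup,
                                     load_reference, read_sam, trim_5prime)

from conftest import mk_read, write_fasta


class TestLoadReference:
    def test_basic_and_casefold(self, tmp_path):
        path = write_fasta(tmp_path / "r.fa", {"c1": "acgt"})
        assert load_reference(path) == {"c1": "ACGT"}

    def test_header_first_token(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text(">c1 description here\nACGT\n")
        assert load_reference(str(path)) == {"c1": "ACGT"}

    def test_duplicate_names_rejected(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text(">c1\nACGT\n>c1\nTTTT\n")
        with pytest.raises(DuplicateSequenceError):
            load_reference(str(path))

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text("")
        with pytest.raises(ValueError):
            load_reference(str(path))


def _sam_record(flag=0, xg=None):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 1000}]})
    a = pysam.AlignedSegment(header)
    a.query_name = "r1"
    a.query_sequence = "ACGT"
    a.query_qualities = [30] * 4
    a.flag = flag
    a.reference_id = 0
    a.reference_start = 10
    a.cigartuples = [(0, 4)]
    if xg is not None:
        a.set_tag("XG", xg)
    return a


class TestAssignBisulfiteStrand:
    @pytest.mark.parametrize("xg,flag,expected", [
        ("CT", 0, "OT"),
        ("GA", 0, "OB"),
        (None, 16, "OB"),
        (None, 0, "OT"),
    ])
    def test_tag_and_flag(self, xg, flag, expected):
        assert assign_bisulfite_strand(_sam_record(flag, xg)) == expected

    def test_contradictory_tag_wins(self, caplog):
        rec = _sam_record(flag=16, xg="CT")
        with caplog.at_level("WARNING"):
            assert assign_bisulfite_strand(rec) == "OT"
        assert "contradicts" in caplog.text

    def test_unparseable_tag_raises(self):
        with pytest.raises(ValueError):
            assign_bisulfite_strand(_sam_record(0, "ZZ"))


class TestTrim5Prime:
    def test_forward_advances_start(self):
        read = mk_read("A" * 50, start=100)
        out = trim_5prime(read, 3)
        assert out.start == 103 and len(out.seq) == 47

    def test_reverse_clips_right_end(self):
        read = mk_read("ACGTA" * 10, start=100, bs="OB")
        out = trim_5prime(read, 3)
        assert out.start == 100 and len(out.seq) == 47
        assert out.seq == ("ACGTA" * 10)[:-3]

    def test_zero_is_identity(self):
        read = mk_read("ACGT", start=5)
        assert trim_5prime(read, 0) is read

    def test_full_length_drops_read(self):
        assert trim_5prime(mk_read("ACGT"), 4) is None

    def test_trim_through_insertion(self):
        # 3 query bases trimmed: 2M consume ref, 1I does not
        read = mk_read("AACGT", start=10, cigar=[("M", 2), ("I", 1), ("M", 2)])
        out = trim_5prime(read, 3)
        assert out.start == 12 and out.seq == "GT"
        assert out.cigartuples == [("M", 2)]


class TestBuildPileup:
    def test_single_call_counted_with_quality(self):
        ref = {"c1": "ACGT"}
        cols = list(build_pileup([mk_read("C", start=1, quals=30)], ref, 20))
        assert len(cols) == 1
        col = cols[0]
        assert col.pos == 1 and col.ref_base == "C"
        assert col.counts == {("OT", "C"): 1}
        assert col.qual_sums == {("OT", "C"): 30}

    def test_low_quality_call_excluded(self):
        cols = list(build_pileup([mk_read("C", start=1, quals=10)],
                                 {"c1": "ACGT"}, 20))
        assert cols == []

    def test_two_reads_same_position(self):
        reads = [mk_read("C", start=1, read_id="a"),
                 mk_read("T", start=1, read_id="b")]
        cols = list(build_pileup(reads, {"c1": "ACGT"}, 20))
        assert cols[0].counts == {("OT", "C"): 1, ("OT", "T"): 1}

    def test_n_calls_excluded(self):
        cols = list(build_pileup([mk_read("N", start=1)], {"c1": "ACGT"}, 20))
        assert cols == []

    def test_read_beyond_contig_end_skipped(self):
        mat = PileupMatrix("c1", "ACGT", 20)
        mat.add_read(mk_read("ACGTA", start=2))
        assert mat.skipped_out_of_range == 1
        assert mat.counts.sum() == 0

    def test_deletion_contributes_nothing(self):
        read = mk_read("AT", start=0, cigar=[("M", 1), ("D", 2), ("M", 1)])
        cols = list(build_pileup([read], {"c1": "ACGTA"}, 20))
        positions = {c.pos for c in cols}
        assert positions == {0, 3}

    def test_single_read_pileup_matches_projection(self, rng):
        # oracle: walk the read's aligned pairs directly
        ref_seq = "".join(rng.choice(list("ACGT"), size=200))
        seq = "".join(rng.choice(list("ACGT"), size=60))
        quals = rng.integers(2, 41, size=60)
        read = mk_read(seq, start=17, quals=quals, bs="OB")
        minQ = 20
        cols = {c.pos: c for c in build_pileup([read], {"c1": ref_seq}, minQ)}
        for qpos, rpos in read.aligned_pairs():
            if quals[qpos] >= minQ and seq[qpos] != "N":
                assert cols[rpos].counts[("OB", seq[qpos])] == 1
            else:
                assert rpos not in cols or \
                    ("OB", seq[qpos]) not in cols[rpos].counts

    def test_column_depth_bounded_by_overlapping_reads(self, rng):
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=300))}
        reads = [mk_read("".join(rng.choice(list("ACGT"), size=50)),
                         start=int(rng.integers(0, 250)),
                         quals=rng.integers(0, 41, size=50),
                         read_id=f"r{i}")
                 for i in range(30)]
        for col in build_pileup(reads, ref, 20):
            n_overlap = sum(1 for r in reads
                            if r.start <= col.pos < r.start + 50)
            assert col.depth() <= n_overlap

    def test_trim_then_pileup_equals_pileup_of_pretrimmed(self, rng):
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=300))}
        reads = [mk_read("".join(rng.choice(list("ACGT"), size=40)),
                         start=int(rng.integers(0, 200)),
                         quals=rng.integers(0, 41, size=40),
                         bs=("OT" if rng.random() < 0.5 else "OB"),
                         read_id=f"r{i}")
                 for i in range(20)]
        n = 3
        trimmed = sorted((trim_5prime(r, n) for r in reads),
                         key=lambda r: r.start)
        got = {c.pos: c.counts for c in build_pileup(trimmed, ref, 20)}
        # oracle: full pileup minus the direct projection of trimmed bases
        expected = {c.pos: dict(c.counts)
                    for c in build_pileup(sorted(reads, key=lambda r: r.start),
                                          ref, 20)}
        for r in reads:
            removed = range(n) if r.aln_strand == "+" else \
                range(len(r.seq) - n, len(r.seq))
            for qpos in removed:
                if r.quals[qpos] >= 20 and r.seq[qpos] != "N":
                    rpos = r.start + qpos
                    key = (r.bs_strand, r.seq[qpos])
                    expected[rpos][key] -= 1
                    if expected[rpos][key] == 0:
                        del expected[rpos][key]
        expected = {p: c for p, c in expected.items() if c}
        assert got == expected


class TestReadSam:
    def test_roundtrip_via_sam_file(self, tmp_path, rng):
        from methylvar.synthetic_bs import write_sam
        ref = {"c1": "".join(rng.choice(list("ACGT"), size=500))}
        reads = [mk_read("ACGTACGTAC", start=i * 7, read_id=f"r{i}",
                         bs=("OT" if i % 2 else "OB")) for i in range(10)]
        path = tmp_path / "t.sam"
        write_sam(reads, ref, str(path))
        back = list(read_sam(str(path)))
        assert len(back) == 10
        for orig, rb in zip(reads, back):
            assert (rb.read_id, rb.start, rb.bs_strand, rb.seq) == \
                (orig.read_id, orig.start, orig.bs_strand, orig.seq)
            assert np.array_equal(rb.quals, orig.quals)
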