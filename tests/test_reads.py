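"""Read ingestion: SAM/BAM CIGAR walking, raw-read classification, filters."""

import subprocess

import pysam
import pytest

from combedit import classify_raw_reads, classify_reads, read_alignments, simulate_library
from combedit.reads import reverse_complement
from combedit.reference import ReferenceError
from combedit.simulate import write_fastq


def _sam_header(ref):
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": ref.full_id, "LN": len(ref.full_contig)},
            {"SN": ref.truncated_id, "LN": len(ref.truncated_contig)},
        ],
    }


def _segment(header, name, seq, tid, cigar, mapq=60, flag=0, start=0):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = tid
    a.reference_start = start
    a.mapping_quality = mapq
    if cigar is not None:
        a.cigartuples = cigar
    return a


def _write_sam(path, ref, segment_specs):
    header = pysam.AlignmentHeader.from_dict(_sam_header(ref))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for spec in segment_specs:
            out.write(_segment(header, *spec[0], **spec[1]))


class TestReadAlignments:
    def test_perfect_and_edited_full_reads(self, ref, tmp_path):
        pos_d = ref.site_positions["D"]
        edited = ref.full_contig[:pos_d] + "G" + ref.full_contig[pos_d + 1:]
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [
            (("clean", ref.full_contig, 0, [(0, 209)]), {}),
            (("edited", edited, 0, [(0, 209)]), {}),
        ])
        obs, stats = read_alignments(sam, ref)
        assert stats.full_reads == 2 and stats.mapped_reads == 2
        by_name = {o.read_id: o for o in obs}
        assert set(by_name["clean"].site_bases.values()) == {"A"}
        assert by_name["edited"].site_bases["D"] == "G"
        assert by_name["edited"].site_bases["C"] == "A"
        assert all(o.covered_all_sites for o in obs)

    def test_truncated_read_has_no_site_bases(self, ref, tmp_path):
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [(("tr", ref.truncated_contig, 1, [(0, 114)]), {})])
        obs, stats = read_alignments(sam, ref)
        assert stats.truncated_reads == 1
        assert obs[0].contig == "truncated" and obs[0].site_bases is None

    def test_mapq_and_unmapped_filters(self, ref, tmp_path):
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [
            (("low", ref.full_contig, 0, [(0, 209)]), {"mapq": 10}),
            (("unmapped", ref.full_contig, -1, None), {"flag": 4, "start": -1}),
            (("good", ref.full_contig, 0, [(0, 209)]), {"mapq": 60}),
        ])
        obs, stats = read_alignments(sam, ref, min_mapq=30)
        assert stats.total_reads == 3
        assert stats.discarded_by_mapq == 1
        assert stats.discarded_unmapped == 1
        assert stats.mapped_reads == 1 == len(obs)

    def test_deletion_over_site_flags_indel(self, ref, tmp_path):
        pos_d = ref.site_positions["D"]
        seq = ref.full_contig[:pos_d] + ref.full_contig[pos_d + 2:]  # 2 nt deletion at D
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [
            (("del", seq, 0, [(0, pos_d), (2, 2), (0, 209 - pos_d - 2)]), {}),
        ])
        obs, stats = read_alignments(sam, ref)
        assert obs[0].has_indel_in_window
        assert stats.flagged_indel_in_window == 1
        assert stats.mapped_reads == 1  # still counted as mapped

    def test_insertion_in_window_flags_indel(self, ref, tmp_path):
        w0, _ = ref.site_map.window()
        cut = w0 + 2
        seq = ref.full_contig[:cut] + "TT" + ref.full_contig[cut:]
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [
            (("ins", seq, 0, [(0, cut), (1, 2), (0, 209 - cut)]), {}),
        ])
        obs, _ = read_alignments(sam, ref)
        assert obs[0].has_indel_in_window

    def test_partial_coverage_flagged(self, ref, tmp_path):
        # soft-clipped read covering only the first part of the window
        w0, _ = ref.site_map.window()
        aligned_len = w0 + 5  # covers some but not all sites
        seq = ref.full_contig[:aligned_len] + "T" * 20
        sam = tmp_path / "lib.sam"
        _write_sam(sam, ref, [
            (("part", seq, 0, [(0, aligned_len), (4, 20)]), {}),
        ])
        obs, stats = read_alignments(sam, ref)
        assert not obs[0].covered_all_sites
        assert obs[0].site_bases is None
        assert stats.flagged_partial_coverage == 1

    def test_contig_name_mismatch_lists_names(self, ref, tmp_path):
        sam = tmp_path / "lib.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 209}]}
        with pysam.AlignmentFile(str(sam), "w", header=header):
            pass
        with pytest.raises(ReferenceError, match="chr1"):
            read_alignments(sam, ref)


class TestClassifyRawReads:
    def test_exact_matches(self, ref, tmp_path):
        fq = tmp_path / "x.fastq"
        write_fastq([("full", ref.full_contig), ("tr", ref.truncated_contig)], fq)
        obs, stats = classify_raw_reads(fq, ref)
        by_name = {o.read_id: o for o in obs}
        assert by_name["full"].contig == "full" and by_name["full"].edit_distance == 0
        assert by_name["tr"].contig == "truncated"
        assert stats.mapped_reads == 2

    def test_reverse_complement_orientation(self, ref):
        reads = [("rc_tr", reverse_complement(ref.truncated_contig)),
                 ("rc_full", reverse_complement(ref.full_contig))]
        obs, _ = classify_reads(reads, ref)
        by_name = {o.read_id: o for o in obs}
        assert by_name["rc_tr"].contig == "truncated"
        assert by_name["rc_full"].contig == "full"
        # site bases extracted from the re-oriented read
        assert set(by_name["rc_full"].site_bases.values()) == {"A"}

    def test_junk_read_unassigned(self, ref):
        obs, stats = classify_reads([("junk", "T" * 180)], ref)
        assert obs[0].contig == "unassigned"
        assert stats.unassigned_reads == 1 and stats.mapped_reads == 0

    def test_empty_file(self, ref, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        obs, stats = classify_raw_reads(fq, ref)
        assert obs == [] and stats.total_reads == 0

    def test_missing_file_raises(self, ref, tmp_path):
        with pytest.raises(FileNotFoundError):
            classify_raw_reads(tmp_path / "nope.fastq", ref)

    def test_no_misassignment_at_one_percent_error(self, ref, profile_pair):
        wt, _ = profile_pair
        reads, truth = simulate_library(ref, wt, 1000, error_rate=0.01, seed=9)
        obs, stats = classify_reads(reads, ref)
        assigned = {o.read_id: o.contig for o in obs}
        for _, row in truth.iterrows():
            assert assigned[row.read_id] == row.isoform
        assert stats.unassigned_reads == 0

    def test_conservation_of_reads(self, ref, profile_pair):
        wt, _ = profile_pair
        reads, _ = simulate_library(ref, wt, 500, error_rate=0.02, seed=2)
        _, stats = classify_reads(reads, ref)
        stats.check()
        assert stats.total_reads == 500


class TestExternalAlignerAgreement:
    def test_bwa_round_trip_matches_truth_and_builtin(self, ref, profile_pair, tmp_path):
        """Map simulated reads with an external aligner (bwa mem); the
        CIGAR-walking SAM reader must reproduce the simulator's splice
        truth, and agree with the built-in classifier on >=99.9% of reads."""
        wt, _ = profile_pair
        reads, truth = simulate_library(ref, wt, 400, error_rate=0.005, seed=21)
        fasta = tmp_path / "ref.fasta"
        ref.to_fasta(fasta)
        fq = tmp_path / "lib.fastq"
        write_fastq(reads, fq)
        sam = tmp_path / "lib.sam"
        subprocess.run(["bwa", "index", str(fasta)], check=True, capture_output=True)
        with open(sam, "w") as out:
            subprocess.run(
                ["bwa", "mem", str(fasta), str(fq)],
                check=True, stdout=out, stderr=subprocess.DEVNULL,
            )
        obs_aln, stats_aln = read_alignments(sam, ref, min_mapq=30)
        truth_counts = truth.isoform.value_counts()
        assert stats_aln.full_reads == truth_counts.get("full", 0)
        assert stats_aln.truncated_reads == truth_counts.get("truncated", 0)

        obs_raw, _ = classify_reads(reads, ref)
        aln = {o.read_id: o.contig for o in obs_aln}
        raw = {o.read_id: o.contig for o in obs_raw}
        shared = set(aln) & set(raw)
        agree = sum(aln[r] == raw[r] for r in shared)
        assert agree / len(shared) >= 0.999
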