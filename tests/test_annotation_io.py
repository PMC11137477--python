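from __future__ import annotations

import gzip

import pytest

from liftcompare.annotation_io import (AnnotationParseError, Assembly, CoordinateError,
                                       LiftCompareError, OrphanFeatureError,
                                       extract_cds_sequence, extract_transcript_sequence,
                                       longest_isoform, match_features, parse_annotation,
                                       write_gff3, write_gtf)
from liftcompare.fixtures import make_reference

from conftest import build_annotation

MINIMAL_GFF3 = """##gff-version 3
chr1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t9\t.\t+\t.\tID=t1;Parent=g1
chr1\tsrc\texon\t1\t9\t.\t+\t.\tID=e1;Parent=t1
"""


def test_minimal_gff3_hierarchy(tmp_path):
    path = tmp_path / "m.gff3"
    path.write_text(MINIMAL_GFF3)
    ann = parse_annotation(path)
    assert ann.gene_ids() == ["g1"]
    assert ann.transcript_ids() == ["t1"]
    assert len(ann.exons("t1")) == 1
    assert ann.source_dialect == "GFF3"


def test_gzip_input_accepted(tmp_path):
    path = tmp_path / "m.gff3.gz"
    with gzip.open(path, "wt") as f:
        f.write(MINIMAL_GFF3)
    assert parse_annotation(path).gene_ids() == ["g1"]


def test_gtf_and_gff3_dialects_build_identical_hierarchies(tmp_path):
    """The same annotation expressed in both dialects parses to one structure."""
    ref = make_reference(n_genes=6, n_chroms=2, coding_fraction=0.8, seed=3)
    g3, gtf = tmp_path / "a.gff3", tmp_path / "a.gtf"
    write_gff3(ref.annotation, g3)
    write_gtf(ref.annotation, gtf)
    a, b = parse_annotation(g3), parse_annotation(gtf)
    assert (a.source_dialect, b.source_dialect) == ("GFF3", "GTF")
    assert a.gene_ids() == b.gene_ids()
    assert a.transcript_ids() == b.transcript_ids()
    for tid in a.transcript_ids():
        spans = lambda ann, kind: sorted(
            (f.start, f.end, f.strand, f.phase)
            for f in ann.children_of[tid] if f.type == kind)
        assert spans(a, "exon") == spans(b, "exon")
        assert spans(a, "CDS") == spans(b, "CDS")


def test_round_trip_preserves_hierarchy(tmp_path):
    ref = make_reference(n_genes=8, n_chroms=2, coding_fraction=0.7, seed=4)
    out = tmp_path / "rt.gff3"
    write_gff3(ref.annotation, out)
    again = parse_annotation(out)
    assert again.gene_ids() == ref.annotation.gene_ids()
    for g in ref.annotation.genes:
        h = again.gene(g.id)
        assert (h.seqid, h.start, h.end, h.strand) == (g.seqid, g.start, g.end, g.strand)
    for tid in ref.annotation.transcript_ids():
        orig = [(f.type, f.start, f.end, f.strand, f.phase)
                for f in sorted(ref.annotation.children_of[tid], key=lambda f: (f.start, f.type))]
        back = [(f.type, f.start, f.end, f.strand, f.phase)
                for f in sorted(again.children_of[tid], key=lambda f: (f.start, f.type))]
        assert orig == back


def test_orphan_child_is_an_error(tmp_path):
    path = tmp_path / "orphan.gff3"
    path.write_text("chr1\ts\texon\t1\t5\t.\t+\t.\tID=e1;Parent=ghost\n")
    with pytest.raises(OrphanFeatureError, match="ghost"):
        parse_annotation(path)


def test_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text(MINIMAL_GFF3 + "chr1\tonly-two-fields\n")
    with pytest.raises(AnnotationParseError, match="line 5"):
        parse_annotation(path)


class TestExtraction:
    def test_single_exon_plus_strand(self):
        asm = Assembly({"chr1": "ATGAAA"})
        ann = build_annotation([("g1", "chr1", "+", [("t1", [(1, 6)], [])])])
        assert extract_transcript_sequence(asm, ann, "t1") == "ATGAAA"

    def test_single_exon_minus_strand_is_reverse_complement(self):
        asm = Assembly({"chr1": "ATGAAA"})
        ann = build_annotation([("g1", "chr1", "-", [("t1", [(1, 6)], [])])])
        assert extract_transcript_sequence(asm, ann, "t1") == "TTTCAT"

    def test_two_exons_splice_out_intron(self):
        asm = Assembly({"chr1": "ATGCCCAAA"})
        ann = build_annotation([("g1", "chr1", "+", [("t1", [(1, 3), (7, 9)], [])])])
        assert extract_transcript_sequence(asm, ann, "t1") == "ATGAAA"

    def test_cds_extraction_and_absence(self):
        asm = Assembly({"chr1": "ATGAAATAA"})
        ann = build_annotation([
            ("g1", "chr1", "+", [("t1", [(1, 9)], [(1, 9, 0)])]),
            ("g2", "chr1", "+", [("t2", [(1, 9)], [])]),
        ])
        assert extract_cds_sequence(asm, ann, "t1") == "ATGAAATAA"
        assert extract_cds_sequence(asm, ann, "t2") is None

    def test_leading_phase_is_trimmed(self):
        asm = Assembly({"chr1": "NATGAAA"})
        ann = build_annotation([("g1", "chr1", "+", [("t1", [(1, 7)], [(1, 7, 1)])])])
        assert extract_cds_sequence(asm, ann, "t1") == "ATGAAA"

    def test_exon_past_sequence_end_raises(self):
        asm = Assembly({"chr1": "ATG"})
        ann = build_annotation([("g1", "chr1", "+", [("t1", [(1, 10)], [])])])
        with pytest.raises(CoordinateError):
            extract_transcript_sequence(asm, ann, "t1")

    def test_minus_strand_fixture_extraction_matches_revcomp(self, standard_fixture):
        """On every '-' gene, extraction equals the reverse complement of the
        '+'-orientation splice of the same intervals."""
        from Bio.Seq import reverse_complement
        ref, _ = standard_fixture
        checked = 0
        for tid in ref.annotation.transcript_ids():
            exons = sorted(ref.annotation.exons(tid), key=lambda f: f.start)
            if exons[0].strand != "-":
                continue
            fwd = "".join(ref.assembly.fetch(f.seqid, f.start, f.end, "+") for f in exons)
            assert extract_transcript_sequence(ref.assembly, ref.annotation, tid) == \
                reverse_complement(fwd)
            checked += 1
        assert checked > 0

    def test_fixture_cds_lengths_are_codon_multiples(self, standard_fixture):
        ref, _ = standard_fixture
        coding = 0
        for tid in ref.annotation.transcript_ids():
            cds = extract_cds_sequence(ref.assembly, ref.annotation, tid)
            if cds is not None:
                assert len(cds) % 3 == 0
                coding += 1
        assert coding > 10


class TestMatching:
    def test_full_intersection(self):
        a = build_annotation([("g1", "c", "+", [("t1", [(1, 3)], [])]),
                              ("g2", "c", "+", [("t2", [(5, 7)], [])])])
        m = match_features(a, a)
        assert m.shared_gene_ids == {"g1", "g2"} and not m.unmapped_ids

    def test_missing_target_gene_is_unmapped(self):
        ref = build_annotation([("g1", "c", "+", [("t1", [(1, 3)], [])]),
                                ("g2", "c", "+", [("t2", [(5, 7)], [])])])
        tgt = build_annotation([("g1", "c", "+", [("t1", [(1, 3)], [])])])
        assert match_features(ref, tgt).unmapped_ids == {"g2"}

    def test_copy_suffix_recognized_and_stranger_reported(self):
        ref = build_annotation([("g1", "c", "+", [("t1", [(1, 3)], [])])])
        tgt = build_annotation([("g1", "c", "+", [("t1", [(1, 3)], [])]),
                                ("g1_1", "c", "+", [("x1", [(5, 7)], [])]),
                                ("alien", "c", "+", [("x2", [(9, 11)], [])])])
        m = match_features(ref, tgt)
        assert m.extra_copy_ids == {"g1_1": "g1"}
        assert m.unrecognized_ids == {"alien"}


class TestLongestIsoform:
    def _two_isoform_annotation(self):
        return build_annotation([
            ("g1", "c", "+", [("tB", [(1, 300)], []),
                              ("tA", [(1, 150), (200, 349)], [])]),
        ])

    def test_longer_isoform_wins(self):
        ann = build_annotation([("g1", "c", "+",
                                 [("t_short", [(1, 300)], []),
                                  ("t_long", [(1, 250), (300, 499)], [])])])
        assert longest_isoform(ann, "g1") == "t_long"

    def test_tie_broken_by_smaller_id(self):
        assert longest_isoform(self._two_isoform_annotation(), "g1") == "tA"

    def test_gene_without_transcripts_raises(self):
        ann = self._two_isoform_annotation()
        with pytest.raises(LiftCompareError):
            longest_isoform(ann, "nope")
        ann.transcripts_of["g1"] = []
        with pytest.raises(LiftCompareError):
            longest_isoform(ann, "g1")
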