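"""Coordinate conventions, round trips, interval arithmetic, and parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itgscan import (
    BedFeature,
    CoverageTrack,
    GeneRecord,
    GenomicInterval,
    HomologyHit,
    ParseError,
    TranscriptModel,
    interval_distance,
    read_bed,
    read_bedgraph,
    read_fasta,
    read_gtf,
    read_homology_tab,
    read_peak_bed,
    read_te_bed,
    tss,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gtf,
    write_homology_tab,
)
from oracles import brute_interval_distance


def ivl(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestGenomicInterval:
    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 100, "x")

    def test_transcript_invariants_enforced(self):
        exons = (ivl(0, 100, strand="+"), ivl(200, 300, strand="+"))
        TranscriptModel("t1", "g1", ivl(0, 300, strand="+"), exons)
        with pytest.raises(ValueError):  # span must match exon chain
            TranscriptModel("t1", "g1", ivl(0, 500, strand="+"), exons)
        with pytest.raises(ValueError):  # overlapping exons
            TranscriptModel(
                "t1", "g1", ivl(0, 300, strand="+"),
                (ivl(0, 250, strand="+"), ivl(200, 300, strand="+")),
            )


class TestIntervalDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (ivl(0, 100), ivl(50, 150), 0),      # overlap
            (ivl(0, 100), ivl(100, 200), 0),     # abutting
            (ivl(0, 100), ivl(350, 400), 250),   # gap 350 - 100
            (ivl(0, 100), ivl(0, 100, chrom="chr2"), None),
        ],
    )
    def test_known_cases(self, a, b, expected):
        assert interval_distance(a, b) == expected
        assert interval_distance(b, a) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(0, 300), st.integers(1, 60)),
                    min_size=2, max_size=2))
    def test_matches_coordinate_set_oracle(self, pairs):
        a = ivl(pairs[0][0], pairs[0][0] + pairs[0][1])
        b = ivl(pairs[1][0], pairs[1][0] + pairs[1][1])
        assert interval_distance(a, b) == brute_interval_distance(a, b)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=3, max_size=3))
    def test_triangle_like_bound(self, triples):
        a, b, c = (ivl(s, s + l) for s, l in triples)
        assert interval_distance(a, c) <= (
            interval_distance(a, b) + b.length + interval_distance(b, c)
        )


class TestTss:
    def test_plus_strand_left_end(self):
        assert tss(GeneRecord("g", ivl(1000, 2000, strand="+"))) == 1000

    def test_minus_strand_right_end(self):
        assert tss(GeneRecord("g", ivl(1000, 2000, strand="-"))) == 1999

    def test_unstranded_falls_back_to_left(self):
        assert tss(GeneRecord("g", ivl(1000, 2000, strand="."))) == 1000


class TestGtf:
    def test_one_based_to_internal(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
        )
        genes, _ = read_gtf(p)
        assert genes[0].interval == ivl(100, 200, strand="+")

    def test_exon_chain_and_span(self, tmp_path):
        p = tmp_path / "a.gtf"
        lines = [
            f'chr1\tsrc\texon\t{s}\t{e}\t.\t+\t.\t'
            f'gene_id "g1"; transcript_id "t1";'
            for s, e in [(1, 100), (201, 300), (401, 500)]
        ]
        p.write_text("\n".join(lines) + "\n")
        _, txs = read_gtf(p)
        t = txs[0]
        assert [(e.start, e.end) for e in t.exons] == [(0, 100), (200, 300), (400, 500)]
        assert (t.interval.start, t.interval.end) == (0, 500)

    def test_missing_attribute_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "ok";\n'
            "chr1\tsrc\tgene\t1\t10\t.\t+\t.\tfoo \"bar\";\n"
        )
        with pytest.raises(ParseError, match=":2"):
            read_gtf(p)

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\tsrc\tgene\t200\t100\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(ParseError, match=":1"):
            read_gtf(p)

    def test_round_trip(self, fixture_dir, tmp_path):
        genes, _ = read_gtf(fixture_dir / "reference.gtf")
        _, txs = read_gtf(fixture_dir / "transcripts.gtf")
        out = tmp_path / "rt.gtf"
        write_gtf(out, genes=genes, transcripts=txs)
        genes2, txs2 = read_gtf(out)
        assert genes2 == genes
        assert txs2 == txs


class TestBed:
    def test_bed4_te(self, tmp_path):
        p = tmp_path / "te.bed"
        p.write_text("chr1\t0\t100\tLTR:TE1\n")
        (rec,) = read_te_bed(p)
        assert rec.te_id == "TE1" and rec.family == "LTR"
        assert rec.interval == ivl(0, 100)

    def test_bed6_strand_preserved(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t5\t10\tn\t3.5\t-\n")
        (f,) = read_bed(p)
        assert f.interval.strand == "-" and f.score == 3.5

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\tzero\t10\n")
        with pytest.raises(ParseError):
            read_bed(p)

    def test_round_trip_random_intervals(self, tmp_path):
        rng = np.random.default_rng(42)
        feats = []
        for i in range(100):
            s = int(rng.integers(0, 10000))
            feats.append(
                BedFeature(
                    ivl(s, s + int(rng.integers(1, 500)),
                        chrom=f"chr{rng.integers(1, 4)}",
                        strand=str(rng.choice(["+", "-", "."]))),
                    name=f"f{i}",
                    score=float(rng.integers(0, 100)),
                )
            )
        p = tmp_path / "rt.bed"
        write_bed(p, feats)
        assert read_bed(p) == feats

    def test_peak_bed_filename_inference(self, tmp_path):
        p = tmp_path / "H3K27ac_rep2.bed"
        p.write_text("chr1\t0\t100\n")
        (peak,) = read_peak_bed(p)
        assert (peak.mark, peak.replicate) == ("H3K27ac", 2)


class TestHomologyTab:
    def _write(self, path, rows):
        with open(path, "w") as fh:
            for q, s, ident, ev in rows:
                fh.write(f"{q}\t{s}\t{ident}\t500\t0\t0\t1\t500\t1\t500\t{ev}\t900\n")

    def test_filters_evalue_and_self_hits(self, tmp_path):
        p = tmp_path / "hits.tsv"
        self._write(p, [
            ("A", "B", 98.0, 1e-30),   # keep
            ("A", "B", 97.0, 1e-3),    # fails threshold
            ("A", "A", 100.0, 1e-50),  # self-hit
            ("C", "D", 88.0, 1e-5),    # exactly at threshold: keep
            ("C", "E", 90.0, 2e-5),    # just above: drop
        ])
        hits = read_homology_tab(p, e_threshold=1e-5)
        assert {(h.query_id, h.subject_id) for h in hits} == {("A", "B"), ("C", "D")}

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("A\tB\t90.0\n")
        with pytest.raises(ParseError):
            read_homology_tab(p)

    def test_round_trip(self, tmp_path):
        hits = [HomologyHit("A", "B", 97.25, 500, 1e-30),
                HomologyHit("B", "C", 88.5, 400, 1e-12)]
        p = tmp_path / "rt.tsv"
        write_homology_tab(p, hits)
        back = read_homology_tab(p, e_threshold=1.0)
        assert [(h.query_id, h.pct_identity) for h in back] == [
            ("A", 97.25), ("B", 88.5)]


class TestCoverage:
    def test_mean_value_with_gaps(self):
        track = CoverageTrack({"chr1": [(0, 10, 2.0), (20, 30, 4.0)]})
        # [0,40): 10*2 + 10*4 = 60 over 40 bases
        assert track.mean_value("chr1", 0, 40) == pytest.approx(1.5)
        assert track.mean_value("chr1", 10, 20) == 0.0
        assert track.mean_value("chr2", 0, 10) == 0.0

    def test_rejects_overlapping_steps(self):
        with pytest.raises(ValueError):
            CoverageTrack({"chr1": [(0, 10, 1.0), (5, 15, 1.0)]})

    def test_bedgraph_round_trip(self, fixture_dir, tmp_path):
        track = read_bedgraph(fixture_dir / "coverage.bedgraph")
        out = tmp_path / "rt.bedgraph"
        write_bedgraph(out, track)
        back = read_bedgraph(out)
        for chrom in track.steps:
            for x, y in zip(track.steps[chrom], back.steps[chrom]):
                np.testing.assert_allclose(x, y, rtol=1e-6)


class TestFasta:
    def test_round_trip(self, tmp_path):
        seqs = {"s1": "ACGTACGT", "s2": "TTTTGGGG"}
        p = tmp_path / "x.fa"
        write_fasta(p, seqs)
        assert read_fasta(p) == seqs
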