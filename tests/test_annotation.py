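import numpy as np
import pytest

from emats.annotation import (
    AnnotationParseError,
    collapse_meta_exons,
    exon_distance_to_gene_5prime,
    flag_alternative,
    gene_length_kb,
    parse_annotation,
    read_regions,
    write_gtf,
    write_regions,
)
from emats.intervals import GenomeInterval

from conftest import union_oracle

TOY_GTF = """\
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "GA"; gene_type "protein_coding";
chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_type "protein_coding";
chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_type "protein_coding";
chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tgene_id "GA"; transcript_id "GA.1"; gene_type "protein_coding";
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "GB"; gene_type "lncRNA";
chr1\tsrc\ttranscript\t5001\t6000\t.\t-\t.\tgene_id "GB"; transcript_id "GB.1"; gene_type "lncRNA";
chr1\tsrc\texon\t5001\t6000\t.\t-\t.\tgene_id "GB"; transcript_id "GB.1"; gene_type "lncRNA";
"""


class TestParse:
    def test_gene_type_filter_and_coordinate_conversion(self, tmp_path):
        path = tmp_path / "toy.gtf"
        path.write_text(TOY_GTF)
        genes = parse_annotation(path, "protein_coding")
        assert [g.gene_id for g in genes] == ["GA"]
        # GTF 1-based closed [1001, 1200] -> 0-based half-open [1000, 1200)
        exon = genes[0].transcripts[0].exons[0]
        assert (exon.start, exon.end) == (1000, 1200)
        assert parse_annotation(path, None)[1].gene_type == "lncRNA"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tonly\tthree\n")
        with pytest.raises(AnnotationParseError, match="line 1"):
            parse_annotation(path)

    def test_unknown_strand_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text(
            'chr1\ts\texon\t1\t10\t.\t*\t.\tgene_id "G"; transcript_id "T";\n'
        )
        with pytest.raises(AnnotationParseError, match="strand"):
            parse_annotation(path, None)

    def test_exon_without_transcript_id_rejected(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\ts\texon\t1\t10\t.\t+\t.\tgene_id "G";\n')
        with pytest.raises(AnnotationParseError, match="transcript"):
            parse_annotation(path, None)

    def test_gtf_round_trip_preserves_intervals(self, tmp_path, small_config):
        from emats.simulate import generate_annotation

        genes, _ = generate_annotation(small_config)
        p1, p2, p3 = (tmp_path / n for n in ("a.gtf", "b.gtf", "c.gtf"))
        write_gtf(genes, p1)
        reparsed = parse_annotation(p1, "protein_coding")
        assert len(reparsed) == len(genes)
        original = {
            (g.gene_id, tx.transcript_id): [(e.start, e.end) for e in tx.exons]
            for g in genes
            for tx in g.transcripts
        }
        for g in reparsed:
            for tx in g.transcripts:
                assert original[(g.gene_id, tx.transcript_id)] == [
                    (e.start, e.end) for e in tx.exons
                ]
        # parse -> write stabilizes after one pass (genes sorted by locus)
        write_gtf(reparsed, p2)
        write_gtf(parse_annotation(p2, "protein_coding"), p3)
        assert p2.read_text() == p3.read_text()


class TestCollapse:
    def test_overlapping_exons_merge(self, gene_factory):
        gene = gene_factory({"t1": [(100, 200)], "t2": [(150, 250)]})
        assert [(m.interval.start, m.interval.end) for m in gene.meta_exons] == [
            (100, 250)
        ]
        assert gene.meta_exons[0].supporting_transcripts == {"t1", "t2"}

    def test_disjoint_and_bookended_exons_stay_separate(self, gene_factory):
        gene = gene_factory({"t1": [(100, 200), (300, 400)], "t2": [(200, 260)]})
        # [100,200) and [200,260) share only a boundary: not merged
        assert [(m.interval.start, m.interval.end) for m in gene.meta_exons] == [
            (100, 200),
            (200, 260),
            (300, 400),
        ]

    def test_single_exon_identity(self, gene_factory):
        gene = gene_factory({"t1": [(10, 20)]})
        assert [(m.interval.start, m.interval.end) for m in gene.meta_exons] == [
            (10, 20)
        ]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_base_union_oracle(self, gene_factory, strand):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            starts = rng.integers(0, 10**5 - 100, n)
            ends = starts + rng.integers(1, 500, n)
            gene = gene_factory(
                {"t1": list(zip(starts.tolist(), ends.tolist()))}, strand=strand
            )
            got = [(m.interval.start, m.interval.end) for m in gene.meta_exons]
            assert got == union_oracle(list(zip(starts.tolist(), ends.tolist())))

    def test_collapse_is_idempotent(self, gene_factory):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 5000, 30)
        ends = starts + rng.integers(1, 400, 30)
        gene = gene_factory({"t1": list(zip(starts.tolist(), ends.tolist()))})
        again = gene_factory(
            {"t1": [(m.interval.start, m.interval.end) for m in gene.meta_exons]}
        )
        assert [(m.interval.start, m.interval.end) for m in again.meta_exons] == [
            (m.interval.start, m.interval.end) for m in gene.meta_exons
        ]


class TestAlternativeFlag:
    def test_exon_missing_from_one_transcript_is_alternative(self, gene_factory):
        gene = gene_factory(
            {
                "t1": [(100, 200), (300, 400)],
                "t2": [(100, 200)],
                "t3": [(100, 200), (300, 400)],
            }
        )
        flags = {
            (m.interval.start, m.interval.end): m.is_alternative
            for m in gene.meta_exons
        }
        assert flags == {(100, 200): False, (300, 400): True}

    def test_single_transcript_gene_is_all_constitutive(self, gene_factory):
        gene = gene_factory({"t1": [(100, 200), (300, 400)]})
        assert all(not m.is_alternative for m in gene.meta_exons)

    def test_empty_gene_rejected(self, gene_factory):
        gene = gene_factory({"t1": [(1, 2)]})
        meta = gene.meta_exons[0]
        gene.transcripts = []
        with pytest.raises(ValueError):
            flag_alternative(meta, gene)
        with pytest.raises(ValueError):
            collapse_meta_exons(gene)


class TestArchitectureMetrics:
    @pytest.mark.parametrize(
        "span,expected", [((0, 1000), 1.0), ((10000, 12500), 2.5), ((5, 6), 0.001)]
    )
    def test_gene_length_kb(self, gene_factory, span, expected):
        gene = gene_factory({"t1": [(span[0], span[1])]}, span=span)
        assert gene_length_kb(gene) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "strand,exon,expected",
        [
            ("+", (2000, 2100), 1000),
            ("-", (7900, 8000), 1000),
            ("+", (1000, 1100), 0),
            ("-", (8900, 9000), 0),
        ],
    )
    def test_distance_to_5prime(self, gene_factory, strand, exon, expected):
        gene = gene_factory({"t1": [exon]}, strand=strand, span=(1000, 9000))
        iv = GenomeInterval("chr1", exon[0], exon[1], strand)
        assert exon_distance_to_gene_5prime(iv, gene) == expected

    def test_exon_outside_span_rejected(self, gene_factory):
        gene = gene_factory({"t1": [(2000, 2100)]}, span=(1000, 9000))
        with pytest.raises(ValueError):
            exon_distance_to_gene_5prime(
                GenomeInterval("chr1", 500, 600, "+"), gene
            )

    def test_strand_mirror_preserves_length_and_distance(self, gene_factory):
        rng = np.random.default_rng(3)
        reflect = 10**6
        for _ in range(25):
            lo = int(rng.integers(0, 10**4))
            hi = lo + int(rng.integers(1000, 10**4))
            es = int(rng.integers(lo, hi - 10))
            ee = es + int(rng.integers(1, hi - es))
            fwd = gene_factory({"t1": [(es, ee)]}, strand="+", span=(lo, hi))
            rev = gene_factory(
                {"t1": [(reflect - ee, reflect - es)]},
                strand="-",
                span=(reflect - hi, reflect - lo),
            )
            assert gene_length_kb(fwd) == gene_length_kb(rev)
            assert exon_distance_to_gene_5prime(
                GenomeInterval("chr1", es, ee, "+"), fwd
            ) == exon_distance_to_gene_5prime(
                GenomeInterval("chr1", reflect - ee, reflect - es, "-"), rev
            )


class TestBedOutput:
    def test_meta_exon_line_and_round_trip(self, tmp_path, gene_factory):
        gene = gene_factory({"t1": [(1000, 1200)]})
        path = tmp_path / "regions.bed"
        write_regions(gene.meta_exons, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t") == ["chr1", "1000", "1200", "G1|unclassified", "0", "+"]
        ivs = read_regions(path)
        assert ivs[0][0] == gene.meta_exons[0].interval

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_regions([], path)
        assert path.read_text().startswith("#")
        assert read_regions(path) == []

    def test_pair_emits_two_lines_sharing_pair_id(self, tmp_path, gene_factory):
        from emats.catalog import EmatsPair

        gene = gene_factory({"t1": [(1000, 1200)], "t2": [(3000, 3100)]})
        wafe, sse = gene.meta_exons
        pair = EmatsPair("G1", wafe, sse, 2000, 0.2, 0.9)
        path = tmp_path / "pair.bed"
        write_regions([pair], path)
        rows = read_regions(path)
        assert len(rows) == 2
        pid_w, pid_s = (r[1].split("|")[0] for r in rows)
        assert pid_w == pid_s
        assert rows[0][2] == 200 and rows[1][2] == 900  # PSI x 1000
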