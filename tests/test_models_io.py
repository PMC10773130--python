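"""Domain types, GTF/TSV I/O and coordinate-convention handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import make_tx
from isocall.io import (
    ExpressionMatrix,
    GtfParseError,
    read_expression,
    read_gtf,
    read_junction_support,
    write_expression,
    write_gtf,
    write_junction_support,
)
from isocall.models import (
    GenomicInterval,
    Junction,
    JunctionSupportTable,
    ReferenceAnnotation,
    TranscriptModel,
    junction_chain,
)


class TestDomainTypes:
    def test_interval_rejects_empty_and_bad_strand(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 20, ".")

    def test_transcript_requires_separated_sorted_exons(self):
        with pytest.raises(ValueError):
            make_tx("t", "chr1", "+", [(0, 10), (10, 20)])  # abutting, no intron
        with pytest.raises(ValueError):
            make_tx("t", "chr1", "+", [(20, 30), (0, 10)])  # unsorted

    def test_mixed_strand_exons_rejected(self):
        exons = (
            GenomicInterval("chr1", 0, 10, "+"),
            GenomicInterval("chr1", 20, 30, "-"),
        )
        with pytest.raises(ValueError):
            TranscriptModel("t", exons)

    @pytest.mark.parametrize(
        "blocks,expected",
        [
            ([(100, 200), (300, 400)], [(200, 300)]),
            ([(50, 500)], []),
            ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
        ],
    )
    def test_junction_chain_definition(self, blocks, expected):
        t = make_tx("t", "chr1", "+", blocks)
        assert [(j.donor, j.acceptor) for j in junction_chain(t)] == expected

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(2, 150)), min_size=1, max_size=12
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_chain_length_is_exons_minus_one(self, steps):
        pos = 0
        blocks = []
        for gap, length in steps:
            start = pos + gap
            blocks.append((start, start + length))
            pos = start + length
        t = make_tx("t", "chr1", "-", blocks)
        assert len(junction_chain(t)) == len(t.exons) - 1

    def test_splice_site_roles_flip_with_strand(self):
        plus = Junction("chr1", 100, 200, "+").sites()
        minus = Junction("chr1", 100, 200, "-").sites()
        assert plus[0][3] == "donor" and plus[1][3] == "acceptor"
        assert minus[0][3] == "acceptor" and minus[1][3] == "donor"


class TestGtf:
    def test_coordinates_convert_to_half_open(self, tmp_path):
        gtf = tmp_path / "q.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\ttranscript_id "T1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\ttranscript_id "T1";\n'
        )
        (model,) = read_gtf(gtf, kind="query")
        assert [(e.start, e.end) for e in model.exons] == [(100, 200), (300, 400)]

    def test_reference_indexes_junctions(self, tmp_path):
        gtf = tmp_path / "r.gtf"
        gtf.write_text(
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\tx\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        ref = read_gtf(gtf, kind="reference")
        assert ref.junction_index == {Junction("chr1", 200, 300, "+")}

    def test_missing_transcript_id_is_parse_error(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "G1";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            read_gtf(gtf, kind="query")

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\texon\t101\n")
        with pytest.raises(GtfParseError, match=r":1:"):
            read_gtf(gtf, kind="query")

    def test_unknown_strand_rejected(self, tmp_path):
        gtf = tmp_path / "dot.gtf"
        gtf.write_text('chr1\tx\texon\t101\t200\t.\t.\t.\ttranscript_id "T1";\n')
        with pytest.raises(GtfParseError, match="strand"):
            read_gtf(gtf, kind="query")

    def test_write_read_round_trip(self, tmp_path):
        models = [
            make_tx("T1", "chr1", "+", [(100, 200), (300, 400)], gene="G1"),
            make_tx("T2", "chr2", "-", [(50, 500)], gene="G2"),
        ]
        path = tmp_path / "rt.gtf"
        write_gtf(models, path)
        back = read_gtf(path, kind="query")
        assert [(m.transcript_id, m.gene_id, m.strand, tuple((e.start, e.end) for e in m.exons)) for m in back] == [
            (m.transcript_id, m.gene_id, m.strand, tuple((e.start, e.end) for e in m.exons)) for m in models
        ]

    def test_parser_agrees_with_gffutils(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        models = [
            make_tx("T1", "chr1", "+", [(100, 200), (300, 400), (600, 700)], gene="G1"),
            make_tx("T2", "chr1", "-", [(1000, 1200)], gene="G2"),
        ]
        path = tmp_path / "x.gtf"
        write_gtf(models, path)
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        ours = {
            m.transcript_id: [(e.start, e.end) for e in m.exons]
            for m in read_gtf(path, kind="query")
        }
        theirs = {}
        for exon in db.features_of_type("exon"):
            tx = exon.attributes["transcript_id"][0]
            theirs.setdefault(tx, []).append((exon.start - 1, exon.end))
        assert ours == {k: sorted(v) for k, v in theirs.items()}


class TestJunctionSupport:
    def test_pooling_is_additive(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            (tmp_path / name).write_text("chr1\t201\t300\t+\t5\n")
        table = read_junction_support([tmp_path / "a.tsv", tmp_path / "b.tsv"])
        assert table.get(Junction("chr1", 200, 300, "+")) == 10

    def test_pooling_order_independent(self, tmp_path):
        (tmp_path / "a.tsv").write_text("chr1\t201\t300\t+\t5\nchr2\t11\t90\t-\t2\n")
        (tmp_path / "b.tsv").write_text("chr1\t201\t300\t+\t7\n")
        t1 = read_junction_support([tmp_path / "a.tsv", tmp_path / "b.tsv"])
        t2 = read_junction_support([tmp_path / "b.tsv", tmp_path / "a.tsv"])
        assert sorted(t1.items()) == sorted(t2.items())

    def test_empty_file_list_gives_zero_lookups(self):
        table = read_junction_support([])
        assert table.get(Junction("chr1", 0, 10, "+")) == 0

    def test_negative_count_rejected(self, tmp_path):
        (tmp_path / "neg.tsv").write_text("chr1\t201\t300\t+\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_junction_support([tmp_path / "neg.tsv"])

    def test_dot_strand_matches_either(self):
        table = JunctionSupportTable()
        table.add("chr1", 200, 300, ".", 4)
        assert table.get(Junction("chr1", 200, 300, "+")) == 4
        assert table.get(Junction("chr1", 200, 300, "-")) == 4

    def test_round_trip(self, tmp_path):
        table = JunctionSupportTable()
        table.add("chr1", 200, 300, "+", 4)
        table.add("chr2", 5, 50, "-", 1)
        write_junction_support(table, tmp_path / "j.tsv")
        back = read_junction_support([tmp_path / "j.tsv"])
        assert sorted(back.items()) == sorted(table.items())


class TestExpression:
    def _matrix(self):
        values = pd.DataFrame(
            [[1.5, 2.25], [0.0, 7.0]],
            index=["TX1", "TX2"],
            columns=["S1", "S2"],
        )
        groups = pd.Series(["tumour", "normal"], index=["S1", "S2"])
        return ExpressionMatrix(values=values, groups=groups)

    def test_round_trip_bit_exact(self, tmp_path):
        m = self._matrix()
        write_expression(m, tmp_path / "m.tsv", tmp_path / "g.tsv")
        back = read_expression(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert back.values.equals(m.values.astype(float))
        assert list(back.groups) == list(m.groups)

    def test_negative_tpm_rejected(self):
        values = pd.DataFrame([[-1.0]], index=["TX1"], columns=["S1"])
        with pytest.raises(ValueError, match="negative"):
            ExpressionMatrix(values=values, groups=pd.Series(["g"], index=["S1"]))

    def test_sample_missing_from_groups_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]], index=["TX1"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="missing"):
            ExpressionMatrix(values=values, groups=pd.Series(["g"], index=["S1"]))


class TestReferenceAnnotation:
    def test_gene_span_covers_transcripts(self):
        ref = ReferenceAnnotation(
            [
                make_tx("T1", "chr1", "+", [(100, 200), (300, 400)], gene="G1"),
                make_tx("T2", "chr1", "+", [(50, 120), (300, 450)], gene="G1"),
            ]
        )
        gene = ref.genes["G1"]
        assert (gene.start, gene.end) == (50, 450)
        assert ref.overlapping_genes("chr1", 0, 60) and not ref.overlapping_genes(
            "chr1", 500, 600
        )

    def test_duplicate_reference_transcript_rejected(self):
        t = make_tx("T1", "chr1", "+", [(0, 10)], gene="G1")
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceAnnotation([t, t])
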