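"""Annotation model: coordinate conventions, intron derivation,
LTR-internal merging, genic flagging, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtetx.annotation import (
    GeneModel,
    GenomicInterval,
    ParseError,
    RepeatRow,
    TranscriptContig,
    derive_introns,
    flag_genic_repeats,
    merge_ltr_internal,
    read_bed12,
    read_gtf,
    read_repeat_table,
    write_bed12,
    write_gtf,
    write_repeat_table,
)


def make_gtf(tmp_path, lines):
    path = tmp_path / "test.gtf"
    path.write_text("".join(lines))
    return path


def exon_line(chrom, start, end, gene, strand="+", feature="exon"):
    return (
        f"{chrom}\tsrc\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}";\n'
    )


class TestReadGtf:
    def test_coordinate_conversion_and_intron(self, tmp_path):
        path = make_gtf(
            tmp_path,
            [exon_line("chr1", 101, 200, "g1"), exon_line("chr1", 301, 400, "g1")],
        )
        (gene,) = read_gtf(path)
        assert [(e.start, e.end) for e in gene.exons] == [(100, 200), (300, 400)]
        assert [(i.start, i.end) for i in gene.introns] == [(200, 300)]

    def test_single_exon_gene_has_no_introns(self, tmp_path):
        (gene,) = read_gtf(make_gtf(tmp_path, [exon_line("chr1", 1, 50, "g1")]))
        assert gene.introns == []

    def test_overlapping_isoform_exons_form_union(self, tmp_path, rng):
        # two isoforms with overlapping exons: exon union must equal the
        # brute-force per-base union, with no duplicate intervals
        iso1 = [(101, 200), (301, 400)]
        iso2 = [(151, 250), (301, 450)]
        path = make_gtf(
            tmp_path,
            [exon_line("chr1", s, e, "g1") for s, e in iso1 + iso2],
        )
        (gene,) = read_gtf(path)
        base_union = set()
        for s, e in iso1 + iso2:
            base_union |= set(range(s - 1, e))
        covered = set()
        for exon in gene.exons:
            block = set(range(exon.start, exon.end))
            assert not block & covered, "duplicate coverage in exon union"
            covered |= block
        assert covered == base_union

    def test_malformed_line_names_line_number(self, tmp_path):
        path = make_gtf(tmp_path, [exon_line("chr1", 1, 50, "g1"), "bad line\n"])
        with pytest.raises(ParseError, match=":2"):
            read_gtf(path)

    def test_gene_without_exons_rejected_with_id(self, tmp_path):
        path = make_gtf(
            tmp_path, [exon_line("chr1", 1, 500, "gX", feature="gene")]
        )
        with pytest.raises(ParseError, match="gX"):
            read_gtf(path)

    def test_round_trip_preserves_coordinates(self, tmp_path, dataset):
        out = tmp_path / "rt.gtf"
        write_gtf(dataset.genes, out)
        back = read_gtf(out)
        orig = {g.gene_id: g for g in dataset.genes}
        assert set(g.gene_id for g in back) == set(orig)
        for g in back:
            assert [(e.start, e.end) for e in g.exons] == [
                (e.start, e.end) for e in orig[g.gene_id].exons
            ]


class TestBed12:
    def test_single_block(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t200\ttx1\t0\t+\t100\t200\t0\t1\t100\t0\n")
        (c,) = read_bed12(path)
        assert [(b.start, b.end) for b in c.blocks] == [(100, 200)]

    def test_block_offsets(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text(
            "chr1\t1000\t1200\ttx1\t0\t+\t1000\t1200\t0\t2\t50,50\t0,150\n"
        )
        (c,) = read_bed12(path)
        assert [(b.start, b.end) for b in c.blocks] == [(1000, 1050), (1150, 1200)]

    def test_block_count_mismatch(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t0\t100\ttx\t0\t+\t0\t100\t0\t2\t50\t0\n")
        with pytest.raises(ParseError, match="blockCount"):
            read_bed12(path)

    def test_block_past_chrom_end(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t0\t100\ttx\t0\t+\t0\t100\t0\t1\t200\t0\n")
        with pytest.raises(ParseError, match="past chromEnd"):
            read_bed12(path)

    def test_round_trip_random_contigs(self, tmp_path, rng):
        contigs = []
        for i in range(50):
            n_blocks = int(rng.integers(1, 5))
            pos = int(rng.integers(0, 10_000))
            blocks = []
            for _ in range(n_blocks):
                length = int(rng.integers(20, 400))
                blocks.append(GenomicInterval("chr1", pos, pos + length))
                pos += length + int(rng.integers(1, 500))
            contigs.append(TranscriptContig(f"tx{i}", "chr1", "+", blocks))
        out = tmp_path / "rt.bed"
        write_bed12(contigs, out)
        back = {c.transcript_id: c for c in read_bed12(out)}
        for c in contigs:
            assert [(b.start, b.end) for b in back[c.transcript_id].blocks] == [
                (b.start, b.end) for b in c.blocks
            ]


class TestRepeatTable:
    def test_class_lookup_and_coordinates(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text(
            "chr1\t101\t200\t+\tAluSx\tSINE/Alu\n"
            "chr1\t301\t500\t-\tHERVH-int\tLTR/ERV1\n"
        )
        rows = read_repeat_table(path)
        assert rows[0].family == "Alu" and rows[0].rte_class == "SINE"
        assert (rows[0].start, rows[0].end) == (100, 200)
        assert rows[1].rte_class == "LTR"

    def test_unknown_class_maps_to_other_with_warning(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("chr1\t1\t100\t+\tWeird1\tUnknownClass/Foo\n")
        with pytest.warns(UserWarning, match="Other"):
            rows = read_repeat_table(path)
        assert rows[0].rte_class == "Other"


def row(chrom, start, end, subfamily, strand="+", cf="LTR/ERV1"):
    return RepeatRow(chrom, start, end, strand, subfamily, cf)


class TestMergeLtrInternal:
    def test_ltr_internal_ltr_merges_to_one_element(self):
        rows = [
            row("chr1", 0, 450, "LTR7Y"),
            row("chr1", 450, 2950, "HERVH-int"),
            row("chr1", 2950, 3400, "LTR7Y"),
        ]
        merged = merge_ltr_internal(rows, gap_tolerance=0)
        assert len(merged) == 1
        el = merged[0]
        assert el.subfamily == "HERVH"
        assert (el.interval.start, el.interval.end) == (0, 3400)
        assert el.rte_class == "LTR"

    def test_solo_ltr_passes_through(self):
        merged = merge_ltr_internal([row("chr1", 0, 450, "LTR7Y")])
        assert len(merged) == 1 and merged[0].subfamily == "LTR7Y"

    def test_gap_tolerance_respected(self):
        rows = [
            row("chr1", 0, 450, "LTR7Y"),
            row("chr1", 700, 3000, "HERVH-int"),
        ]
        assert len(merge_ltr_internal(rows, gap_tolerance=100)) == 2
        assert len(merge_ltr_internal(rows, gap_tolerance=300)) == 1

    def test_different_strands_never_merge(self):
        rows = [
            row("chr1", 0, 450, "LTR7Y", strand="+"),
            row("chr1", 460, 2900, "HERVH-int", strand="-"),
        ]
        assert len(merge_ltr_internal(rows)) == 2

    def test_negative_gap_tolerance_rejected(self):
        with pytest.raises(ValueError):
            merge_ltr_internal([], gap_tolerance=-1)

    def test_random_rows_match_chain_enumeration_oracle(self, rng):
        # oracle: walk sorted rows, linking consecutive pairs exactly when
        # same chrom/strand, gap <= tol, and one is an internal model whose
        # element the other belongs to; merged count = number of chains
        subfams = ["LTR7Y", "HERVH-int", "AluSx", "LTR5A", "HERVK-int"]
        cf = {
            "LTR7Y": "LTR/ERV1", "HERVH-int": "LTR/ERV1", "AluSx": "SINE/Alu",
            "LTR5A": "LTR/ERVK", "HERVK-int": "LTR/ERVK",
        }
        pairing = {"HERVH": ("LTR7*",), "HERVK": ("LTR5*",)}
        tol = 50
        for _ in range(30):
            rows = []
            pos = 0
            for _ in range(int(rng.integers(2, 12))):
                pos += int(rng.integers(0, 150))
                length = int(rng.integers(100, 500))
                sf = subfams[int(rng.integers(len(subfams)))]
                rows.append(row("chr1", pos, pos + length, sf, cf=cf[sf]))
                pos += length

            def links(a, b):
                if b.start - a.end > tol or a.strand != b.strand:
                    return False
                for x, y in ((a, b), (b, a)):
                    if x.subfamily.endswith("-int"):
                        base = x.subfamily[:-4]
                        if y.subfamily == x.subfamily or any(
                            y.subfamily.startswith(p[:-1])
                            for p in pairing.get(base, ())
                        ):
                            return True
                return False

            chains = 1
            for a, b in zip(rows, rows[1:]):
                if not links(a, b):
                    chains += 1
            merged = merge_ltr_internal(rows, gap_tolerance=tol, pairing=pairing)
            assert len(merged) == chains

    def test_idempotent(self, dataset):
        merged = merge_ltr_internal(dataset.repeat_rows)
        rows_again = [
            RepeatRow(
                e.interval.chrom, e.interval.start, e.interval.end,
                e.interval.strand, e.subfamily,
                f"{e.rte_class}/{e.family}",
            )
            for e in merged
        ]
        merged2 = merge_ltr_internal(rows_again)
        assert [
            (e.interval.chrom, e.interval.start, e.interval.end, e.subfamily)
            for e in merged
        ] == [
            (e.interval.chrom, e.interval.start, e.interval.end, e.subfamily)
            for e in merged2
        ]


class TestIntrons:
    def test_simple_gap(self):
        g = GeneModel(
            "g", "chr1", "+",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)],
        )
        assert [(i.start, i.end) for i in derive_introns(g)] == [(100, 200)]

    def test_exons_and_introns_tile_gene_body(self, rng):
        for _ in range(25):
            pos = int(rng.integers(0, 1000))
            exons = []
            for _ in range(int(rng.integers(1, 6))):
                length = int(rng.integers(50, 300))
                exons.append(GenomicInterval("chr1", pos, pos + length))
                pos += length + int(rng.integers(1, 800))
            g = GeneModel("g", "chr1", "+", exons)
            body = set(range(g.gene_body.start, g.gene_body.end))
            exon_bases = set()
            for e in g.exons:
                exon_bases |= set(range(e.start, e.end))
            intron_bases = set()
            for i in g.introns:
                block = set(range(i.start, i.end))
                assert not block & intron_bases
                intron_bases |= block
            assert not exon_bases & intron_bases
            assert exon_bases | intron_bases == body
            assert len(g.introns) == len(g.exons) - 1


@st.composite
def exon_lists(draw):
    """Arbitrary (possibly overlapping) exon intervals on one chromosome."""
    n = draw(st.integers(1, 8))
    exons = []
    for _ in range(n):
        start = draw(st.integers(0, 5000))
        length = draw(st.integers(1, 400))
        exons.append(GenomicInterval("chr1", start, start + length))
    return exons


class TestGeneModelProperties:
    @settings(max_examples=100, deadline=None)
    @given(exon_lists())
    def test_exon_union_and_introns_partition_gene_body(self, exons):
        g = GeneModel("g", "chr1", "+", exons)
        bases = set()
        for raw in exons:
            bases |= set(range(raw.start, raw.end))
        union_bases = set()
        for e in g.exons:
            block = set(range(e.start, e.end))
            assert not block & union_bases
            union_bases |= block
        assert union_bases == bases
        intron_bases = set()
        for i in g.introns:
            intron_bases |= set(range(i.start, i.end))
        body = set(range(g.gene_body.start, g.gene_body.end))
        assert union_bases | intron_bases == body
        assert not union_bases & intron_bases


class TestGenicFlag:
    def _repeat(self, chrom, start, end):
        from rtetx.annotation import RepeatElement

        return RepeatElement(
            "r1", GenomicInterval(chrom, start, end, "+"), "AluSx", "Alu", "SINE"
        )

    def test_repeat_inside_intron_is_genic(self):
        g = GeneModel(
            "g", "chr1", "+",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 2000, 2100)],
        )
        (rep,) = flag_genic_repeats([self._repeat("chr1", 500, 800)], [g])
        assert rep.genic is True

    def test_half_open_abutment_is_intergenic(self):
        g = GeneModel("g", "chr1", "+", [GenomicInterval("chr1", 1000, 2000)])
        (rep,) = flag_genic_repeats([self._repeat("chr1", 700, 1000)], [g])
        assert rep.genic is False

    def test_partition_on_dataset(self, dataset):
        genic = sum(r.genic for r in dataset.repeats)
        intergenic = sum(not r.genic for r in dataset.repeats)
        assert genic + intergenic == len(dataset.repeats)
        assert all(r.genic is not None for r in dataset.repeats)

    def test_repeat_round_trip(self, tmp_path, dataset):
        out = tmp_path / "r.tsv"
        write_repeat_table(dataset.repeats, out)
        back = read_repeat_table(out)
        orig = sorted(
            (r.interval.chrom, r.interval.start, r.interval.end, r.subfamily)
            for r in dataset.repeats
        )
        got = sorted((r.chrom, r.start, r.end, r.subfamily) for r in back)
        assert got == orig
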