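"""Domain types, FASTA/exon-table IO and molecular weight."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrscan.core import (
    AMINO_ACIDS,
    EmptyInputError,
    ExonRecord,
    ProteinRecord,
    ValidationError,
    molecular_weight,
    read_exon_table,
    read_fasta,
    to_one_based,
    to_zero_based,
    validate_architecture,
    write_exon_table,
    write_fasta,
)
from lrrscan.core import DomainSpan

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKL\n")
        (rec,) = read_fasta(p)
        assert rec.id == "x" and rec.sequence == "MKL"

    def test_order_and_case(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nmkl\n>b\nACD\nEFG\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].sequence == "MKL"  # upper-cased
        assert recs[1].sequence == "ACDEFG"  # wrapped lines joined

    def test_illegal_residue_names_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">bad\nMKB\n")
        with pytest.raises(ValidationError, match="'bad'.*position 3"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_fasta(p)

    @given(seqs=st.lists(sequences, min_size=1, max_size=4))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_round_trip(self, seqs, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("fa") / "r.fasta"
        records = [ProteinRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        write_fasta(records, tmp)
        back = read_fasta(tmp)
        assert [(r.id, r.sequence) for r in back] == [
            (r.id, r.sequence) for r in records
        ]


class TestExonTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "e.tsv"
        body = "\n".join("\t".join(map(str, r)) for r in rows)
        p.write_text("exon_number\tprotein_start\tprotein_end\n" + body + "\n")
        return p

    def test_basic(self, tmp_path):
        exons = read_exon_table(self._write(tmp_path, [(7, 1, 20), (8, 21, 48)]))
        assert [(e.exon_number, e.protein_start, e.protein_end) for e in exons] == [
            (7, 1, 20),
            (8, 21, 48),
        ]
        assert exons[1].length_aa == 28

    def test_unsorted_rows_sorted(self, tmp_path):
        exons = read_exon_table(self._write(tmp_path, [(8, 21, 48), (7, 1, 20)]))
        assert [e.exon_number for e in exons] == [7, 8]

    def test_overlap_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="overlap"):
            read_exon_table(self._write(tmp_path, [(7, 1, 20), (8, 15, 48)]))

    def test_non_integer_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="non-integer"):
            read_exon_table(self._write(tmp_path, [(7, 1, "twenty")]))

    def test_round_trip(self, tmp_path):
        exons = [ExonRecord(7, 1, 20), ExonRecord(8, 21, 48)]
        p = tmp_path / "w.tsv"
        write_exon_table(exons, p)
        back = read_exon_table(p)
        assert [(e.exon_number, e.protein_start, e.protein_end) for e in back] == [
            (7, 1, 20),
            (8, 21, 48),
        ]


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight(ProteinRecord("g", "G")) == pytest.approx(
            0.07507, abs=1e-4
        )

    def test_diglycine_loses_one_water(self):
        assert molecular_weight(ProteinRecord("gg", "GG")) == pytest.approx(
            0.13212, abs=1e-4
        )

    @given(a=sequences, b=sequences)
    @settings(max_examples=50, derandomize=True)
    def test_additivity(self, a, b):
        """MW(a+b) = MW(a) + MW(b) - one water (18.02 Da)."""
        whole = molecular_weight(a + b)
        parts = molecular_weight(a) + molecular_weight(b) - 0.01802
        assert whole == pytest.approx(parts, abs=1e-5)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            molecular_weight("MKX")


class TestCoordinates:
    @given(start=st.integers(1, 10_000), length=st.integers(1, 500))
    @settings(max_examples=50, derandomize=True)
    def test_conversion_round_trip(self, start, length):
        end = start + length - 1
        assert to_one_based(*to_zero_based(start, end)) == (start, end)

    def test_position_addressing(self):
        rec = ProteinRecord("p", "MKLV")
        assert rec.residue(1) == "M" and rec.residue(4) == "V"
        assert rec.slice(2, 3) == "KL"

    def test_domain_overlap_rejected(self):
        spans = [DomainSpan("uCARD", 1, 197), DomainSpan("NACHT", 150, 369)]
        with pytest.raises(ValidationError, match="overlap"):
            validate_architecture(spans)

    def test_domain_sorted(self):
        spans = validate_architecture(
            [DomainSpan("NACHT", 198, 369), DomainSpan("uCARD", 1, 197)]
        )
        assert [s.name for s in spans] == ["uCARD", "NACHT"]


class TestGff3Converter:
    def test_exon_lines_with_protein_spans(self, tmp_path):
        from lrrscan.core import gff3_to_exon_table

        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t999\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t1\t84\t.\t+\t.\t"
            "ID=e8;exon_number=8;protein_start=21;protein_end=48\n"
            "chr1\tsrc\texon\t85\t144\t.\t+\t.\t"
            "ID=e7;exon_number=7;protein_start=1;protein_end=20\n"
        )
        out = tmp_path / "t.tsv"
        exons = gff3_to_exon_table(gff, out)
        assert [(e.exon_number, e.protein_start, e.protein_end) for e in exons] == [
            (7, 1, 20),
            (8, 21, 48),
        ]
        # the written TSV is the contract: it must read back identically
        assert [
            (e.exon_number, e.protein_start, e.protein_end)
            for e in read_exon_table(out)
        ] == [(7, 1, 20), (8, 21, 48)]

    def test_missing_attribute_rejected(self, tmp_path):
        from lrrscan.core import gff3_to_exon_table

        gff = tmp_path / "t.gff3"
        gff.write_text("chr1\tsrc\texon\t1\t84\t.\t+\t.\tID=e8;exon_number=8\n")
        with pytest.raises(ValidationError, match="missing attribute"):
            gff3_to_exon_table(gff, tmp_path / "t.tsv")
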