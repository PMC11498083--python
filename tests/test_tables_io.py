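"""Parsing, validation and round-trip fidelity of every file format."""

import pytest

from viropost import (
    AlignmentRow,
    BinRecord,
    CheckVRow,
    ContigSeq,
    CoverageRow,
    DetectionRecord,
    GenomadRow,
    Placement,
    SchemaError,
    ValidationError,
    join_detection_rows,
    read_fasta,
    read_table,
    write_fasta,
    write_table,
)
from viropost.tables_io import normalize_quality, read_coverage_table


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text(">c1\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].contig_id == "c1"
        assert recs[0].length == 4

    def test_description_dropped_from_id(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text(">c1 some description words\nACGT\n")
        assert read_fasta(p)[0].contig_id == "c1"

    def test_wrapped_sequence_is_joined(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text(">c1\nACGT\nACGT\nAC\n")
        assert read_fasta(p)[0].sequence == "ACGTACGTAC"

    def test_duplicate_id_is_error(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text(">c1\nACGT\n>c1\nGGGG\n")
        with pytest.raises(ValidationError, match="c1"):
            read_fasta(p)

    def test_empty_sequence_is_error(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text(">c1\n>c2\nACGT\n")
        with pytest.raises(ValidationError, match="empty"):
            read_fasta(p)

    def test_non_fasta_reports_line(self, tmp_path):
        p = tmp_path / "a.fna"
        p.write_text("contig\tscore\nc1\t0.9\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_fasta(p)

    def test_write_read_roundtrip(self, tmp_path):
        contigs = [ContigSeq("c1", "ACGT" * 40), ContigSeq("c2", "GGCC")]
        p = tmp_path / "out.fna"
        write_fasta(contigs, p)
        back = read_fasta(p)
        assert [(c.contig_id, c.sequence) for c in back] == [
            (c.contig_id, c.sequence) for c in contigs
        ]


# ---------------------------------------------------------------------------
# Record invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    def test_score_outside_unit_interval(self):
        with pytest.raises(ValidationError, match="virus_score"):
            GenomadRow("c1", 1000, virus_score=1.5)

    def test_hallmarks_bounded_by_genes(self):
        with pytest.raises(ValidationError, match="hallmarks"):
            GenomadRow("c1", 1000, n_genes=2, n_hallmarks=3)

    def test_provirus_coords_require_provirus_topology(self):
        with pytest.raises(ValidationError, match="provirus"):
            GenomadRow("c1", 1000, topology="linear", provirus_coords=(10, 500))
        with pytest.raises(ValidationError, match="provirus"):
            GenomadRow("c1", 1000, topology="provirus")

    def test_gene_sum_bounded(self):
        with pytest.raises(ValidationError, match="gene_count"):
            CheckVRow("c1", 1000, gene_count=3, viral_genes=2, host_genes=2)

    def test_trimmed_region_requires_flag(self):
        with pytest.raises(ValidationError, match="provirus"):
            CheckVRow("c1", 1000, trimmed_region=(1, 500))

    def test_contig_id_whitespace_rejected(self):
        with pytest.raises(ValidationError):
            ContigSeq("c 1", "ACGT")

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValidationError):
            ContigSeq("c1", "ACGT!!")

    def test_detection_provirus_length_must_match_region(self):
        with pytest.raises(ValidationError, match="span"):
            DetectionRecord("p|provirus_10_20", is_provirus=True,
                            parent_contig_id="p", region=(10, 20), length=5)

    def test_placement_span_ordering(self):
        with pytest.raises(ValidationError):
            Placement("c1", 50, 10)


class TestQualityNormalization:
    @pytest.mark.parametrize("raw,expected", [
        ("high-quality", "High-quality"),
        ("HIGH-QUALITY", "High-quality"),
        ("medium quality", "Medium-quality"),
        ("not_determined", "Not-determined"),
        ("Complete", "Complete"),
    ])
    def test_case_and_separator_folding(self, raw, expected):
        assert normalize_quality(raw) == expected

    def test_unknown_maps_to_not_determined_with_warning(self):
        with pytest.warns(UserWarning, match="unknown quality"):
            assert normalize_quality("splendid") == "Not-determined"


# ---------------------------------------------------------------------------
# Table round trips
# ---------------------------------------------------------------------------

GENOMAD_ROWS = [
    GenomadRow("c1", 5000, "linear", None, 7, 0.93, 2, "Viruses;Caudoviricetes"),
    GenomadRow("c2", 8000, "provirus", (100, 4200), 5, 0.81, 1, ""),
    GenomadRow("c3", 2600, "circular-DTR", None, 3, 0.7, 0, ""),
]
CHECKV_ROWS = [
    CheckVRow("c1", 5000, 7, 5, 1, "High-quality", 97.5, False, None),
    CheckVRow("c2", 8000, 5, 3, 2, "Medium-quality", None, True, (100, 4200)),
]
COVERAGE_ROWS = [
    CoverageRow("c1", "S1", 12.5, 0.9, 420),
    CoverageRow("c2", "S1", 0.0, 0.0, 0),
]
ALIGNMENT_ROWS = [
    AlignmentRow("c1", "c2", 97.125, 4000, 100, 3, 1, 4000, 4200, 201, 0.0, 7000.5),
]
DETECTION_ROWS = [
    DetectionRecord("S1__c1", "S1", False, None, None, 5000, 0.93, 2, 7, 5, 1,
                    "High-quality", 97.5, "Viruses;Caudoviricetes", "dsDNA",
                    "prokaryotic", 1),
    DetectionRecord("S1__c2|provirus_100_4200", "S1", True, "S1__c2",
                    (100, 4200), 4101, 0.81, 1, 5, 3, 0, "Medium-quality",
                    None, "", "unknown", "unknown", 2),
]
PLACEMENT_ROWS = [Placement("c1", 1, 150), Placement("c1", 151, 300)]
BIN_ROWS = [BinRecord("vBin_1", ["c1", "c2"], 1, 9000, "Medium-quality")]


@pytest.mark.parametrize("rows,schema", [
    (GENOMAD_ROWS, "genomad"),
    (CHECKV_ROWS, "checkv"),
    (COVERAGE_ROWS, "coverage"),
    (ALIGNMENT_ROWS, "alignment"),
    (DETECTION_ROWS, "detection"),
    (PLACEMENT_ROWS, "placement"),
    (BIN_ROWS, "bin"),
], ids=lambda v: v if isinstance(v, str) else "")
def test_roundtrip_identity(tmp_path, rows, schema):
    """parse(serialize(x)) == x on all typed fields, for every schema."""
    p = tmp_path / "t.tsv"
    write_table(rows, p, schema)
    assert read_table(p, schema) == rows


def test_empty_row_list_writes_header_only(tmp_path):
    p = tmp_path / "t.tsv"
    write_table([], p, "genomad")
    lines = p.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("contig_id\t")
    assert read_table(p, "genomad") == []


def test_missing_value_written_as_na(tmp_path):
    p = tmp_path / "t.tsv"
    write_table([CHECKV_ROWS[1]], p, "checkv")
    row = p.read_text().splitlines()[1].split("\t")
    assert "NA" in row  # completeness is missing


# ---------------------------------------------------------------------------
# Header dialects and schema errors
# ---------------------------------------------------------------------------

class TestDialects:
    def test_genomad_native_headers(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "seq_name\tlength\ttopology\tcoordinates\tn_genes\tscore\thallmarks\ttaxonomy\n"
            "c1\t5000\tNo terminal repeats\tNA\t7\t0.93\t2\tViruses\n"
        )
        rows = read_table(p, "genomad")
        assert rows[0].contig_id == "c1"
        assert rows[0].virus_score == 0.93
        assert rows[0].n_hallmarks == 2
        assert rows[0].topology == "linear"

    def test_checkv_native_headers(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "contig_id\tcontig_length\tgene_count\tviral_genes\thost_genes\t"
            "checkv_quality\tcompleteness\tprovirus\n"
            "c1\t5000\t7\t5\t1\thigh-quality\t97.5\tNo\n"
        )
        rows = read_table(p, "checkv")
        assert rows[0].quality == "High-quality"
        assert rows[0].provirus_flag is False

    def test_coverm_style_coverage(self, tmp_path):
        p = tmp_path / "cov.tsv"
        p.write_text(
            "Contig\tMean\tCovered Fraction\tRead Count\nc1\t3.5\t0.8\t120\n"
        )
        rows = read_coverage_table(p, sample_id="S9")
        assert rows[0].sample_id == "S9"
        assert rows[0].mean_depth == 3.5

    def test_missing_required_column_names_it(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("seq_name\tlength\ttopology\tn_genes\thallmarks\nc1\t5\tlinear\t1\t0\n")
        with pytest.raises(SchemaError, match="virus_score"):
            read_table(p, "genomad")


# ---------------------------------------------------------------------------
# Detector/quality join
# ---------------------------------------------------------------------------

class TestDetectionJoin:
    def _rows(self, n):
        g = [GenomadRow(f"c{i}", 5000, "linear", None, 5, 0.9, 1, "") for i in range(n)]
        c = [CheckVRow(f"c{i}", 5000, 5, 3, 1, "Medium-quality") for i in range(n)]
        return g, c

    def test_full_join(self):
        g, c = self._rows(3)
        assert len(join_detection_rows(g, c, "S1")) == 3

    def test_partial_join_warns_and_excludes(self):
        g, c = self._rows(3)
        with pytest.warns(UserWarning, match="only in detector"):
            records = join_detection_rows(g, c[:2], "S1")
        assert len(records) == 2

    def test_empty_join_is_error(self):
        g, _ = self._rows(2)
        c = [CheckVRow("other", 5000, 5, 3, 1)]
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError, match="zero rows"):
                join_detection_rows(g, c)

    def test_provirus_topology_becomes_provirus_record(self):
        g = [GenomadRow("c1", 9000, "provirus", (1001, 5000), 5, 0.9, 1, "")]
        c = [CheckVRow("c1", 9000, 5, 3, 1, "Medium-quality")]
        rec = join_detection_rows(g, c)[0]
        assert rec.is_provirus
        assert rec.contig_id == "c1|provirus_1001_5000"
        assert rec.parent_contig_id == "c1"
        assert rec.length == 4000

    def test_provirus_flag_without_region_warns_and_stays_plain(self):
        g = [GenomadRow("c1", 9000, "linear", None, 5, 0.9, 1, "")]
        c = [CheckVRow("c1", 9000, 5, 3, 1, "Medium-quality",
                       provirus_flag=True)]
        with pytest.warns(UserWarning, match="without trimmed"):
            rec = join_detection_rows(g, c)[0]
        assert not rec.is_provirus
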