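"""Header prefixing, presets, taxonomy inference, provirus reconciliation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viropost import (
    CONSERVATIVE,
    ConfigError,
    ContigSeq,
    RELAXED,
    ValidationError,
    filter_min_seq_size,
    infer_genome_type,
    load_taxon_map,
    merge_virus_provirus,
    passes_preset,
    prefix_headers,
    reconcile_provirus_rounds,
)


# ---------------------------------------------------------------------------
# prefix_headers / filter_min_seq_size
# ---------------------------------------------------------------------------

class TestPrefixHeaders:
    def test_prefix_applied(self):
        out = prefix_headers([ContigSeq("c1", "ACGT")], "S1", enabled=True)
        assert out[0].contig_id == "S1__c1"

    def test_disabled_is_identity(self):
        out = prefix_headers([ContigSeq("c1", "ACGT")], "S1", enabled=False)
        assert out[0].contig_id == "c1"

    def test_idempotent(self):
        once = prefix_headers([ContigSeq("c1", "ACGT")], "S1")
        twice = prefix_headers(once, "S1")
        assert twice[0].contig_id == "S1__c1"

    def test_resulting_duplicates_are_error(self):
        contigs = [ContigSeq("S1__c1", "ACGT"), ContigSeq("c1", "GGGG")]
        with pytest.raises(ValidationError, match="duplicate"):
            prefix_headers(contigs, "S1")

    def test_bad_sample_id(self):
        with pytest.raises(ValidationError):
            prefix_headers([ContigSeq("c1", "ACGT")], "S__1")


class TestMinSeqSize:
    def test_inclusive_boundary(self):
        contigs = [ContigSeq(f"c{i}", "A" * n)
                   for i, n in enumerate([1000, 2500, 3000])]
        kept = filter_min_seq_size(contigs, 2500)
        assert [c.length for c in kept] == [2500, 3000]

    def test_zero_is_identity(self):
        contigs = [ContigSeq("c1", "ACGT")]
        assert filter_min_seq_size(contigs, 0) == contigs

    def test_empty_input(self):
        assert filter_min_seq_size([], 2500) == []

    def test_negative_min_is_config_error(self):
        with pytest.raises(ConfigError):
            filter_min_seq_size([], -1)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

class TestPresets:
    @pytest.mark.parametrize("score,length,hallmarks,preset,expected", [
        (0.85, 3000, 2, CONSERVATIVE, True),
        (0.75, 3000, 2, CONSERVATIVE, False),
        (0.75, 3000, 2, RELAXED, True),
        (0.80, 2500, 1, CONSERVATIVE, True),   # all three boundaries inclusive
        (0.70, 2500, 0, RELAXED, True),
        (0.69, 3000, 2, RELAXED, False),
        (0.90, 2499, 2, CONSERVATIVE, False),
        (0.90, 3000, 0, CONSERVATIVE, False),
    ])
    def test_threshold_application(self, make_record, score, length,
                                   hallmarks, preset, expected):
        record = make_record(length=length, virus_score=score,
                             n_hallmarks=hallmarks)
        assert passes_preset(record, preset) is expected

    def test_missing_score_is_error(self, make_record):
        record = make_record(virus_score=None)
        with pytest.raises(ValidationError, match="virus_score"):
            passes_preset(record, CONSERVATIVE)

    @settings(max_examples=200, derandomize=True)
    @given(
        score=st.floats(0, 1), length=st.integers(1, 100_000),
        hallmarks=st.integers(0, 20),
        d_score=st.floats(0, 0.2), d_len=st.integers(0, 5000),
        d_hall=st.integers(0, 5),
    )
    def test_monotone_in_all_three_inputs(self, score, length, hallmarks,
                                          d_score, d_len, d_hall):
        """Raising score, length or hallmarks never flips pass -> fail."""
        from viropost import DetectionRecord

        def rec(sc, ln, hm):
            return DetectionRecord("c1", length=ln, virus_score=sc,
                                   n_hallmarks=hm, n_genes=hm)

        base = rec(score, length, hallmarks)
        better = rec(min(1.0, score + d_score), length + d_len,
                     hallmarks + d_hall)
        if passes_preset(base, CONSERVATIVE):
            assert passes_preset(better, CONSERVATIVE)


# ---------------------------------------------------------------------------
# Genome type / host domain
# ---------------------------------------------------------------------------

class TestInferGenomeType:
    def test_caudoviricetes(self):
        lineage = "Viruses;Duplodnaviria;Heunggongvirae;Uroviricota;Caudoviricetes"
        assert infer_genome_type(lineage) == ("dsDNA", "prokaryotic")

    def test_empty_lineage(self):
        assert infer_genome_type("") == ("unknown", "unknown")

    def test_most_specific_rank_wins(self):
        mapping = {"Realm": ("RNA", "unknown"), "Klass": ("dsDNA", "prokaryotic")}
        assert infer_genome_type("Realm;Klass", mapping) == ("dsDNA", "prokaryotic")
        assert infer_genome_type("Klass;Realm", mapping) == ("RNA", "unknown")

    def test_yaml_override(self, tmp_path):
        p = tmp_path / "map.yaml"
        p.write_text("MyTaxon: [ssDNA, eukaryotic]\n"
                     "Other:\n  genome_type: RNA\n  host_domain: unknown\n")
        mapping = load_taxon_map(p)
        assert infer_genome_type("x;MyTaxon", mapping) == ("ssDNA", "eukaryotic")

    def test_malformed_mapping_is_config_error(self, tmp_path):
        p = tmp_path / "map.yaml"
        p.write_text("MyTaxon: [notatype, prokaryotic]\n")
        with pytest.raises(ConfigError):
            load_taxon_map(p)


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def _virus(make_record, cid, **kw):
    return make_record(contig_id=cid, **kw)


def _child(make_record, parent, start, end, **kw):
    return make_record(
        contig_id=f"{parent}|provirus_{start}_{end}", is_provirus=True,
        parent_contig_id=parent, region=(start, end),
        length=end - start + 1, round=2, **kw,
    )


class TestReconcile:
    def test_substitution(self, make_record):
        r1 = [_virus(make_record, "A"),
              _virus(make_record, "B")]
        r2 = [_child(make_record, "B", 100, 5000)]
        out = reconcile_provirus_rounds(r1, r2)
        assert {r.contig_id for r in out} == {"A", "B|provirus_100_5000"}

    def test_empty_round2_is_identity(self, make_record):
        r1 = [_virus(make_record, "A"), _virus(make_record, "B")]
        assert reconcile_provirus_rounds(r1, []) == r1

    def test_two_children_counting(self, make_record):
        r1 = [_virus(make_record, c) for c in "ABC"]
        r2 = [_child(make_record, "B", 100, 2000),
              _child(make_record, "B", 5000, 8000)]
        out = reconcile_provirus_rounds(r1, r2)
        assert len(out) == len(r1) - 1 + 2
        assert not any(r.contig_id == "B" for r in out)

    def test_orphan_child_is_error(self, make_record):
        with pytest.raises(ValidationError, match="orphan"):
            reconcile_provirus_rounds(
                [_virus(make_record, "A")],
                [_child(make_record, "Z", 1, 100)],
            )

    def test_overlapping_children_warn_but_kept(self, make_record):
        r1 = [_virus(make_record, "B")]
        r2 = [_child(make_record, "B", 100, 2000),
              _child(make_record, "B", 1500, 4000)]
        with pytest.warns(UserWarning, match="overlapping"):
            out = reconcile_provirus_rounds(r1, r2)
        assert len(out) == 2

    def test_rescored_round1_provirus_is_replaced(self, make_record):
        """A round-1 record already carrying a provirus id is matched by
        its parent and substituted."""
        r1 = [make_record(contig_id="P|provirus_801_4300", is_provirus=True,
                          parent_contig_id="P", region=(801, 4300),
                          length=3500)]
        r2 = [_child(make_record, "P", 801, 4300, virus_score=0.95)]
        out = reconcile_provirus_rounds(r1, r2)
        assert len(out) == 1
        assert out[0].virus_score == 0.95
        assert out[0].round == 2

    def test_non_provirus_records_pass_through_untouched(self, make_record):
        rng = np.random.default_rng(11)
        r1 = [_virus(make_record, f"V{i}", virus_score=float(rng.uniform(0.7, 1)))
              for i in range(20)]
        parents = [_virus(make_record, f"P{i}") for i in range(3)]
        r2 = [_child(make_record, f"P{i}", 10, 2000) for i in range(3)]
        out = reconcile_provirus_rounds(r1 + parents, r2)
        assert [r for r in out if r.contig_id.startswith("V")] == r1


# ---------------------------------------------------------------------------
# Merge of records with sequences
# ---------------------------------------------------------------------------

class TestMergeVirusProvirus:
    def test_one_based_inclusive_slice(self, make_record):
        contigs = {"P": ContigSeq("P", "AAAACGTTTT")}
        rec = make_record(contig_id="P|provirus_5_7", is_provirus=True,
                          parent_contig_id="P", region=(5, 7), length=3)
        _, seqs = merge_virus_provirus([rec], contigs)
        assert seqs[0].sequence == "CGT"

    def test_cardinality_and_id_set_equality(self, make_record):
        contigs = {f"v{i}": ContigSeq(f"v{i}", "ACGT" * 100) for i in range(3)}
        contigs["P"] = ContigSeq("P", "ACGT" * 1000)
        records = [make_record(contig_id=f"v{i}", length=400) for i in range(3)]
        records += [
            make_record(contig_id=f"P|provirus_{s}_{e}", is_provirus=True,
                        parent_contig_id="P", region=(s, e), length=e - s + 1)
            for s, e in [(1, 1000), (2001, 3000)]
        ]
        recs, seqs = merge_virus_provirus(records, contigs)
        assert len(recs) == len(seqs) == 5
        assert [r.contig_id for r in recs] == [c.contig_id for c in seqs]

    def test_sorted_by_sample_then_id(self, make_record):
        contigs = {c: ContigSeq(c, "ACGT") for c in ("b", "a")}
        records = [make_record(contig_id="b", sample_id="S2", length=4),
                   make_record(contig_id="a", sample_id="S1", length=4)]
        recs, _ = merge_virus_provirus(records, contigs)
        assert [r.contig_id for r in recs] == ["a", "b"]

    def test_missing_sequence_is_error(self, make_record):
        with pytest.raises(ValidationError, match="missing"):
            merge_virus_provirus([make_record(contig_id="ghost")], {})

    def test_region_beyond_parent_is_error(self, make_record):
        contigs = {"P": ContigSeq("P", "ACGT")}
        rec = make_record(contig_id="P|provirus_2_9", is_provirus=True,
                          parent_contig_id="P", region=(2, 9), length=8)
        with pytest.raises(ValidationError, match="exceeds"):
            merge_virus_provirus([rec], contigs)
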