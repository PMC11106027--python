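"""Variant ingest: parsing, AC filtering, merging, mapping, refinement."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyxpop.scan import ProteinSequence
from polyxpop.variants import (
    VariantRecord,
    VariantSet,
    filter_by_ac,
    map_to_uniprot,
    merge_variant_sets,
    parse_variant_table,
    parse_vep_vcf,
    read_id_mapping,
    refine_duplication,
    refine_duplications,
    write_variant_table,
)


def rec(pid="ENSP01", ref="Q", pos=10, vtype="missense", alt="R", ins=None,
        span=1, ac=100):
    return VariantRecord(pid, ref, pos, vtype, alt_aa=alt if vtype == "missense" else None,
                         inserted_seq=ins, span=span, allele_count=ac)


class TestRecordInvariants:
    def test_synonymous_rejected(self):
        with pytest.raises(ValueError, match="synonymous"):
            rec(ref="Q", alt="Q")

    def test_zero_allele_count_rejected(self):
        with pytest.raises(ValueError):
            rec(ac=0)

    def test_insertion_needs_sequence(self):
        with pytest.raises(ValueError):
            VariantRecord("ENSP01", "Q", 5, "insertion")

    def test_interval_by_type(self):
        assert rec(vtype="missense").interval == (10, 10)
        assert rec(vtype="deletion", alt=None, span=3).interval == (10, 12)
        assert rec(vtype="insertion", alt=None, ins="QP").interval == (10, 10)


class TestParseTable:
    HEADER = "ensembl_protein_id\tref_aa\tposition\tvtype\talt_aa\tinserted_seq\tspan\tallele_count\n"

    def test_round_trip(self, tmp_path):
        records = [
            rec(pos=3), rec(pos=7, vtype="deletion", alt=None, span=2),
            rec(pos=9, vtype="insertion", alt=None, ins="QQ"),
        ]
        path = tmp_path / "v.tsv"
        write_variant_table(VariantSet(records), path)
        back = parse_variant_table(path)
        assert [r.key for r in back.records] == [r.key for r in records]
        assert [r.allele_count for r in back.records] == [100, 100, 100]

    def test_synonymous_row_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "v.tsv"
        path.write_text(self.HEADER + "ENSP01\tQ\t10\tmissense\tQ\t.\t1\t50\n"
                        "ENSP01\tQ\t11\tmissense\tR\t.\t1\t50\n")
        vs = parse_variant_table(path)
        assert len(vs) == 1 and vs.records[0].alt_aa == "R"

    def test_missing_column_aborts(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("ensembl_protein_id\tref_aa\n" "ENSP01\tQ\n")
        with pytest.raises(ValueError, match="missing column"):
            parse_variant_table(path)

    def test_too_many_bad_rows_abort(self, tmp_path):
        path = tmp_path / "v.tsv"
        rows = ["ENSP01\tQ\t10\tmissense\tR\t.\t1\t0\n"] * 5  # AC=0 invalid
        path.write_text(self.HEADER + "".join(rows))
        with pytest.raises(ValueError, match="malformed"):
            parse_variant_table(path)


class TestFilterAndMerge:
    def test_threshold_boundary(self):
        vs = VariantSet([rec(pos=1, ac=99), rec(pos=2, ac=100)])
        kept = filter_by_ac(vs, 100)
        assert [r.position for r in kept.records] == [2]
        assert kept.ac_threshold == 100

    def test_min_ac_one_is_identity(self):
        vs = VariantSet([rec(pos=1, ac=1)])
        assert len(filter_by_ac(vs, 1)) == 1

    def test_pooling_sums_allele_counts_before_threshold(self):
        exome = VariantSet([rec(pos=5, ac=6)], source_label="exome")
        genome = VariantSet([rec(pos=5, ac=5)], source_label="genome")
        merged = merge_variant_sets(exome, genome, min_ac=10)
        assert len(merged) == 1
        assert merged.records[0].allele_count == 11
        assert merged.source_label == "merged"

    def test_single_source_below_threshold_removed(self):
        exome = VariantSet([rec(pos=5, ac=9)])
        merged = merge_variant_sets(exome, VariantSet([]), min_ac=10)
        assert len(merged) == 0

    def test_union_mode_requires_individual_pass(self):
        exome = VariantSet([rec(pos=5, ac=6)])
        genome = VariantSet([rec(pos=5, ac=5)])
        assert len(merge_variant_sets(exome, genome, min_ac=10, mode="union")) == 0

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=200), max_size=20),
           st.integers(min_value=1, max_value=100), st.integers(min_value=1, max_value=100))
    def test_filter_composition(self, acs, a, b):
        vs = VariantSet([rec(pos=i + 1, ac=ac) for i, ac in enumerate(acs)])
        twice = filter_by_ac(filter_by_ac(vs, a), b)
        once = filter_by_ac(vs, max(a, b))
        assert [r.key for r in twice.records] == [r.key for r in once.records]

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 30), st.integers(1, 50)), max_size=15),
           st.lists(st.tuples(st.integers(1, 30), st.integers(1, 50)), max_size=15))
    def test_merge_commutes_and_conserves_pooled_ac(self, a, b):
        sa = VariantSet([rec(pos=p, ac=ac) for p, ac in dict(a).items()])
        sb = VariantSet([rec(pos=p, ac=ac) for p, ac in dict(b).items()])
        ab = merge_variant_sets(sa, sb, min_ac=1)
        ba = merge_variant_sets(sb, sa, min_ac=1)
        assert {r.key: r.allele_count for r in ab} == {r.key: r.allele_count for r in ba}
        total = sum(r.allele_count for r in sa) + sum(r.allele_count for r in sb)
        assert sum(r.allele_count for r in ab) == total


class TestMapping:
    PROTEOME = [ProteinSequence("P1", "MAAAQQQQLE")]

    def test_agreeing_record_gains_accession(self):
        vs = VariantSet([rec(pid="ENSP01", ref="Q", pos=5)])
        mapped, report = map_to_uniprot(vs, {"ENSP01": "P1"}, self.PROTEOME)
        assert mapped.records[0].uniprot_acc == "P1"
        assert report.n_kept == 1

    def test_reference_mismatch_dropped_and_counted(self):
        vs = VariantSet([rec(pid="ENSP01", ref="Q", pos=2)])  # proteome has A
        mapped, report = map_to_uniprot(vs, {"ENSP01": "P1"}, self.PROTEOME)
        assert len(mapped) == 0 and report.n_mismatch == 1

    def test_unmapped_id_dropped_and_counted(self):
        vs = VariantSet([rec(pid="ENSP99")])
        mapped, report = map_to_uniprot(vs, {"ENSP01": "P1"}, self.PROTEOME)
        assert len(mapped) == 0 and report.n_unmapped == 1

    def test_all_retained_records_agree_with_proteome(self, small_synthetic):
        from polyxpop.simulate import id_mapping_for
        _, proteome, _, vs, _ = small_synthetic
        index = {p.protein_id: p for p in proteome}
        mapped, _ = map_to_uniprot(vs, id_mapping_for(proteome), proteome)
        for r in mapped.records:
            if r.ref_aa != "-":
                assert index[r.uniprot_acc].residue(r.position) == r.ref_aa

    def test_read_id_mapping(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("ensembl_protein_id\tuniprot_acc\nENSP01\tP1\nENSP01\tP2\n")
        assert read_id_mapping(path) == {"ENSP01": "P1"}  # first mapping retained


class TestDuplicationRefinement:
    PROTEIN = ProteinSequence("P1", "MAAQQQQLEV")  # polyQ at 4-7

    def ins(self, pos, seq):
        return VariantRecord("P1", "Q", pos, "insertion", inserted_seq=seq, allele_count=5)

    def test_single_q_inside_run_becomes_duplication(self):
        out = refine_duplication(self.ins(7, "Q"), self.PROTEIN)
        assert out.vtype == "duplication"

    def test_non_matching_insertion_unchanged(self):
        assert refine_duplication(self.ins(7, "P"), self.PROTEIN).vtype == "insertion"

    @pytest.mark.parametrize(
        "pos,seq,expected",
        [
            (7, "QQ", "duplication"),   # preceding "QQ" matches
            (4, "QQ", "insertion"),     # preceding 2-mer is "AQ"
            (7, "QQQQ", "duplication"), # whole tract copied
            (7, "QQQQQ", "insertion"),  # would need 5 preceding, run has 4 + A
            (1, "MM", "insertion"),     # window extends before residue 1
            (1, "M", "duplication"),    # single-residue copy at the terminus
            (3, "MA", "insertion"),     # preceding 2-mer is "AA"
            (3, "AA", "duplication"),   # non-repeat duplication also detected
        ],
    )
    def test_rule_enumeration(self, pos, seq, expected):
        assert refine_duplication(self.ins(pos, seq), self.PROTEIN).vtype == expected

    def test_refine_all_leaves_non_insertions_alone(self):
        vs = VariantSet([self.ins(7, "Q"), rec(pid="P1", ref="Q", pos=5)])
        out = refine_duplications(vs, [self.PROTEIN])
        assert [r.vtype for r in out.records] == ["duplication", "missense"]


class TestVcfAdapter:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">\n'
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        'Format: Allele|Consequence|ENSP|Protein_position|Amino_acids|ALLELE_NUM">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\t.\tA\tG\t.\t.\tAC=120;CSQ=G|missense_variant|ENSP01|10|Q/R|1\n"
        "1\t200\t.\tC\tT\t.\t.\tAC=50;CSQ=T|synonymous_variant|ENSP01|20|L|1\n"
        "1\t300\t.\tG\tA,C\t.\t.\tAC=30,40;CSQ="
        "A|missense_variant|ENSP01|30|Q/H|1,C|stop_gained|ENSP01|30|Q/*|2\n"
        "1\t400\t.\tG\tGAA\t.\t.\tAC=15;CSQ=GAA|inframe_insertion|ENSP02|5-6|Q/QQQ|1\n"
    )

    def test_consequence_mapping_and_per_allele_records(self, tmp_path):
        path = tmp_path / "mini.vcf"
        path.write_text(self.VCF)
        vs = parse_vep_vcf(path)
        by_type = {}
        for r in vs.records:
            by_type.setdefault(r.vtype, []).append(r)
        assert len(by_type["missense"]) == 2  # synonymous dropped
        assert {r.allele_count for r in by_type["missense"]} == {120, 30}
        assert by_type["stop"][0].allele_count == 40  # second allele's AC
        assert by_type["insertion"][0].inserted_seq == "QQ"  # anchored ref stripped
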