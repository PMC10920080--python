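"""Unit and property tests for variant ingestion, filtering and keys."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivermosaic.variants import (
    SampleRecord,
    Variant,
    detect_kras_hotspot,
    filter_by_af,
    identity_key,
    load_sample_sheet,
    normalize_alleles,
    read_ddpcr_table,
    read_variants,
    subtract_denylist,
    subtract_matched_normal,
    write_variants_tsv,
)


def make_variant(pos=100, ref="C", alt="A", af=0.5, **kw):
    return Variant(chrom="chr1", pos=pos, ref=ref, alt=alt, af=af, **kw)


class TestVariantInvariants:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            make_variant(ref="C", alt="C")

    def test_af_out_of_range(self):
        with pytest.raises(ValueError):
            make_variant(af=1.5)

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            make_variant(pos=0)

    def test_lowercase_alleles_rejected(self):
        with pytest.raises(ValueError):
            make_variant(ref="c")


class TestNormalization:
    def test_shared_suffix_trimmed(self):
        assert normalize_alleles(100, "CAG", "CG") == (100, "CA", "C")

    def test_shared_prefix_trimmed_and_pos_advanced(self):
        assert normalize_alleles(100, "CAT", "CGT") == (101, "A", "G")

    def test_anchor_base_kept(self):
        # deletion keeps its anchor base
        assert normalize_alleles(100, "CAA", "C") == (100, "CAA", "C")

    def test_snv_untouched(self):
        assert normalize_alleles(7, "G", "T") == (7, "G", "T")


class TestTSVReading:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\taf\n"
            "S1\tchr12\t25398284\tC\tA\t0.31\n"
        )
        records = read_variants(path, "tsv")
        assert len(records) == 1
        (record,) = records
        assert record.sample_id == "S1"
        (v,) = record.variants
        assert (v.chrom, v.pos, v.ref, v.alt, v.af) == ("chr12", 25398284, "C", "A", 0.31)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(
            "sample_id\tchrom\tpos\tref\talt\taf\n"
            "S1\tchr1\t100\tC\tA\t0.5\n"
            "S1\tchr1\tnot_a_pos\tC\tA\t0.5\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            read_variants(path, "tsv")

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text("sample_id\tchrom\tpos\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_variants(path, "tsv")

    def test_round_trip(self, tmp_path):
        rng = random.Random(5)
        records = []
        for s in range(3):
            variants = {
                Variant(
                    chrom=f"chr{rng.randint(1, 3)}",
                    pos=rng.randint(1, 10_000),
                    ref=rng.choice("AC"),
                    alt=rng.choice("GT"),
                    af=round(rng.random(), 4),
                )
                for _ in range(10)
            }
            records.append(SampleRecord(f"S{s}", None, None, variants))
        path = tmp_path / "rt.tsv"
        write_variants_tsv(records, path)
        reread = read_variants(path, "tsv")
        original = {r.sample_id: r.variants for r in records}
        for record in reread:
            got = {identity_key(v) for v in record.variants}
            want = {identity_key(v) for v in original[record.sample_id]}
            assert got == want
            assert record.variants == original[record.sample_id]


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr12>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


class TestVCFReading:
    def _write(self, tmp_path, body, samples="S1"):
        path = tmp_path / "calls.vcf"
        path.write_text(VCF_HEADER.format(samples=samples) + body)
        return path

    def test_multiallelic_split(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr12\t100\t.\tC\tA,T\t50\tPASS\t.\tGT:AF\t1/2:0.3,0.2\n",
        )
        (record,) = read_variants(path, "vcf")
        alts = sorted((v.alt, v.af) for v in record.variants)
        assert alts == [("A", pytest.approx(0.3)), ("T", pytest.approx(0.2))]
        assert all(v.ref == "C" and v.pos == 100 for v in record.variants)

    def test_af_from_allelic_depths(self, tmp_path):
        path = self._write(
            tmp_path, "chr12\t200\t.\tG\tA\t50\tPASS\t.\tGT:AD\t0/1:70,30\n"
        )
        (record,) = read_variants(path, "vcf")
        (v,) = record.variants
        assert v.af == pytest.approx(0.30)

    def test_missing_af_and_depths_errors(self, tmp_path):
        path = self._write(tmp_path, "chr12\t200\t.\tG\tA\t50\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="AF"):
            read_variants(path, "vcf")

    def test_multi_sample_genotype_assignment(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr12\t300\t.\tT\tG\t50\tPASS\t.\tGT:AF\t0/1:0.4\t0/0:0.0\n",
            samples="S1\tS2",
        )
        records = {r.sample_id: r.variants for r in read_variants(path, "vcf")}
        assert len(records.get("S1", ())) == 1
        assert len(records.get("S2", ())) == 0


class TestAFFilter:
    def test_threshold_inclusive(self):
        v = make_variant(af=0.20)
        assert filter_by_af({v}, 0.2) == {v}

    def test_below_threshold_removed(self):
        assert filter_by_af({make_variant(af=0.19)}, 0.2) == set()

    def test_empty_input(self):
        assert filter_by_af(set(), 0.2) == set()

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_by_af(set(), 0.0)

    @given(
        afs=st.lists(st.floats(min_value=0, max_value=1), max_size=30),
        t1=st.floats(min_value=0.01, max_value=1),
        t2=st.floats(min_value=0.01, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_monotone(self, afs, t1, t2):
        variants = {make_variant(pos=i + 1, af=af) for i, af in enumerate(afs)}
        once = filter_by_af(variants, t1)
        assert filter_by_af(once, t1) == once
        lo, hi = sorted([t1, t2])
        assert filter_by_af(variants, hi) <= filter_by_af(variants, lo)


class TestNormalSubtraction:
    def _records(self, tumour_afs, normal_positions):
        tumour = SampleRecord(
            "T1", "P1", "primary_tumour",
            {make_variant(pos=p, af=af) for p, af in tumour_afs},
        )
        normal = SampleRecord(
            "N1", "P1", "normal",
            {make_variant(pos=p, af=0.5) for p in normal_positions},
        )
        return tumour, normal

    def test_shared_variant_removed(self):
        tumour, normal = self._records([(100, 0.5), (200, 0.4)], [100])
        result = subtract_matched_normal(tumour, normal)
        assert {v.pos for v in result.variants} == {200}

    def test_empty_normal_keeps_tumour(self):
        tumour, normal = self._records([(100, 0.5)], [])
        assert subtract_matched_normal(tumour, normal).variants == tumour.variants

    def test_tumour_subset_of_normal_empties(self):
        tumour, normal = self._records([(100, 0.5)], [100, 200])
        assert subtract_matched_normal(tumour, normal).variants == set()

    def test_patient_mismatch_errors(self):
        tumour, _ = self._records([(100, 0.5)], [])
        normal = SampleRecord("N2", "P2", "normal", set())
        with pytest.raises(ValueError, match="patient"):
            subtract_matched_normal(tumour, normal)

    @given(
        tumour_data=st.sets(
            st.tuples(st.integers(1, 50), st.floats(0.01, 1.0)), max_size=20
        ),
        normal_positions=st.sets(st.integers(1, 50), max_size=20),
        threshold=st.floats(0.05, 0.95),
    )
    @settings(max_examples=100, deadline=None)
    def test_filter_subtract_commutes(self, tumour_data, normal_positions, threshold):
        by_pos = {}
        for p, af in tumour_data:
            by_pos.setdefault(p, af)
        tumour, normal = self._records(list(by_pos.items()), normal_positions)

        a = subtract_matched_normal(
            SampleRecord("T1", "P1", "primary_tumour",
                         filter_by_af(tumour.variants, threshold)),
            normal,
        ).variants
        b = filter_by_af(subtract_matched_normal(tumour, normal).variants, threshold)
        assert {identity_key(v) for v in a} == {identity_key(v) for v in b}


class TestDenylist:
    def test_seeded_polymorphism_removed(self):
        p72r = make_variant(pos=7570215, af=0.5, gene="TP53",
                            consequence="missense", protein_change="P72R")
        other = make_variant(pos=7570500, af=0.5, gene="TP53",
                             consequence="missense", protein_change="R175H")
        record = SampleRecord("T1", "P1", "primary_tumour", {p72r, other})
        result = subtract_denylist(record)
        assert result.variants == {other}


class TestIdentityKey:
    def test_same_substitution_equal_keys(self):
        a = make_variant(af=0.3)
        b = make_variant(af=0.6)
        assert identity_key(a) == identity_key(b)

    def test_protein_mode_collapses_same_effect(self):
        # two nucleotide events, same synonymous protein effect
        a = make_variant(pos=349, ref="C", alt="T", gene="CDKN2A",
                         consequence="synonymous", protein_change="L117L")
        b = make_variant(pos=351, ref="G", alt="A", gene="CDKN2A",
                         consequence="synonymous", protein_change="L117L")
        assert identity_key(a) != identity_key(b)
        assert identity_key(a, "protein") == identity_key(b, "protein")

    def test_different_positions_unequal(self):
        assert identity_key(make_variant(pos=5)) != identity_key(make_variant(pos=6))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            identity_key(make_variant(), "nonsense_mode")


class TestKrasHotspots:
    def _kras(self, change, consequence="missense"):
        return make_variant(
            pos=hash(change) % 1000 + 1, gene="KRAS",
            consequence=consequence, protein_change=change,
        )

    def test_g12v_is_hotspot(self):
        calls = detect_kras_hotspot([self._kras("G12V")])
        assert [c.mutation_label for c in calls] == ["G12V"]
        assert calls[0].assay == "sequencing"

    def test_t20m_not_hotspot(self):
        assert detect_kras_hotspot([self._kras("T20M")]) == []

    def test_synonymous_codon12_not_hotspot(self):
        assert detect_kras_hotspot([self._kras("G12G", "synonymous")]) == []

    def test_q61_collapses_to_q61x(self):
        calls = detect_kras_hotspot([self._kras("Q61H")])
        assert [c.mutation_label for c in calls] == ["Q61x"]

    def test_non_panel_codon12_label(self):
        calls = detect_kras_hotspot([self._kras("G13S")])
        assert [c.mutation_label for c in calls] == ["other_codon12_13"]

    def test_non_kras_ignored(self):
        v = make_variant(gene="TP53", consequence="missense", protein_change="G12V")
        assert detect_kras_hotspot([v]) == []


class TestAuxTables:
    def test_sample_sheet_abbreviations(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        path.write_text(
            "sample_id\tpatient_id\ttissue_class\tage\n"
            "S1\tP1\tPT\t45\n"
            "S2\tP1\tAWM\t45\n"
        )
        sheet = load_sample_sheet(path)
        assert sheet["S1"]["tissue_class"] == "primary_tumour"
        assert sheet["S2"]["tissue_class"] == "abdominal_wall_met"

    def test_sample_sheet_rejects_unknown_class(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        path.write_text("sample_id\tpatient_id\ttissue_class\nS1\tP1\tbogus\n")
        with pytest.raises(ValueError, match="bogus"):
            load_sample_sheet(path)

    def test_ddpcr_result_vocabulary(self, tmp_path):
        path = tmp_path / "dd.tsv"
        path.write_text(
            "patient_id\tsample_id\tmutation_label\tresult\nP1\tS1\tG12D\tmaybe\n"
        )
        with pytest.raises(ValueError, match="positive/negative"):
            read_ddpcr_table(path)
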