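import pytest

from wexscape.core import (
    ChromosomeModel,
    CohortDataset,
    ContextUnavailable,
    GenomeModel,
    MutationRecord,
    RowParseError,
    SchemaError,
    SegmentRecord,
    ValidationError,
    VariantClass,
    VariantType,
    classify_variant_type,
    parse_variant_class,
    revcomp,
    trinucleotide_context,
)
from wexscape.io import (
    read_cohort,
    read_mutation_table,
    read_sample_sheet,
    read_segment_table,
    write_cohort,
)

from .conftest import make_meta


def _mut(**kw):
    base = dict(sample_id="S1", chrom="chr1", pos=100, ref="C", alt="T",
                gene="TP53", variant_class=VariantClass.MISSENSE,
                variant_type=VariantType.SNV, alt_count=10, ref_count=90)
    base.update(kw)
    return MutationRecord(**base)


class TestMutationRecord:
    def test_vaf(self):
        assert _mut().vaf == pytest.approx(0.1)

    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "T", VariantType.SNV),
        ("CT", "C", VariantType.INDEL),
        ("C", "CAT", VariantType.INDEL),
    ])
    def test_variant_type_from_allele_lengths(self, ref, alt, expected):
        assert classify_variant_type(ref, alt) is expected

    def test_type_allele_consistency_enforced(self):
        with pytest.raises(ValidationError):
            _mut(ref="CT", alt="C", variant_type=VariantType.SNV)

    def test_context_middle_base_must_match_ref(self):
        with pytest.raises(ValidationError):
            _mut(context3="ATA")
        assert _mut(context3="ACA").context3 == "ACA"

    @pytest.mark.parametrize("kw", [
        {"pos": 0}, {"alt_count": -1}, {"ref_count": -2},
    ])
    def test_invariants(self, kw):
        with pytest.raises(ValidationError):
            _mut(**kw)


class TestSegmentRecord:
    def test_major_minor(self):
        s = SegmentRecord("S1", "chr1", 1, 10, 3, 1)
        assert s.cn_major == 2 and s.length == 10

    @pytest.mark.parametrize("kw", [
        {"start": 10, "end": 1}, {"cn_total": 2, "cn_minor": 3}, {"cn_minor": -1},
    ])
    def test_invariants(self, kw):
        base = dict(sample_id="S1", chrom="chr1", start=1, end=10, cn_total=2, cn_minor=1)
        base.update(kw)
        with pytest.raises(ValidationError):
            SegmentRecord(**base)


class TestVariantClassMapping:
    @pytest.mark.parametrize("label,expected", [
        ("Missense_Mutation", VariantClass.MISSENSE),
        ("Nonsense_Mutation", VariantClass.NONSENSE),
        ("Silent", VariantClass.SILENT),
        ("Frame_Shift_Del", VariantClass.FRAMESHIFT_INDEL),
        ("weird_unknown", VariantClass.OTHER),
    ])
    def test_synonyms(self, label, expected):
        assert parse_variant_class(label) is expected


class TestGenomeModel:
    def test_centromere_must_sit_inside(self):
        with pytest.raises(ValidationError):
            ChromosomeModel("chrZ", 100, 150, 200)

    def test_arm_boundaries(self, toy_genome):
        c = toy_genome["chr1"]
        assert c.p_arm == (1, 50_000_000)
        assert c.q_arm == (53_000_001, 100_000_000)

    def test_unknown_chromosome(self, toy_genome):
        with pytest.raises(ValidationError):
            toy_genome["chr99"]

    def test_bundled_model_loads(self, genome):
        assert "chr17" in genome
        assert genome["chr1"].length == 249_250_621


class TestTrinucleotideContext:
    def test_forward_strand(self):
        assert trinucleotide_context("c", 3, {"c": "ACGTA"}) == "CGT"

    def test_case_folding(self):
        assert trinucleotide_context("c", 3, {"c": "acgta"}) == "CGT"

    @pytest.mark.parametrize("pos", [1, 5])
    def test_edges_unavailable(self, pos):
        with pytest.raises(ContextUnavailable):
            trinucleotide_context("c", pos, {"c": "ACGTA"})

    def test_revcomp(self):
        assert revcomp("TGT") == "ACA"


class TestReaders:
    def _write(self, tmp_path, name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_mutation_table_derives_variant_type(self, tmp_path):
        p = self._write(tmp_path, "m.tsv",
            "sample_id\tchrom\tpos\tref\talt\tgene\tvariant_class\talt_count\tref_count\n"
            "S1\tchr1\t100\tC\tT\tTP53\tmissense\t10\t90\n"
            "S1\tchr1\t200\tCT\tC\tPTEN\tframeshift_indel\t5\t95\n")
        recs = read_mutation_table(p)
        assert [r.variant_type for r in recs] == [VariantType.SNV, VariantType.INDEL]

    def test_missing_column_is_schema_error(self, tmp_path):
        p = self._write(tmp_path, "m.tsv",
            "sample_id\tchrom\tpos\tref\talt\tvariant_class\talt_count\tref_count\n"
            "S1\tchr1\t100\tC\tT\tmissense\t10\t90\n")
        with pytest.raises(SchemaError, match="gene"):
            read_mutation_table(p)

    def test_column_mapping(self, tmp_path):
        p = self._write(tmp_path, "m.tsv",
            "sample_id\tchrom\tpos\tref\talt\tHugo_Symbol\tvariant_class\talt_count\tref_count\n"
            "S1\tchr1\t100\tC\tT\tTP53\tmissense\t10\t90\n")
        recs = read_mutation_table(p, columns={"gene": "Hugo_Symbol"})
        assert recs[0].gene == "TP53"

    def test_non_integer_count_names_line(self, tmp_path):
        p = self._write(tmp_path, "m.tsv",
            "sample_id\tchrom\tpos\tref\talt\tgene\tvariant_class\talt_count\tref_count\n"
            "S1\tchr1\t100\tC\tT\tTP53\tmissense\tten\t90\n")
        with pytest.raises(RowParseError, match="line 2"):
            read_mutation_table(p)

    def test_segments_abutting_ok_overlap_rejected(self, tmp_path):
        header = "sample_id\tchrom\tstart\tend\tcn_total\tcn_minor\n"
        ok = self._write(tmp_path, "ok.tsv",
                         header + "S1\tchr1\t1\t10\t2\t1\nS1\tchr1\t11\t20\t3\t1\n")
        assert len(read_segment_table(ok)) == 2
        bad = self._write(tmp_path, "bad.tsv",
                          header + "S1\tchr1\t1\t10\t2\t1\nS1\tchr1\t5\t20\t3\t1\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_segment_table(bad)

    def test_cn_minor_above_total_rejected(self, tmp_path):
        p = self._write(tmp_path, "s.tsv",
            "sample_id\tchrom\tstart\tend\tcn_total\tcn_minor\nS1\tchr1\t1\t10\t1\t2\n")
        with pytest.raises(RowParseError):
            read_segment_table(p)

    def test_sample_sheet_controlled_vocabulary(self, tmp_path):
        header = "sample_id\tgroup\tsubtype\tage\tpurity\tploidy\tpanel_size_mb\n"
        good = self._write(tmp_path, "good.tsv", header + "S1\tIBC\tTN\t50\t0.7\t2.0\t50\n")
        assert read_sample_sheet(good)[0].purity == 0.7
        bad = self._write(tmp_path, "bad.tsv", header + "S1\tIBC\tLuminalZ\t50\t0.7\t2.0\t50\n")
        with pytest.raises(ValidationError, match="TN"):
            read_sample_sheet(bad)

    def test_sample_sheet_rejects_zero_purity_and_duplicates(self, tmp_path):
        header = "sample_id\tgroup\tsubtype\tage\tpurity\tploidy\tpanel_size_mb\n"
        zero = self._write(tmp_path, "zero.tsv", header + "S1\tIBC\tTN\t50\t0\t2.0\t50\n")
        with pytest.raises(ValidationError):
            read_sample_sheet(zero)
        dup = self._write(tmp_path, "dup.tsv",
                          header + "S1\tIBC\tTN\t50\t0.7\t2.0\t50\nS1\tnonIBC\tTN\t60\t0.6\t2.0\t50\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_sample_sheet(dup)


class TestCohortDataset:
    def test_unknown_sample_rejected(self):
        with pytest.raises(ValidationError):
            CohortDataset(mutations=[_mut(sample_id="ghost")], segments=[],
                          samples=[make_meta()])

    def test_round_trip(self, tmp_path, small_cohort):
        dataset, _ = small_cohort
        paths = [tmp_path / n for n in ("m.tsv", "s.tsv", "p.tsv")]
        write_cohort(dataset, *paths)
        back = read_cohort(*paths)
        assert back.mutations == dataset.mutations
        assert back.segments == sorted(
            dataset.segments, key=lambda s: (s.sample_id, s.chrom, s.start))
        assert back.samples == dataset.samples
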