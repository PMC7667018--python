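"""Annotation table model, parsing, spacer arithmetic and validation."""

import pytest
from hypothesis import given, strategies as st

from mitocomp.annotation import (
    AnnotationError, GeneFeature, MitoAnnotation, extract_feature_seq,
    feature_length, intergenic_spacers, parse_feature_table, to_bed,
    validate_annotation, write_feature_table,
)
from mitocomp.genes import UnknownGeneError, gene_class, normalize_gene_name


TOY_TSV = (
    "gene\tdirection\tstart\tend\tsize\tintergenic\n"
    "cox1\tF\t1\t90\t90\t10\n"
    "trnV\tR\t101\t170\t70\t0\n"
    "CR\t-\t171\t200\t30\t\n"
)


class TestParsing:
    def test_published_fixture_reconstruction(self, pbidens_table):
        assert len(pbidens_table.features) == 38
        assert pbidens_table.class_counts() == {"PCG": 13, "tRNA": 22,
                                         "rRNA": 2, "CR": 1}
        assert pbidens_table.genome_length == 15641
        assert pbidens_table.get("CR").strand is None

    def test_header_only_is_an_error(self):
        with pytest.raises(AnnotationError, match="empty"):
            parse_feature_table("gene\tdirection\tstart\tend\n")

    @pytest.mark.parametrize("text", ["", "\n\n"])
    def test_blank_input_is_an_error(self, text):
        with pytest.raises(AnnotationError):
            parse_feature_table(text)

    def test_round_trip_is_identity_on_toy_table(self):
        a = parse_feature_table(TOY_TSV)
        b = parse_feature_table(write_feature_table(a))
        assert a.features == b.features
        assert a.genome_length == b.genome_length

    def test_round_trip_is_identity_on_published_fixture(self, pbidens_table):
        again = parse_feature_table(write_feature_table(pbidens_table),
                                    source_id=pbidens_table.source_id)
        assert again.features == pbidens_table.features
        assert again.genome_length == pbidens_table.genome_length

    def test_dash_variants_and_thousands_separators(self):
        text = ("gene\tdirection\tlocation\tsize\tintergenic\n"
                "cob\tF\t9015–10,149\t1135\t0\n"
                "trnS2\tF\t10,150—10,217\t68\t−15\n"
                "CR\t—\t10300-10400\t\t–\n")
        a = parse_feature_table(text)
        assert a.get("cob").end == 10149
        assert a.get("trnS2").declared_spacer == -15
        assert a.get("CR").declared_spacer is None

    def test_unknown_gene_label_rejected_unless_flagged(self):
        text = "gene\tdirection\tstart\tend\nmystery7\tF\t1\t50\n"
        with pytest.raises(UnknownGeneError):
            parse_feature_table(text)
        a = parse_feature_table(text, allow_nonstandard=True)
        assert a.features[0].name == "mystery7"

    def test_duplicate_gene_rejected_unless_flagged(self):
        text = ("gene\tdirection\tstart\tend\n"
                "cox1\tF\t1\t50\ncox1\tF\t60\t100\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            parse_feature_table(text)
        assert len(parse_feature_table(text, allow_nonstandard=True).features) == 2

    def test_unparseable_coordinates(self):
        with pytest.raises(AnnotationError):
            parse_feature_table("gene\tdirection\tlocation\ncox1\tF\tabc-def\n")

    @pytest.mark.parametrize("alias,canonical", [
        ("COI", "cox1"), ("cytb", "cob"), ("ND4L", "nad4L"),
        ("12S", "rrnS"), ("lrRNA", "rrnL"), ("trnL(UUR)", "trnL2"),
        ("tRNS(AGN)", "trnS1"), ("D-loop", "CR"), ("trnm", "trnM"),
    ])
    def test_gene_name_aliases(self, alias, canonical):
        assert normalize_gene_name(alias) == canonical

    def test_ambiguous_leucine_alias_rejected(self):
        with pytest.raises(UnknownGeneError, match="ambiguous"):
            normalize_gene_name("trnL")

    @pytest.mark.parametrize("name,cls", [
        ("cox1", "PCG"), ("cob", "PCG"), ("nad4L", "PCG"), ("atp8", "PCG"),
        ("trnS1", "tRNA"), ("rrnL", "rRNA"), ("CR", "CR"),
    ])
    def test_gene_class_mapping(self, name, cls):
        assert gene_class(name) == cls


class TestLengthsAndSpacers:
    @pytest.mark.parametrize("start,end,length", [
        (12613, 12685, 73),   # trnV as published
        (5, 5, 1),
        (1, 1560, 1560),
    ])
    def test_feature_length_non_wrapping(self, start, end, length):
        f = GeneFeature("trnV", "R", start, end)
        assert feature_length(f) == length

    def test_feature_length_wrapping_counts_through_origin(self):
        f = GeneFeature("trnV", "R", 15640, 3)
        assert feature_length(f, genome_length=15641) == 5
        with pytest.raises(AnnotationError):
            feature_length(f)

    def test_published_sizes_match_except_nad4(self, pbidens_table):
        mismatched = [
            f.name for f in pbidens_table.features
            if f.declared_size is not None
            and feature_length(f, pbidens_table.genome_length) != f.declared_size]
        assert mismatched == ["nad4"]

    def test_published_spacers_match_except_nad5(self, pbidens_table):
        computed = dict(intergenic_spacers(pbidens_table))
        mismatched = [f.name for f in pbidens_table.features
                      if f.declared_spacer is not None
                      and computed[f.name] != f.declared_spacer]
        assert mismatched == ["nad5"]

    @pytest.mark.parametrize("name,expected", [
        ("cox1", -25),    # overlap with trnL2
        ("trnS2", 15),
        ("trnG", 0),      # abutting
        ("trnY", 0),      # wrap back to cox1
    ])
    def test_spacer_examples(self, pbidens_table, name, expected):
        assert dict(intergenic_spacers(pbidens_table))[name] == expected

    def test_spacers_need_two_features(self):
        a = MitoAnnotation((GeneFeature("cox1", "F", 1, 90),))
        with pytest.raises(AnnotationError):
            intergenic_spacers(a)

    @given(st.lists(st.tuples(st.integers(50, 400), st.integers(0, 30)),
                    min_size=2, max_size=12))
    def test_tiling_annotations_close_the_circle(self, blocks):
        """Sum of (length + spacer) over a tiling annotation equals the
        genome length."""
        feats, pos = [], 1
        names = iter(["cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3",
                      "nad4", "nad5", "nad6", "atp6", "atp8"])
        for length, spacer in blocks:
            feats.append(GeneFeature(next(names), "F", pos, pos + length - 1))
            pos += length + spacer
        a = MitoAnnotation(tuple(feats), genome_length=pos - 1)
        total = sum(feature_length(f, a.genome_length) for f in feats) \
            + sum(s for _, s in intergenic_spacers(a))
        assert total == a.genome_length

    @given(st.integers(1, 10_000), st.integers(0, 5_000))
    def test_length_formula_for_random_features(self, start, extent):
        f = GeneFeature("cox1", "F", start, start + extent)
        assert feature_length(f) == extent + 1


class TestValidation:
    def test_published_fixture_flags_only_the_nad4_inconsistency(self, pbidens_table):
        report = validate_annotation(pbidens_table)
        assert [(i.feature, i.code) for i in report.issues] == [
            ("nad4", "SIZE_MISMATCH"), ("nad5", "SPACER_MISMATCH")]
        assert not report.ok

    def test_consistent_toy_annotation_is_clean(self):
        a = parse_feature_table(
            "gene\tdirection\tstart\tend\tsize\tintergenic\n"
            "cox1\tF\t1\t90\t90\t10\n"
            "trnV\tR\t101\t170\t70\t\n")
        assert validate_annotation(a).ok

    def test_same_strand_pcg_overlap_is_a_note_not_an_issue(self, pbidens_table):
        report = validate_annotation(pbidens_table)
        overlap_features = {n.feature for n in report.notes}
        assert "atp8" in overlap_features  # the published 7 bp overlap
        assert all(n.code == "OVERLAP_NOTE" for n in report.notes)
        assert "atp8" not in {i.feature for i in report.issues}

    def test_count_anomaly_for_incomplete_genome_with_cr(self):
        a = parse_feature_table(TOY_TSV)   # has CR, so counts are checked
        codes = {i.code for i in validate_annotation(a).issues}
        assert "COUNT_ANOMALY" in codes

    def test_sequence_length_mismatch_detected(self, pbidens_table):
        report = validate_annotation(pbidens_table, genome_seq="ACGT" * 10)
        assert any(i.code == "COORD_OUT_OF_RANGE" for i in report.issues)


class TestSequenceExtraction:
    @pytest.mark.parametrize("strand,expected", [("F", "ACG"), ("R", "CGT")])
    def test_extraction_is_strand_aware(self, strand, expected):
        f = GeneFeature("cox1", strand, 2, 4)
        assert extract_feature_seq("AACGT", f) == expected

    def test_wrapping_extraction_concatenates_tail_and_head(self):
        f = GeneFeature("cox1", "F", 5, 2)
        assert extract_feature_seq("AACGT", f) == "TAA"

    def test_linear_sequence_rejects_out_of_range(self):
        f = GeneFeature("cox1", "F", 2, 10)
        with pytest.raises(AnnotationError):
            extract_feature_seq("AACGT", f)

    def test_extraction_length_matches_feature_length(self, pbidens_table, sim42):
        for f in pbidens_table.features:
            seq = extract_feature_seq(sim42.sequence, f)
            assert len(seq) == feature_length(f, pbidens_table.genome_length)


def test_bed_export_is_zero_based_half_open(pbidens_table):
    lines = to_bed(pbidens_table).splitlines()
    assert lines[0].split("\t") == ["KY808394", "0", "1560", "cox1", "0", "+"]
    trnv = [l for l in lines if "\ttrnV\t" in l][0]
    assert trnv.split("\t")[1:3] == ["12612", "12685"]
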