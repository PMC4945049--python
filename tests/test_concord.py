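import numpy as np
import pandas as pd
import pytest

from plasmacnv.concord import (CONSISTENT, INCONSISTENT, PARTLY,
                               CytobandTable, TruthEvent, classify,
                               clopper_pearson, overlap_kb, parse_truth,
                               performance, performance_from_counts,
                               read_truth_manifest)
from plasmacnv.fcaps import CnvCall


@pytest.fixture(scope="module")
def bands():
    return CytobandTable.shipped()


def call(sid, chrom, s_kb, e_kb, d):
    return CnvCall(sid, chrom, s_kb * 1000, e_kb * 1000, d, 1.0, 5.0)


def truth(sid, chrom, s_kb, e_kb, d):
    return TruthEvent(sid, chrom, s_kb, e_kb, d)


class TestCytobands:
    def test_exact_band(self, bands):
        assert bands.band_interval("chr5", "p15.2") == (9_800_000, 15_000_000)

    def test_prefix_union(self, bands):
        # p14 spans p14.3 through p14.1
        assert bands.band_interval("chr5", "p14") == (18_400_000, 28_900_000)
        # p15 spans p15.33 through p15.1
        assert bands.band_interval("chr5", "p15") == (0, 18_400_000)

    def test_prefix_does_not_leak_across_levels(self, bands):
        # p11 must not swallow p11.x-less neighbours like p12
        s, e = bands.band_interval("chr18", "p11")
        assert (s, e) == (0, 17_200_000)

    def test_unknown_band_raises(self, bands):
        with pytest.raises(KeyError):
            bands.band_interval("chr5", "p99")


class TestParseTruth:
    def test_array_string_verbatim_kb(self, bands):
        ev, = parse_truth("arr 13q21.2(60,399–61,730)×3", bands, "LMQ155")
        assert (ev.chrom, ev.start_kb, ev.end_kb, ev.direction) \
            == ("chr13", 60_399, 61_730, "gain")
        assert ev.size_mb == pytest.approx(1.331)
        assert ev.source == "array"

    def test_euploid_karyotype_empty(self, bands):
        assert parse_truth("46,XY", bands) == []
        assert parse_truth("46,XX", bands) == []

    def test_single_band_deletion(self, bands):
        ev, = parse_truth("46,XY,del(5)(p14)", bands, "mic0012")
        assert (ev.start_kb, ev.end_kb) == (18_400, 28_900)
        assert ev.size_mb == pytest.approx(10.5)

    # clinical strings with the event size each implies (Mb)
    CLINICAL = [
        ("46,XX,dup(1)(p36)", "chr1", "gain", 28.0),
        ("46,XX,del(4)(q24q26.1)", "chr4", "loss", 24.8),
        ("46,XX,del(5)(p15.33p15.2)", "chr5", "loss", 15.0),
        ("46,XX,del(5)(p13)", "chr5", "loss", 13.6),
        ("46,XX,del(5)(p15p11)", "chr5", "loss", 48.4),
        ("46,XX,del(5)(p15.32p14.3)", "chr5", "loss", 18.8),
        ("46,XY,del(5)(p15)", "chr5", "loss", 18.4),
        ("46,XX,del(9)(q22q32)", "chr9", "loss", 27.3),
        ("46, XX, del(10)(q22.3q23.2)", "chr10", "loss", 11.8),
        ("46,XY,del(11)(q13.3q14.3)", "chr11", "loss", 22.5),
        ("46,XY,del(18) (p11.3p11.2)", "chr18", "loss", 15.4),
        ("46,XX,del(18)(p11)", "chr18", "loss", 17.2),
        ("46,XX,del(18)(q21)", "chr18", "loss", 18.1),
        ("46,XY,del(18)(q21.3q23)", "chr18", "loss", 24.2),
        ("46,XX,del(18)(p11.32p11.21)", "chr18", "loss", 15.4),
        ("46,XX,del(X)(q23q25)", "chrX", "loss", 20.0),
        ("46,XX,del(X)(q24q28)", "chrX", "loss", 38.7),
        ("46,XX,?del(7)(q32)", "chr7", "loss", 5.5),
        ("46,XY,del(15)(q26.2q26.3)", "chr15", "loss", 9.1),
        ("arr 18q11.2.q12.1(25,341–28,865) ×1", "chr18", "loss", 3.5),
        ("arr 18q22.3.q23(69,461–78,014)×1", "chr18", "loss", 8.6),
        ("arr 13q31.1(80,281–83,294)×1", "chr13", "loss", 3.0),
    ]

    @pytest.mark.parametrize("raw,chrom,direction,size_mb", CLINICAL)
    def test_clinical_dialects(self, bands, raw, chrom, direction, size_mb):
        ev, = parse_truth(raw, bands)
        assert ev.chrom == chrom and ev.direction == direction
        assert ev.size_mb == pytest.approx(size_mb, abs=0.051)

    def test_multiple_events_in_one_string(self, bands):
        evs = parse_truth("46,XX,del(4)(q34.3q35.2), dup(7)(p22p21.1)", bands)
        assert [(e.chrom, e.direction) for e in evs] \
            == [("chr4", "loss"), ("chr7", "gain")]

    @pytest.mark.parametrize("raw", [
        "46,XX,-14,+der(3;14)(q21;p13)",
        "47,XX,mos +i(18)(p11)[7]/46,xx[23]",
        "46,XX,Xp-",
        "gibberish",
    ])
    def test_complex_forms_raise_with_guidance(self, bands, raw):
        with pytest.raises(ValueError):
            parse_truth(raw, bands)

    def test_manifest_coordinate_override(self, bands, tmp_path):
        df = pd.DataFrame([
            {"sample_id": "L00626", "chrom": "chr18", "start_kb": 0,
             "end_kb": 17_200, "direction": "gain", "origin": "fetal",
             "source_string": "47,XX,mos +i(18)(p11)[7]/46,xx[23]"},
            {"sample_id": "E1", "chrom": "", "start_kb": None,
             "end_kb": None, "direction": "", "origin": "",
             "source_string": "46,XX,del(5)(p14)"},
        ])
        p = tmp_path / "truth.tsv"
        df.to_csv(p, sep="\t", index=False)
        evs = read_truth_manifest(p, bands)
        assert evs[0].direction == "gain" and evs[0].end_kb == 17_200
        assert evs[1].chrom == "chr5" and evs[1].start_kb == 18_400


class TestOverlap:
    # printed coordinate pairs with their printed overlaps (kb)
    WORKED = [
        ((69_461, 78_014), (59_800, 75_091), 5_630),   # 5.6 Mb
        ((25_341, 28_865), (23_066, 27_505), 2_164),   # 2.2 Mb
        ((60_399, 61_730), (58_259, 63_190), 1_331),   # 1.3 Mb
        ((80_281, 83_294), (81_667, 85_377), 1_627),   # 1.6 Mb
    ]

    @pytest.mark.parametrize("a,b,expected", WORKED)
    def test_printed_overlaps(self, a, b, expected):
        assert overlap_kb(a, b) == expected
        assert overlap_kb(b, a) == expected     # symmetry

    def test_disjoint(self):
        assert overlap_kb((0, 100), (200, 300)) == 0

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            overlap_kb(truth("s", "chr1", 0, 10, "loss"),
                       truth("s", "chr2", 0, 10, "loss"))


class TestClassify:
    def test_truth_fully_covered_is_consistent(self):
        rec, = classify([call("s", "chr13", 58_259, 63_190, "gain")],
                        [truth("s", "chr13", 60_399, 61_730, "gain")])
        assert rec.klass == CONSISTENT and rec.frac_truth == 1.0

    def test_call_contained_in_truth_is_consistent(self):
        rec, = classify([call("s", "chr5", 569, 9_545, "loss")],
                        [truth("s", "chr5", 0, 15_000, "loss")])
        assert rec.klass == CONSISTENT

    def test_half_overlap_of_either_interval_is_consistent(self):
        # >50% of the truth only (truth-relative), like EH00601
        rec, = classify([call("s", "chr13", 81_667, 85_377, "loss")],
                        [truth("s", "chr13", 80_281, 83_294, "loss")])
        assert rec.klass == CONSISTENT
        assert rec.frac_truth > 0.5 > rec.frac_call

    def test_small_overlap_is_partly_consistent(self):
        rec, = classify([call("s", "chr5", 608, 20_832, "loss")],
                        [truth("s", "chr5", 18_400, 28_900, "loss")])
        assert rec.klass == PARTLY and rec.overlap_kb == 2_432

    def test_no_overlap_same_chromosome_is_partly_consistent(self):
        rec, = classify([call("s", "chr5", 63, 17_216, "loss")],
                        [truth("s", "chr5", 28_900, 42_500, "loss")])
        assert rec.klass == PARTLY and rec.overlap_kb == 0

    def test_missing_call_is_inconsistent(self):
        rec, = classify([], [truth("s", "chr9", 87_600, 114_900, "loss")])
        assert rec.klass == INCONSISTENT and rec.call is None

    def test_direction_mismatch_is_inconsistent(self):
        rec, = classify([call("s", "chr5", 0, 15_000, "gain")],
                        [truth("s", "chr5", 0, 15_000, "loss")])
        assert rec.klass == INCONSISTENT

    def test_call_matched_to_at_most_one_truth(self):
        # one call spanning two truth events may satisfy only one
        c = call("s", "chr1", 0, 50_000, "loss")
        recs = classify([c], [truth("s", "chr1", 0, 20_000, "loss"),
                              truth("s", "chr1", 30_000, 50_000, "loss")])
        assert sorted(r.klass for r in recs) == [CONSISTENT, INCONSISTENT]

    def test_samples_do_not_cross_talk(self):
        recs = classify([call("other", "chr5", 0, 15_000, "loss")],
                        [truth("s", "chr5", 0, 15_000, "loss")])
        assert recs[0].klass == INCONSISTENT


class TestPerformance:
    def test_reproduces_published_screening_rates(self):
        perf = {p.stratum: p for p in performance_from_counts(
            {">10Mb": {"consistent": 21, "partly": 3, "inconsistent": 3,
                       "fp_calls": 6},
             "<10Mb": {"consistent": 7, "partly": 1, "inconsistent": 3,
                       "fp_calls": 8}}, euploid_n=886)}
        assert 100 * perf["total"].sensitivity == pytest.approx(84.21, abs=0.01)
        assert 100 * perf["total"].specificity == pytest.approx(98.42, abs=0.01)
        assert 100 * perf[">10Mb"].sensitivity == pytest.approx(88.89, abs=0.01)
        assert 100 * perf[">10Mb"].specificity == pytest.approx(99.32, abs=0.01)
        assert 100 * perf["<10Mb"].sensitivity == pytest.approx(72.73, abs=0.01)
        assert 100 * perf["<10Mb"].specificity == pytest.approx(99.09, abs=0.01)
        assert 100 * perf["total"].ppv == pytest.approx(69.57, abs=0.01)

    def test_exact_binomial_cis_match_published(self):
        assert clopper_pearson(32, 38) == pytest.approx((0.6875, 0.9398),
                                                        abs=0.002)
        assert clopper_pearson(872, 886) == pytest.approx((0.9736, 0.9913),
                                                          abs=0.002)

    def test_perfect_classifier(self):
        p, = [x for x in performance_from_counts(
            {"total": {"consistent": 10, "partly": 0, "inconsistent": 0,
                       "fp_calls": 0}}, euploid_n=50)
            if x.stratum == "total"]
        assert p.sensitivity == 1.0 and p.specificity == 1.0
        assert p.sensitivity_ci[1] == 1.0

    def test_empty_stratum_reports_na(self):
        records = classify([call("s", "chr1", 0, 20_000, "loss")],
                           [truth("s", "chr1", 0, 20_000, "loss")])
        perf = {p.stratum: p for p in performance(records, {"e1": []})}
        assert perf["<10Mb"].sensitivity is None
        assert perf[">10Mb"].sensitivity == 1.0

    def test_fp_stratified_by_call_size_and_sample_counted_once(self):
        records = []
        euploid = {"e1": [call("e1", "chr1", 0, 20_000, "loss"),
                          call("e1", "chr2", 0, 2_000, "gain")],
                   "e2": [], "e3": []}
        perf = {p.stratum: p for p in performance(records, euploid)}
        assert perf[">10Mb"].fp_calls == 1 and perf["<10Mb"].fp_calls == 1
        # e1 has FPs in both strata but is one false-positive sample overall
        assert perf["total"].fp_samples == 1
        assert perf["total"].specificity == pytest.approx(2 / 3)
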