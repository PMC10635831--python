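import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasgb._kmers import revcomp
from metasgb.align import ReadAlignment, align_reads, filter_alignments, write_sam, alignments_from_sam
from metasgb.markerdb import MarkerDatabase, MarkerGene
from metasgb.profiler import (
    MarkerCoverage,
    apply_unclassified,
    clade_coverage,
    compute_marker_coverages,
    detect_and_normalize,
    detected_marker_fraction,
    estimate_unclassified,
    profile_sample,
    read_profile_tsv,
    robust_average,
    write_profile_tsv,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _db(markers_by_sgb, taxonomy=None, known=None, glen=None):
    markers = {
        sgb: [
            MarkerGene(mid, sgb, seq, is_quasi=quasi, ext_sgbs=ext)
            for (mid, seq, quasi, ext) in mks
        ]
        for sgb, mks in markers_by_sgb.items()
    }
    taxonomy = taxonomy or {
        sgb: f"k__Bacteria|p__P|c__C|o__O|f__F|g__G{sgb}|s__S{sgb}"
        for sgb in markers
    }
    return MarkerDatabase(
        version="test",
        markers=markers,
        taxonomy=taxonomy,
        avg_genome_length=glen or {sgb: 10000.0 for sgb in markers},
        is_known=known or {sgb: True for sgb in markers},
    )


@pytest.fixture(scope="module")
def toy_db():
    rng = np.random.default_rng(11)
    mks = {
        "SGB1": [(f"m1_{i}", _random_seq(rng, 600), False, []) for i in range(10)],
        "SGB2": [(f"m2_{i}", _random_seq(rng, 600), False, []) for i in range(10)],
    }
    return _db(mks)


class TestAlignReads:
    def test_exact_substring_maps_uniquely(self, toy_db):
        marker = toy_db.markers["SGB1"][0]
        read = marker.sequence[100:250]
        alns = align_reads([("r1", read, "I" * 150)], toy_db)
        assert len(alns) == 1
        a = alns[0]
        assert (a.marker_id, a.start, a.mapq, a.n_mismatches) == (
            marker.marker_id, 100, 60, 0,
        )

    def test_reverse_complement_read_maps(self, toy_db):
        marker = toy_db.markers["SGB1"][1]
        read = revcomp(marker.sequence[50:200])
        alns = align_reads([("r1", read, "I" * 150)], toy_db, keep_sequences=True)
        assert len(alns) == 1
        assert alns[0].start == 50
        assert alns[0].seq == marker.sequence[50:200]  # stored marker-oriented

    def test_multi_marker_tie_gets_mapq_zero(self):
        rng = np.random.default_rng(12)
        shared = _random_seq(rng, 600)
        db = _db({
            "SGB1": [("mA", shared, False, [])] + [
                (f"mA{i}", _random_seq(rng, 600), False, []) for i in range(9)
            ],
            "SGB2": [("mB", shared, False, [])] + [
                (f"mB{i}", _random_seq(rng, 600), False, []) for i in range(9)
            ],
        })
        alns = align_reads([("r1", shared[10:160], "I" * 150)], db)
        assert len(alns) == 1 and alns[0].mapq == 0
        assert filter_alignments(alns) == []

    def test_foreign_read_unmapped(self, toy_db):
        rng = np.random.default_rng(13)
        alns = align_reads([("r1", _random_seq(rng, 150), "I" * 150)], toy_db)
        assert alns == []

    def test_mismatched_read_still_maps(self, toy_db):
        marker = toy_db.markers["SGB1"][2]
        read = list(marker.sequence[0:150])
        for pos in (40, 90):  # 2 substitutions, ~98.7% identity
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        alns = align_reads([("r1", "".join(read), "I" * 150)], toy_db)
        assert len(alns) == 1 and alns[0].n_mismatches == 2

    def test_sam_round_trip(self, toy_db, tmp_path):
        marker = toy_db.markers["SGB2"][0]
        reads = [
            ("r1", marker.sequence[0:150], "I" * 150),
            ("r2", revcomp(marker.sequence[200:350]), "J" * 150),
        ]
        alns = align_reads(reads, toy_db, keep_sequences=True)
        sam = tmp_path / "x.sam"
        write_sam(alns, toy_db, sam)
        back = alignments_from_sam(sam)
        assert [(a.marker_id, a.start, a.mapq) for a in back] == [
            (a.marker_id, a.start, a.mapq) for a in alns
        ]
        assert back[1].seq == alns[1].seq


class TestFilterAlignments:
    def _aln(self, read_len=150, mapq=60):
        return ReadAlignment("r", "m", 0, read_len, read_len, mapq, 0)

    def test_short_read_discarded(self):
        assert filter_alignments([self._aln(read_len=69)]) == []
        assert len(filter_alignments([self._aln(read_len=70)])) == 1

    def test_mapq_boundary(self):
        assert filter_alignments([self._aln(mapq=4)]) == []
        assert len(filter_alignments([self._aln(mapq=5)])) == 1

    def test_empty_input(self):
        assert filter_alignments([]) == []


class TestRobustAverage:
    def test_example_five_values(self):
        assert robust_average([1, 2, 3, 4, 5], 0.2) == pytest.approx(3.0)

    @pytest.mark.parametrize("q", [0.0, 0.1, 0.2, 0.4])
    def test_constant_vector(self, q):
        assert robust_average([2.5] * 7, q) == pytest.approx(2.5)

    def test_tiny_vectors_plain_mean(self):
        assert robust_average([1.0, 5.0], 0.2) == pytest.approx(3.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=3, max_size=50),
        st.floats(0, 0.45),
    )
    def test_matches_sort_and_slice_oracle(self, values, q):
        cut = math.floor(q * len(values))
        kept = sorted(values)[cut : len(values) - cut]
        expected = sum(kept) / len(kept)
        assert robust_average(values, q) == pytest.approx(expected, rel=1e-9)


class TestCladeCoverage:
    def _cov(self, depths):
        return {
            f"m{i}": MarkerCoverage(f"m{i}", d, 1.0, 1 if d > 0 else 0)
            for i, d in enumerate(depths)
        }

    def test_zeros_included_in_vector(self):
        db = _db({"S": [(f"m{i}", "A" * 450, False, []) for i in range(10)]})
        cov = self._cov([4.0] * 5)  # five markers unseen -> depth 0
        c = clade_coverage("S", cov, db, {}, stat_q=0.2)
        # sorted [0,0,0,0,0,4,4,4,4,4]; drop 2 each side -> mean of [0,0,0,4,4,4]
        assert c == pytest.approx(2.0)

    def test_quasi_dropped_when_external_present(self):
        db = _db({
            "S": [(f"m{i}", "A" * 450, False, []) for i in range(9)]
            + [("mq", "A" * 450, True, [("E", 0.005)])],
        })
        cov = self._cov([1.0] * 9)
        cov["mq"] = MarkerCoverage("mq", 100.0, 1.0, 50)
        # stat_q=0 isolates the exclusion rule from the quantile truncation
        with_ext = clade_coverage("S", cov, db, {"E": 0.40}, stat_q=0.0)
        at_boundary = clade_coverage("S", cov, db, {"E": 0.33}, stat_q=0.0)
        without_ext = clade_coverage("S", cov, db, {"E": 0.20}, stat_q=0.0)
        assert with_ext == pytest.approx(1.0)  # quasi excluded entirely
        assert at_boundary == pytest.approx(1.0)  # >= 33% is inclusive
        assert without_ext == pytest.approx((9 + 100) / 10)  # quasi kept


class TestDetectAndNormalize:
    def _db100(self):
        return _db({
            "S1": [(f"a{i}", "A" * 450, False, []) for i in range(100)],
            "S2": [(f"b{i}", "A" * 450, False, []) for i in range(100)],
        })

    def test_detection_threshold_inclusive_at_20_percent(self):
        db = self._db100()
        prof = detect_and_normalize(
            {"S1": 1.0, "S2": 1.0}, {"S1": 0.20, "S2": 0.19}, db
        )
        assert prof.detected_sgbs() == {"S1"}

    def test_equal_coverages_split_fifty_fifty(self):
        db = self._db100()
        prof = detect_and_normalize(
            {"S1": 2.0, "S2": 2.0}, {"S1": 1.0, "S2": 1.0}, db
        )
        ab = prof.sgb_abundances()
        assert ab["S1"] == pytest.approx(50.0)
        assert ab["S2"] == pytest.approx(50.0)

    def test_rank_additivity_and_normalization(self):
        db = _db(
            {
                "S1": [(f"a{i}", "A" * 450, False, []) for i in range(10)],
                "S2": [(f"b{i}", "A" * 450, False, []) for i in range(10)],
                "S3": [(f"c{i}", "A" * 450, False, []) for i in range(10)],
            },
            taxonomy={
                "S1": "k__B|p__P|c__C|o__O|f__F|g__G1|s__X1",
                "S2": "k__B|p__P|c__C|o__O|f__F|g__G1|s__X2",
                "S3": "k__B|p__P|c__C|o__O|f__F|g__G2|s__X3",
            },
        )
        prof = detect_and_normalize(
            {"S1": 3.0, "S2": 2.0, "S3": 5.0},
            {"S1": 1.0, "S2": 1.0, "S3": 1.0},
            db,
        )
        f = prof.frame.set_index("clade_name")["relative_abundance"]
        assert f["k__B|p__P|c__C|o__O|f__F|g__G1"] == pytest.approx(50.0)
        assert f["k__B|p__P|c__C|o__O|f__F|g__G2"] == pytest.approx(50.0)
        assert f["k__B"] == pytest.approx(100.0)
        # per rank, detected clades sum to 100
        for rank in ("kingdom", "genus", "species", "SGB"):
            tot = prof.frame[prof.frame["rank"] == rank]["relative_abundance"].sum()
            assert tot == pytest.approx(100.0, abs=1e-9)

    def test_nothing_detected_empty_profile(self):
        db = self._db100()
        prof = detect_and_normalize({}, {}, db)
        assert len(prof.frame) == 0


class TestUnclassified:
    def _profile(self, sgbs, covs):
        db = _db({s: [(f"{s}m{i}", "A" * 450, False, []) for i in range(10)] for s in sgbs})
        prof = detect_and_normalize(
            {s: 1.0 for s in sgbs}, {s: 1.0 for s in sgbs}, db
        )
        prof.avg_nonzero_coverage = dict(zip(sgbs, covs))
        return prof, db

    def test_exact_balance_gives_zero(self):
        prof, db = self._profile(["S"], [5.0])
        db.avg_genome_length["S"] = 2000.0
        assert estimate_unclassified(prof, db, 100, 100.0) == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        prof, db = self._profile(["S"], [2.0])
        db.avg_genome_length["S"] = 10000.0
        pct = estimate_unclassified(prof, db, 1000, 100.0)
        assert pct == pytest.approx(80.0)

    def test_usgb_length_inflated_seven_percent(self):
        prof, db = self._profile(["S"], [2.0])
        db.avg_genome_length["S"] = 10000.0
        db.is_known["S"] = False
        pct = estimate_unclassified(prof, db, 1000, 100.0)
        # classified = 2 * 10700 / 100 = 214 reads
        assert pct == pytest.approx(100 * (1000 - 214) / 1000)

    def test_clamped_to_zero(self):
        prof, db = self._profile(["S"], [50.0])
        db.avg_genome_length["S"] = 10000.0
        assert estimate_unclassified(prof, db, 100, 100.0) == 0.0

    def test_invalid_read_length_rejected(self):
        prof, db = self._profile(["S"], [1.0])
        with pytest.raises(ValueError):
            estimate_unclassified(prof, db, 100, 0.0)

    def test_abundances_rescaled_to_complement(self):
        prof, _ = self._profile(["S1", "S2"], [1.0, 1.0])
        apply_unclassified(prof, 30.0)
        sgb_total = sum(prof.sgb_abundances().values())
        assert sgb_total == pytest.approx(70.0)


def test_profile_tsv_round_trip(tmp_path, toy_db):
    prof = detect_and_normalize(
        {"SGB1": 2.0, "SGB2": 6.0}, {"SGB1": 1.0, "SGB2": 1.0}, toy_db
    )
    apply_unclassified(prof, 20.0)
    out = tmp_path / "profile.tsv"
    write_profile_tsv(prof, out, version="metasgb test")
    back = read_profile_tsv(out)
    assert back.unclassified_percent == pytest.approx(20.0)
    assert back.sgb_abundances() == pytest.approx(prof.sgb_abundances(), rel=1e-4)


def test_mapping_file_input_path(tmp_path, toy_db):
    """Pre-performed two-column read->marker mappings drive coverage-only
    profiling."""
    from metasgb.align import read_mapping_file

    lines = []
    for m in toy_db.markers["SGB2"]:
        for i in range(6):
            lines.append(f"r{m.marker_id}_{i}\t{m.marker_id}")
    path = tmp_path / "sample.map"
    path.write_text("\n".join(lines) + "\n")
    alns = read_mapping_file(path, read_length=150)
    assert len(alns) == 60
    prof = profile_sample(
        alignments=alns, db=toy_db, total_reads=60, avg_read_length=150
    )
    assert prof.detected_sgbs() == {"SGB2"}


def test_profile_sample_end_to_end(toy_db):
    """Reads tiled from one marker set detect exactly that SGB."""
    rng = np.random.default_rng(21)
    reads = []
    for m in toy_db.markers["SGB1"]:
        for start in range(0, 450, 30):
            reads.append((f"r{len(reads)}", m.sequence[start : start + 150], "I" * 150))
    prof = profile_sample(reads=reads, db=toy_db)
    assert prof.detected_sgbs() == {"SGB1"}
    assert prof.sgb_abundances()["SGB1"] == pytest.approx(100.0)
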