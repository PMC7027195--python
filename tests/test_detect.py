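"""Detection: planted-truth checks and the exhaustive brute-force oracle."""

import numpy as np
import pytest

from swingerscan import (
    IDENTITY,
    DetectionParams,
    ReferenceDB,
    apply_transformation,
    batch_detect,
    conjugate_by_complement,
    detect_swinger,
    enumerate_transformations,
    invert,
    parse_name,
    reverse_complement,
)
from swingerscan.detect import read_tabular_hits

from conftest import random_dna

ALL = enumerate_transformations()


def brute_force_detect(read, ref, min_matches=0):
    """Independent oracle: enumerate every (transformation, orientation,
    offset) and score the ungapped overlay by direct base comparison.

    Returns (transformation, strand, ref_start_1based, score, margin)
    for the maximum-score overlay, ties broken like the detector
    (fewer moved bases, name, strand, position); margin is the gap to the
    best-scoring different transformation.
    """
    rc = reverse_complement(read)
    candidates = []
    for t in (IDENTITY,) + ALL:
        for strand, oriented in (("+", read), ("-", rc)):
            query = apply_transformation(t, oriented)
            for offset in range(len(ref) - len(query) + 1):
                m = sum(a == b for a, b in
                        zip(query, ref[offset:offset + len(query)]))
                score = 2 * m - 3 * (len(query) - m)
                candidates.append(
                    (score, t.moved_bases, t.name, strand, offset, t))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3], c[4]))
    best = candidates[0]
    margin = next((best[0] - c[0] for c in candidates if c[5] is not best[5]),
                  best[0])
    return best[5], best[3], best[4] + 1, best[0], margin


class TestDetectSwinger:
    def test_planted_swinger_read_recovered(self, small_reference, small_db):
        ref = small_reference["ref1"]
        frag = ref[4000:4200]
        read = apply_transformation("A↔T", frag)
        hit = detect_swinger(read, small_db)
        assert hit.classification == "swinger"
        assert hit.detection_transformation.name == "A↔T"
        assert hit.transcription_transformation.name == "A↔T"
        assert (hit.alignment.ref_start, hit.alignment.ref_end) == (4001, 4200)
        assert hit.alignment.percent_identity == 100.0
        assert hit.alignment.strand == "+"

    def test_verbatim_substring_is_canonical(self, small_reference, small_db):
        read = small_reference["ref1"][2000:2200]
        hit = detect_swinger(read, small_db)
        assert hit.classification == "canonical"
        assert hit.detection_transformation is IDENTITY

    def test_short_read_reports_length_threshold(self, small_reference, small_db):
        read = small_reference["ref1"][100:130]  # 30 nt < min 40
        hit = detect_swinger(read, small_db)
        assert hit.classification == "unidentified"
        assert hit.reason == "below minimum aligned length"
        assert hit.alignment is None

    def test_empty_inputs_rejected(self, small_db):
        with pytest.raises(ValueError):
            detect_swinger("", small_db)
        with pytest.raises(ValueError):
            ReferenceDB({})
        with pytest.raises(ValueError):
            ReferenceDB({"r": ""})

    def test_minus_strand_hits_report_conjugate_transcription(self, rng):
        """A read transcribed with exchange t from the minus strand is
        detected on strand '-' with transcription class c∘t∘c."""
        ref = random_dna(rng, 400)
        db = ReferenceDB({"ref": ref})
        frag = ref[100:220]
        for t in ALL:
            read = apply_transformation(t, reverse_complement(frag))
            hit = detect_swinger(read, db)
            assert hit.classification == "swinger"
            assert hit.alignment.strand == "-"
            assert hit.transcription_transformation is conjugate_by_complement(t)
            assert (hit.alignment.ref_start, hit.alignment.ref_end) == (101, 220)

    def test_equal_score_transformations_flag_ambiguous(self, rng):
        ref = random_dna(rng, 100) + "A" * 60 + random_dna(rng, 40)
        db = ReferenceDB({"ref": ref})
        hit = detect_swinger("C" * 50, db)
        assert hit.classification == "swinger"
        assert hit.ambiguous
        # winner has the fewest moved bases among the tied descriptions
        assert hit.detection_transformation.name == "A↔C"


class TestOracleEquivalence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_detect_matches_exhaustive_enumeration(self, rng, strand):
        """On small references the detector agrees with the brute-force
        (transformation × orientation × offset) oracle whenever the oracle's
        optimum is unique."""
        params = DetectionParams(canonical_first=False)
        for trial in range(6):
            ref = random_dna(rng, 200)
            frag = ref[40 + trial * 5:88 + trial * 5]  # 48 nt
            t_true = ALL[rng.integers(len(ALL))]
            oriented = frag if strand == "+" else reverse_complement(frag)
            read = apply_transformation(invert(t_true), oriented)
            if strand == "-":
                read = reverse_complement(read)
            t_o, strand_o, start_o, score_o, margin = brute_force_detect(read, ref)
            if margin == 0:
                continue
            hit = detect_swinger(read, ReferenceDB({"ref": ref}), params)
            assert hit.detection_transformation is t_o
            assert hit.alignment.strand == strand_o
            assert hit.alignment.ref_start == start_o
            assert hit.alignment.score == score_o


class TestBatchDetect:
    def test_mixed_canonical_and_swinger_counts(self, small_reference, small_db):
        ref = small_reference["ref1"]
        reads = []
        for i in range(5):
            reads.append((f"c{i}", ref[i * 500:i * 500 + 150]))
        for i in range(5):
            reads.append((f"s{i}", apply_transformation(
                "A→T→C→G→A", ref[3000 + i * 400:3000 + i * 400 + 150])))
        hits = batch_detect(reads, small_db)
        assert [h.read_id for h in hits] == [r[0] for r in reads]
        from collections import Counter
        counts = Counter(h.classification for h in hits)
        assert counts == {"canonical": 5, "swinger": 5}

    def test_empty_stream(self, small_db):
        assert batch_detect([], small_db) == []

    def test_invalid_read_skipped_with_warning(self, small_db, small_reference, caplog):
        reads = [("bad", "ACGT!!"), ("good", small_reference["ref1"][:150])]
        with caplog.at_level("WARNING"):
            hits = batch_detect(reads, small_db)
        assert [h.read_id for h in hits] == ["good"]
        assert any("bad" in r.message for r in caplog.records)


def test_tabular_hit_import_normalises_minus_strand():
    import io

    text = ("q1\tref1\t97.500\t200\t5\t0\t1\t200\t900\t701\t1e-50\t250\tA↔T\n"
            "q2\tref1\t100.000\t100\t0\t0\t1\t100\t10\t109\t1e-40\t180\tidentity\n")
    hits = read_tabular_hits(io.StringIO(text))
    assert hits[0].classification == "swinger"
    assert hits[0].alignment.strand == "-"
    assert (hits[0].alignment.ref_start, hits[0].alignment.ref_end) == (701, 900)
    assert hits[0].transcription_transformation is parse_name("A↔T")
    assert hits[1].classification == "canonical"
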