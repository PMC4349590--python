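"""PQS / i-motif scanning: pattern semantics, overlap modes, strand duality."""

import numpy as np
import pytest

from g4pipe.scanner import (
    MotifClass,
    PQSPattern,
    count_pqs_unigenes,
    decompose_pqs,
    find_g4,
    find_imotif,
    hits_from_bed,
    scan_transcripts,
    write_bed,
    write_hits_tsv,
)
from g4pipe.seqio import TranscriptRecord, reverse_complement

from conftest import random_dna
from oracles import brute_force_pqs_intervals, parses_as_pqs


class TestFindG4Examples:
    def test_minimal_instance(self):
        (hit,) = find_g4("GGGAGGGAGGGAGGG")
        assert hit.interval == (0, 15)
        assert hit.tract_lengths == (3, 3, 3, 3)
        assert hit.loop_lengths == (1, 1, 1)

    def test_eight_base_gap_breaks_the_match(self):
        assert find_g4("GGG" + "A" * 8 + "GGGAGGGAGGG") == []

    def test_default_mode_consumes_five_tracts_greedily(self):
        seq = "GGGAGGGAGGGAGGGAGGG"
        (hit,) = find_g4(seq)
        assert hit.interval == (0, 19) and hit.n_tracts == 5

    def test_exhaustive_mode_matches_brute_force_on_five_tracts(self):
        seq = "GGGAGGGAGGGAGGGAGGG"
        got = {h.interval for h in find_g4(seq, mode="exhaustive")}
        assert got == brute_force_pqs_intervals(seq)

    def test_loops_may_contain_g_and_n(self):
        # "." in the pattern is unrestricted: G and N loops are legal
        (hit,) = find_g4("GGGNGGGGGGGGAGGG", mode="default")
        assert hit.interval == (0, 16)

    def test_illegal_alphabet_is_error(self):
        with pytest.raises(ValueError):
            find_g4("GGGAXGGA")


class TestIMotif:
    def test_minimal_instance(self):
        (hit,) = find_imotif("CCCACCCACCCACCC")
        assert hit.interval == (0, 15) and hit.motif_class is MotifClass.IMOTIF

    def test_g_rich_sequence_has_no_imotif(self):
        assert find_imotif("GGGAGGGAGGGAGGG") == []

    def test_strand_duality_on_random_sequences(self, rng):
        for _ in range(150):
            seq = random_dna(rng, 80, "GACCCT")
            L = len(seq)
            im = {h.interval for h in find_imotif(seq, mode="exhaustive")}
            g4 = {
                (L - e, L - s)
                for s, e in (
                    h.interval for h in find_g4(reverse_complement(seq), mode="exhaustive")
                )
            }
            assert im == g4


class TestOverlapSemantics:
    def test_default_hits_are_subset_of_exhaustive(self, rng):
        for _ in range(150):
            seq = random_dna(rng, 120, "GGGACT")
            default = {h.interval for h in find_g4(seq)}
            exhaustive = {h.interval for h in find_g4(seq, mode="exhaustive")}
            assert default <= exhaustive

    def test_exhaustive_equals_brute_force_on_grich_sequences(self, rng):
        for _ in range(200):
            seq = random_dna(rng, 70, "GGGACT")
            got = {h.interval for h in find_g4(seq, mode="exhaustive")}
            assert got == brute_force_pqs_intervals(seq)

    def test_validation_closure_with_independent_parser(self, rng):
        for _ in range(100):
            seq = random_dna(rng, 100, "GGGACT")
            for mode in ("default", "exhaustive"):
                for h in find_g4(seq, mode=mode):
                    assert parses_as_pqs(h.matched_seq)
                    assert sum(h.tract_lengths) + sum(h.loop_lengths) == len(h.matched_seq)
                    assert len(h.tract_lengths) == len(h.loop_lengths) + 1 >= 4
                    assert all(t >= 3 for t in h.tract_lengths)
                    assert all(1 <= l <= 7 for l in h.loop_lengths)


class TestPatternParameters:
    def test_custom_tract_minimum(self):
        p = PQSPattern(g_run_min=2)
        assert find_g4("GGAGGAGGAGG", p) != []
        assert find_g4("GGAGGAGGAGG", PQSPattern()) == []

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PQSPattern(g_run_min=1)
        with pytest.raises(ValueError):
            PQSPattern(loop_min=5, loop_max=2)

    def test_all_g_run_parses_with_g_loops(self):
        # 15 consecutive Gs split into four tracts with single-G loops
        assert decompose_pqs("G" * 15, PQSPattern()) is not None
        assert decompose_pqs("G" * 14, PQSPattern()) is None


class TestCountingAndOutput:
    def test_unigene_count_deduplicates(self):
        recs = [
            TranscriptRecord("u1", "GGGAGGGAGGGAGGG" + "T" * 20 + "GGGAGGGAGGGAGGG"),
            TranscriptRecord("u2", "GGGTGGGTGGGTGGG"),
            TranscriptRecord("u3", "ACGT" * 10),
        ]
        hits = scan_transcripts(recs, motif="g4")
        assert len(hits) == 3
        assert count_pqs_unigenes(hits, MotifClass.G4) == 2
        assert count_pqs_unigenes(hits, MotifClass.IMOTIF) == 0
        assert count_pqs_unigenes([]) == 0

    def test_bed_roundtrip_and_tsv(self, tmp_path, small_transcripts):
        hits = scan_transcripts(small_transcripts)
        bed, tsv = tmp_path / "h.bed", tmp_path / "h.tsv"
        write_bed(hits, bed)
        write_hits_tsv(hits, tsv)
        back = hits_from_bed(bed, small_transcripts)
        assert [(h.transcript_id, h.interval, h.motif_class) for h in back] == [
            (h.transcript_id, h.interval, h.motif_class) for h in hits
        ]
        lines = tsv.read_text().splitlines()
        assert lines[0].startswith("transcript_id\t")
        assert len(lines) == len(hits) + 1
        # 1-based inclusive start is 0-based start + 1
        for h, line in zip(hits, lines[1:]):
            cols = line.split("\t")
            assert int(cols[3]) == h.start + 1 and int(cols[4]) == h.end

    def test_empty_hit_set_writes_header_only_bed(self, tmp_path):
        bed = tmp_path / "empty.bed"
        write_bed([], bed)
        content = bed.read_text()
        assert content.startswith("#") and len(content.splitlines()) == 1
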