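"""Synthetic-data generator: determinism, construction soundness, truth labels."""

import numpy as np
import pytest

from g4pipe.filtering import FilterThresholds, Rule, adapter_match_length, filter_fastq_paired
from g4pipe.orf import RegionLabel, find_longest_orf
from g4pipe.scanner import MotifClass, PQSPattern, find_g4, find_imotif
from g4pipe.seqio import write_fastq
from g4pipe.simulate import (
    DEFAULT_SIM_ADAPTER,
    MotifPlantSpec,
    contains_pqs_pattern,
    generate_background,
    generate_reads,
    plant_motifs,
    simulate_transcriptome,
)

from conftest import random_dna
from oracles import brute_force_pqs_intervals, parses_as_pqs


class TestPatternChecker:
    def test_agrees_with_brute_force_on_random_strings(self, rng):
        for _ in range(300):
            seq = random_dna(rng, 60, "GGCCAT")
            expected = bool(brute_force_pqs_intervals(seq, "G")) or bool(
                brute_force_pqs_intervals(seq, "C")
            )
            assert contains_pqs_pattern(seq) == expected

    def test_single_long_run_counts_split_tracts(self):
        assert contains_pqs_pattern("G" * 15)
        assert not contains_pqs_pattern("G" * 14)
        assert contains_pqs_pattern("T" + "C" * 15 + "T")


class TestGenerateBackground:
    def test_deterministic_for_fixed_seed(self):
        a = generate_background(10, 300, 0.4, seed=7)
        b = generate_background(10, 300, 0.4, seed=7)
        assert a == b
        assert a != generate_background(10, 300, 0.4, seed=8)

    def test_output_is_pattern_free_by_independent_parser(self):
        for rec in generate_background(20, 300, 0.5, seed=3):
            assert not brute_force_pqs_intervals(rec.seq, "G")
            assert not brute_force_pqs_intervals(rec.seq, "C")

    def test_gc_content_within_three_standard_errors(self):
        gc = 0.4
        records = generate_background(100, 1000, gc, seed=19)
        seq = "".join(r.seq for r in records)
        observed = (seq.count("G") + seq.count("C")) / len(seq)
        se = np.sqrt(gc * (1 - gc) / len(seq))
        assert abs(observed - gc) <= 3 * se

    def test_rejection_budget_error_mentions_gc(self):
        with pytest.raises(RuntimeError, match="gc"):
            generate_background(1, 500, 0.95, seed=0, max_tries=5)

    def test_invalid_gc(self):
        with pytest.raises(ValueError):
            generate_background(1, 100, 1.0, seed=0)


class TestPlantMotifs:
    def test_explicit_offset_interval_arithmetic(self):
        bg = generate_background(1, 100, 0.4, seed=2)
        spec = MotifPlantSpec(offset=10, transcript_index=0)  # 4x3 tracts, loops 1,1,1
        planted, truth = plant_motifs(bg, [spec], seed=0)
        (m,) = truth
        assert (m.start, m.end) == (10, 25)
        assert planted[0].seq[10:25] == "GGGAGGGAGGGAGGG"
        assert len(planted[0].seq) == 100  # length-preserving splice

    def test_planted_imotif_parses_as_imotif(self):
        spec = MotifPlantSpec(
            motif_class=MotifClass.IMOTIF, n_tracts=5, tract_length=4,
            loop_lengths=(2, 7, 1, 3),
        )
        assert parses_as_pqs(spec.motif_string(), base="C")
        assert not parses_as_pqs(spec.motif_string(), base="G")

    def test_overlapping_explicit_plants_raise(self):
        bg = generate_background(1, 100, 0.4, seed=2)
        specs = [
            MotifPlantSpec(offset=10, transcript_index=0),
            MotifPlantSpec(offset=20, transcript_index=0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            plant_motifs(bg, specs, seed=0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MotifPlantSpec(n_tracts=3, loop_lengths=(1, 1))
        with pytest.raises(ValueError):
            MotifPlantSpec(loop_lengths=(1, 1, 8))


class TestSimulateTranscriptome:
    def test_truth_intervals_covered_by_exhaustive_scan(self, rng):
        specs = []
        for k in range(40):
            nt = int(rng.integers(4, 6))
            specs.append(
                MotifPlantSpec(
                    motif_class=MotifClass.G4 if k % 2 == 0 else MotifClass.IMOTIF,
                    n_tracts=nt,
                    tract_length=int(rng.integers(3, 6)),
                    loop_lengths=tuple(int(x) for x in rng.integers(1, 8, size=nt - 1)),
                )
            )
        records, truth, _ = simulate_transcriptome(20, 400, specs, seed=6)
        by_id = {r.id: r.seq for r in records}
        assert len(truth.motifs) == 40
        for m in truth.motifs:
            finder = find_g4 if m.motif_class is MotifClass.G4 else find_imotif
            intervals = {h.interval for h in finder(by_id[m.transcript_id], mode="exhaustive")}
            assert (m.start, m.end) in intervals

    def test_no_motifs_outside_truth_per_class(self):
        specs = [MotifPlantSpec(motif_class=MotifClass.IMOTIF, transcript_index=0)]
        records, truth, _ = simulate_transcriptome(5, 300, specs, seed=9)
        for rec in records[1:]:
            assert find_g4(rec.seq, mode="exhaustive") == []
            assert find_imotif(rec.seq, mode="exhaustive") == []
        assert find_g4(records[0].seq, mode="exhaustive") == []

    def test_orf_scaffold_is_the_longest_orf(self):
        specs = [
            MotifPlantSpec(target_region=r, transcript_index=i % 6)
            for i, r in enumerate(
                [RegionLabel.FIVE_UTR, RegionLabel.CDS, RegionLabel.THREE_UTR] * 4
            )
        ]
        records, truth, orf_map = simulate_transcriptome(
            6, 600, specs, seed=4, with_orf=True
        )
        for rec in records:
            ann = find_longest_orf(rec.seq, min_codons=50)
            assert ann.has_orf
            assert (ann.orf_start, ann.orf_end) == orf_map[rec.id]
        for m in truth.motifs:
            start, end = orf_map[m.transcript_id]
            if m.target_region is RegionLabel.FIVE_UTR:
                assert m.end <= start
            elif m.target_region is RegionLabel.CDS:
                assert start <= m.start and m.end <= end
            else:
                assert m.start >= end


class TestGenerateReads:
    def test_zero_fractions_keep_everything(self):
        transcripts = generate_background(3, 300, 0.5, seed=1)
        pairs, truth = generate_reads(transcripts, 30, seed=5)
        assert all(t.rule is Rule.NONE for t in truth)
        kept, report = filter_fastq_paired(
            pairs, FilterThresholds(adapter_seq=DEFAULT_SIM_ADAPTER)
        )
        assert report.n_kept == 30 and len(kept) == 30

    def test_each_violating_pair_breaks_exactly_its_rule(self):
        transcripts = generate_background(3, 300, 0.5, seed=1)
        pairs, truth = generate_reads(
            transcripts, 60, 100, 0.2, 0.2, 0.2, seed=13
        )
        t = FilterThresholds(adapter_seq=DEFAULT_SIM_ADAPTER)
        for (r1, r2), label in zip(pairs, truth):
            broken = set()
            for r in (r1, r2):
                if adapter_match_length(r.seq, DEFAULT_SIM_ADAPTER) > 9:
                    broken.add(Rule.ADAPTER)
                if r.seq.count("N") / r.length > 0.03:
                    broken.add(Rule.N)
                if sum(1 for q in r.quals if q < 3) / r.length > 0.5:
                    broken.add(Rule.QUALITY)
            assert broken == (set() if label.rule is Rule.NONE else {label.rule})

    def test_fastq_bytes_deterministic(self, tmp_path):
        transcripts = generate_background(2, 300, 0.5, seed=1)
        files = []
        for run in (1, 2):
            pairs, _ = generate_reads(transcripts, 20, 100, 0.1, 0.1, 0.1, seed=21)
            out = tmp_path / f"run{run}.fastq"
            write_fastq([p[0] for p in pairs] + [p[1] for p in pairs], out)
            files.append(out.read_bytes())
        assert files[0] == files[1]

    def test_read_length_exceeding_transcripts_is_error(self):
        transcripts = generate_background(2, 80, 0.5, seed=1)
        with pytest.raises(ValueError, match="read_length"):
            generate_reads(transcripts, 10, read_length=100)

    def test_fraction_sum_validation(self):
        transcripts = generate_background(1, 200, 0.5, seed=1)
        with pytest.raises(ValueError):
            generate_reads(transcripts, 10, frac_adapter=0.5, frac_n=0.4, frac_lowq=0.3)
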