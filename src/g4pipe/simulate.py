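"""Synthetic transcriptomes and read sets with planted ground truth.

Every pipeline stage gets a fixture with known truth and no external data:

* pattern-free background transcripts at a controlled GC content
  (rejection-resampled against an independent run-chain checker, so the
  scanner under test never certifies its own fixtures);
* optional ORF scaffolds (ATG ... stop placed at planned coordinates, with
  competing in-frame starts/stops cleared) so region-targeted planting and
  UTR/CDS classification have a constructed answer;
* G4 / i-motif instances spliced in at known coordinates, length-preserving;
* paired FASTQ read sets in which a chosen fraction of pairs violates
  exactly one of the three filtering rules, strictly, and is labeled.

Planted motifs use homopolymer loops (A for G4, T for i-motif).  This keeps
a plant free of stop codons — {G,A} and {C,T} strings contain no TAA/TAG/TGA
— so CDS plants cannot truncate the scaffolded ORF, and it avoids
manufacturing the complementary pattern by accident (C-loops of length >= 3
between G-tracts would themselves chain into an i-motif).

All generators are deterministic for a fixed seed; per-transcript child
streams are spawned from one ``numpy`` SeedSequence so a retry on one
transcript never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .filtering import FilterThresholds, Rule, adapter_match_length
from .scanner import MotifClass, PQSPattern
from .orf import RegionLabel, STOP_CODONS
from .seqio import ReadRecord, TranscriptRecord

__all__ = [
    "MotifPlantSpec",
    "MotifTruth",
    "ReadTruth",
    "TruthTable",
    "contains_pqs_pattern",
    "generate_background",
    "plant_motifs",
    "simulate_transcriptome",
    "generate_reads",
    "DEFAULT_SIM_ADAPTER",
]

# TruSeq-style adapter used only to *simulate* contamination; the filter
# itself never assumes an adapter sequence.
DEFAULT_SIM_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_LOOP_BASE = {MotifClass.G4: "A", MotifClass.IMOTIF: "T"}
_TRACT_BASE = {MotifClass.G4: "G", MotifClass.IMOTIF: "C"}


# ---------------------------------------------------------------------------
# independent pattern checker (run-chain arithmetic, no regex, no scanner)
# ---------------------------------------------------------------------------

def contains_pqs_pattern(seq: str, p: PQSPattern | None = None) -> bool:
    """True iff ``seq`` contains a G4 or i-motif match under ``p``.

    Independent of the scanner: maximal base runs of length >= g_run_min are
    enumerated; a run of length L can host ``1 + (L - g) // (g + loop_min)``
    tracts (extra tracts separated by in-run loops); a match exists iff some
    window of consecutive runs, all inter-run gaps within [loop_min,
    loop_max], reaches the required tract total.  Exact for loop_min == 1.
    """
    p = p or PQSPattern()
    if p.loop_min != 1:
        raise NotImplementedError("run-chain checker assumes loop_min == 1")
    g = p.g_run_min
    for base in ("G", "C"):
        runs: list[tuple[int, int]] = []  # (start, length), maximal, length >= g
        i, n = 0, len(seq)
        while i < n:
            if seq[i] == base:
                j = i
                while j < n and seq[j] == base:
                    j += 1
                if j - i >= g:
                    runs.append((i, j - i))
                i = j
            else:
                i += 1
        caps = [1 + (length - g) // (g + p.loop_min) for _, length in runs]
        # total tract capacity of each maximal gap-connected block of runs
        total = 0
        for right in range(len(runs)):
            if right > 0:
                gap = runs[right][0] - (runs[right - 1][0] + runs[right - 1][1])
                if gap > p.loop_max:
                    total = 0
            total += caps[right]
            if total >= p.min_tracts:
                return True
    return False


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifTruth:
    transcript_id: str
    start: int
    end: int
    motif_class: MotifClass
    target_region: RegionLabel | None = None


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    rule: Rule  # Rule.NONE for clean pairs


@dataclass
class TruthTable:
    """Ground truth of a simulation: planted motifs and labeled read pairs."""

    motifs: list[MotifTruth]
    reads: list[ReadTruth]

    def motif_transcripts(self, motif_class: MotifClass) -> set[str]:
        return {m.transcript_id for m in self.motifs if m.motif_class is motif_class}

    def write_tsv(self, path: str | Path) -> None:
        lines = ["kind\tid\tstart\tend\tmotif_class\ttarget_region\trule"]
        for m in self.motifs:
            region = m.target_region.value if m.target_region else "."
            lines.append(
                f"motif\t{m.transcript_id}\t{m.start}\t{m.end}\t"
                f"{m.motif_class.value}\t{region}\t."
            )
        for r in self.reads:
            lines.append(f"read\t{r.read_id}\t.\t.\t.\t.\t{r.rule.value}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# background transcripts
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=probs))


def generate_background(
    n: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    p: PQSPattern | None = None,
    max_tries: int = 1000,
    id_prefix: str = "synthetic_unigene",
) -> list[TranscriptRecord]:
    """``n`` i.i.d. transcripts at GC content ``gc``, guaranteed pattern-free.

    Each sequence is resampled until the independent checker finds neither a
    G4 nor an i-motif match.  Raises if the rejection budget is exhausted
    (pathological gc near 1); the fix is a lower gc.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    p = p or PQSPattern()
    sub_seeds = np.random.SeedSequence(seed).spawn(n)
    records = []
    for i in range(n):
        rng = np.random.default_rng(sub_seeds[i])
        records.append(
            TranscriptRecord(
                id=f"{id_prefix}_{i + 1}",
                seq=_clean_background(rng, length, gc, p, max_tries),
            )
        )
    return records


def _clean_background(
    rng: np.random.Generator, length: int, gc: float, p: PQSPattern, max_tries: int
) -> str:
    for _ in range(max_tries):
        seq = "".join(_random_bases(rng, length, gc))
        if not contains_pqs_pattern(seq, p):
            return seq
    raise RuntimeError(
        f"could not draw a pattern-free background of length {length} at "
        f"gc={gc} within {max_tries} tries; lower gc"
    )


# ---------------------------------------------------------------------------
# ORF scaffolding
# ---------------------------------------------------------------------------

def _scaffold_orf(chars: list[str], orf_start: int, orf_end: int) -> None:
    """Place ATG...TAA at the designed span and clear competing signals.

    In-frame stops inside the CDS and in-frame upstream ATGs (which would
    extend the ORF 5'-ward) are mutated at their third base to T, which
    never creates a stop, a start, or a G/C run.
    """
    chars[orf_start : orf_start + 3] = "ATG"
    chars[orf_end - 3 : orf_end] = "TAA"
    for i in range(orf_start + 3, orf_end - 3, 3):
        if "".join(chars[i : i + 3]) in STOP_CODONS:
            chars[i + 2] = "T"
    frame = orf_start % 3
    for i in range(frame, orf_start - 2, 3):
        if i + 3 <= orf_start and "".join(chars[i : i + 3]) == "ATG":
            chars[i + 2] = "T"


def _enumerate_longest_orf(seq: str, min_codons: int) -> tuple[int, int] | None:
    """Independent brute-force longest-ORF oracle: all (ATG, next stop) pairs."""
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (-len, start, frame)
    for frame in range(3):
        starts = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] == "ATG"]
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        for s in starts:
            nxt = [t for t in stops if t >= s + 3]
            if not nxt:
                continue
            end = min(nxt) + 3
            if (end - s) // 3 >= min_codons:
                cand = (-(end - s), s, frame)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return best[1], best[1] - best[0]


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPlantSpec:
    """One motif to splice into a transcript.

    ``transcript_index`` and ``offset`` may be None, meaning the generator
    places the motif randomly (within ``target_region`` if one is set).
    """

    motif_class: MotifClass = MotifClass.G4
    n_tracts: int = 4
    tract_length: int = 3
    loop_lengths: tuple[int, ...] = (1, 1, 1)
    target_region: RegionLabel | None = None
    transcript_index: int | None = None
    offset: int | None = None

    def __post_init__(self) -> None:
        if self.n_tracts < 4:
            raise ValueError("a quadruplex needs >= 4 tracts")
        if self.tract_length < 3:
            raise ValueError("tract_length must be >= 3")
        if len(self.loop_lengths) != self.n_tracts - 1:
            raise ValueError("need exactly n_tracts - 1 loop lengths")
        if any(not 1 <= l <= 7 for l in self.loop_lengths):
            raise ValueError("loop lengths must lie in [1, 7]")

    @property
    def length(self) -> int:
        return self.n_tracts * self.tract_length + sum(self.loop_lengths)

    def motif_string(self) -> str:
        tract = _TRACT_BASE[self.motif_class] * self.tract_length
        loop_base = _LOOP_BASE[self.motif_class]
        parts = [tract]
        for l in self.loop_lengths:
            parts.append(loop_base * l)
            parts.append(tract)
        return "".join(parts)


def _region_bounds(
    region: RegionLabel | None, orf: tuple[int, int] | None, length: int
) -> tuple[int, int]:
    if region is None or orf is None:
        return 0, length
    orf_start, orf_end = orf
    if region is RegionLabel.FIVE_UTR:
        return 0, orf_start
    if region is RegionLabel.CDS:
        # stay clear of the ATG and the stop codon
        return orf_start + 3, orf_end - 3
    if region is RegionLabel.THREE_UTR:
        return orf_end, length
    raise ValueError(f"cannot target region {region}")


def _place(
    spec: MotifPlantSpec,
    length: int,
    taken: list[tuple[int, int]],
    orf: tuple[int, int] | None,
    rng: np.random.Generator,
) -> tuple[int, int]:
    lo, hi = _region_bounds(spec.target_region, orf, length)
    m = spec.length
    if spec.offset is not None:
        start = spec.offset
        if not (lo <= start and start + m <= hi):
            raise ValueError(
                f"explicit offset {start} does not fit motif of length {m} "
                f"in [{lo}, {hi})"
            )
        if any(start < e and s < start + m for s, e in taken):
            raise ValueError(f"planted motif at offset {start} overlaps another plant")
        return start, start + m
    if hi - lo < m:
        raise ValueError(f"region [{lo},{hi}) too short for motif of length {m}")
    for _ in range(200):
        start = int(rng.integers(lo, hi - m + 1))
        if not any(start < e and s < start + m for s, e in taken):
            return start, start + m
    raise ValueError("could not place motif without overlap; too many plants")


def plant_motifs(
    transcripts: Sequence[TranscriptRecord],
    specs: Iterable[MotifPlantSpec],
    seed: int = 0,
    orfs: dict[str, tuple[int, int]] | None = None,
) -> tuple[list[TranscriptRecord], list[MotifTruth]]:
    """Splice motifs into transcripts (length-preserving) and record truth.

    Specs without a transcript index are assigned round-robin.  Explicitly
    overlapping plants raise; random placement avoids overlap by resampling.
    """
    rng = np.random.default_rng(seed)
    orfs = orfs or {}
    chars = [list(t.seq) for t in transcripts]
    taken: list[list[tuple[int, int]]] = [[] for _ in transcripts]
    truth: list[MotifTruth] = []
    for k, spec in enumerate(specs):
        idx = spec.transcript_index if spec.transcript_index is not None else k % len(transcripts)
        rec = transcripts[idx]
        start, end = _place(
            spec, rec.length, taken[idx], orfs.get(rec.id), rng
        )
        chars[idx][start:end] = spec.motif_string()
        taken[idx].append((start, end))
        truth.append(
            MotifTruth(
                transcript_id=rec.id,
                start=start,
                end=end,
                motif_class=spec.motif_class,
                target_region=spec.target_region,
            )
        )
    planted = [
        TranscriptRecord(id=t.id, seq="".join(c)) for t, c in zip(transcripts, chars)
    ]
    return planted, truth


# ---------------------------------------------------------------------------
# whole-transcriptome simulation with verification and per-transcript retry
# ---------------------------------------------------------------------------

def simulate_transcriptome(
    n_transcripts: int,
    length: int,
    specs: Sequence[MotifPlantSpec],
    gc: float = 0.5,
    seed: int = 0,
    with_orf: bool = False,
    min_codons: int = 50,
    p: PQSPattern | None = None,
    max_tries: int = 50,
) -> tuple[list[TranscriptRecord], TruthTable, dict[str, tuple[int, int]]]:
    """Generate a planted transcriptome plus its truth table.

    Per transcript: draw a pattern-free background, optionally scaffold an
    ORF at ~25-70% of the length, plant this transcript's motifs, then
    verify (a) the sequence with plants masked is still pattern-free under
    the independent checker and (b) the scaffolded ORF is still the unique
    longest ORF per an independent enumerator.  Failed constructions are
    redrawn from the transcript's own child random stream, so results stay
    deterministic for a fixed seed.
    """
    p = p or PQSPattern()
    if with_orf and length < 60 * 3 + 60:
        raise ValueError("transcripts too short to scaffold an ORF with UTRs")
    by_index: dict[int, list[MotifPlantSpec]] = {}
    for k, spec in enumerate(specs):
        idx = spec.transcript_index if spec.transcript_index is not None else k % n_transcripts
        if not 0 <= idx < n_transcripts:
            raise ValueError(f"transcript_index {idx} out of range")
        by_index.setdefault(idx, []).append(spec)

    sub_seeds = np.random.SeedSequence(seed).spawn(n_transcripts)
    records: list[TranscriptRecord] = []
    truth_motifs: list[MotifTruth] = []
    orf_map: dict[str, tuple[int, int]] = {}
    for i in range(n_transcripts):
        rng = np.random.default_rng(sub_seeds[i])
        tid = f"synthetic_unigene_{i + 1}"
        for _ in range(max_tries):
            built = _build_one(
                tid, length, gc, by_index.get(i, []), rng, with_orf, min_codons, p
            )
            if built is not None:
                seq, motifs, orf = built
                records.append(TranscriptRecord(id=tid, seq=seq))
                truth_motifs.extend(motifs)
                if orf is not None:
                    orf_map[tid] = orf
                break
        else:
            raise RuntimeError(
                f"failed to construct transcript {tid} in {max_tries} tries; "
                "lower gc or plant fewer/shorter motifs"
            )
    return records, TruthTable(motifs=truth_motifs, reads=[]), orf_map


def _build_one(
    tid: str,
    length: int,
    gc: float,
    specs: list[MotifPlantSpec],
    rng: np.random.Generator,
    with_orf: bool,
    min_codons: int,
    p: PQSPattern,
):
    chars = list(_clean_background(rng, length, gc, p, 1000))
    orf: tuple[int, int] | None = None
    if with_orf:
        orf_start = int(rng.integers(int(0.20 * length), int(0.30 * length)))
        span = 3 * max(min_codons, int(0.45 * length) // 3)
        orf_end = orf_start + span
        if orf_end > length - int(0.15 * length):
            orf_end = orf_start + 3 * ((length - int(0.15 * length) - orf_start) // 3)
        _scaffold_orf(chars, orf_start, orf_end)
        orf = (orf_start, orf_end)

    taken: list[tuple[int, int]] = []
    motifs: list[MotifTruth] = []
    for spec in specs:
        try:
            start, end = _place(spec, length, taken, orf, rng)
        except ValueError:
            return None
        chars[start:end] = spec.motif_string()
        taken.append((start, end))
        motifs.append(
            MotifTruth(
                transcript_id=tid,
                start=start,
                end=end,
                motif_class=spec.motif_class,
                target_region=spec.target_region,
            )
        )
    seq = "".join(chars)

    # verification: mask plants with inert A's, re-check pattern-freeness
    masked = list(seq)
    for s, e in taken:
        masked[s:e] = "A" * (e - s)
    if contains_pqs_pattern("".join(masked), p):
        return None
    if orf is not None:
        found = _enumerate_longest_orf(seq, min_codons)
        if found != orf:
            return None
    return seq, motifs, orf


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def generate_reads(
    transcripts: Sequence[TranscriptRecord],
    n_reads: int,
    read_length: int = 100,
    frac_adapter: float = 0.0,
    frac_n: float = 0.0,
    frac_lowq: float = 0.0,
    adapter_seq: str = DEFAULT_SIM_ADAPTER,
    seed: int = 0,
    base_qual: int = 38,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[ReadTruth]]:
    """Paired reads with labeled, mutually exclusive filter-rule violations.

    The three fractions give the share of pairs that strictly violate the
    adapter, N, and low-quality rule respectively (one mate each).  Every
    generated pair is checked against the rules it must and must not break
    and redrawn otherwise, so the labels are exact by construction.
    """
    if frac_adapter + frac_n + frac_lowq > 1:
        raise ValueError("violation fractions must sum to <= 1")
    usable = [t for t in transcripts if t.length >= read_length]
    if not usable:
        raise ValueError(f"no transcript is >= read_length ({read_length} bp)")
    rng = np.random.default_rng(seed)
    labels = (
        [Rule.ADAPTER] * round(frac_adapter * n_reads)
        + [Rule.N] * round(frac_n * n_reads)
        + [Rule.QUALITY] * round(frac_lowq * n_reads)
    )
    labels += [Rule.NONE] * (n_reads - len(labels))
    labels = [labels[j] for j in rng.permutation(len(labels))]

    thresholds = FilterThresholds(adapter_seq=adapter_seq)
    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truth: list[ReadTruth] = []
    for i, label in enumerate(labels):
        rid = f"sim_read_{i + 1}"
        for _ in range(100):
            pair = _draw_pair(rid, usable, read_length, label, adapter_seq, base_qual, rng)
            if _violates_exactly(pair, label, thresholds):
                break
        else:
            raise RuntimeError(f"could not construct a clean {label.value} pair")
        pairs.append(pair)
        truth.append(ReadTruth(read_id=rid, rule=label))
    return pairs, truth


def _draw_pair(
    rid: str,
    transcripts: Sequence[TranscriptRecord],
    read_length: int,
    label: Rule,
    adapter_seq: str,
    base_qual: int,
    rng: np.random.Generator,
) -> tuple[ReadRecord, ReadRecord]:
    from .seqio import reverse_complement

    t = transcripts[int(rng.integers(len(transcripts)))]
    frag_len = min(t.length, 2 * read_length)
    pos = int(rng.integers(0, t.length - frag_len + 1))
    frag = t.seq[pos : pos + frag_len]
    seq1 = list(frag[:read_length])
    seq2 = list(reverse_complement(frag)[:read_length])
    q1 = [base_qual] * read_length
    q2 = [base_qual] * read_length
    mate = int(rng.integers(2))
    seq, quals = (seq1, q1) if mate == 0 else (seq2, q2)

    if label is Rule.ADAPTER:
        # insert > 9 exact adapter bases
        ins = int(rng.integers(10, min(len(adapter_seq), read_length) + 1))
        at = int(rng.integers(0, read_length - ins + 1))
        seq[at : at + ins] = adapter_seq[:ins]
    elif label is Rule.N:
        # strictly more than 3% N
        lo = int(np.floor(0.03 * read_length)) + 1
        k = int(rng.integers(lo, max(lo + 1, int(0.10 * read_length) + 1)))
        for j in rng.choice(read_length, size=k, replace=False):
            seq[j] = "N"
    elif label is Rule.QUALITY:
        # strictly more than 50% of bases below Q3
        lo = read_length // 2 + 1
        k = int(rng.integers(lo, read_length + 1))
        for j in rng.choice(read_length, size=k, replace=False):
            quals[j] = int(rng.integers(0, 3))
    return (
        ReadRecord(id=f"{rid}/1", seq="".join(seq1), quals=tuple(q1)),
        ReadRecord(id=f"{rid}/2", seq="".join(seq2), quals=tuple(q2)),
    )


def _rule_flags(read: ReadRecord, t: FilterThresholds) -> dict[Rule, bool]:
    n = read.length
    return {
        Rule.ADAPTER: adapter_match_length(read.seq, t.adapter_seq) > t.adapter_min_excess_bp
        if t.adapter_seq
        else False,
        Rule.N: read.seq.count("N") / n > t.max_n_fraction,
        Rule.QUALITY: sum(1 for q in read.quals if q < t.lowq_cutoff) / n
        > t.max_lowq_fraction,
    }


def _violates_exactly(
    pair: tuple[ReadRecord, ReadRecord], label: Rule, t: FilterThresholds
) -> bool:
    flags = [_rule_flags(r, t) for r in pair]
    broken = {rule for f in flags for rule, v in f.items() if v}
    if label is Rule.NONE:
        return not broken
    return broken == {label}
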