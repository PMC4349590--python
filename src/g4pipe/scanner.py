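"""Putative quadruplex sequence (PQS) and i-motif scanning.

A putative G-quadruplex-forming sequence is modelled, as in quadparser-style
screens, as four or more G-tracts (runs of >= 3 guanines by default)
separated by loops of 1-7 unrestricted bases:

    G{3,}.{1,7}G{3,}.{1,7}G{3,}.{1,7}G{3,}

The i-motif is predicted with the complementary pattern — the same grammar
with C-tracts — applied to the given strand, which is equivalent to scanning
the reverse complement for G4 and mapping coordinates back.

Two overlap semantics are provided:

``default``
    left-to-right, non-overlapping, greedy matching — exactly what a regex
    engine does with the pattern above, so a long G-rich region yields one
    maximal hit.  Implemented with the standard library ``re`` engine.
``exhaustive``
    every (start, end) substring that parses as tracts-and-loops, including
    overlapping and nested matches; implemented as a memoized reachability
    search over tract/loop boundaries.

Loop characters are unrestricted (``.`` in the pattern), so loops may
contain G, C or N; in particular a single long G run can parse with
G-containing loops.  No "loop must not extend a tract" correction is
applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .seqio import TranscriptRecord, normalize_seq

__all__ = [
    "MotifClass",
    "PQSPattern",
    "QuadruplexHit",
    "find_g4",
    "find_imotif",
    "scan_transcripts",
    "count_pqs_unigenes",
    "decompose_pqs",
    "write_bed",
    "write_hits_tsv",
]

Mode = Literal["default", "exhaustive"]


class MotifClass(str, Enum):
    G4 = "G4"
    IMOTIF = "IMOTIF"


@dataclass(frozen=True)
class PQSPattern:
    """Tract/loop grammar of a quadruplex-forming sequence.

    ``min_repeat_units`` counts the repeated (loop + tract) units after the
    leading tract, so the default of 3 demands >= 4 tracts in total.
    """

    g_run_min: int = 3
    loop_min: int = 1
    loop_max: int = 7
    min_repeat_units: int = 3

    def __post_init__(self) -> None:
        if self.g_run_min < 2:
            raise ValueError("g_run_min must be >= 2")
        if not 1 <= self.loop_min <= self.loop_max:
            raise ValueError("need 1 <= loop_min <= loop_max")
        if self.min_repeat_units < 1:
            raise ValueError("min_repeat_units must be >= 1")

    @property
    def min_tracts(self) -> int:
        return self.min_repeat_units + 1

    def regex(self, base: str = "G") -> re.Pattern[str]:
        g, lo, hi, k = self.g_run_min, self.loop_min, self.loop_max, self.min_repeat_units
        return re.compile(f"{base}{{{g},}}(?:.{{{lo},{hi}}}{base}{{{g},}}){{{k},}}")


@dataclass(frozen=True)
class QuadruplexHit:
    """One predicted PQS or i-motif occurrence on a transcript.

    Coordinates are 0-based half-open.  ``tract_lengths`` and
    ``loop_lengths`` give one deterministic tract/loop decomposition of
    ``matched_seq`` (tracts absorbed greedily, longest first).
    """

    transcript_id: str
    start: int
    end: int
    motif_class: MotifClass
    matched_seq: str
    tract_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    region: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.matched_seq):
            raise ValueError("interval length disagrees with matched_seq")
        if sum(self.tract_lengths) + sum(self.loop_lengths) != len(self.matched_seq):
            raise ValueError("tract/loop decomposition does not tile matched_seq")
        if len(self.tract_lengths) != len(self.loop_lengths) + 1:
            raise ValueError("need exactly one more tract than loops")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_tracts(self) -> int:
        return len(self.tract_lengths)


def decompose_pqs(
    s: str, p: PQSPattern, base: str = "G"
) -> tuple[tuple[int, ...], tuple[int, ...]] | None:
    """Deterministic tract/loop decomposition of a full string, or None.

    Depth-first with tracts taken longest-first and loops shortest-first,
    returning the first complete parse; failed (position, tract-count)
    states are memoized.  A run of guanines is thereby absorbed whole by
    the tract that starts it whenever the remainder still parses.
    """
    n = len(s)
    need = p.min_tracts
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if s[i] == base else 0
    dead: set[tuple[int, int]] = set()

    def walk(pos: int, done: int) -> list[int] | None:
        """Return flat [t1, l1, t2, ...] parsing s[pos:] exactly, or None."""
        done = min(done, need)
        if (pos, done) in dead:
            return None
        r = run[pos] if pos < n else 0
        if r >= p.g_run_min:
            for t in range(r, p.g_run_min - 1, -1):  # longest tract first
                e = pos + t
                if e == n:
                    if done + 1 >= need:
                        return [t]
                    continue
                for l in range(p.loop_min, p.loop_max + 1):
                    if e + l >= n:
                        break
                    rest = walk(e + l, done + 1)
                    if rest is not None:
                        return [t, l] + rest
        dead.add((pos, done))
        return None

    flat = walk(0, 0)
    if flat is None:
        return None
    return tuple(flat[0::2]), tuple(flat[1::2])


def _exhaustive_intervals(seq: str, p: PQSPattern, base: str) -> list[tuple[int, int]]:
    """All (start, end) with seq[start:end] parsing under the grammar.

    Memoized forward reachability over "tract starts here" states; the
    tract count is capped at the minimum required, keeping the state space
    O(n * min_tracts).
    """
    n = len(seq)
    need = p.min_tracts
    g, lo, hi = p.g_run_min, p.loop_min, p.loop_max
    run = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run[i] = run[i + 1] + 1 if seq[i] == base else 0

    memo: dict[tuple[int, int], frozenset[int]] = {}

    def ends_from(pos: int, done: int) -> frozenset[int]:
        done = min(done, need)
        key = (pos, done)
        hit = memo.get(key)
        if hit is not None:
            return hit
        out: set[int] = set()
        r = run[pos]
        if r >= g:
            d2 = min(done + 1, need)
            if d2 >= need:
                # any prefix of the run long enough to be a tract may end here
                out.update(range(pos + g, pos + r + 1))
            for t in range(g, r + 1):
                e = pos + t
                for l in range(lo, hi + 1):
                    nxt = e + l
                    if nxt + g <= n and run[nxt] >= g:
                        out |= ends_from(nxt, d2)
        res = frozenset(out)
        memo[key] = res
        return res

    found: list[tuple[int, int]] = []
    for i in range(n):
        if run[i] >= g:
            for e in sorted(ends_from(i, 0)):
                found.append((i, e))
    found.sort()
    return found


def _make_hit(
    seq: str, start: int, end: int, p: PQSPattern, base: str, cls: MotifClass, tid: str
) -> QuadruplexHit:
    sub = seq[start:end]
    dec = decompose_pqs(sub, p, base)
    if dec is None:  # pragma: no cover - scanner only emits parseable intervals
        raise AssertionError(f"interval [{start},{end}) does not parse")
    return QuadruplexHit(
        transcript_id=tid,
        start=start,
        end=end,
        motif_class=cls,
        matched_seq=sub,
        tract_lengths=dec[0],
        loop_lengths=dec[1],
    )


def _find(
    seq: str, p: PQSPattern, mode: Mode, base: str, cls: MotifClass, transcript_id: str
) -> list[QuadruplexHit]:
    seq = normalize_seq(seq, "scan input")
    if mode == "default":
        intervals = [m.span() for m in p.regex(base).finditer(seq)]
    elif mode == "exhaustive":
        intervals = _exhaustive_intervals(seq, p, base)
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    return [_make_hit(seq, s, e, p, base, cls, transcript_id) for s, e in intervals]


def find_g4(
    seq: str,
    p: PQSPattern | None = None,
    mode: Mode = "default",
    transcript_id: str = "",
) -> list[QuadruplexHit]:
    """G-quadruplex hits on the forward strand of ``seq``."""
    return _find(seq, p or PQSPattern(), mode, "G", MotifClass.G4, transcript_id)


def find_imotif(
    seq: str,
    p: PQSPattern | None = None,
    mode: Mode = "default",
    transcript_id: str = "",
) -> list[QuadruplexHit]:
    """i-motif hits: the C-tract complement of the G4 grammar on this strand."""
    return _find(seq, p or PQSPattern(), mode, "C", MotifClass.IMOTIF, transcript_id)


def scan_transcripts(
    records: Iterable[TranscriptRecord],
    p: PQSPattern | None = None,
    mode: Mode = "default",
    motif: Literal["g4", "imotif", "both"] = "both",
) -> list[QuadruplexHit]:
    """Scan a transcript collection for G4 and/or i-motif hits."""
    p = p or PQSPattern()
    hits: list[QuadruplexHit] = []
    for rec in records:
        if motif in ("g4", "both"):
            hits.extend(find_g4(rec.seq, p, mode, transcript_id=rec.id))
        if motif in ("imotif", "both"):
            hits.extend(find_imotif(rec.seq, p, mode, transcript_id=rec.id))
    return hits


def count_pqs_unigenes(
    hits: Iterable[QuadruplexHit], motif_class: MotifClass | None = None
) -> int:
    """Number of distinct transcripts carrying >= 1 hit (of one class if given)."""
    return len(
        {
            h.transcript_id
            for h in hits
            if motif_class is None or h.motif_class is motif_class
        }
    )


def write_bed(hits: Sequence[QuadruplexHit], path: str | Path) -> None:
    """BED6: chrom=transcript, score=tract count, strand + for G4 / - for i-motif."""
    lines = ["# BED6: transcript_id\tstart\tend\tname\tn_tracts\tstrand"]
    for i, h in enumerate(hits, 1):
        strand = "+" if h.motif_class is MotifClass.G4 else "-"
        lines.append(
            f"{h.transcript_id}\t{h.start}\t{h.end}\t"
            f"{h.motif_class.value}_{i}\t{h.n_tracts}\t{strand}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_hits_tsv(hits: Sequence[QuadruplexHit], path: str | Path) -> None:
    """TSV with both 0-based half-open and 1-based inclusive coordinates."""
    header = (
        "transcript_id\tstart0\tend0\tstart1\tend1\tmotif_class\t"
        "n_tracts\ttract_lengths\tloop_lengths\tregion\tmatched_seq"
    )
    lines = [header]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.transcript_id,
                    str(h.start),
                    str(h.end),
                    str(h.start + 1),
                    str(h.end),
                    h.motif_class.value,
                    str(h.n_tracts),
                    ",".join(map(str, h.tract_lengths)),
                    ",".join(map(str, h.loop_lengths)) or ".",
                    h.region or ".",
                    h.matched_seq,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def with_region(hit: QuadruplexHit, region: str) -> QuadruplexHit:
    """Copy of ``hit`` with its region label filled in."""
    return replace(hit, region=region)


def hits_from_bed(
    path: str | Path,
    records: Iterable[TranscriptRecord],
    p: PQSPattern | None = None,
) -> list[QuadruplexHit]:
    """Rebuild hits written by :func:`write_bed`, re-deriving decompositions."""
    p = p or PQSPattern()
    by_id = {r.id: r for r in records}
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, _name, _score, strand = line.split("\t")[:6]
        rec = by_id.get(chrom)
        if rec is None:
            raise KeyError(f"BED hit references unknown transcript {chrom!r}")
        cls = MotifClass.G4 if strand == "+" else MotifClass.IMOTIF
        base = "G" if cls is MotifClass.G4 else "C"
        hits.append(_make_hit(rec.seq, int(start), int(end), p, base, cls, chrom))
    return hits
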