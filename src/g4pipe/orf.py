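"""Longest-ORF prediction and 5'UTR / CDS / 3'UTR localization of hits.

Assembled unigenes are treated as sense-strand transcripts, so only the
three forward frames are scanned.  An ORF runs from an ATG to the next
in-frame stop codon (TAA/TAG/TGA), stop included in the span; ORFs lacking
a stop before the transcript end are not accepted, which keeps the
UTR/CDS/UTR partition well-defined.  The longest ORF with at least
``min_codons`` codons wins; ties break toward the smallest start, then the
smallest frame.

A quadruplex hit is assigned the region containing the majority of its
interval, with ties broken toward the 5'-most region; transcripts without
an accepted ORF yield NO_ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .scanner import QuadruplexHit, with_region
from .seqio import TranscriptRecord, normalize_seq

__all__ = [
    "RegionLabel",
    "OrfAnnotation",
    "find_longest_orf",
    "classify_region",
    "annotate_hits",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


class RegionLabel(str, Enum):
    FIVE_UTR = "FIVE_UTR"
    CDS = "CDS"
    THREE_UTR = "THREE_UTR"
    NO_ORF = "NO_ORF"


@dataclass(frozen=True)
class OrfAnnotation:
    """Longest forward-frame ORF of a transcript (absent if has_orf is False).

    ``orf_start`` points at the A of the ATG; ``orf_end`` is exclusive,
    just past the stop codon; the span length is a multiple of 3.
    """

    transcript_id: str
    has_orf: bool
    orf_start: int = 0
    orf_end: int = 0
    frame: int = 0

    def __post_init__(self) -> None:
        if self.has_orf:
            if (self.orf_end - self.orf_start) % 3 != 0:
                raise ValueError("ORF span must be a multiple of 3")
            if self.orf_start % 3 != self.frame:
                raise ValueError("frame disagrees with orf_start")


def find_longest_orf(
    seq: str, min_codons: int = 50, transcript_id: str = ""
) -> OrfAnnotation:
    """Longest ATG->stop ORF over the three forward frames.

    ``min_codons`` counts codons in the full span including the stop.
    Within a frame, each stop closes the ORF opened by the earliest ATG
    since the previous stop (the longest ORF ending at that stop).
    """
    seq = normalize_seq(seq, "ORF scan input")
    n = len(seq)
    best: tuple[int, int, int] | None = None  # (-length, start, frame)
    for frame in range(3):
        open_atg: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_atg is not None:
                    length = i + 3 - open_atg
                    if length // 3 >= min_codons:
                        cand = (-length, open_atg, frame)
                        if best is None or cand < best:
                            best = cand
                    open_atg = None
            elif codon == START_CODON and open_atg is None:
                open_atg = i
    if best is None:
        return OrfAnnotation(transcript_id=transcript_id, has_orf=False)
    neg_len, start, frame = best
    return OrfAnnotation(
        transcript_id=transcript_id,
        has_orf=True,
        orf_start=start,
        orf_end=start - neg_len,
        frame=frame,
    )


def classify_region(hit: QuadruplexHit, orf: OrfAnnotation, transcript_length: int) -> RegionLabel:
    """Region containing the majority of the hit interval; ties go 5'-ward."""
    if hit.transcript_id and orf.transcript_id and hit.transcript_id != orf.transcript_id:
        raise ValueError(
            f"hit on {hit.transcript_id!r} classified against ORF of "
            f"{orf.transcript_id!r}"
        )
    if not orf.has_orf:
        return RegionLabel.NO_ORF
    bounds = [
        (RegionLabel.FIVE_UTR, 0, orf.orf_start),
        (RegionLabel.CDS, orf.orf_start, orf.orf_end),
        (RegionLabel.THREE_UTR, orf.orf_end, transcript_length),
    ]
    best_label = RegionLabel.FIVE_UTR
    best_overlap = -1
    for label, lo, hi in bounds:  # 5'-most first, so strict ">" keeps ties 5'-ward
        overlap = max(0, min(hit.end, hi) - max(hit.start, lo))
        if overlap > best_overlap:
            best_label, best_overlap = label, overlap
    return best_label


def annotate_hits(
    hits: Iterable[QuadruplexHit],
    records: Iterable[TranscriptRecord],
    min_codons: int = 50,
) -> tuple[list[QuadruplexHit], dict[str, OrfAnnotation]]:
    """Fill the region label of every hit from its transcript's longest ORF."""
    by_id = {r.id: r for r in records}
    orfs: dict[str, OrfAnnotation] = {}
    annotated: list[QuadruplexHit] = []
    for hit in hits:
        rec = by_id.get(hit.transcript_id)
        if rec is None:
            raise KeyError(f"hit references unknown transcript {hit.transcript_id!r}")
        if hit.transcript_id not in orfs:
            orfs[hit.transcript_id] = find_longest_orf(
                rec.seq, min_codons, transcript_id=rec.id
            )
        label = classify_region(hit, orfs[hit.transcript_id], rec.length)
        annotated.append(with_region(hit, label.value))
    return annotated, orfs
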