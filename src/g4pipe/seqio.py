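"""Sequence records and FASTA/FASTQ input/output.

Transcripts (assembled unigenes) and raw reads are the two record types the
pipeline touches.  On ingest every sequence is normalized to the DNA alphabet
{A, C, G, T, N}: lowercase is uppercased and RNA U is mapped to T, because
assembled ESTs are cDNA and all downstream pattern scanning is DNA-based.
IUPAC ambiguity codes other than N are rejected rather than silently mapped.

Parsing and serialization are delegated to Biopython (``Bio.SeqIO``); this
module adds validation, normalization and transparent gzip handling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "reverse_complement",
    "normalize_seq",
]

DNA_ALPHABET = frozenset("ACGTN")
MAX_PHRED = 93

_NORMALIZE = str.maketrans("acgtnuU", "ACGTNTT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A sequence file or record violates the expected format."""


def normalize_seq(seq: str, context: str = "sequence") -> str:
    """Uppercase, map U->T, and verify the {A,C,G,T,N} alphabet.

    Raises :class:`FormatError` naming ``context`` if any other character
    (including IUPAC ambiguity codes such as R/Y/S/W) is present.
    """
    norm = seq.translate(_NORMALIZE)
    bad = set(norm) - DNA_ALPHABET
    if bad:
        raise FormatError(
            f"{context}: illegal character(s) {sorted(bad)!r}; "
            "allowed alphabet is A/C/G/T/N (U accepted and mapped to T)"
        )
    return norm


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    norm = normalize_seq(seq, "reverse_complement input")
    return norm.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled unigene: identifier plus normalized DNA sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("transcript with empty identifier")
        if not self.seq:
            raise FormatError(f"transcript {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", normalize_seq(self.seq, f"transcript {self.id!r}"))

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: sequence plus per-base Phred quality scores."""

    id: str
    seq: str
    quals: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_seq(self.seq, f"read {self.id!r}"))
        object.__setattr__(self, "quals", tuple(self.quals))
        if len(self.quals) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: {len(self.quals)} quality scores for "
                f"{len(self.seq)} bases"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.quals):
            raise FormatError(f"read {self.id!r}: Phred score outside [0, {MAX_PHRED}]")

    @property
    def length(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly gzipped) FASTA file into transcript records.

    Order is preserved; duplicate identifiers and malformed entries raise
    :class:`FormatError`.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in seen:
                    raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
                seen.add(rec.id)
                records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq)))
        except ValueError as exc:  # Biopython parse failure
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns (bit-stable output)."""
    bio = (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio, handle, "fasta")


def read_fastq(path: str | Path, phred_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream reads from a 4-line (possibly gzipped) FASTQ file.

    Qualities are decoded as ``ord(char) - phred_offset`` with offset 33
    (Sanger / CASAVA >= 1.8) or 64 (older Illumina).
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                yield ReadRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    quals=tuple(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, phred_offset: int = 33) -> None:
    """Write reads as 4-line FASTQ at the given Phred offset."""
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    with _open_text(path, "wt") as handle:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            SeqIO.write(rec, handle, fmt)
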