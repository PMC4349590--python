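"""Raw-read quality filtering.

Implements the three removal rules applied to HiSeq reads before assembly:

1. adapter contamination — a read sharing an exact substring of more than
   ``adapter_min_excess_bp`` (default 9) bases with the adapter is removed;
2. ambiguous bases — more than ``max_n_fraction`` (default 3%) of bases
   called N;
3. low quality — more than ``max_lowq_fraction`` (default 50%) of bases with
   Phred quality strictly below ``lowq_cutoff`` (default Q < 3).

All three thresholds are strict ("more than"): a read sitting exactly at a
boundary is kept.  Whole reads (or whole pairs) are discarded, never trimmed.
Rules are evaluated in the fixed order adapter -> N -> quality, which only
matters for attributing a removal to its first failing rule; the keep/remove
decision itself is order-independent.

Adapter detection is the longest exact common substring between read and
adapter.  No adapter sequence ships as a default: it is a required input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable

from .seqio import ReadRecord

__all__ = [
    "Rule",
    "FilterThresholds",
    "FilterReport",
    "adapter_match_length",
    "filter_read",
    "filter_fastq",
    "filter_fastq_paired",
]


class Rule(str, Enum):
    """Removal rules, in evaluation order; NONE means the read is kept."""

    ADAPTER = "adapter"
    N = "N"
    QUALITY = "quality"
    NONE = "none"


@dataclass(frozen=True)
class FilterThresholds:
    """Strict thresholds for the three removal rules.

    adapter_seq is mandatory for adapter screening; with ``adapter_seq=None``
    the adapter rule is skipped (reads can then only fail the N or quality
    rule).
    """

    adapter_seq: str | None = None
    adapter_min_excess_bp: int = 9
    max_n_fraction: float = 0.03
    max_lowq_fraction: float = 0.50
    lowq_cutoff: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")
        if not 0.0 <= self.max_lowq_fraction <= 1.0:
            raise ValueError("max_lowq_fraction must be in [0, 1]")
        if self.adapter_min_excess_bp < 0:
            raise ValueError("adapter_min_excess_bp must be >= 0")
        if self.lowq_cutoff < 0:
            raise ValueError("lowq_cutoff must be >= 0")
        if self.adapter_seq is not None and not self.adapter_seq:
            raise ValueError("adapter_seq must be non-empty when provided")


@dataclass
class FilterReport:
    """Per-rule removal counts; removals are attributed to the first failing rule."""

    n_input: int = 0
    n_removed_adapter: int = 0
    n_removed_n: int = 0
    n_removed_quality: int = 0

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_removed_adapter
            - self.n_removed_n
            - self.n_removed_quality
        )

    def _tally(self, rule: Rule) -> None:
        self.n_input += 1
        if rule is Rule.ADAPTER:
            self.n_removed_adapter += 1
        elif rule is Rule.N:
            self.n_removed_n += 1
        elif rule is Rule.QUALITY:
            self.n_removed_quality += 1

    def to_dict(self) -> dict[str, int]:
        d = asdict(self)
        d["n_kept"] = self.n_kept
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def adapter_match_length(read_seq: str, adapter_seq: str) -> int:
    """Length of the longest exact common substring of read and adapter.

    Classic O(n*m) dynamic programme over suffix-match lengths; returns 0
    when the two strings share no character.
    """
    if not read_seq or not adapter_seq:
        raise ValueError("read and adapter must both be non-empty")
    m = len(adapter_seq)
    best = 0
    prev = [0] * (m + 1)
    for rc in read_seq:
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if rc == adapter_seq[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def filter_read(read: ReadRecord, t: FilterThresholds) -> Rule:
    """First failing rule for a single read, or ``Rule.NONE`` if it is kept.

    A read is removed iff its adapter match exceeds ``adapter_min_excess_bp``,
    OR its N fraction exceeds ``max_n_fraction``, OR its fraction of bases
    below ``lowq_cutoff`` exceeds ``max_lowq_fraction`` — all strictly.
    """
    n = read.length
    if n == 0:
        raise ValueError(f"read {read.id!r} has zero length")
    if t.adapter_seq is not None:
        if adapter_match_length(read.seq, t.adapter_seq) > t.adapter_min_excess_bp:
            return Rule.ADAPTER
    if read.seq.count("N") / n > t.max_n_fraction:
        return Rule.N
    if sum(1 for q in read.quals if q < t.lowq_cutoff) / n > t.max_lowq_fraction:
        return Rule.QUALITY
    return Rule.NONE


def filter_fastq(
    reads: Iterable[ReadRecord], t: FilterThresholds
) -> tuple[list[ReadRecord], FilterReport]:
    """Filter a single-end read stream; returns kept reads and the tally."""
    report = FilterReport()
    kept = []
    for read in reads:
        rule = filter_read(read, t)
        report._tally(rule)
        if rule is Rule.NONE:
            kept.append(read)
    return kept, report


# rule attribution order for pairs: the pair is charged to the earlier rule
# among the two mates' first failing rules
_RULE_ORDER = {Rule.ADAPTER: 0, Rule.N: 1, Rule.QUALITY: 2, Rule.NONE: 3}


def filter_fastq_paired(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    t: FilterThresholds,
) -> tuple[list[tuple[ReadRecord, ReadRecord]], FilterReport]:
    """Filter mate pairs: a pair is dropped if either mate fails any rule.

    The report counts pairs; a dropped pair is attributed to the first rule
    (in adapter -> N -> quality order) failed by either mate.
    """
    report = FilterReport()
    kept = []
    for r1, r2 in pairs:
        rules = sorted((filter_read(r1, t), filter_read(r2, t)), key=_RULE_ORDER.get)
        report._tally(rules[0])
        if rules[0] is Rule.NONE:
            kept.append((r1, r2))
    return kept, report
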