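"""Assembly summary statistics for a set of unigenes.

Count, total/mean length, N50, longest sequence, the fraction of sequences
strictly longer than a cutoff (500 bp by default), and a fixed-width binned
length distribution suitable for a histogram.

N50 follows the standard contig definition: with lengths sorted in
descending order, the length at which the running cumulative sum first
reaches at least half of the total assembly length.  No interpolation;
the value is always an element of the input multiset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import TranscriptRecord

__all__ = ["AssemblySummary", "n50", "summarize", "plot_length_distribution"]


def n50(lengths: Iterable[int]) -> int:
    """Contig N50 of a multiset of positive sequence lengths."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("n50 of an empty length multiset is undefined")
    if any(x <= 0 for x in ls):
        raise ValueError("lengths must be positive integers")
    total = sum(ls)
    cum = 0
    for x in ls:
        cum += x
        if 2 * cum >= total:  # first length reaching >= half the total
            return x
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class AssemblySummary:
    """Unigene-level summary of an assembly.

    ``bins`` holds ``(label, count)`` pairs over half-open intervals
    ``[k*w+1, (k+1)*w]`` of width ``w``; lengths above ``bin_ceiling`` are
    lumped into a final open-ended bin.
    """

    n_sequences: int
    total_length: int
    mean_length: float
    n50: int
    max_length: int
    cutoff: int
    frac_over_cutoff: float
    bin_width: int
    bins: tuple[tuple[str, int], ...]

    def to_dict(self) -> dict:
        d = {
            "n_sequences": self.n_sequences,
            "total_length": self.total_length,
            "mean_length": self.mean_length,
            "n50": self.n50,
            "max_length": self.max_length,
            "cutoff": self.cutoff,
            "frac_over_cutoff": self.frac_over_cutoff,
            "bin_width": self.bin_width,
            "bins": [[label, count] for label, count in self.bins],
        }
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_hist_tsv(self, path: str | Path) -> None:
        lines = ["bin_label\tcount"]
        lines += [f"{label}\t{count}" for label, count in self.bins]
        Path(path).write_text("\n".join(lines) + "\n")


def summarize(
    records: Sequence[TranscriptRecord],
    cutoff: int = 500,
    bin_width: int = 100,
    bin_ceiling: int = 2000,
) -> AssemblySummary:
    """Summarize an assembly the way transcriptome reports present it.

    ``frac_over_cutoff`` counts lengths strictly greater than ``cutoff``
    ("more than 500 bp").  The mean is exact (total / n), not rounded.
    """
    if not records:
        raise ValueError("cannot summarize an empty assembly")
    if bin_width <= 0 or bin_ceiling < bin_width:
        raise ValueError("bin_width must be positive and bin_ceiling >= bin_width")
    lengths = [r.length for r in records]
    total = sum(lengths)
    n_over = sum(1 for x in lengths if x > cutoff)

    n_bins = bin_ceiling // bin_width
    counts = [0] * (n_bins + 1)  # +1 for the open-ended tail bin
    for x in lengths:
        k = (x - 1) // bin_width  # x in [k*w+1, (k+1)*w]
        counts[min(k, n_bins)] += 1
    labels = [f"{k * bin_width + 1}-{(k + 1) * bin_width}" for k in range(n_bins)]
    labels.append(f">{n_bins * bin_width}")

    return AssemblySummary(
        n_sequences=len(lengths),
        total_length=total,
        mean_length=total / len(lengths),
        n50=n50(lengths),
        max_length=max(lengths),
        cutoff=cutoff,
        frac_over_cutoff=n_over / len(lengths),
        bin_width=bin_width,
        bins=tuple(zip(labels, counts)),
    )


def plot_length_distribution(summary: AssemblySummary, path: str | Path) -> None:
    """Bar plot of the binned length distribution (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [b[0] for b in summary.bins]
    counts = [b[1] for b in summary.bins]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(counts)), counts, color="#4878a8")
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_xlabel("unigene length (bp)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
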