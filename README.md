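# g4pipe

Quadruplex screening for de novo transcriptome assemblies.

Plant transcriptomes assembled from short reads (e.g. flower-bud EST/unigene
sets from non-model species) are routinely mined for sequence elements that
can fold into non-canonical secondary structures. `g4pipe` re-implements, as
a tested and reusable pipeline, the bespoke computational stages of such a
study:

* **read filtering** — the three stringent removal rules applied to raw
  HiSeq reads before assembly: more than 9 bp of exact adapter match, more
  than 3% ambiguous (`N`) bases, or more than 50% of bases with Phred
  quality Q < 3. All thresholds strict; whole reads (or pairs) are
  discarded, never trimmed.
* **assembly statistics** — unigene count, total/mean length, N50, longest
  sequence, fraction of unigenes longer than a cutoff (500 bp), and a
  binned length distribution.
* **PQS / i-motif scanning** — putative G-quadruplex-forming sequences
  matched by the quadparser-style pattern
  `G{3,}.{1,7}G{3,}.{1,7}G{3,}.{1,7}G{3,}`
  (four or more G-tracts of ≥ 3 guanines separated by loops of 1–7
  unrestricted bases, `d(G3+L1-7)3+G3+`), and i-motifs by the complementary
  C-tract pattern on the same strand. Two overlap semantics: `default`
  (left-to-right non-overlapping greedy, exactly what a regex engine
  returns) and `exhaustive` (every substring that parses, including
  overlapping and nested occurrences).
* **UTR/CDS localization** — the longest forward-frame ATG→stop ORF
  partitions each transcript into 5'UTR / CDS / 3'UTR; each hit is labelled
  by majority overlap.
* **synthetic data with ground truth** — pattern-free background
  transcripts (rejection-sampled against an independent checker), planted
  motifs at known coordinates and regions, scaffolded ORFs, and read sets
  with labelled single-rule violations, so every stage can be verified
  exactly without external data.

## Library example

```python
>>> from g4pipe import find_g4
>>> for h in find_g4("TTAGGGTGGGTAGGGTGGGTTAGCT"):
...     print(h.interval, h.tract_lengths, h.loop_lengths, h.matched_seq)
(3, 19) (3, 3, 3, 3) (1, 2, 1) GGGTGGGTAGGGTGGG
```

The hit spans positions 3–19 (0-based, half-open): four G-tracts of length
3 with loops of 1, 2 and 1 bases between them.

## CLI example

Simulate 50 unigene-like transcripts (600 bp, GC 0.5) with scaffolded ORFs
and three planted motifs, then run the whole pipeline:

```bash
g4pipe simulate transcripts --config sim.yaml --out-dir sim/
g4pipe run-all --fasta sim/transcripts.fasta --mode exhaustive --out-dir run/
```

with `sim.yaml`:

```yaml
n_transcripts: 50
length: 600
gc: 0.5
seed: 11
with_orf: true
motifs:
  - {motif_class: G4, n_tracts: 4, tract_length: 3, loop_lengths: [1, 2, 1], target_region: FIVE_UTR}
  - {motif_class: G4, n_tracts: 5, tract_length: 4, loop_lengths: [3, 1, 7, 2], target_region: THREE_UTR}
  - {motif_class: IMOTIF, n_tracts: 4, tract_length: 3, loop_lengths: [2, 2, 2], target_region: CDS}
```

`run/summary.json` then contains (output printed by the run above):

```json
"pqs": {
  "g4_unigene_count": 2,
  "imotif_unigene_count": 1,
  "any_unigene_count": 3,
  "n_hits": 25,
  "region_counts": {"FIVE_UTR": 1, "CDS": 4, "THREE_UTR": 20, "NO_ORF": 0}
}
```

Two unigenes carry a G-quadruplex and one carries an i-motif — exactly the
transcripts the simulation planted into. `n_hits` is 25 because exhaustive
mode also reports the nested/overlapping sub-matches inside the long
five-tract plant (all 20 of them fall in the 3'UTR where it was planted).
The assembly block reports `n_sequences: 50`, `mean_length: 600.0`,
`n50: 600`, `frac_over_cutoff: 1.0`, as expected for fixed-length
simulated transcripts. Other subcommands: `filter-reads`, `stats`, `scan`,
`localize` (see `g4pipe <cmd> --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch on a freshly simulated corpus
derived from the seed — 100 transcripts with 100 planted motifs of both
classes, and 1,000 read pairs with 10% planted violations per filtering
rule — runs filter → stats → scan → localize, and verifies the pipeline's
per-class unigene counts and filtering report against the simulation's
ground truth, exiting non-zero on any disagreement.

## Layout

| module | contents |
| --- | --- |
| `g4pipe.seqio` | `TranscriptRecord`, `ReadRecord`, FASTA/FASTQ I/O, reverse complement |
| `g4pipe.filtering` | `FilterThresholds`, the three removal rules, per-rule report |
| `g4pipe.stats` | `n50`, `summarize`, length histogram |
| `g4pipe.scanner` | `PQSPattern`, `find_g4`, `find_imotif`, overlap modes, BED/TSV output |
| `g4pipe.orf` | `find_longest_orf`, `classify_region`, hit annotation |
| `g4pipe.simulate` | planted transcriptomes, labelled read sets, truth tables |
| `g4pipe.pipeline` / `g4pipe.cli` | end-to-end orchestration and the `g4pipe` command |

See `docs/methods.md` for the modelling choices, their rationale, and known
limitations.
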