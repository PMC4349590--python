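# Methods

## The PQS model

A putative G-quadruplex-forming sequence (PQS) is modelled purely at the
sequence level as

```
G{g,} ( .{lmin,lmax} G{g,} ){k,}
```

with defaults `g = 3` (tract minimum), `lmin = 1`, `lmax = 7` (loop bounds)
and `k = 3` repeat units, i.e. at least four G-tracts separated by loops of
1–7 bases — the classic `d(G3+L1-7)3+G3+` motif grammar used by
quadparser-style screens. The i-motif, the C-rich structure on the strand
complementary to a G4-forming strand, is predicted with the same grammar
over C-tracts applied to the given strand; for the exhaustive semantics
this is provably identical to scanning the reverse complement for G4 and
mapping intervals through `i ↦ L − i`, and the test suite asserts that
identity rather than assuming it.

Two deliberate consequences of the grammar are preserved rather than
"corrected", because the loop positions are unrestricted (`.`):

* loops may contain G, C or N — in particular a single run of ≥ 15
  guanines parses as four tracts joined by single-G loops;
* no thermodynamic plausibility is assessed. This is a sequence screen,
  not a folding prediction (no G4Hunter/cGcC-style scoring).

### Overlap semantics

Regex engines return left-to-right, non-overlapping, greedy matches, so a
G-rich region yields one maximal hit. That is the `default` mode (built on
the standard library `re` engine) and matches what a small scanning script
would have produced. Because non-overlapping scanning is an
implementation convention, not part of the motif definition, an
`exhaustive` mode enumerates *every* `(start, end)` substring that parses
— overlapping, nested, and mid-run starts included — via a memoized
reachability search over tract/loop boundaries (states are (position,
tract-count capped at the minimum), so the search is linear-ish in
practice and exact). Default-mode hits are a subset of exhaustive-mode
hits; planted-truth recall is always assessed in exhaustive mode.

Every emitted hit carries one deterministic tract/loop decomposition,
computed by a backtracking parser that absorbs tract runs longest-first
and takes loops shortest-first; a G-run is therefore consumed whole by the
tract that starts it whenever the remainder still parses (it is split only
when splitting is the only way to reach four tracts, e.g. inside long
homopolymer runs).

## Read filtering

Three removal rules, applied to whole reads, with strict inequalities:

| rule | threshold | reading |
| --- | --- | --- |
| adapter | longest exact common substring > 9 bp | "more than 9 bp of adaptor" |
| ambiguous | N fraction > 0.03 | "more than 3% ambiguous bases" |
| quality | fraction of bases with Q < 3 > 0.50 | "more than 50% with Q < 3.0" |

Reads exactly at a boundary (3 N in 100 bp; 50 of 100 bases at Q 2; a 9-bp
adapter match) are kept. Adapter detection is the longest exact common
substring (O(n·m) dynamic programme): no aligner, no mismatches — a
deterministic, oracle-checkable operationalization chosen because neither
the adapter sequence nor the matching tolerance of the original filtering
is recorded anywhere; for the same reason the adapter sequence is a
required input with no default. For paired input a pair is dropped if
either mate fails any rule; the report attributes each removal to the
first failing rule in the fixed order adapter → N → quality (attribution
order only — the keep/drop decision is order-independent). Phred+33 is the
default encoding (HiSeq 2000 / CASAVA ≥ 1.8 era), +64 selectable.

## Assembly statistics

N50 is the standard contig definition: sort lengths descending and return
the first length at which the cumulative sum reaches at least half the
total (integer arithmetic, no interpolation; always an element of the
input). "Longer than the cutoff" is strict (`> 500` by default), matching
the literal wording the statistic usually accompanies. The length
histogram uses half-open bins `[k·w+1, (k+1)·w]` of width 100 bp with an
open-ended tail above a configurable ceiling (default 2,000 bp); the
ceiling is a presentation choice only and does not affect any statistic.

## ORF-based localization

How published transcriptome screens place motifs in the 5'/3' UTR is
usually not stated (most plausibly via BLAST alignment to homologs). The
declared substitute here: the longest ATG→stop ORF over the three forward
frames (unigenes are treated as sense-strand cDNA; antisense structure is
already captured by the i-motif pattern), stop codon included in the span,
no partial ORFs (an ORF must terminate before the transcript end, which
keeps the 5'UTR/CDS/3'UTR partition exact). `min_codons` (default 50, a
conventional short-ORF floor, counted over the span including the stop) is
an explicit flag, not a buried constant. A hit is labelled by the region
containing the majority of its bases; exact ties break toward the 5'-most
region; transcripts without an accepted ORF yield `NO_ORF`.

## Synthetic data: what it emulates and what it does not

The generator produces the *stated world* every test runs in:

* **Backgrounds** are i.i.d. bases at a chosen GC content (default 0.5,
  length 300–600 bp — unigene-like scales), rejection-resampled until an
  independent checker finds no G4 and no i-motif. The checker is run-chain
  arithmetic (maximal base runs, per-run tract capacity
  `1 + (L−g)//(g+1)`, gap-connected blocks), shares no code with the
  scanner, and is itself validated against the brute-force parser in the
  tests — the unit under test never certifies its own fixtures.
* **Plants** are spliced in length-preserving at known coordinates. Loops
  are homopolymeric (A for G4, T for i-motif): strings over {G,A} or
  {C,T} contain no stop codon, so a CDS plant cannot truncate a
  scaffolded ORF, and G-tracts separated by C-loops of length ≥ 3 would
  themselves chain into an i-motif, which homopolymer loops avoid.
  Plants of one class cannot create matches of the other class (they add
  no bases of the other tract letter), so per-class unigene counts are
  exact by construction.
* **ORF scaffolds** place ATG…TAA at planned coordinates (~20–30% to
  ~65–75% of the length), clear competing in-frame stops and upstream
  starts by third-base mutation to T (never creates a start, a stop, or a
  G/C run), and are verified post hoc against an independent brute-force
  ORF enumerator; a transcript whose construction is broken (e.g. by an
  unlucky plant boundary codon) is redrawn from its own child random
  stream, so one retry never perturbs other transcripts and everything is
  reproducible from the seed.
* **Reads** are substrings of the transcripts in innocent-looking pairs
  (mate 2 reverse-complemented, flat Q 38); violating pairs breach exactly
  one rule strictly (≥ 10 exact adapter bases; N fraction drawn in
  (3%, 10%]; low-Q fraction in (50%, 100%]) in one mate, and every pair is
  checked against all three rules and redrawn on any unintended breach, so
  truth labels are exact. Default planted fractions in the acceptance
  runs are 10% per rule, 1,000 pairs.

Not emulated: sequencing error models (no quality-by-cycle decay, no
indels), coverage/expression structure, real UTR length distributions, and
chimeric or redundant assembly artifacts. A green test therefore
establishes algorithmic correctness against the stated rules and planted
truth — not biological realism of the corpus, and not that the screen's
hits would fold in vivo.

## Numerical and degenerate-input conventions

* Coordinates 0-based half-open internally and in BED; the TSV adds
  1-based inclusive columns.
* Sequence ingest uppercases, maps U→T (cDNA), rejects IUPAC codes other
  than N (their scan semantics would be undefined), and reports the
  offending record by name. FASTA output wraps at 60 columns for
  bit-stable round trips.
* Empty length multisets, empty assemblies, zero-length reads and
  malformed records raise; an empty hit set is valid output (header-only
  BED, zero counts).
* All randomness flows through `numpy` Generators seeded from explicit
  integers; per-transcript streams are spawned from one `SeedSequence`.

## Known limitations

* Exact-substring adapter detection misses adapters with sequencing
  errors; this is declared, not incidental (see above).
* Longest-ORF localization is a heuristic stand-in for homology-based CDS
  annotation and will mislabel transcripts whose true CDS is not the
  longest ORF (fusion artifacts, long 5'UTR uORF-rich genes).
* The independent background checker assumes `loop_min = 1` (the default
  grammar); other loop minima fall back to an error rather than a wrong
  answer.
* Unigene-level counts ignore motif multiplicity; a transcript with both
  motif classes counts once per class.
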