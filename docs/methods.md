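# Methods

## Model and assumptions

`gapweld` treats gap closing as flank-anchored local alignment. Each
maximal N-run in a scaffold is a gap; the N-free sequence on each side is
the only evidence used to locate the gap in another dataset. The method
assumes (a) the draft is locally correct outside gaps — flanks are real
sequence, possibly low quality near the gap edge; (b) at least one dataset
sequence spans the gap with enough flank homology to anchor both sides;
(c) the alignment near the junction is locally collinear (no large indel
straddling a hit boundary).

Three gap geometries are handled. A **positive** gap needs sequence
inserted. A **zero** gap closes by deleting the Ns and joining the flanks.
A **negative** gap arises when the flanking contigs actually overlap (a
scaffolder placed Ns between contigs that share sequence); closing removes
the N-run and one copy of the overlap. Negative closure is off by default
(`allow_negative`) because it deletes draft sequence on the strength of a
coordinate calculation alone.

Coordinates are 0-based half-open everywhere internally; the human-readable
logs use 1-based inclusive coordinates (stated in their header) to match
BLAST convention.

## Alignment engine

Production alignments run through BLAST+ (`makeblastdb` once per dataset,
`blastn` once per round with all flank queries batched). Tabular output
with the fixed column order

```
qseqid sseqid qstart qend sstart send bitscore evalue pident length nident
```

is parsed into forward-strand-normalised hits: minus-strand hits (reported
with `sstart > send`) become forward half-open intervals plus an
orientation flag, so downstream geometry works in one coordinate system.
Low-complexity filtering is disabled (`-dust no`): flanks are short,
specific queries and masking them costs closures.

The package also contains `oracle_align`, an exact affine-gap local
aligner (Gotoh recurrences; a gap of length k costs `open + k·extend`,
matching BLAST's convention). It exists to verify the engine contract and
the geometry code against ground truth, is guarded to 10^6 cells, and is
independently re-checked in the tests against a second, separately written
score-only dynamic program.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `end_length` | 300 bp | flank window per side; also the conflict window |
| `trim` | 0 bp | gap-adjacent bases skipped (low-quality contig edges); shifts the window, does not shrink it |
| `min_flank` | 20 bp | below this a flank cannot anchor a meaningful hit; gap logged `unalignable` |
| `min_score` | 25 bits | hit filter; bit score is used as "score" throughout |
| `max_evalue` | 1e-7 | hit filter |
| `min_identity` | 70 % | hit filter |
| match/mismatch | +1/−3 | blastn scoring (legal combination) |
| open/extend gap | 5/2 | blastn defaults for +1/−3 |
| `word_size` | 11 | blastn seed length |
| `max_alignments` | 50 | hits kept per query, by descending score |
| `max_insert` / `max_remove` | 500/500 bp | per-closure caps; the right-side cap includes the negative-gap overlap |
| `min_query_coverage` | 40 % | per-hit fraction of the flank that must align — the same coverage notion the validator applies |
| `max_n_fraction` | 0 | N content tolerated in a replacement (closing must not reintroduce Ns) |
| `max_rounds` | 3 | rounds stop earlier when one closes nothing |

Candidate ranking: highest sum of the two anchor bit scores, then greater
min-side score, smaller |insert|, lexicographic subject id, smaller subject
start, orientation — a total order, so selection is independent of
candidate enumeration order.

## Editing geometry

With `removed_left = trim +` (unaligned gap-adjacent tail of the left
flank) and `removed_right` symmetric, the edit replaces

```
[gap.start − removed_left, gap.end + removed_right + max(−insert_len, 0))
```

by the oriented subject segment between the two hits (empty for zero and
negative gaps). Unaligned tails are deliberately *replaced by the
dataset's copy* of the same region rather than kept verbatim: they sit
between two confident anchors, where the draft's edge bases are the least
trustworthy sequence involved. Negative-gap overlap is removed from the
right side by subject-coordinate arithmetic; if the junction contains an
indel this can be off by its size, which is why `allow_negative` is opt-in
and every removal is capped and logged.

## Rounds and conflict safety

All flanks are extracted and aligned before any edit in a round, and all
bookkeeping stays in round-input coordinates; edits are spliced in together
at the end of the round. A gap is eligible only when neither of its flank
windows (nor, re-checked, its own cut interval) intersects an interval
already scheduled for editing this round on that scaffold; otherwise it is
logged `deferred_conflict` and retried next round against the re-scanned
assembly. This guarantees a closure can never mutate a sequence another
gap used as its alignment query. The pipeline has no randomness; identical
inputs give byte-identical FASTA, logs and statistics.

Multiple dataset files are pooled into one BLAST database (duplicate ids
across files are an error), so the best fill wins globally rather than by
dataset priority.

## Validation

`validate` reimplements a three-criterion reference check with the same
engine contract as closing: (1) each flank aligns over ≥ 40 % of its
length; (2) flanks and insert each reach the identity threshold;
(3) the closed region beats the insert-free flank join. Criteria 2 and 3
use an *effective identity* — identical bases / (alignment columns +
unaligned query bases) — because plain local identity fails in both
directions: a scrambled insert can carry a tiny 100 %-identity spurious
hit, and the insert-free join scores 100 % whenever one flank aligns
perfectly, which would make criterion 3 unsatisfiable even for a perfect
fill. Criterion 2 applies the threshold to each component separately. For
empty-insert closures criterion 3 degrades to ≥, since the compared
regions are the same sequence. Queries shorter than 30 bp use
`blastn-short`; validation alignments use a permissive e-value so coverage
and identity, not significance, decide.

## Synthetic fixtures

The generator emulates the study conditions end to end: a seeded
pseudorandom reference (GC configurable), a draft derived from it
containing the three gap kinds at chosen positions, and a dataset of
fragments spanning each gap region with ≥ `end_length` context per side
(mean length 2 kb, sd 200 bp, ~2 spanning fragments per gap), an optional
per-base substitution error rate, an optional fraction of
reverse-complemented fragments, and GC/length-matched decoy fragments from
an unrelated random sequence. The standard mix is a 100 kb genome with 20
evenly spaced gaps cycling positive/positive/zero/negative (fills
10–400 bp, overlaps 5–60 bp, N-runs 5–50 bp) — small enough that a full
multi-round run takes seconds on one CPU while exercising every code path,
including the insert/removal limits and both strands.

All sampling flows through explicitly seeded generators; the error model
has its own stream so error-free and noisy datasets correspond
fragment-by-fragment. What the fixtures do **not** model: indel errors
(substitutions only), read quality values, repeats shared between gap
regions, chimeric dataset sequences, and genome-scale repeat structure.
Passing the synthetic suites therefore demonstrates the geometry, strand
handling, bookkeeping and thresholds are correct — not that closure rates
on a repeat-rich real genome will match.

## Numerical and degenerate-input choices

* Hits are sorted (query, −score, subject, coordinates) before the
  per-query cap, making engine output order irrelevant.
* Flanks stop at interior Ns and at scaffold bounds; boundary N-runs
  (scaffold starts/ends with N) are reported but never filled — there is
  nothing to anchor one side.
* `min_gap_run` defaults to 1: any N is a gap.
* The exact aligner breaks score ties by smallest query start, then
  smallest subject start.
* Replacements containing any N are rejected by default.

## Known limitations

* One subject sequence must span the whole gap; two-fragment chimeric
  fills are out of scope.
* Negative-gap arithmetic assumes junction collinearity (above).
* Bit score is used where a raw score threshold might also be defensible;
  it is the engine's primary ranking statistic and is documented as the
  package's choice.
* Validation requires the closed region to be reconstructible from the
  logs; the log format therefore stores flank sequences, making TSVs a few
  hundred bytes per gap larger than a minimal format.
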