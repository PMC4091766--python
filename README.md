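# gapweld

Draft genome assemblies ship with gaps: runs of `N` between contigs where
the assembler could not resolve the sequence. When alternative data exist —
a second assembly of the same reads, contigs from another platform, long
reads — much of that missing sequence is already sitting in them. `gapweld`
closes gaps by alignment: it extracts the sequence flanking each N-run,
aligns both flanks against the alternative datasets with nucleotide BLAST,
pairs left/right hits on the same dataset sequence, and splices the
best-scoring spanning sequence into the draft.

It is intended for genome-finishing work: given `draft.fa` and one or more
dataset FASTA files, it edits the draft in conflict-safe rounds and leaves a
complete audit trail of every change.

## Method

For a gap `g` on a scaffold, let `L` and `R` be up to `end_length` bases of
N-free sequence on each side (an optional `trim` skips the bases nearest the
gap, which are often low quality). Both flanks are aligned separately
against every dataset sequence; hits are filtered by minimum bit score,
maximum e-value and minimum identity. A pair of hits (one per flank) on the
same subject and strand, in flank order along the subject, defines a fill
candidate with

```
insert_len = s_start(R hit) − s_end(L hit)        (oriented subject frame)
```

* `insert_len > 0` — the subject sequence between the hits replaces the
  N-run (plus any unaligned flank tails, which are replaced by the
  dataset's version of the same bases);
* `insert_len = 0` — the flanks are joined and the Ns deleted;
* `insert_len < 0` — a *negative gap*: the flanking contigs truly overlap,
  and closing removes the overlap (enabled with `--negative-gaps`).

Candidates violating `--max-insert` / `--max-remove`, hit coverage, or the
N-content cap are discarded; the survivor with the highest combined bit
score wins. Gaps whose flank windows would be touched by an edit made
earlier in the same round are deferred to the next round, so a closure can
never corrupt a neighbouring gap's alignment query. Rounds repeat until no
gap closes or `--max-rounds` is reached.

Closures can be checked against a reference genome (`gapweld validate`):
a closure is accepted when (1) both flanks align over ≥ 40% of their
length, (2) flanks and insert each align at or above the identity
threshold, and (3) the closed region matches the reference better than the
un-inserted flank join did.

## Worked example

Generate a synthetic benchmark with known ground truth (100 kb genome,
20 mixed positive/zero/negative gaps, error-free spanning fragments plus
decoys), close it, and validate against the reference:

```
$ gapweld fixtures --seed 5 --out fx
$ gapweld close --draft fx/draft.fa --datasets fx/dataset.fa \
      --out run/run --negative-gaps
gapweld: round 1: 20 gaps seen, 20 closed (0 deferred)
gapweld: round 2: 0 gaps seen, 0 closed (0 deferred)
closed 20 of 20 gaps in 2 round(s); +2335 / -597 bases

$ gapweld validate --before fx/draft.fa --after run/run.round2.fasta \
      --log run/run.round1.tsv --log run/run.round2.tsv \
      --reference fx/reference.fa --out run/validation.tsv
validated 20 of 20 closed gaps
```

All 20 gaps close in the first round; `+2335 / -597 bases` is the total
sequence inserted and removed (removals come from the five overlapping
"negative" gaps and from replaced flank tails), and the edited assembly is
byte-identical to the reference genome the fixture was derived from. Each
round writes `run.roundK.fasta` (edited assembly), `run.roundK.log`
(human-readable, one block per gap with both hits and the inserted
sequence) and `run.roundK.tsv` (machine-parseable); `run.stats.tsv`
summarises gaps closed and bases inserted/removed per round.

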