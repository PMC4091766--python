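"""Synthetic reference/draft/dataset triples with known ground truth.

The generator emulates the inputs a gap closer sees in practice: a finished
reference genome, a draft derived from it whose scaffolds contain N-run gaps
of three kinds, and a dataset of fragments (standing in for alternative
assemblies or long reads) that span the gap regions, optionally carrying
substitution errors and reverse-complemented orientations, plus unrelated
decoy fragments.

Gap kinds mirror how real drafts go wrong:

* ``positive``  — ``true_fill_length`` reference bases were replaced by an
  N-run: closing must insert sequence.
* ``zero``      — an N-run was inserted between adjacent reference bases:
  closing just deletes the Ns.
* ``negative``  — ``overlap`` reference bases are duplicated on both sides
  of an N-run (overlapping contig ends): closing removes the Ns and one
  copy of the duplication.

With ``substitution_rate = 0`` the expected post-closure sequence is exactly
the reference, which is what end-to-end tests assert.  All sampling flows
through explicitly seeded generators, so every artifact is byte-identical
across runs for a given spec.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .assembly_model import SeqRecord, revcomp, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GapSpec:
    """One planned gap: where it goes and what closing it should restore."""

    position: float  # fraction of genome length
    n_run: int
    kind: Literal["positive", "zero", "negative"]
    fill_length: int = 0  # positive gaps: reference bases hidden by the N-run
    overlap: int = 0  # negative gaps: bases duplicated on both sides

    def __post_init__(self) -> None:
        if not (0 < self.position < 1):
            raise ValueError("gap position must be a fraction in (0, 1)")
        if self.n_run < 1:
            raise ValueError("n_run must be >= 1")
        if self.kind == "positive" and self.fill_length < 1:
            raise ValueError("positive gaps need fill_length >= 1")
        if self.kind == "negative" and self.overlap < 1:
            raise ValueError("negative gaps need overlap >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one synthetic reference/draft/dataset triple."""

    genome_length: int = 100_000
    gc_content: float = 0.5
    seed: int = 0
    gaps: tuple[GapSpec, ...] = ()
    fragment_length_mean: float = 2000.0
    fragment_length_sd: float = 200.0
    coverage: float = 2.0  # spanning fragments per gap region
    substitution_rate: float = 0.0
    reverse_complement_fraction: float = 0.0
    decoys: int = 5
    end_length: int = 300  # flank context each fragment must span

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 0.2):
            raise ValueError("substitution_rate must be in [0, 0.2]")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")


@dataclass(frozen=True)
class GapTruth:
    """Ground truth for one generated gap, in reference and draft coordinates."""

    index: int
    kind: str
    ref_pos: int  # junction point / fill start on the reference
    draft_start: int  # N-run interval in the final draft
    draft_end: int
    fill_seq: str  # what a correct closure inserts ("" for zero/negative)
    overlap: int


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def make_reference(spec: FixtureSpec) -> SeqRecord:
    """Pseudorandom reference genome at the target GC content."""
    rng = np.random.default_rng(spec.seed)
    return SeqRecord("reference", _random_seq(rng, spec.genome_length, spec.gc_content))


def make_gapped_draft(reference: SeqRecord, spec: FixtureSpec) -> tuple[SeqRecord, list[GapTruth]]:
    """Derive a gapped draft scaffold from the reference, plus a truth table."""
    gaps = sorted(spec.gaps, key=lambda g: g.position)
    n = len(reference.seq)
    # reference interval each gap consumes: [pos, pos + fill_length) for
    # positive gaps, the single point pos otherwise
    placed: list[tuple[int, int, GapSpec]] = []
    prev_end = spec.end_length
    for g in gaps:
        pos = int(round(g.position * n))
        span = g.fill_length if g.kind == "positive" else 0
        reach_left = max(g.overlap, spec.end_length)
        if pos - reach_left < prev_end:
            raise ValueError(f"gap at fraction {g.position} leaves too little flank")
        placed.append((pos, pos + span, g))
        prev_end = pos + span + spec.end_length
    if placed and placed[-1][1] + spec.end_length > n:
        raise ValueError("last gap leaves too little right flank")

    pieces: list[str] = []
    truths: list[GapTruth] = []
    cursor = 0
    offset = 0  # draft minus reference coordinate
    for i, (start, end, g) in enumerate(placed):
        pieces.append(reference.seq[cursor:start])
        draft_start = start + offset
        if g.kind == "positive":
            pieces.append("N" * g.n_run)
            fill = reference.seq[start:end]
            offset += g.n_run - g.fill_length
        elif g.kind == "zero":
            pieces.append("N" * g.n_run)
            fill = ""
            offset += g.n_run
        else:  # negative: duplicate the overlap on the right of the N-run
            pieces.append("N" * g.n_run)
            pieces.append(reference.seq[start - g.overlap : start])
            fill = ""
            offset += g.n_run + g.overlap
        truths.append(
            GapTruth(index=i, kind=g.kind, ref_pos=start,
                     draft_start=draft_start, draft_end=draft_start + g.n_run,
                     fill_seq=fill, overlap=g.overlap if g.kind == "negative" else 0)
        )
        cursor = end
    pieces.append(reference.seq[cursor:])
    return SeqRecord("draft", "".join(pieces)), truths


def make_dataset(reference: SeqRecord, spec: FixtureSpec) -> list[SeqRecord]:
    """Fragments spanning every gap region, plus error model and decoys.

    Every gap gets at least one fragment covering its true reference region
    plus ``end_length`` context on each side, so both flanks can anchor.
    Substitutions are sampled per base at ``substitution_rate``; a
    ``reverse_complement_fraction`` of fragments is flipped.  Decoys come
    from an unrelated random sequence with matched length/GC so threshold
    filters are genuinely exercised.
    """
    rng = np.random.default_rng(spec.seed + 1)
    # separate stream for the error model: fragment placement is identical
    # across substitution rates, so error-free and noisy datasets correspond
    # fragment-by-fragment
    mut_rng = np.random.default_rng(spec.seed + 2)
    n = len(reference.seq)
    frags: list[SeqRecord] = []
    counter = 0
    for g in sorted(spec.gaps, key=lambda x: x.position):
        pos = int(round(g.position * n))
        span = g.fill_length if g.kind == "positive" else 0
        need_start = max(0, pos - max(g.overlap, spec.end_length))
        need_end = min(n, pos + span + spec.end_length)
        for _ in range(max(1, int(round(spec.coverage)))):
            length = int(rng.normal(spec.fragment_length_mean, spec.fragment_length_sd))
            length = max(length, need_end - need_start)
            if length > n:
                raise ValueError("fragment longer than reference")
            lo = max(0, need_end - length)
            hi = min(need_start, n - length)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
            seq = reference.seq[start : start + length]
            seq = _mutate(mut_rng, seq, spec.substitution_rate)
            if rng.random() < spec.reverse_complement_fraction:
                seq = revcomp(seq)
            frags.append(SeqRecord(f"frag{counter}", seq))
            counter += 1
    decoy_rng = np.random.default_rng(spec.seed + 10_007)
    for d in range(spec.decoys):
        length = max(50, int(decoy_rng.normal(spec.fragment_length_mean,
                                              spec.fragment_length_sd)))
        frags.append(SeqRecord(f"decoy{d}", _random_seq(decoy_rng, length, spec.gc_content)))
    return frags


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.nonzero(mask)[0]:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def standard_gap_mix(
    n_gaps: int = 20,
    rng_seed: int = 0,
    fill_range: tuple[int, int] = (10, 400),
    overlap_range: tuple[int, int] = (5, 60),
    n_run_range: tuple[int, int] = (5, 50),
) -> tuple[GapSpec, ...]:
    """An evenly spaced mix of positive/zero/negative gaps.

    Kinds cycle positive, positive, zero, negative so positives dominate (as
    they do in real drafts) while the other kinds are always represented.
    """
    rng = np.random.default_rng(rng_seed)
    kinds = ["positive", "positive", "zero", "negative"]
    specs = []
    for i in range(n_gaps):
        kind = kinds[i % len(kinds)]
        position = (i + 1) / (n_gaps + 1)
        n_run = int(rng.integers(*n_run_range))
        if kind == "positive":
            specs.append(GapSpec(position, n_run, "positive",
                                 fill_length=int(rng.integers(*fill_range))))
        elif kind == "zero":
            specs.append(GapSpec(position, n_run, "zero"))
        else:
            specs.append(GapSpec(position, n_run, "negative",
                                 overlap=int(rng.integers(*overlap_range))))
    return tuple(specs)


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write reference.fa, draft.fa, dataset.fa and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(spec)
    draft, truths = make_gapped_draft(reference, spec)
    dataset = make_dataset(reference, spec)
    paths = {
        "reference": outdir / "reference.fa",
        "draft": outdir / "draft.fa",
        "dataset": outdir / "dataset.fa",
        "truth": outdir / "truth.tsv",
    }
    write_fasta([reference], paths["reference"])
    write_fasta([draft], paths["draft"])
    write_fasta(dataset, paths["dataset"])
    pd.DataFrame(
        [{"index": t.index, "kind": t.kind, "ref_pos": t.ref_pos,
          "draft_start": t.draft_start, "draft_end": t.draft_end,
          "overlap": t.overlap, "fill_seq": t.fill_seq or "."}
         for t in truths]
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
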