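"""Sequence containers, FASTA I/O, gap discovery and coordinate bookkeeping.

A *gap* is a maximal run of ``N`` characters inside a scaffold, marking
unsequenced bases between the contigs the scaffold joins.  All coordinates in
this package are 0-based half-open; human-readable logs convert to 1-based
inclusive (stated in their headers).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

# Uppercase IUPAC nucleotide codes; only N defines gaps, the rest are kept
# verbatim so degenerate bases survive round-trips.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

_NONIUPAC_RE = re.compile(f"[^{''.join(sorted(IUPAC_CODES))}]")


class AssemblyError(ValueError):
    """Raised for malformed sequence input or coordinate bookkeeping bugs."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (scaffold or dataset contig/read)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AssemblyError("sequence record has an empty id")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Gap:
    """A maximal N-run inside a scaffold.

    ``fillable`` is False for runs touching either end of the scaffold: such
    runs have no flank on one side, so there is nothing to anchor an
    alignment to and they are reported but never edited.
    """

    scaffold_id: str
    start: int
    end: int
    fillable: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, delta: int) -> "Gap":
        return Gap(self.scaffold_id, self.start + delta, self.end + delta, self.fillable)


@dataclass(frozen=True)
class FlankPair:
    """The alignable sequence immediately left/right of one gap.

    ``trim`` bases adjacent to the gap are skipped on each side (contig edges
    are frequently low quality); the spans record exactly which scaffold
    interval each flank was copied from.  Flanks never contain N: extraction
    stops before a neighbouring gap's run.
    """

    gap: Gap
    left_seq: str
    right_seq: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    trim: int


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; the record id is the header token before the
    first whitespace.  Empty files, duplicate ids and non-IUPAC characters
    are errors.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = _NONIUPAC_RE.search(seq)
        if bad:
            raise AssemblyError(
                f"{path}: record {rec.id!r} has non-IUPAC character "
                f"{bad.group()!r} at position {bad.start() + 1}"
            )
        if rec.id in seen:
            raise AssemblyError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=seq))
    if not records:
        raise AssemblyError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with the given line width; round-trips exactly."""
    if not records:
        raise AssemblyError("refusing to write an empty FASTA file")
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


def find_gaps(record: SeqRecord, min_gap_run: int = 1) -> list[Gap]:
    """Locate maximal N-runs of length >= ``min_gap_run``, sorted by start."""
    if min_gap_run < 1:
        raise AssemblyError("min_gap_run must be >= 1")
    seq = record.seq
    n = len(seq)
    gaps: list[Gap] = []
    i = 0
    while i < n:
        if seq[i] == "N":
            j = i + 1
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_gap_run:
                fillable = i > 0 and j < n
                gaps.append(Gap(record.id, i, j, fillable))
            i = j
        else:
            i += 1
    return gaps


def extract_flanks(record: SeqRecord, gap: Gap, end_length: int, trim: int = 0) -> FlankPair:
    """Copy up to ``end_length`` alignable bases from each side of a gap.

    ``trim`` shifts each window away from the gap (the ``trim`` bases nearest
    the gap are skipped as likely low quality); the window keeps its full
    ``end_length`` width.  Flanks are truncated at the scaffold bounds and at
    any interior N, so a flank never bridges into a neighbouring gap.  Either
    flank may come back empty (caller decides whether that makes the gap
    unalignable).
    """
    if not gap.fillable:
        raise AssemblyError(f"gap [{gap.start},{gap.end}) in {gap.scaffold_id} is not fillable")
    if not (end_length > trim >= 0):
        raise AssemblyError("require end_length > trim >= 0")
    seq = record.seq
    want = end_length

    left_end = gap.start - trim
    left_start = max(0, left_end - want)
    # stop at interior N: keep only the N-free suffix of the window
    window = seq[left_start:left_end] if left_end > 0 else ""
    cut = window.rfind("N")
    if cut != -1:
        left_start += cut + 1
        window = window[cut + 1 :]
    left_seq = window

    right_start = gap.end + trim
    right_end = min(len(seq), right_start + want)
    window = seq[right_start:right_end] if right_start < len(seq) else ""
    cut = window.find("N")
    if cut != -1:
        right_end = right_start + cut
        window = window[:cut]
    right_seq = window

    return FlankPair(
        gap=gap,
        left_seq=left_seq,
        right_seq=right_seq,
        left_span=(left_start, max(left_start, left_end)),
        right_span=(min(right_start, right_end), right_end),
        trim=trim,
    )


def shift_downstream(gaps: Iterable[Gap], edit_at: int, delta: int) -> list[Gap]:
    """Shift gaps at/after a scaffold edit point by ``delta`` bases."""
    out: list[Gap] = []
    for g in gaps:
        if g.start < edit_at < g.end:
            raise AssemblyError(f"edit point {edit_at} falls inside gap [{g.start},{g.end})")
        if g.start >= edit_at:
            ng = g.shifted(delta)
            if ng.start < 0:
                raise AssemblyError("coordinate shift produced a negative offset")
            out.append(ng)
        else:
            out.append(g)
    return out
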