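"""Pair flank hits into fill candidates, pick the best, build and apply edits.

Geometry, in the *oriented* subject frame (the subject itself for forward
candidates, its reverse complement for reverse ones): the left flank must hit
before the right flank; the subject sequence between the two hits is the fill.

    insert_len = right_hit_fill_coord - left_hit_fill_coord

A negative ``insert_len`` means the true flanking contigs overlap (a
"negative gap"): closing removes the overlap instead of inserting sequence.
Scaffold bases between the aligned flank ends and the N-run (unaligned
gap-adjacent tails plus any ``trim``) are treated as removable low-quality
edge sequence and replaced by the dataset's version, which sits inside the
fill interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alignment_engine import AlignmentHit
from .assembly_model import AssemblyError, FlankPair, SeqRecord, revcomp


@dataclass(frozen=True)
class ClosureLimits:
    """Caps on how much a single closure may insert or remove."""

    max_insert: int = 500
    max_remove: int = 500
    allow_negative: bool = False
    allow_zero: bool = True
    min_query_coverage: float = 0.40  # per-hit fraction of flank that must align
    max_n_fraction: float = 0.0  # N content tolerated in the replacement

    def __post_init__(self) -> None:
        if self.max_insert < 0 or self.max_remove < 0:
            raise ValueError("max_insert and max_remove must be >= 0")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")


@dataclass(frozen=True)
class FillCandidate:
    """One geometrically valid (left hit, right hit) pairing for a gap."""

    gap_scaffold: str
    subject_id: str
    orientation: str
    left_hit: AlignmentHit
    right_hit: AlignmentHit
    insert_len: int
    removed_left: int
    removed_right: int
    insert_seq: str
    combined_score: float


@dataclass(frozen=True)
class ClosureEdit:
    """A concrete scaffold edit: replace [cut_start, cut_end) by ``replacement``."""

    scaffold_id: str
    cut_start: int
    cut_end: int
    replacement: str

    @property
    def delta(self) -> int:
        return len(self.replacement) - (self.cut_end - self.cut_start)


def _oriented(hit: AlignmentHit, subject_len: int) -> tuple[int, int]:
    """Subject interval of a hit in the oriented (query-forward) frame."""
    if hit.orientation == "forward":
        return hit.s_start, hit.s_end
    return subject_len - hit.s_end, subject_len - hit.s_start


def enumerate_candidates(
    left_hits: Sequence[AlignmentHit],
    right_hits: Sequence[AlignmentHit],
    flanks: FlankPair,
    subjects: dict[str, str],
    limits: ClosureLimits,
    scaffold_len: int | None = None,
) -> list[FillCandidate]:
    """All (left, right) hit pairs that yield a valid fill geometry.

    Hits must share subject and orientation, sit in flank order in the
    oriented subject frame, cover enough of their flank, and respect the
    insert/removal limits.  Returns an empty list when nothing qualifies.
    """
    len_l, len_r = len(flanks.left_seq), len(flanks.right_seq)
    gap = flanks.gap
    out: list[FillCandidate] = []
    for lh in left_hits:
        if (lh.q_end - lh.q_start) < limits.min_query_coverage * len_l:
            continue
        subj = subjects.get(lh.subject_id)
        if subj is None:
            continue
        slen = len(subj)
        lt_start, lt_end = _oriented(lh, slen)
        for rh in right_hits:
            if rh.subject_id != lh.subject_id or rh.orientation != lh.orientation:
                continue
            if (rh.q_end - rh.q_start) < limits.min_query_coverage * len_r:
                continue
            rt_start, rt_end = _oriented(rh, slen)
            if not (lt_start <= rt_start and lt_end <= rt_end):
                continue  # hits out of flank order on the subject
            insert_len = rt_start - lt_end
            if insert_len > limits.max_insert or insert_len < -limits.max_remove:
                continue
            if insert_len < 0 and not limits.allow_negative:
                continue
            if insert_len == 0 and not limits.allow_zero:
                continue
            removed_left = flanks.trim + (len_l - lh.q_end)
            removed_right = flanks.trim + rh.q_start
            overlap = max(-insert_len, 0)
            if removed_left > limits.max_remove:
                continue
            if removed_right + overlap > limits.max_remove:
                continue
            if scaffold_len is not None and gap.end + removed_right + overlap > scaffold_len:
                continue  # overlap removal would run off the scaffold
            if gap.start - removed_left < 0:
                continue
            if insert_len > 0:
                oriented_subj = subj if lh.orientation == "forward" else revcomp(subj)
                insert_seq = oriented_subj[lt_end:rt_start]
                if insert_seq:
                    n_frac = insert_seq.count("N") / len(insert_seq)
                    if n_frac > limits.max_n_fraction:
                        continue
            else:
                insert_seq = ""
            out.append(
                FillCandidate(
                    gap_scaffold=gap.scaffold_id,
                    subject_id=lh.subject_id,
                    orientation=lh.orientation,
                    left_hit=lh,
                    right_hit=rh,
                    insert_len=insert_len,
                    removed_left=removed_left,
                    removed_right=removed_right,
                    insert_seq=insert_seq,
                    combined_score=lh.score + rh.score,
                )
            )
    return out


def select_best(candidates: Sequence[FillCandidate]) -> FillCandidate | None:
    """Highest combined score; deterministic, order-independent tie-break."""
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda c: (
            -c.combined_score,
            -min(c.left_hit.score, c.right_hit.score),
            abs(c.insert_len),
            c.subject_id,
            c.left_hit.s_start,
            c.orientation,
        ),
    )


def make_edit(candidate: FillCandidate, flanks: FlankPair) -> ClosureEdit:
    """Translate a candidate's geometry into a scaffold edit.

    The cut always contains the whole N-run; for negative gaps the overlap
    is removed from the right side under a local-collinearity assumption
    (no indel correction at the junction).
    """
    gap = flanks.gap
    cut_start = gap.start - candidate.removed_left
    cut_end = gap.end + candidate.removed_right + max(-candidate.insert_len, 0)
    if cut_start < 0:
        raise AssemblyError("edit escapes scaffold start (geometry bug)")
    return ClosureEdit(
        scaffold_id=gap.scaffold_id,
        cut_start=cut_start,
        cut_end=cut_end,
        replacement=candidate.insert_seq,
    )


def apply_edit(record: SeqRecord, edit: ClosureEdit) -> SeqRecord:
    """Splice ``edit.replacement`` into the scaffold over [cut_start, cut_end)."""
    if edit.scaffold_id != record.id:
        raise AssemblyError(f"edit targets {edit.scaffold_id!r}, record is {record.id!r}")
    if not (0 <= edit.cut_start <= edit.cut_end <= len(record.seq)):
        raise AssemblyError(
            f"cut [{edit.cut_start},{edit.cut_end}) out of bounds for {record.id!r} "
            f"(length {len(record.seq)})"
        )
    seq = record.seq[: edit.cut_start] + edit.replacement + record.seq[edit.cut_end :]
    return SeqRecord(record.id, seq)
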