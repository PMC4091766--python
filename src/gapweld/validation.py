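"""Reference-based correctness check for closed gaps.

A closure is *validated* against a trusted reference genome when three
criteria all hold:

1. both flanking regions align to the reference over at least
   ``min_flank_coverage`` of their length (default 40%, measured against the
   contig-end length the closer used);
2. the flanks and the inserted sequence each align with identity at or above
   ``min_identity`` (the same threshold the closer used);
3. the closed region (left flank + insert + right flank) matches the
   reference better than the flanks joined *without* the insertion did.

Criteria 2 and 3 measure an *effective* identity: identical bases divided by
alignment columns plus unaligned query bases.  A plain local-alignment
identity misbehaves in both directions — a wrong insert can carry a tiny
100%-identity spurious hit (criterion 2), and the un-inserted join scores
100% whenever a single flank aligns perfectly, which would make criterion 3
unsatisfiable even for a perfect fill.  The effective identity penalises
mismatches, indels and missing coverage together, so inserting the true
sequence strictly improves it and a scrambled insert cannot pass.
For closures with an empty insert (negative and zero-length fills) the
joined region *is* the insert-free region, so criterion 3 degrades to >=.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment_engine import AlignmentHit, AlignmentParams, BlastIndex, align_queries, build_index
from .assembly_model import SeqRecord
from .driver import STATUS_CLOSED, ClosureRecord

_SHORT_QUERY = 30  # below this, blastn-short is needed to seed at all
_PERMISSIVE = AlignmentParams(min_score=0.0, max_evalue=1e4, min_identity=0.0)


@dataclass(frozen=True)
class ValidationThresholds:
    min_flank_coverage: float = 0.40
    min_identity: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.min_flank_coverage <= 1):
            raise ValueError("min_flank_coverage must be in (0, 1]")
        if not (0 < self.min_identity <= 100):
            raise ValueError("min_identity must be in (0, 100]")


@dataclass(frozen=True)
class ValidationVerdict:
    gap_id: str
    criterion1: bool
    criterion2: bool
    criterion3: bool
    identity_before: float
    identity_after: float
    reason: str = ""

    @property
    def overall(self) -> bool:
        return self.criterion1 and self.criterion2 and self.criterion3


def _batched_hits(
    queries: Sequence[tuple[str, str]], index: BlastIndex, threads: int = 1
) -> dict[str, list[AlignmentHit]]:
    """Permissive alignment of mixed-length queries; short ones use blastn-short."""
    longq = [(q, s) for q, s in queries if len(s) >= _SHORT_QUERY]
    shortq = [(q, s) for q, s in queries if 0 < len(s) < _SHORT_QUERY]
    hits: list[AlignmentHit] = []
    if longq:
        hits += align_queries(longq, index, _PERMISSIVE, threads=threads,
                              apply_score_filters=False)
    if shortq:
        hits += align_queries(shortq, index, _PERMISSIVE, threads=threads,
                              task="blastn-short", apply_score_filters=False)
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    return by_query


def _effective_identity(hits: Sequence[AlignmentHit], query_len: int) -> float:
    """Best (identical bases) / (alignment columns + unaligned query bases)."""
    best = 0.0
    for h in hits:
        unaligned = query_len - (h.q_end - h.q_start)
        denom = h.aln_length + unaligned
        if denom > 0:
            best = max(best, 100.0 * h.n_ident / denom)
    return best


def _covered(hits: Sequence[AlignmentHit], query_len: int, min_cov: float) -> bool:
    return any((h.q_end - h.q_start) >= min_cov * query_len for h in hits)


def _verdict_from_hits(
    gap_id: str,
    left_flank: str,
    insert_seq: str,
    right_flank: str,
    hits: dict[str, list[AlignmentHit]],
    prefix: str,
    thresholds: ValidationThresholds,
) -> ValidationVerdict:
    hl = hits.get(f"{prefix}L", [])
    hr = hits.get(f"{prefix}R", [])
    hi = hits.get(f"{prefix}I", [])
    hj = hits.get(f"{prefix}J", [])
    hb = hits.get(f"{prefix}B", [])

    c1 = _covered(hl, len(left_flank), thresholds.min_flank_coverage) and _covered(
        hr, len(right_flank), thresholds.min_flank_coverage
    )
    idents = [_effective_identity(hl, len(left_flank)),
              _effective_identity(hr, len(right_flank))]
    if insert_seq:
        idents.append(_effective_identity(hi, len(insert_seq)))
    c2 = all(x >= thresholds.min_identity for x in idents)

    joined_len = len(left_flank) + len(insert_seq) + len(right_flank)
    before_len = len(left_flank) + len(right_flank)
    after = _effective_identity(hj, joined_len)
    before = _effective_identity(hb, before_len)
    c3 = after > before if insert_seq else after >= before

    reason = ""
    if not (hl and hr):
        reason = "flank_unalignable"
    return ValidationVerdict(gap_id, c1, c2, c3, before, after, reason)


def validate_closure(
    left_flank: str,
    insert_seq: str,
    right_flank: str,
    reference: SeqRecord | Sequence[SeqRecord],
    thresholds: ValidationThresholds = ValidationThresholds(),
    index: BlastIndex | None = None,
) -> ValidationVerdict:
    """Apply the three criteria to one closed region.

    ``index`` may carry a prebuilt reference database; otherwise one is
    formatted in a temporary directory.
    """
    refs = [reference] if isinstance(reference, SeqRecord) else list(reference)
    queries = [("vL", left_flank), ("vR", right_flank),
               ("vJ", left_flank + insert_seq + right_flank),
               ("vB", left_flank + right_flank)]
    if insert_seq:
        queries.append(("vI", insert_seq))
    if index is not None:
        hits = _batched_hits(queries, index)
    else:
        with tempfile.TemporaryDirectory(prefix="gapweld_val_") as tmp:
            hits = _batched_hits(queries, build_index(refs, tmp))
    return _verdict_from_hits("gap", left_flank, insert_seq, right_flank, hits, "v", thresholds)


def validate_all(
    draft_before: Sequence[SeqRecord],
    draft_after: Sequence[SeqRecord],
    records: Sequence[ClosureRecord],
    reference: SeqRecord | Sequence[SeqRecord],
    thresholds: ValidationThresholds = ValidationThresholds(),
    threads: int = 1,
) -> pd.DataFrame:
    """Verdicts for every closed gap in ``records``, plus a totals row.

    Closed regions are reconstructed from the log records (flank sequences
    and inserted sequence are stored there), so no coordinate archaeology
    across rounds is needed.  The final row (``round == "total"``) reports
    n validated (``overall``) out of n closed (``n_closed``).
    """
    refs = [reference] if isinstance(reference, SeqRecord) else list(reference)
    closed = [r for r in records if r.status == STATUS_CLOSED]
    rows: list[dict] = []
    if closed:
        queries: list[tuple[str, str]] = []
        for i, r in enumerate(closed):
            p = f"c{i}"
            queries += [(f"{p}L", r.left_flank_seq), (f"{p}R", r.right_flank_seq),
                        (f"{p}J", r.left_flank_seq + r.insert_seq + r.right_flank_seq),
                        (f"{p}B", r.left_flank_seq + r.right_flank_seq)]
            if r.insert_seq:
                queries.append((f"{p}I", r.insert_seq))
        with tempfile.TemporaryDirectory(prefix="gapweld_val_") as tmp:
            index = build_index(refs, tmp)
            hits = _batched_hits(queries, index, threads=threads)
        for i, r in enumerate(closed):
            gap_id = f"{r.scaffold_id}:{r.gap_ordinal}:r{r.round}"
            v = _verdict_from_hits(gap_id, r.left_flank_seq, r.insert_seq,
                                   r.right_flank_seq, hits, f"c{i}", thresholds)
            rows.append(
                {"round": r.round, "scaffold_id": r.scaffold_id,
                 "gap_ordinal": r.gap_ordinal,
                 "criterion1": v.criterion1, "criterion2": v.criterion2,
                 "criterion3": v.criterion3,
                 "identity_before": v.identity_before,
                 "identity_after": v.identity_after,
                 "overall": v.overall}
            )
    n_valid = sum(1 for row in rows if row["overall"])
    counts = {f"criterion{k}": sum(r[f"criterion{k}"] for r in rows) for k in (1, 2, 3)}
    rows.append(
        {"round": "total", "scaffold_id": "", "gap_ordinal": len(closed),
         **counts,
         "identity_before": float("nan"), "identity_after": float("nan"),
         "overall": n_valid}
    )
    cols = ["round", "scaffold_id", "gap_ordinal", "criterion1", "criterion2",
            "criterion3", "identity_before", "identity_after", "overall"]
    return pd.DataFrame(rows, columns=cols)
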