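"""Multi-round, conflict-safe orchestration of gap closing.

Gaps close to each other are the reason for rounds: closing one gap edits
scaffold sequence that may serve as the *query flank* of a neighbour.  Within
a round a gap is therefore eligible only if neither of its flank windows
(``end_length`` on each side) touches an interval already edited this round
on the same scaffold; everyone else is deferred to the next round, which
re-scans the edited assembly from scratch.  Rounds stop when one closes
nothing or ``max_rounds`` is reached.  Each round emits a FASTA, a
human-readable log and a machine-parseable TSV; a final statistics table
summarises the run.  The whole pipeline is deterministic: identical inputs
produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment_engine import (
    AlignmentHit,
    AlignmentParams,
    BlastIndex,
    align_queries,
    build_index,
)
from .assembly_model import (
    AssemblyError,
    FlankPair,
    Gap,
    SeqRecord,
    extract_flanks,
    find_gaps,
    read_fasta,
    write_fasta,
)
from .closure_core import (
    ClosureEdit,
    ClosureLimits,
    enumerate_candidates,
    make_edit,
    select_best,
)

logger = logging.getLogger("gapweld")

STATUS_CLOSED = "closed"
STATUS_NO_CANDIDATE = "no_candidate"
STATUS_DEFERRED = "deferred_conflict"
STATUS_UNALIGNABLE = "unalignable"


@dataclass(frozen=True)
class RunConfig:
    """Everything one closing run needs; no randomness anywhere."""

    draft_path: str
    dataset_paths: tuple[str, ...]
    output_prefix: str
    end_length: int = 300
    trim: int = 0
    align: AlignmentParams = field(default_factory=AlignmentParams)
    limits: ClosureLimits = field(default_factory=ClosureLimits)
    max_rounds: int = 3
    min_flank: int = 20
    fasta_width: int = 70
    threads: int = 1

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if not (self.end_length > self.trim):
            raise ValueError("end_length must exceed trim")


@dataclass
class ClosureRecord:
    """Log entry for one gap's outcome in one round.

    Coordinates are 0-based half-open in the round-*input* assembly.  The
    flank sequences actually used as alignment queries are stored so closed
    regions can be reconstructed from the log alone (validation needs this).
    """

    round: int
    scaffold_id: str
    gap_ordinal: int
    gap_start: int
    gap_end: int
    gap_length: int
    status: str
    subject_id: str = ""
    orientation: str = ""
    left_hit: AlignmentHit | None = None
    right_hit: AlignmentHit | None = None
    insert_len: int | None = None
    removed_left: int | None = None
    removed_right: int | None = None
    insert_seq: str = ""
    left_flank_seq: str = ""
    right_flank_seq: str = ""
    cut_start: int | None = None
    cut_end: int | None = None
    note: str = ""


@dataclass
class RunStats:
    """Per-round and total closure accounting."""

    rounds: list[dict] = field(default_factory=list)

    def add_round(self, round_no: int, gaps_before: int, closed: int,
                  inserted: int, removed: int, negative: int) -> None:
        self.rounds.append(
            {
                "round": round_no,
                "gaps_before": gaps_before,
                "gaps_closed": closed,
                "gaps_remaining": gaps_before - closed,
                "bases_inserted": inserted,
                "bases_removed": removed,
                "negative_gaps_closed": negative,
            }
        )

    @property
    def totals(self) -> dict:
        keys = ("gaps_closed", "bases_inserted", "bases_removed", "negative_gaps_closed")
        tot = {k: sum(r[k] for r in self.rounds) for k in keys}
        tot["gaps_before"] = self.rounds[0]["gaps_before"] if self.rounds else 0
        tot["gaps_remaining"] = self.rounds[-1]["gaps_remaining"] if self.rounds else 0
        return tot

    def to_frame(self) -> pd.DataFrame:
        cols = ["round", "gaps_before", "gaps_closed", "gaps_remaining",
                "bases_inserted", "bases_removed", "negative_gaps_closed"]
        rows = [dict(r) for r in self.rounds]
        t = self.totals
        rows.append({"round": "total", **{c: t.get(c, "") for c in cols if c != "round"}})
        return pd.DataFrame(rows, columns=cols)


def _overlaps(a: int, b: int, c: int, d: int) -> bool:
    return a < d and c < b


def run_round(
    assembly: Sequence[SeqRecord],
    indices: Sequence[BlastIndex],
    config: RunConfig,
    round_no: int,
) -> tuple[list[SeqRecord], list[ClosureRecord]]:
    """Close every eligible gap once; defer conflicting neighbours.

    All bookkeeping is in round-input coordinates: flanks are extracted
    before any edit, and edits are spliced in together at the end, so a
    deferred gap's query sequence is guaranteed untouched.
    """
    # 1. discover gaps and extract flanks everywhere
    per_scaffold: dict[str, list[Gap]] = {}
    flank_map: dict[tuple[str, int], FlankPair] = {}
    queries: list[tuple[str, str]] = []
    qmeta: dict[str, tuple[str, int, str]] = {}
    for rec in assembly:
        gaps = find_gaps(rec)
        per_scaffold[rec.id] = gaps
        for k, gap in enumerate(gaps):
            if not gap.fillable:
                continue
            fp = extract_flanks(rec, gap, config.end_length, config.trim)
            flank_map[(rec.id, k)] = fp
            if len(fp.left_seq) >= config.min_flank and len(fp.right_seq) >= config.min_flank:
                for side, seq in (("L", fp.left_seq), ("R", fp.right_seq)):
                    qid = f"q{len(queries)}"
                    queries.append((qid, seq))
                    qmeta[qid] = (rec.id, k, side)

    # 2. one batched alignment per dataset index, hits pooled
    hits_by_gap: dict[tuple[str, int, str], list[AlignmentHit]] = {}
    subjects: dict[str, str] = {}
    for index in indices:
        subjects.update(index.subjects)
        for h in align_queries(queries, index, config.align, threads=config.threads):
            hits_by_gap.setdefault(qmeta[h.query_id], []).append(h)

    # 3. per scaffold, resolve gaps in coordinate order with conflict windows
    records: list[ClosureRecord] = []
    new_assembly: list[SeqRecord] = []
    for rec in assembly:
        edited: list[tuple[int, int]] = []
        edits: list[ClosureEdit] = []
        for k, gap in enumerate(per_scaffold[rec.id]):
            cr = ClosureRecord(
                round=round_no, scaffold_id=rec.id, gap_ordinal=k,
                gap_start=gap.start, gap_end=gap.end, gap_length=gap.length,
                status=STATUS_NO_CANDIDATE,
            )
            if not gap.fillable:
                cr.status = STATUS_UNALIGNABLE
                cr.note = "boundary_gap"
                records.append(cr)
                continue
            fp = flank_map[(rec.id, k)]
            cr.left_flank_seq, cr.right_flank_seq = fp.left_seq, fp.right_seq
            if len(fp.left_seq) < config.min_flank or len(fp.right_seq) < config.min_flank:
                cr.status = STATUS_UNALIGNABLE
                cr.note = f"flank_below_min_flank={config.min_flank}"
                records.append(cr)
                continue
            win_l = (gap.start - config.end_length, gap.start)
            win_r = (gap.end, gap.end + config.end_length)
            conflict = next(
                (iv for iv in edited
                 if _overlaps(*win_l, *iv) or _overlaps(*win_r, *iv)),
                None,
            )
            if conflict is not None:
                cr.status = STATUS_DEFERRED
                cr.note = f"conflicts_with_edited_interval={conflict[0]}..{conflict[1]}"
                records.append(cr)
                continue
            left_hits = hits_by_gap.get((rec.id, k, "L"), [])
            right_hits = hits_by_gap.get((rec.id, k, "R"), [])
            cands = enumerate_candidates(
                left_hits, right_hits, fp, subjects, config.limits,
                scaffold_len=len(rec.seq),
            )
            best = select_best(cands)
            if best is None:
                cr.status = STATUS_NO_CANDIDATE
                records.append(cr)
                continue
            edit = make_edit(best, fp)
            # a wide removal can escape the flank windows: re-check the cut itself
            if any(_overlaps(edit.cut_start, edit.cut_end, *iv) for iv in edited):
                cr.status = STATUS_DEFERRED
                cr.note = "cut_conflicts_with_edited_interval"
                records.append(cr)
                continue
            edits.append(edit)
            edited.append((edit.cut_start, edit.cut_end))
            cr.status = STATUS_CLOSED
            cr.subject_id = best.subject_id
            cr.orientation = best.orientation
            cr.left_hit, cr.right_hit = best.left_hit, best.right_hit
            cr.insert_len = best.insert_len
            cr.removed_left, cr.removed_right = best.removed_left, best.removed_right
            cr.insert_seq = best.insert_seq
            cr.cut_start, cr.cut_end = edit.cut_start, edit.cut_end
            records.append(cr)

        # 4. splice all edits in, left to right
        if edits:
            edits.sort(key=lambda e: e.cut_start)
            pieces: list[str] = []
            pos = 0
            for e in edits:
                pieces.append(rec.seq[pos : e.cut_start])
                pieces.append(e.replacement)
                pos = e.cut_end
            pieces.append(rec.seq[pos:])
            new_assembly.append(SeqRecord(rec.id, "".join(pieces)))
        else:
            new_assembly.append(rec)
    return new_assembly, records


def run(config: RunConfig) -> RunStats:
    """Execute the full multi-round pipeline and write all outputs.

    Round k's FASTA is round k+1's input; changes are incremental.  Writes
    ``<prefix>.round<k>.fasta``, ``.round<k>.log``, ``.round<k>.tsv`` and a
    final ``<prefix>.stats.tsv``.
    """
    assembly = read_fasta(config.draft_path)
    dataset: list[SeqRecord] = []
    seen: set[str] = set()
    for p in config.dataset_paths:
        for r in read_fasta(p):
            if r.id in seen:
                raise AssemblyError(f"duplicate sequence id {r.id!r} across pooled datasets")
            seen.add(r.id)
            dataset.append(r)

    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stats = RunStats()
    with tempfile.TemporaryDirectory(prefix="gapweld_db_") as workdir:
        index = build_index(dataset, workdir)
        for round_no in range(1, config.max_rounds + 1):
            gaps_before = sum(len(find_gaps(r)) for r in assembly)
            assembly, records = run_round(assembly, [index], config, round_no)
            closed = [r for r in records if r.status == STATUS_CLOSED]
            inserted = sum(len(r.insert_seq) for r in closed)
            removed = sum((r.cut_end - r.cut_start) for r in closed)
            negative = sum(1 for r in closed if (r.insert_len or 0) < 0)
            stats.add_round(round_no, gaps_before, len(closed), inserted, removed, negative)
            write_fasta(assembly, f"{prefix}.round{round_no}.fasta", width=config.fasta_width)
            write_log(records, f"{prefix}.round{round_no}.log", f"{prefix}.round{round_no}.tsv")
            logger.info(
                "round %d: %d gaps seen, %d closed (%d deferred)",
                round_no, gaps_before, len(closed),
                sum(1 for r in records if r.status == STATUS_DEFERRED),
            )
            if not closed:
                break
    stats.to_frame().to_csv(f"{prefix}.stats.tsv", sep="\t", index=False)
    return stats


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "round", "scaffold_id", "gap_ordinal", "gap_start", "gap_end", "gap_length",
    "status", "subject_id", "orientation",
    "left_score", "left_evalue", "left_identity",
    "left_q_start", "left_q_end", "left_s_start", "left_s_end",
    "right_score", "right_evalue", "right_identity",
    "right_q_start", "right_q_end", "right_s_start", "right_s_end",
    "insert_len", "removed_left", "removed_right",
    "cut_start", "cut_end", "insert_seq", "left_flank_seq", "right_flank_seq",
    "note",
]

_MISSING = "."


def _hit_cells(h: AlignmentHit | None) -> list[str]:
    if h is None:
        return [_MISSING] * 7
    return [f"{h.score:g}", f"{h.evalue:g}", f"{h.identity:g}",
            str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end)]


def write_log(records: Sequence[ClosureRecord], path: str | Path,
              tsv_path: str | Path | None = None) -> None:
    """Write the human-readable round log, plus a TSV companion.

    The text log uses 1-based inclusive coordinates (matching BLAST
    convention); the TSV keeps the package's 0-based half-open internals.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# gapweld round log; coordinates 1-based inclusive\n")
        for r in records:
            fh.write(
                f"gap {r.gap_ordinal + 1} scaffold={r.scaffold_id} "
                f"interval={r.gap_start + 1}..{r.gap_end} length={r.gap_length} "
                f"status={r.status}\n"
            )
            if r.status == STATUS_CLOSED:
                fh.write(
                    f"  subject={r.subject_id} orientation={r.orientation} "
                    f"insert_len={r.insert_len} removed_left={r.removed_left} "
                    f"removed_right={r.removed_right}\n"
                )
                for label, h in (("left ", r.left_hit), ("right", r.right_hit)):
                    assert h is not None
                    fh.write(
                        f"  {label}: score={h.score:g} evalue={h.evalue:g} "
                        f"identity={h.identity:g} q={h.q_start + 1}..{h.q_end} "
                        f"s={h.s_start + 1}..{h.s_end}\n"
                    )
                fh.write(f"  inserted={r.insert_seq or '-'}\n")
            elif r.note:
                fh.write(f"  note={r.note}\n")
    if tsv_path is None:
        tsv_path = path.with_suffix(".tsv")
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for r in records:
            w.writerow(
                [r.round, r.scaffold_id, r.gap_ordinal, r.gap_start, r.gap_end,
                 r.gap_length, r.status, r.subject_id or _MISSING,
                 r.orientation or _MISSING]
                + _hit_cells(r.left_hit) + _hit_cells(r.right_hit)
                + [x if x is not None else _MISSING
                   for x in (r.insert_len, r.removed_left, r.removed_right,
                             r.cut_start, r.cut_end)]
                + [r.insert_seq or _MISSING, r.left_flank_seq or _MISSING,
                   r.right_flank_seq or _MISSING, r.note or _MISSING]
            )


def read_log_tsv(path: str | Path) -> list[ClosureRecord]:
    """Parse a round TSV back into :class:`ClosureRecord` objects."""
    out: list[ClosureRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            def _i(key: str) -> int | None:
                v = row[key]
                return None if v == _MISSING else int(v)

            def _hit(side: str) -> AlignmentHit | None:
                if row[f"{side}_score"] == _MISSING:
                    return None
                return AlignmentHit(
                    query_id=f"{row['scaffold_id']}:{row['gap_ordinal']}:{side}",
                    subject_id=row["subject_id"],
                    q_start=int(row[f"{side}_q_start"]), q_end=int(row[f"{side}_q_end"]),
                    s_start=int(row[f"{side}_s_start"]), s_end=int(row[f"{side}_s_end"]),
                    orientation=row["orientation"],
                    score=float(row[f"{side}_score"]), evalue=float(row[f"{side}_evalue"]),
                    identity=float(row[f"{side}_identity"]),
                    aln_length=int(row[f"{side}_q_end"]) - int(row[f"{side}_q_start"]),
                )

            out.append(
                ClosureRecord(
                    round=int(row["round"]), scaffold_id=row["scaffold_id"],
                    gap_ordinal=int(row["gap_ordinal"]),
                    gap_start=int(row["gap_start"]), gap_end=int(row["gap_end"]),
                    gap_length=int(row["gap_length"]), status=row["status"],
                    subject_id="" if row["subject_id"] == _MISSING else row["subject_id"],
                    orientation="" if row["orientation"] == _MISSING else row["orientation"],
                    left_hit=_hit("left"), right_hit=_hit("right"),
                    insert_len=_i("insert_len"),
                    removed_left=_i("removed_left"), removed_right=_i("removed_right"),
                    insert_seq="" if row["insert_seq"] == _MISSING else row["insert_seq"],
                    left_flank_seq="" if row["left_flank_seq"] == _MISSING else row["left_flank_seq"],
                    right_flank_seq="" if row["right_flank_seq"] == _MISSING else row["right_flank_seq"],
                    cut_start=_i("cut_start"), cut_end=_i("cut_end"),
                    note="" if row["note"] == _MISSING else row["note"],
                )
            )
    return out
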