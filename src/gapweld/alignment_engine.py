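"""Nucleotide local alignment: BLAST+ subprocess driver plus an exact oracle.

The production path shells out to ``makeblastdb``/``blastn`` (the engine the
original gap-closing approach was built on) and parses tabular output into
strand-normalised :class:`AlignmentHit` objects.  ``oracle_align`` is an
exact affine-gap Smith-Waterman aligner used as an engine-independent
cross-check in tests; it is never on the production path for large inputs.

Tabular contract (fixed column order, ``-outfmt 6``):

    qseqid sseqid qstart qend sstart send bitscore evalue pident length nident

BLAST reports 1-based inclusive coordinates with ``sstart > send`` on
minus-strand hits; the parser converts everything to 0-based half-open
intervals on the subject *forward* strand plus an orientation flag, so one
canonical coordinate system feeds the pairing geometry downstream.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .assembly_model import SeqRecord, write_fasta

BLAST_OUTFMT = "6 qseqid sseqid qstart qend sstart send bitscore evalue pident length nident"


class EngineError(RuntimeError):
    """External aligner failure or unparseable output."""


@dataclass(frozen=True)
class AlignmentParams:
    """Thresholds and scoring passed to the alignment engine.

    ``min_score`` is a bit-score threshold (the engine's primary ranking
    statistic).  Defaults are conventional blastn settings with conservative
    hit filters; every field is user-overridable.
    """

    min_score: float = 25.0
    max_evalue: float = 1e-7
    min_identity: float = 70.0
    match: int = 1
    mismatch: int = -3
    open_gap: int = 5
    extend_gap: int = 2
    word_size: int = 11
    max_alignments: int = 50

    def __post_init__(self) -> None:
        if not (0 <= self.min_identity <= 100):
            raise ValueError("min_identity must be in [0, 100]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.max_alignments < 1:
            raise ValueError("max_alignments must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One flank-vs-dataset local alignment, forward-strand normalised.

    ``orientation == "reverse"`` means the query matched the reverse
    complement of ``subject[s_start:s_end)``.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str  # "forward" | "reverse"
    score: float
    evalue: float
    identity: float
    aln_length: int
    n_ident: int = 0


class BlastIndex:
    """Handle for a formatted BLAST nucleotide database.

    Built once per dataset and reused across rounds.  Keeps the dataset
    records in memory so candidate geometry can slice subject sequence.
    """

    def __init__(self, db_path: Path, records: Sequence[SeqRecord]):
        self.db_path = db_path
        self.subjects = {r.id: r.seq for r in records}


def _run(cmd: list[str]) -> str:
    try:
        proc = subprocess.run(cmd, capture_output=True, text=True)
    except FileNotFoundError as exc:
        raise EngineError(f"external tool not found: {cmd[0]}") from exc
    if proc.returncode != 0:
        raise EngineError(f"{cmd[0]} exited {proc.returncode}: {proc.stderr.strip()}")
    return proc.stdout


def build_index(dataset: Sequence[SeqRecord], workdir: str | Path) -> BlastIndex:
    """Format ``dataset`` as a BLAST nucleotide database under ``workdir``."""
    if not dataset:
        raise EngineError("cannot index an empty dataset")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    fasta = workdir / "dataset.fa"
    write_fasta(dataset, fasta)
    db = workdir / "dataset.db"
    _run(["makeblastdb", "-in", str(fasta), "-dbtype", "nucl", "-out", str(db)])
    return BlastIndex(db, dataset)


def align_queries(
    flanks: Sequence[tuple[str, str]],
    index: BlastIndex,
    params: AlignmentParams,
    threads: int = 1,
    task: str | None = None,
    apply_score_filters: bool = True,
) -> list[AlignmentHit]:
    """Align query sequences against an indexed dataset.

    Returns threshold-passing hits, at most ``params.max_alignments`` per
    query kept by descending score, in a deterministic order.  ``task``
    overrides blastn's task selection (validation uses ``blastn-short`` for
    short queries); ``apply_score_filters=False`` drops the score/evalue/
    identity thresholds, used when the caller wants raw coverage statistics.
    """
    if not flanks:
        return []
    for qid, seq in flanks:
        if "N" in seq:
            raise EngineError(f"query {qid!r} contains N; flanks must be real sequence")

    with tempfile.TemporaryDirectory(prefix="gapweld_q_") as tmp:
        qpath = Path(tmp) / "queries.fa"
        write_fasta([SeqRecord(qid, seq) for qid, seq in flanks], qpath)
        cmd = [
            "blastn",
            "-task", task or "blastn",
            "-query", str(qpath),
            "-db", str(index.db_path),
            "-outfmt", BLAST_OUTFMT,
            "-reward", str(params.match),
            "-penalty", str(params.mismatch),
            "-gapopen", str(params.open_gap),
            "-gapextend", str(params.extend_gap),
            "-dust", "no",
            "-max_target_seqs", str(max(params.max_alignments, 10)),
            "-num_threads", str(threads),
        ]
        if (task or "blastn") not in ("blastn-short",):
            cmd += ["-word_size", str(params.word_size)]
        if apply_score_filters:
            cmd += ["-evalue", str(params.max_evalue), "-perc_identity", str(params.min_identity)]
        else:
            cmd += ["-evalue", "1e4"]
        out = _run(cmd)

    hits = _parse_tabular(out)
    if apply_score_filters:
        hits = filter_hits(hits, params)
    # deterministic order + per-query cap by descending score
    hits.sort(key=lambda h: (h.query_id, -h.score, h.subject_id, h.s_start, h.q_start, h.orientation))
    capped: list[AlignmentHit] = []
    per_query: dict[str, int] = {}
    for h in hits:
        c = per_query.get(h.query_id, 0)
        if c < params.max_alignments:
            capped.append(h)
            per_query[h.query_id] = c + 1
    return capped


def _parse_tabular(text: str) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 11:
            raise EngineError(f"unparseable tabular line {lineno}: {line!r}")
        try:
            qid, sid = fields[0], fields[1]
            qs, qe, ss, se = (int(x) for x in fields[2:6])
            score, evalue, pident = float(fields[6]), float(fields[7]), float(fields[8])
            length, nident = int(fields[9]), int(fields[10])
        except ValueError as exc:
            raise EngineError(f"unparseable tabular line {lineno}: {line!r}") from exc
        if ss <= se:
            orientation, s_start, s_end = "forward", ss - 1, se
        else:
            orientation, s_start, s_end = "reverse", se - 1, ss
        hits.append(
            AlignmentHit(
                query_id=qid, subject_id=sid,
                q_start=qs - 1, q_end=qe,
                s_start=s_start, s_end=s_end,
                orientation=orientation,
                score=score, evalue=evalue, identity=pident,
                aln_length=length, n_ident=nident,
            )
        )
    return hits


def filter_hits(hits: Sequence[AlignmentHit], params: AlignmentParams) -> list[AlignmentHit]:
    """Keep hits passing score, e-value and identity thresholds (idempotent)."""
    return [
        h
        for h in hits
        if h.score >= params.min_score
        and h.evalue <= params.max_evalue
        and h.identity >= params.min_identity
    ]


# ---------------------------------------------------------------------------
# Exact oracle aligner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleAlignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float
    n_ident: int
    aln_length: int


_ORACLE_GUARD = 10**6


def oracle_align(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -3,
    open_gap: int = 5,
    extend_gap: int = 2,
) -> OracleAlignment | None:
    """Optimal local alignment under BLAST-style affine gap costs.

    A gap of length k costs ``open_gap + k * extend_gap``.  Returns None when
    no alignment scores above zero.  Ties are broken deterministically:
    among optimal alignments, smallest ``q_start`` then smallest ``s_start``.
    Guarded to |query|x|subject| <= 1e6 cells — this is a verification
    oracle, not a production aligner.
    """
    nq, ns = len(query), len(subject)
    if nq * ns > _ORACLE_GUARD:
        raise ValueError("oracle_align guard exceeded: |query|*|subject| > 1e6")
    if nq == 0 or ns == 0:
        return None

    NEG = -(10**9)
    first_gap = open_gap + extend_gap
    # H: best local score ending at (i, j); E: ending with gap in subject
    # (consuming query); F: ending with gap in query (consuming subject)
    H = [[0] * (ns + 1) for _ in range(nq + 1)]
    E = [[NEG] * (ns + 1) for _ in range(nq + 1)]
    F = [[NEG] * (ns + 1) for _ in range(nq + 1)]
    best = 0
    for i in range(1, nq + 1):
        qi = query[i - 1]
        Hi, Him = H[i], H[i - 1]
        Ei, Eim = E[i], E[i - 1]
        Fi = F[i]
        for j in range(1, ns + 1):
            e = max(Him[j] - first_gap, Eim[j] - extend_gap)
            f = max(Hi[j - 1] - first_gap, Fi[j - 1] - extend_gap)
            sub = match if qi == subject[j - 1] else mismatch
            h = max(0, Him[j - 1] + sub, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best = h
    if best == 0:
        return None

    ends = [(i, j) for i in range(1, nq + 1) for j in range(1, ns + 1) if H[i][j] == best]
    candidates = []
    for i0, j0 in ends:
        tb = _traceback(query, subject, H, E, F, i0, j0, match, mismatch, first_gap, extend_gap)
        candidates.append(tb)
    candidates.sort(key=lambda t: (t.q_start, t.s_start, t.q_end, t.s_end))
    return candidates[0]


def _traceback(query, subject, H, E, F, i, j, match, mismatch, first_gap, extend_gap) -> OracleAlignment:
    q_end, s_end = i, j
    n_ident = 0
    cols = 0
    state = "H"
    while True:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            sub = match if query[i - 1] == subject[j - 1] else mismatch
            if i > 0 and j > 0 and h == H[i - 1][j - 1] + sub:
                if query[i - 1] == subject[j - 1]:
                    n_ident += 1
                cols += 1
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            elif h == F[i][j]:
                state = "F"
            else:  # pragma: no cover - recurrence guarantees one branch
                raise AssertionError("traceback desync")
        elif state == "E":
            cols += 1
            if E[i][j] == H[i - 1][j] - first_gap:
                i -= 1
                state = "H"
            else:
                i -= 1
                state = "E"
        else:  # F
            cols += 1
            if F[i][j] == H[i][j - 1] - first_gap:
                j -= 1
                state = "H"
            else:
                j -= 1
                state = "F"
    identity = 100.0 * n_ident / cols if cols else 0.0
    return OracleAlignment(
        score=H[q_end][s_end],
        q_start=i, q_end=q_end,
        s_start=j, s_end=s_end,
        identity=identity, n_ident=n_ident, aln_length=cols,
    )


def engine_available() -> bool:
    """True when the BLAST+ binaries are on PATH."""
    return shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None
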