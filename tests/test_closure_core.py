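"""Candidate geometry, selection and editing.

``brute_force_pairs`` re-derives the candidate set by applying every
constraint literally to every (left, right) hit pair; ``enumerate_candidates``
must agree with it on randomized instances.
"""

import itertools
import random

import pytest

from gapweld.alignment_engine import AlignmentHit
from gapweld.assembly_model import AssemblyError, FlankPair, Gap, SeqRecord, revcomp
from gapweld.closure_core import (
    ClosureLimits,
    FillCandidate,
    apply_edit,
    ClosureEdit,
    enumerate_candidates,
    make_edit,
    select_best,
)


def _hit(qid, sid, q, s, orientation="forward", score=100.0):
    return AlignmentHit(qid, sid, q[0], q[1], s[0], s[1], orientation,
                        score, 1e-30, 100.0, q[1] - q[0])


def _flanks(left, right, n_run=10, left_at=500, trim=0):
    gap = Gap("scaf", left_at, left_at + n_run, True)
    return FlankPair(gap, left, right,
                     (left_at - trim - len(left), left_at - trim),
                     (gap.end + trim, gap.end + trim + len(right)), trim)


def brute_force_pairs(left_hits, right_hits, flanks, subjects, limits):
    """Literal re-statement of every pairing constraint."""
    out = []
    for lh, rh in itertools.product(left_hits, right_hits):
        if lh.subject_id != rh.subject_id or lh.orientation != rh.orientation:
            continue
        subj = subjects[lh.subject_id]
        if lh.q_end - lh.q_start < limits.min_query_coverage * len(flanks.left_seq):
            continue
        if rh.q_end - rh.q_start < limits.min_query_coverage * len(flanks.right_seq):
            continue
        n = len(subj)
        if lh.orientation == "forward":
            lt, rt = (lh.s_start, lh.s_end), (rh.s_start, rh.s_end)
        else:
            lt = (n - lh.s_end, n - lh.s_start)
            rt = (n - rh.s_end, n - rh.s_start)
        if not (lt[0] <= rt[0] and lt[1] <= rt[1]):
            continue
        insert_len = rt[0] - lt[1]
        if not (-limits.max_remove <= insert_len <= limits.max_insert):
            continue
        if insert_len < 0 and not limits.allow_negative:
            continue
        if insert_len == 0 and not limits.allow_zero:
            continue
        removed_left = flanks.trim + len(flanks.left_seq) - lh.q_end
        removed_right = flanks.trim + rh.q_start
        if removed_left > limits.max_remove:
            continue
        if removed_right + max(-insert_len, 0) > limits.max_remove:
            continue
        if flanks.gap.start - removed_left < 0:
            continue
        oriented = subj if lh.orientation == "forward" else revcomp(subj)
        insert_seq = oriented[lt[1] : rt[0]] if insert_len > 0 else ""
        if insert_seq and insert_seq.count("N") / len(insert_seq) > limits.max_n_fraction:
            continue
        out.append((lh, rh, insert_len, removed_left, removed_right, insert_seq))
    return out


class TestEnumerateCandidates:
    def test_exact_overlap_construction(self, small_reference):
        ref = small_reference.seq
        left, fill, right = ref[0:50], ref[50:80], ref[80:130]
        subject = left + fill + right
        flanks = _flanks(left, right)
        lh = _hit("L", "s", (0, 50), (0, 50))
        rh = _hit("R", "s", (0, 50), (80, 130))
        cands = enumerate_candidates([lh], [rh], flanks, {"s": subject}, ClosureLimits())
        assert len(cands) == 1
        c = cands[0]
        assert (c.insert_len, c.removed_left, c.removed_right) == (30, 0, 0)
        assert c.insert_seq == fill
        assert c.combined_score == 200.0

    def test_reverse_strand_symmetry(self, small_reference):
        ref = small_reference.seq
        left, fill, right = ref[0:50], ref[50:80], ref[80:130]
        subject = revcomp(left + fill + right)
        flanks = _flanks(left, right)
        # minus-strand blast hits: forward-normalised subject intervals
        lh = _hit("L", "s", (0, 50), (80, 130), "reverse")
        rh = _hit("R", "s", (0, 50), (0, 50), "reverse")
        cands = enumerate_candidates([lh], [rh], flanks, {"s": subject}, ClosureLimits())
        assert len(cands) == 1
        assert cands[0].orientation == "reverse"
        assert cands[0].insert_seq == fill

    def test_negative_overlap_requires_option(self):
        left, right = "A" * 50, "C" * 50
        flanks = _flanks(left, right)
        lh = _hit("L", "s", (0, 50), (0, 50))
        rh = _hit("R", "s", (0, 50), (38, 88))  # overlaps left hit by 12
        subject = {"s": "G" * 100}
        assert enumerate_candidates([lh], [rh], flanks, subject, ClosureLimits()) == []
        cands = enumerate_candidates(
            [lh], [rh], flanks, subject, ClosureLimits(allow_negative=True)
        )
        assert len(cands) == 1
        assert cands[0].insert_len == -12
        assert cands[0].insert_seq == ""

    def test_matches_brute_force_on_random_instances(self):
        rnd = random.Random(424242)
        for case in range(60):
            subj_len = rnd.randint(60, 1000)
            flank_len = rnd.randint(20, 200)
            left = "A" * flank_len
            right = "C" * flank_len
            trim = rnd.choice([0, 0, 3])
            flanks = _flanks(left, right, n_run=rnd.randint(1, 30),
                             left_at=rnd.randint(300, 600), trim=trim)
            subjects = {f"s{i}": "G" * subj_len for i in range(2)}
            limits = ClosureLimits(
                max_insert=rnd.choice([50, 200, 500]),
                max_remove=rnd.choice([20, 100, 500]),
                allow_negative=rnd.random() < 0.5,
                allow_zero=rnd.random() < 0.8,
            )

            def rand_hits(qid, n):
                hits = []
                for _ in range(n):
                    qa = rnd.randint(0, flank_len - 10)
                    qb = rnd.randint(qa + 5, flank_len)
                    sa = rnd.randint(0, subj_len - 10)
                    sb = rnd.randint(sa + 5, subj_len)
                    hits.append(_hit(qid, f"s{rnd.randint(0, 1)}", (qa, qb), (sa, sb),
                                     rnd.choice(["forward", "reverse"]),
                                     score=float(rnd.randint(20, 200))))
                return hits

            lh, rh = rand_hits("L", 6), rand_hits("R", 6)
            got = enumerate_candidates(lh, rh, flanks, subjects, limits)
            expected = brute_force_pairs(lh, rh, flanks, subjects, limits)
            assert [
                (c.left_hit, c.right_hit, c.insert_len, c.removed_left,
                 c.removed_right, c.insert_seq)
                for c in got
            ] == expected, f"case {case}"


def _cand(score_l=50.0, score_r=50.0, insert_len=10, subject="s", s_start=0,
          removed=(0, 0), insert_seq=None):
    lh = _hit("L", subject, (0, 50), (s_start, s_start + 50), score=score_l)
    rh = _hit("R", subject, (0, 50), (s_start + 60, s_start + 110), score=score_r)
    return FillCandidate("scaf", subject, "forward", lh, rh, insert_len,
                         removed[0], removed[1],
                         insert_seq if insert_seq is not None else "T" * max(insert_len, 0),
                         score_l + score_r)


class TestSelectBest:
    def test_highest_combined_score_wins(self):
        a, b = _cand(40, 40), _cand(50, 45)
        assert select_best([a, b]) is b

    def test_empty_gives_none(self):
        assert select_best([]) is None

    def test_tie_breaks(self):
        # equal combined: greater min-side score wins
        a, b = _cand(60, 40), _cand(55, 45)
        assert select_best([a, b]) is b
        # then smaller |insert_len|
        a, b = _cand(insert_len=30), _cand(insert_len=10)
        assert select_best([a, b]) is b
        # then lexicographically smallest subject
        a, b = _cand(subject="sB"), _cand(subject="sA")
        assert select_best([a, b]) is b

    def test_order_independence(self):
        rnd = random.Random(7)
        cands = [_cand(float(rnd.randint(30, 60)), float(rnd.randint(30, 60)),
                       insert_len=rnd.randint(-5, 40), subject=f"s{rnd.randint(0,3)}",
                       s_start=rnd.randint(0, 50)) for _ in range(12)]
        picks = set()
        for _ in range(10):
            rnd.shuffle(cands)
            c = select_best(cands)
            picks.add((c.subject_id, c.combined_score, c.insert_len, c.left_hit.s_start))
        assert len(picks) == 1


class TestMakeAndApplyEdit:
    def test_positive_gap_arithmetic(self):
        flanks = _flanks("A" * 50, "C" * 50, n_run=10, left_at=500)
        c = _cand(insert_len=30)
        edit = make_edit(c, flanks)
        assert (edit.cut_start, edit.cut_end) == (500, 510)
        assert edit.delta == 20

    def test_negative_gap_removes_overlap_on_right(self):
        flanks = _flanks("A" * 50, "C" * 50, n_run=5, left_at=500)
        c = _cand(insert_len=-12, insert_seq="")
        edit = make_edit(c, flanks)
        assert (edit.cut_start, edit.cut_end) == (500, 517)
        assert edit.replacement == ""
        assert edit.delta == -17

    def test_zero_gap_joins_flanks(self):
        flanks = _flanks("A" * 50, "C" * 50, n_run=8, left_at=500)
        c = _cand(insert_len=0, insert_seq="")
        edit = make_edit(c, flanks)
        assert edit.delta == -8

    def test_apply_edit_replaces_interval(self):
        rec = SeqRecord("s", "AAANNNCCC")
        out = apply_edit(rec, ClosureEdit("s", 3, 6, "GGG"))
        assert out.seq == "AAAGGGCCC"
        out = apply_edit(rec, ClosureEdit("s", 3, 6, ""))
        assert out.seq == "AAACCC"

    def test_apply_edit_bounds_checked(self):
        rec = SeqRecord("s", "AAANNNCCC")
        with pytest.raises(AssemblyError):
            apply_edit(rec, ClosureEdit("s", 3, 20, ""))
        with pytest.raises(AssemblyError):
            apply_edit(rec, ClosureEdit("other", 3, 6, ""))
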