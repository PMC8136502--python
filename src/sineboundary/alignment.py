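"""Pairwise alignment primitives shared by the repeat classifier and the
insertion scanner.

Two scoring schemes are used throughout the package:

* ``CLASSIFY_SCORING`` -- match +1, mismatch -1, gap open -2, gap extend -1.
  Used for local alignment of sequences against repeat consensuses.
* ``MIN_GAP_SCORING`` -- match +1, mismatch -1, gap open 0, gap extend -1.
  The minimum-gap-penalty scheme used for strain-vs-strain comparison, under
  which a long insertion aligns as a single contiguous gap (its cost grows
  only linearly with length).

A gap of length L costs ``gap_open + L * gap_extend`` (both values are
penalties expressed as negative scores).

Alignments are represented as compact op-run lists (CIGAR-like): ``'M'`` for
aligned columns (match or mismatch), ``'D'`` for bases present only in the
query, ``'I'`` for bases present only in the subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class DPBudgetError(ValueError):
    """Raised when a full dynamic-programming alignment would exceed the
    configured cell budget; callers should fall back to seeded/banded
    alignment (see :func:`sineboundary.polymorphism.align_genomes`)."""


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0

    #: Small extra open penalty so that among equal-scoring alignments the
    #: one with the fewest gap runs is chosen (under a zero gap-open cost a
    #: long gap may otherwise be scattered across coincidental matches).
    #: Legitimate scores are integers under these schemes, so the epsilon
    #: never changes which alignments are optimal as long as the total
    #: (runs x epsilon) stays below 1; exact scores are recovered by
    #: rescoring / rounding.
    TIE_EPSILON = 1e-4

    def make_aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        # Biopython charges open_gap_score for the first gap base.
        aligner.open_gap_score = self.gap_open + self.gap_extend - self.TIE_EPSILON
        aligner.extend_gap_score = self.gap_extend
        return aligner

    def gap_cost(self, length: int) -> float:
        if length <= 0:
            return 0.0
        return -(self.gap_open + length * self.gap_extend)


CLASSIFY_SCORING = AlignScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
MIN_GAP_SCORING = AlignScoring(match=1, mismatch=-1, gap_open=0, gap_extend=-1)

#: Maximum number of DP cells for a direct global alignment.
DEFAULT_DP_BUDGET = 30_000_000


@dataclass
class PairwiseAlignment:
    """A global alignment of ``query`` and ``subject`` as op runs.

    Invariant: M+D op lengths sum to ``len(query)``, M+I to ``len(subject)``.
    """

    query: str
    subject: str
    ops: list[tuple[str, int]] = field(default_factory=list)
    score: float = 0.0

    def validate(self) -> None:
        q = sum(n for op, n in self.ops if op in "MD")
        s = sum(n for op, n in self.ops if op in "MI")
        if q != len(self.query) or s != len(self.subject):
            raise ValueError(
                f"op runs cover {q}/{s} bases but sequences are "
                f"{len(self.query)}/{len(self.subject)}"
            )

    def gapped(self) -> tuple[str, str]:
        """Render as two gapped strings (for display and tests)."""
        qi = si = 0
        qrow, srow = [], []
        for op, n in self.ops:
            if op == "M":
                qrow.append(self.query[qi : qi + n])
                srow.append(self.subject[si : si + n])
                qi += n
                si += n
            elif op == "D":
                qrow.append(self.query[qi : qi + n])
                srow.append("-" * n)
                qi += n
            else:  # I
                qrow.append("-" * n)
                srow.append(self.subject[si : si + n])
                si += n
        return "".join(qrow), "".join(srow)

    def rescore(self, scoring: AlignScoring) -> float:
        qi = si = 0
        total = 0.0
        for op, n in self.ops:
            if op == "M":
                for a, b in zip(self.query[qi : qi + n], self.subject[si : si + n]):
                    total += scoring.match if a == b else scoring.mismatch
                qi += n
                si += n
            else:
                total -= scoring.gap_cost(n)
                if op == "D":
                    qi += n
                else:
                    si += n
        return total


@dataclass
class LocalHitAlignment:
    """A local alignment with the aligned spans on both sequences."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    ops: list[tuple[str, int]]
    score: float

    def stats(self, query: str, subject: str) -> tuple[int, int, int]:
        """Return (aligned_columns, mismatches, gap_events) over the hit."""
        qi, si = self.q_start, self.s_start
        cols = mism = gaps = 0
        for op, n in self.ops:
            if op == "M":
                cols += n
                for a, b in zip(query[qi : qi + n], subject[si : si + n]):
                    if a != b:
                        mism += 1
                qi += n
                si += n
            else:
                gaps += 1
                if op == "D":
                    qi += n
                else:
                    si += n
        return cols, mism, gaps


def _blocks_to_ops(aligned, q_len: int, s_len: int, terminal: bool):
    """Convert Biopython ``alignment.aligned`` block pairs to op runs.

    With ``terminal=True`` leading/trailing unaligned stretches become
    terminal D/I ops (global rendering); otherwise they are dropped and the
    aligned span is returned alongside the ops.
    """
    tblocks, qblocks = aligned  # target == our query, query == our subject
    ops: list[tuple[str, int]] = []
    if len(tblocks) == 0:
        if terminal:
            if q_len:
                ops.append(("D", q_len))
            if s_len:
                ops.append(("I", s_len))
            return ops, 0, q_len, 0, s_len
        return ops, 0, 0, 0, 0
    t_prev = tblocks[0][0]
    s_prev = qblocks[0][0]
    q_start, s_start = int(t_prev), int(s_prev)
    if terminal:
        if q_start:
            ops.append(("D", q_start))
        if s_start:
            ops.append(("I", s_start))
    for (t0, t1), (s0, s1) in zip(tblocks, qblocks):
        dt, ds = int(t0) - int(t_prev), int(s0) - int(s_prev)
        if dt:
            ops.append(("D", dt))
        if ds:
            ops.append(("I", ds))
        ops.append(("M", int(t1) - int(t0)))
        t_prev, s_prev = t1, s1
    q_end, s_end = int(t_prev), int(s_prev)
    if terminal:
        if q_len - q_end:
            ops.append(("D", q_len - q_end))
        if s_len - s_end:
            ops.append(("I", s_len - s_end))
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged, q_start, q_end, s_start, s_end


def global_align(
    query: str,
    subject: str,
    scoring: AlignScoring = MIN_GAP_SCORING,
    dp_budget: int = DEFAULT_DP_BUDGET,
) -> PairwiseAlignment:
    """Optimal global alignment; raises :class:`DPBudgetError` when the DP
    matrix would exceed ``dp_budget`` cells."""
    if not query or not subject:
        ops = []
        if query:
            ops.append(("D", len(query)))
        if subject:
            ops.append(("I", len(subject)))
        score = -scoring.gap_cost(max(len(query), len(subject)))
        return PairwiseAlignment(query, subject, ops, score)
    if len(query) * len(subject) > dp_budget:
        raise DPBudgetError(
            f"{len(query)} x {len(subject)} exceeds DP budget {dp_budget}; "
            "use anchored alignment (align_genomes)"
        )
    aligner = scoring.make_aligner("global")
    aln = aligner.align(query, subject)[0]
    ops, *_ = _blocks_to_ops(aln.aligned, len(query), len(subject), terminal=True)
    result = PairwiseAlignment(query, subject, list(ops), 0.0)
    result.validate()
    result.score = result.rescore(scoring)  # exact score, without tie epsilon
    return result


def local_align_score(
    query: str, subject: str, scoring: AlignScoring = CLASSIFY_SCORING
) -> float:
    if not query or not subject:
        return 0.0
    aligner = scoring.make_aligner("local")
    return round(float(aligner.score(query, subject)), 1)


def local_align(
    query: str, subject: str, scoring: AlignScoring = CLASSIFY_SCORING
) -> LocalHitAlignment:
    if not query or not subject:
        return LocalHitAlignment(0, 0, 0, 0, [], 0.0)
    aligner = scoring.make_aligner("local")
    aln = aligner.align(query, subject)[0]
    ops, q0, q1, s0, s1 = _blocks_to_ops(
        aln.aligned, len(query), len(subject), terminal=False
    )
    return LocalHitAlignment(q0, q1, s0, s1, list(ops), round(float(aln.score), 1))
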