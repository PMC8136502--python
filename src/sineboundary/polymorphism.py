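"""Strain-vs-strain insertion-polymorphism scanning.

The comparison uses a minimum-gap-penalty alignment (gap open 0, gap extend
-1) so that a 120-300 bp insertion aligns as one contiguous internal gap.
Internal gaps with well-aligned flanks become candidates; a candidate whose
gap sequence is occupied >80% by a single repeat hit is called a
polymorphic insertion carried by the strain holding the extra bases.

Whole-genome pairs exceed any direct DP budget, so :func:`align_genomes`
anchors the alignment on unique shared k-mers (collinear chaining via
longest increasing subsequence) and runs the min-gap DP only between
anchors.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kmers import unique_kmer_positions
from .alignment import (
    MIN_GAP_SCORING,
    DPBudgetError,
    PairwiseAlignment,
    global_align,
)
from .repeat_toolkit import ConsensusLibrary, classify_sequence


def align_min_gap(
    query: str,
    subject: str,
    dp_budget: int = 30_000_000,
) -> PairwiseAlignment:
    """Optimal global alignment under (match +1, mismatch -1, gap open 0,
    gap extend -1). Raises :class:`DPBudgetError` above the cell budget --
    callers should then use :func:`align_genomes`."""
    return global_align(query, subject, MIN_GAP_SCORING, dp_budget=dp_budget)


def _lis_indices(values: np.ndarray) -> list[int]:
    """Indices of a longest strictly-increasing subsequence."""
    tails: list[int] = []  # values
    tails_idx: list[int] = []
    parent = np.full(len(values), -1, dtype=np.int64)
    vals = values.tolist()
    for i, v in enumerate(vals):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        out.append(i)
        i = parent[i]
    return out[::-1]


def align_genomes(
    query: str,
    subject: str,
    k: int = 21,
    segment_budget: int = 30_000_000,
) -> PairwiseAlignment:
    """Anchored global alignment of two near-identical genomes.

    k-mers unique within each sequence and shared between them become
    anchors; the longest collinear anchor chain is kept, overlapping
    anchors merged into exact-match runs, and inter-run segments aligned by
    the min-gap DP.
    """
    if not query or not subject:
        return align_min_gap(query, subject)
    cq, pq = unique_kmer_positions(query, k)
    cs, ps = unique_kmer_positions(subject, k)
    common, iq, is_ = np.intersect1d(cq, cs, assume_unique=True,
                                     return_indices=True)
    if common.size == 0:
        return align_min_gap(query, subject, dp_budget=segment_budget)
    a_pos = pq[iq]
    b_pos = ps[is_]
    order = np.argsort(a_pos, kind="stable")
    a_pos, b_pos = a_pos[order], b_pos[order]
    keep = _lis_indices(b_pos)
    a_pos, b_pos = a_pos[keep], b_pos[keep]

    # merge overlapping same-diagonal anchors into exact-match runs
    runs: list[list[int]] = []  # [a_start, b_start, length]
    for a, b in zip(a_pos.tolist(), b_pos.tolist()):
        if runs:
            ra, rb, rl = runs[-1]
            same_diag = (a - b == ra - rb)
            if same_diag and a <= ra + rl:  # overlapping/adjacent exact match
                runs[-1][2] = max(rl, a + k - ra)
                continue
            if a < ra + rl or b < rb + rl:  # conflicts with previous run: drop
                continue
        runs.append([a, b, k])

    ops: list[tuple[str, int]] = []
    score = 0.0

    def add_ops(new_ops: list[tuple[str, int]]) -> None:
        for op, n in new_ops:
            if n <= 0:
                continue
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))

    qi = si = 0
    for ra, rb, rl in runs:
        seg_q, seg_s = query[qi:ra], subject[si:rb]
        if seg_q or seg_s:
            sub = global_align(seg_q, seg_s, MIN_GAP_SCORING,
                               dp_budget=segment_budget)
            add_ops(sub.ops)
            score += sub.score
        add_ops([("M", rl)])
        score += rl
        qi, si = ra + rl, rb + rl
    seg_q, seg_s = query[qi:], subject[si:]
    if seg_q or seg_s:
        sub = global_align(seg_q, seg_s, MIN_GAP_SCORING,
                           dp_budget=segment_budget)
        add_ops(sub.ops)
        score += sub.score
    aln = PairwiseAlignment(query, subject, [(op, n) for op, n in ops], score)
    aln.validate()
    return aln


@dataclass
class GapCandidate:
    contig: str
    carrier: str  # strain holding the extra bases
    start: int  # leftmost-normalised gap start, carrier coordinates
    length: int
    other_pos: int  # breakpoint in the gap-free strain's coordinates
    gap_seq: str
    left_flank_len: int
    right_flank_len: int
    left_identity: float
    right_identity: float
    tsd_len: int = 0

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class InsertionCall:
    candidate: GapCandidate
    subfamily: str
    family: str
    divergence: float
    occupancy: float
    strand: str
    fragment: bool = False  # repeat hit does not reach the consensus ends

    @property
    def carrier(self) -> str:
        return self.candidate.carrier


def extract_internal_gaps(
    aln: PairwiseAlignment,
    min_len: int = 120,
    max_len: int = 300,
    min_flank: int = 50,
    min_flank_identity: float = 0.90,
    flank_window: int = 100,
    contig: str = "chrS",
    strain_names: tuple[str, str] = ("A", "B"),
) -> list[GapCandidate]:
    """Internal gaps of ``min_len``..``max_len`` with both flanks well
    aligned. Gap starts are normalised to the leftmost equivalent position
    (target-site duplications make the placement ambiguous); the
    equivalence range is reported as ``tsd_len``."""
    aln.validate()
    # expand to per-column arrays
    total = sum(n for _, n in aln.ops)
    colop = np.empty(total, dtype="<U1")
    pos = 0
    for op, n in aln.ops:
        colop[pos : pos + n] = op
        pos += n
    is_m = colop == "M"
    is_d = colop == "D"
    qpos = np.cumsum(colop != "I") - 1  # query coordinate at each column
    spos = np.cumsum(colop != "D") - 1
    q_arr = np.frombuffer(aln.query.encode(), dtype=np.uint8)
    s_arr = np.frombuffer(aln.subject.encode(), dtype=np.uint8)
    match = np.zeros(total, dtype=bool)
    match[is_m] = q_arr[qpos[is_m]] == s_arr[spos[is_m]]
    cum_m = np.concatenate([[0], np.cumsum(is_m)])
    cum_match = np.concatenate([[0], np.cumsum(match)])

    # gap runs
    out: list[GapCandidate] = []
    i = 0
    while i < total:
        if colop[i] == "M":
            i += 1
            continue
        j = i
        while j < total and colop[j] == colop[i]:
            j += 1
        length = j - i
        if i == 0 or j == total or not (min_len <= length <= max_len):
            i = j
            continue
        lw0 = max(0, i - flank_window)
        l_aligned = int(cum_m[i] - cum_m[lw0])
        l_match = int(cum_match[i] - cum_match[lw0])
        rw1 = min(total, j + flank_window)
        r_aligned = int(cum_m[rw1] - cum_m[j])
        r_match = int(cum_match[rw1] - cum_match[j])
        if l_aligned < min_flank or r_aligned < min_flank:
            i = j
            continue
        l_ident = l_match / l_aligned
        r_ident = r_match / r_aligned
        if l_ident < min_flank_identity or r_ident < min_flank_identity:
            i = j
            continue
        if colop[i] == "D":
            carrier, carrier_seq = strain_names[0], aln.query
            c0 = int(qpos[i])
            other_pos = int(spos[j]) if j < total else len(aln.subject)
        else:
            carrier, carrier_seq = strain_names[1], aln.subject
            c0 = int(spos[i])
            other_pos = int(qpos[j]) if j < total else len(aln.query)
        # leftmost normalisation within the target-site duplication
        shifts = 0
        while (c0 - shifts > 0
               and carrier_seq[c0 - shifts - 1] == carrier_seq[c0 - shifts + length - 1]):
            shifts += 1
        c0 -= shifts
        other_pos -= shifts
        tsd = 0
        while (c0 + tsd < len(carrier_seq) - length
               and carrier_seq[c0 + tsd] == carrier_seq[c0 + length + tsd]):
            tsd += 1
        out.append(GapCandidate(
            contig=contig, carrier=carrier, start=c0, length=length,
            other_pos=other_pos,
            gap_seq=carrier_seq[c0 : c0 + length],
            left_flank_len=l_aligned, right_flank_len=r_aligned,
            left_identity=l_ident, right_identity=r_ident,
            tsd_len=min(tsd, length),
        ))
        i = j
    return out


def _extend_homopolymer(
    seq: str, start: int, end: int, max_interrupt: int = 2
) -> tuple[int, int]:
    """Extend a repeat hit across flanking A/T homopolymer tails, the way
    repeat annotators absorb the retrotransposon poly-A tail. Up to
    ``max_interrupt`` non-tail bases may interrupt the run (e.g. a mutated
    base between the aligned body and the tail)."""
    j, last, miss = end, end, 0
    while j < len(seq):
        if seq[j] == "A":
            last = j + 1
        else:
            miss += 1
            if miss > max_interrupt:
                break
        j += 1
    end = last
    j, first, miss = start - 1, start, 0
    while j >= 0:
        if seq[j] == "T":
            first = j
        else:
            miss += 1
            if miss > max_interrupt:
                break
        j -= 1
    start = first
    return start, end


def call_insertions(
    cands: list[GapCandidate],
    lib: ConsensusLibrary,
    min_occupancy: float = 0.80,
    min_score: float = 20.0,
    extend_polya: bool = True,
) -> list[InsertionCall]:
    """Classify each gap sequence; keep candidates whose repeat hit occupies
    strictly more than ``min_occupancy`` of the gapped region."""
    calls: list[InsertionCall] = []
    for cand in cands:
        hit = classify_sequence(cand.gap_seq, lib, min_score=min_score)
        if hit is None:
            continue
        start, end = hit.q_start, hit.q_end
        if extend_polya:
            start, end = _extend_homopolymer(cand.gap_seq, start, end)
        occupancy = (end - start) / cand.length
        if occupancy <= min_occupancy:
            continue
        cons_len = len(lib[hit.subfamily].sequence)
        calls.append(InsertionCall(
            candidate=cand, subfamily=hit.subfamily,
            family=lib[hit.subfamily].family,
            divergence=hit.divergence, occupancy=occupancy,
            strand=hit.strand,
            fragment=(hit.q_end - hit.q_start) < 0.9 * cons_len,
        ))
    return calls


def scan_genome_pair(
    genome_a: str,
    genome_b: str,
    lib: ConsensusLibrary,
    min_len: int = 120,
    max_len: int = 300,
    min_occupancy: float = 0.80,
    min_flank: int = 50,
    min_flank_identity: float = 0.90,
    contig: str = "chrS",
    strain_names: tuple[str, str] = ("A", "B"),
) -> list[InsertionCall]:
    """End-to-end scan: anchored alignment, gap extraction, repeat calls."""
    aln = align_genomes(genome_a, genome_b)
    cands = extract_internal_gaps(
        aln, min_len=min_len, max_len=max_len, min_flank=min_flank,
        min_flank_identity=min_flank_identity, contig=contig,
        strain_names=strain_names,
    )
    return call_insertions(cands, lib, min_occupancy=min_occupancy)


def summarize_polymorphisms(calls: list[InsertionCall]) -> pd.DataFrame:
    """Carrier x subfamily cross-tabulation (all-zero table when empty)."""
    if not calls:
        return pd.DataFrame()
    df = pd.DataFrame({
        "carrier": [c.carrier for c in calls],
        "subfamily": [c.subfamily for c in calls],
        "length": [c.candidate.length for c in calls],
    })
    return pd.crosstab(df["carrier"], df["subfamily"])


def length_histogram(calls: list[InsertionCall], bin_size: int = 20) -> pd.Series:
    lengths = pd.Series([c.candidate.length for c in calls], dtype=int)
    if lengths.empty:
        return pd.Series(dtype=int)
    bins = (lengths // bin_size) * bin_size
    return bins.value_counts().sort_index()
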